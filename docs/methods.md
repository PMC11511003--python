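# Methods

## Model

The dehiscence-zone (DZ) gene regulatory network is modelled as a
synchronous Boolean network: nodes are grouped regulators (functionally
redundant paralogs share one node — SHP1/SHP2 → `SHP`, JAG/FIL/YAB3 →
`JFY`, AS1/AS2 → `AS`; ARF6/8 activity is folded into the `MIR172`
activation rule), each node is binary, and all nodes update
simultaneously by their Boolean rule. Stable cell types are fixed-point
attractors; basins of attraction partition the full 2^n state space.
Attractors are enumerated exactly by pointer doubling on the tabulated
successor map (every trajectory of a deterministic finite map ends in a
unique cycle), with a guard at 24 nodes; the enumeration is checked in
the test suite against a brute-force oracle that iterates the update
from every start state.

Assumptions inherited from the Boolean formalism: two expression levels
per node, no explicit time scales, deterministic synchronous updates,
and a single-cell (non-spatial) view of the medio-lateral axis. Hormone
signalling (GA/auxin/cytokinin) is not modelled; its net effect is
absorbed into the transcriptional rules.

## Rule transcription and its provenance

The original study's machine-readable rule listing is not publicly
deposited, so the shipped rule files are a reconstruction built from
(a) the signed interaction catalogue (`data/interactions.csv`, 51
records: 33 well-supported, 4 suggested, 14 protein–protein), (b) the
reported transient-assay results for NTT/FIL on the *FUL* and *SHP*
promoters, and (c) the published wild-type and mutant attractor
behaviour. The reconstruction was selected from a family of
catalogue-consistent variants using only the attractor constraints
(four wild-type fixed points matched one-to-one to V/LL/SL/R; the
mutant-panel phenotypes; failure of the pre-NTT network to separate LL
from SL) — never the robustness statistics. The exact transcription is
pinned by truth-table hash (`final` 682847d79b8182be, `initial`
dcba5d46c6138b63) in the tests, and every CLI run logs the hash of the
model it used.

Final (12-node) rules and the origin of each term:

| rule | provenance |
| --- | --- |
| `FUL = (FUL \| (JFY & AS)) & !NTT` | JFY→FUL, AS→FUL, FUL autoactivation catalogued; NTT represses the *FUL* promoter in transient assays |
| `SHP = JFY & (NTT \| !FUL)` | JFY→SHP catalogued; FUL⊣SHP catalogued; NTT+FIL jointly over-rule FUL repression (transient assays) |
| `IND = SHP & !FUL` | both catalogued; the quantitative ALC/SPT feedback on *IND* is deliberately left out (see Limitations) |
| `ALC = (IND \| SHP) & NTT & !FUL` | IND→ALC, SHP→ALC, FUL⊣ALC catalogued; the NTT requirement is hypothetical — it confines ALC to the SL, where NTT protein is localized, answering the absence of any known *ALC* repressor |
| `SPT = (IND \| SHP) & !FUL` | all catalogued |
| `RPL = BP & !JFY` | both catalogued |
| `BP = NTT & !AS & !JFY & !FUL & !SHP` | NTT→BP, AS⊣BP, JFY⊣BP catalogued; the FUL and SHP terms are hypothetical valve/margin exclusion of replum identity (SHP–BP and NTT–BP physical interactions are catalogued) |
| `JFY = !BP & !RPL` | both catalogued (replum factors repress lateral factors); NTT⊣JFY acts indirectly through NTT→BP⊣JFY, consistent with the catalogued indirect repression |
| `AS = !SHP & !BP & !RPL` | SHP⊣AS suggested (PWM); BP/RPL terms are hypothetical medial–lateral antagonism mirroring RPL⊣FIL |
| `AP2 = !MIR172 & !FUL` | both catalogued |
| `MIR172 = FUL & !AP2` | FUL(+ARF6/8)→miR172 catalogued with ARF6/8 = !AP2 folded in; AP2⊣miR172 catalogued |
| `NTT = NTT` | autoactivation catalogued |

The initial (11-node) model keeps only pre-NTT, asterisk-flagged
catalogue content: no NTT node, `FUL = JFY & AS` (no autoactivation),
`ALC = (IND | SHP) & !FUL` (no NTT gate), and `BP = BP & !AS & !JFY`
(self-maintenance, a suggested interaction, replacing the NTT input).
Its fixed points are V, R and a single *merged* valve-margin state with
ALC on — LL and SL are not separated, which is the documented failure
that motivated the extension. One catalogued interaction count is worth
noting: the catalogue flags exactly 22 records as initial-model
content; the SHP→ALC record's flag was restored editorially (its
sibling IND→ALC carries one, and the documented total is 22).

Cell-type profiles (`data/profiles.csv`) constrain only nodes whose
tissue activity is established: FUL on only in V; SHP/IND on in LL and
SL; ALC only in SL; RPL/BP only in R; NTT in SL and R; JFY in V and the
margin; AS in V. AP2, MIR172 and SPT are unconstrained. All four final
profiles are pairwise distinguishable on shared markers.

## Mutant simulation

Constitutive mutants clamp a node to 0 (LOF) or 1 (GOF); the clamped
node ignores its rule. Each fixed point of the clamped network is
classified by exact match on **all** marker nodes, including the
clamped one; anything else is "novel". Including clamped nodes is a
deliberate choice: a margin state without IND is biologically not a
lignification layer (IND drives lignification), and excluding clamped
nodes would label it LL and overstate the model's agreement with the
*ind* phenotype. Attractor counts quoted for mutants refer to fixed
points, matching the column layout of the published mutant panel.
"Converging" marker-identical fixed points (as in FUL GOF) are counted
as distinct attractors.

## Robustness

Two perturbation schemes, each applied to the focal network and to an
ensemble of 1000 topology-matched random networks (same nodes, same
per-node regulator sets, uniform random non-constant truth tables; a
degree-only-preserving mode is available behind a flag):

**Function perturbation.** A draw picks `max(1, round(0.1·n))` node
functions (one, for n = 11–12 — the minimum-one convention matters and
is applied consistently) and flips one uniformly chosen output bit of
each function's truth table. A draw "recovers" when every original
attractor is still an attractor of the perturbed network; an original
cycle survives exactly when none of its states addresses a flipped
truth-table entry, which gives a closed form for the recovery
probability. Both the closed form and a seeded Monte-Carlo estimate
(default 10,000 draws, binomial SE < 0.5 percentage points) are
reported, along with the per-attractor survival proportion (the two
readings of "recovered its original attractors").

**State (transition) perturbation.** A draw flips `max(1,
round(0.1·n))` bits of a state vector and measures the normalized
Hamming distance between the synchronous successors of the original
and perturbed states; with one flipped bit the mean over every (state,
bit) pair is computed exactly. This one-step divergence discriminates
canalized from random logic on identical wiring. The literal
transition-table edit (flip one successor bit in `round(0.1·2^n)`
table rows, distance = differing bits / n·2^n) is also implemented and
tested, but its expected distance is the same constant for every
network of a given size, so the divergence statistic is the one
compared against the ensemble.

Significance uses the add-one empirical estimator `p = (1 + #{random
networks scoring ≥ focal}) / (ensemble + 1)`, which cannot return 0.
All randomness flows from a single recorded seed; identical
configurations reproduce bit-identical summaries.

Because these statistics are functions of the exact truth tables, they
differ quantitatively from the published values under this
reconstruction: at seed 1 the focal recovery is 53.1% (published
57.64%), the ensemble median 30.7% (20.8%), the focal divergence
0.082 (0.071) and the ensemble mean 0.123 ± 0.008 (0.190 ± 0.005).
The qualitative conclusion — the DZ wiring is markedly more robust
than random logic on the same topology — holds, decisively so for the
divergence statistic (p ≈ 0.001) and directionally for function
recovery (focal above the ensemble median, p ≈ 0.11).

## Continuous conversion

Each node becomes a concentration `x_i ∈ [0,1]` with

    dx_i/dt = σ_h(ω_i(x)) − γ_i x_i

where `ω_i` is the fuzzy-logic reading of the Boolean rule (NOT → 1−x,
AND → min, OR → max; equal to `f_i` on corners) and `σ_h` is the
logistic of steepness `h` rescaled so σ_h(0)=0, σ_h(1)=1. Defaults:
h = 10 (saturating gain), γ = 1 (unit decay, so corner steady states
sit at the Boolean values), steady state declared when max |dx/dt|
stays below 1e−6 over the trailing 5% of a 100-time-unit horizon
(LSODA, rtol 1e−8); non-convergence is reported, not raised. Note that
with this normalization the corners 0 and 1 are steady states of a
1-node self-activation for *every* h > 0 (σ′ₕ(½) = h/(4·tanh(h/4)) ≥
1), so the system is bistable at all gains rather than undergoing a
pitchfork at a finite h as the unnormalized logistic would.

Cyclic attractors are resolved by integrating from the exact corner
embedding of each cycle state plus a ±0.01 jittered replicate; a cycle
counts as resolved only when every start converges and all shadows
(x_i > 0.5) agree — corner/jitter disagreement flags knife-edge
convergence onto a separatrix (the synchronous toggle's 00↔11 flip is
the canonical example). The shipped wild-type final network has no
cyclic attractors, so its resolution report is empty; the machinery is
exercised on mutant cycles (the *shp* LOF 2-cycle is reported
knife-edge) and on toy oscillators, and the wild-type report is
asserted stable across an order of magnitude in h (5–50).

## Constraint-based rule search

Edges carry MPU/MNU (mandatory positive/negative unambiguous: the
regulator must be essential and the function monotone in the stated
sign) or OPPA/ONPA (optional, possibly ambiguous: unconstrained)
classes. Per-node truth tables are enumerated exhaustively (guard: ≤ 4
regulators), pruned against required fixed points (a required state
fixing a node's regulators and its value pins one table entry), and
surviving assignments are verified with the independent attractor
enumerator; "meaningful network" is operationalized strictly as
satisfaction of the fixed-point constraints. On the initial DZ
topology with the four cell-type profiles required, the search returns
empty — provably so, because the LL and SL profiles address the same
ALC truth-table entry with opposite outputs — reproducing the negative
inference result that motivated adding NTT.

## Synthetic data

The package's null-data generator is the topology-matched random
ensemble: it emulates the wiring statistics of the DZ network while
destroying its logic, which is exactly the null the robustness
comparison needs. It does not emulate expression noise, measurement
error, or multicellular context, so passing robustness tests say
nothing about inference from real transcriptome data — they quantify
the dynamical distinctiveness of the curated wiring only. Toy fixtures
(identity, negation, toggle) have closed-form attractor structure and
anchor the oracle tests.

## Known limitations

- The rules are a reconstruction; robustness magnitudes (not the
  qualitative separations) are transcription-dependent, as flagged
  above and guarded by the truth-table hash.
- Leaving out the quantitative ALC/SPT feedback on *IND* (required to
  keep IND silent in the *shp* simulation) makes SPT a pure sink: the
  *spt* LOF simulation leaves the attractor set unchanged, and the
  reported ectopic *IND* expression in *spt*/*alc* knockouts is not
  reproduced.
- SHP GOF loses the replum fixed point through the hypothetical SHP
  exclusion of BP; the published panel shows the margin shift but was
  not legible enough to constrain the replum column.
- Asynchronous and probabilistic updating, multilevel nodes, and
  spatially coupled cells are out of scope.
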