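"""Perturbation semantics, the random ensemble, and summary statistics."""

import numpy as np
import pytest

from dzgrn import find_attractors, parse_rules
from dzgrn.attractors import build_transition_table
from dzgrn.robustness import (
    RobustnessConfig,
    attractor_recovery,
    exact_function_recovery,
    normalized_hamming,
    perturb_functions,
    perturb_transitions,
    random_network_like,
    run_robustness,
    state_perturbation_distance,
)


class TestPerturbFunctions:
    def test_minimum_one_function_altered(self, toggle):
        rng = np.random.default_rng(0)
        perturbed = perturb_functions(toggle, 0.01, rng)  # round(.02)=0 -> 1
        changed = [
            n for n in toggle.nodes
            if perturbed.node_tables()[n] != toggle.node_tables()[n]
        ]
        assert len(changed) == 1

    def test_single_bit_flip_per_altered_function(self, final_net):
        rng = np.random.default_rng(1)
        for _ in range(20):
            perturbed = perturb_functions(final_net, 0.1, rng)
            diffs = []
            for n in final_net.nodes:
                regs0, t0 = final_net.node_tables()[n]
                regs1, t1 = perturbed.node_tables()[n]
                assert regs0 == regs1  # wiring untouched
                diffs.append(sum(a != b for a, b in zip(t0, t1)))
            # round(0.1 * 12) = 1 function altered, by exactly one bit
            assert sorted(diffs)[-1] == 1 and sum(diffs) == 1

    def test_identity_rule_flips_become_one_input_variants(self, identity_net):
        # the only single-bit flips of the 1-input identity table are the
        # two constants' neighbours: [1,1] (tautology) and [0,0]
        seen = set()
        for seed in range(20):
            p = perturb_functions(identity_net, 1.0, np.random.default_rng(seed))
            seen.add(tuple(p.node_tables()["A"][1]))
        assert seen <= {(1, 1), (0, 0)}
        assert len(seen) == 2


class TestRecovery:
    def test_unperturbed_recovery_is_one(self, final_net, final_attractors):
        assert attractor_recovery(final_attractors, final_net) == 1.0

    def test_disjoint_recovery_is_zero(self, identity_net, negation_net):
        original = find_attractors(identity_net)
        assert attractor_recovery(original, negation_net) == 0.0

    def test_node_order_mismatch_rejected(self, toggle):
        other = parse_rules("targets, factors\nB, !A\nA, !B\n")
        with pytest.raises(ValueError):
            attractor_recovery(find_attractors(toggle), other)

    def test_exact_recovery_matches_enumeration_on_toy(self, toggle):
        """Closed form equals averaging attractor_recovery over every
        possible single-bit truth-table flip."""
        original = find_attractors(toggle)
        total_all = total_prop = 0.0
        draws = 0
        for name in toggle.nodes:
            regs = toggle.regulators(name)
            _, table = toggle.node_tables()[name]
            for k in range(len(table)):
                flipped = list(table)
                flipped[k] ^= 1
                from dzgrn.network import expr_from_table
                from dataclasses import replace

                rules = dict(toggle.rules)
                rules[name] = expr_from_table(regs, flipped)
                pert = replace(toggle, rules=rules)
                prop = attractor_recovery(original, pert)
                total_all += prop == 1.0
                total_prop += prop
                draws += 1
        exact_all, exact_prop = exact_function_recovery(toggle, original)
        assert exact_all == pytest.approx(total_all / draws)
        assert exact_prop == pytest.approx(total_prop / draws)


class TestTransitionTable:
    def test_zero_fraction_leaves_table_unchanged(self, toggle):
        table = build_transition_table(toggle)
        perturbed = perturb_transitions(table, 0.01, np.random.default_rng(0))
        assert normalized_hamming(table, perturbed) == 0.0

    def test_single_entry_single_bit(self, identity_net):
        table = build_transition_table(identity_net)
        perturbed = perturb_transitions(table, 0.5, np.random.default_rng(0))
        # one of the two successors has its single bit flipped: 1/(1*2)
        assert normalized_hamming(table, perturbed) == pytest.approx(0.5)

    def test_twelve_node_alteration_count(self, final_net):
        table = build_transition_table(final_net)
        perturbed = perturb_transitions(table, 0.1, np.random.default_rng(5))
        ndiff = int((table.successor != perturbed.successor).sum())
        assert ndiff == round(0.1 * 4096) == 410

    def test_hamming_identity_and_complement(self, toggle):
        table = build_transition_table(toggle)
        assert normalized_hamming(table, table) == 0.0
        from dzgrn.attractors import TransitionTable

        complement = TransitionTable(
            nodes=table.nodes, successor=table.successor ^ 0b11
        )
        assert normalized_hamming(table, complement) == 1.0

    def test_single_bit_in_two_node_table_is_one_eighth(self, toggle):
        table = build_transition_table(toggle)
        from dzgrn.attractors import TransitionTable

        succ = table.successor.copy()
        succ[0] ^= 1
        assert normalized_hamming(
            table, TransitionTable(nodes=table.nodes, successor=succ)
        ) == pytest.approx(1 / 8)


class TestRandomEnsemble:
    def test_regulator_sets_preserved(self, final_net):
        rand = random_network_like(final_net, np.random.default_rng(0))
        for n in final_net.nodes:
            assert set(rand.regulators(n)) == set(final_net.regulators(n))

    def test_no_constant_functions(self, final_net):
        rng = np.random.default_rng(2)
        for _ in range(5):
            rand = random_network_like(final_net, rng)
            for n in rand.nodes:
                _, table = rand.node_tables()[n]
                if len(table) > 1:
                    assert 0 < sum(table) < len(table)

    def test_different_seeds_differ(self, final_net):
        a = random_network_like(final_net, np.random.default_rng(1))
        b = random_network_like(final_net, np.random.default_rng(2))
        assert a.node_tables() != b.node_tables()

    def test_degree_only_mode_keeps_in_degrees(self, final_net):
        rand = random_network_like(
            final_net, np.random.default_rng(3), preserve="degrees"
        )
        for n in final_net.nodes:
            assert len(rand.regulators(n)) == len(final_net.regulators(n))


class TestStatePerturbation:
    def test_distance_zero_for_insensitive_network(self):
        net = parse_rules("targets, factors\nA, 1\nB, 0\n")
        assert state_perturbation_distance(net) == 0.0

    def test_monotone_in_fraction_on_toy(self):
        """One-step divergence grows (in expectation) with the number of
        flipped state bits."""
        net = parse_rules(
            "targets, factors\nA, B & C\nB, !C | A\nC, A & !B\nD, C | B\n"
        )
        d1 = state_perturbation_distance(net, fraction=0.25)  # 1 bit
        d2 = state_perturbation_distance(
            net, fraction=0.5, rng=np.random.default_rng(0), samples=40_000
        )  # 2 bits
        assert d2 > d1 > 0


class TestRunRobustness:
    @pytest.fixture(scope="class")
    @staticmethod
    def small_config():
        return RobustnessConfig(ensemble_size=30, replicates=200, seed=11)

    def test_seed_reproducibility(self, final_net, small_config):
        a = run_robustness(final_net, small_config, mode="functions")
        b = run_robustness(final_net, small_config, mode="functions")
        assert a.focal_recovery == b.focal_recovery
        assert np.array_equal(a.ensemble_recoveries, b.ensemble_recoveries)

    def test_functions_summary_ranges(self, final_net, small_config):
        s = run_robustness(final_net, small_config, mode="functions")
        assert 0 <= s.focal_recovery <= 1
        assert 0 <= s.focal_recovery_exact <= 1
        assert np.all((s.ensemble_recoveries >= 0) & (s.ensemble_recoveries <= 1))
        assert 0 < s.p_value <= 1

    def test_transitions_summary_and_separation(self, final_net, small_config):
        s = run_robustness(final_net, small_config, mode="transitions")
        assert 0 <= s.focal_hamming <= 1
        assert s.focal_hamming < s.ensemble_mean
        assert 0 < s.p_value <= 1

    def test_mc_estimate_consistent_with_exact(self, final_net):
        config = RobustnessConfig(ensemble_size=1, replicates=3000, seed=4)
        s = run_robustness(final_net, config, mode="functions")
        # 3000 draws: binomial SE ~ 0.009; allow 4 sigma
        assert abs(s.focal_recovery - s.focal_recovery_exact) < 0.04

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            RobustnessConfig(fraction=0.0)
        with pytest.raises(ValueError):
            RobustnessConfig(ensemble_size=0)
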