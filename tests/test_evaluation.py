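import itertools

import numpy as np
import pytest

from mscrecomb import (PosteriorSummary, ReplicateResult, SimulationDesign,
                       ci_coverage, compare_segment_trees,
                       clade_probabilities, make_sample_map,
                       recombination_summary, recovery_stats, rrmse,
                       simulate_locus)
from mscrecomb.evaluation import parameter_table


def make_result(rep, mean, lo, hi, truth, map_tree=None, clade_probs=None):
    summary = PosteriorSummary(means={"tau_R": mean},
                               hpd={"tau_R": (lo, hi)}, ess={},
                               map_tree=map_tree,
                               clade_probs=clade_probs or {})
    return ReplicateResult(replicate=rep, summary=summary,
                           truth_params={"tau_R": truth})


class TestRrmse:
    def test_constant_relative_error(self):
        truth = 0.004
        assert rrmse([1.1 * truth] * 7, truth) == pytest.approx(0.1)

    def test_perfect_estimates(self):
        assert rrmse([0.02, 0.02, 0.02], 0.02) == 0.0

    def test_hand_computed_case(self):
        assert rrmse([1.0, 3.0], 2.0) == pytest.approx(0.5)

    def test_nonpositive_truth_rejected(self):
        with pytest.raises(ValueError):
            rrmse([1.0], 0.0)

    def test_dominates_relative_bias(self):
        # rrmse^2 >= (bias/truth)^2 (variance decomposition)
        rng = np.random.default_rng(1)
        truth = 0.01
        est = truth * (1 + 0.2 * rng.standard_normal(50) + 0.1)
        rel_bias = (est.mean() - truth) / truth
        assert rrmse(est, truth) ** 2 >= rel_bias ** 2 - 1e-12


class TestCoverage:
    def test_always_inside(self):
        res = [make_result(i, 0.01, 0.005, 0.02, 0.01) for i in range(5)]
        assert ci_coverage(res, "tau_R") == 1.0

    def test_never_inside(self):
        res = [make_result(i, 0.01, 0.02, 0.03, 0.01) for i in range(5)]
        assert ci_coverage(res, "tau_R") == 0.0

    def test_two_of_three(self):
        res = [make_result(0, 0.01, 0.005, 0.02, 0.01),
               make_result(1, 0.01, 0.009, 0.011, 0.01),
               make_result(2, 0.01, 0.02, 0.03, 0.01)]
        assert ci_coverage(res, "tau_R") == pytest.approx(2 / 3)

    def test_unknown_parameter(self):
        res = [make_result(0, 0.01, 0.005, 0.02, 0.01)]
        with pytest.raises(KeyError):
            ci_coverage(res, "tau_Q")

    def test_parameter_table_fields(self):
        res = [make_result(i, 0.012, 0.008, 0.02, 0.01) for i in range(4)]
        tab = parameter_table(res)
        row = tab.loc["tau_R"]
        assert row["bias"] == pytest.approx(0.002)
        assert row["relative_bias"] == pytest.approx(0.2)
        assert row["coverage"] == 1.0
        assert row["rrmse"] == pytest.approx(0.2)
        assert row["ci_width"] == pytest.approx(0.012)


class TestRecovery:
    def test_all_true(self, three_species_tree):
        truth_newick = "((A,B),C);"
        cp = clade_probabilities([truth_newick])
        res = [make_result(i, 1, 0, 2, 1, map_tree=truth_newick,
                           clade_probs=cp) for i in range(10)]
        rep = recovery_stats(res, three_species_tree)
        assert rep.recovery_probability == 1.0
        assert all(v == 1.0 for v in rep.clade_recovery.values())

    def test_counting(self, three_species_tree):
        res = ([make_result(i, 1, 0, 2, 1, map_tree="((A,B),C);",
                            clade_probs={frozenset("AB"): 0.5})
                for i in range(24)]
               + [make_result(i, 1, 0, 2, 1, map_tree="((A,C),B);",
                              clade_probs={frozenset("AC"): 0.9})
                  for i in range(76)])
        rep = recovery_stats(res, three_species_tree)
        assert rep.recovery_probability == pytest.approx(0.24)
        assert rep.clade_recovery["(A,B)"] == pytest.approx(0.24)

    def test_clade_posterior_averaging(self, three_species_tree):
        res = [make_result(0, 1, 0, 2, 1, map_tree="((A,B),C);",
                           clade_probs={frozenset("AB"): 0.5}),
               make_result(1, 1, 0, 2, 1, map_tree="((A,B),C);",
                           clade_probs={frozenset("AB"): 0.7})]
        rep = recovery_stats(res, three_species_tree)
        assert rep.clade_mean_posterior["(A,B)"] == pytest.approx(0.6)


class TestRecombinationSummary:
    def test_counting(self):
        mean, zero = recombination_summary([0, 0, 3])
        assert mean == pytest.approx(1.0)
        assert zero == pytest.approx(2 / 3)

    def test_all_zero(self):
        assert recombination_summary([0, 0, 0, 0]) == (0.0, 1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            recombination_summary([])


class TestSegmentTreeComparison:
    def test_no_recombination(self, balanced_tree_b, rng):
        smap = make_sample_map(balanced_tree_b, 2)
        design = SimulationDesign(S=2, L=1, n=500, rho=0.0,
                                  theta_base=0.0025, R=1, seed=1)
        g = simulate_locus(balanced_tree_b, smap, design, rng)
        distinct, classes = compare_segment_trees(g)
        assert distinct == 1 and classes == []

    def test_brute_force_distinct_count(self, balanced_tree_b, rng):
        from mscrecomb.evaluation import _topology_key

        smap = make_sample_map(balanced_tree_b, 2)
        design = SimulationDesign(S=2, L=1, n=500, rho=5.0,
                                  theta_base=0.0025, R=1, seed=2)
        for seed in range(6):
            g = simulate_locus(balanced_tree_b, smap, design,
                               np.random.default_rng(seed))
            distinct, classes = compare_segment_trees(g)
            trees = [t for _, _, t in g.segment_trees()]
            # brute force: all-pairs comparison of rooted label clades
            seen = []
            for t in trees:
                key = _topology_key(t)
                if not any(key == other for other in seen):
                    seen.append(key)
            assert distinct == len(seen)
            assert len(classes) == len(trees) - 1
            # invisible events: identical neighbouring trees class "none"
            for i, cls in enumerate(classes):
                same_ages = trees[i].age == trees[i + 1].age
                same_topo = (_topology_key(trees[i])
                             == _topology_key(trees[i + 1]))
                if cls == "none":
                    assert same_topo
                if cls == "topology":
                    assert not same_topo
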