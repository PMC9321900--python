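import io
import math

import dendropy
import numpy as np
import pytest

from mscrecomb import (SimulationDesign, count_recombination_events,
                       locus_rng, make_sample_map, marginal_tree_at,
                       simulate_locus, write_segment_trees)
from conftest import simulate_counts


def _simulate(net, S, rho, theta, seed, n=500):
    smap = make_sample_map(net, S)
    design = SimulationDesign(S=S, L=1, n=n, rho=rho, theta_base=theta,
                              R=1, seed=seed)
    rng = np.random.default_rng(seed)
    return simulate_locus(net, smap, design, rng)


class TestBasics:
    def test_no_recombination_single_segment(self, balanced_tree_b):
        g = _simulate(balanced_tree_b, 2, 0.0, 0.0025, seed=1)
        assert g.num_segments == 1
        assert count_recombination_events(g) == 0
        t0 = marginal_tree_at(g, 0)
        assert marginal_tree_at(g, g.n - 1).age == t0.age
        assert len(t0.labels) == 10

    def test_event_count_is_event_list_length(self, balanced_tree_b):
        g = _simulate(balanced_tree_b, 2, 5.0, 0.0025, seed=2)
        assert count_recombination_events(g) == len(g.events)
        assert g.num_events >= g.num_segments - 1  # repeat links collapse

    def test_segment_lengths_sum_to_locus_length(self, balanced_tree_b):
        for seed in range(5):
            g = _simulate(balanced_tree_b, 2, 2.0, 0.0025, seed=seed)
            lengths = [r - l for l, r in g.segments()]
            assert sum(lengths) == g.n
            assert all(x > 0 for x in lengths)

    def test_site_out_of_range(self, balanced_tree_b):
        g = _simulate(balanced_tree_b, 2, 0.0, 0.0025, seed=3)
        with pytest.raises(IndexError):
            marginal_tree_at(g, g.n)

    def test_marginal_trees_are_dated_and_complete(self, msci_tree_b):
        g = _simulate(msci_tree_b, 2, 1.0, 0.0025, seed=4)
        for left, _right, tree in g.segment_trees():
            assert len(tree.labels) == 10
            for v, p in tree.parent.items():
                assert tree.age[p] >= tree.age[v]

    def test_reproducible_given_seed(self, balanced_tree_b):
        smap = make_sample_map(balanced_tree_b, 2)
        design = SimulationDesign(S=2, L=4, n=500, rho=0.5,
                                  theta_base=0.0025, R=2, seed=99)
        a = simulate_locus(balanced_tree_b, smap, design, locus_rng(design, 1, 2))
        b = simulate_locus(balanced_tree_b, smap, design, locus_rng(design, 1, 2))
        c = simulate_locus(balanced_tree_b, smap, design, locus_rng(design, 1, 3))
        assert a.events == b.events and a.records == b.records
        assert a.events != c.events or a.records != c.records


class TestSegmentTreeOutput:
    def test_single_segment_line(self, balanced_tree_b):
        g = _simulate(balanced_tree_b, 2, 0.0, 0.0025, seed=5)
        buf = io.StringIO()
        write_segment_trees(g, buf)
        lines = buf.getvalue().strip().split("\n")
        assert len(lines) == 1 and lines[0].startswith("[500]")

    def test_lengths_and_newick_roundtrip(self, balanced_tree_b):
        g = _simulate(balanced_tree_b, 2, 3.0, 0.0025, seed=6)
        buf = io.StringIO()
        write_segment_trees(g, buf)
        lines = buf.getvalue().strip().split("\n")
        assert len(lines) == g.num_segments
        total = 0
        for line, (left, right, tree) in zip(lines, g.segment_trees()):
            length = int(line[1:line.index("]")])
            total += length
            parsed = dendropy.Tree.get(data=line[line.index("]") + 1:],
                                       schema="newick")
            ages = {}
            parsed.calc_node_ages(ultrametricity_precision=1e-6)
            depth = {leaf.taxon.label: leaf.distance_from_root()
                     for leaf in parsed.leaf_node_iter()}
            # ultrametric to printed precision; root age preserved
            root_age = parsed.seed_node.age
            assert root_age == pytest.approx(tree.age[tree.root], rel=1e-6)
        assert total == g.n


class TestCoalescentDistributions:
    def test_pairwise_tmrca_mean_is_half_theta(self, single_population):
        theta = single_population.theta["A"]
        smap = make_sample_map(single_population, 2)
        design = SimulationDesign(S=2, L=1, n=500, rho=0.0,
                                  theta_base=theta, R=1, seed=7)
        rng = np.random.default_rng(7)
        ages = np.empty(20000)
        for i in range(ages.size):
            g = simulate_locus(single_population, smap, design, rng)
            tree = g.tree_at(0)
            ages[i] = tree.age[tree.root]
        se = ages.std() / math.sqrt(ages.size)
        assert abs(ages.mean() - theta / 2) < 4 * se

    def test_three_species_discordance_probability(self, three_species_tree):
        # P(each discordant rooted topology) = (1/3) exp(-2*dtau/theta)
        theta = 0.01
        dtau = three_species_tree.age["R"] - three_species_tree.age["U"]
        expect = math.exp(-2 * dtau / theta) / 3
        smap = make_sample_map(three_species_tree, 1)
        design = SimulationDesign(S=1, L=1, n=500, rho=0.0,
                                  theta_base=theta, R=1, seed=8)
        rng = np.random.default_rng(8)
        nrep = 20000
        counts = {"AB": 0, "AC": 0, "BC": 0}
        for _ in range(nrep):
            g = simulate_locus(three_species_tree, smap, design, rng)
            tree = g.tree_at(0)
            kids = tree.children[tree.root]
            inner = kids[0] if tree.children.get(kids[0]) else kids[1]
            pair = "".join(sorted(tree.labels[c][0]
                                  for c in tree.children[inner]))
            counts[pair] += 1
        for discordant in ("AC", "BC"):
            p_hat = counts[discordant] / nrep
            se = math.sqrt(expect * (1 - expect) / nrep)
            assert abs(p_hat - expect) < 4 * se

    def test_hybrid_routing_frequency_matches_phi(self, msci_tree_b):
        # a single C lineage takes the donor parent with probability 0.3
        smap = make_sample_map(msci_tree_b, 1, species=["C", "A"])
        design = SimulationDesign(S=1, L=1, n=500, rho=0.0,
                                  theta_base=0.0025, R=1, seed=9)
        rng = np.random.default_rng(9)
        nrep = 5000
        donor = 0
        for _ in range(nrep):
            g = simulate_locus(msci_tree_b, smap, design, rng)
            takes = [took for h, _nodes, took in g.routing if h == "Y"]
            assert len(takes) == 1
            donor += takes[0]
        se = math.sqrt(0.3 * 0.7 / nrep)
        assert abs(donor / nrep - 0.3) < 4 * se


class TestEventCountLaws:
    def test_mean_events_increase_with_rho_and_s(self, balanced_tree_b):
        m_low = simulate_counts(balanced_tree_b, 2, 0.05, 0.0025, 1500, 11).mean()
        m_mid = simulate_counts(balanced_tree_b, 2, 0.5, 0.0025, 800, 12).mean()
        m_s8 = simulate_counts(balanced_tree_b, 8, 0.5, 0.0025, 400, 13).mean()
        assert m_low < m_mid < m_s8

    def test_theta_invariance_of_event_counts(self):
        from scipy.stats import ks_2samp
        from mscrecomb import build_study_model

        c1 = simulate_counts(build_study_model("A01-B", 0.0025), 2, 0.5,
                             0.0025, 3000, 14)
        c2 = simulate_counts(build_study_model("A01-B", 0.01), 2, 0.5,
                             0.01, 3000, 15)
        assert ks_2samp(c1, c2).pvalue > 0.01
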