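"""Edge-level inference and NBS permutation machinery."""

from math import comb

import numpy as np
import pytest

from rrbscope.nbs import (EdgeStats, edge_ttests, nbs_test, node_degrees,
                          paired_differences, threshold_and_components)

from conftest import make_matrix, random_connectivity

CH4 = ("A", "B", "C", "D")


def _mats_from_edge_values(values, channels=CH4, edge=(0, 1), condition="HRIS",
                           base=None, rng=None):
    """One matrix per subject with a chosen value on one edge, noise elsewhere."""
    rng = rng or np.random.default_rng(0)
    mats = []
    for s, v in enumerate(values):
        m = rng.uniform(0.1, 0.2, size=(len(channels),) * 2)
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        m[edge[0], edge[1]] = m[edge[1], edge[0]] = v
        mats.append(make_matrix(m, subject_id=f"s{s}", condition=condition,
                                channels=channels))
    return mats


class TestEdgeTtests:
    def test_identical_groups_all_null(self):
        rng = np.random.default_rng(1)
        base = random_connectivity(rng, CH4)
        mats = [make_matrix(base.values, subject_id=f"s{i}", channels=CH4)
                for i in range(6)]
        stats = edge_ttests(mats, "two_sample", groups=["A"] * 3 + ["B"] * 3)
        assert np.all(stats.t == 0) and np.all(stats.p == 1)
        # truly zero-variance edges are flagged (some may carry 1-ulp residue)
        assert stats.flagged.sum() >= len(stats.edges) - 1

    def test_pooled_t_hand_value(self):
        # edge values A={1,2,3}, B={4,5,6} scaled into [0,1]: t is scale-free
        mats = _mats_from_edge_values(np.array([1, 2, 3, 4, 5, 6]) / 10.0)
        stats = edge_ttests(mats, "two_sample", groups=["g1"] * 3 + ["g2"] * 3)
        e = stats.edges.index(("A", "B"))
        assert stats.t[e] == pytest.approx(-3.674, abs=1e-3)
        assert stats.df == 4

    def test_paired_constant_difference_capped(self):
        # condition difference constant +0.1 on one edge: degenerate, p minimal
        rng = np.random.default_rng(2)
        mats = []
        for s in range(4):
            base = rng.uniform(0.1, 0.2, size=(4, 4))
            base = (base + base.T) / 2
            np.fill_diagonal(base, 0)
            hi = base.copy()
            hi[0, 1] = hi[1, 0] = base[0, 1] + 0.1
            mats.append(make_matrix(hi, subject_id=f"s{s}", condition="HRIS", channels=CH4))
            mats.append(make_matrix(base, subject_id=f"s{s}", condition="LRIS", channels=CH4))
        stats = edge_ttests(mats, "paired")
        e = stats.edges.index(("A", "B"))
        assert stats.t[e] > 1e5  # capped, not inf
        assert stats.p[e] < 1e-30  # minimal but still positive
        assert np.isfinite(stats.t).all()

    def test_unknown_design_raises(self):
        mats = _mats_from_edge_values([0.1, 0.2])
        with pytest.raises(ValueError):
            edge_ttests(mats, "anova")


class TestComponents:
    def _stats(self, sig_edges, channels=("A", "B", "C", "D", "E")):
        n = len(channels)
        edges = tuple((channels[i], channels[j])
                      for i, j in zip(*np.triu_indices(n, k=1)))
        p = np.ones(len(edges))
        t = np.zeros(len(edges))
        for e in sig_edges:
            i = edges.index(e)
            p[i] = 1e-4
            t[i] = 5.0
        return EdgeStats(channels=tuple(channels), edges=edges, t=t, p=p,
                         design="two_sample", direction=1, df=10)

    def test_two_components(self):
        comps = threshold_and_components(
            self._stats([("A", "B"), ("B", "C"), ("D", "E")]))
        assert sorted(len(c) for c in comps) == [1, 2]
        nodes = [set(np.ravel([list(e) for e in c])) for c in comps]
        assert {"A", "B", "C"} in nodes and {"D", "E"} in nodes

    def test_empty(self):
        assert threshold_and_components(self._stats([])) == []

    def test_complete_graph_component(self):
        all_edges = [("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"), ("C", "D")]
        comps = threshold_and_components(self._stats(all_edges))
        assert len(comps) == 1 and len(comps[0]) == 6

    def test_direction_filter(self):
        stats = self._stats([("A", "B")])
        stats.t[stats.edges.index(("A", "B"))] = -5.0  # wrong sign for direction +1
        assert threshold_and_components(stats) == []

    def test_alpha_monotonicity(self):
        rng = np.random.default_rng(0)
        n_edges = 10
        edges = tuple((f"n{i}", f"n{j}") for i, j in zip(*np.triu_indices(5, k=1)))
        stats = EdgeStats(channels=tuple(f"n{i}" for i in range(5)), edges=edges,
                          t=rng.normal(size=n_edges), p=rng.uniform(size=n_edges),
                          design="two_sample", direction=0, df=10)
        sizes = []
        for alpha in (0.8, 0.5, 0.2, 0.05):
            comps = threshold_and_components(stats, edge_alpha=alpha)
            sizes.append(sum(len(c) for c in comps))
        assert sizes == sorted(sizes, reverse=True)


class TestNodeDegrees:
    def test_simple(self):
        assert node_degrees([("A", "B"), ("A", "C")]) == {"A": 2, "B": 1, "C": 1}

    def test_handshake_lemma(self):
        rng = np.random.default_rng(5)
        edges = [(f"n{i}", f"n{j}") for i, j in
                 {tuple(sorted(rng.integers(0, 8, 2))) for _ in range(15)} if i != j]
        deg = node_degrees(edges)
        assert sum(deg.values()) == 2 * len(edges)

    def test_reported_degree_table_implies_16_edges(self):
        # published degree table of the dissonant subnetwork: 10 electrodes
        degrees = {"C3": 4, "P4": 4, "Pz": 4, "Cz": 4, "P3": 3,
                   "F7": 3, "T7": 3, "T8": 3, "P7": 3, "F8": 1}
        total = sum(degrees.values())
        assert total == 32
        assert total // 2 == 16  # handshake lemma: 16 edges in the component


class TestNBS:
    def test_no_suprathreshold_edges_all_p_one(self):
        rng = np.random.default_rng(0)
        mats = [random_connectivity(rng, CH4, subject_id=f"s{i}") for i in range(10)]
        res = nbs_test(mats, "two_sample", groups=["A"] * 5 + ["B"] * 5,
                       edge_alpha=1e-6, n_perm=200, seed=1)
        assert res.observed_max_size == 0
        assert res.components == []

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(3)
        mats = [random_connectivity(rng, CH4, subject_id=f"s{i}") for i in range(12)]
        labels = ["A"] * 6 + ["B"] * 6
        a = nbs_test(mats, "two_sample", groups=labels, n_perm=300, seed=7)
        b = nbs_test(mats, "two_sample", groups=labels, n_perm=300, seed=7)
        assert np.array_equal(a.null_max_sizes, b.null_max_sizes)
        assert np.array_equal(a.component_p, b.component_p)

    def test_exact_enumeration_matches_sampled(self):
        # 4+4 subjects: C(8,4)=70 assignments -> exact path; sampled null agrees
        channels = tuple(f"c{i}" for i in range(6))
        rng = np.random.default_rng(11)
        mats = [random_connectivity(rng, channels, subject_id=f"s{i}",
                                    bump_edges=[(0, 1), (0, 2)] if i < 4 else (),
                                    bump=0.25)
                for i in range(8)]
        labels = ["A"] * 4 + ["B"] * 4
        exact = nbs_test(mats, "two_sample", groups=labels, edge_alpha=0.05,
                         direction=1, n_perm=1000, seed=0)
        assert exact.exact and exact.n_perm == comb(8, 4)
        sampled = nbs_test(mats, "two_sample", groups=labels, edge_alpha=0.05,
                           direction=1, n_perm=64, seed=5)
        assert not sampled.exact
        for pe, ps in zip(exact.component_p, sampled.component_p):
            se = 2 * np.sqrt(pe * (1 - pe) / 64) + 1.0 / 64
            assert abs(pe - ps) <= max(2 * se, 0.05)

    def test_paired_sign_flip_null(self):
        # paired design with 5 subjects: 2^5=32 sign patterns -> exact
        channels = CH4
        rng = np.random.default_rng(8)
        mats = []
        for s in range(5):
            for cond in ("HRIS", "LRIS"):
                mats.append(random_connectivity(rng, channels, subject_id=f"s{s}",
                                                condition=cond))
        ordered = paired_differences(mats)
        res = nbs_test(ordered, "paired", edge_alpha=0.05, n_perm=100, seed=0)
        assert res.exact and res.n_perm == 32
        assert np.all(res.component_p >= 1.0 / 32)

    def test_permutation_p_floor(self):
        # planted huge effect: p bottoms out at 1/(n_perm+1), never 0
        channels = tuple(f"c{i}" for i in range(8))
        rng = np.random.default_rng(4)
        mats = [random_connectivity(rng, channels, subject_id=f"s{i}",
                                    bump_edges=[(0, 1), (1, 2), (2, 3)] if i < 10 else (),
                                    bump=0.5)
                for i in range(20)]
        res = nbs_test(mats, "two_sample", groups=["A"] * 10 + ["B"] * 10,
                       direction=1, n_perm=199, seed=0)
        assert len(res.significant) >= 1
        assert res.component_p.min() >= 1.0 / 200
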