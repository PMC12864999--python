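"""Cluster-based permutation testing: statistics, clustering, Monte Carlo."""

import itertools

import numpy as np
import pytest

from prestim.clusterperm import (NeighbourGraph, _max_cluster_sums,
                                 form_clusters, permutation_test,
                                 samplewise_stat)


class TestNeighbourGraph:
    def test_template_graph_invariants(self):
        from prestim.simulate import SCALP_CHANNELS

        g = NeighbourGraph.from_template(SCALP_CHANNELS)
        adj = g.adjacency
        assert (adj == adj.T).all()
        assert not adj.diagonal().any()
        assert g.degrees.min() >= 1

    def test_occipital_neighbours_are_local(self):
        from prestim.simulate import SCALP_CHANNELS

        g = NeighbourGraph.from_template(SCALP_CHANNELS)
        oz = SCALP_CHANNELS.index("Oz")
        names = {SCALP_CHANNELS[j] for j in np.flatnonzero(g.adjacency[oz])}
        assert names <= {"O1", "O2", "PO3", "POz", "PO4", "PO7", "PO8"}
        assert {"O1", "O2"} <= names

    def test_serialisation_round_trip(self):
        g = NeighbourGraph.grid(["a", "b", "c"])
        import json

        payload = json.loads(g.to_json())
        assert payload["neighbours"]["b"] == ["a", "c"]


class TestSamplewiseStat:
    def test_identical_paired_groups_t_zero(self):
        a = np.random.default_rng(0).normal(size=(5, 2, 3, 4))
        t, p = samplewise_stat([a, a.copy()], "paired_t")
        assert np.allclose(t, 0.0)
        assert np.allclose(p, 1.0)

    def test_single_voxel_shift_is_volume_max(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, size=(10, 3, 4, 5))
        b = rng.normal(0, 1, size=(10, 3, 4, 5))
        a[:, 1, 2, 3] += 50.0
        t, _ = samplewise_stat([a, b])
        assert np.unravel_index(np.abs(t).argmax(), t.shape) == (1, 2, 3)

    def test_f_identical_groups_near_zero(self):
        base = np.random.default_rng(2).normal(size=(6, 2, 2, 2))
        f, p = samplewise_stat([base, base.copy(), base.copy()], "F")
        assert np.allclose(f, 0.0, atol=1e-20)

    def test_paired_unequal_sizes_error(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="equal"):
            samplewise_stat([rng.normal(size=(4, 2)),
                             rng.normal(size=(5, 2))], "paired_t")

    def test_t_matches_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(3)
        a = rng.normal(0.5, 1, size=(8, 6))
        b = rng.normal(0.0, 1, size=(9, 6))
        t, p = samplewise_stat([a, b])
        ref = stats.ttest_ind(a, b, axis=0)
        assert np.allclose(t, ref.statistic)
        assert np.allclose(p, ref.pvalue)


class TestFormClusters:
    def _volumes(self, sig_voxels, shape=(3, 4, 5), value=5.0):
        stat = np.zeros(shape)
        p = np.ones(shape)
        for vox in sig_voxels:
            stat[vox] = value
            p[vox] = 0.001
        return stat, p

    def test_no_suprathreshold_empty(self):
        stat, p = self._volumes([])
        assert form_clusters(stat, p) == []

    def test_non_neighbouring_channels_two_clusters(self):
        graph = NeighbourGraph.grid(["a", "b", "c"])
        stat, p = self._volumes([(0, 1, 1), (2, 1, 1)])
        clusters = form_clusters(stat, p, neighbours=graph)
        assert len(clusters) == 2

    def test_neighbouring_channels_merge(self):
        graph = NeighbourGraph.grid(["a", "b", "c"])
        stat, p = self._volumes([(0, 1, 1), (1, 1, 1)])
        clusters = form_clusters(stat, p, neighbours=graph)
        assert len(clusters) == 1
        assert clusters[0].cluster_stat == pytest.approx(10.0)

    def test_block_on_one_channel_single_cluster(self):
        voxels = [(0, f, t) for f in (1, 2, 3) for t in (1, 2, 3)]
        stat, p = self._volumes(voxels)
        clusters = form_clusters(stat, p)
        assert len(clusters) == 1
        assert len(clusters[0].members) == 9
        assert clusters[0].cluster_stat == pytest.approx(45.0)

    def test_polarities_never_merge(self):
        stat = np.zeros((1, 3, 1))
        p = np.full((1, 3, 1), 0.001)
        stat[0, 0, 0], stat[0, 1, 0], stat[0, 2, 0] = 4.0, -4.0, 4.0
        clusters = form_clusters(stat, p)
        pol = sorted(c.polarity for c in clusters)
        assert pol == ["negative", "positive", "positive"]

    def test_p_exactly_alpha_excluded(self):
        stat = np.full((1, 1, 1), 3.0)
        p = np.full((1, 1, 1), 0.05)
        assert form_clusters(stat, p, alpha_sample=0.05) == []


class TestPermutationTest:
    def test_monte_carlo_matches_exhaustive_enumeration(self):
        """4-vs-4 toy: MC p at 4000 randomizations within 3 binomial SDs
        of the exact p over all 70 label splits."""
        rng = np.random.default_rng(42)
        a = rng.normal(1.0, 1.0, size=(4, 2, 3, 1))
        b = rng.normal(0.0, 1.0, size=(4, 2, 3, 1))
        graph = NeighbourGraph.grid(["c1", "c2"])
        res = permutation_test([a, b], n_randomizations=4000,
                               neighbours=graph,
                               rng=np.random.default_rng(0))
        pooled = np.concatenate([a, b])
        pairs = graph.pairs()
        null = []
        for comb in itertools.combinations(range(8), 4):
            rest = [i for i in range(8) if i not in comb]
            s, p = samplewise_stat([pooled[list(comb)], pooled[rest]])
            null.append(_max_cluster_sums(s, p, 0.05, pairs, True)[0])
        null = np.array(null)
        checked = 0
        for c in res["clusters"]:
            if c.polarity != "positive":
                continue
            exact = (null >= c.cluster_stat).mean()
            sd = np.sqrt(max(exact * (1 - exact), 1e-12) / 4000)
            assert abs(c.p_value - exact) <= max(3 * sd, 1.5 / 4001)
            checked += 1
        assert checked >= 1

    def test_bit_reproducible_with_seed(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, size=(5, 3, 4, 4))
        b = rng.normal(0, 1, size=(5, 3, 4, 4))
        g = NeighbourGraph.grid(["x", "y", "z"])
        r1 = permutation_test([a, b], n_randomizations=200, neighbours=g,
                              rng=np.random.default_rng(7))
        r2 = permutation_test([a, b], n_randomizations=200, neighbours=g,
                              rng=np.random.default_rng(7))
        assert np.array_equal(r1["null_max_positive"],
                              r2["null_max_positive"])
        assert [c.p_value for c in r1["clusters"]] == \
            [c.p_value for c in r2["clusters"]]

    def test_p_floor_and_range(self):
        rng = np.random.default_rng(6)
        a = rng.normal(5.0, 0.2, size=(6, 2, 2, 2))
        b = rng.normal(0.0, 0.2, size=(6, 2, 2, 2))
        g = NeighbourGraph.grid(["u", "v"])
        res = permutation_test([a, b], n_randomizations=400, neighbours=g,
                               rng=rng)
        for c in res["clusters"]:
            assert 1.0 / 401 <= c.p_value <= 1.0

    def test_effect_monotonicity_on_fixed_noise(self):
        """A larger injected shift never shrinks the max cluster sum."""
        rng = np.random.default_rng(8)
        base_a = rng.normal(0, 1, size=(6, 3, 5, 5))
        base_b = rng.normal(0, 1, size=(6, 3, 5, 5))
        g = NeighbourGraph.grid(["a", "b", "c"])
        maxima = []
        for shift in (0.5, 1.5, 4.0):
            a = base_a.copy()
            a[:, 1, 1:4, 1:4] += shift
            s, p = samplewise_stat([a, base_b])
            maxima.append(_max_cluster_sums(s, p, 0.05, g.pairs(), True)[0])
        assert maxima[0] <= maxima[1] <= maxima[2]

    def test_localises_injected_late_window_effect(self, posterior_config):
        """A shift injected at occipital channels / 5 Hz band / late bins
        yields a significant positive cluster containing those voxels."""
        rng = np.random.default_rng(9)
        n_sub, shape = 8, (9, 10, 10)  # posterior chans x 10 freqs x 10 bins
        a = rng.normal(0, 1, size=(n_sub, *shape))
        b = rng.normal(0, 1, size=(n_sub, *shape))
        occ = [6, 7, 8]  # O1, Oz, O2 in the posterior layout
        a[:, occ, 3:6, 4:] += 2.5
        g = NeighbourGraph.from_template(posterior_config.channel_labels[:9])
        res = permutation_test([a, b], n_randomizations=500, neighbours=g,
                               rng=np.random.default_rng(10))
        sig_pos = [c for c in res["clusters"]
                   if c.significant and c.polarity == "positive"]
        assert sig_pos
        members = set().union(*(c.member_set() for c in sig_pos))
        target = {(c, f, t) for c in occ for f in (3, 4, 5)
                  for t in range(4, 10)}
        assert len(members & target) / len(target) > 0.8

    def test_f_variant_single_sided(self):
        rng = np.random.default_rng(11)
        gs = [rng.normal(m, 1, size=(5, 2, 3, 3)) for m in (0, 0, 3)]
        g = NeighbourGraph.grid(["p", "q"])
        res = permutation_test(gs, kind="F", n_randomizations=300,
                               alpha_cluster=0.05, neighbours=g,
                               rng=np.random.default_rng(12))
        assert all(c.polarity == "positive" for c in res["clusters"])
        assert any(c.significant for c in res["clusters"])

    def test_low_randomization_count_warns_in_provenance(self):
        rng = np.random.default_rng(13)
        a = rng.normal(size=(3, 2, 2, 2))
        b = rng.normal(size=(3, 2, 2, 2))
        res = permutation_test([a, b], n_randomizations=50, rng=rng)
        assert "warning" in res["provenance"]
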