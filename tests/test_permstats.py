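"""Cluster permutation machinery: adjacency, clustering rules, null validity."""

import numpy as np
import pytest
from scipy import stats

from toteeg import (ChannelLayout, biosemi32_layout, build_adjacency,
                    cluster_permutation_test)

from oracles import exhaustive_two_condition_cluster_p


class TestAdjacency:
    def test_two_close_channels_share_one_edge(self):
        layout = ChannelLayout(names=["a", "b"], pos=[[0.0, 0.0], [0.1, 0.0]])
        adj = build_adjacency(layout, threshold=1.0)
        assert adj.matrix[0, 1] and adj.matrix[1, 0]
        assert adj.mean_degree == 1.0

    def test_symmetric_and_irreflexive(self):
        adj = build_adjacency(biosemi32_layout())
        assert np.array_equal(adj.matrix, adj.matrix.T)
        assert not adj.matrix.diagonal().any()

    def test_biosemi32_mean_degree_near_template(self):
        adj = build_adjacency(biosemi32_layout())
        assert 5.0 <= adj.mean_degree <= 7.0

    def test_collinear_layout_falls_back_to_knn(self):
        layout = ChannelLayout(names=list("abcd"),
                               pos=[[0, 0], [1, 0], [2, 0], [3, 0]])
        adj = build_adjacency(layout, k=1)
        assert adj.matrix.any()
        assert np.array_equal(adj.matrix, adj.matrix.T)

    def test_layout_csv_roundtrip(self, tmp_path):
        layout = biosemi32_layout()
        layout.to_csv(tmp_path / "layout.csv")
        back = ChannelLayout.from_csv(tmp_path / "layout.csv")
        assert back.names == layout.names
        assert np.allclose(back.pos, layout.pos)


def _chain_adjacency(n):
    m = np.zeros((n, n), dtype=bool)
    for i in range(n - 1):
        m[i, i + 1] = m[i + 1, i] = True
    return m


class TestClusterPermutationF:
    def test_identical_conditions_yield_no_clusters(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal((6, 1, 4, 8))
        data = np.repeat(base, 5, axis=1)  # all conditions identical
        res = cluster_permutation_test(data, "dependent_F",
                                       _chain_adjacency(4), n_perm=200, seed=0)
        assert res.clusters == []

    def test_monte_carlo_p_matches_exhaustive_enumeration(self):
        """3 participants, 2 conditions: MC p within the binomial 99% CI of
        the exact p from all 2^3 condition swaps."""
        rng = np.random.default_rng(7)
        data = rng.standard_normal((3, 2, 2, 2)) * 0.3
        data[:, 1, :, :] += 2.0  # a condition effect across all points
        adj = _chain_adjacency(2)
        n_perm = 2000
        res = cluster_permutation_test(
            data, "dependent_F", adj, n_perm=n_perm, min_channels=1, seed=5)
        assert res.clusters, "expected an observed cluster"
        p_mc = res.clusters[0]["p"]

        # neighbour map over flattened (channel, freq) points
        nf = 2
        neigh = {}
        for ch in range(2):
            for fi in range(2):
                i = ch * nf + fi
                neigh[i] = []
                if fi + 1 < nf:
                    neigh[i].append(ch * nf + fi + 1)
                if fi > 0:
                    neigh[i].append(ch * nf + fi - 1)
                for ch2 in range(2):
                    if adj[ch, ch2]:
                        neigh[i].append(ch2 * nf + fi)
        crit = stats.f.isf(0.05, 1, 2)
        p_exact = exhaustive_two_condition_cluster_p(
            data.reshape(3, 2, -1), crit, neigh)
        half_width = 2.576 * np.sqrt(p_exact * (1 - p_exact) / n_perm) + 1.0 / n_perm
        assert abs(p_mc - p_exact) <= half_width

    def test_injected_effect_recovered(self):
        """A block-linear effect at a known channel/frequency patch is
        recovered: aggregated over 20 seeds, the significant cluster covers
        >=90% of injected points with <=5% spurious members."""
        n_ch, n_f = 32, 40  # full cap, 1-40 Hz at 1 Hz
        adj = build_adjacency(biosemi32_layout(n_ch))
        # posterior channels (P7..P10 block of the cap) in the alpha band
        truth = {(c, f) for c in range(10, 20) for f in range(7, 13)}
        covered = total_truth = spurious = total_members = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            data = rng.standard_normal((8, 5, n_ch, n_f))
            for b in range(5):
                for c, f in truth:
                    data[:, b, c, f] += b * 1.5
            res = cluster_permutation_test(data, "dependent_F", adj,
                                           n_perm=200, seed=seed)
            assert res.significant, f"no significant cluster for seed {seed}"
            members = set(map(tuple, res.significant[0]["members"]))
            covered += len(members & truth)
            total_truth += len(truth)
            spurious += len(members - truth)
            total_members += len(members)
        assert covered / total_truth >= 0.90
        assert spurious / total_members <= 0.05

    def test_effect_scaling_is_monotone(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal((6, 5, 4, 8))
        effect = np.zeros((5, 4, 8))
        effect[:, 1:3, 2:5] = np.arange(5)[:, None, None]
        stats_out = []
        for scale in (0.5, 1.0, 2.0, 4.0):
            res = cluster_permutation_test(base + scale * effect[None],
                                           "dependent_F", _chain_adjacency(4),
                                           n_perm=100, seed=1)
            best = max((c["stat_sum"] for c in res.clusters), default=0.0)
            stats_out.append(best)
        assert all(b >= a for a, b in zip(stats_out, stats_out[1:]))

    def test_channel_reordering_invariance(self):
        rng = np.random.default_rng(9)
        data = rng.standard_normal((6, 3, 5, 6))
        data[:, 2, 1:4, 2:5] += 1.5
        adj = _chain_adjacency(5)
        res = cluster_permutation_test(data, "dependent_F", adj, n_perm=300, seed=4)
        perm = np.array([4, 2, 0, 1, 3])
        res_p = cluster_permutation_test(data[:, :, perm], "dependent_F",
                                         adj[perm][:, perm], n_perm=300, seed=4)
        assert [c["p"] for c in res.clusters] == [c["p"] for c in res_p.clusters]

    def test_min_channels_discards_single_channel_clusters(self):
        rng = np.random.default_rng(11)
        data = rng.standard_normal((8, 5, 4, 10)) * 0.2
        for b in range(5):  # strong effect confined to one channel
            data[:, b, 2, 3:8] += b * 2.0
        adj = _chain_adjacency(4)
        res1 = cluster_permutation_test(data, "dependent_F", adj, n_perm=100,
                                        min_channels=1, seed=2)
        res2 = cluster_permutation_test(data, "dependent_F", adj, n_perm=100,
                                        min_channels=2, seed=2)
        assert any(len({m[0] for m in c["members"]}) == 1 for c in res1.clusters)
        assert all(len({m[0] for m in c["members"]}) >= 2 for c in res2.clusters)

    def test_few_permutations_warn(self):
        data = np.random.default_rng(0).standard_normal((4, 2, 2, 3))
        with pytest.warns(UserWarning):
            cluster_permutation_test(data, "dependent_F", _chain_adjacency(2),
                                     n_perm=50, seed=0)


class TestClusterPermutationT:
    def test_strong_positive_effect_found(self):
        rng = np.random.default_rng(21)
        maps = rng.standard_normal((10, 4, 8)) * 0.3
        maps[:, 1:3, 2:6] += 1.5
        res = cluster_permutation_test(maps, "dependent_t", _chain_adjacency(4),
                                       n_perm=500, seed=3)
        assert res.significant
        assert res.significant[0]["sign"] == 1
        assert res.settings["cluster_alpha"] == 0.025

    def test_negative_effects_get_negative_sign(self):
        rng = np.random.default_rng(22)
        maps = rng.standard_normal((10, 4, 8)) * 0.3
        maps[:, 1:3, 2:6] -= 1.5
        res = cluster_permutation_test(maps, "dependent_t", _chain_adjacency(4),
                                       n_perm=500, seed=3)
        assert res.significant and res.significant[0]["sign"] == -1
        assert res.significant[0]["stat_sum"] < 0

    def test_null_maps_rarely_significant(self):
        rng = np.random.default_rng(23)
        hits = 0
        for _ in range(20):
            maps = rng.standard_normal((8, 3, 6))
            res = cluster_permutation_test(maps, "dependent_t",
                                           _chain_adjacency(3), n_perm=200,
                                           seed=int(rng.integers(2**31)))
            hits += bool(res.significant)
        assert hits <= 3

    def test_json_export_roundtrip(self, tmp_path):
        rng = np.random.default_rng(5)
        maps = rng.standard_normal((6, 3, 5)) + 1.0
        res = cluster_permutation_test(maps, "dependent_t", _chain_adjacency(3),
                                       n_perm=200, seed=1)
        import json
        payload = json.loads(res.to_json(tmp_path / "res.json"))
        assert payload["stat"] == "dependent_t"
        assert payload["n_perm"] == 200
        for c in payload["clusters"]:
            assert set(c) == {"members", "stat_sum", "sign", "p"}
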