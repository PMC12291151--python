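import itertools

import networkx as nx
import numpy as np
import pytest

from smlmnet.locio import LocalizationTable
from smlmnet.modules import (
    dispersion_filter,
    greedy_newman,
    modularity,
    module_count_sweep,
    network_views,
    newman_modules,
    two_module_summary,
)
from smlmnet.segment import Blob, labels_to_blobs
from smlmnet.simulate import simulate_corners


def exhaustive_best_q(n, edges):
    """Brute-force maximum modularity over all partitions of n nodes."""
    def partitions(collection):
        if len(collection) == 1:
            yield [collection]
            return
        first, rest = collection[0], collection[1:]
        for smaller in partitions(rest):
            for k, subset in enumerate(smaller):
                yield smaller[:k] + [[first] + subset] + smaller[k + 1:]
            yield [[first]] + smaller

    best = -1.0
    for part in partitions(list(range(n))):
        labels = np.empty(n, dtype=int)
        for c, block in enumerate(part):
            labels[block] = c
        best = max(best, modularity(n, edges, labels))
    return best


def _blob(coords):
    coords = np.asarray(coords, dtype=float)
    table = LocalizationTable(coords=coords)
    blob = Blob(id=0, members=np.arange(len(coords)),
                centroid=coords.mean(axis=0))
    return blob, table


class TestGreedyNewman:
    def test_two_triangles_q_half(self):
        edges = [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]
        labels, Q = greedy_newman(6, edges)
        assert Q == pytest.approx(0.5)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]
        # exhaustive search confirms 0.5 is the optimum
        assert exhaustive_best_q(6, edges) == pytest.approx(0.5)

    def test_complete_graph_single_module(self):
        edges = list(itertools.combinations(range(5), 2))
        labels, Q = greedy_newman(5, edges)
        assert len(set(labels)) == 1 and Q == pytest.approx(0.0)
        assert exhaustive_best_q(5, edges) == pytest.approx(0.0)

    def test_no_edges_all_singletons(self):
        labels, Q = greedy_newman(4, [])
        assert sorted(labels) == [0, 1, 2, 3] and Q == 0.0

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_on_small_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 8))
        edges = [e for e in itertools.combinations(range(n), 2)
                 if rng.uniform() < 0.45]
        labels, Q = greedy_newman(n, edges)
        best = exhaustive_best_q(n, edges)
        # greedy agglomeration is optimal or a documented lower bound
        assert Q <= best + 1e-9
        assert Q == pytest.approx(modularity(n, edges, labels))

    def test_agrees_with_networkx_greedy(self):
        # independent implementation of the same algorithm family
        rng = np.random.default_rng(3)
        n = 20
        edges = [e for e in itertools.combinations(range(n), 2)
                 if rng.uniform() < 0.2]
        labels, Q = greedy_newman(n, edges)
        G = nx.Graph()
        G.add_nodes_from(range(n))
        G.add_edges_from(edges)
        comms = nx.community.greedy_modularity_communities(G)
        q_nx = nx.community.modularity(G, comms)
        assert Q == pytest.approx(q_nx, abs=0.05)

    def test_node_order_invariance(self):
        edges = [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (2, 3)]
        labels, Q = greedy_newman(6, edges)
        perm = [5, 4, 3, 2, 1, 0]
        permuted = [(min(perm[i], perm[j]), max(perm[i], perm[j]))
                    for i, j in edges]
        labels2, Q2 = greedy_newman(6, permuted)
        assert Q == pytest.approx(Q2)
        # same partition after undoing the permutation
        undo = np.asarray([labels2[perm[i]] for i in range(6)])
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(labels, undo) == 1.0


class TestNewmanModules:
    def test_two_well_separated_point_clusters(self, rng):
        a = rng.normal([0, 0], 1.0, size=(10, 2))
        b = rng.normal([50, 0], 1.0, size=(10, 2))
        blob, table = _blob(np.vstack([a, b]))
        dec = newman_modules(blob, table, threshold_r=10.0)
        assert dec.n_modules == 2
        assert dec.centroid_distances[0] == pytest.approx(50.0, abs=2.0)

    def test_single_node_blob(self):
        blob, table = _blob([[1.0, 1.0]])
        dec = newman_modules(blob, table, threshold_r=5.0)
        assert dec.n_modules == 1 and dec.Q == 0.0

    def test_disconnected_components_separate_modules(self):
        blob, table = _blob([[0, 0], [1, 0], [100, 0], [101, 0.0]])
        dec = newman_modules(blob, table, threshold_r=5.0)
        assert dec.n_modules == 2

    def test_centroids_are_module_means(self, rng):
        pts = rng.uniform(0, 30, size=(15, 2))
        blob, table = _blob(pts)
        dec = newman_modules(blob, table, threshold_r=10.0)
        for c in range(dec.n_modules):
            np.testing.assert_allclose(
                dec.module_centroids[c],
                pts[dec.module_labels == c].mean(axis=0))


class TestModuleCountSweep:
    def test_tiny_threshold_all_singletons(self, rng):
        pts = rng.uniform(0, 100, size=(8, 2))
        blob, table = _blob(pts)
        sweep = module_count_sweep([blob], table, [0.01])
        assert sweep[0.01] == {8: 1}

    def test_huge_threshold_one_module(self, rng):
        pts = rng.uniform(0, 10, size=(8, 2))
        blob, table = _blob(pts)
        sweep = module_count_sweep([blob], table, [1000.0])
        assert sweep[1000.0] == {1: 1}

    def test_two_module_count_peaks_near_ten_nm(self):
        # corners with molecules 12 nm apart and blink sd 4: the count of
        # 2-module blobs over a 6-20 nm sweep should peak around 10 nm
        table, truth = simulate_corners(n_corners=150, spacing=12.0,
                                        blink_mean=6.0, loc_sd=4.0, seed=11)
        blobs = labels_to_blobs(table, truth["corner_id"].to_numpy())
        thresholds = np.arange(6.0, 21.0, 1.0)
        sweep = module_count_sweep(blobs, table, thresholds)
        two_counts = {r: hist.get(2, 0) for r, hist in sweep.items()}
        best = max(two_counts, key=two_counts.get)
        assert 8.0 <= best <= 13.0


class TestDispersionFilter:
    def test_constant_distances_flagged(self):
        pairs = [(n, 5.0) for n in range(5, 20) for _ in range(3)]
        res = dispersion_filter(pairs)
        np.testing.assert_allclose(res.index_of_dispersion, 0.0)
        assert res.inflection_n is None

    def test_cubic_inflection_recovered_at_eleven(self):
        # construct bin data whose index of dispersion follows a cubic
        # with analytic inflection at n = 11
        pairs = []
        for n in range(5, 18):
            target_iod = ((n - 11.0) ** 3 + 300.0) / 1000.0
            mu = 10.0
            delta = np.sqrt(target_iod * mu / 2.0)
            pairs += [(n, mu + delta), (n, mu - delta)]
        res = dispersion_filter(pairs)
        assert res.inflection_n == 11

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            dispersion_filter([(5, 1.0), (5, 2.0), (6, 1.0), (6, 2.0)])


class TestTwoModuleSummary:
    def test_planted_separation_recovered_in_noise_free_limit(self):
        coords, labels = [], []
        D = 40.0
        rng = np.random.default_rng(0)
        for c in range(20):
            base = np.array([c * 500.0, 0.0])
            for mol in range(2):
                pos = base + [mol * D, 0.0]
                coords.append(pos + rng.normal(0, 0.01, size=(6, 2)))
                labels += [c] * 6
        table = LocalizationTable(coords=np.vstack(coords))
        blobs = labels_to_blobs(table, np.asarray(labels))
        res = two_module_summary(blobs, table, threshold_r=10.0)
        assert res["mean_distance"] == pytest.approx(D, abs=0.1)
        assert res["n_blobs_used"] == 20

    def test_synthetic_corner_spacing_within_one_nm(self):
        table, truth = simulate_corners(n_corners=400, spacing=12.0,
                                        blink_mean=6.0, loc_sd=4.0, seed=29)
        blobs = labels_to_blobs(table, truth["corner_id"].to_numpy())
        res = two_module_summary(blobs, table, threshold_r=10.0, min_locs=11)
        assert res["mean_distance"] == pytest.approx(12.0, abs=1.0)

    def test_threshold_stability_of_recovered_distance(self):
        # over modularity thresholds 9-14 nm the recovered spacing varies
        # by less than 10%
        table, truth = simulate_corners(n_corners=250, spacing=12.0,
                                        blink_mean=6.0, loc_sd=4.0, seed=31)
        blobs = labels_to_blobs(table, truth["corner_id"].to_numpy())
        means = [
            two_module_summary(blobs, table, r, min_locs=11)["mean_distance"]
            for r in (9.0, 10.0, 11.0, 12.0, 13.0, 14.0)
        ]
        assert (max(means) - min(means)) / np.mean(means) < 0.10

    def test_no_qualifying_blobs_rejected(self):
        blob, table = _blob([[0, 0], [1, 0.0]])
        with pytest.raises(ValueError):
            two_module_summary([blob], table, threshold_r=5.0, min_locs=100)


class TestNetworkViews:
    def test_zero_threshold_no_edges(self, rng):
        blob, table = _blob(rng.uniform(0, 10, size=(6, 2)))
        views = network_views(blob, table, [0.0, 5.0])
        assert len(views[0.0]) == 0

    def test_edge_nesting_over_thresholds(self, rng):
        blob, table = _blob(rng.uniform(0, 50, size=(20, 2)))
        views = network_views(blob, table, [5.0, 15.0, 40.0, 100.0])
        prev = set()
        for r in (5.0, 15.0, 40.0, 100.0):
            current = set(map(tuple, views[r]))
            assert prev <= current
            prev = current

    def test_octagon_pair_classes_gain_edges_by_scale(self):
        # ideal octagon with tight corners: intra-corner pairs connect by
        # 10 nm, adjacent corners by 50 nm, opposing corners by 100 nm
        ang = np.arange(8) * np.pi / 4
        corners = 53.5 * np.column_stack([np.cos(ang), np.sin(ang)])
        pts = []
        corner_id = []
        for k, c in enumerate(corners):
            radial = np.array([np.cos(ang[k]), np.sin(ang[k])])
            tangent = np.array([-np.sin(ang[k]), np.cos(ang[k])])
            # corner spread <= 5 nm: two tangent points and one inward point
            pts += [c - 2.5 * tangent, c + 2.5 * tangent, c - 5.0 * radial]
            corner_id += [k, k, k]
        pts = np.asarray(pts)
        blob, table = _blob(pts)
        corner_id = np.asarray(corner_id)
        views = network_views(blob, table, [10.0, 50.0, 100.0])

        def classes(edges):
            intra = adj = opp = 0
            for i, j in edges:
                dk = abs(corner_id[i] - corner_id[j])
                dk = min(dk, 8 - dk)
                intra += dk == 0
                adj += dk == 1
                opp += dk == 4
            return intra, adj, opp

        intra10, adj10, opp10 = classes(views[10.0])
        intra50, adj50, opp50 = classes(views[50.0])
        intra100, adj100, opp100 = classes(views[100.0])
        assert intra10 > 0 and adj10 == 0 and opp10 == 0
        assert adj50 > 0 and opp50 == 0
        assert opp100 > 0
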