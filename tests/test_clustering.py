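"""Group graph construction, Leiden partitioning, reactor-entropy tuning."""

import itertools

import numpy as np
import pandas as pd
import pytest

from perturbsig import (
    GroupGraph,
    LogRatioMatrix,
    build_group_graph,
    cluster_logratio_profile,
    cluster_permutation_test,
    leiden_partition,
    reactor_entropy,
    tune_resolution,
)


def _pairwise_table(groups, nonsig_pairs, f=1.7):
    rows = []
    for a, b in itertools.combinations(groups, 2):
        nonsig = frozenset((a, b)) in {frozenset(p) for p in nonsig_pairs}
        rows.append((a, b, f, 0.5 if nonsig else 0.001, 0.5 if nonsig else 0.002))
    t = pd.DataFrame(rows, columns=["group_a", "group_b", "pseudo_F", "p_raw", "p_adjusted"])
    t["significant"] = t["p_adjusted"] <= 0.06
    return t


TEN = [f"g{i}" for i in range(10)]


class TestBuildGroupGraph:
    def test_all_significant_gives_isolated_nodes(self):
        g = build_group_graph(_pairwise_table(TEN, []), TEN)
        assert len(g.nodes) == 10 and len(g.edges) == 0

    def test_single_nonsignificant_pair(self):
        g = build_group_graph(_pairwise_table(TEN, [("g0", "g1")], f=1.7), TEN)
        assert g.edges == [("g0", "g1")] and g.weights == [1.7]

    def test_fully_nonsignificant_gives_45_edges(self):
        allpairs = list(itertools.combinations(TEN, 2))
        g = build_group_graph(_pairwise_table(TEN, allpairs), TEN)
        assert len(g.edges) == 45

    def test_missing_pair_rows_error(self):
        t = _pairwise_table(TEN, []).iloc[:-2]
        with pytest.raises(ValueError, match="missing group pairs"):
            build_group_graph(t, TEN)

    def test_edge_set_monotone_in_alpha(self):
        rng = np.random.default_rng(0)
        rows = []
        for a, b in itertools.combinations(TEN, 2):
            p = rng.uniform()
            rows.append((a, b, 1.0, p, p))
        t = pd.DataFrame(rows, columns=["group_a", "group_b", "pseudo_F", "p_raw", "p_adjusted"])
        lo = build_group_graph(t, TEN, alpha=0.06)
        hi = build_group_graph(t, TEN, alpha=0.4)
        assert set(hi.edges) <= set(lo.edges)

    def test_invert_weights_option(self):
        g = build_group_graph(
            _pairwise_table(TEN, [("g0", "g1")], f=2.0), TEN, invert_weights=True
        )
        assert g.weights == [0.5]


def _newman_modularity(nodes, edges, weights, membership, gamma=1.0):
    """Weighted configuration-model modularity computed from first principles."""
    w_total = sum(weights)
    strength = {v: 0.0 for v in nodes}
    for (a, b), w in zip(edges, weights):
        strength[a] += w
        strength[b] += w
    q = 0.0
    for (a, b), w in zip(edges, weights):
        if membership[a] == membership[b]:
            q += w / w_total
    for c in set(membership.values()):
        k_c = sum(strength[v] for v in nodes if membership[v] == c)
        q -= gamma * (k_c / (2 * w_total)) ** 2
    return q


def _all_partitions(items):
    if not items:
        yield {}
        return
    first, rest = items[0], items[1:]
    for part in _all_partitions(rest):
        n_used = len(set(part.values())) if part else 0
        for c in range(n_used + 1):
            yield {first: c, **part}


class TestLeiden:
    def _triangles(self):
        nodes = list("abcdef")
        edges = [("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("e", "f"), ("d", "f")]
        return GroupGraph(nodes, edges, [1.0] * 6, alpha=0.06)

    def test_two_triangles_split_and_attain_max_modularity(self):
        g = self._triangles()
        part = leiden_partition(g, resolution=1.0, seed=0)
        assert len(set(part.values())) == 2
        assert part["a"] == part["b"] == part["c"]
        assert part["d"] == part["e"] == part["f"]
        # enumeration oracle: no partition of the 6 nodes scores higher
        q_leiden = _newman_modularity(g.nodes, g.edges, g.weights, part)
        best = max(
            _newman_modularity(g.nodes, g.edges, g.weights, cand)
            for cand in _all_partitions(g.nodes)
        )
        assert q_leiden == pytest.approx(best, abs=1e-12)

    def test_edgeless_graph_gives_singletons(self):
        g = GroupGraph(TEN, [], [], alpha=0.06)
        part = leiden_partition(g, 1.0, seed=0)
        assert len(set(part.values())) == 10

    def test_deterministic_given_seed(self):
        g = self._triangles()
        assert leiden_partition(g, 1.0, seed=5) == leiden_partition(g, 1.0, seed=5)

    def test_disconnected_components_never_merge(self):
        g = self._triangles()
        part = leiden_partition(g, resolution=0.01, seed=0)
        assert part["a"] != part["d"]

    def test_resolution_must_be_positive(self):
        with pytest.raises(ValueError, match="resolution"):
            leiden_partition(self._triangles(), 0.0, seed=0)


class TestReactorEntropy:
    def test_point_mass_zero(self):
        part = {"g0": 0, "g1": 0, "g2": 1}
        assert reactor_entropy(part, {"g0": 5, "g1": 3, "g2": 0}) == 0.0

    def test_uniform_maximum(self):
        part = {f"g{i}": i for i in range(4)}
        h = reactor_entropy(part, {f"g{i}": 3 for i in range(4)})
        assert h == pytest.approx(np.log(4), abs=1e-12)

    def test_eight_two_split(self):
        part = {"a": 0, "b": 1}
        h = reactor_entropy(part, {"a": 8, "b": 2})
        assert h == pytest.approx(0.5004, abs=1e-4)

    def test_no_reactors_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            reactor_entropy({"a": 0}, {"a": 0})


class TestTuneResolution:
    def _planted(self):
        # reactor groups g0-g2 form a tight clique; g3-g5 a second clique
        nodes = [f"g{i}" for i in range(6)]
        edges = [("g0", "g1"), ("g1", "g2"), ("g0", "g2"),
                 ("g3", "g4"), ("g4", "g5"), ("g3", "g5")]
        graph = GroupGraph(nodes, edges, [2.0] * 6, alpha=0.06)
        reactors = {"g0": 5, "g1": 4, "g2": 6, "g3": 0, "g4": 1, "g5": 0}
        return graph, reactors

    def test_reactor_component_isolated(self):
        graph, reactors = self._planted()
        result = tune_resolution(graph, reactors, seed=0)
        clusters_of_reactor_groups = {result.partition[g] for g in ("g0", "g1", "g2")}
        assert len(clusters_of_reactor_groups) == 1
        assert result.reactor_counts[result.partition["g0"]] == 15

    def test_tie_breaks_to_largest_resolution(self):
        graph = GroupGraph(["a", "b"], [], [], alpha=0.06)
        result = tune_resolution(graph, {"a": 3, "b": 0}, [0.1, 1.0, 2.5], seed=0)
        assert result.resolution == 2.5  # entropy 0 everywhere: largest res wins

    def test_singleton_grid(self):
        graph, reactors = self._planted()
        result = tune_resolution(graph, reactors, [0.7], seed=0)
        assert result.resolution == 0.7

    def test_empty_grid_rejected(self):
        graph, reactors = self._planted()
        with pytest.raises(ValueError, match="grid"):
            tune_resolution(graph, reactors, [], seed=0)


class TestClusterPermutationTest:
    def test_perfect_concentration_is_significant(self, rng):
        groups = np.repeat([f"g{i}" for i in range(6)], 8)
        partition = {f"g{i}": (0 if i < 2 else 1) for i in range(6)}
        reactors = np.array([g in ("g0", "g1") for g in groups])
        p = cluster_permutation_test(partition, reactors, groups, n_perm=9_999, seed=0)
        assert p <= 0.01

    def test_single_cluster_degenerate(self, rng):
        groups = np.repeat(["a", "b"], 6)
        partition = {"a": 0, "b": 0}
        reactors = np.zeros(12, dtype=bool)
        reactors[:3] = True
        p = cluster_permutation_test(partition, reactors, groups, n_perm=99, seed=0)
        assert p == 1.0

    def test_add_one_lower_bound(self, rng):
        groups = np.repeat(["a", "b"], 5)
        partition = {"a": 0, "b": 1}
        reactors = np.array([True] * 5 + [False] * 5)
        p = cluster_permutation_test(partition, reactors, groups, n_perm=49, seed=2)
        assert p >= 1 / 50


class TestClusterProfile:
    def _lr(self, values):
        d = values.shape[1]
        return LogRatioMatrix(values, [(f"T{j}", "ref") for j in range(d)], "ALR", "ref")

    def test_identical_rows_zero_width_ci(self):
        vals = np.tile([1.5, -2.0], (4, 1))
        prof = cluster_logratio_profile(self._lr(vals), np.zeros(4, dtype=int))
        assert (prof["ci_high"] - prof["ci_low"]).abs().max() == 0.0

    def test_means_match_brute_force(self, rng):
        vals = rng.normal(size=(12, 3))
        clusters = np.repeat([0, 1], 6)
        prof = cluster_logratio_profile(self._lr(vals), clusters)
        for c in (0, 1):
            for j in range(3):
                row = prof[(prof.cluster == c) & (prof.feature == f"T{j}/ref")].iloc[0]
                assert row["mean"] == pytest.approx(vals[clusters == c, j].mean(), abs=1e-12)

    def test_negation_antisymmetry(self, rng):
        vals = rng.normal(size=(10, 2))
        clusters = np.repeat([0, 1], 5)
        a = cluster_logratio_profile(self._lr(vals), clusters)
        b = cluster_logratio_profile(self._lr(-vals), clusters)
        np.testing.assert_allclose(a["mean"], -b["mean"], atol=1e-12)
        np.testing.assert_allclose(a["ci_low"], -b["ci_high"].to_numpy(), atol=1e-12)

    def test_single_sample_cluster_flagged(self, rng):
        vals = rng.normal(size=(5, 2))
        clusters = np.array([0, 0, 0, 0, 1])
        prof = cluster_logratio_profile(self._lr(vals), clusters)
        solo = prof[prof.cluster == 1]
        assert solo["ci_undefined"].all() and solo["ci_low"].isna().all()
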