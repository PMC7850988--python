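"""Reactor-entropy-tuned Leiden clustering of strain-food groups.

Groups whose perturbations a pairwise PERMANOVA could *not* distinguish
(BH-adjusted p above alpha) are joined by an edge weighted by the pair's
pseudo-F; Leiden community detection then partitions the graph, with the
resolution parameter tuned to (1) minimize the Shannon entropy of the
anaphylaxis-reactor distribution across clusters and (2) among ties prefer
the largest resolution (maximizing cluster count).  Significance of reactor
concentration is assessed by permuting reactor labels across mice.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd

from .types import LogRatioMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GroupGraph",
    "GroupClusterResult",
    "build_group_graph",
    "leiden_partition",
    "reactor_entropy",
    "tune_resolution",
    "cluster_permutation_test",
    "cluster_logratio_profile",
]


@dataclass
class GroupGraph:
    """Similarity graph over strain-food groups.

    Edges join pairs whose BH-adjusted pairwise PERMANOVA p exceeded
    ``alpha`` (no detectable perturbation difference); weight is the pair's
    pseudo-F (or its inverse with ``invert_weights``).
    """

    nodes: list[str]
    edges: list[tuple[str, str]]
    weights: list[float]
    alpha: float

    def to_igraph(self) -> ig.Graph:
        g = ig.Graph()
        g.add_vertices(self.nodes)
        g.add_edges(self.edges)
        g.es["weight"] = list(self.weights)
        return g

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(a, b, w) for (a, b), w in zip(self.edges, self.weights)],
            columns=["group_a", "group_b", "weight"],
        )


@dataclass
class GroupClusterResult:
    partition: dict[str, int]
    resolution: float
    n_clusters: int
    reactor_entropy: float
    reactor_counts: dict[int, int]
    grid: pd.DataFrame  # resolution, n_clusters, entropy per grid point
    permutation_p: float | None = None

    def to_dict(self) -> dict:
        return {
            "partition": self.partition,
            "resolution": self.resolution,
            "n_clusters": self.n_clusters,
            "reactor_entropy": self.reactor_entropy,
            "reactor_counts": {str(k): v for k, v in self.reactor_counts.items()},
            "permutation_p": self.permutation_p,
        }


def build_group_graph(
    pairwise: pd.DataFrame,
    groups: list[str] | None = None,
    alpha: float = 0.06,
    invert_weights: bool = False,
) -> GroupGraph:
    """Edges between group pairs *not* separated at the BH-adjusted level alpha.

    ``pairwise`` is the table from :func:`perturbsig.stats.pairwise_permanova`
    and must cover every unordered pair of ``groups`` (default: all groups
    appearing in the table).  Isolated nodes are retained.
    """
    if groups is None:
        groups = sorted(set(pairwise["group_a"]) | set(pairwise["group_b"]))
    want = {frozenset(p) for p in itertools.combinations(groups, 2)}
    have = {frozenset((a, b)) for a, b in zip(pairwise["group_a"], pairwise["group_b"])}
    missing = want - have
    if missing:
        raise ValueError(f"pairwise table missing group pairs: {sorted(map(sorted, missing))[:5]}")
    edges, weights = [], []
    for _, row in pairwise.iterrows():
        if frozenset((row["group_a"], row["group_b"])) not in want:
            continue
        if np.isnan(row["p_adjusted"]) or row["p_adjusted"] <= alpha:
            continue
        w = float(row["pseudo_F"])
        if invert_weights:
            w = 1.0 / w
        if w <= 0:
            raise ValueError(f"nonpositive edge weight for pair {row['group_a']},{row['group_b']}")
        edges.append((str(row["group_a"]), str(row["group_b"])))
        weights.append(w)
    return GroupGraph([str(g) for g in groups], edges, weights, alpha)


def leiden_partition(
    graph: GroupGraph, resolution: float, seed: int = 0
) -> dict[str, int]:
    """Leiden communities under the configuration-modularity objective.

    Deterministic given seed; an edgeless graph yields singleton clusters.
    Communities are connected subgraphs, so disconnected components never
    share a cluster.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    g = graph.to_igraph()
    if g.ecount() == 0:
        return {v: i for i, v in enumerate(graph.nodes)}
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,  # iterate to convergence
    )
    return {v["name"]: m for v, m in zip(g.vs, part.membership)}


def reactor_entropy(
    partition: dict[str, int], reactor_counts_per_group: dict[str, int]
) -> float:
    """Shannon entropy of the reactor distribution across clusters.

    H = -sum_c q_c ln q_c with q_c the share of all reactor mice whose
    group landed in cluster c; 0 ln 0 = 0.  Zero when every reactor sits in
    one cluster, ln(k) when reactors split evenly over k clusters.
    """
    totals: dict[int, float] = {}
    for group, count in reactor_counts_per_group.items():
        if count < 0:
            raise ValueError("reactor counts must be nonnegative")
        c = partition[group]
        totals[c] = totals.get(c, 0.0) + count
    total = sum(totals.values())
    if total <= 0:
        raise ValueError("no reactors: entropy objective undefined")
    q = np.array([v / total for v in totals.values() if v > 0])
    return float(-(q * np.log(q)).sum())


def tune_resolution(
    graph: GroupGraph,
    reactor_counts_per_group: dict[str, int],
    resolution_grid=None,
    seed: int = 0,
) -> GroupClusterResult:
    """Scan the resolution grid; minimize reactor entropy, then maximize resolution.

    Default grid: 40 log-spaced values in [0.05, 5].  Among minimal-entropy
    grid points the largest resolution wins (more clusters).
    """
    if resolution_grid is None:
        resolution_grid = np.geomspace(0.05, 5.0, 40)
    resolution_grid = np.asarray(list(resolution_grid), dtype=float)
    if resolution_grid.size == 0 or (resolution_grid <= 0).any():
        raise ValueError("resolution grid must be nonempty and positive")
    rows = []
    parts = []
    for res in resolution_grid:
        part = leiden_partition(graph, float(res), seed)
        h = reactor_entropy(part, reactor_counts_per_group)
        rows.append((float(res), len(set(part.values())), h))
        parts.append(part)
    grid = pd.DataFrame(rows, columns=["resolution", "n_clusters", "entropy"])
    h_min = grid["entropy"].min()
    best = grid.index[(grid["entropy"] <= h_min + 1e-12)].max()  # largest resolution
    part = parts[best]
    counts: dict[int, int] = {}
    for group, cnt in reactor_counts_per_group.items():
        counts[part[group]] = counts.get(part[group], 0) + int(cnt)
    return GroupClusterResult(
        partition=part,
        resolution=float(grid.loc[best, "resolution"]),
        n_clusters=int(grid.loc[best, "n_clusters"]),
        reactor_entropy=float(grid.loc[best, "entropy"]),
        reactor_counts=counts,
        grid=grid,
    )


def cluster_permutation_test(
    partition: dict[str, int],
    reactor_labels,
    group_of_mouse,
    n_perm: int = 9_999,
    seed: int = 0,
) -> float:
    """Is reactor concentration in clusters better than random? (entropy tail)

    The observed statistic is the reactor entropy of the fixed partition;
    the null permutes per-mouse reactor labels (group sizes fixed) and
    recomputes entropy.  p = (#{null <= observed} + 1) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    reactor_labels = np.asarray(reactor_labels, dtype=bool)
    group_of_mouse = np.asarray(group_of_mouse)
    cluster_of_mouse = np.array([partition[g] for g in group_of_mouse])

    def entropy_of(labels: np.ndarray) -> float:
        total = labels.sum()
        q = np.array(
            [labels[cluster_of_mouse == c].sum() / total for c in set(cluster_of_mouse)]
        )
        q = q[q > 0]
        return float(-(q * np.log(q)).sum())

    observed = entropy_of(reactor_labels)
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        if entropy_of(rng.permutation(reactor_labels)) <= observed + 1e-12:
            b += 1
    return (b + 1) / (n_perm + 1)


def cluster_logratio_profile(
    signature: LogRatioMatrix, sample_clusters
) -> pd.DataFrame:
    """Per-cluster mean and normal 95% CI of each signature log-ratio.

    Positive means read as enrichment of the numerator taxon relative to
    the signature denominator within the cluster; negative as depletion.
    Single-sample clusters get NaN CIs flagged ``ci_undefined``.
    """
    clusters = np.asarray(sample_clusters)
    if clusters.shape[0] != signature.values.shape[0]:
        raise ValueError("one cluster label per sample required")
    rows = []
    for c in sorted(pd.unique(clusters).tolist()):
        block = signature.values[clusters == c]
        n = block.shape[0]
        means = block.mean(axis=0)
        if n > 1:
            se = block.std(axis=0, ddof=1) / np.sqrt(n)
            lo, hi = means - 1.96 * se, means + 1.96 * se
            undef = False
        else:
            lo = hi = np.full(block.shape[1], np.nan)
            undef = True
        for j, label in enumerate(signature.label_strings):
            rows.append((c, label, means[j], lo[j], hi[j], n, undef))
    return pd.DataFrame(
        rows, columns=["cluster", "feature", "mean", "ci_low", "ci_high", "n", "ci_undefined"]
    )
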