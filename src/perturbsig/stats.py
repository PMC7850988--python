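"""Permutation-based multivariate inference on distance matrices.

One-way PERMANOVA (pseudo-F from the Gower-centered distance
decomposition), the PERMDISP2 homogeneity-of-dispersion test, pairwise
PERMANOVA with Benjamini-Hochberg correction, and a per-feature
Kruskal-Wallis screen.  Empirical p-values use the add-one rule
p = (b + 1) / (m + 1) throughout; when the number of distinct label
arrangements is small the permutation null is enumerated exactly.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from skbio.stats.distance import DistanceMatrix
from statsmodels.stats.multitest import multipletests
from sympy.utilities.iterables import multiset_permutations

from .ordination import double_centered_eig
from .types import LogRatioMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PermanovaResult",
    "permanova",
    "permdisp",
    "pairwise_permanova",
    "kruskal_wallis_screen",
]

EXACT_ENUMERATION_LIMIT = 20_000


@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    df_between: int
    df_within: int
    sums_of_squares: tuple[float, float, float]  # (between, within, total)
    method: str = "sampled"

    def to_dict(self) -> dict:
        ss = self.sums_of_squares
        return {
            "pseudo_F": self.pseudo_F,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "df_between": self.df_between,
            "df_within": self.df_within,
            "ss_between": ss[0],
            "ss_within": ss[1],
            "ss_total": ss[2],
            "method": self.method,
        }


def _validate_groups(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    codes, uniques = pd.factorize(labels)
    counts = np.bincount(codes)
    if len(uniques) < 2:
        raise ValueError("PERMANOVA requires at least 2 groups")
    singles = [str(uniques[g]) for g in np.flatnonzero(counts < 2)]
    if singles:
        raise ValueError(f"groups with a single sample: {singles}")
    return codes, counts


def _permanova_f(d2: np.ndarray, codes: np.ndarray, counts: np.ndarray) -> tuple[float, float, float]:
    """(F, SS_between, SS_within) from squared distances and group codes."""
    n = d2.shape[0]
    a = counts.size
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(a):
        mask = codes == g
        ss_within += d2[np.ix_(mask, mask)].sum() / (2.0 * counts[g])
    ss_between = ss_total - ss_within
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    return f, ss_between, ss_within


def _n_distinct_arrangements(counts: np.ndarray) -> int:
    n = int(counts.sum())
    total = math.factorial(n)
    for c in counts:
        total //= math.factorial(int(c))
    return total


def permanova(
    dist: DistanceMatrix,
    labels,
    n_perm: int = 9_999,
    seed: int = 0,
    method: str = "auto",
) -> PermanovaResult:
    """One-way PERMANOVA: pseudo-F with a whole-label permutation p-value.

    ``method`` is ``auto`` (exact enumeration when the distinct label
    arrangements number <= 20,000, else Monte-Carlo sampling), ``exact``,
    or ``sampled``.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != dist.shape[0]:
        raise ValueError("one label per sample required")
    codes, counts = _validate_groups(labels)
    d2 = np.asarray(dist.data, dtype=float) ** 2
    n, a = codes.size, counts.size
    f_obs, ss_b, ss_w = _permanova_f(d2, codes, counts)
    ss_t = ss_b + ss_w

    n_exact = _n_distinct_arrangements(counts)
    use_exact = method == "exact" or (method == "auto" and n_exact <= EXACT_ENUMERATION_LIMIT)
    if use_exact:
        b = 0
        for arrangement in multiset_permutations(codes.tolist()):
            f_perm, _, _ = _permanova_f(d2, np.asarray(arrangement), counts)
            if f_perm >= f_obs - 1e-12:
                b += 1
        p = b / n_exact
        return PermanovaResult(
            float(f_obs), float(p), n_exact, a - 1, n - a, (ss_b, ss_w, ss_t), "exact"
        )

    rng = np.random.default_rng(seed)
    b = 0
    perm = codes.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        f_perm, _, _ = _permanova_f(d2, perm, counts)
        if f_perm >= f_obs - 1e-12:
            b += 1
    p = (b + 1) / (n_perm + 1)
    return PermanovaResult(
        float(f_obs), float(p), n_perm, a - 1, n - a, (ss_b, ss_w, ss_t), "sampled"
    )


def centroid_distances(dist: DistanceMatrix, labels) -> np.ndarray:
    """Distance of each sample to its group centroid in PCoA space.

    Axes with negative eigenvalue ('imaginary' coordinates, which arise for
    semi-metric inputs) contribute negatively, following Anderson's
    correction: z_i = sqrt(max(d+^2 - d-^2, 0)).
    """
    labels = np.asarray(labels)
    codes, _ = pd.factorize(labels)
    vals, vecs = double_centered_eig(dist)
    tol = 1e-9
    pos = vals > tol
    neg = vals < -tol
    c_pos = vecs[:, pos] * np.sqrt(vals[pos])
    c_neg = vecs[:, neg] * np.sqrt(-vals[neg])
    z = np.zeros(codes.size)
    for g in np.unique(codes):
        mask = codes == g
        d2_pos = ((c_pos[mask] - c_pos[mask].mean(axis=0)) ** 2).sum(axis=1)
        if c_neg.shape[1]:
            d2_neg = ((c_neg[mask] - c_neg[mask].mean(axis=0)) ** 2).sum(axis=1)
        else:
            d2_neg = 0.0
        z[mask] = np.sqrt(np.clip(d2_pos - d2_neg, 0.0, None))
    return z


def _anova_f(z: np.ndarray, codes: np.ndarray, counts: np.ndarray) -> float:
    n, a = z.size, counts.size
    grand = z.mean()
    ss_b = 0.0
    ss_w = 0.0
    for g in range(a):
        zg = z[codes == g]
        ss_b += counts[g] * (zg.mean() - grand) ** 2
        ss_w += ((zg - zg.mean()) ** 2).sum()
    if ss_w == 0:
        return 0.0 if ss_b == 0 else np.inf
    return (ss_b / (a - 1)) / (ss_w / (n - a))


def permdisp(
    dist: DistanceMatrix,
    labels,
    n_perm: int = 9_999,
    seed: int = 0,
) -> PermanovaResult:
    """PERMDISP2: permutation test for homogeneity of multivariate dispersion.

    Each sample's distance to its group centroid (in PCoA space, with the
    negative-eigenvalue correction) is the response of a one-way ANOVA;
    significance comes from permuting group labels over those distances.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != dist.shape[0]:
        raise ValueError("one label per sample required")
    codes, counts = _validate_groups(labels)
    n, a = codes.size, counts.size
    z = centroid_distances(dist, labels)
    f_obs = _anova_f(z, codes, counts)
    grand = z.mean()
    ss_b = sum(counts[g] * (z[codes == g].mean() - grand) ** 2 for g in range(a))
    ss_w = sum(((z[codes == g] - z[codes == g].mean()) ** 2).sum() for g in range(a))

    rng = np.random.default_rng(seed)
    b = 0
    perm = codes.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        if _anova_f(z, perm, counts) >= f_obs - 1e-12:
            b += 1
    p = (b + 1) / (n_perm + 1)
    return PermanovaResult(
        float(f_obs), float(p), n_perm, a - 1, n - a,
        (float(ss_b), float(ss_w), float(ss_b + ss_w)), "sampled",
    )


def pairwise_permanova(
    dist: DistanceMatrix,
    labels,
    n_perm: int = 9_999,
    seed: int = 0,
    alpha: float = 0.06,
) -> pd.DataFrame:
    """PERMANOVA on every group pair with BH correction across all pairs.

    Returns one row per unordered pair: group_a, group_b, pseudo_F, p_raw,
    p_adjusted, significant (p_adjusted <= alpha).  Pairs whose sub-test
    fails (e.g. a single-sample group) are recorded with NaN statistics.
    """
    labels = np.asarray(labels)
    ids = np.asarray(dist.ids)
    groups = sorted(pd.unique(labels).tolist())
    if len(groups) < 2:
        raise ValueError("pairwise PERMANOVA requires at least 2 groups")
    child_seeds = np.random.SeedSequence(seed).spawn(len(groups) * (len(groups) - 1) // 2)
    rows = []
    for k, (ga, gb) in enumerate(itertools.combinations(groups, 2)):
        mask = (labels == ga) | (labels == gb)
        sub = dist.filter(ids[mask].tolist())
        try:
            res = permanova(
                sub, labels[mask], n_perm=n_perm,
                seed=int(child_seeds[k].generate_state(1)[0] % (2**31)),
            )
            rows.append((ga, gb, res.pseudo_F, res.p_value))
        except ValueError as exc:
            logger.warning("pairwise PERMANOVA failed for (%s, %s): %s", ga, gb, exc)
            rows.append((ga, gb, np.nan, np.nan))
    table = pd.DataFrame(rows, columns=["group_a", "group_b", "pseudo_F", "p_raw"])
    ok = table["p_raw"].notna()
    adj = np.full(len(table), np.nan)
    if ok.any():
        adj[ok.to_numpy()] = multipletests(table.loc[ok, "p_raw"], method="fdr_bh")[1]
    table["p_adjusted"] = adj
    table["significant"] = table["p_adjusted"] <= alpha
    return table


def kruskal_wallis_screen(lr: LogRatioMatrix, clusters) -> pd.DataFrame:
    """Per-feature Kruskal-Wallis H across clusters, BH-adjusted.

    Constant features get H = 0, p = 1 and are flagged ``degenerate``.
    """
    clusters = np.asarray(clusters)
    if clusters.shape[0] != lr.values.shape[0]:
        raise ValueError("one cluster label per sample required")
    codes, uniques = pd.factorize(clusters)
    counts = np.bincount(codes)
    if len(uniques) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 clusters with >= 2 samples each")
    rows = []
    for j, label in enumerate(lr.label_strings):
        col = lr.values[:, j]
        samples = [col[codes == g] for g in range(len(uniques))]
        if np.allclose(col, col[0]):
            rows.append((label, 0.0, 1.0, True))
            continue
        h, p = sps.kruskal(*samples)
        rows.append((label, float(h), float(p), False))
    out = pd.DataFrame(rows, columns=["feature", "H", "p_raw", "degenerate"])
    out["p_adjusted"] = multipletests(out["p_raw"], method="fdr_bh")[1]
    return out[["feature", "H", "p_raw", "p_adjusted", "degenerate"]]
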