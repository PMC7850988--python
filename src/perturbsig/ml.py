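"""Random-forest log-ratio signature discovery.

Feature selection (Boruta for the binary strain task, recursive feature
elimination for the multiclass strain-food task) is re-run inside every
training fold of a repeated stratified cross-validation, so held-out AUROC
estimates are not biased by selection leakage.  Model significance comes
from an empirical permutation test over label shuffles; the final signature
is selected and fit on the full data set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest, rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold

from .types import LogRatioMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CvPlan",
    "SignatureModel",
    "make_cv_plan",
    "boruta_select",
    "rfe_select",
    "hand_till_auc",
    "evaluate_cv",
    "permutation_test_model",
    "fit_final_signature",
]

#: forest defaults: 500 trees, sqrt(d) features per split, unlimited depth
DEFAULT_RF_PARAMS = {"n_estimators": 500, "max_features": "sqrt"}


def _forest(rf_params: dict | None, seed: int) -> RandomForestClassifier:
    params = dict(DEFAULT_RF_PARAMS)
    if rf_params:
        params.update(rf_params)
    return RandomForestClassifier(random_state=seed, **params)


def _seed_stream(seed: int):
    rng = np.random.default_rng(seed)
    while True:
        yield int(rng.integers(0, 2**31 - 1))


# ---------------------------------------------------------------------------
# cross-validation plans


@dataclass
class CvPlan:
    """Assignment of samples to test folds for each of ``r`` repeats."""

    folds: list[tuple[int, int, np.ndarray]]  # (repeat, fold, test indices)
    k: int
    r: int
    stratify_on: np.ndarray
    seed: int


def make_cv_plan(labels, k: int, r: int, seed: int = 0) -> CvPlan:
    """Stratified k-fold plan repeated r times, deterministic given seed.

    If some class has fewer than ``k`` members, ``k`` is reduced to the
    minimum class size with a warning; a class with a single member is an
    error (it cannot be stratified).
    """
    labels = np.asarray(labels)
    counts = pd.Series(labels).value_counts()
    singletons = counts[counts < 2]
    if len(singletons):
        raise ValueError(f"classes with a single member: {list(singletons.index)}")
    min_count = int(counts.min())
    if k > min_count:
        logger.warning("reducing k from %d to smallest class size %d", k, min_count)
        k = min_count
    splitter = RepeatedStratifiedKFold(n_splits=k, n_repeats=r, random_state=seed)
    folds = []
    for i, (_, test_idx) in enumerate(splitter.split(np.zeros(len(labels)), labels)):
        folds.append((i // k, i % k, np.asarray(test_idx)))
    return CvPlan(folds, k, r, labels, seed)


# ---------------------------------------------------------------------------
# feature selectors (array core + LogRatioMatrix wrappers)


def _drop_constant(x: np.ndarray) -> np.ndarray:
    keep = np.flatnonzero(x.std(axis=0) > 0)
    if keep.size < x.shape[1]:
        logger.info("dropping %d constant feature(s) before selection", x.shape[1] - keep.size)
    return keep


def _boruta_indices(
    x: np.ndarray,
    y: np.ndarray,
    seed: int,
    rf_params: dict | None = None,
    max_iter: int = 100,
    alpha: float = 0.05,
) -> np.ndarray:
    """Boruta: binomial hit test of real-feature importance vs max shadow.

    Each iteration appends a column-shuffled shadow copy of every feature,
    fits a forest, and scores a 'hit' for real features whose importance
    exceeds the best shadow.  Features whose hit count is binomially
    significant (one-sided, level ``alpha``) are confirmed; significantly
    low counts are rejected; leftover tentative features are kept when
    their median importance beats the median max-shadow importance.
    """
    keep = _drop_constant(x)
    xk = x[:, keep]
    d = xk.shape[1]
    if d == 0:
        return np.array([], dtype=int)
    rng = np.random.default_rng(seed)
    seeds = _seed_stream(seed + 1)
    hits = np.zeros(d, dtype=int)
    real_hist = np.empty((max_iter, d))
    shadow_hist = np.empty(max_iter)
    for it in range(max_iter):
        shadow = rng.permuted(xk, axis=0)
        rf = _forest(rf_params, next(seeds))
        rf.fit(np.hstack([xk, shadow]), y)
        imp = rf.feature_importances_
        real, shad_max = imp[:d], imp[d:].max()
        hits += real > shad_max
        real_hist[it] = real
        shadow_hist[it] = shad_max
    confirmed = np.zeros(d, dtype=bool)
    tentative = np.zeros(d, dtype=bool)
    for j in range(d):
        p_hi = binomtest(int(hits[j]), max_iter, 0.5, alternative="greater").pvalue
        p_lo = binomtest(int(hits[j]), max_iter, 0.5, alternative="less").pvalue
        if p_hi < alpha:
            confirmed[j] = True
        elif p_lo >= alpha:
            tentative[j] = True
    resolved = tentative & (np.median(real_hist, axis=0) > np.median(shadow_hist))
    return keep[confirmed | resolved]


def _inner_cv_auroc(
    x: np.ndarray,
    y: np.ndarray,
    seed: int,
    rf_params: dict | None,
    inner_k: int = 3,
) -> tuple[float, float]:
    """(mean, standard error) of held-out Hand-Till AUROC over inner folds."""
    classes = np.unique(y)
    inner_k = min(inner_k, int(pd.Series(y).value_counts().min()))
    splitter = StratifiedKFold(n_splits=max(inner_k, 2), shuffle=True, random_state=seed)
    seeds = _seed_stream(seed + 17)
    scores = []
    for train, test in splitter.split(x, y):
        if len(np.unique(y[test])) < 2:
            continue
        rf = _forest(rf_params, next(seeds))
        rf.fit(x[train], y[train])
        proba = rf.predict_proba(x[test])
        scores.append(hand_till_auc(y[test], proba, rf.classes_))
    scores = np.asarray(scores)
    se = scores.std(ddof=1) / np.sqrt(len(scores)) if len(scores) > 1 else 0.0
    return float(scores.mean()), float(se)


def _rfe_indices(
    x: np.ndarray,
    y: np.ndarray,
    seed: int,
    rf_params: dict | None = None,
    drop_fraction: float = 0.2,
    inner_k: int = 3,
) -> np.ndarray:
    """RF-RFE: drop the lowest-importance 20% per step, one-SE subset choice.

    Tracks inner-CV AUROC at every subset size and returns the smallest
    subset whose AUROC is within one standard error of the best.
    """
    keep = _drop_constant(x)
    if keep.size < 3:
        logger.warning("fewer than 3 usable features; returning them unchanged")
        return keep
    seeds = _seed_stream(seed)
    remaining = keep.copy()
    path: list[tuple[np.ndarray, float, float]] = []
    while remaining.size >= 1:
        mean, se = _inner_cv_auroc(x[:, remaining], y, next(seeds), rf_params, inner_k)
        path.append((remaining.copy(), mean, se))
        if remaining.size == 1:
            break
        rf = _forest(rf_params, next(seeds))
        rf.fit(x[:, remaining], y)
        n_drop = max(1, int(round(drop_fraction * remaining.size)))
        order = np.argsort(rf.feature_importances_)
        remaining = np.sort(remaining[order[n_drop:]])
    best_idx = int(np.argmax([m for _, m, _ in path]))
    threshold = path[best_idx][1] - path[best_idx][2]
    eligible = [(subset, m) for subset, m, _ in path if m >= threshold - 1e-12]
    subset = min(eligible, key=lambda t: t[0].size)[0]
    return subset


def boruta_select(
    features: LogRatioMatrix,
    labels,
    rf_params: dict | None = None,
    seed: int = 0,
    max_iter: int = 100,
) -> list[str]:
    """Boruta all-relevant selection; returns selected ``num/den`` labels."""
    y = np.asarray(labels)
    if len(np.unique(y)) != 2:
        raise ValueError("Boruta selection here expects a binary outcome")
    if features.n_features < 2:
        raise ValueError("need at least 2 features")
    idx = _boruta_indices(features.values, y, seed, rf_params, max_iter)
    names = features.label_strings
    return [names[j] for j in idx]


def rfe_select(
    features: LogRatioMatrix,
    labels,
    rf_params: dict | None = None,
    seed: int = 0,
    drop_fraction: float = 0.2,
) -> list[str]:
    """Recursive feature elimination; returns selected ``num/den`` labels."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    idx = _rfe_indices(features.values, y, seed, rf_params, drop_fraction)
    names = features.label_strings
    return [names[j] for j in idx]


_SELECTORS = {"boruta": _boruta_indices, "rfe": _rfe_indices}


def _select(selector: str, x, y, seed, rf_params, selector_kwargs) -> np.ndarray:
    if selector == "none":
        return np.arange(x.shape[1])
    idx = _SELECTORS[selector](x, y, seed, rf_params, **(selector_kwargs or {}))
    if idx.size == 0:
        logger.warning("selector %r chose no features; falling back to all", selector)
        return np.arange(x.shape[1])
    return idx


# ---------------------------------------------------------------------------
# AUROC


def hand_till_auc(y_true, proba: np.ndarray, classes) -> float:
    """Multiclass AUROC of Hand & Till: mean pairwise AUC over class pairs.

    For classes i, j the pairwise term is (A(i|j) + A(j|i)) / 2, where
    A(i|j) ranks class-i against class-j samples by the class-i score
    (midrank tie handling).  Pairs with a class absent from ``y_true`` are
    skipped.  For two classes this is the ordinary rank-based AUC.
    """
    y_true = np.asarray(y_true)
    classes = np.asarray(classes)
    present = [c for c in classes if (y_true == c).any()]
    if len(present) < 2:
        raise ValueError("need at least 2 classes present in y_true")
    col = {c: k for k, c in enumerate(classes)}

    def a_given(ci, cj) -> float:
        # probability a class-ci sample outranks a class-cj sample on score ci
        scores = proba[:, col[ci]]
        mask = (y_true == ci) | (y_true == cj)
        ranks = rankdata(scores[mask])
        ni = int((y_true[mask] == ci).sum())
        nj = int((y_true[mask] == cj).sum())
        ri = ranks[y_true[mask] == ci].sum()
        return (ri - ni * (ni + 1) / 2.0) / (ni * nj)

    vals = []
    for a in range(len(present)):
        for b in range(a + 1, len(present)):
            ci, cj = present[a], present[b]
            vals.append(0.5 * (a_given(ci, cj) + a_given(cj, ci)))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# cross-validated evaluation and permutation test


@dataclass
class CvEvaluation:
    mean_auroc: float
    pooled_auroc: float
    fold_table: pd.DataFrame


def evaluate_cv(
    features: LogRatioMatrix | np.ndarray,
    labels,
    plan: CvPlan,
    selector: str = "none",
    rf_params: dict | None = None,
    seed: int = 0,
    selector_kwargs: dict | None = None,
) -> CvEvaluation:
    """Held-out AUROC with fold-internal feature selection.

    The selector runs on each training fold only; the forest is fit on the
    selected columns and scored on the held-out fold (binary: rank AUC,
    multiclass: Hand-Till).  Returns the mean over folds x repeats, the
    pooled AUROC over all held-out predictions, and a per-fold table.
    """
    x = features.values if isinstance(features, LogRatioMatrix) else np.asarray(features)
    y = np.asarray(labels)
    classes = np.unique(y)
    seeds = _seed_stream(seed)
    rows = []
    pooled_proba = np.zeros((len(y), len(classes)))
    pooled_hits = np.zeros(len(y), dtype=int)
    for repeat, fold, test_idx in plan.folds:
        train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
        sel_seed, fit_seed = next(seeds), next(seeds)
        if len(np.unique(y[test_idx])) < 2:
            logger.warning("repeat %d fold %d has a single class in test; skipped", repeat, fold)
            continue
        sel = _select(selector, x[train_idx], y[train_idx], sel_seed, rf_params, selector_kwargs)
        rf = _forest(rf_params, fit_seed)
        rf.fit(x[np.ix_(train_idx, sel)], y[train_idx])
        proba_small = rf.predict_proba(x[np.ix_(test_idx, sel)])
        proba = np.zeros((len(test_idx), len(classes)))
        for k, c in enumerate(rf.classes_):
            proba[:, np.flatnonzero(classes == c)[0]] = proba_small[:, k]
        auc = hand_till_auc(y[test_idx], proba, classes)
        rows.append((repeat, fold, len(test_idx), len(sel), auc))
        pooled_proba[test_idx] += proba
        pooled_hits[test_idx] += 1
    if not rows:
        raise ValueError("no evaluable folds (every test fold was single-class)")
    table = pd.DataFrame(rows, columns=["repeat", "fold", "n_test", "n_features", "auroc"])
    scored = pooled_hits > 0
    pooled = hand_till_auc(
        y[scored], pooled_proba[scored] / pooled_hits[scored, None], classes
    )
    return CvEvaluation(float(table["auroc"].mean()), float(pooled), table)


def permutation_test_model(
    features: LogRatioMatrix | np.ndarray,
    labels,
    plan: CvPlan,
    selector: str = "none",
    rf_params: dict | None = None,
    n_perm: int = 100,
    seed: int = 0,
    selector_kwargs: dict | None = None,
) -> tuple[float, float, np.ndarray]:
    """Empirical p for the CV AUROC under label permutation.

    p = (#{permuted AUROC >= observed} + 1) / (n_perm + 1).  Returns
    (observed mean AUROC, p, permuted AUROCs).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(labels)
    observed = evaluate_cv(features, y, plan, selector, rf_params, seed, selector_kwargs)
    rng = np.random.default_rng(seed + 10_007)
    null = np.empty(n_perm)
    for b in range(n_perm):
        y_perm = rng.permutation(y)
        try:
            ev = evaluate_cv(
                features, y_perm, plan, selector, rf_params,
                int(rng.integers(0, 2**31 - 1)), selector_kwargs,
            )
            null[b] = ev.mean_auroc
        except ValueError:
            null[b] = np.nan
    valid = null[~np.isnan(null)]
    exceed = int((valid >= observed.mean_auroc - 1e-12).sum())
    p = (exceed + 1) / (len(valid) + 1)
    return observed.mean_auroc, float(p), null


# ---------------------------------------------------------------------------
# final model


@dataclass
class SignatureModel:
    """Selected log-ratio signature with importances and group means.

    ``group_means`` is the per-group mean signature (one row per observed
    group, one column per selected feature); ``importances`` are
    permutation-accuracy decreases from the final forest.
    """

    selected_features: list[str]
    importances: pd.Series
    task: str
    group_means: pd.DataFrame
    seed: int
    cv_auroc: float | None = None
    pooled_auroc: float | None = None
    empirical_p: float | None = None
    model: RandomForestClassifier | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "selected_features": self.selected_features,
            "importances": self.importances.to_dict(),
            "cv_auroc": self.cv_auroc,
            "pooled_auroc": self.pooled_auroc,
            "empirical_p": self.empirical_p,
            "group_means": {
                str(g): row.to_dict() for g, row in self.group_means.iterrows()
            },
            "seed": self.seed,
        }


def fit_final_signature(
    features: LogRatioMatrix,
    labels,
    selector: str = "none",
    rf_params: dict | None = None,
    seed: int = 0,
    task: str = "binary strain",
    groups=None,
    selector_kwargs: dict | None = None,
) -> SignatureModel:
    """Select on the full data, train the final forest, summarize per group.

    ``groups`` defaults to the class labels; the group-mean signature S-bar
    averages each selected log-ratio within each group.
    """
    x = features.values
    y = np.asarray(labels)
    names = np.asarray(features.label_strings)
    seeds = _seed_stream(seed)
    if selector == "none":
        sel = np.arange(x.shape[1])
    else:
        sel = _SELECTORS[selector](x, y, next(seeds), rf_params, **(selector_kwargs or {}))
    if sel.size == 0:
        logger.warning("EMPTY SIGNATURE: selector %r confirmed no features", selector)
        return SignatureModel([], pd.Series(dtype=float), task, pd.DataFrame(), seed)
    rf = _forest(rf_params, next(seeds))
    rf.fit(x[:, sel], y)
    pi = permutation_importance(
        rf, x[:, sel], y, scoring="accuracy", n_repeats=10, random_state=next(seeds)
    )
    importances = pd.Series(pi.importances_mean, index=names[sel]).sort_values(
        ascending=False
    )
    group_labels = np.asarray(groups) if groups is not None else y
    frame = pd.DataFrame(x[:, sel], columns=names[sel])
    frame["__group"] = group_labels
    s_bar = frame.groupby("__group").mean()
    s_bar.index.name = "group"
    return SignatureModel([str(f) for f in names[sel]], importances, task, s_bar, seed, model=rf)
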