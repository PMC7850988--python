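"""Compositional algebra on the simplex.

Closure, multiplicative zero replacement, the Aitchison perturbation
operator, the ALR/CLR/PLR log-ratio transforms, and the Aitchison distance.
All logs are natural; tolerances are 1e-9 unless noted.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
from skbio.stats.distance import DistanceMatrix

from .types import LogRatioMatrix, SimplexMatrix, Transform

logger = logging.getLogger(__name__)

__all__ = [
    "closure",
    "impute_zeros",
    "perturb",
    "log_ratio_transform",
    "aitchison_distance",
    "logratio_distance",
]


def closure(
    counts: np.ndarray,
    taxa_ids: list[str] | None = None,
    sample_ids: list[str] | None = None,
) -> SimplexMatrix:
    """Map each row of a nonnegative matrix onto the unit simplex.

    C[x]_j = x_j / sum_k x_k.  Scale-invariant: closure(c*x) == closure(x)
    for any c > 0.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    if (counts < 0).any():
        i, j = np.argwhere(counts < 0)[0]
        raise ValueError(f"negative entry at row {i}, column {j}; counts must be >= 0")
    sums = counts.sum(axis=1)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        names = [sample_ids[i] if sample_ids else f"row {i}" for i in zero[:5]]
        raise ValueError(f"all-zero rows cannot be closed: {names}")
    if taxa_ids is None:
        taxa_ids = [f"T{j}" for j in range(counts.shape[1])]
    return SimplexMatrix(counts / sums[:, None], list(taxa_ids), sample_ids)


def impute_zeros(
    x_closed: SimplexMatrix,
    y_closed: SimplexMatrix,
    delta: float | None = None,
) -> tuple[SimplexMatrix, SimplexMatrix]:
    """Multiplicative zero replacement with a single shared constant.

    Zero cells of the closed pre (X') and post (Y') tables become delta; the
    nonzero cells of a row are shrunk by (1 - z*delta), z the row's zero
    count, so the row stays on the simplex.  By default delta is the
    smallest nonzero proportion found anywhere in either table; pass
    ``delta`` explicitly for sensitivity analysis.
    """
    if x_closed.taxa_ids != y_closed.taxa_ids:
        raise ValueError("pre and post tables must share identical taxa order")
    x, y = x_closed.values, y_closed.values
    if delta is None:
        nonzero = np.concatenate([x[x > 0], y[y > 0]])
        delta = float(nonzero.min())
    if not 0 < delta < 1:
        raise ValueError(f"delta must lie in (0, 1); got {delta}")

    def _replace(mat: np.ndarray, which: str) -> np.ndarray:
        zeros = mat == 0
        n_zero = zeros.sum(axis=1)
        shrink = 1.0 - n_zero * delta
        if (shrink <= 0).any():
            i = int(np.argmin(shrink))
            raise ValueError(
                f"delta={delta:.3g} with {int(n_zero[i])} zeros in {which} row {i} "
                "drives the nonzero multiplier <= 0; pass a smaller explicit delta"
            )
        out = mat * shrink[:, None]
        out[zeros] = delta
        return out

    x_imp = _replace(x, "pre")
    y_imp = _replace(y, "post")
    mk = lambda v, src: SimplexMatrix(v, list(src.taxa_ids), src.sample_ids, delta=delta)
    return mk(x_imp, x_closed), mk(y_imp, y_closed)


def perturb(y_imp: SimplexMatrix, x_imp: SimplexMatrix) -> SimplexMatrix:
    """Aitchison perturbation difference Z = Y (-) X = C[Y / X].

    Z expresses the relative (compositional) change from X to Y; the
    operation inverts exactly: C[X * Z] == Y row-wise.
    """
    if x_imp.taxa_ids != y_imp.taxa_ids:
        raise ValueError("perturb requires identical taxa order in both tables")
    if x_imp.values.shape != y_imp.values.shape:
        raise ValueError("perturb requires matched sample order (same shape)")
    for name, mat in (("pre", x_imp.values), ("post", y_imp.values)):
        if (mat <= 0).any():
            raise ValueError(
                f"nonpositive entries in {name} composition; run impute_zeros first"
            )
    z = y_imp.values / x_imp.values
    out = closure(z, list(x_imp.taxa_ids), x_imp.sample_ids)
    out.delta = x_imp.delta
    return out


def log_ratio_transform(
    comp: SimplexMatrix,
    transform: Transform,
    reference: str | None = None,
    clr_weights: np.ndarray | None = None,
) -> LogRatioMatrix:
    """ALR, CLR or PLR transform of a strictly positive composition.

    ALR: ln(x_j / x_ref) for every taxon j except the reference (d = P-1).
    CLR: ln(x_j / g(x)) with g the (weighted) geometric mean (d = P); the
    weight hook defaults to uniform.  PLR: ln(x_i / x_j) for every unordered
    taxon pair i < j in taxa order (d = P(P-1)/2).
    """
    x = comp.values
    if (x <= 0).any():
        raise ValueError("log-ratio transforms require strictly positive entries")
    taxa = comp.taxa_ids
    logx = np.log(x)
    if transform == "ALR":
        if reference is None:
            raise ValueError("ALR requires a reference taxon")
        try:
            p = taxa.index(reference)
        except ValueError:
            raise ValueError(f"reference taxon {reference!r} not in taxa_ids") from None
        keep = [j for j in range(len(taxa)) if j != p]
        vals = logx[:, keep] - logx[:, [p]]
        labels = [(taxa[j], reference) for j in keep]
        return LogRatioMatrix(vals, labels, "ALR", reference, comp.sample_ids)
    if transform == "CLR":
        if clr_weights is None:
            w = np.full(len(taxa), 1.0 / len(taxa))
        else:
            w = np.asarray(clr_weights, dtype=float)
            if w.shape != (len(taxa),) or (w <= 0).any():
                raise ValueError("clr_weights must be positive, one per taxon")
            w = w / w.sum()
        gm = logx @ w
        vals = logx - gm[:, None]
        labels = [(t, "g(x)") for t in taxa]
        return LogRatioMatrix(vals, labels, "CLR", None, comp.sample_ids)
    if transform == "PLR":
        pairs = list(itertools.combinations(range(len(taxa)), 2))
        vals = np.column_stack([logx[:, i] - logx[:, j] for i, j in pairs])
        labels = [(taxa[i], taxa[j]) for i, j in pairs]
        return LogRatioMatrix(vals, labels, "PLR", None, comp.sample_ids)
    raise ValueError(f"unknown transform {transform!r}")


def _ids(n: int, sample_ids: list[str] | None) -> list[str]:
    return sample_ids if sample_ids is not None else [f"S{i}" for i in range(n)]


def aitchison_distance(
    comp: SimplexMatrix, clr_weights: np.ndarray | None = None
) -> DistanceMatrix:
    """Aitchison distance: Euclidean distance between CLR rows.

    Equals the full pairwise-log-ratio distance scaled by 1/sqrt(P), so the
    CLR route avoids materializing the P(P-1)/2 PLR columns.
    """
    clr = log_ratio_transform(comp, "CLR", clr_weights=clr_weights)
    return logratio_distance(clr)


def logratio_distance(lr: LogRatioMatrix) -> DistanceMatrix:
    """Euclidean distance over log-ratio features (used on the signatures)."""
    v = lr.values
    if not np.isfinite(v).all():
        raise ValueError("log-ratio values must be finite")
    if v.shape[1] >= 1 and np.allclose(v, v[0:1, :], atol=1e-12) and v.shape[0] > 1:
        logger.warning(
            "all samples identical over %d feature(s); distance matrix is zero "
            "(degenerate geometry)",
            v.shape[1],
        )
    sq = (v**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (v @ v.T)
    np.fill_diagonal(d2, 0.0)
    d = np.sqrt(np.clip(d2, 0.0, None))
    d = (d + d.T) / 2.0
    return DistanceMatrix(d, _ids(v.shape[0], lr.sample_ids))
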