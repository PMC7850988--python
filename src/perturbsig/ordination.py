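"""Classical scaling (PCoA) and symmetric Procrustes correlation."""

from __future__ import annotations

import logging

import numpy as np
from scipy.linalg import orthogonal_procrustes
from skbio.stats.distance import DistanceMatrix

from .types import OrdinationConfig

logger = logging.getLogger(__name__)

__all__ = ["pcoa", "procrustes_correlation"]

_EIG_TOL = 1e-9


def double_centered_eig(dist: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the Gower-centered matrix -1/2 J D^2 J.

    Returns (eigenvalues, eigenvectors) sorted by decreasing eigenvalue,
    negatives included — callers that need the 'imaginary' axes (e.g. the
    dispersion test) take the negative part themselves.
    """
    d = np.asarray(dist.data, dtype=float)
    n = d.shape[0]
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    g = a - row - col + a.mean()
    vals, vecs = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def pcoa(dist: DistanceMatrix, k: int | None = None) -> OrdinationConfig:
    """Principal coordinate analysis of a distance matrix.

    Coordinates are eigenvectors scaled by sqrt(eigenvalue); axes with
    eigenvalue <= 1e-9 are dropped.  If ``k`` exceeds the number of
    positive axes it is truncated with a warning.
    """
    n = dist.shape[0]
    vals, vecs = double_centered_eig(dist)
    pos = vals > _EIG_TOL
    vals_pos, vecs_pos = vals[pos], vecs[:, pos]
    if k is None:
        k = vals_pos.size  # may be 0 for fully degenerate input
    elif not 1 <= k <= max(n - 1, 1):
        raise ValueError(f"k must satisfy 1 <= k <= n-1; got k={k}, n={n}")
    if k > vals_pos.size:
        logger.warning(
            "requested k=%d axes but only %d have positive eigenvalue; truncating",
            k,
            vals_pos.size,
        )
        k = vals_pos.size
    coords = vecs_pos[:, :k] * np.sqrt(vals_pos[:k])
    if k == 0:  # fully degenerate input (e.g. all-zero distances)
        coords = np.zeros((n, 0))
    return OrdinationConfig(coords, vals_pos[:k], list(dist.ids))


def _standardize(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=0, keepdims=True)
    norm = np.linalg.norm(x)
    if norm == 0:
        raise ValueError("configuration has zero variance; Procrustes undefined")
    return x / norm


def procrustes_correlation(a: OrdinationConfig, b: OrdinationConfig) -> float:
    """Symmetric Procrustes correlation sqrt(1 - m^2) between configurations.

    Both configurations are centred and scaled to unit Frobenius norm,
    zero-padded to equal width, and optimally rotated/scaled; m^2 is the
    minimized residual sum of squares.  Invariant under translation,
    rotation, reflection and isotropic scaling of either input.
    """
    if a.sample_ids != b.sample_ids:
        raise ValueError("configurations must cover the same samples in order")
    n = a.coordinates.shape[0]
    if n < 3:
        raise ValueError("Procrustes requires at least 3 samples")
    width = max(a.coordinates.shape[1], b.coordinates.shape[1], 1)
    pad = lambda x: np.pad(x, ((0, 0), (0, width - x.shape[1])))
    x = _standardize(pad(a.coordinates))
    y = _standardize(pad(b.coordinates))
    r, scale = orthogonal_procrustes(x, y)
    # after unit-norm standardization the optimal scaling is the trace term
    m2 = 1.0 - scale**2
    m2 = min(max(m2, 0.0), 1.0)
    return float(np.sqrt(1.0 - m2))
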