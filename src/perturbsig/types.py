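"""Core containers for paired compositional microbiome data.

A *composition* carries only relative information: the vector of taxon
proportions lives on the unit simplex after closure.  The containers here
track provenance (taxon identifiers, the zero-imputation constant, the ALR
reference) through every transform so downstream signatures can be read
back as named log-ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

Transform = Literal["ALR", "CLR", "PLR"]

REQUIRED_METADATA_COLUMNS = ("mouse_id", "strain", "food", "reactor")


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate {what} identifiers: {dupes[:5]}")
    return ids


@dataclass
class PairedCountStudy:
    """Pre- and post-exposure count tables, row-paired by mouse.

    ``metadata`` must contain ``mouse_id``, ``strain``, ``food`` and a
    boolean ``reactor`` flag (anaphylaxis on challenge); a ``group`` column
    (``strain:food``) is derived if absent.
    """

    pre_counts: np.ndarray
    post_counts: np.ndarray
    sample_ids: list[str]
    taxa_ids: list[str]
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.pre_counts = np.asarray(self.pre_counts, dtype=float)
        self.post_counts = np.asarray(self.post_counts, dtype=float)
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.taxa_ids = _check_unique(self.taxa_ids, "taxon")
        n, p = self.pre_counts.shape
        if self.post_counts.shape != (n, p):
            raise ValueError(
                f"pre {self.pre_counts.shape} and post {self.post_counts.shape} "
                "count tables must share shape (paired samples, same taxa)"
            )
        if len(self.sample_ids) != n or len(self.taxa_ids) != p:
            raise ValueError("identifier lengths do not match count-table shape")
        for name, mat in (("pre", self.pre_counts), ("post", self.post_counts)):
            if (mat < 0).any():
                raise ValueError(f"negative counts in {name} table")
            zero_rows = np.flatnonzero(mat.sum(axis=1) == 0)
            if zero_rows.size:
                bad = [self.sample_ids[i] for i in zero_rows[:5]]
                raise ValueError(f"all-zero {name} rows for samples {bad}")
        missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in self.metadata.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")
        if len(self.metadata) != n:
            raise ValueError("metadata row count does not match sample count")
        self.metadata = self.metadata.reset_index(drop=True)
        if "group" not in self.metadata.columns:
            self.metadata["group"] = (
                self.metadata["strain"].astype(str) + ":" + self.metadata["food"].astype(str)
            )

    @property
    def n_samples(self) -> int:
        return self.pre_counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.pre_counts.shape[1]

    @property
    def groups(self) -> np.ndarray:
        return self.metadata["group"].to_numpy()


@dataclass
class SimplexMatrix:
    """Strictly positive row-stochastic matrix (samples x taxa).

    ``delta`` records the multiplicative zero-replacement constant once
    imputation has run; it is ``None`` for freshly closed data.
    """

    values: np.ndarray
    taxa_ids: list[str]
    sample_ids: list[str] | None = None
    delta: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.taxa_ids = [str(t) for t in self.taxa_ids]
        if self.values.ndim != 2 or self.values.shape[1] != len(self.taxa_ids):
            raise ValueError("values must be n x P with one column per taxon id")
        sums = self.values.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            worst = float(np.abs(sums - 1.0).max())
            raise ValueError(f"rows must sum to 1 (worst deviation {worst:.3e})")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        idx = self.sample_ids if self.sample_ids is not None else range(self.n_samples)
        return pd.DataFrame(self.values, index=idx, columns=self.taxa_ids)


@dataclass
class LogRatioMatrix:
    """Log-ratio-transformed samples with feature provenance.

    Each feature label is a ``(numerator, denominator)`` taxon pair; for ALR
    the denominator is the single reference taxon, for CLR it is the
    geometric mean (labelled ``"g(x)"``).
    """

    values: np.ndarray
    feature_labels: list[tuple[str, str]]
    transform: Transform
    reference_taxon: str | None = None
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.feature_labels):
            raise ValueError("values must be n x d with one column per feature label")
        if self.transform == "ALR":
            if self.reference_taxon is None:
                raise ValueError("ALR matrix requires a reference taxon")
            if any(num == self.reference_taxon for num, _ in self.feature_labels):
                raise ValueError("ALR reference must not appear among numerators")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def label_strings(self) -> list[str]:
        return [f"{num}/{den}" for num, den in self.feature_labels]

    def subset(self, labels: Sequence[str]) -> "LogRatioMatrix":
        """Restrict to the named ``num/den`` features, preserving order of *labels*."""
        lut = {lab: j for j, lab in enumerate(self.label_strings)}
        missing = [l for l in labels if l not in lut]
        if missing:
            raise KeyError(f"unknown log-ratio features: {missing[:5]}")
        idx = [lut[l] for l in labels]
        return LogRatioMatrix(
            values=self.values[:, idx],
            feature_labels=[self.feature_labels[j] for j in idx],
            transform=self.transform,
            reference_taxon=self.reference_taxon,
            sample_ids=self.sample_ids,
        )

    def to_frame(self) -> pd.DataFrame:
        idx = self.sample_ids if self.sample_ids is not None else range(self.values.shape[0])
        return pd.DataFrame(self.values, index=idx, columns=self.label_strings)


@dataclass
class OrdinationConfig:
    """Principal-coordinate configuration: coordinates scaled by sqrt(eigenvalue)."""

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValueError("eigenvalues must be nonincreasing")
        if np.any(self.eigenvalues < -1e-9):
            raise ValueError("retained eigenvalues must be nonnegative")


@dataclass
class ReferenceSelectionResult:
    """Outcome of Procrustes-based ALR denominator selection."""

    reference_taxon: str
    correlations: pd.Series  # indexed by candidate taxon
    configuration_pair: tuple[OrdinationConfig, OrdinationConfig] | None = None

    def to_frame(self) -> pd.DataFrame:
        out = self.correlations.rename("procrustes_correlation").to_frame()
        out.index.name = "taxon"
        out["selected"] = out.index == self.reference_taxon
        return out.reset_index()
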