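"""Procrustes-based selection of the ALR reference denominator.

The additive log-ratio transform needs one taxon as denominator.  Rather
than picking it by abundance, every candidate is scored by how well the
inter-sample configuration of its (P-1)-dimensional ALR space matches the
full pairwise-log-ratio (PLR) configuration, via symmetric Procrustes; the
winner preserves the Aitchison geometry best at a fraction of the
dimension.  The full-PLR configuration is computed through the equivalent
CLR/Aitchison route so the P(P-1)/2 PLR columns are never materialized.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .composition import aitchison_distance, log_ratio_transform, logratio_distance
from .ordination import pcoa, procrustes_correlation
from .types import ReferenceSelectionResult, SimplexMatrix

logger = logging.getLogger(__name__)

__all__ = ["select_alr_reference"]


def select_alr_reference(
    comp: SimplexMatrix, candidates: list[str] | None = None
) -> ReferenceSelectionResult:
    """Choose the ALR reference maximizing Procrustes match to full-PLR geometry.

    For each candidate taxon the ALR configuration (PCoA of Euclidean
    distances in ALR space) is compared with the PCoA of the Aitchison
    (= scaled full-PLR) distances; the candidate with the largest Procrustes
    correlation wins.  Deterministic; ties break to the lowest taxon index.
    """
    n, p = comp.values.shape
    if n < 4:
        raise ValueError(f"reference selection needs n >= 4 samples; got n={n}")
    if p < 3:
        raise ValueError(f"reference selection needs P >= 3 taxa; got P={p}")
    if candidates is None:
        candidates = list(comp.taxa_ids)
    target_config = pcoa(aitchison_distance(comp))

    corrs: dict[str, float] = {}
    for taxon in candidates:
        alr = log_ratio_transform(comp, "ALR", reference=taxon)
        corrs[taxon] = procrustes_correlation(pcoa(logratio_distance(alr)), target_config)

    series = pd.Series(corrs, name="procrustes_correlation")
    best_val = series.max()
    winners = [t for t in candidates if series[t] == best_val]
    if len(winners) > 1:
        logger.info(
            "Procrustes tie among %d candidates at %.6f; keeping lowest index (%s)",
            len(winners),
            best_val,
            winners[0],
        )
    best = winners[0]
    best_config = pcoa(
        logratio_distance(log_ratio_transform(comp, "ALR", reference=best))
    )
    return ReferenceSelectionResult(best, series, (best_config, target_config))
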