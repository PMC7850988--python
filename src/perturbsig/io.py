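"""Plain-text I/O: count tables, metadata, distances, log-ratio tables.

Count tables are TSV, samples x taxa, with a header row of taxon ids and
the sample id in the first column.  Metadata is TSV keyed by ``mouse_id``
with ``strain``, ``food`` and boolean ``reactor`` columns.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from skbio.stats.distance import DistanceMatrix

from .types import REQUIRED_METADATA_COLUMNS, LogRatioMatrix, PairedCountStudy, SimplexMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_counts_tsv",
    "write_counts_tsv",
    "read_metadata_tsv",
    "write_distance_tsv",
    "write_logratio_tsv",
    "write_study",
    "load_study",
]


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index = table.index.astype(str)
    table.columns = table.columns.astype(str)
    return table


def write_counts_tsv(path: str | Path, counts: np.ndarray, sample_ids, taxa_ids) -> None:
    pd.DataFrame(counts, index=sample_ids, columns=taxa_ids).rename_axis("sample_id").to_csv(
        path, sep="\t"
    )


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"mouse_id": str})
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata file {path} missing required columns: {missing}")
    meta["reactor"] = meta["reactor"].astype(bool)
    return meta


def write_distance_tsv(path: str | Path, dist: DistanceMatrix) -> None:
    pd.DataFrame(dist.data, index=dist.ids, columns=dist.ids).rename_axis("sample_id").to_csv(
        path, sep="\t"
    )


def write_logratio_tsv(path: str | Path, lr: LogRatioMatrix) -> None:
    lr.to_frame().rename_axis("sample_id").to_csv(path, sep="\t")


def write_composition_tsv(path: str | Path, comp: SimplexMatrix) -> None:
    comp.to_frame().rename_axis("sample_id").to_csv(path, sep="\t")


def write_study(study: PairedCountStudy, outdir: str | Path) -> dict[str, Path]:
    """Write pre/post count tables and metadata TSVs; returns their paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pre": outdir / "pre_counts.tsv",
        "post": outdir / "post_counts.tsv",
        "metadata": outdir / "metadata.tsv",
    }
    write_counts_tsv(paths["pre"], study.pre_counts, study.sample_ids, study.taxa_ids)
    write_counts_tsv(paths["post"], study.post_counts, study.sample_ids, study.taxa_ids)
    study.metadata.to_csv(paths["metadata"], sep="\t", index=False)
    return paths


def load_study(
    pre_path: str | Path, post_path: str | Path, metadata_path: str | Path
) -> PairedCountStudy:
    """Load and pair pre/post count tables with metadata.

    Taxa are intersected (order taken from the pre table) and samples
    paired by mouse id; unpaired samples are dropped with a logged list.
    """
    pre = read_counts_tsv(pre_path)
    post = read_counts_tsv(post_path)
    meta = read_metadata_tsv(metadata_path)
    if pre.index.duplicated().any() or post.index.duplicated().any():
        raise ValueError("duplicate mouse_id within a timepoint table")

    shared_taxa = [t for t in pre.columns if t in set(post.columns)]
    if not shared_taxa:
        raise ValueError("no overlapping taxa between pre and post tables")
    dropped = sorted((set(pre.columns) | set(post.columns)) - set(shared_taxa))
    if dropped:
        logger.warning("dropping %d taxa absent from one table: %s", len(dropped), dropped[:5])

    shared_samples = [s for s in pre.index if s in set(post.index) and s in set(meta["mouse_id"])]
    unpaired = sorted((set(pre.index) | set(post.index)) - set(shared_samples))
    if unpaired:
        logger.warning("dropping %d unpaired samples: %s", len(unpaired), unpaired[:5])
    if not shared_samples:
        raise ValueError("no samples shared between pre, post and metadata")

    meta = meta.set_index("mouse_id").loc[shared_samples].reset_index()
    return PairedCountStudy(
        pre_counts=pre.loc[shared_samples, shared_taxa].to_numpy(float),
        post_counts=post.loc[shared_samples, shared_taxa].to_numpy(float),
        sample_ids=list(shared_samples),
        taxa_ids=list(shared_taxa),
        metadata=meta,
    )
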