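"""End-to-end drivers for the two published analyses.

``run_baseline_analysis`` asks whether the *pre-exposure* microbiome
separates the two mouse strains: closure -> shared-delta zero imputation ->
Procrustes-selected ALR -> fold-internal Boruta + random forest (binary
AUROC, permuted-label p) -> final strain signature -> PERMANOVA on
signature distances.

``run_perturbation_analysis`` asks how the *change* in composition depends
on strain and food: Aitchison perturbation Z = post (-) pre -> ALR ->
fold-internal RF-RFE multiclass signature -> PERMANOVA / PERMDISP2 /
pairwise PERMANOVA (BH, alpha = 0.06) -> similarity-graph Leiden clustering
tuned by reactor entropy -> cluster permutation test, Kruskal-Wallis screen
and per-cluster log-ratio profiles.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import yaml
from pydantic import BaseModel, Field

from . import clustering as clu
from . import stats as st
from .alr_reference import select_alr_reference
from .composition import closure, impute_zeros, log_ratio_transform, logratio_distance, perturb
from .io import write_distance_tsv, write_logratio_tsv
from .ml import evaluate_cv, fit_final_signature, make_cv_plan, permutation_test_model
from .ordination import pcoa
from .types import PairedCountStudy

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "BaselineReport",
    "PerturbationReport",
    "run_baseline_analysis",
    "run_perturbation_analysis",
]


class CvScheme(BaseModel):
    k: int
    r: int


class PipelineConfig(BaseModel):
    """Knobs for both analyses; defaults follow the published design."""

    alpha: float = 0.06  # BH significance level for pairwise PERMANOVA
    n_perm: int = 9_999  # distance-based permutation tests
    model_n_perm: int = 100  # permuted-label models per ML task
    binary_cv: CvScheme = Field(default_factory=lambda: CvScheme(k=10, r=10))
    multiclass_cv: CvScheme = Field(default_factory=lambda: CvScheme(k=5, r=10))
    binary_selector: str = "boruta"
    multiclass_selector: str = "rfe"
    rf_params: dict[str, Any] = Field(default_factory=dict)
    selector_kwargs: dict[str, Any] = Field(default_factory=dict)
    resolution_grid_min: float = 0.05
    resolution_grid_max: float = 5.0
    resolution_grid_size: int = 40
    invert_edge_weights: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def resolution_grid(self) -> np.ndarray:
        return np.geomspace(
            self.resolution_grid_min, self.resolution_grid_max, self.resolution_grid_size
        )


class PermutationTestReport(BaseModel):
    pseudo_F: float
    p_value: float
    n_permutations: int


class BaselineReport(BaseModel):
    analysis: str = "baseline"
    config: dict[str, Any]
    input_hashes: dict[str, str]
    n_samples: int
    n_taxa: int
    delta: float
    alr_reference: str
    alr_dim: int
    cv_auroc: float
    pooled_auroc: float
    empirical_p: float
    n_signature_features: int
    signature_features: list[str]
    permanova: PermutationTestReport


class PerturbationReport(BaseModel):
    analysis: str = "perturbation"
    config: dict[str, Any]
    input_hashes: dict[str, str]
    n_samples: int
    n_taxa: int
    n_groups: int
    delta: float
    alr_reference: str
    alr_dim: int
    cv_auroc: float
    pooled_auroc: float
    empirical_p: float
    n_signature_features: int
    signature_features: list[str]
    permanova: PermutationTestReport
    permdisp: PermutationTestReport
    n_pairwise_comparisons: int
    n_nonsignificant_pairs: int
    n_clusters: int
    resolution: float
    reactor_entropy: float
    reactor_counts: dict[str, int]
    top_cluster_reactor_fraction: float
    cluster_permutation_p: float
    n_kw_significant: int


def _hashes(study: PairedCountStudy) -> dict[str, str]:
    h = lambda a: hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()[:16]
    return {
        "pre_counts": h(study.pre_counts),
        "post_counts": h(study.post_counts),
        "metadata": hashlib.sha256(
            study.metadata.to_csv(index=False).encode()
        ).hexdigest()[:16],
    }


def _prepare_compositions(study: PairedCountStudy):
    x_closed = closure(study.pre_counts, study.taxa_ids, study.sample_ids)
    y_closed = closure(study.post_counts, study.taxa_ids, study.sample_ids)
    return impute_zeros(x_closed, y_closed)


def _write(outdir: str | Path | None, name: str, payload) -> None:
    if outdir is None:
        return
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / name
    if name.endswith(".json"):
        path.write_text(json.dumps(payload, indent=2, default=str))
    else:
        payload.to_csv(path, sep="\t", index=False)


def run_baseline_analysis(
    study: PairedCountStudy, config: PipelineConfig, outdir: str | Path | None = None
) -> tuple[BaselineReport, dict[str, Any]]:
    """Strain signature of the pre-exposure microbiome (binary task)."""
    x_imp, _ = _prepare_compositions(study)
    logger.info("baseline: n=%d, P=%d, delta=%.3g", study.n_samples, study.n_taxa, x_imp.delta)
    selection = select_alr_reference(x_imp)
    alr = log_ratio_transform(x_imp, "ALR", reference=selection.reference_taxon)
    logger.info("baseline ALR: reference=%s, d=%d", selection.reference_taxon, alr.n_features)

    strain = study.metadata["strain"].to_numpy()
    plan = make_cv_plan(strain, config.binary_cv.k, config.binary_cv.r, config.seed)
    observed, p_model, null_aurocs = permutation_test_model(
        alr, strain, plan, config.binary_selector, config.rf_params,
        config.model_n_perm, config.seed, config.selector_kwargs,
    )
    cv = evaluate_cv(
        alr, strain, plan, config.binary_selector, config.rf_params,
        config.seed, config.selector_kwargs,
    )
    model = fit_final_signature(
        alr, strain, config.binary_selector, config.rf_params, config.seed,
        task="binary strain", selector_kwargs=config.selector_kwargs,
    )
    model.cv_auroc, model.pooled_auroc, model.empirical_p = cv.mean_auroc, cv.pooled_auroc, p_model

    signature = alr.subset(model.selected_features) if model.selected_features else alr
    dist = logratio_distance(signature)
    ordination = pcoa(dist)
    perma = st.permanova(dist, strain, config.n_perm, config.seed)

    report = BaselineReport(
        config=config.model_dump(),
        input_hashes=_hashes(study),
        n_samples=study.n_samples,
        n_taxa=study.n_taxa,
        delta=float(x_imp.delta),
        alr_reference=selection.reference_taxon,
        alr_dim=alr.n_features,
        cv_auroc=cv.mean_auroc,
        pooled_auroc=cv.pooled_auroc,
        empirical_p=p_model,
        n_signature_features=len(model.selected_features),
        signature_features=model.selected_features,
        permanova=PermutationTestReport(
            pseudo_F=perma.pseudo_F, p_value=perma.p_value, n_permutations=perma.n_permutations
        ),
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write(outdir, "baseline_report.json", report.model_dump())
        _write(outdir, "baseline_reference_selection.tsv", selection.to_frame())
        _write(outdir, "baseline_signature_model.json", model.to_dict())
        _write(outdir, "baseline_fold_table.tsv", cv.fold_table)
        write_logratio_tsv(outdir / "baseline_signature.tsv", signature)
        write_distance_tsv(outdir / "baseline_distances.tsv", dist)
    artifacts = {
        "imputed_pre": x_imp,
        "reference_selection": selection,
        "alr": alr,
        "plan": plan,
        "cv": cv,
        "null_aurocs": null_aurocs,
        "model": model,
        "signature": signature,
        "distances": dist,
        "ordination": ordination,
        "permanova": perma,
    }
    return report, artifacts


def run_perturbation_analysis(
    study: PairedCountStudy, config: PipelineConfig, outdir: str | Path | None = None
) -> tuple[PerturbationReport, dict[str, Any]]:
    """Strain-food signature of the pre-to-post perturbation (multiclass task)."""
    x_imp, y_imp = _prepare_compositions(study)
    z = perturb(y_imp, x_imp)
    logger.info("perturbation: n=%d, P=%d, delta=%.3g", study.n_samples, study.n_taxa, x_imp.delta)
    selection = select_alr_reference(z)
    alr = log_ratio_transform(z, "ALR", reference=selection.reference_taxon)
    logger.info("perturbation ALR: reference=%s, d=%d", selection.reference_taxon, alr.n_features)

    groups = study.groups
    plan = make_cv_plan(groups, config.multiclass_cv.k, config.multiclass_cv.r, config.seed)
    observed, p_model, null_aurocs = permutation_test_model(
        alr, groups, plan, config.multiclass_selector, config.rf_params,
        config.model_n_perm, config.seed, config.selector_kwargs,
    )
    cv = evaluate_cv(
        alr, groups, plan, config.multiclass_selector, config.rf_params,
        config.seed, config.selector_kwargs,
    )
    model = fit_final_signature(
        alr, groups, config.multiclass_selector, config.rf_params, config.seed,
        task="multiclass strain-food", selector_kwargs=config.selector_kwargs,
    )
    model.cv_auroc, model.pooled_auroc, model.empirical_p = cv.mean_auroc, cv.pooled_auroc, p_model

    signature = alr.subset(model.selected_features) if model.selected_features else alr
    dist = logratio_distance(signature)
    ordination = pcoa(dist)
    perma = st.permanova(dist, groups, config.n_perm, config.seed, method="sampled")
    disp = st.permdisp(dist, groups, config.n_perm, config.seed)
    pairwise = st.pairwise_permanova(dist, groups, config.n_perm, config.seed, config.alpha)

    graph = clu.build_group_graph(
        pairwise, sorted(set(groups)), config.alpha, config.invert_edge_weights
    )
    reactor_counts = (
        study.metadata.groupby("group")["reactor"].sum().astype(int).to_dict()
    )
    tuned = clu.tune_resolution(graph, reactor_counts, config.resolution_grid(), config.seed)
    tuned.permutation_p = clu.cluster_permutation_test(
        tuned.partition,
        study.metadata["reactor"].to_numpy(),
        groups,
        config.n_perm,
        config.seed,
    )
    sample_clusters = np.array([tuned.partition[g] for g in groups])
    kw = st.kruskal_wallis_screen(signature, sample_clusters)
    profile = clu.cluster_logratio_profile(signature, sample_clusters)

    total_reactors = sum(tuned.reactor_counts.values())
    top_fraction = (
        max(tuned.reactor_counts.values()) / total_reactors if total_reactors else float("nan")
    )
    report = PerturbationReport(
        config=config.model_dump(),
        input_hashes=_hashes(study),
        n_samples=study.n_samples,
        n_taxa=study.n_taxa,
        n_groups=len(set(groups)),
        delta=float(x_imp.delta),
        alr_reference=selection.reference_taxon,
        alr_dim=alr.n_features,
        cv_auroc=cv.mean_auroc,
        pooled_auroc=cv.pooled_auroc,
        empirical_p=p_model,
        n_signature_features=len(model.selected_features),
        signature_features=model.selected_features,
        permanova=PermutationTestReport(
            pseudo_F=perma.pseudo_F, p_value=perma.p_value, n_permutations=perma.n_permutations
        ),
        permdisp=PermutationTestReport(
            pseudo_F=disp.pseudo_F, p_value=disp.p_value, n_permutations=disp.n_permutations
        ),
        n_pairwise_comparisons=len(pairwise),
        n_nonsignificant_pairs=int((~pairwise["significant"]).sum()),
        n_clusters=tuned.n_clusters,
        resolution=tuned.resolution,
        reactor_entropy=tuned.reactor_entropy,
        reactor_counts={str(k): v for k, v in tuned.reactor_counts.items()},
        top_cluster_reactor_fraction=float(top_fraction),
        cluster_permutation_p=float(tuned.permutation_p),
        n_kw_significant=int((kw["p_adjusted"] <= 0.05).sum()),
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write(outdir, "perturbation_report.json", report.model_dump())
        _write(outdir, "perturbation_reference_selection.tsv", selection.to_frame())
        _write(outdir, "perturbation_signature_model.json", model.to_dict())
        _write(outdir, "perturbation_fold_table.tsv", cv.fold_table)
        _write(outdir, "pairwise_permanova.tsv", pairwise)
        _write(outdir, "group_graph_edges.tsv", graph.edge_frame())
        _write(outdir, "cluster_result.json", tuned.to_dict())
        _write(outdir, "kruskal_wallis.tsv", kw)
        _write(outdir, "cluster_profile.tsv", profile)
        write_logratio_tsv(outdir / "perturbation_signature.tsv", signature)
        write_distance_tsv(outdir / "perturbation_distances.tsv", dist)
    artifacts = {
        "imputed": (x_imp, y_imp),
        "perturbation": z,
        "reference_selection": selection,
        "alr": alr,
        "plan": plan,
        "cv": cv,
        "null_aurocs": null_aurocs,
        "model": model,
        "signature": signature,
        "distances": dist,
        "ordination": ordination,
        "permanova": perma,
        "permdisp": disp,
        "pairwise": pairwise,
        "graph": graph,
        "clusters": tuned,
        "kruskal_wallis": kw,
        "profile": profile,
    }
    return report, artifacts
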