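"""Synthetic paired pre/post microbiome studies with known ground truth.

The generator emulates the study design the pipeline targets: two mouse
strains (one anaphylaxis-prone, one resistant) each exposed to one of five
food proteins, giving ten strain-food groups; 16S-style taxon counts are
drawn per mouse before and after exposure.  Latent compositions follow a
logistic-normal model so that planted effects compose exactly in Aitchison
geometry: the pre-exposure composition is a strain baseline (with a set of
strain-informative taxa shifted on the log scale), the post-exposure
composition is the pre composition perturbed by a group-specific log-shift
vector, and reactor groups receive an extra depletion of a designated
gut-barrier taxon.  Counts are multinomial at finite sequencing depth, so
zeros arise naturally for rare taxa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .composition import closure
from .types import PairedCountStudy

__all__ = ["StudyConfig", "GroundTruth", "generate_study", "zero_fraction"]

STRAINS = ("CC027", "C3H")
FOODS = ("peanut", "walnut", "milk", "egg", "PBS")
DEFAULT_GROUPS = tuple(f"{s}:{f}" for s in STRAINS for f in FOODS)
#: the anaphylaxis-prone strain reacts to peanut, walnut and egg
DEFAULT_REACTOR_GROUPS = ("CC027:peanut", "CC027:walnut", "CC027:egg")


@dataclass
class StudyConfig:
    """Generating parameters; defaults mirror the target study design.

    Log-scale effect sizes are shifts of ln-abundance; ``overdispersion``
    is the per-taxon logistic-normal standard deviation of mouse-to-mouse
    variation around the strain baseline.
    """

    n_per_group: int = 8
    groups: tuple[str, ...] = DEFAULT_GROUPS
    P: int = 230
    depth: int = 20_000
    n_strain_effect_taxa: int = 6
    strain_effect_size: float = 2.5
    n_perturbed_taxa_per_group: int = 5
    perturbation_effect_size: float = 2.0
    reactor_groups: tuple[str, ...] = DEFAULT_REACTOR_GROUPS
    barrier_taxon_depletion: float = 2.5
    reactor_rate_in_reactor_groups: float = 0.7
    reactor_rate_elsewhere: float = 0.02
    overdispersion: float = 0.6
    base_log_sd: float = 3.5
    zero_rate_target: float = 0.55
    seed: int = 0

    def validate(self) -> None:
        if self.P < 5:
            raise ValueError("P must be >= 5")
        if self.depth < 100:
            raise ValueError("depth must be >= 100")
        if not set(self.reactor_groups) <= set(self.groups):
            raise ValueError("reactor_groups must be a subset of groups")
        for name in (
            "strain_effect_size",
            "perturbation_effect_size",
            "barrier_taxon_depletion",
            "overdispersion",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")


@dataclass
class GroundTruth:
    """Generating parameters realized for a particular study draw."""

    group_perturbations: pd.DataFrame  # groups x taxa, each row a composition
    strain_effect_taxa: list[str]
    barrier_taxon: str
    reactor_labels: pd.Series  # per mouse
    latent_pre: np.ndarray  # n x P compositions (delta-free)
    latent_post: np.ndarray


def _strain_of(group: str) -> str:
    return group.split(":")[0]


def generate_study(config: StudyConfig) -> tuple[PairedCountStudy, GroundTruth]:
    """Draw a paired study; byte-identical given the same config (incl. seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    P = config.P
    taxa = [f"V{j}" for j in range(P)]

    # community baseline: lognormal mean abundances give realistic rare tails
    base_log = rng.normal(0.0, config.base_log_sd, size=P)
    # strain-informative taxa, excluding the barrier taxon (last index kept
    # aside); the barrier taxon models an abundant mucin-degrader, so pin it
    # to a prevalent baseline — a depletion of an undetectable taxon would
    # leave no trace in finite-depth counts
    barrier_idx = P - 1
    base_log[barrier_idx] = config.base_log_sd
    candidates = rng.permutation(P - 1)
    strain_taxa_idx = np.sort(candidates[: config.n_strain_effect_taxa])
    strain_shift = np.zeros(P)
    signs = np.where(np.arange(config.n_strain_effect_taxa) % 2 == 0, 1.0, -1.0)
    strain_shift[strain_taxa_idx] = signs * config.strain_effect_size

    # per-group perturbation log-shift vectors; reactor groups share one
    # direction (their exposures drive the microbiome the same way), with the
    # barrier-taxon depletion on top, so clustering has structure to recover
    pert_shift: dict[str, np.ndarray] = {}
    pool = [j for j in range(P - 1) if j not in set(strain_taxa_idx)]
    shared = np.zeros(P)
    picked = rng.choice(pool, size=config.n_perturbed_taxa_per_group, replace=False)
    shared[picked] = rng.choice([-1.0, 1.0], size=picked.size) * config.perturbation_effect_size
    shared[barrier_idx] -= config.barrier_taxon_depletion
    for g in config.groups:
        if g in config.reactor_groups:
            pert_shift[g] = shared.copy()
            continue
        shift = np.zeros(P)
        picked = rng.choice(pool, size=config.n_perturbed_taxa_per_group, replace=False)
        shift[picked] = rng.choice([-1.0, 1.0], size=picked.size) * config.perturbation_effect_size
        pert_shift[g] = shift

    rows_pre, rows_post, meta = [], [], []
    for g in config.groups:
        strain = _strain_of(g)
        strain_centroid = base_log + (strain_shift if strain == STRAINS[0] else -strain_shift)
        p_react = (
            config.reactor_rate_in_reactor_groups
            if g in config.reactor_groups
            else config.reactor_rate_elsewhere
        )
        for m in range(config.n_per_group):
            noise = rng.normal(0.0, config.overdispersion, size=P)
            log_pre = strain_centroid + noise
            log_post = log_pre + pert_shift[g] + rng.normal(
                0.0, config.overdispersion / 2.0, size=P
            )
            rows_pre.append(log_pre)
            rows_post.append(log_post)
            meta.append(
                {
                    "mouse_id": f"{g.replace(':', '_')}_m{m}",
                    "strain": strain,
                    "food": g.split(":")[1],
                    "group": g,
                    "reactor": bool(rng.random() < p_react),
                }
            )

    latent_pre = np.exp(np.asarray(rows_pre))
    latent_pre /= latent_pre.sum(axis=1, keepdims=True)
    latent_post = np.exp(np.asarray(rows_post))
    latent_post /= latent_post.sum(axis=1, keepdims=True)

    pre_counts = np.vstack(
        [rng.multinomial(config.depth, p) for p in latent_pre]
    )
    post_counts = np.vstack(
        [rng.multinomial(config.depth, p) for p in latent_post]
    )
    metadata = pd.DataFrame(meta)
    # multinomial draws can zero an entire ultra-sparse row in principle;
    # guard by granting one read to the most abundant latent taxon
    for counts, latent in ((pre_counts, latent_pre), (post_counts, latent_post)):
        dead = np.flatnonzero(counts.sum(axis=1) == 0)
        for i in dead:
            counts[i, int(np.argmax(latent[i]))] = 1

    study = PairedCountStudy(
        pre_counts=pre_counts,
        post_counts=post_counts,
        sample_ids=metadata["mouse_id"].tolist(),
        taxa_ids=taxa,
        metadata=metadata,
    )
    truth_pert = pd.DataFrame(
        {g: closure(np.exp(pert_shift[g])[None, :]).values[0] for g in config.groups},
        index=taxa,
    ).T
    truth = GroundTruth(
        group_perturbations=truth_pert,
        strain_effect_taxa=[taxa[j] for j in strain_taxa_idx],
        barrier_taxon=taxa[barrier_idx],
        reactor_labels=metadata.set_index("mouse_id")["reactor"],
        latent_pre=latent_pre,
        latent_post=latent_post,
    )
    return study, truth


def zero_fraction(counts: np.ndarray) -> float:
    """Fraction of zero cells in a count matrix."""
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("empty count matrix")
    return float((counts == 0).mean())
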