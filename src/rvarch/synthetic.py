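"""Synthetic multi-ancestry case-control cohorts.

Cohorts are generated under a latent-liability threshold model so that
every downstream stage (QC, matching, association, burden, enrichment,
scores) can be exercised without access to protected genotype data.
Rare variants are grouped into genes and carry mask-structured dominant
carrier effects; common variants carry additive per-allele effects.
Effects are expressed on the log-odds scale: the latent noise is
standard logistic and the disease threshold is ``logit(1 - K)``, so a
carrier effect of ``b`` is exactly a conditional log-odds-ratio of
``b`` — the scale on which the burden and single-variant modules
estimate effects.

Population structure is controllable: each ancestry cluster has
per-variant allele-frequency multipliers and an optional liability
offset, and principal-component surrogates are drawn around cluster
centroids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .masks import MASK_NAMES


class SimulationError(RuntimeError):
    """Requested cohort cannot be drawn within the population cap."""


@dataclass
class GeneSpec:
    """A gene with ``n_variants`` rare variants and per-mask carrier effects.

    ``mask_labels`` gives the stratum of each variant (length
    ``n_variants``, values from the seven mask names); ``effects`` maps a
    mask name to the log-odds carrier effect shared by its variants.
    Variants in masks without an entry have effect 0.
    """

    gene_id: str
    n_variants: int
    maf_range: tuple[float, float] = (1e-4, 5e-3)
    mask_labels: list[str] | None = None
    effects: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.01):
            raise ValueError("rare-variant MAFs must lie in (0, 0.01]")
        if self.mask_labels is None:
            # cycle through the strata for coverage
            self.mask_labels = [
                MASK_NAMES[i % len(MASK_NAMES)] for i in range(self.n_variants)
            ]
        if len(self.mask_labels) != self.n_variants:
            raise ValueError("mask_labels length must equal n_variants")
        unknown = set(self.mask_labels) - set(MASK_NAMES)
        unknown |= set(self.effects) - set(MASK_NAMES)
        if unknown:
            raise ValueError(f"unknown mask labels: {sorted(unknown)}")


@dataclass
class CommonVariantSpec:
    """A common variant with per-cluster MAF and an additive log-odds effect."""

    variant_id: str
    maf: float
    effect: float = 0.0

    def __post_init__(self):
        if not (0.01 < self.maf < 0.5):
            raise ValueError("common-variant MAF must lie in (0.01, 0.5)")


@dataclass
class CohortConfig:
    """Study design for :func:`simulate_cohort`.

    Defaults mirror the study conditions the package targets: 3,005
    cases, 9,777 ancestry-matched controls, disease prevalence 8%, and
    all of the second study's controls shared with the first.
    """

    n_cases: int = 3005
    n_controls: int = 9777
    n_clusters: int = 3
    prevalence: float = 0.08
    genes: list[GeneSpec] = field(default_factory=list)
    common_variants: list[CommonVariantSpec] = field(default_factory=list)
    shared_control_fraction: float = 1.0
    seed: int = 0
    cluster_weights: list[float] | None = None
    cluster_maf_multipliers: list[float] | None = None
    cluster_liability_offsets: list[float] | None = None
    population_cap_factor: int = 50

    def __post_init__(self):
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("n_cases and n_controls must be positive")
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must lie in (0, 1)")
        if not (0 <= self.shared_control_fraction <= 1):
            raise ValueError("shared_control_fraction must lie in [0, 1]")
        k = self.n_clusters
        if self.cluster_weights is None:
            self.cluster_weights = [1.0 / k] * k
        if self.cluster_maf_multipliers is None:
            self.cluster_maf_multipliers = [1.0] * k
        if self.cluster_liability_offsets is None:
            self.cluster_liability_offsets = [0.0] * k
        if any(m <= 0 for m in self.cluster_maf_multipliers):
            raise ValueError("cluster MAF multipliers must be positive")
        for name in ("cluster_weights", "cluster_maf_multipliers", "cluster_liability_offsets"):
            if len(getattr(self, name)) != k:
                raise ValueError(f"{name} must have length n_clusters")
        if not self.genes and not self.common_variants:
            # default panel: null rare-variant genes plus common variants
            # with modest odds ratios (OR ~1.15-1.3)
            self.genes = default_gene_panel(20, 8)
            self.common_variants = [
                CommonVariantSpec(f"cv{i}", maf, effect)
                for i, (maf, effect) in enumerate(
                    [(0.3, 0.14), (0.2, 0.26), (0.4, 0.10), (0.1, 0.18), (0.25, 0.0)]
                )
            ]


@dataclass
class SimulatedCohort:
    """A sampled case-control cohort with its generating truth.

    ``dosages`` is samples x variants in {0,1,2}; ``variants`` holds
    per-variant metadata (gene, mask stratum, per-cluster MAFs, true
    effect); ``samples`` holds phenotype, cluster label and PC1-PC10
    surrogates; ``truth`` records the generating parameters including
    each sample's genetic linear predictor.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame
    truth: dict
    config: CohortConfig

    @property
    def phenotype(self) -> np.ndarray:
        return self.samples["phenotype"].to_numpy()

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def covariate_matrix(self, n_pcs: int = 10, clusters: bool = True) -> np.ndarray:
        """Design columns: PC1..PCn plus cluster indicator contrasts."""
        cols = [self.samples[f"PC{i}"].to_numpy() for i in range(1, n_pcs + 1)]
        if clusters and self.config.n_clusters > 1:
            lab = self.samples["cluster"].to_numpy()
            for c in range(1, self.config.n_clusters):
                cols.append((lab == c).astype(float))
        return np.column_stack(cols)


def effective_sample_size(n_cases: int, n_controls: int) -> float:
    """Balanced-design equivalent sample size ``4ab/(a+b)``.

    The value usually quoted for an unbalanced case-control study; report
    rounded to the nearest integer.
    """
    if n_cases < 0 or n_controls < 0:
        raise ValueError("counts must be non-negative")
    if n_cases == 0 and n_controls == 0:
        raise ValueError("effective sample size undefined for an empty study")
    return 4.0 * n_cases * n_controls / (n_cases + n_controls)


def _variant_table(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    idx = 0
    for gene in config.genes:
        lo, hi = gene.maf_range
        mafs = rng.uniform(lo, hi, size=gene.n_variants)
        for j in range(gene.n_variants):
            mask = gene.mask_labels[j]
            rows.append(
                {
                    "variant_id": f"{gene.gene_id}:v{j}",
                    "gene_id": gene.gene_id,
                    "mask": mask,
                    "base_maf": mafs[j],
                    "effect": float(gene.effects.get(mask, 0.0)),
                    "is_common": False,
                    "chrom": str(1 + idx % 22),
                    "pos": 1000 + 1000 * idx,
                }
            )
            idx += 1
    for cv in config.common_variants:
        rows.append(
            {
                "variant_id": cv.variant_id,
                "gene_id": "",
                "mask": "",
                "base_maf": cv.maf,
                "effect": float(cv.effect),
                "is_common": True,
                "chrom": str(1 + idx % 22),
                "pos": 1000 + 1000 * idx,
            }
        )
        idx += 1
    if not rows:
        raise ValueError("config defines no variants")
    return pd.DataFrame(rows)


def _cluster_mafs(config: CohortConfig, base_maf: np.ndarray) -> np.ndarray:
    mult = np.asarray(config.cluster_maf_multipliers)[:, None]
    return np.clip(base_maf[None, :] * mult, 1e-6, 0.5)


def _genetic_lin_pred(
    dos: np.ndarray, variants: pd.DataFrame, config: CohortConfig
) -> np.ndarray:
    """Per-sample genetic linear predictor on the log-odds scale.

    Common variants contribute additively per allele; rare variants
    contribute their gene/mask carrier effect once if the sample carries
    at least one allele of that gene-stratum (dominant carrier coding,
    matching burden-test carrier aggregation).
    """
    lin = np.zeros(dos.shape[0])
    common = variants["is_common"].to_numpy()
    if common.any():
        lin += dos[:, common] @ variants.loc[common, "effect"].to_numpy()
    rare = variants.index[~common]
    if len(rare):
        sub = variants.loc[rare]
        for (gene, mask), grp in sub.groupby(["gene_id", "mask"], sort=False):
            eff = grp["effect"].iloc[0]
            if eff == 0.0:
                continue
            carrier = (dos[:, grp.index.to_numpy()] > 0).any(axis=1)
            lin += eff * carrier
    return lin


def simulate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Draw a case-control cohort under the logistic liability model.

    Individuals are sampled from a finite background population (capped
    at ``population_cap_factor`` times the requested cohort size);
    disease status is ``liability > logit(1 - K)`` with liability = sum
    of variant effects + cluster offset + standard logistic noise.
    Raises :class:`SimulationError` if the cap cannot supply the
    requested case count.
    """
    rng = np.random.default_rng(config.seed)
    variants = _variant_table(config, rng)
    cmafs = _cluster_mafs(config, variants["base_maf"].to_numpy())
    threshold = logit(1.0 - config.prevalence)
    offsets = np.asarray(config.cluster_liability_offsets)

    n_target = config.n_cases + config.n_controls
    cap = config.population_cap_factor * n_target
    # expected population needed to yield the case count, with head-room
    chunk = min(cap, int(np.ceil(1.5 * config.n_cases / config.prevalence)) + n_target)

    case_dos, case_meta = [], []
    ctrl_dos, ctrl_meta = [], []
    n_cases_found = n_ctrls_found = 0
    drawn = 0
    while (n_cases_found < config.n_cases or n_ctrls_found < config.n_controls):
        if drawn >= cap:
            raise SimulationError(
                f"population cap {cap} exhausted with {n_cases_found} cases "
                f"(requested {config.n_cases}) at prevalence {config.prevalence}"
            )
        size = min(chunk, cap - drawn)
        drawn += size
        cluster = rng.choice(config.n_clusters, size=size, p=config.cluster_weights)
        dos = rng.binomial(2, cmafs[cluster, :]).astype(np.int8)
        lin = _genetic_lin_pred(dos, variants, config) + offsets[cluster]
        liab = lin + rng.logistic(size=size)
        case = liab > threshold
        need_case = config.n_cases - n_cases_found
        need_ctrl = config.n_controls - n_ctrls_found
        ci = np.flatnonzero(case)[:need_case]
        ki = np.flatnonzero(~case)[:need_ctrl]
        case_dos.append(dos[ci])
        ctrl_dos.append(dos[ki])
        case_meta.append(np.column_stack([cluster[ci], lin[ci]]))
        ctrl_meta.append(np.column_stack([cluster[ki], lin[ki]]))
        n_cases_found += len(ci)
        n_ctrls_found += len(ki)

    dosages = np.vstack(case_dos + ctrl_dos)
    meta = np.vstack(case_meta + ctrl_meta)
    phenotype = np.concatenate(
        [np.ones(config.n_cases, dtype=int), np.zeros(config.n_controls, dtype=int)]
    )
    cluster = meta[:, 0].astype(int)
    lin = meta[:, 1]

    centroids = rng.normal(0.0, 1.0, size=(config.n_clusters, 10))
    pcs = centroids[cluster] + rng.normal(0.0, 0.3, size=(len(cluster), 10))
    samples = pd.DataFrame(
        {
            "sample_id": [f"S{i:06d}" for i in range(len(cluster))],
            "phenotype": phenotype,
            "cluster": cluster,
        }
    )
    for i in range(10):
        samples[f"PC{i + 1}"] = pcs[:, i]

    truth = {
        "threshold": float(threshold),
        "lin_pred": lin,
        "gene_effects": {
            g.gene_id: dict(g.effects) for g in config.genes
        },
        "cluster_mafs": cmafs,
        "population_drawn": drawn,
    }
    return SimulatedCohort(
        dosages=dosages, variants=variants, samples=samples, truth=truth, config=config
    )


def spike_truth(
    cohort: SimulatedCohort,
    gene_id: str,
    mask: str,
    effect: float,
    seed: int | None = None,
) -> SimulatedCohort:
    """Re-draw phenotypes with an extra carrier effect on one gene-mask.

    Keeps the sampled genotypes; each sample's disease status is
    re-drawn as Bernoulli at its conditional probability under the
    modified linear predictor (so case/control counts become random).
    The recorded truth is updated.
    """
    variants = cohort.variants
    sel = (variants["gene_id"] == gene_id) & (variants["mask"] == mask)
    if gene_id not in {g.gene_id for g in cohort.config.genes}:
        raise KeyError(f"unknown gene {gene_id!r}")
    if not sel.any():
        raise KeyError(f"gene {gene_id!r} has no variants in mask {mask!r}")
    rng = np.random.default_rng(cohort.config.seed + 1 if seed is None else seed)
    carrier = (cohort.dosages[:, sel.to_numpy()] > 0).any(axis=1)
    lin = cohort.truth["lin_pred"] + effect * carrier
    p_case = expit(lin - cohort.truth["threshold"])
    phenotype = rng.binomial(1, p_case)

    samples = cohort.samples.copy()
    samples["phenotype"] = phenotype
    truth = dict(cohort.truth)
    truth["lin_pred"] = lin
    gene_effects = {g: dict(e) for g, e in truth["gene_effects"].items()}
    gene_effects.setdefault(gene_id, {})
    gene_effects[gene_id][mask] = gene_effects[gene_id].get(mask, 0.0) + effect
    truth["gene_effects"] = gene_effects
    new_variants = variants.copy()
    new_variants.loc[sel, "effect"] += effect
    return SimulatedCohort(
        dosages=cohort.dosages,
        variants=new_variants,
        samples=samples,
        truth=truth,
        config=cohort.config,
    )


def default_gene_panel(
    n_genes: int = 20,
    n_variants: int = 8,
    effects: dict[str, float] | None = None,
    spiked: dict[str, dict[str, float]] | None = None,
) -> list[GeneSpec]:
    """Convenience panel of null genes with optional spiked effects."""
    genes = []
    for i in range(n_genes):
        gid = f"GENE{i:03d}"
        eff = dict(effects or {})
        if spiked and gid in spiked:
            eff.update(spiked[gid])
        genes.append(GeneSpec(gene_id=gid, n_variants=n_variants, effects=eff))
    return genes
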