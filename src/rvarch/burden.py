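"""Gene-level burden association over seven nested masks.

For each gene, variants are stratified by deleteriousness
(:mod:`rvarch.masks`), mask ``m`` aggregates strata ``1..m``, and a
Firth penalized logistic regression of phenotype on the per-sample mask
allele count gives one test per non-empty mask.  The per-mask P values
are consolidated into a single gene P by a minimum-P test corrected for
the effective number of independent masks, estimated from the
correlation of the per-sample mask burden scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .firth import firth_lrt
from .masks import MASK_NAMES, assign_strata


@dataclass
class MaskBurdenResult:
    """Burden fit for one gene-mask."""

    mask: str
    beta: float
    se: float
    p: float
    n_carriers: int
    cumulative_af: float


@dataclass
class GeneAssociation:
    """Per-gene burden results across masks with consolidated P."""

    gene_id: str
    per_mask: dict[str, MaskBurdenResult] = field(default_factory=dict)
    m_eff: float = np.nan
    consolidated_p: float = np.nan
    best_mask: str | None = None
    transcript_set: str = "best_guess"

    @property
    def best(self) -> MaskBurdenResult | None:
        return self.per_mask.get(self.best_mask) if self.best_mask else None


def build_masks(annotations: pd.DataFrame) -> dict[str, dict[str, list]]:
    """Group variants per gene and nested mask.

    ``annotations`` needs ``variant_id``, ``gene_id`` and the columns
    :func:`rvarch.masks.assign_strata` consumes.  Returns
    ``{gene: {mask: [variant ids in strata 1..m]}}`` (masks nest).
    """
    strata = assign_strata(annotations)
    out: dict[str, dict[str, list]] = {}
    for gene, grp in annotations.groupby("gene_id", sort=False):
        if not gene:
            continue
        gene_masks: dict[str, list] = {}
        acc: list = []
        for mask in MASK_NAMES:
            in_stratum = grp.index[strata.loc[grp.index] == mask]
            acc = acc + list(grp.loc[in_stratum, "variant_id"])
            gene_masks[mask] = list(acc)
        out[str(gene)] = gene_masks
    return out


def mask_burden_scores(
    dosages: np.ndarray,
    variant_ids: list[str],
    gene_masks: dict[str, list],
) -> pd.DataFrame:
    """Per-sample mask allele counts (0/1/2 summed over mask variants)."""
    col = {v: j for j, v in enumerate(variant_ids)}
    scores = {}
    for mask in MASK_NAMES:
        vids = [v for v in gene_masks.get(mask, []) if v in col]
        if not vids:
            scores[mask] = np.zeros(dosages.shape[0])
        else:
            scores[mask] = dosages[:, [col[v] for v in vids]].sum(axis=1).astype(float)
    return pd.DataFrame(scores)


def burden_test(
    burden_score: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    mask: str = "",
) -> MaskBurdenResult | None:
    """Firth regression of phenotype on the mask allele count.

    Returns None (with no result) when the mask has zero carriers.
    """
    burden_score = np.asarray(burden_score, dtype=float)
    n_carriers = int((burden_score > 0).sum())
    if n_carriers == 0:
        return None
    n = len(burden_score)
    cols = [np.ones(n), burden_score]
    if covariates is not None and np.asarray(covariates).size:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.extend(cov.T)
    X = np.column_stack(cols)
    y = np.asarray(phenotype, dtype=int)
    fit, p = firth_lrt(X, y, test_col=1)
    cum_af = float(burden_score.sum() / (2.0 * n))
    return MaskBurdenResult(
        mask=mask,
        beta=float(fit.beta[1]),
        se=float(fit.se[1]),
        p=p,
        n_carriers=n_carriers,
        cumulative_af=cum_af,
    )


def effective_mask_count(mask_scores: pd.DataFrame | np.ndarray) -> float:
    """Effective number of independent masks (Li-Ji eigenvalue method).

    Takes the per-sample burden scores across masks, drops constant
    columns, and maps the eigenvalues ``l`` of their correlation matrix
    through ``f(l) = 1(l >= 1) + (l - floor(l))``.  One mask, or
    perfectly correlated masks, give Meff = 1.
    """
    S = np.asarray(mask_scores, dtype=float)
    if S.ndim == 1:
        return 1.0
    keep = S.std(axis=0) > 0
    S = S[:, keep]
    if S.shape[1] == 0:
        raise ValueError("all mask scores are constant")
    if S.shape[1] == 1:
        return 1.0
    corr = np.corrcoef(S, rowvar=False)
    ev = np.abs(np.linalg.eigvalsh(corr))
    return float(np.sum((ev >= 1).astype(float) + (ev - np.floor(ev))))


def consolidate_min_p(per_mask_ps: dict[str, float] | list[float], m_eff: float) -> float:
    """Sidak-corrected minimum P: ``1 - (1 - min P)^Meff``, capped at 1."""
    ps = list(per_mask_ps.values()) if isinstance(per_mask_ps, dict) else list(per_mask_ps)
    ps = [p for p in ps if np.isfinite(p)]
    if not ps:
        return np.nan
    if m_eff < 1:
        raise ValueError("Meff must be >= 1")
    pmin = min(ps)
    # expm1/log1p form is exact for tiny pmin
    return float(min(1.0, -np.expm1(m_eff * np.log1p(-min(pmin, 1.0)))))


def gene_significance_threshold(alpha: float = 0.05, n_genes: int = 19020) -> float:
    """Gene-level Bonferroni threshold ``alpha / n_genes`` (2 sig figs)."""
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    t = alpha / n_genes
    return float(np.format_float_positional(t, precision=2, unique=False, fractional=False))


def gene_burden_scan(
    dosages: np.ndarray,
    variant_ids: list[str],
    phenotype: np.ndarray,
    annotations: pd.DataFrame,
    covariates: np.ndarray | None = None,
) -> list[GeneAssociation]:
    """Full burden scan: masks, per-mask Firth tests, Meff, consolidation."""
    gene_masks = build_masks(annotations)
    results = []
    for gene, masks in gene_masks.items():
        scores = mask_burden_scores(dosages, variant_ids, masks)
        assoc = GeneAssociation(gene_id=gene)
        nonempty = scores.columns[(scores.sum(axis=0) > 0).to_numpy()]
        for mask in nonempty:
            res = burden_test(scores[mask].to_numpy(), phenotype, covariates, mask=mask)
            if res is not None:
                assoc.per_mask[mask] = res
        if not assoc.per_mask:
            continue
        assoc.m_eff = effective_mask_count(scores[list(assoc.per_mask)])
        ps = {m: r.p for m, r in assoc.per_mask.items()}
        assoc.consolidated_p = consolidate_min_p(ps, assoc.m_eff)
        assoc.best_mask = min(ps, key=ps.get)
        results.append(assoc)
    return results


def gene_results_frame(results: list[GeneAssociation]) -> pd.DataFrame:
    """Tidy per-gene summary of a burden scan."""
    rows = []
    for r in results:
        best = r.best
        rows.append(
            {
                "gene_id": r.gene_id,
                "consolidated_p": r.consolidated_p,
                "m_eff": r.m_eff,
                "best_mask": r.best_mask,
                "beta": best.beta if best else np.nan,
                "se": best.se if best else np.nan,
                "n_carriers": best.n_carriers if best else 0,
                "cumulative_af": best.cumulative_af if best else np.nan,
                "n_masks": len(r.per_mask),
            }
        )
    return pd.DataFrame(rows)
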