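"""Single-variant Firth association and inverse-variance meta-analysis.

Per ancestry cluster, each variant's dosage is tested with Firth
penalized logistic regression adjusted for the principal components
that pass a univariate pre-screen; the per-cluster estimates are then
combined by fixed-effects inverse-variance weighting.  P values come
from the penalized likelihood-ratio test, which is better calibrated
than Wald at rare-variant counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
import statsmodels.api as sm

from .firth import FirthResult, firth_fit, firth_lrt

#: exome-wide significance for coding variants
CODING_ALPHA = 4.3e-7
#: genome-wide significance for non-coding variants
NONCODING_ALPHA = 5.0e-8


@dataclass
class AssociationResult:
    """One variant's Firth association in one cluster (or meta-analysed)."""

    variant_id: str
    beta: float
    se: float
    p: float
    maf: float = np.nan
    n_cases: int = 0
    n_controls: int = 0
    cluster_id: int | None = None
    n_carriers: int = 0
    low_confidence: bool = False
    converged: bool = True
    skipped: str | None = None

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))


@dataclass
class MetaResult:
    """Fixed-effects inverse-variance combination across clusters."""

    variant_id: str
    beta: float
    se: float
    p: float
    inputs: list[AssociationResult] = field(default_factory=list)

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))


def screen_covariates(
    covariates: np.ndarray, phenotype: np.ndarray, alpha: float = 0.005
) -> np.ndarray:
    """Indices of covariate columns univariately associated with outcome.

    Each column is tested alone (plus intercept) by logistic regression;
    columns with P < ``alpha`` (the Bonferroni-corrected screen) are
    retained for adjustment.
    """
    covariates = np.asarray(covariates, dtype=float)
    keep = []
    for j in range(covariates.shape[1]):
        X = sm.add_constant(covariates[:, j])
        try:
            fit = sm.Logit(phenotype, X).fit(disp=False, maxiter=200)
            p = fit.pvalues[1]
        except Exception:
            p = 1.0
        if p < alpha:
            keep.append(j)
    return np.asarray(keep, dtype=int)


def firth_test(
    dosage: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    variant_id: str = "",
    cluster_id: int | None = None,
) -> AssociationResult:
    """Firth penalized-LRT association of one variant.

    Monomorphic variants are skipped with a reason; variants with fewer
    than 2 carriers are tested (the penalty keeps them finite) but
    flagged ``low_confidence``.
    """
    dosage = np.asarray(dosage, dtype=float)
    phenotype = np.asarray(phenotype, dtype=int)
    n = len(dosage)
    if dosage.min() == dosage.max():
        return AssociationResult(
            variant_id=variant_id,
            beta=np.nan,
            se=np.nan,
            p=np.nan,
            cluster_id=cluster_id,
            skipped="monomorphic",
        )
    cols = [np.ones(n), dosage]
    if covariates is not None and np.asarray(covariates).size:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        cols.extend(cov.T)
    X = np.column_stack(cols)
    fit, p = firth_lrt(X, phenotype, test_col=1)
    maf = float(dosage.mean() / 2.0)
    maf = min(maf, 1.0 - maf)
    n_carriers = int((dosage > 0).sum())
    return AssociationResult(
        variant_id=variant_id,
        beta=float(fit.beta[1]),
        se=float(fit.se[1]),
        p=p,
        maf=maf,
        n_cases=int(phenotype.sum()),
        n_controls=int((1 - phenotype).sum()),
        cluster_id=cluster_id,
        n_carriers=n_carriers,
        low_confidence=n_carriers < 2,
        converged=fit.converged,
    )


def meta_analyze(results: list[AssociationResult]) -> MetaResult:
    """Fixed-effects inverse-variance meta-analysis of cluster results.

    ``beta = sum(w_i b_i)/sum(w_i)`` with ``w = 1/SE^2``;
    ``SE = sum(w)^(-1/2)``; two-sided normal P.
    """
    usable = [r for r in results if r.skipped is None and np.isfinite(r.se) and r.se > 0]
    if not usable:
        raise ValueError("no usable cluster results to combine")
    ids = {r.variant_id for r in usable}
    if len(ids) > 1:
        raise ValueError(f"results mix variants: {sorted(ids)}")
    w = np.array([1.0 / r.se**2 for r in usable])
    b = np.array([r.beta for r in usable])
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = beta / se
    p = float(2.0 * norm.sf(abs(z)))
    return MetaResult(variant_id=usable[0].variant_id, beta=beta, se=se, p=p, inputs=usable)


def exome_wide_flags(results: pd.DataFrame, coding_col: str = "coding") -> pd.DataFrame:
    """Mark exome-/genome-wide significant variants.

    Coding variants are significant at P < 4.3e-7, non-coding at
    P < 5.0e-8 (strict inequalities).
    """
    out = results.copy()
    p = out["p"].to_numpy(dtype=float)
    coding = out[coding_col].to_numpy(dtype=bool)
    out["significant"] = np.where(coding, p < CODING_ALPHA, p < NONCODING_ALPHA)
    return out


def associate_cohort(
    dosages: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None,
    cluster_labels: np.ndarray,
    variant_ids: list[str] | None = None,
    screen_alpha: float = 0.005,
) -> pd.DataFrame:
    """Per-cluster Firth tests plus meta-analysis for every variant.

    Covariates are pre-screened per cluster at ``screen_alpha``.
    Returns a tidy frame of the meta-analysed results (clusters in which
    the variant is monomorphic drop out, as under QC exclusions).
    """
    if variant_ids is None:
        variant_ids = [f"v{j}" for j in range(dosages.shape[1])]
    rows = []
    clusters = np.unique(cluster_labels)
    per_cluster_cov = {}
    for c in clusters:
        m = cluster_labels == c
        if covariates is None:
            per_cluster_cov[c] = None
        else:
            keep = screen_covariates(covariates[m], phenotype[m], alpha=screen_alpha)
            per_cluster_cov[c] = covariates[m][:, keep] if len(keep) else None
    for j, vid in enumerate(variant_ids):
        cluster_results = []
        for c in clusters:
            m = cluster_labels == c
            res = firth_test(
                dosages[m, j], phenotype[m], per_cluster_cov[c], variant_id=vid, cluster_id=int(c)
            )
            if res.skipped is None:
                cluster_results.append(res)
        if not cluster_results:
            continue
        meta = meta_analyze(cluster_results)
        n_alleles = sum(2 * (r.n_cases + r.n_controls) for r in cluster_results)
        maf = sum(r.maf * 2 * (r.n_cases + r.n_controls) for r in cluster_results) / n_alleles
        rows.append(
            {
                "variant_id": vid,
                "beta": meta.beta,
                "se": meta.se,
                "p": meta.p,
                "odds_ratio": meta.odds_ratio,
                "maf": maf,
                "n_clusters": len(cluster_results),
            }
        )
    return pd.DataFrame(rows)
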