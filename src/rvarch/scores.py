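"""Per-sample common, rare and combined variant contribution scores.

The common-variant score is a weighted risk-allele sum, z-standardized
within each ancestry and converted to the log-odds scale by the
ancestry-specific effect per standard deviation of score.  The
rare-variant score weights each carried variant by the "unique"-fit
effect of the most stringent mask containing it (the mask's burden
effect re-estimated on the variants not already captured by more
stringent masks), after winner's-curse correction of effects for genes
selected by P value.  The combined score is their sum, so all three
live on the log-odds scale and an ``OR >= 3`` cut is ``score >=
ln 3``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .firth import firth_lrt
from .masks import MASK_NAMES

#: per-SD log-odds effect of the common-variant score by ancestry,
#: from the external polygenic-score calibration
DEFAULT_ANCESTRY_BETAS = {
    "European": 0.89,
    "African American": 0.37,
    "Latino": 0.91,
}


@dataclass
class SampleScores:
    """Per-sample contribution scores on the log-odds scale."""

    sample_id: str
    common: float
    rare: float
    mody_carrier: bool = False

    @property
    def combined(self) -> float:
        return self.common + self.rare


def percent(k: int, n: int) -> float:
    """Percentage rounded half-up to one decimal (reporting convention)."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    # exact rational ratio so half-way cases round as intended
    ratio = Decimal(100 * k) / Decimal(n)
    return float(ratio.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def common_score(
    dosages: np.ndarray,
    weights: np.ndarray,
    ancestry: np.ndarray,
    ancestry_betas: dict[str, float] | None = None,
) -> np.ndarray:
    """Ancestry-standardized weighted allele score on the log-odds scale.

    ``dosages`` is samples x score variants (risk-allele dosage),
    ``weights`` the per-variant effect sizes.  The weighted sum is
    z-standardized within each ancestry and multiplied by that
    ancestry's per-SD effect.
    """
    if ancestry_betas is None:
        ancestry_betas = DEFAULT_ANCESTRY_BETAS
    raw = np.asarray(dosages, dtype=float) @ np.asarray(weights, dtype=float)
    ancestry = np.asarray(ancestry)
    out = np.empty_like(raw)
    for a in np.unique(ancestry):
        if a not in ancestry_betas:
            raise KeyError(f"no per-SD effect for ancestry {a!r}")
        m = ancestry == a
        mu, sd = raw[m].mean(), raw[m].std()
        z = (raw[m] - mu) / sd if sd > 0 else np.zeros(m.sum())
        out[m] = ancestry_betas[a] * z
    return out


def unique_mask_effects(
    dosages: np.ndarray,
    variant_ids: list[str],
    gene_masks: dict[str, list[str]],
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    wc_correct_fn=None,
) -> dict[str, dict]:
    """"Unique"-fit effect of each mask stratum of one gene.

    For mask ``m`` the effect is re-estimated on the variants unique to
    stratum ``m`` (present in mask ``m`` but not in mask ``m-1``), by
    Firth regression of phenotype on the unique-variant allele count.
    ``wc_correct_fn`` (effect, se) -> corrected effect optionally
    applies the winner's-curse correction.  Returns
    ``{mask: {"beta": effect used, "variants": unique variant ids}}``
    for strata with carriers.
    """
    col = {v: j for j, v in enumerate(variant_ids)}
    out: dict[str, dict] = {}
    prev: set[str] = set()
    n = dosages.shape[0]
    for mask in MASK_NAMES:
        members = [v for v in gene_masks.get(mask, []) if v in col]
        unique = [v for v in members if v not in prev]
        prev.update(members)
        if not unique:
            continue
        count = dosages[:, [col[v] for v in unique]].sum(axis=1).astype(float)
        if not (count > 0).any():
            continue
        cols = [np.ones(n), count]
        if covariates is not None and np.asarray(covariates).size:
            cov = np.asarray(covariates, dtype=float)
            if cov.ndim == 1:
                cov = cov[:, None]
            cols.extend(cov.T)
        X = np.column_stack(cols)
        fit, _ = firth_lrt(X, np.asarray(phenotype, dtype=int), test_col=1)
        beta, se = float(fit.beta[1]), float(fit.se[1])
        if wc_correct_fn is not None:
            beta = float(wc_correct_fn(beta, se))
        out[mask] = {"beta": beta, "variants": unique}
    return out


def rare_score_unique_fit(
    dosages: np.ndarray,
    variant_ids: list[str],
    gene_mask_table: dict[str, dict[str, list[str]]],
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    gene_list: list[str] | None = None,
    wc_correct_fn=None,
) -> np.ndarray:
    """Per-sample rare-variant contribution score.

    Each carried variant contributes the unique-fit effect of its most
    stringent containing mask; a sample's score sums these carrier
    contributions over the configured gene list.  Genes without any
    qualifying mask contribute zero.
    """
    col = {v: j for j, v in enumerate(variant_ids)}
    score = np.zeros(dosages.shape[0])
    genes = gene_list if gene_list is not None else list(gene_mask_table)
    for gene in genes:
        masks = gene_mask_table.get(gene)
        if not masks:
            continue
        fits = unique_mask_effects(
            dosages, variant_ids, masks, phenotype, covariates, wc_correct_fn
        )
        for mask, fit in fits.items():
            idx = [col[v] for v in fit["variants"]]
            carrier = (dosages[:, idx] > 0).any(axis=1)
            score += fit["beta"] * carrier
    return score


def classify_and_report(
    scores: pd.DataFrame,
    or_threshold: float = 3.0,
) -> pd.DataFrame:
    """Mutually exclusive high-risk categories with counts and percentages.

    ``scores`` needs columns ``common``, ``rare``, ``combined`` (log-odds
    scale) and boolean ``mody``.  Precedence: monogenic (MODY) carrier,
    then rare score >= ln(OR), then common, then combined; the union row
    aggregates them.  Percentages are half-up to one decimal.
    """
    cut = float(np.log(or_threshold))
    n = len(scores)
    mody = scores["mody"].to_numpy(dtype=bool)
    rare = ~mody & (scores["rare"].to_numpy() >= cut)
    common = ~mody & ~rare & (scores["common"].to_numpy() >= cut)
    combined = ~mody & ~rare & ~common & (scores["combined"].to_numpy() >= cut)
    union = mody | rare | common | combined
    rows = []
    for name, mask in (
        ("mody", mody),
        ("rare", rare),
        ("common", common),
        ("combined", combined),
        ("union", union),
    ):
        k = int(mask.sum())
        rows.append({"category": name, "count": k, "percent": percent(k, n)})
    return pd.DataFrame(rows)


def phenotype_association(
    scores: pd.DataFrame,
    phenotypes: pd.DataFrame,
    score_cols: tuple[str, ...] = ("rare", "common"),
    exclude_mody: bool = True,
) -> pd.DataFrame:
    """Linear regression of each phenotype on each per-SD score.

    Scores are standardized to unit SD so the reported beta is per-SD;
    MODY carriers are removed first when ``exclude_mody``.  Phenotype
    columns with no observations yield an NA row.
    """
    df = scores.join(phenotypes)
    if exclude_mody and "mody" in df:
        df = df.loc[~df["mody"].astype(bool)]
    rows = []
    for sc in score_cols:
        s = df[sc].to_numpy(dtype=float)
        sd = s.std()
        z = (s - s.mean()) / sd if sd > 0 else s * 0.0
        for ph in phenotypes.columns:
            y = df[ph].to_numpy(dtype=float)
            ok = np.isfinite(y) & np.isfinite(z)
            if ok.sum() < 3:
                rows.append(
                    {"score": sc, "phenotype": ph, "beta": np.nan, "se": np.nan,
                     "p": np.nan, "n": int(ok.sum())}
                )
                continue
            X = sm.add_constant(z[ok])
            fit = sm.OLS(y[ok], X).fit()
            rows.append(
                {
                    "score": sc,
                    "phenotype": ph,
                    "beta": float(fit.params[1]),
                    "se": float(fit.bse[1]),
                    "p": float(fit.pvalues[1]),
                    "n": int(ok.sum()),
                }
            )
    return pd.DataFrame(rows)


def group_mean_comparison(
    values: np.ndarray, group: np.ndarray
) -> dict[str, float]:
    """Difference in phenotype means between two groups via a GLM.

    ``group`` is a boolean indicator (e.g. MODY carrier); returns the
    estimated difference (group True minus False), its SE and P from a
    Gaussian GLM, equivalent to the two-sample comparison.
    """
    values = np.asarray(values, dtype=float)
    group = np.asarray(group, dtype=bool)
    ok = np.isfinite(values)
    X = sm.add_constant(group[ok].astype(float))
    fit = sm.GLM(values[ok], X, family=sm.families.Gaussian()).fit()
    return {
        "difference": float(fit.params[1]),
        "se": float(fit.bse[1]),
        "p": float(fit.pvalues[1]),
        "mean_group": float(values[ok][group[ok]].mean()),
        "mean_rest": float(values[ok][~group[ok]].mean()),
    }
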