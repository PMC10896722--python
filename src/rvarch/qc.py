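"""Variant quality-control filters applied before association testing.

Six numbered rules, applied per ancestry cluster to biallelic autosomal
variants:

1. differential-missingness P >= 1e-4 (cases vs controls);
2. Hardy-Weinberg exact P >= 1e-4;
3. (alt GQ >= 95 and call rate >= 0.95) or
   (alt GQ < 95 and call rate >= 0.99 and diff-missingness P >= 1e-3
   and HWE P >= 1e-3);
4. read depth >= 50 or (depth < 50 and diff-missingness P >= 1e-3 and
   HWE P >= 1e-3 overall, in cases and in controls);
5. Firth P >= 0.05 x Fisher exact P;
6. passing gnomAD random-forest flag.

Both small-count tests are exact: Fisher's exact test for differential
missingness and the conditional exact Hardy-Weinberg test (distribution
of the heterozygote count given allele counts; plain P, no mid-P).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import fisher_exact

RULE_NAMES = (
    "biallelic_autosomal",
    "rule1_diff_missingness",
    "rule2_hwe",
    "rule3_gq_callrate",
    "rule4_depth",
    "rule5_firth_vs_fisher",
    "rule6_gnomad_rf",
)


def diff_missingness_test(
    case_called: int, case_missing: int, control_called: int, control_missing: int
) -> float:
    """Two-sided Fisher's exact P for differential missingness.

    The 2x2 table is called/missing by case/control.  An empty margin
    (no missing calls anywhere, or no called genotypes) carries no
    information and returns P = 1 with a warning.
    """
    if min(case_called, case_missing, control_called, control_missing) < 0:
        raise ValueError("counts must be non-negative")
    if case_called + case_missing == 0 or control_called + control_missing == 0:
        raise ValueError("each group needs at least one sample")
    table = np.array([[case_called, case_missing], [control_called, control_missing]])
    if table.sum(axis=0).min() == 0:
        warnings.warn("empty margin in missingness table; P set to 1", stacklevel=2)
        return 1.0
    return float(fisher_exact(table, alternative="two-sided")[1])


def hwe_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg equilibrium test P.

    Sums, over the conditional distribution of the heterozygote count
    given the minor-allele count, the probabilities of all outcomes no
    more probable than the observed one (no mid-P).  Monomorphic sites
    return 1.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("no genotyped samples")
    n_alt = 2 * n_hom_alt + n_het
    n_minor = min(n_alt, 2 * n - n_alt)
    if n_minor == 0:
        return 1.0
    # heterozygote counts share the parity of the minor-allele count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hets - hom_minor
    # log P(het = h | n, n_minor) up to a constant
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(hom_minor + 1)
        - gammaln(hom_major + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    observed = np.flatnonzero(hets == n_het)
    if len(observed) == 0:  # parity mismatch: impossible configuration
        raise ValueError("heterozygote count inconsistent with allele count")
    p_obs = p[observed[0]]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def apply_variant_filters(
    records: pd.DataFrame, tally: bool = True
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the six QC rules; return (passing records, per-rule failure tally).

    ``records`` needs columns: ``biallelic``, ``autosomal``,
    ``diff_missingness_p``, ``hwe_p``, ``hwe_p_cases``,
    ``hwe_p_controls``, ``alt_gq``, ``call_rate``, ``depth``,
    ``firth_p``, ``fisher_p``, ``gnomad_rf_pass``.  Missing (NaN) values
    fail the branch that consumes them.  A variant may fail several
    rules; the tally counts every rule it fails.
    """

    def col(name):
        if name not in records.columns:
            raise KeyError(f"QC column missing: {name}")
        return records[name]

    def ge(series, thresh):
        # NaN-safe: missing values fail
        return series.to_numpy(dtype=float) >= thresh

    ba = col("biallelic").fillna(False).to_numpy(dtype=bool) & col("autosomal").fillna(
        False
    ).to_numpy(dtype=bool)
    dm = col("diff_missingness_p")
    hwe = col("hwe_p")
    r1 = ge(dm, 1e-4)
    r2 = ge(hwe, 1e-4)
    gq_hi = ge(col("alt_gq"), 95)
    r3 = (gq_hi & ge(col("call_rate"), 0.95)) | (
        ~gq_hi & ge(col("call_rate"), 0.99) & ge(dm, 1e-3) & ge(hwe, 1e-3)
    )
    depth_hi = ge(col("depth"), 50)
    r4 = depth_hi | (
        ~depth_hi
        & ge(dm, 1e-3)
        & ge(hwe, 1e-3)
        & ge(col("hwe_p_cases"), 1e-3)
        & ge(col("hwe_p_controls"), 1e-3)
    )
    r5 = col("firth_p").to_numpy(dtype=float) >= 0.05 * col("fisher_p").to_numpy(
        dtype=float
    )
    r5 = np.nan_to_num(r5, nan=False) if r5.dtype != bool else r5
    r6 = col("gnomad_rf_pass").fillna(False).to_numpy(dtype=bool)

    rules = {
        "biallelic_autosomal": ba,
        "rule1_diff_missingness": r1,
        "rule2_hwe": r2,
        "rule3_gq_callrate": r3,
        "rule4_depth": r4,
        "rule5_firth_vs_fisher": r5,
        "rule6_gnomad_rf": r6,
    }
    keep = np.ones(len(records), dtype=bool)
    failures: dict[str, int] = {}
    for name, ok in rules.items():
        failures[name] = int((~ok).sum())
        keep &= ok
    return records.loc[keep], failures
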