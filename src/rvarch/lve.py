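"""Liability variance explained (LVE) by variants and genes.

A biallelic site with genotype frequencies ``(p_AA, p_Aa, p_aa)`` and
relative risks ``(1, RR1, RR2)`` at disease prevalence ``K`` implies
penetrances ``f_i = K RR_i / sum(p_j RR_j)``.  Under the
liability-threshold model the disease threshold is ``T = Phi^-1(1-K)``
and genotype ``i`` has mean liability ``mu_i = T - Phi^-1(1 - f_i)``;
the liability variance attributable to the site is the variance of the
genotype means, and

    LVE = V / (V + 1),   V = sum(p_i mu_i^2) - (sum(p_i mu_i))^2.

Observed effect sizes inflate LVE by roughly the square of their
standard error; the corrected estimate subtracts the LVE a null variant
would show from estimation noise of that magnitude.  Gene-level
("burden") signals are treated as pseudo-variants at their cumulative
allele frequency, with the standard error inflated to match the
multiple-mask-corrected P value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .winners_curse import WcInput, wc_correct, wc_sample_propagate


@dataclass
class LiabilityModel:
    """Genotype frequencies, relative risks and prevalence for one site."""

    p_aa: float  # non-carrier homozygote frequency (risk allele absent)
    p_ab: float
    p_bb: float
    rr1: float = 1.0
    rr2: float = 1.0
    prevalence: float = 0.08

    def __post_init__(self):
        total = self.p_aa + self.p_ab + self.p_bb
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"genotype frequencies sum to {total}, not 1")
        if self.rr1 < 0 or self.rr2 < 0:
            raise ValueError("relative risks must be non-negative")
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must lie in (0, 1)")

    @classmethod
    def from_maf(cls, maf: float, rr1: float, rr2: float, prevalence: float = 0.08):
        """Hardy-Weinberg genotype frequencies at the risk-allele frequency."""
        q = maf
        return cls((1 - q) ** 2, 2 * q * (1 - q), q**2, rr1, rr2, prevalence)

    def penetrances(self) -> np.ndarray:
        p = np.array([self.p_aa, self.p_ab, self.p_bb])
        rr = np.array([1.0, self.rr1, self.rr2])
        f = self.prevalence * rr / np.sum(p * rr)
        if np.any(f > 1.0 + 1e-12) or np.any(f < 0):
            raise ValueError(f"implied penetrances outside [0, 1]: {f}")
        return np.clip(f, 0.0, 1.0)


@dataclass
class LveEstimate:
    """Raw and noise-corrected LVE (corrected may be negative; kept)."""

    lve_raw: float
    correction: float
    lve_corrected: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    negative_after_correction: bool = False


def or_to_rr(
    odds_ratio: float, prevalence: float = 0.08, maf: float | None = None
) -> tuple[float, float]:
    """Per-allele relative risks implied by an additive (log-odds) OR.

    With ``maf`` given, the non-carrier penetrance ``f0`` solves the
    marginal constraint ``sum(p_i f_i) = K`` (bisection) where
    ``odds_i = odds_0 * OR^i``; without it, ``f0`` is anchored at the
    prevalence itself (exact in the rare-variant limit).  Returns
    ``(RR1, RR2) = (f1/f0, f2/f0)``.
    """
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")
    K = prevalence

    def penetrances(odds0):
        odds = odds0 * odds_ratio ** np.arange(3)
        return odds / (1.0 + odds)

    if maf is None:
        f = penetrances(K / (1.0 - K))
    else:
        q = maf
        pg = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])

        def marginal(odds0):
            return float(np.sum(pg * penetrances(odds0)) - K)

        odds0 = brentq(marginal, 1e-12, 1e6)
        f = penetrances(odds0)
    if np.any(f > 1.0):
        raise ValueError("implied penetrance exceeds 1")
    return float(f[1] / f[0]), float(f[2] / f[0])


def lve_single(model: LiabilityModel, scale: str = "lve") -> float:
    """Liability variance explained by one site.

    ``scale='lve'`` returns ``V/(V+1)`` (the share of total liability
    variance, residual variance 1); ``scale='V'`` returns the raw
    between-genotype variance.
    """
    f = model.penetrances()
    T = norm.isf(model.prevalence)
    # truncate penetrances of exactly 0/1 for the probit inverse
    f = np.clip(f, 1e-15, 1 - 1e-15)
    mu = T - norm.isf(f)
    p = np.array([model.p_aa, model.p_ab, model.p_bb])
    V = float(np.sum(p * mu**2) - np.sum(p * mu) ** 2)
    if scale == "V":
        return V
    return V / (V + 1.0)


def lve_from_beta(
    beta: float, maf: float, prevalence: float = 0.08, anchor_maf: bool = True
) -> float:
    """LVE of a variant with log-OR ``beta`` at risk-allele frequency ``maf``."""
    orr = float(np.exp(beta))
    rr1, rr2 = or_to_rr(orr, prevalence, maf=maf if anchor_maf else None)
    return lve_single(LiabilityModel.from_maf(maf, rr1, rr2, prevalence))


def lve_bias_correct(
    beta: float,
    se: float,
    maf: float,
    prevalence: float = 0.08,
) -> LveEstimate:
    """Subtract the estimation-noise contribution from a raw LVE.

    The raw LVE uses the observed effect; the correction term is the
    (sign-symmetrised) LVE a truly null variant would show with an
    estimated effect of one standard error, which equals the expected
    noise inflation to second order.  Negative corrected values are
    reported, not clipped, so that set sums stay unbiased.
    """
    if se < 0:
        raise ValueError("standard error must be non-negative")
    raw = lve_from_beta(beta, maf, prevalence)
    if se == 0:
        return LveEstimate(lve_raw=raw, correction=0.0, lve_corrected=raw)
    corr = 0.5 * (
        lve_from_beta(se, maf, prevalence) + lve_from_beta(-se, maf, prevalence)
    )
    corrected = raw - corr
    return LveEstimate(
        lve_raw=raw,
        correction=corr,
        lve_corrected=corrected,
        negative_after_correction=corrected < 0,
    )


def meff_inflated_se(beta: float, p_raw: float, p_corrected: float, se_raw: float) -> float:
    """Standard error matching the multiple-mask-corrected P value.

    Converts the corrected P to a two-sided z and back-solves
    ``se = |beta| / z``; with no correction (``p_corrected == p_raw``)
    the raw SE is returned unchanged.
    """
    if p_corrected <= p_raw * (1 + 1e-12):
        return se_raw
    z = norm.isf(p_corrected / 2.0)
    if z <= 0:
        raise ValueError("corrected P too large to imply a z-score")
    return abs(beta) / z


def gene_lve(
    beta: float,
    se: float,
    cumulative_af: float,
    p_raw: float | None = None,
    p_corrected: float | None = None,
    wc_input: WcInput | None = None,
    prevalence: float = 0.08,
) -> LveEstimate:
    """LVE of a gene-level burden signal as a pseudo-variant.

    The gene's cumulative allele frequency plays the role of the allele
    frequency (carriers split by Hardy-Weinberg); the SE is inflated to
    the effective-mask-corrected P when both P values are supplied; the
    winner's-curse-corrected effect is used when the gene was
    ascertained by P (``wc_input`` given).
    """
    use_se = se
    if p_raw is not None and p_corrected is not None:
        use_se = meff_inflated_se(beta, p_raw, p_corrected, se)
    use_beta = beta
    if wc_input is not None:
        use_beta = wc_correct(wc_input).beta_true
    return lve_bias_correct(use_beta, use_se, cumulative_af, prevalence)


def architecture_compare(
    inputs_a: list[WcInput],
    mafs_a: list[float],
    inputs_b: list[WcInput],
    mafs_b: list[float],
    prevalence: float = 0.08,
    n_samples: int = 200,
    seed: int | None = None,
) -> tuple[float, tuple[float, float]]:
    """Fold difference in summed LVE between two variant sets.

    ``fold = sum(LVE_A) / sum(LVE_B)`` with winner's-curse-corrected
    effects; the CI propagates effect-size uncertainty jointly over both
    sets by likelihood sampling.  Fails if the denominator sum is <= 0.
    """
    if not inputs_a or not inputs_b:
        raise ValueError("both sets must be non-empty")
    n_a = len(inputs_a)
    all_inputs = list(inputs_a) + list(inputs_b)
    mafs = np.asarray(list(mafs_a) + list(mafs_b), dtype=float)

    def fold_stat(betas: np.ndarray) -> float:
        lves = np.array(
            [lve_from_beta(b, m, prevalence) for b, m in zip(betas, mafs)]
        )
        denom = lves[n_a:].sum()
        if denom <= 0:
            return np.nan
        return float(lves[:n_a].sum() / denom)

    point, ci, reps = wc_sample_propagate(
        all_inputs, fold_stat, n_samples=n_samples, seed=seed
    )
    if not np.isfinite(point):
        raise ValueError("denominator set has non-positive total LVE")
    return point, ci
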