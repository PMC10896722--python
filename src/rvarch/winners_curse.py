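"""Winner's-curse correction of ascertained effect sizes.

Effects selected because they crossed a significance threshold are
biased away from zero.  Conditional on ascertainment at z-score
threshold ``c``, the likelihood of the observed effect ``b_obs`` (with
standard error ``s``) given the true effect ``b`` is

    phi((b_obs - b)/s) / s
    -------------------------------------  for |b_obs/s| >= c,
    Phi(b/s - c) + Phi(-b/s - c)

with phi/Phi the standard normal density/CDF.  The corrected effect is
the conditional maximum-likelihood estimate; confidence intervals come
from the chi-squared(1) approximation to the log-likelihood-ratio, and
uncertainty in set-level statistics is propagated by repeatedly
sampling a chi-squared log-likelihood drop and solving for the matching
effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import chi2, norm


@dataclass
class WcInput:
    """An ascertained observed effect: ``beta_obs`` +/- ``se`` at threshold ``c``.

    ``c`` is the (two-tailed) z-score corresponding to the ascertainment
    P-value threshold; the conditioning event ``|beta_obs/se| >= c``
    must hold.
    """

    beta_obs: float
    se: float
    c: float = 0.0

    def __post_init__(self):
        if self.se <= 0:
            raise ValueError("standard error must be positive")
        if self.c < 0:
            raise ValueError("ascertainment threshold must be non-negative")
        if abs(self.beta_obs / self.se) < self.c - 1e-12:
            raise ValueError(
                "observed effect does not satisfy the ascertainment condition"
            )


@dataclass
class WcEstimate:
    """Corrected effect with likelihood-ratio confidence interval."""

    beta_true: float
    ci_low: float
    ci_high: float
    loglik: float
    ci_level: float = 0.95


def threshold_from_pvalue(p_threshold: float, two_tailed: bool = True) -> float:
    """z-score ascertainment threshold matching a P-value threshold."""
    if not (0 < p_threshold <= 1):
        raise ValueError("p_threshold must lie in (0, 1]")
    if two_tailed:
        return float(norm.isf(p_threshold / 2.0))
    return float(norm.isf(p_threshold))


def wc_loglik(beta_true: float | np.ndarray, inp: WcInput) -> float | np.ndarray:
    """Conditional log-likelihood of ``beta_obs`` given ``beta_true``.

    With ``c = 0`` the denominator is 1 and this is the plain normal
    log-density.
    """
    b = np.asarray(beta_true, dtype=float)
    s, c = inp.se, inp.c
    dens = norm.logpdf((inp.beta_obs - b) / s) - np.log(s)
    if c > 0:
        denom = norm.cdf(b / s - c) + norm.cdf(-b / s - c)
        with np.errstate(divide="ignore"):
            dens = dens - np.log(denom)
    out = dens
    return float(out) if np.isscalar(beta_true) else out


def wc_correct(inp: WcInput, ci_level: float = 0.95) -> WcEstimate:
    """Conditional-MLE winner's-curse correction with chi-squared CI.

    The MLE is found by bounded 1-D optimization on
    ``[-|b_obs| - 10s, |b_obs| + 10s]``; CI endpoints solve
    ``loglik(MLE) - loglik(b) = chi2_1(ci_level)/2`` by bracketed root
    finding on each side.
    """
    lo = -abs(inp.beta_obs) - 10.0 * inp.se
    hi = abs(inp.beta_obs) + 10.0 * inp.se
    res = minimize_scalar(
        lambda b: -wc_loglik(b, inp), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:
        raise RuntimeError(f"winner's-curse MLE did not converge: {res.message}")
    bhat = float(res.x)
    llmax = float(-res.fun)
    # with no selection the MLE is exactly beta_obs
    if inp.c == 0:
        bhat = float(inp.beta_obs)
        llmax = float(wc_loglik(bhat, inp))
    drop = 0.5 * chi2.ppf(ci_level, 1)

    def g(b):
        return (llmax - wc_loglik(b, inp)) - drop

    span = inp.se
    left = bhat - span
    while g(left) < 0:
        span *= 2.0
        left = bhat - span
        if span > 1e6 * inp.se:
            raise RuntimeError("CI lower bracket not found")
    ci_low = brentq(g, left, bhat)
    span = inp.se
    right = bhat + span
    while g(right) < 0:
        span *= 2.0
        right = bhat + span
        if span > 1e6 * inp.se:
            raise RuntimeError("CI upper bracket not found")
    ci_high = brentq(g, bhat, right)
    return WcEstimate(
        beta_true=bhat, ci_low=float(ci_low), ci_high=float(ci_high),
        loglik=llmax, ci_level=ci_level,
    )


def _solve_loglik_root(inp: WcInput, bhat: float, llmax: float, drop: float,
                       side: int) -> float:
    """Effect on the given side of the MLE whose loglik is ``llmax - drop``."""

    def g(b):
        return (llmax - wc_loglik(b, inp)) - drop

    span = inp.se
    x = bhat + side * span
    while g(x) < 0:
        span *= 2.0
        x = bhat + side * span
        if span > 1e7 * inp.se:
            raise RuntimeError("likelihood root bracket not found")
    lo, hi = (x, bhat) if side < 0 else (bhat, x)
    return float(brentq(g, lo, hi))


def wc_sample_propagate(
    inputs: Sequence[WcInput],
    statistic: Callable[[np.ndarray], float],
    n_samples: int = 1000,
    ci_level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, tuple[float, float], np.ndarray]:
    """Propagate effect-size uncertainty into a set-level statistic.

    Per replicate and per variant: draw a chi-squared(1) log-likelihood
    drop, solve for the effect with that conditional likelihood (the
    side of the MLE chosen by a fair coin), and evaluate ``statistic``
    on the vector of sampled effects.  Returns the statistic at the
    corrected MLEs, the CI from replicate quantiles, and the replicate
    values.  Replicates in which root finding fails are dropped (and
    reflected in the returned replicate count).
    """
    rng = np.random.default_rng(seed)
    mles = [wc_correct(inp, ci_level) for inp in inputs]
    point = float(statistic(np.array([m.beta_true for m in mles])))
    reps = []
    for _ in range(n_samples):
        sampled = np.empty(len(inputs))
        ok = True
        for i, (inp, m) in enumerate(zip(inputs, mles)):
            drop = 0.5 * rng.chisquare(1)
            side = 1 if rng.random() < 0.5 else -1
            try:
                sampled[i] = _solve_loglik_root(inp, m.beta_true, m.loglik, drop, side)
            except RuntimeError:
                ok = False
                break
        if ok:
            reps.append(statistic(sampled))
    reps = np.asarray(reps, dtype=float)
    if reps.size == 0:
        raise RuntimeError("every propagation replicate failed")
    alpha = 1.0 - ci_level
    ci = (
        float(np.quantile(reps, alpha / 2)),
        float(np.quantile(reps, 1 - alpha / 2)),
    )
    return point, ci, reps
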