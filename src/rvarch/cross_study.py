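"""Cross-study effect-size calibration under shared controls.

When two case-control studies share controls and differ in sample
size, naive comparisons of their effect sizes are confounded: shared
controls induce correlation between the estimates, and any selection
of variants by P value in one study induces winner's curse.  This
module simulates the two studies jointly under the null (binomial
genotypes; phenotype coded 0 = case, 1 = control; per-variant ordinary
linear regression — the same construction used to calibrate the
empirical comparisons) and summarizes the expected sign concordance
and the expected fraction of variants with the larger absolute effect
in one study, with and without selection.  The calibrated null
proportion then feeds a one-sided binomial test of the observed count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binomtest
from scipy.stats import t as t_dist


@dataclass
class StudyPairDesign:
    """Two case-control studies sharing a block of control participants.

    Defaults mirror the empirical design the package targets: a
    3,005/9,777 youth-onset study whose controls are all drawn from the
    24,440 controls of a 29,791-case adult-onset study.
    """

    n_cases_1: int = 3005
    n_controls_1: int = 9777
    n_cases_2: int = 29791
    n_controls_2: int = 24440
    n_shared_controls: int = 9777
    n_variants: int = 17
    mafs: list[float] = field(default_factory=lambda: [0.2] * 17)
    n_replicates: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n_shared_controls > min(self.n_controls_1, self.n_controls_2):
            raise ValueError("shared controls exceed a study's control count")
        if len(self.mafs) != self.n_variants:
            raise ValueError("mafs length must equal n_variants")
        if any(not (0 < m <= 0.5) for m in self.mafs):
            raise ValueError("MAFs must lie in (0, 0.5]")


@dataclass
class ConcordanceStats:
    """Null expectations (and SEs across replicates) of the comparisons."""

    sign_concordance: float
    sign_concordance_se: float
    frac_larger_in_study1: float
    frac_larger_in_study1_se: float
    n_replicates_used: int
    n_replicates_empty: int = 0


def _multinomial_genotype_stats(
    rng: np.random.Generator, n: int, maf: float, size: int
) -> tuple[np.ndarray, np.ndarray]:
    """(sum g, sum g^2) for ``n`` HWE genotypes at ``maf``, ``size`` replicates."""
    probs = [(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2]
    counts = rng.multinomial(n, probs, size=size)
    s = counts[:, 1] + 2 * counts[:, 2]
    s2 = counts[:, 1] + 4 * counts[:, 2]
    return s.astype(float), s2.astype(float)


def simulate_null_pair(design: StudyPairDesign) -> dict[str, np.ndarray]:
    """Simulate replicate effect/P matrices for the two null studies.

    Returns arrays of shape (n_replicates, n_variants): ``beta1``,
    ``beta2``, ``p1``, ``p2``.  Genotypes are binomial at the stated
    MAF; the shared controls carry identical genotypes in both studies;
    phenotype is 0 for cases and 1 for controls; estimates come from
    per-variant ordinary least squares (computed in closed form from
    genotype-count sufficient statistics).
    """
    rng = np.random.default_rng(design.seed)
    R, V = design.n_replicates, design.n_variants
    out = {k: np.empty((R, V)) for k in ("beta1", "beta2", "p1", "p2")}

    for j, maf in enumerate(design.mafs):
        s_case1, s2_case1 = _multinomial_genotype_stats(rng, design.n_cases_1, maf, R)
        s_case2, s2_case2 = _multinomial_genotype_stats(rng, design.n_cases_2, maf, R)
        s_sh, s2_sh = _multinomial_genotype_stats(rng, design.n_shared_controls, maf, R)
        s_own1, s2_own1 = _multinomial_genotype_stats(
            rng, design.n_controls_1 - design.n_shared_controls, maf, R
        )
        s_own2, s2_own2 = _multinomial_genotype_stats(
            rng, design.n_controls_2 - design.n_shared_controls, maf, R
        )
        for study, (sc, s2c, so, s2o, n_case, n_ctrl) in {
            1: (s_case1, s2_case1, s_own1, s2_own1, design.n_cases_1, design.n_controls_1),
            2: (s_case2, s2_case2, s_own2, s2_own2, design.n_cases_2, design.n_controls_2),
        }.items():
            s_ctrl = so + s_sh
            s2_ctrl = s2o + s2_sh
            n = n_case + n_ctrl
            S = sc + s_ctrl
            S2 = s2c + s2_ctrl
            sxx = S2 - S**2 / n
            # y: 0 for cases, 1 for controls
            sxy = s_ctrl - S * (n_ctrl / n)
            syy = n_ctrl - n_ctrl**2 / n
            with np.errstate(divide="ignore", invalid="ignore"):
                beta = sxy / sxx
                rss = syy - beta * sxy
                sigma2 = rss / (n - 2)
                se = np.sqrt(sigma2 / sxx)
                tstat = beta / se
            p = 2.0 * t_dist.sf(np.abs(tstat), df=n - 2)
            beta = np.nan_to_num(beta, nan=0.0)
            p = np.nan_to_num(p, nan=1.0)
            out[f"beta{study}"][:, j] = beta
            out[f"p{study}"][:, j] = p
    return out


def concordance_stats(
    replicates: dict[str, np.ndarray],
    selection: str = "none",
    p_threshold: float | None = None,
    top_k: int | None = None,
    select_in: int = 1,
) -> ConcordanceStats:
    """Null expectations of sign concordance and larger-|effect| fraction.

    ``selection`` is ``"none"``, ``"p_threshold"`` (keep variants with
    P below ``p_threshold`` in study ``select_in``) or ``"top_k"``
    (keep the ``top_k`` smallest P values in study ``select_in``).
    Expectations and standard errors are taken across replicates;
    replicates with an empty selection contribute nothing and are
    counted.
    """
    b1, b2 = replicates["beta1"], replicates["beta2"]
    psel = replicates[f"p{select_in}"]
    R = b1.shape[0]
    conc, larger = [], []
    n_empty = 0
    for r in range(R):
        if selection == "none":
            idx = np.arange(b1.shape[1])
        elif selection == "p_threshold":
            idx = np.flatnonzero(psel[r] < p_threshold)
        elif selection == "top_k":
            idx = np.argsort(psel[r])[:top_k]
        else:
            raise ValueError(f"unknown selection rule {selection!r}")
        if len(idx) == 0:
            n_empty += 1
            continue
        # exact-zero estimates occur on the integer genotype-count lattice;
        # a zero has no direction, so sign ties contribute 1/2
        prod = np.sign(b1[r, idx]) * np.sign(b2[r, idx])
        conc.append(np.mean((prod > 0) + 0.5 * (prod == 0)))
        a1, a2 = np.abs(b1[r, idx]), np.abs(b2[r, idx])
        larger.append(np.mean((a1 > a2) + 0.5 * (a1 == a2)))
    conc = np.asarray(conc)
    larger = np.asarray(larger)
    if conc.size == 0:
        raise ValueError("selection empty in every replicate")
    return ConcordanceStats(
        sign_concordance=float(conc.mean()),
        sign_concordance_se=float(conc.std(ddof=1) / np.sqrt(len(conc)))
        if len(conc) > 1
        else np.nan,
        frac_larger_in_study1=float(larger.mean()),
        frac_larger_in_study1_se=float(larger.std(ddof=1) / np.sqrt(len(larger)))
        if len(larger) > 1
        else np.nan,
        n_replicates_used=int(len(conc)),
        n_replicates_empty=n_empty,
    )


def calibrated_binomial_test(k_observed: int, n: int, p_null: float) -> float:
    """One-sided binomial tail ``P(X >= k)`` at the calibrated null proportion."""
    if not (0 <= k_observed <= n):
        raise ValueError("k_observed must lie in [0, n]")
    if not (0 < p_null < 1):
        raise ValueError("p_null must lie in (0, 1)")
    return float(binomtest(k_observed, n, p_null, alternative="greater").pvalue)
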