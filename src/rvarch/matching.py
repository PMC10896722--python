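"""Ancestry clustering and SVD-based external-control matching.

Cases and prospective external controls are first clustered on genetic
principal components with a Gaussian mixture (model order by BIC).
Within a cluster, controls are ranked by the norm of their residual
after projection onto the top left-singular subspace of the
standardized case genotype matrix; the selected control set is the
largest residual-norm threshold set whose case-vs-control null
association scan has genomic inflation lambda < 2 and more than a
minimum number of controls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.stats import chi2
from sklearn.mixture import GaussianMixture

#: median of the chi-squared(1) distribution
CHI2_1_MEDIAN = float(chi2.ppf(0.5, 1))


class MatchingError(RuntimeError):
    """No residual-norm threshold satisfies the selection constraints."""


@dataclass
class MatchResult:
    """Outcome of inflation-gated control selection for one cluster."""

    residual_norms: np.ndarray
    selected: np.ndarray  # indices into the control matrix
    threshold: float
    genomic_lambda: float
    cluster_id: int | None = None


def cluster_ancestry(
    pcs: np.ndarray, max_k: int = 10, seed: int = 0
) -> np.ndarray:
    """Cluster samples on principal components by Gaussian mixtures.

    Fits full-covariance mixtures for 1..max_k components and keeps the
    BIC-optimal model; deterministic given ``seed``.
    """
    pcs = np.asarray(pcs, dtype=float)
    if pcs.ndim != 2 or pcs.shape[1] < 2:
        raise ValueError("need a samples x components matrix with >= 2 components")
    if not np.all(np.isfinite(pcs)):
        raise ValueError("PCs must be finite")
    if len(pcs) < max_k:
        raise ValueError("fewer samples than candidate clusters")
    best = None
    best_bic = np.inf
    for k in range(1, max_k + 1):
        gm = GaussianMixture(n_components=k, covariance_type="full", random_state=seed, n_init=3)
        gm.fit(pcs)
        bic = gm.bic(pcs)
        if bic < best_bic:
            best, best_bic = gm, bic
    return best.predict(pcs)


def _standardize(case: np.ndarray, control: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = case.mean(axis=0)
    sd = case.std(axis=0)
    sd[sd == 0] = 1.0
    return (case - mu) / sd, (control - mu) / sd


def svd_control_ranking(
    case_genotypes: np.ndarray,
    control_genotypes: np.ndarray,
    k_vectors: int | None = None,
) -> np.ndarray:
    """Residual norm of each control after projection onto the case subspace.

    Columns are standardized to the case mean/SD; the top ``k_vectors``
    right-singular directions of the standardized case matrix span the
    case row space onto which each control row is projected.  Lower
    residual norm = better match.  ``k_vectors=None`` picks the smallest
    k explaining 90% of the squared singular values.
    """
    case = np.asarray(case_genotypes, dtype=float)
    ctrl = np.asarray(control_genotypes, dtype=float)
    if case.shape[1] != ctrl.shape[1]:
        raise ValueError("case and control matrices must share variant columns")
    case_s, ctrl_s = _standardize(case, ctrl)
    # Vt rows span the case row space (directions of the left singular
    # vectors' images); projecting controls onto them mirrors projecting
    # onto the span of the case profile subspace.
    _, s, vt = np.linalg.svd(case_s, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0
    if k_vectors is None:
        energy = np.cumsum(s**2) / np.sum(s**2)
        k_vectors = int(np.searchsorted(energy, 0.90) + 1)
    if k_vectors > rank:
        raise ValueError(f"k_vectors={k_vectors} exceeds case matrix rank {rank}")
    basis = vt[:k_vectors]
    proj = ctrl_s @ basis.T @ basis
    return np.linalg.norm(ctrl_s - proj, axis=1)


def genomic_inflation(chi2_stats: np.ndarray) -> float:
    """Genomic inflation factor: median chi-squared over the null median."""
    stats = np.asarray(chi2_stats, dtype=float)
    if stats.size == 0:
        raise ValueError("no association statistics supplied")
    if np.any(stats < 0):
        raise ValueError("chi-squared statistics must be non-negative")
    return float(np.median(stats) / CHI2_1_MEDIAN)


def qq_slope(pvalues: np.ndarray) -> float:
    """Slope of the P-value QQ plot against the uniform expectation.

    Least-squares slope of the sorted observed P values on the uniform
    plotting positions ``(i - 0.5)/n``.  Unity indicates a calibrated
    test; the linear scale keeps the estimate stable (the log-scale
    slope is dominated by the handful of smallest P values).
    """
    p = np.sort(np.asarray(pvalues, dtype=float))
    if p.size < 3:
        raise ValueError("need at least 3 P values")
    expected = (np.arange(1, p.size + 1) - 0.5) / p.size
    return float(np.polyfit(expected, p, 1)[0])


def allele_count_chi2(
    case_genotypes: np.ndarray, control_genotypes: np.ndarray
) -> np.ndarray:
    """Per-variant 1-df allele-count chi-squared between cases and controls.

    The fast null scan used when gating control selection on genomic
    inflation; monomorphic variants contribute 0.
    """
    na, nb = 2 * case_genotypes.shape[0], 2 * control_genotypes.shape[0]
    a = case_genotypes.sum(axis=0).astype(float)
    b = control_genotypes.sum(axis=0).astype(float)
    p = (a + b) / (na + nb)
    var = p * (1 - p) * (1.0 / na + 1.0 / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = (a / na - b / nb) ** 2 / var
    return np.nan_to_num(stat, nan=0.0, posinf=0.0)


def select_controls(
    case_genotypes: np.ndarray,
    control_genotypes: np.ndarray,
    residual_norms: np.ndarray | None = None,
    *,
    lambda_max: float = 2.0,
    min_controls: int = 500,
    n_thresholds: int = 100,
    assoc_fn: Callable[[np.ndarray, np.ndarray], np.ndarray] = allele_count_chi2,
    cluster_id: int | None = None,
) -> MatchResult:
    """Pick the largest control set with genomic inflation below the gate.

    Scans ``n_thresholds`` quantiles of the residual-norm distribution
    from most to least inclusive; for each candidate set runs the null
    association scan (``assoc_fn``) of cases against the included
    controls and computes lambda.  Returns the first (largest) set with
    lambda < ``lambda_max`` and more than ``min_controls`` controls;
    raises :class:`MatchingError` (reporting the best lambda achieved)
    if none qualifies.
    """
    if residual_norms is None:
        residual_norms = svd_control_ranking(case_genotypes, control_genotypes)
    residual_norms = np.asarray(residual_norms, dtype=float)
    qs = np.quantile(residual_norms, np.linspace(1.0, 0.0, n_thresholds + 1))
    best_lambda = np.inf
    for thr in qs:
        idx = np.flatnonzero(residual_norms <= thr)
        if len(idx) <= min_controls:
            break
        stats = assoc_fn(case_genotypes, control_genotypes[idx])
        lam = genomic_inflation(stats)
        best_lambda = min(best_lambda, lam)
        if lam < lambda_max:
            return MatchResult(
                residual_norms=residual_norms,
                selected=idx,
                threshold=float(thr),
                genomic_lambda=lam,
                cluster_id=cluster_id,
            )
    raise MatchingError(
        f"no threshold gave lambda < {lambda_max} with > {min_controls} controls "
        f"(best lambda {best_lambda:.3f})"
    )
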