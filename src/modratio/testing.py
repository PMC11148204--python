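"""The modularization test: statistic, corrections, p-values, decisions.

Under a candidate modularization the moment ratios indexed by each
equality set share one value. The statistic T is half the difference
between the total weighted sum of squared ratios and the weighted
within-set means, i.e. a precision-weighted within-set dispersion.
Under the null, with independent ratios and exact variances, T follows
a gamma distribution with shape zeta = (d_x0 - d_x)/2 and scale 1. Two
corrections keep the finite-sample test conservative: an eigenvalue
bound lambda_max for correlated ratios, and a floor alpha_min on the
nominal level that accounts for denominators near zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .estimators import (
    DEFAULT_THETA,
    LambdaMode,
    PairMomentEstimate,
    ProductCovariance,
    RatioCovariance,
    RatioVector,
    nested_products,
    product_covariance,
    ratio_covariance,
    ratio_vector,
    vec_index,
)
from .samples import SampleMatrix
from .structure import IndexSetFamily, Modularization, degrees_of_freedom, index_sets

__all__ = [
    "TestOptions",
    "TestResult",
    "BMatrix",
    "b_matrix",
    "test_statistic",
    "lambda_max",
    "alpha_min",
    "gamma_pvalue",
    "decide",
    "estimate_ratios",
    "test_modularization",
    "test_candidates",
    "rank2_residual",
]


@dataclass
class TestOptions:
    """Parameters of the decision rule.

    alpha_star is the overall nominal significance level, split evenly
    over ``n_hypotheses`` candidates tested on the same samples.
    """

    theta: float = DEFAULT_THETA
    lambda_mode: LambdaMode = LambdaMode.CORRECTED
    alpha_star: float = 0.01
    n_hypotheses: int = 1
    apply_lambda_max: bool = True

    def __post_init__(self):
        self.lambda_mode = LambdaMode(self.lambda_mode)
        if not 0 < self.alpha_star < 1:
            raise ValueError("alpha_star must lie in (0, 1)")
        if self.n_hypotheses < 1:
            raise ValueError("n_hypotheses must be at least 1")


@dataclass
class TestResult:
    """Outcome of testing one candidate modularization."""

    label: str
    T: float
    zeta: float
    p_value: float
    lambda_max: float
    alpha_min: float
    reject: bool
    family: IndexSetFamily


@dataclass
class BMatrix:
    """Symmetric moment-ratio matrix with the cutoff mask.

    Entry (k, l) estimates E[s_k s_l s_ref] / (E[s_k s_ref] E[s_l s_ref]);
    the diagonal is undefined (NaN). Within a functional module all rows
    restricted to outside columns coincide in the population.
    """

    entries: np.ndarray
    cutoff_mask: np.ndarray


def b_matrix(s: SampleMatrix, theta: float = DEFAULT_THETA) -> BMatrix:
    """Estimate the full moment-ratio matrix of a centered sample matrix."""
    d = s.d
    if d < 4:
        raise ValueError("need at least 4 components")
    rv, _, _ = estimate_ratios(s, theta=theta, lambda_mode=LambdaMode.ASYMPTOTIC)
    n = d - 1
    entries = np.full((n, n), np.nan)
    mask = np.zeros((n, n), dtype=bool)
    for k in range(1, n + 1):
        for l in range(k + 1, n + 1):
            v = vec_index(k, l, d)
            entries[k - 1, l - 1] = entries[l - 1, k - 1] = rv.b_hat[v - 1]
            cut = bool(rv.cutoff_mask[v - 1])
            mask[k - 1, l - 1] = mask[l - 1, k - 1] = cut
    return BMatrix(entries=entries, cutoff_mask=mask)


def _weights(sigma_diag: np.ndarray) -> np.ndarray:
    """Inverse variances with 1/inf := 0."""
    w = np.zeros_like(sigma_diag)
    finite = np.isfinite(sigma_diag) & (sigma_diag > 0)
    w[finite] = 1.0 / sigma_diag[finite]
    return w


def test_statistic(rv: RatioVector, rc: RatioCovariance, f: IndexSetFamily) -> float:
    """Precision-weighted within-set dispersion of the ratio vector.

    T = 1/2 sum_k w_k b_k^2 - 1/2 sum_c (sum_{l in X_c} w_l b_l)^2 / sum_{l in X_c} w_l

    with w = 1/diag(Sigma) and 1/inf := 0. Singleton sets cancel exactly
    between the two sums; cut-off ratios carry zero weight and drop out.
    T is non-negative by the variance-decomposition identity.
    """
    if rv.d_x0 != f.d_x0:
        raise ValueError("ratio vector and index family disagree on d_x0")
    w = _weights(np.diag(rc.sigma))
    b = rv.b_hat
    total = 0.5 * float(np.sum(w * b * b))
    between = 0.0
    for xc in f.sets:
        idx = np.fromiter((v - 1 for v in xc), dtype=int)
        sw = float(np.sum(w[idx]))
        if sw > 0:
            between += float(np.sum(w[idx] * b[idx])) ** 2 / sw
    t = total - 0.5 * between
    return max(t, 0.0)


def lambda_max(rc: RatioCovariance, f: IndexSetFamily) -> float:
    """Largest eigenvalue of the correlation submatrix of constrained ratios.

    Scaling the covariance by this factor keeps the gamma-tail test
    conservative when ratios are correlated. Ratios in singleton sets
    and cut-off ratios are excluded (diagonal scaler 0); with no
    surviving constrained ratio the test is vacuous and the factor is 1.
    """
    sigma = rc.sigma
    d_x0 = sigma.shape[0]
    active = np.zeros(d_x0, dtype=bool)
    for xc in f.constrained_sets():
        for v in xc:
            active[v - 1] = True
    diag = np.diag(sigma)
    active &= np.isfinite(diag) & (diag > 0)
    if not np.any(active):
        return 1.0
    idx = np.where(active)[0]
    sub = sigma[np.ix_(idx, idx)]
    scale = 1.0 / np.sqrt(np.diag(sub))
    corr = sub * scale[:, None] * scale[None, :]
    return float(np.linalg.eigvalsh(corr)[-1])


def alpha_min(d_x0: int, theta: float) -> float:
    """Smallest admissible nominal level for the given cutoff.

    Accounts for the probability that a truly nonzero denominator is cut
    off (or a near-zero one survives); for theta <= 1 the bound is
    vacuous and 0 is returned.
    """
    if theta <= 1:
        return 0.0
    if d_x0 == 0:
        return 0.0
    log_term = d_x0 * (
        np.log(special.erf((theta - 1) / np.sqrt(2)))
        + np.log(special.erf(6 / np.sqrt(2)))
    )
    return float(-special.expm1(log_term))


def gamma_pvalue(t: float, zeta: float) -> float:
    """Upper tail of Gamma(zeta, 1) at t; a vacuous test (zeta = 0) gives 1."""
    if t < 0:
        raise ValueError("T must be non-negative")
    if zeta < 0:
        raise ValueError("zeta must be non-negative")
    if zeta == 0:
        return 1.0
    # regularized upper incomplete gamma; accurate far below 1e-10
    return float(special.gammaincc(zeta, t))


def decide(p: float, opts: TestOptions, a_min: float) -> bool:
    """Reject iff p <= alpha_Gamma / n_hypotheses.

    alpha_Gamma = (alpha_star - alpha_min) / (1 - alpha_min) deflates the
    nominal level by the unavoidable error mass of the cutoff rule.
    """
    if opts.alpha_star <= a_min:
        raise ValueError(
            "nominal level below minimal level; increase alpha or reduce d_x0"
        )
    alpha_gamma = (opts.alpha_star - a_min) / (1.0 - a_min)
    return p <= alpha_gamma / opts.n_hypotheses


def estimate_ratios(
    s: SampleMatrix,
    theta: float = DEFAULT_THETA,
    lambda_mode: LambdaMode = LambdaMode.CORRECTED,
) -> tuple[RatioVector, RatioCovariance, list[PairMomentEstimate]]:
    """Estimate all nested-moment ratios of a sample matrix at once.

    Returns the cut-off ratio vector, its full covariance matrix and the
    underlying pair estimates, ordered by ratio index. The estimates can
    be reused to score many candidate modularizations against the same
    samples.
    """
    d = s.d
    estimates = [
        nested_products(s, k, l)
        for k in range(1, d - 1)
        for l in range(k + 1, d)
        if l <= d - 1
    ]
    estimates.sort(key=lambda e: e.v)
    cov = ProductCovariance()
    for i, e_i in enumerate(estimates):
        for e_j in estimates[i:]:
            cov.blocks[(e_i.v, e_j.v)] = product_covariance(e_i, e_j)
    rv = ratio_vector(estimates, cov, theta)
    rc = ratio_covariance(estimates, cov, rv, lambda_mode)
    return rv, rc, estimates


def _score_family(
    rv: RatioVector,
    rc: RatioCovariance,
    f: IndexSetFamily,
    opts: TestOptions,
    label: str,
) -> TestResult:
    lam_max = lambda_max(rc, f) if opts.apply_lambda_max else 1.0
    scaled = RatioCovariance(sigma=rc.sigma * lam_max, lambda_mode=rc.lambda_mode)
    t = test_statistic(rv, scaled, f)
    zeta = degrees_of_freedom(f)
    p = gamma_pvalue(t, zeta)
    a_min = alpha_min(f.d_x0, opts.theta)
    reject = decide(p, opts, a_min)
    return TestResult(
        label=label,
        T=t,
        zeta=zeta,
        p_value=p,
        lambda_max=lam_max,
        alpha_min=a_min,
        reject=reject,
        family=f,
    )


def test_modularization(
    s: SampleMatrix, m: Modularization, opts: TestOptions | None = None
) -> TestResult:
    """Run the full pipeline for one candidate modularization."""
    opts = opts or TestOptions()
    rv, rc, _ = estimate_ratios(s, theta=opts.theta, lambda_mode=opts.lambda_mode)
    f = index_sets(m, s.d)
    return _score_family(rv, rc, f, opts, m.label)


def test_candidates(
    s: SampleMatrix, candidates: list[Modularization], opts: TestOptions | None = None
) -> list[TestResult]:
    """Test many candidates on the same samples, estimating moments once.

    ``n_hypotheses`` defaults to the number of candidates when the
    options leave it at 1.
    """
    opts = opts or TestOptions()
    if opts.n_hypotheses == 1 and len(candidates) > 1:
        opts = TestOptions(
            theta=opts.theta,
            lambda_mode=opts.lambda_mode,
            alpha_star=opts.alpha_star,
            n_hypotheses=len(candidates),
            apply_lambda_max=opts.apply_lambda_max,
        )
    rv, rc, _ = estimate_ratios(s, theta=opts.theta, lambda_mode=opts.lambda_mode)
    results = []
    for m in candidates:
        f = index_sets(m, s.d)
        results.append(_score_family(rv, rc, f, opts, m.label))
    return results


def rank2_residual(moment_matrix: np.ndarray) -> float:
    """Deviation of a population moment matrix from the rank-2 condition.

    For monomial sequences P_n (inside a module) and Q_m (outside) with
    P_1 = Q_1 = 1, a binary interface variable exists iff every moment
    E[P_n Q_m] is reproduced from the first two rows and columns through
    the inverse of the leading 2x2 block M. Returns the maximum absolute
    reconstruction error; exactly 0 (up to round-off) for any matrix of
    rank <= 2 with invertible leading block. Population-level oracle:
    operates on exact moments, not on finite-sample estimates.
    """
    e = np.asarray(moment_matrix, dtype=float)
    if e.ndim != 2 or e.shape[0] < 2 or e.shape[1] < 2:
        raise ValueError("need at least a 2x2 moment matrix")
    m = e[:2, :2]
    if abs(np.linalg.det(m)) < 1e-12 * max(1.0, float(np.abs(m).max()) ** 2):
        raise ValueError("condition inapplicable: leading 2x2 block is singular")
    recon = e[:, :2] @ np.linalg.inv(m) @ e[:2, :]
    return float(np.abs(e - recon).max())


def _gamma_sf_check(t: float, zeta: float) -> float:
    """Cross-check path via scipy.stats (kept for validation in tests)."""
    return float(stats.gamma.sf(t, a=zeta))
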