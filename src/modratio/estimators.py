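"""Moment-ratio estimators and their covariance.

A functional module with a binary interface variable forces ratios of
mixed moments of the observable components to coincide. This module
estimates those ratios from finite samples together with the
signal-to-noise statistic of each denominator, a finite-sample variance
inflation factor, and the (extended-real) covariance matrix of the
ratio vector. Ratios whose denominator cannot be distinguished from
zero are cut off: their value is set to 0 and their variance to +inf,
which removes them from the test statistic downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .samples import SampleMatrix

__all__ = [
    "LambdaMode",
    "PairMomentEstimate",
    "ProductCovariance",
    "RatioVector",
    "RatioCovariance",
    "DEFAULT_THETA",
    "XI_COEFFICIENTS",
    "vec_index",
    "ratio_count",
    "nested_products",
    "single_module_products",
    "product_covariance",
    "ratio_vector",
    "lambda_factor",
    "ratio_covariance",
    "check_autocorrelation",
]

#: Default cutoff for the denominator signal-to-noise statistic.
DEFAULT_THETA = 5.0

#: Polynomial coefficients of the finite-sample variance inflation factor.
XI_COEFFICIENTS = (1.367, 2.047, 4.735, -1.923, -1.231, 2.790)


class LambdaMode(str, Enum):
    """Variance inflation regime for the ratio covariance."""

    ASYMPTOTIC = "asymptotic"
    CORRECTED = "corrected"


@dataclass
class PairMomentEstimate:
    """Numerator/denominator sample moments for one ratio index.

    ``phi`` holds the per-term products: column 0 contributes to the
    numerator estimate, column 1 to the denominator estimate. The
    estimates are the column means.
    """

    v: int
    b1_hat: float
    b2_hat: float
    phi: np.ndarray  # (n_terms, 2)

    @property
    def n_terms(self) -> int:
        return self.phi.shape[0]


@dataclass
class ProductCovariance:
    """2x2 sample covariance blocks of the per-term products, keyed (v, w)."""

    blocks: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)

    def block(self, v: int, w: int) -> np.ndarray:
        if (v, w) in self.blocks:
            return self.blocks[(v, w)]
        return self.blocks[(w, v)].T


@dataclass
class RatioVector:
    """Estimated moment ratios with the denominator cutoff applied."""

    b_hat: np.ndarray
    rho: np.ndarray
    theta: float
    n_terms: int

    @property
    def d_x0(self) -> int:
        return self.b_hat.shape[0]

    @property
    def cutoff_mask(self) -> np.ndarray:
        """True where the ratio was cut off (denominator indistinct from 0)."""
        return np.abs(self.rho) < self.theta


@dataclass
class RatioCovariance:
    """Extended-real covariance of the ratio vector.

    Diagonal entries of cut-off ratios are +inf; their off-diagonal
    entries are 0. Wherever downstream formulas consume the inverse,
    1/inf is taken as 0.
    """

    sigma: np.ndarray
    lambda_mode: LambdaMode


def vec_index(k: int, l: int, d: int) -> int:
    """Map a component pair (k < l, both below the reference) to a ratio index.

    The map is the row-major enumeration of the strict upper triangle of
    the (d-1)x(d-1) ratio matrix and is bijective onto 1..(d-1)(d-2)/2.
    """
    if not (1 <= k < l <= d - 1):
        raise ValueError(f"invalid pair (k={k}, l={l}) for d={d}")
    return (d - 3) * (d - 2) // 2 - (d - 2 - k) * (d - 1 - k) // 2 + l - 1


def ratio_count(d: int) -> int:
    """Number of moment ratios for ``d`` components (reference included)."""
    return (d - 1) * (d - 2) // 2


def nested_products(s: SampleMatrix, k: int, l: int) -> PairMomentEstimate:
    """Per-term products for the nested-modularization moment ratio.

    The ratio for pair (k, l) is E[s_k s_l s_d] / (E[s_k s_d] E[s_l s_d])
    with s_d the reference component. The numerator is estimated from the
    odd-indexed samples; the denominator product pairs the first and
    second halves of the recording so that one product term estimates
    the product of the two second moments.
    """
    if not s.centered:
        raise ValueError("samples must be centered")
    d = s.d
    if not (1 <= k < l <= d - 1):
        raise ValueError(f"invalid pair (k={k}, l={l}) for d={d}")
    n_t = s.n_samples
    if n_t % 2 != 0 or n_t < 4:
        raise ValueError("need an even sample count of at least 4")
    half = n_t // 2
    sk, sl, sd = s.values[k - 1], s.values[l - 1], s.values[d - 1]

    phi = np.empty((half, 2))
    odd = slice(0, n_t, 2)  # 1-based odd samples
    phi[:, 0] = sk[odd] * sl[odd] * sd[odd]
    phi[:, 1] = sk[:half] * sd[:half] * sl[half:] * sd[half:]
    b1, b2 = phi.mean(axis=0)
    return PairMomentEstimate(v=vec_index(k, l, d), b1_hat=b1, b2_hat=b2, phi=phi)


def single_module_products(
    s: SampleMatrix, k: int, l: int, ref: int, sample_slice: slice | None = None
) -> PairMomentEstimate:
    """Per-term products for the single-module moment ratio E[s_k s_l]/E[s_k s_ref].

    Every sample contributes one product term. ``sample_slice`` restricts
    the estimate to a subset of samples, which the regulatory-network
    pipeline uses to estimate the two ratios of a subnetwork on disjoint
    halves of the recording (removing their correlation by construction).
    """
    if not s.centered:
        raise ValueError("samples must be centered")
    if len({k, l, ref}) != 3:
        raise ValueError("k, l, ref must be distinct components")
    sk = s.component(k)
    sl = s.component(l)
    sr = s.component(ref)
    if sample_slice is not None:
        sk, sl, sr = sk[sample_slice], sl[sample_slice], sr[sample_slice]
    phi = np.column_stack([sk * sl, sk * sr])
    b1, b2 = phi.mean(axis=0)
    return PairMomentEstimate(v=0, b1_hat=b1, b2_hat=b2, phi=phi)


def product_covariance(e_v: PairMomentEstimate, e_w: PairMomentEstimate) -> np.ndarray:
    """2x2 sample covariance block between the product terms of two ratios."""
    n = e_v.n_terms
    if e_w.n_terms != n:
        raise ValueError("estimates must share the same number of product terms")
    if n < 2:
        raise ValueError("need at least 2 product terms for a covariance")
    dev_v = e_v.phi - np.array([e_v.b1_hat, e_v.b2_hat])
    dev_w = e_w.phi - np.array([e_w.b1_hat, e_w.b2_hat])
    return dev_v.T @ dev_w / (n - 1)


def _rho_single(b2: float, var22: float, n_terms: int) -> float:
    """Signal-to-noise of one denominator estimate, b2 / SE(b2)."""
    if var22 <= 0.0:
        # degenerate: constant product terms
        return np.inf if b2 != 0.0 else 0.0
    return float(np.sqrt(n_terms / var22) * b2)


def ratio_vector(
    estimates: list[PairMomentEstimate],
    cov: ProductCovariance,
    theta: float = DEFAULT_THETA,
) -> RatioVector:
    """Assemble the cut-off ratio vector from pair estimates.

    A ratio is set to 0 when |rho| < theta (strict), i.e. when its
    denominator estimate is less than ``theta`` standard errors away
    from zero; the hard cutoff keeps the expectation of the estimated
    ratio finite.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    d_x0 = len(estimates)
    b_hat = np.zeros(d_x0)
    rho = np.zeros(d_x0)
    n_terms = estimates[0].n_terms
    for i, e in enumerate(estimates):
        var22 = cov.block(e.v, e.v)[1, 1]
        rho[i] = _rho_single(e.b2_hat, var22, n_terms)
        if np.abs(rho[i]) >= theta:
            b_hat[i] = e.b1_hat / e.b2_hat
    return RatioVector(b_hat=b_hat, rho=rho, theta=theta, n_terms=n_terms)


def lambda_factor(rho: float, mode: LambdaMode = LambdaMode.CORRECTED) -> float:
    """Finite-sample variance inflation for one surviving moment ratio.

    In the asymptotic regime the factor is exactly 1. The corrected
    regime evaluates an even polynomial in 6/rho fitted to the
    finite-sample variance of a normal ratio estimator; it approaches
    xi_0 = 1.367 as |rho| grows.
    """
    mode = LambdaMode(mode)
    if mode is LambdaMode.ASYMPTOTIC:
        return 1.0
    if rho == 0.0:
        raise ValueError("lambda correction undefined at rho = 0; cut off upstream")
    if np.isinf(rho):
        return XI_COEFFICIENTS[0]
    xi = XI_COEFFICIENTS
    u = (rho / 6.0) ** -2
    return xi[0] * (1.0 + sum(xi[n] * u**n for n in range(1, 6)))


def ratio_covariance(
    estimates: list[PairMomentEstimate],
    cov: ProductCovariance,
    rv: RatioVector,
    mode: LambdaMode = LambdaMode.CORRECTED,
) -> RatioCovariance:
    """Delta-method covariance of the ratio vector, with cutoffs as +inf/0.

    For two surviving ratios v, w with denominator estimates b2 and
    product-term covariance blocks S = Sigma'^{(v,w)} the entry is

        sqrt(lam_v lam_w) / (n b2_v b2_w) *
            (S_11 - r_w S_12 - r_v S_21 + r_v r_w S_22)

    where r = b1/b2 and n is the number of product terms per ratio.
    """
    mode = LambdaMode(mode)
    d_x0 = len(estimates)
    if rv.d_x0 != d_x0:
        raise ValueError("inconsistent dimensions")
    cut = rv.cutoff_mask
    lam = np.ones(d_x0)
    if mode is LambdaMode.CORRECTED:
        for i in range(d_x0):
            if not cut[i]:
                lam[i] = lambda_factor(rv.rho[i], mode)
    sigma = np.zeros((d_x0, d_x0))
    n = rv.n_terms
    for i in range(d_x0):
        if cut[i]:
            sigma[i, i] = np.inf
            continue
        for j in range(i, d_x0):
            if cut[j]:
                continue
            e_i, e_j = estimates[i], estimates[j]
            blk = cov.block(e_i.v, e_j.v)
            ri = e_i.b1_hat / e_i.b2_hat
            rj = e_j.b1_hat / e_j.b2_hat
            val = (
                np.sqrt(lam[i] * lam[j])
                / (n * e_i.b2_hat * e_j.b2_hat)
                * (blk[0, 0] - rj * blk[0, 1] - ri * blk[1, 0] + ri * rj * blk[1, 1])
            )
            sigma[i, j] = val
            sigma[j, i] = val
    # clip tiny negative variances arising from floating-point cancellation
    diag = np.diag(sigma).copy()
    finite = np.isfinite(diag)
    diag[finite] = np.maximum(diag[finite], 0.0)
    np.fill_diagonal(sigma, diag)
    return RatioCovariance(sigma=sigma, lambda_mode=mode)


def check_autocorrelation(series: np.ndarray, lag: int = 1) -> float:
    """Normalized autocovariance at ``lag``; adequacy gate for i.i.d. sampling.

    Recordings are subsampled in time until this drops below a small
    threshold (0.05 in the applications) before the test is applied.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size <= lag:
        raise ValueError("series must be 1-D and longer than the lag")
    x = x - x.mean()
    var = np.dot(x, x) / x.size
    if var == 0:
        raise ValueError("series has zero variance")
    return float(np.dot(x[:-lag], x[lag:]) / x.size / var)
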