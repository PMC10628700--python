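"""Univariable two-sample MR estimators and diagnostics.

All estimators consume a single-exposure :class:`~cismr.sumstats.HarmonizedSet`
of J allele-aligned per-variant associations (beta_Xj, sigma_Xj) and
(beta_Yj, sigma_Yj), and return an :class:`MREstimate` of the causal effect
theta of a 1-SD exposure change on the outcome (log-odds for binary
outcomes).

Implemented methods
-------------------
* per-variant Wald ratios with first-order (NOME) weights sigma_Yj^-2,
* inverse-variance-weighted (IVW) pooling, fixed or multiplicative
  random effects (overdispersion phi = max(1, Q/(J-1))),
* profile maximum likelihood under the bivariate normal measurement model,
* the weighted median (consistent while valid instruments contribute more
  than half the weight), with a parametric-bootstrap standard error,
* MR-Egger regression with its intercept test for directional pleiotropy,
* Cochran's Q heterogeneity statistic and leave-one-out re-estimation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .sumstats import HarmonizedSet

__all__ = [
    "RatioEstimates",
    "MREstimate",
    "ratio_estimates",
    "ivw",
    "max_likelihood",
    "weighted_median",
    "weighted_median_point",
    "egger",
    "leave_one_out",
    "to_odds_ratio",
    "wald_ratio",
]

Z95 = stats.norm.ppf(0.975)


@dataclass
class RatioEstimates:
    """Per-variant Wald ratios beta_Y/beta_X with first-order SEs and weights."""

    variants: list[str]
    ratio: np.ndarray
    ratio_se: np.ndarray

    @property
    def weight(self) -> np.ndarray:
        return 1.0 / self.ratio_se**2


@dataclass
class MREstimate:
    """One method's causal estimate with its inference and heterogeneity."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    q_stat: float | None = None
    q_pvalue: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pvalue: float | None = None
    overdispersion_phi: float | None = None

    def __post_init__(self) -> None:
        if self.se <= 0 or not np.isfinite(self.se):
            raise ValueError("se must be positive and finite")
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


def _check_single_exposure(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if h.n_exposures != 1:
        raise ValueError("estimator requires a single-exposure HarmonizedSet")
    bx = h.exposure_betas.reshape(-1)
    sx = h.exposure_ses.reshape(-1)
    return bx, sx, h.outcome_betas, h.outcome_ses


def ratio_estimates(h: HarmonizedSet) -> RatioEstimates:
    """Wald ratios beta_Yj / beta_Xj with first-order SEs sigma_Yj/|beta_Xj|."""
    bx, _, by, sy = _check_single_exposure(h)
    zero = np.flatnonzero(bx == 0)
    if zero.size:
        raise ValueError(f"zero exposure beta for variant {h.variants[zero[0]]!r}")
    return RatioEstimates(list(h.variants), by / bx, sy / np.abs(bx))


def wald_ratio(h: HarmonizedSet) -> MREstimate:
    """Single-SNP causal estimate (J = 1), normal inference."""
    r = ratio_estimates(h)
    if len(r.variants) != 1:
        raise ValueError("wald_ratio is for J = 1; use ivw for J >= 2")
    beta, se = float(r.ratio[0]), float(r.ratio_se[0])
    p = 2 * stats.norm.sf(abs(beta / se))
    return MREstimate("wald_ratio", beta, se, beta - Z95 * se, beta + Z95 * se, p, 1)


def ivw(h: HarmonizedSet, model: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted estimate of the causal effect.

    Equivalent to the zero-intercept weighted least-squares slope of
    beta_Y on beta_X with weights sigma_Y^-2.  Under ``multiplicative_random``
    (the primary model here) the fixed-effect SE is inflated by
    sqrt(phi), phi = max(1, Q/(J-1)), so heterogeneity between variants
    widens but never narrows the interval.
    """
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW model {model!r}")
    r = ratio_estimates(h)
    j = len(r.variants)
    if j < 2:
        raise ValueError("IVW requires J >= 2 variants; use wald_ratio for a single SNP")
    w = r.weight
    beta = float(np.sum(w * r.ratio) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (r.ratio - beta) ** 2))
    phi = max(1.0, q / (j - 1))
    se = se_fixed * np.sqrt(phi) if model == "multiplicative_random" else se_fixed
    p = 2 * stats.norm.sf(abs(beta / se))
    return MREstimate(
        method="ivw_mre" if model == "multiplicative_random" else "ivw_fe",
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pvalue=float(p),
        n_snps=j,
        q_stat=q,
        q_pvalue=float(stats.chi2.sf(q, j - 1)),
        overdispersion_phi=phi,
    )


def _profile_negloglik(theta: float, bx, sx, by, sy) -> float:
    # profiling the latent instrument effects xi_j leaves a weighted
    # residual of beta_Y - theta*beta_X with variance sigma_Y^2 + theta^2 sigma_X^2
    return float(0.5 * np.sum((by - theta * bx) ** 2 / (sy**2 + theta**2 * sx**2)))


def max_likelihood(h: HarmonizedSet, xtol: float = 1e-10) -> MREstimate:
    """Maximum-likelihood estimate under the bivariate normal model.

    beta_Xj ~ N(xi_j, sigma_Xj^2) and beta_Yj ~ N(theta*xi_j, sigma_Yj^2),
    independent across variants and between sides.  The latent xi_j are
    profiled out analytically; theta is found by 1-D minimisation and its
    SE comes from the curvature (observed information) of the profile
    log-likelihood at the optimum.
    """
    bx, sx, by, sy = _check_single_exposure(h)
    if len(bx) < 2:
        raise ValueError("maximum likelihood requires J >= 2 variants")
    start = ivw(h, "fixed").beta
    res = optimize.minimize_scalar(
        _profile_negloglik,
        bracket=(start - 1.0, start + 1.0),
        args=(bx, sx, by, sy),
        method="brent",
        options={"xtol": xtol},
    )
    if not res.success or not np.isfinite(res.x):
        raise RuntimeError(f"ML optimizer failed to converge: {res}")
    theta = float(res.x)
    eps = 1e-5 * (abs(theta) + 1.0)
    info = (
        _profile_negloglik(theta + eps, bx, sx, by, sy)
        - 2 * _profile_negloglik(theta, bx, sx, by, sy)
        + _profile_negloglik(theta - eps, bx, sx, by, sy)
    ) / eps**2
    if info <= 0:
        raise RuntimeError("non-positive observed information at the ML optimum")
    se = float(info**-0.5)
    p = 2 * stats.norm.sf(abs(theta / se))
    return MREstimate("max_likelihood", theta, se, theta - Z95 * se, theta + Z95 * se, float(p), len(bx))


def weighted_median_point(ratio: np.ndarray, weight: np.ndarray) -> float:
    """Weight-0.5 quantile of the ratio distribution by linear interpolation.

    Ratios are sorted ascending; with standardized cumulative weights
    s_j = (sum_{k<=j} w_k - w_j/2) / sum w, the estimate interpolates the
    ordered ratios at s = 0.5.
    """
    order = np.argsort(ratio)
    r = np.asarray(ratio, dtype=float)[order]
    w = np.asarray(weight, dtype=float)[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, r))


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int | None = None) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Consistent when instruments carrying more than half the total weight
    are valid.  The SE is the standard deviation of the estimate over
    ``n_boot`` replicates resampling beta_Xj and beta_Yj from normals
    centred at their observed values; ``seed`` fixes the stream.
    """
    bx, sx, by, sy = _check_single_exposure(h)
    j = len(bx)
    if j < 3:
        raise ValueError("weighted median requires J >= 3 variants")
    if seed is None:
        raise ValueError("weighted_median requires an explicit seed for reproducibility")
    r = ratio_estimates(h)
    beta = weighted_median_point(r.ratio, r.weight)
    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, j))
    by_b = rng.normal(by, sy, size=(n_boot, j))
    boots = np.empty(n_boot)
    for i in range(n_boot):
        ratio_b = by_b[i] / bx_b[i]
        weight_b = (np.abs(bx_b[i]) / sy) ** 2
        boots[i] = weighted_median_point(ratio_b, weight_b)
    se = float(np.std(boots, ddof=1))
    p = 2 * stats.norm.sf(abs(beta / se))
    return MREstimate("weighted_median", beta, se, beta - Z95 * se, beta + Z95 * se, float(p), j)


def egger(h: HarmonizedSet) -> MREstimate:
    """MR-Egger regression: WLS of beta_Y on beta_X with a free intercept.

    The slope estimates the causal effect under InSIDE; the intercept
    estimates average directional pleiotropy and its two-sided t test
    (J - 2 df) is the pleiotropy test.  Variant pairs are first oriented
    so every beta_X is positive (Egger is not orientation-invariant).
    """
    bx, _, by, sy = _check_single_exposure(h)
    j = len(bx)
    if j < 3:
        raise ValueError("MR-Egger requires J >= 3 variants")
    sign = np.where(bx < 0, -1.0, 1.0)
    x = bx * sign
    y = by * sign
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in exposure betas; Egger slope not identified")
    w = 1.0 / sy**2
    design = np.column_stack([np.ones(j), x])
    xtwx = design.T @ (w[:, None] * design)
    xtwy = design.T @ (w * y)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = y - design @ coef
    q = float(np.sum(w * resid**2))
    phi = max(1.0, q / (j - 2))
    cov = np.linalg.inv(xtwx) * phi
    slope, intercept = float(coef[1]), float(coef[0])
    se_slope = float(np.sqrt(cov[1, 1]))
    se_int = float(np.sqrt(cov[0, 0]))
    tdist = stats.t(j - 2)
    t95 = tdist.ppf(0.975)
    p_slope = 2 * tdist.sf(abs(slope / se_slope))
    p_int = 2 * tdist.sf(abs(intercept / se_int))
    return MREstimate(
        method="egger",
        beta=slope,
        se=se_slope,
        ci_low=slope - t95 * se_slope,
        ci_high=slope + t95 * se_slope,
        pvalue=float(p_slope),
        n_snps=j,
        q_stat=q,
        q_pvalue=float(stats.chi2.sf(q, j - 2)),
        egger_intercept=intercept,
        egger_intercept_se=se_int,
        egger_intercept_pvalue=float(p_int),
        overdispersion_phi=phi,
    )


def leave_one_out(h: HarmonizedSet) -> list[tuple[str, MREstimate]]:
    """IVW (multiplicative random effects) re-estimated leaving out each variant."""
    if h.n_snps < 3:
        raise ValueError("leave-one-out requires J >= 3 variants")
    out = []
    for i, v in enumerate(h.variants):
        keep = [k for k in range(h.n_snps) if k != i]
        out.append((v, ivw(h.subset(keep), "multiplicative_random")))
    return out


def to_odds_ratio(e: MREstimate) -> tuple[float, float, float]:
    """Exponentiate a log-odds estimate and its CI to the odds-ratio scale."""
    return float(np.exp(e.beta)), float(np.exp(e.ci_low)), float(np.exp(e.ci_high))


def estimates_table(estimates: Sequence[MREstimate], odds_ratio: bool = False):
    """Results table (one row per method) mirroring the standard MR layout."""
    import pandas as pd

    rows = []
    for e in estimates:
        row = {
            "method": e.method,
            "beta": e.beta,
            "se": e.se,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
            "pvalue": e.pvalue,
            "n_snps": e.n_snps,
            "Q": e.q_stat,
            "P_Q": e.q_pvalue,
            "egger_intercept": e.egger_intercept,
            "P_pleiotropy": e.egger_intercept_pvalue,
        }
        if odds_ratio:
            orv, lo, hi = to_odds_ratio(e)
            row.update({"OR": orv, "OR_ci_low": lo, "OR_ci_high": hi})
        rows.append(row)
    return pd.DataFrame(rows)
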