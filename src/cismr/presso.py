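"""MR-PRESSO: residual-sum global test, per-variant outlier test, and
distortion test for horizontal pleiotropy.

The observed residual sum of squares is built from leave-one-out IVW
slopes: RSS_j = w_j (beta_Yj - theta_(-j) beta_Xj)^2 with w_j = sigma_Yj^-2,
so each variant is scored against a fit it did not influence.  The null
distribution of the total (and of each per-variant term) is simulated
parametrically by redrawing the summary statistics from their assumed
normal sampling distributions; outliers are variants whose per-term
empirical p falls below a Bonferroni-adjusted threshold.  The distortion
test compares the shift between the raw and outlier-corrected IVW
estimates against the shift induced by removing equally many variants at
random.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimators import MREstimate, ivw
from .sumstats import HarmonizedSet

__all__ = ["PressoResult", "presso_run"]


@dataclass
class PressoResult:
    rss_observed: float
    global_pvalue: float
    per_snp_pvalues: np.ndarray
    outlier_ids: list[str]
    beta_raw: MREstimate
    beta_corrected: MREstimate
    distortion_pvalue: float | None
    n_sim: int
    seed: int


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """IVW slope excluding each variant in turn; supports (n_sim, J) input."""
    a = np.sum(w * by * bx, axis=-1, keepdims=True)
    b = np.sum(w * bx**2, axis=-1, keepdims=True)
    return (a - w * by * bx) / (b - w * bx**2)


def presso_run(
    h: HarmonizedSet,
    n_sim: int = 1000,
    significance: float = 0.05,
    seed: int | None = None,
) -> PressoResult:
    """Run the global, outlier and distortion tests on a harmonized set.

    Requires J >= 4 (each leave-one-out slope then rests on >= 3 variants)
    and ``n_sim >= 100``.  Empirical p-values carry the (r+1)/(n+1)
    correction, so the smallest attainable p is 1/(n_sim+1).  Outliers are
    variants with per-term p below ``significance``/J; the corrected
    estimate is multiplicative-random-effects IVW on the remainder.
    """
    if h.n_snps < 4:
        raise ValueError("MR-PRESSO requires J >= 4 variants")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    if seed is None:
        raise ValueError("presso_run requires an explicit seed")
    bx = h.exposure_betas.reshape(-1)
    sx = h.exposure_ses.reshape(-1)
    by = h.outcome_betas
    sy = h.outcome_ses
    j = h.n_snps
    w = 1.0 / sy**2

    theta_loo = _loo_slopes(bx, by, w)
    rss_j = w * (by - theta_loo * bx) ** 2
    rss_observed = float(np.sum(rss_j))

    rng = np.random.default_rng(seed)
    bx_s = rng.normal(bx, sx, size=(n_sim, j))
    by_s = rng.normal(theta_loo * bx, sy, size=(n_sim, j))
    theta_loo_s = _loo_slopes(bx_s, by_s, w)
    rss_j_s = w * (by_s - theta_loo_s * bx_s) ** 2
    rss_s = np.sum(rss_j_s, axis=1)

    global_pvalue = float((1 + np.sum(rss_s >= rss_observed)) / (n_sim + 1))
    per_snp_pvalues = (1 + np.sum(rss_j_s >= rss_j, axis=0)) / (n_sim + 1)
    outlier_mask = per_snp_pvalues < significance / j
    outlier_ids = [v for v, o in zip(h.variants, outlier_mask) if o]

    beta_raw = ivw(h, "multiplicative_random")
    keep = [i for i in range(j) if not outlier_mask[i]]
    if len(keep) < 2:
        raise ValueError("all (or nearly all) variants flagged as outliers; no estimable corrected set")
    beta_corrected = ivw(h.subset(keep), "multiplicative_random")

    distortion_pvalue = None
    n_out = int(outlier_mask.sum())
    if n_out:
        observed_shift = beta_raw.beta - beta_corrected.beta
        shifts = np.empty(n_sim)
        for i in range(n_sim):
            drop = rng.choice(j, size=n_out, replace=False)
            keep_i = np.setdiff1d(np.arange(j), drop)
            w_k = w[keep_i]
            shifts[i] = beta_raw.beta - np.sum(w_k * by[keep_i] * bx[keep_i]) / np.sum(w_k * bx[keep_i] ** 2)
        distortion_pvalue = float((1 + np.sum(np.abs(shifts) >= abs(observed_shift))) / (n_sim + 1))

    return PressoResult(
        rss_observed=rss_observed,
        global_pvalue=global_pvalue,
        per_snp_pvalues=per_snp_pvalues,
        outlier_ids=outlier_ids,
        beta_raw=beta_raw,
        beta_corrected=beta_corrected,
        distortion_pvalue=distortion_pvalue,
        n_sim=n_sim,
        seed=seed,
    )
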