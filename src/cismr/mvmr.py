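"""Multivariable MR and two-step network mediation.

Multivariable MR regresses the per-variant outcome associations jointly on
several exposures' associations (zero intercept, weights sigma_Yj^-2),
giving each exposure's *direct* effect conditional on the others.  The
two-step mediation decomposition multiplies the exposure->mediator effect
(a) by the mediator->outcome effect (b) to form the indirect effect, and
reports the proportion of the total effect mediated, with a delta-method
(or optional Monte-Carlo) confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimators import MREstimate, Z95
from .sumstats import HarmonizedSet

__all__ = ["MVMREstimate", "MediationResult", "mvmr_fit", "mediation_two_step", "attenuation"]


@dataclass
class MVMREstimate:
    """Direct effects of K exposures from one joint weighted regression."""

    exposures: list[str]
    betas: np.ndarray
    ses: np.ndarray
    pvalues: np.ndarray
    n_snps: int
    q_stat: float
    overdispersion_phi: float

    def estimate_for(self, exposure: str) -> MREstimate:
        """One exposure's direct effect wrapped as an MREstimate."""
        k = self.exposures.index(exposure)
        b, s = float(self.betas[k]), float(self.ses[k])
        return MREstimate(
            method="mvmr",
            beta=b,
            se=s,
            ci_low=b - Z95 * s,
            ci_high=b + Z95 * s,
            pvalue=float(self.pvalues[k]),
            n_snps=self.n_snps,
            overdispersion_phi=self.overdispersion_phi,
        )

    @property
    def conditioned_on(self) -> list[str]:
        return self.exposures[1:]


@dataclass
class MediationResult:
    """Total/indirect decomposition with proportion mediated (percent)."""

    total: MREstimate
    step1: MREstimate  # exposure -> mediator (a)
    step2: MREstimate  # mediator -> outcome (b)
    indirect: float
    indirect_se: float
    proportion_mediated: float | None  # percent
    proportion_ci: tuple[float, float] | None  # percent
    method_note: str


def mvmr_fit(h: HarmonizedSet) -> MVMREstimate:
    """Zero-intercept WLS of outcome betas on the K exposure beta columns.

    Weights are sigma_Yj^-2; standard errors carry the same multiplicative
    overdispersion floor max(1, Q/(J-K)) as univariable random-effects IVW,
    with normal p-values.  Requires J > K and a full-rank exposure matrix
    (a rank-deficient design raises, naming the collinear columns).  With
    K = 1 the fit reduces exactly to univariable random-effects IVW.
    """
    x = h.exposure_betas
    if x.ndim == 1:
        x = x.reshape(-1, 1)
    j, k = x.shape
    if j <= k:
        raise ValueError(f"mvmr_fit requires J > K (J={j}, K={k})")
    if np.linalg.matrix_rank(x) < k:
        corr = np.corrcoef(x, rowvar=False)
        pairs = [
            (h.exposure_labels[a], h.exposure_labels[b])
            for a in range(k)
            for b in range(a + 1, k)
            if abs(corr[a, b]) > 0.999
        ]
        raise ValueError(f"rank-deficient exposure matrix; collinear exposures: {pairs or h.exposure_labels}")
    w = 1.0 / h.outcome_ses**2
    xtwx = x.T @ (w[:, None] * x)
    xtwy = x.T @ (w * h.outcome_betas)
    betas = np.linalg.solve(xtwx, xtwy)
    resid = h.outcome_betas - x @ betas
    q = float(np.sum(w * resid**2))
    phi = max(1.0, q / (j - k))
    cov = np.linalg.inv(xtwx) * phi
    ses = np.sqrt(np.diag(cov))
    pvalues = 2 * stats.norm.sf(np.abs(betas / ses))
    return MVMREstimate(
        exposures=list(h.exposure_labels) or [f"x{i}" for i in range(k)],
        betas=betas,
        ses=ses,
        pvalues=pvalues,
        n_snps=j,
        q_stat=q,
        overdispersion_phi=phi,
    )


def mediation_two_step(
    total: MREstimate,
    a: MREstimate,
    b: MREstimate,
    ci_method: str = "delta",
    n_draws: int = 100_000,
    seed: int = 0,
) -> MediationResult:
    """Product-of-coefficients mediation from three MR estimates.

    indirect = a*b with delta-method SE sqrt(a^2 se_b^2 + b^2 se_a^2);
    proportion mediated = a*b / total, reported as a percentage with a 95%
    CI by the delta method treating the three estimates as independent
    (``ci_method='delta'``), or by Monte-Carlo propagation
    (``ci_method='montecarlo'``).  A zero total effect leaves the
    proportion undefined (None).
    """
    ab = a.beta * b.beta
    ab_se = float(np.sqrt(a.beta**2 * b.se**2 + b.beta**2 * a.se**2))
    if total.beta == 0:
        return MediationResult(total, a, b, ab, ab_se, None, None, "undefined: zero total effect")
    prop = ab / total.beta
    if ci_method == "delta":
        var = (
            (b.beta / total.beta) ** 2 * a.se**2
            + (a.beta / total.beta) ** 2 * b.se**2
            + (ab / total.beta**2) ** 2 * total.se**2
        )
        half = Z95 * np.sqrt(var)
        ci = (100 * (prop - half), 100 * (prop + half))
        note = "delta-method CI, independent estimates"
    elif ci_method == "montecarlo":
        rng = np.random.default_rng(seed)
        props = (
            rng.normal(a.beta, a.se, n_draws)
            * rng.normal(b.beta, b.se, n_draws)
            / rng.normal(total.beta, total.se, n_draws)
        )
        lo, hi = np.percentile(props, [2.5, 97.5])
        ci = (100 * float(lo), 100 * float(hi))
        note = f"Monte-Carlo percentile CI ({n_draws} draws, seed {seed})"
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return MediationResult(total, a, b, ab, ab_se, 100 * prop, ci, note)


def attenuation(total_beta: float, adjusted_beta: float) -> float:
    """Percent attenuation of an effect after adjustment: 100*(1 - adj/total)."""
    if total_beta == 0:
        raise ValueError("attenuation undefined for zero total effect")
    return 100.0 * (1.0 - adjusted_beta / total_beta)
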