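"""Repeated-simulation studies of estimator behaviour.

These routines run the full generate -> harmonize -> estimate path many
times under controlled conditions and summarise operating characteristics:
type-I error of the random-effects IVW test, estimator consistency, the
weighted-median breakdown as invalid instruments accumulate weight,
MR-PRESSO outlier detection, the mediator-driven sign reversal, and
coverage of the mediation proportion's confidence interval.

Precision conventions
---------------------
Calibration scenarios (null rejection, consistency, PRESSO) use the
generator's default sampling noise, which follows the nominal sample sizes
of the emulated consortium GWAS.  The weighted-median breakdown sweep
instead uses high-precision instruments (equal weights, small SEs): the
breakdown point is a large-sample property of the weight fraction carried
by invalid instruments, and shrinking the sampling noise keeps the sweep's
answer from being dominated by finite-sample scatter rather than the
boundary itself.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .estimators import ivw, weighted_median_point, ratio_estimates
from .mvmr import mediation_two_step, mvmr_fit
from .presso import presso_run
from .simulate import MediatorChain, ScenarioConfig, generate_mediation_scenario, generate_pair
from .sumstats import harmonize_multi, harmonize_pair

__all__ = [
    "weighted_median_sweep",
    "breakdown_fraction",
    "null_rejection_rate",
    "estimator_consistency",
    "presso_outlier_detection",
    "presso_null_rejection",
    "sign_reversal_rate",
    "mediation_recovery",
]

_MAX_SEED = 2**31 - 1


def _subseeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, _MAX_SEED, size=n)


def _harmonized(config: ScenarioConfig):
    exposure, outcome, truth = generate_pair(config)
    return harmonize_pair(exposure, outcome), truth


def weighted_median_sweep(
    fractions: np.ndarray | None = None,
    n_rep: int = 1000,
    seed: int = 0,
    n_snps: int = 20,
    theta: float = 0.1,
    pleio_offset: float = 0.1,
    sigma: float = 0.002,
    xi_mean: float = 0.35,
) -> pd.DataFrame:
    """Bias of weighted median and IVW versus invalid-weight fraction.

    Instruments have equal latent effects (hence near-equal weights), so an
    invalid fraction of instruments carries the same fraction of total
    weight.  Returns one row per fraction with the mean estimates and the
    absolute bias of their means.
    """
    if fractions is None:
        fractions = np.arange(0.30, 0.601, 0.05)
    rows = []
    for fi, frac in enumerate(fractions):
        seeds = _subseeds(seed + fi, n_rep)
        wm = np.empty(n_rep)
        iv = np.empty(n_rep)
        for i in range(n_rep):
            cfg = ScenarioConfig(
                n_snps=n_snps,
                true_theta=theta,
                xi_mean=xi_mean,
                xi_sd=0.0,
                sigma_x=sigma,
                sigma_y=sigma,
                pleiotropy="directional",
                pleio_mean=pleio_offset,
                invalid_fraction=float(frac),
                seed=int(seeds[i]),
            )
            h, _ = _harmonized(cfg)
            r = ratio_estimates(h)
            wm[i] = weighted_median_point(r.ratio, r.weight)
            iv[i] = ivw(h).beta
        rows.append(
            {
                "invalid_weight_pct": round(100 * float(frac)),
                "wm_mean": wm.mean(),
                "wm_abs_bias": abs(wm.mean() - theta),
                "ivw_mean": iv.mean(),
                "ivw_abs_bias": abs(iv.mean() - theta),
                "n_rep": n_rep,
            }
        )
    return pd.DataFrame(rows)


def breakdown_fraction(sweep: pd.DataFrame, tol: float = 0.01) -> float:
    """Largest sampled invalid-weight percentage strictly below which the
    weighted-median bias stays under ``tol``.

    If every sampled fraction is unbiased the largest sampled fraction is
    returned.
    """
    df = sweep.sort_values("invalid_weight_pct").reset_index(drop=True)
    best = None
    for i in range(len(df)):
        if (df["wm_abs_bias"][:i] < tol).all():
            best = float(df["invalid_weight_pct"][i])
    if best is not None and (df["wm_abs_bias"] < tol).all():
        best = float(df["invalid_weight_pct"].iloc[-1])
    return best


def null_rejection_rate(
    n_rep: int = 2000, seed: int = 0, n_snps: int = 13, alpha: float = 0.05
) -> float:
    """Type-I error of the multiplicative random-effects IVW test at theta=0."""
    seeds = _subseeds(seed, n_rep)
    rejections = 0
    for i in range(n_rep):
        h, _ = _harmonized(ScenarioConfig(n_snps=n_snps, true_theta=0.0, seed=int(seeds[i])))
        rejections += ivw(h).pvalue < alpha
    return rejections / n_rep


def estimator_consistency(
    n_rep: int = 1000, seed: int = 0, theta: float = 0.1, n_snps: int = 13
) -> float:
    """Mean IVW estimate under a nonzero causal effect with strong instruments."""
    seeds = _subseeds(seed, n_rep)
    est = np.empty(n_rep)
    for i in range(n_rep):
        h, _ = _harmonized(ScenarioConfig(n_snps=n_snps, true_theta=theta, seed=int(seeds[i])))
        est[i] = ivw(h).beta
    return float(est.mean())


def _outlier_config(seed: int, n_snps: int = 11, theta: float = 0.1) -> ScenarioConfig:
    # one gross outlier whose Wald ratio sits near 1.0 against a clean
    # theta=0.1 background; the noise scale keeps the outlier's own residual
    # unmistakable (~26 sigma) while the slope distortion it induces on the
    # clean variants' leave-one-out residuals stays within their null spread
    return ScenarioConfig(
        n_snps=n_snps,
        true_theta=theta,
        xi_sd=0.05,
        sigma_x=0.012,
        sigma_y=0.012,
        outlier_fraction=1.0 / n_snps,
        outlier_effect=0.9 * 0.35,
        seed=seed,
    )


def presso_outlier_detection(
    n_rep: int = 100, seed: int = 0, n_sim: int = 1000
) -> tuple[float, float]:
    """MR-PRESSO detection of a single injected outlier.

    Returns (fraction of replicates flagging the true outlier, mean
    absolute error of the outlier-corrected estimate against theta).
    """
    seeds = _subseeds(seed, n_rep)
    hits = 0
    err = np.empty(n_rep)
    for i in range(n_rep):
        cfg = _outlier_config(int(seeds[i]))
        exposure, outcome, truth = generate_pair(cfg)
        h = harmonize_pair(exposure, outcome)
        res = presso_run(h, n_sim=n_sim, seed=int(seeds[i]))
        true_ids = {h.variants[k] for k in truth["outlier_idx"]}
        hits += true_ids <= set(res.outlier_ids)
        err[i] = abs(res.beta_corrected.beta - cfg.true_theta)
    return hits / n_rep, float(err.mean())


def presso_null_rejection(
    n_rep: int = 500, seed: int = 0, n_snps: int = 10, n_sim: int = 300
) -> float:
    """Global-test rejection rate at 0.05 under a clean (no-pleiotropy) null."""
    seeds = _subseeds(seed, n_rep)
    rejections = 0
    for i in range(n_rep):
        cfg = ScenarioConfig(n_snps=n_snps, true_theta=0.1, seed=int(seeds[i]))
        exposure, outcome, _ = generate_pair(cfg)
        h = harmonize_pair(exposure, outcome)
        rejections += presso_run(h, n_sim=n_sim, seed=int(seeds[i])).global_pvalue < 0.05
    return rejections / n_rep


def _mediation_fits(bundle):
    x_ids = set(bundle.x_instruments)
    exp_x = [r for r in bundle.exposure if r.variant_id in x_ids]
    out_x = [r for r in bundle.outcome if r.variant_id in x_ids]
    med_x = [r for r in bundle.mediator if r.variant_id in x_ids]
    total = ivw(harmonize_pair(exp_x, out_x))
    a = ivw(harmonize_pair(exp_x, med_x))
    joint = mvmr_fit(
        harmonize_multi({"exposure": bundle.exposure, "mediator": bundle.mediator}, bundle.outcome)
    )
    return total, a, joint


def sign_reversal_rate(n_rep: int = 200, seed: int = 0, chain: MediatorChain | None = None) -> float:
    """Fraction of replicates showing the mediator-driven sign reversal.

    A replicate counts when the univariable exposure -> outcome estimate is
    positive while the mediator-adjusted multivariable direct estimate is
    negative (the configuration of the ``apoB_reversal`` preset).
    """
    if chain is None:
        from .simulate import load_preset

        chain = load_preset("apoB_reversal").mediator_chain
    seeds = _subseeds(seed, n_rep)
    hits = 0
    for i in range(n_rep):
        cfg = ScenarioConfig(mediator_chain=chain, seed=int(seeds[i]))
        bundle = generate_mediation_scenario(cfg)
        total, _, joint = _mediation_fits(bundle)
        direct = joint.estimate_for("exposure").beta
        hits += (total.beta > 0) and (direct < 0)
    return hits / n_rep


def mediation_recovery(
    n_rep: int = 1000, seed: int = 0, chain: MediatorChain | None = None
) -> tuple[float, float]:
    """Recovery of the true proportion mediated and CI coverage.

    Runs the two-step network decomposition (step-2 effect from the joint
    mediator+exposure fit) on fresh draws of the mediation scenario.
    Returns (mean estimated proportion in percent, fraction of delta-method
    95% CIs covering the generator's true proportion).
    """
    if chain is None:
        from .simulate import load_preset

        chain = load_preset("apoB_mediation").mediator_chain
    true_pct = 100 * chain.proportion_mediated
    seeds = _subseeds(seed, n_rep)
    props = np.empty(n_rep)
    covered = 0
    for i in range(n_rep):
        cfg = ScenarioConfig(mediator_chain=chain, seed=int(seeds[i]))
        bundle = generate_mediation_scenario(cfg)
        total, a, joint = _mediation_fits(bundle)
        b = joint.estimate_for("mediator")
        res = mediation_two_step(total, a, b)
        props[i] = res.proportion_mediated
        lo, hi = res.proportion_ci
        covered += lo <= true_pct <= hi
    return float(props.mean()), covered / n_rep
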