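"""Seeded generator of GWAS summary statistics for desk-scale MR studies.

The generator mirrors the measurement model the estimators assume: latent
instrument effects xi_j on the exposure, observed with sampling noise on
both the exposure side (beta_Xj ~ N(xi_j, sigma_x^2)) and the outcome side
(beta_Yj ~ N(theta*xi_j + alpha_j, sigma_y^2)), where theta is the causal
effect on the log-odds scale and alpha_j is a horizontal-pleiotropy offset
(zero, balanced, or directional on a controlled fraction of instruments).
It can additionally emulate gross outliers, an exposure -> mediator ->
outcome chain (for multivariable MR and mediation recovery), and block LD
structure for clumping fixtures.  Every draw is governed by a single seed
and every latent quantity is returned in a truth record.

Default per-variant standard errors follow the nominal sample sizes of the
emulated data sources: a 30,931-person protein GWAS on the exposure side
and a ~185,000-person case-control GWAS on the outcome side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import yaml

from .instruments import LDMatrix
from .sumstats import AssociationRecord

__all__ = [
    "ScenarioConfig",
    "MediatorChain",
    "LDBlock",
    "MediationBundle",
    "generate_pair",
    "generate_mediation_scenario",
    "generate_ld_fixture",
    "se_from_n",
    "load_preset",
    "available_presets",
]

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "A")]


def se_from_n(n: float, eaf: float = 0.3, var_explained: float = 1.0) -> float:
    """Approximate per-allele SE for a trait in SD units: 1/sqrt(n*2f(1-f)*v)."""
    return 1.0 / math.sqrt(n * 2 * eaf * (1 - eaf) * var_explained)


@dataclass
class MediatorChain:
    """Exposure -> mediator -> outcome chain: X -a-> M -b-> Y, X -theta_direct-> Y."""

    a: float
    b: float
    theta_direct: float
    n_mediator_snps: int = 20
    sigma_m: float = se_from_n(439_214)  # mediator-side SE (large lipid GWAS scale)

    @property
    def total(self) -> float:
        return self.theta_direct + self.a * self.b

    @property
    def proportion_mediated(self) -> float:
        return self.a * self.b / self.total


@dataclass
class LDBlock:
    n_variants: int
    within_r2: float
    span_bp: int = 50_000


@dataclass
class ScenarioConfig:
    """Generative conditions for one synthetic two-sample MR dataset."""

    n_snps: int = 13
    true_theta: float = 0.0
    xi_mean: float = 0.35
    xi_sd: float = 0.05
    sigma_x: float = se_from_n(30_931)  # exposure pQTL GWAS scale (~0.0088)
    sigma_y: float = 0.0076  # log-odds SE at ~60k cases / ~120k controls
    pleiotropy: str = "none"  # none | balanced | directional
    pleio_mean: float = 0.0
    pleio_sd: float = 0.0
    invalid_fraction: float = 0.0  # fraction of instruments carrying the directional offset
    outlier_fraction: float = 0.0
    outlier_effect: float = 0.0
    mediator_chain: MediatorChain | None = None
    n_exposures: int = 1
    ld_block_spec: list[LDBlock] = field(default_factory=list)
    n_exposure_samples: int = 30_931
    n_outcome_samples: int = 184_305
    chromosome: str = "2"
    position_start: int = 113_000_000
    position_step: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValueError("sigma_x and sigma_y must be > 0")
        if not (0 <= self.outlier_fraction < 1):
            raise ValueError("outlier_fraction must be in [0,1)")
        if not (0 <= self.invalid_fraction <= 1):
            raise ValueError("invalid_fraction must be in [0,1]")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy model {self.pleiotropy!r}")


@dataclass
class MediationBundle:
    exposure: list[AssociationRecord]
    mediator: list[AssociationRecord]
    outcome: list[AssociationRecord]
    x_instruments: list[str]
    m_instruments: list[str]
    truth: dict


def _normal_p(beta: np.ndarray, se: float | np.ndarray) -> np.ndarray:
    from scipy import stats

    return np.clip(2 * stats.norm.sf(np.abs(beta / se)), np.nextafter(0, 1), 1.0)


def _records(
    rng: np.random.Generator,
    ids: Sequence[str],
    beta: np.ndarray,
    se: float | np.ndarray,
    trait: str,
    config: ScenarioConfig,
    eaf: np.ndarray,
    alleles: list[tuple[str, str]],
    n_samples: int,
    positions: Sequence[int],
) -> list[AssociationRecord]:
    se_arr = np.broadcast_to(np.asarray(se, dtype=float), (len(ids),))
    pvals = _normal_p(beta, se_arr)
    return [
        AssociationRecord(
            variant_id=ids[i],
            chromosome=config.chromosome,
            position=int(positions[i]),
            effect_allele=alleles[i][0],
            other_allele=alleles[i][1],
            eaf=float(eaf[i]),
            beta=float(beta[i]),
            se=float(se_arr[i]),
            pvalue=float(pvals[i]),
            n=n_samples,
            trait=trait,
        )
        for i in range(len(ids))
    ]


def _variant_frame(rng: np.random.Generator, n: int, config: ScenarioConfig, prefix: str = "rs"):
    ids = [f"{prefix}{i + 1:04d}" for i in range(n)]
    positions = [config.position_start + i * config.position_step for i in range(n)]
    eaf = rng.uniform(0.1, 0.9, size=n)
    alleles = [_ALLELE_PAIRS[int(k)] for k in rng.integers(0, len(_ALLELE_PAIRS), size=n)]
    return ids, positions, eaf, alleles


def generate_pair(config: ScenarioConfig):
    """Generate one exposure/outcome summary-statistics pair plus its truth.

    Returns ``(exposure_records, outcome_records, truth)`` where ``truth``
    stores every latent quantity (xi, alpha, outlier indices, theta) needed
    to score recovery.  Identical configs (including seed) give identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    j = config.n_snps
    ids, positions, eaf, alleles = _variant_frame(rng, j, config)
    xi = config.xi_mean + config.xi_sd * rng.standard_normal(j)

    alpha = np.zeros(j)
    invalid_idx = np.array([], dtype=int)
    if config.pleiotropy == "balanced":
        alpha = config.pleio_sd * rng.standard_normal(j)
        invalid_idx = np.arange(j)
    elif config.pleiotropy == "directional":
        k = int(round(config.invalid_fraction * j))
        invalid_idx = np.sort(rng.choice(j, size=k, replace=False))
        alpha[invalid_idx] = config.pleio_mean + config.pleio_sd * rng.standard_normal(k)

    outlier_idx = np.array([], dtype=int)
    if config.outlier_fraction > 0:
        m = max(1, int(round(config.outlier_fraction * j)))
        outlier_idx = np.sort(rng.choice(j, size=m, replace=False))
        alpha = alpha.copy()
        alpha[outlier_idx] += config.outlier_effect

    beta_x = xi + config.sigma_x * rng.standard_normal(j)
    beta_y = config.true_theta * xi + alpha + config.sigma_y * rng.standard_normal(j)

    exposure = _records(
        rng, ids, beta_x, config.sigma_x, "exposure", config, eaf, alleles, config.n_exposure_samples, positions
    )
    outcome = _records(
        rng, ids, beta_y, config.sigma_y, "outcome", config, eaf, alleles, config.n_outcome_samples, positions
    )
    truth = {
        "theta": config.true_theta,
        "xi": xi,
        "alpha": alpha,
        "invalid_idx": invalid_idx,
        "outlier_idx": outlier_idx,
        "sigma_x": config.sigma_x,
        "sigma_y": config.sigma_y,
    }
    return exposure, outcome, truth


def generate_mediation_scenario(config: ScenarioConfig) -> MediationBundle:
    """Three-trait bundle consistent with an X -> M -> Y causal chain.

    The exposure has ``n_snps`` instruments (latent effects xi_j); the
    mediator additionally has ``n_mediator_snps`` instruments of its own
    (latent effects eta_k, no effect on X).  Structural equations:
    beta_M = a*beta_X_latent + eta, beta_Y = theta_direct*beta_X_latent +
    b*beta_M_latent, so the total X -> Y effect is theta_direct + a*b by
    construction; all latents are recorded in the truth.
    """
    chain = config.mediator_chain
    if chain is None:
        raise ValueError("mediator_chain must be set for a mediation scenario")
    rng = np.random.default_rng(config.seed)
    jx, jm = config.n_snps, chain.n_mediator_snps
    j = jx + jm
    ids, positions, eaf, alleles = _variant_frame(rng, j, config)
    xi = np.zeros(j)
    eta = np.zeros(j)
    xi[:jx] = config.xi_mean + config.xi_sd * rng.standard_normal(jx)
    eta[jx:] = config.xi_mean + config.xi_sd * rng.standard_normal(jm)

    m_latent = chain.a * xi + eta
    y_latent = chain.theta_direct * xi + chain.b * m_latent

    beta_x = xi + config.sigma_x * rng.standard_normal(j)
    beta_m = m_latent + chain.sigma_m * rng.standard_normal(j)
    beta_y = y_latent + config.sigma_y * rng.standard_normal(j)

    exposure = _records(
        rng, ids, beta_x, config.sigma_x, "exposure", config, eaf, alleles, config.n_exposure_samples, positions
    )
    mediator = _records(
        rng, ids, beta_m, chain.sigma_m, "mediator", config, eaf, alleles, config.n_outcome_samples, positions
    )
    outcome = _records(
        rng, ids, beta_y, config.sigma_y, "outcome", config, eaf, alleles, config.n_outcome_samples, positions
    )
    truth = {
        "a": chain.a,
        "b": chain.b,
        "theta_direct": chain.theta_direct,
        "total": chain.total,
        "proportion_mediated": chain.proportion_mediated,
        "xi": xi,
        "eta": eta,
    }
    return MediationBundle(exposure, mediator, outcome, ids[:jx], ids[jx:], truth)


def generate_ld_fixture(config: ScenarioConfig):
    """Records with positions plus a block-diagonal LD matrix for clumping.

    Each block's first variant gets the smallest p-value, so with
    within-block r2 above the clumping threshold the expected survivor set
    is exactly the block leads.  Blocks are separated by ten times the
    largest block span, keeping cross-block pairs outside any reasonable
    clumping distance only when the caller configures it so.
    """
    if not config.ld_block_spec:
        raise ValueError("ld_block_spec must be set for an LD fixture")
    rng = np.random.default_rng(config.seed)
    records: list[AssociationRecord] = []
    ids: list[str] = []
    blocks: list[list[str]] = []
    pos = config.position_start
    gap = 10 * max(b.span_bp for b in config.ld_block_spec)
    counter = 0
    for bi, block in enumerate(config.ld_block_spec):
        step = block.span_bp // max(1, block.n_variants - 1) if block.n_variants > 1 else 0
        members = []
        for vi in range(block.n_variants):
            counter += 1
            vid = f"rs{counter:04d}"
            # block lead (vi == 0) carries the smallest p within the block;
            # effects are cis-pQTL scale (~0.35 SD per allele)
            se = 0.01
            beta = 0.35 - 0.035 * vi + 0.002 * bi
            eaf = float(rng.uniform(0.1, 0.9))
            ea, oa = _ALLELE_PAIRS[int(rng.integers(0, len(_ALLELE_PAIRS)))]
            records.append(
                AssociationRecord(
                    variant_id=vid,
                    chromosome=config.chromosome,
                    position=pos + vi * step,
                    effect_allele=ea,
                    other_allele=oa,
                    eaf=eaf,
                    beta=beta,
                    se=se,
                    pvalue=float(_normal_p(np.array([beta]), se)[0]),
                    n=config.n_exposure_samples,
                    trait="exposure",
                )
            )
            members.append(vid)
            ids.append(vid)
        blocks.append(members)
        pos += block.span_bp + gap
    n = len(ids)
    idx = {v: i for i, v in enumerate(ids)}
    r2 = np.eye(n)
    for block, spec in zip(blocks, config.ld_block_spec):
        for a in block:
            for b in block:
                if a != b:
                    r2[idx[a], idx[b]] = spec.within_r2
    return records, LDMatrix(ids, r2)


# ---------------------------------------------------------------------------
# Scenario presets
# ---------------------------------------------------------------------------


def available_presets() -> list[str]:
    root = resources.files("cismr") / "presets"
    return sorted(p.name.removesuffix(".yaml") for p in root.iterdir() if p.name.endswith(".yaml"))


def load_preset(name: str, seed: int = 0) -> ScenarioConfig:
    """Load a shipped scenario preset (e.g. ``apoB_reversal``) by name."""
    path = resources.files("cismr") / "presets" / f"{name}.yaml"
    if not path.is_file():
        raise KeyError(f"unknown preset {name!r}; available: {available_presets()}")
    raw = yaml.safe_load(path.read_text())
    chain = raw.pop("mediator_chain", None)
    blocks = raw.pop("ld_block_spec", None)
    cfg = ScenarioConfig(
        mediator_chain=MediatorChain(**chain) if chain else None,
        ld_block_spec=[LDBlock(**b) for b in blocks] if blocks else [],
        seed=seed,
        **raw,
    )
    return cfg
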