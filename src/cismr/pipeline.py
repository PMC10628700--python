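"""The full study workflow: screens, adjustments, mediation, reverse MR.

A study is described by a YAML configuration naming instrument sources and
analysis cells.  ``run_study`` executes every configured cell — validity
and cardiovascular-outcome screens (unadjusted alpha), the risk-factor and
lifestyle screens (Bonferroni-corrected at alpha/m), multivariable-MR
adjustments, two-step network mediation, reverse-direction MR and the
lifestyle attenuation comparison — and writes delimited report tables plus
a structured run log.  ``simulate_study`` fabricates a complete synthetic
study (summary-statistic files, LD matrix, proxy table and configuration)
so the whole workflow runs at desk scale; its trait roster and per-trait
effects mirror the emulated study's layout.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .estimators import egger, ivw, max_likelihood, to_odds_ratio, wald_ratio, weighted_median
from .instruments import InstrumentConfig, LDMatrix, clump, scale_to_sd, select_cis_significant
from .mvmr import attenuation, mediation_two_step, mvmr_fit
from .presso import presso_run
from .simulate import (
    LDBlock,
    MediatorChain,
    ScenarioConfig,
    generate_ld_fixture,
    generate_mediation_scenario,
    load_preset,
    se_from_n,
)
from .sumstats import (
    AssociationRecord,
    ProxyTable,
    harmonize_multi,
    harmonize_pair,
    read_sumstats,
    resolve_proxies,
    write_sumstats,
)

__all__ = [
    "StudyConfig",
    "bonferroni_threshold",
    "run_screen",
    "run_mvmr_adjustments",
    "run_mediation",
    "run_reverse",
    "run_lifestyle_attenuation",
    "run_study",
    "simulate_study",
]

_METHOD_MIN_J = {"ivw": 2, "max_likelihood": 2, "weighted_median": 3, "egger": 3, "presso": 4}


def bonferroni_threshold(alpha_family: float, m: int) -> tuple[float, str]:
    """Family-wise threshold alpha/m, raw and rounded to 3 decimals for display."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not (0 < alpha_family < 1):
        raise ValueError("alpha_family must be in (0,1)")
    raw = alpha_family / m
    return raw, f"<{round(raw, 3):g}"


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class InstrumentSource:
    """Where an exposure's instruments come from.

    Either a prebuilt instrument file (every row is an instrument), or a
    sumstats file plus cis-window/clumping configuration and an LD matrix.
    """

    label: str
    sumstats: str
    prebuilt: bool = False
    prebuilt_significant: bool = False  # instruments = genome-wide significant rows
    ld_matrix: str | None = None
    instrument: InstrumentConfig | None = None
    sd: float = 1.0

    def build(self, base: Path, log: list[str]) -> list[AssociationRecord]:
        res = read_sumstats(base / self.sumstats, trait=self.label)
        if res.dropped:
            log.append(f"instrument source {self.label}: dropped rows {dict(res.dropped)}")
        records = res.records
        if self.prebuilt:
            log.append(f"instrument source {self.label}: prebuilt, {len(records)} instruments")
        elif self.prebuilt_significant:
            records = [r for r in records if r.pvalue < 5e-8]
            log.append(f"instrument source {self.label}: {len(records)} genome-wide significant instruments")
        else:
            if self.instrument is None or self.ld_matrix is None:
                raise ValueError(f"instrument source {self.label}: needs instrument config and LD matrix")
            cis = select_cis_significant(records, self.instrument)
            ld = LDMatrix.from_file(base / self.ld_matrix)
            records = clump(cis, ld, self.instrument)
            log.append(
                f"instrument source {self.label}: {len(cis)} cis-significant, {len(records)} after clumping"
            )
        if self.sd != 1.0:
            records = scale_to_sd(records, self.sd)
        return records


@dataclass
class ScreenSpec:
    label: str
    sumstats: str
    set: str  # validity | cvd | risk_factors | lifestyle | reverse
    exposure: str = ""  # instrument source name; default = study exposure
    binary: bool = False
    proxies: str | None = None


@dataclass
class AdjustmentSpec:
    adjuster: str  # instrument source name for the adjusting exposure
    outcome_label: str
    outcome_sumstats: str
    exposure: str = ""


@dataclass
class MediationSpec:
    mediator: str  # instrument source name for the mediator
    outcome_label: str
    outcome_sumstats: str
    exposure: str = ""
    b_mode: str = "network"  # network | univariable


@dataclass
class AttenuationSpec:
    lifestyle: str  # instrument source name for the lifestyle exposure
    adjuster: str  # instrument source for the mediating exposure (IL-1Ra role)
    outcome_label: str
    outcome_sumstats: str


@dataclass
class StudyConfig:
    seed: int
    base_dir: Path
    exposure: str  # name of the primary instrument source
    instrument_sources: dict[str, InstrumentSource]
    screens: list[ScreenSpec] = field(default_factory=list)
    adjustments: list[AdjustmentSpec] = field(default_factory=list)
    mediation: list[MediationSpec] = field(default_factory=list)
    attenuation: list[AttenuationSpec] = field(default_factory=list)
    methods: list[str] = field(default_factory=lambda: ["ivw", "max_likelihood", "weighted_median", "egger", "presso"])
    alpha_family: float = 0.05
    n_boot: int = 1000
    n_sim: int = 1000
    proxy_r2_min: float = 0.8

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        sources = {}
        for name, spec in raw["instrument_sources"].items():
            inst = spec.get("instrument")
            sources[name] = InstrumentSource(
                label=name,
                sumstats=spec["sumstats"],
                prebuilt=spec.get("prebuilt", False),
                prebuilt_significant=spec.get("prebuilt_significant", False),
                ld_matrix=spec.get("ld_matrix"),
                instrument=InstrumentConfig(**inst) if inst else None,
                sd=spec.get("sd", 1.0),
            )
        return cls(
            seed=int(raw["seed"]),
            base_dir=path.parent,
            exposure=raw["exposure"],
            instrument_sources=sources,
            screens=[ScreenSpec(**s) for s in raw.get("screens", [])],
            adjustments=[AdjustmentSpec(**s) for s in raw.get("adjustments", [])],
            mediation=[MediationSpec(**s) for s in raw.get("mediation", [])],
            attenuation=[AttenuationSpec(**s) for s in raw.get("attenuation", [])],
            methods=raw.get("methods", ["ivw", "max_likelihood", "weighted_median", "egger", "presso"]),
            alpha_family=raw.get("alpha_family", 0.05),
            n_boot=raw.get("n_boot", 1000),
            n_sim=raw.get("n_sim", 1000),
            proxy_r2_min=raw.get("proxy_r2_min", 0.8),
        )


def _cell_seed(base_seed: int, *parts: str) -> int:
    """Deterministic per-cell seed below 2^31, stable across runs."""
    return (base_seed + zlib.crc32("|".join(parts).encode())) % (2**31 - 1)


# ---------------------------------------------------------------------------
# Screens
# ---------------------------------------------------------------------------


def _load_outcome(config: StudyConfig, spec, instruments, log: list[str]):
    res = read_sumstats(config.base_dir / spec.sumstats, trait=spec.label)
    if res.dropped:
        log.append(f"outcome {spec.label}: dropped rows {dict(res.dropped)}")
    outcome = res.records
    have = {r.variant_id for r in outcome}
    missing = [r.variant_id for r in instruments if r.variant_id not in have]
    if missing and getattr(spec, "proxies", None):
        table = ProxyTable.from_file(config.base_dir / spec.proxies)
        resolution = resolve_proxies(missing, table, outcome, config.proxy_r2_min)
        for target, rec in resolution.substitutions:
            outcome = [r for r in outcome if r.variant_id != rec.variant_id] + [rec]
            log.append(f"outcome {spec.label}: proxy substituted for {target}")
        for target in resolution.unresolved:
            log.append(f"outcome {spec.label}: no proxy found for {target}; instrument unused")
    elif missing:
        log.append(f"outcome {spec.label}: {len(missing)} instruments absent, no proxy table")
    return outcome


def _run_methods(config: StudyConfig, h, label: str, binary: bool, log: list[str]) -> list[dict]:
    rows = []
    for method in config.methods:
        row = {"outcome": label, "method": method, "n_snps": h.n_snps}
        min_j = _METHOD_MIN_J.get(method, 2)
        if h.n_snps < min_j:
            row["note"] = f"failed: J={h.n_snps} below minimum {min_j} for {method}"
            log.append(f"{label}/{method}: {row['note']}")
            rows.append(row)
            continue
        try:
            if method == "ivw":
                est = ivw(h) if h.n_snps >= 2 else wald_ratio(h)
            elif method == "max_likelihood":
                est = max_likelihood(h)
            elif method == "weighted_median":
                est = weighted_median(h, n_boot=config.n_boot, seed=_cell_seed(config.seed, label, method))
            elif method == "egger":
                est = egger(h)
            elif method == "presso":
                res = presso_run(h, n_sim=config.n_sim, seed=_cell_seed(config.seed, label, method))
                est = res.beta_corrected
                row.update(
                    {
                        "presso_global_p": res.global_pvalue,
                        "presso_outliers": ",".join(res.outlier_ids) or "none",
                        "presso_distortion_p": res.distortion_pvalue,
                    }
                )
            else:
                row["note"] = f"failed: unknown method {method}"
                rows.append(row)
                continue
        except (ValueError, RuntimeError) as exc:
            row["note"] = f"failed: {exc}"
            log.append(f"{label}/{method}: {row['note']}")
            rows.append(row)
            continue
        row.update(
            {
                "beta": est.beta,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "pvalue": est.pvalue,
                "Q": est.q_stat,
                "P_Q": est.q_pvalue,
                "egger_intercept": est.egger_intercept,
                "P_pleiotropy": est.egger_intercept_pvalue,
                "note": "",
            }
        )
        if binary:
            orv, lo, hi = to_odds_ratio(est)
            row.update({"OR": orv, "OR_ci_low": lo, "OR_ci_high": hi})
        rows.append(row)
    return rows


def run_screen(config: StudyConfig, trait_set: str, log: list[str] | None = None) -> pd.DataFrame:
    """Run the estimator battery for every screen trait in ``trait_set``.

    Validity/CVD (and reverse) screens are flagged at the unadjusted family
    alpha; the risk-factor and lifestyle screens at alpha/m for the m
    traits configured in the set.  Every configured (trait, method) cell
    yields a row, carrying a failure note when a method is inapplicable.
    """
    log = [] if log is None else log
    specs = [s for s in config.screens if s.set == trait_set]
    if not specs:
        return pd.DataFrame()
    if trait_set in ("risk_factors", "lifestyle"):
        threshold, display = bonferroni_threshold(config.alpha_family, len(specs))
    else:
        threshold, display = config.alpha_family, f"<{config.alpha_family:g}"
    all_rows = []
    for spec in specs:
        source = config.instrument_sources[spec.exposure or config.exposure]
        instruments = source.build(config.base_dir, log)
        outcome = _load_outcome(config, spec, instruments, log)
        h = harmonize_pair(instruments, outcome)
        for v, flag in h.provenance.items():
            if flag.startswith("dropped"):
                log.append(f"outcome {spec.label}: variant {v} {flag}")
        rows = _run_methods(config, h, spec.label, spec.binary, log)
        for row in rows:
            row["exposure"] = source.label
            row["trait_set"] = trait_set
            row["p_threshold"] = threshold
            row["p_threshold_display"] = display
            row["significant"] = bool(row.get("pvalue", 1.0) < threshold) if "pvalue" in row else False
        all_rows.extend(rows)
    df = pd.DataFrame(all_rows)
    front = ["trait_set", "exposure", "outcome", "method"]
    return df[front + [c for c in df.columns if c not in front]]


# ---------------------------------------------------------------------------
# MVMR adjustment, mediation, attenuation
# ---------------------------------------------------------------------------


def _joint_fit(config: StudyConfig, exposure_name: str, other_name: str, outcome_spec, log: list[str]):
    """Univariable exposure estimate plus joint (exposure, other) MVMR fit."""
    exp_source = config.instrument_sources[exposure_name]
    other_source = config.instrument_sources[other_name]
    exp_records = read_sumstats(config.base_dir / exp_source.sumstats, trait=exposure_name).records
    other_records = read_sumstats(config.base_dir / other_source.sumstats, trait=other_name).records
    exp_instr = exp_source.build(config.base_dir, log)
    other_instr = other_source.build(config.base_dir, log)
    instrument_ids = {r.variant_id for r in exp_instr} | {r.variant_id for r in other_instr}
    outcome = read_sumstats(config.base_dir / outcome_spec[1], trait=outcome_spec[0]).records

    uni = ivw(harmonize_pair(exp_instr, outcome))
    exp_union = [r for r in exp_records if r.variant_id in instrument_ids]
    other_union = [r for r in other_records if r.variant_id in instrument_ids]
    joint = mvmr_fit(
        harmonize_multi({exposure_name: exp_union, other_name: other_union}, outcome)
    )
    return uni, joint, exp_instr, other_instr


def run_mvmr_adjustments(config: StudyConfig, log: list[str] | None = None) -> pd.DataFrame:
    """Exposure direct effect after adjusting for each configured trait."""
    log = [] if log is None else log
    rows = []
    for spec in config.adjustments:
        exposure_name = spec.exposure or config.exposure
        uni, joint, _, _ = _joint_fit(
            config, exposure_name, spec.adjuster, (spec.outcome_label, spec.outcome_sumstats), log
        )
        direct = joint.estimate_for(exposure_name)
        or_u, or_u_lo, or_u_hi = to_odds_ratio(uni)
        or_a, or_a_lo, or_a_hi = to_odds_ratio(direct)
        rows.append(
            {
                "exposure": exposure_name,
                "adjusted_for": spec.adjuster,
                "outcome": spec.outcome_label,
                "n_snps": joint.n_snps,
                "beta_unadjusted": uni.beta,
                "OR_unadjusted": or_u,
                "OR_unadjusted_ci_low": or_u_lo,
                "OR_unadjusted_ci_high": or_u_hi,
                "beta_adjusted": direct.beta,
                "se_adjusted": direct.se,
                "pvalue_adjusted": direct.pvalue,
                "OR_adjusted": or_a,
                "OR_adjusted_ci_low": or_a_lo,
                "OR_adjusted_ci_high": or_a_hi,
            }
        )
        log.append(
            f"mvmr {exposure_name}+{spec.adjuster} -> {spec.outcome_label}: "
            f"unadjusted OR {or_u:.3f}, adjusted OR {or_a:.3f}"
        )
    return pd.DataFrame(rows)


def run_mediation(config: StudyConfig, log: list[str] | None = None) -> pd.DataFrame:
    """Two-step network mediation for every configured triple."""
    log = [] if log is None else log
    rows = []
    for spec in config.mediation:
        exposure_name = spec.exposure or config.exposure
        uni, joint, exp_instr, med_instr = _joint_fit(
            config, exposure_name, spec.mediator, (spec.outcome_label, spec.outcome_sumstats), log
        )
        med_source = config.instrument_sources[spec.mediator]
        med_records = read_sumstats(config.base_dir / med_source.sumstats, trait=spec.mediator).records
        a = ivw(harmonize_pair(exp_instr, med_records))
        if spec.b_mode == "network":
            b = joint.estimate_for(spec.mediator)
        else:
            outcome = read_sumstats(config.base_dir / spec.outcome_sumstats, trait=spec.outcome_label).records
            b = ivw(harmonize_pair(med_instr, outcome))
        res = mediation_two_step(uni, a, b)
        rows.append(
            {
                "exposure": exposure_name,
                "mediator": spec.mediator,
                "outcome": spec.outcome_label,
                "total_beta": uni.beta,
                "a_beta": a.beta,
                "b_beta": b.beta,
                "b_mode": spec.b_mode,
                "indirect": res.indirect,
                "indirect_se": res.indirect_se,
                "proportion_mediated_pct": res.proportion_mediated,
                "proportion_ci_low_pct": None if res.proportion_ci is None else res.proportion_ci[0],
                "proportion_ci_high_pct": None if res.proportion_ci is None else res.proportion_ci[1],
                "note": res.method_note,
            }
        )
        log.append(
            f"mediation {exposure_name} -> {spec.mediator} -> {spec.outcome_label}: "
            f"proportion {res.proportion_mediated if res.proportion_mediated is None else round(res.proportion_mediated, 1)}%"
        )
    return pd.DataFrame(rows)


def run_reverse(config: StudyConfig, log: list[str] | None = None) -> pd.DataFrame:
    """Reverse-direction screen: disease instruments, exposure as outcome."""
    return run_screen(config, "reverse", log)


def run_lifestyle_attenuation(config: StudyConfig, log: list[str] | None = None) -> pd.DataFrame:
    """Attenuation of lifestyle -> outcome effects on adjusting for the exposure."""
    log = [] if log is None else log
    rows = []
    for spec in config.attenuation:
        uni, joint, _, _ = _joint_fit(
            config, spec.lifestyle, spec.adjuster, (spec.outcome_label, spec.outcome_sumstats), log
        )
        direct = joint.estimate_for(spec.lifestyle)
        if uni.beta == 0:
            pct = None
            note = "undefined: zero total effect"
        else:
            pct = attenuation(uni.beta, direct.beta)
            note = ""
        rows.append(
            {
                "lifestyle": spec.lifestyle,
                "adjusted_for": spec.adjuster,
                "outcome": spec.outcome_label,
                "beta_total": uni.beta,
                "beta_adjusted": direct.beta,
                "attenuation_pct": pct,
                "note": note,
            }
        )
        log.append(f"attenuation {spec.lifestyle} -> {spec.outcome_label}: {pct if pct is None else round(pct, 1)}%")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Whole-study driver
# ---------------------------------------------------------------------------

_FLOAT_FORMAT = "%.6g"


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)


def run_study(config: StudyConfig, outdir) -> dict[str, pd.DataFrame]:
    """Run every configured analysis and write report tables plus a run log.

    Identical configuration and seed produce byte-identical outputs.  The
    validity and CVD screens are flagged at the unadjusted 0.05 level; only
    the risk-factor and lifestyle screens carry a Bonferroni correction
    (see the report footer note).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"study seed: {config.seed}", f"alpha_family: {config.alpha_family}"]
    reports: dict[str, pd.DataFrame] = {}
    for trait_set in ("validity", "cvd", "risk_factors", "lifestyle"):
        df = run_screen(config, trait_set, log)
        if not df.empty:
            reports[f"screen_{trait_set}"] = df
            _write(df, outdir / f"screen_{trait_set}.tsv")
    if config.adjustments:
        reports["mvmr_adjustments"] = run_mvmr_adjustments(config, log)
        _write(reports["mvmr_adjustments"], outdir / "mvmr_adjustments.tsv")
    if config.mediation:
        reports["mediation"] = run_mediation(config, log)
        _write(reports["mediation"], outdir / "mediation.tsv")
    reverse_df = run_reverse(config, log)
    if not reverse_df.empty:
        reports["reverse"] = reverse_df
        _write(reverse_df, outdir / "reverse.tsv")
    if config.attenuation:
        reports["lifestyle_attenuation"] = run_lifestyle_attenuation(config, log)
        _write(reports["lifestyle_attenuation"], outdir / "lifestyle_attenuation.tsv")
    log.append(
        "note: validity/CVD/reverse screens use the unadjusted family alpha; "
        "only the risk-factor and lifestyle screens are Bonferroni-corrected"
    )
    (outdir / "run.log").write_text("\n".join(log) + "\n")
    return reports


# ---------------------------------------------------------------------------
# Synthetic study generation
# ---------------------------------------------------------------------------

# trait roster emulating the study layout: (label, set, binary, true effect
# of the exposure on the trait in SD or log-odds units, per-variant SE).
# Binary-trait SEs follow the nominal case/control counts of the emulated
# consortia; blood-pressure SEs are widened to reflect mmHg-scale GWAS.
_SCREEN_ROSTER = [
    ("RA", "validity", True, -0.30, 0.0127),
    ("CRP", "validity", False, -0.18, se_from_n(204_402)),
    ("CHD", "cvd", True, np.log(1.09), 0.0076),
    ("MI", "cvd", True, np.log(1.13), 0.0086),
    ("HF", "cvd", True, 0.0, 0.0073),
    ("AF", "cvd", True, 0.0, 0.0065),
    ("IS", "cvd", True, 0.0, 0.0087),
    ("ApoA1", "risk_factors", False, 0.034, se_from_n(393_193)),
    ("ApoB", "risk_factors", False, 0.049, se_from_n(439_214)),
    ("HDL", "risk_factors", False, 0.017, se_from_n(403_943)),
    ("LDL", "risk_factors", False, 0.048, se_from_n(440_546)),
    ("TG", "risk_factors", False, 0.047, se_from_n(441_016)),
    ("FG", "risk_factors", False, 0.017, se_from_n(281_416)),
    ("FI", "risk_factors", False, 0.002, se_from_n(213_650)),
    ("HbA1C", "risk_factors", False, 0.000, se_from_n(215_977)),
    ("SBP", "risk_factors", False, -0.19, 0.16),
    ("DBP", "risk_factors", False, -0.03, 0.10),
]

# lifestyle traits as exposures acting on the study exposure (effects in SD
# units per SD of lifestyle trait)
_LIFESTYLE_ROSTER = [
    ("BMI", 0.10),
    ("WaistCircumference", 0.10),
    ("SmokingInitiation", 0.0),
    ("SmokingIndex", 0.05),
    ("AlcoholDrinking", 0.0),
    ("AlcoholDependence", 0.0),
    ("CoffeeConsumption", 0.0),
    ("CaffeineConsumption", 0.0),
    ("ModVigPhysicalActivity", 0.0),
    ("VigPhysicalActivity", 0.0),
    ("SedentaryBehaviour", 0.08),
    ("SleepDuration", -0.08),
    ("Insomnia", 0.08),
]

# lifestyle -> CHD chains mediated by the exposure, calibrated so the true
# attenuation matches the emulated scenario (~48%, ~16%, ~13%)
_ATTENUATION_CHAINS = {
    "SleepDuration": (-0.08, 0.478),
    "SmokingIndex": (0.05, 0.156),
    "SedentaryBehaviour": (0.08, 0.131),
}

_IL1RA_EXPOSURE_SE = se_from_n(30_931)
_CHD_SE = 0.0076


def _prebuilt_instruments(
    rng: np.random.Generator, label: str, n_snps: int, chromosome: str, start: int
) -> list[AssociationRecord]:
    from .simulate import _ALLELE_PAIRS, _normal_p

    beta = 0.30 + 0.05 * rng.standard_normal(n_snps)
    se = 0.004
    recs = []
    for i in range(n_snps):
        ea, oa = _ALLELE_PAIRS[int(rng.integers(0, len(_ALLELE_PAIRS)))]
        b = float(beta[i])
        recs.append(
            AssociationRecord(
                variant_id=f"{label.lower()}_{i + 1:03d}",
                chromosome=chromosome,
                position=start + i * 100_000,
                effect_allele=ea,
                other_allele=oa,
                eaf=float(rng.uniform(0.1, 0.9)),
                beta=b,
                se=se,
                pvalue=float(_normal_p(np.array([b]), se)[0]),
                n=250_000,
                trait=label,
            )
        )
    return recs


def _outcome_records(
    rng: np.random.Generator,
    instruments: list[AssociationRecord],
    label: str,
    theta: float,
    sigma: float,
    n_samples: int = 184_305,
) -> list[AssociationRecord]:
    from dataclasses import replace

    from .simulate import _normal_p

    recs = []
    for r in instruments:
        beta = theta * r.beta + sigma * rng.standard_normal()
        recs.append(
            replace(
                r,
                trait=label,
                beta=float(beta),
                se=float(sigma),
                pvalue=float(_normal_p(np.array([beta]), sigma)[0]),
                n=n_samples,
            )
        )
    return recs


def simulate_study(outdir, seed: int) -> Path:
    """Write a complete synthetic study (data files + configuration).

    The exposure is a cis protein-QTL dataset: 13 LD blocks of 3 correlated
    variants inside the cis window (the 13 block leads form the instrument)
    plus decoy variants outside the window or below genome-wide
    significance.  Outcome, risk-factor and lifestyle files follow the
    roster above; one CHD instrument is withheld and recoverable through
    the proxy table.  Returns the path of the written study YAML.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    # --- exposure: cis region with LD blocks + decoys -----------------
    anchor_start, anchor_end = 113_875_000, 113_891_000
    fixture_cfg = ScenarioConfig(
        ld_block_spec=[LDBlock(n_variants=3, within_r2=0.9, span_bp=40_000) for _ in range(13)],
        position_start=anchor_start - 4_000_000,
        seed=int(rng.integers(2**31 - 1)),
    )
    cis_records, ld = generate_ld_fixture(fixture_cfg)
    from dataclasses import replace

    from .simulate import _normal_p

    decoys = []
    far_pos = anchor_end + 5_000_001  # just outside the cis window
    for i, (beta, pos) in enumerate(
        [(0.30, far_pos), (0.28, far_pos + 200_000), (0.004, anchor_start), (0.003, anchor_start + 5_000)]
    ):
        se = 0.01 if beta > 0.01 else 0.01
        decoys.append(
            AssociationRecord(
                variant_id=f"decoy{i + 1:02d}",
                chromosome="2",
                position=pos,
                effect_allele="A",
                other_allele="G",
                eaf=0.3,
                beta=beta,
                se=0.01,
                pvalue=float(_normal_p(np.array([beta]), 0.01)[0]),
                n=30_931,
                trait="IL1Ra",
            )
        )
    exposure_records = [replace(r, trait="IL1Ra", se=_IL1RA_EXPOSURE_SE) for r in cis_records] + decoys
    exposure_records = [
        replace(r, pvalue=float(_normal_p(np.array([r.beta]), r.se)[0])) for r in exposure_records
    ]
    write_sumstats(exposure_records, outdir / "il1ra_cis.tsv")
    ld_all = LDMatrix(
        ld.variant_ids + [d.variant_id for d in decoys],
        np.pad(ld.r2, ((0, len(decoys)), (0, len(decoys)))) + np.diag([0] * len(ld.variant_ids) + [1] * len(decoys)),
    )
    ld_all.to_file(outdir / "ld.tsv")

    instrument_cfg = dict(
        anchor_chromosome="2",
        anchor_start=anchor_start,
        anchor_end=anchor_end,
        window_bp=5_000_000,
        p_threshold=5e-8,
        clump_r2=0.1,
        clump_distance_kb=10_000.0,
    )
    sources: dict[str, dict] = {
        "IL1Ra": {"sumstats": "il1ra_cis.tsv", "ld_matrix": "ld.tsv", "instrument": instrument_cfg}
    }
    screens: list[dict] = []

    lead_ids = [f"rs{1 + 3 * b:04d}" for b in range(13)]

    # --- outcome screens ----------------------------------------------
    for label, trait_set, binary, theta, sigma in _SCREEN_ROSTER:
        out = _outcome_records(rng, [r for r in exposure_records if not r.variant_id.startswith("decoy")],
                               label, theta, sigma)
        spec = {"label": label, "sumstats": f"{label.lower()}.tsv", "set": trait_set, "binary": binary}
        if label == "CHD":
            # withhold one instrument; its block-mate serves as proxy (r2=0.9)
            withheld = lead_ids[0]
            mate = f"rs{2:04d}"
            out = [r for r in out if r.variant_id != withheld]
            from .sumstats import ProxyEntry

            mate_rec = next(r for r in out if r.variant_id == mate)
            withheld_rec = next(r for r in exposure_records if r.variant_id == withheld)
            mapping = {
                mate_rec.effect_allele: withheld_rec.effect_allele,
                mate_rec.other_allele: withheld_rec.other_allele,
            }
            ProxyTable([ProxyEntry(withheld, mate, 0.9, mapping)]).to_file(outdir / "proxies_chd.tsv")
            spec["proxies"] = "proxies_chd.tsv"
        write_sumstats(out, outdir / spec["sumstats"])
        screens.append(spec)

    # --- lifestyle screen (roles swapped) ------------------------------
    for i, (label, effect) in enumerate(_LIFESTYLE_ROSTER):
        instr = _prebuilt_instruments(rng, label, 10, chromosome=str(3 + i), start=10_000_000)
        write_sumstats(instr, outdir / f"{label.lower()}_instruments.tsv")
        il1ra_out = _outcome_records(rng, instr, "IL1Ra", effect, _IL1RA_EXPOSURE_SE, n_samples=30_931)
        write_sumstats(il1ra_out, outdir / f"il1ra_at_{label.lower()}.tsv")
        sources[label] = {"sumstats": f"{label.lower()}_instruments.tsv", "prebuilt": True}
        screens.append(
            {
                "label": "IL1Ra",
                "sumstats": f"il1ra_at_{label.lower()}.tsv",
                "set": "lifestyle",
                "exposure": label,
                "binary": False,
            }
        )

    # --- reverse MR -----------------------------------------------------
    for label in ("CHD", "MI"):
        instr = _prebuilt_instruments(rng, f"{label}rev", 15, chromosome="9", start=22_000_000)
        write_sumstats(instr, outdir / f"{label.lower()}_rev_instruments.tsv")
        il1ra_out = _outcome_records(rng, instr, "IL1Ra", 0.0, _IL1RA_EXPOSURE_SE, n_samples=30_931)
        write_sumstats(il1ra_out, outdir / f"il1ra_at_{label.lower()}_rev.tsv")
        sources[f"{label}rev"] = {"sumstats": f"{label.lower()}_rev_instruments.tsv", "prebuilt": True}
        screens.append(
            {
                "label": "IL1Ra",
                "sumstats": f"il1ra_at_{label.lower()}_rev.tsv",
                "set": "reverse",
                "exposure": f"{label}rev",
                "binary": False,
            }
        )

    # --- MVMR adjustment and mediation bundles -------------------------
    adjustments: list[dict] = []
    mediation: list[dict] = []
    for preset, tag in (("apoB_reversal", "rev"), ("apoB_mediation", "med")):
        chain = load_preset(preset).mediator_chain
        bundle = generate_mediation_scenario(
            ScenarioConfig(mediator_chain=chain, seed=int(rng.integers(2**31 - 1)))
        )
        write_sumstats(bundle.exposure, outdir / f"bundle_{tag}_il1ra.tsv")
        write_sumstats(bundle.mediator, outdir / f"bundle_{tag}_apob.tsv")
        write_sumstats(bundle.outcome, outdir / f"bundle_{tag}_chd.tsv")
        sources[f"IL1Ra_{tag}"] = {"sumstats": f"bundle_{tag}_il1ra.tsv", "prebuilt_significant": True}
        sources[f"ApoB_{tag}"] = {"sumstats": f"bundle_{tag}_apob.tsv", "prebuilt_significant": True}
        if tag == "rev":
            adjustments.append(
                {
                    "exposure": f"IL1Ra_{tag}",
                    "adjuster": f"ApoB_{tag}",
                    "outcome_label": "CHD",
                    "outcome_sumstats": f"bundle_{tag}_chd.tsv",
                }
            )
        else:
            mediation.append(
                {
                    "exposure": f"IL1Ra_{tag}",
                    "mediator": f"ApoB_{tag}",
                    "outcome_label": "CHD",
                    "outcome_sumstats": f"bundle_{tag}_chd.tsv",
                }
            )

    # --- lifestyle attenuation bundles ---------------------------------
    attenuation_specs: list[dict] = []
    for label, (a_eff, target) in _ATTENUATION_CHAINS.items():
        b_eff = float(np.log(1.09))  # exposure -> CHD effect along the chain
        indirect = a_eff * b_eff
        total = indirect / target
        chain = MediatorChain(
            a=a_eff, b=b_eff, theta_direct=total - indirect, n_mediator_snps=13, sigma_m=_IL1RA_EXPOSURE_SE
        )
        bundle = generate_mediation_scenario(
            ScenarioConfig(
                mediator_chain=chain,
                n_snps=20,
                sigma_y=_CHD_SE,
                seed=int(rng.integers(2**31 - 1)),
            )
        )
        tag = label.lower()
        write_sumstats(bundle.exposure, outdir / f"att_{tag}_lifestyle.tsv")
        write_sumstats(bundle.mediator, outdir / f"att_{tag}_il1ra.tsv")
        write_sumstats(bundle.outcome, outdir / f"att_{tag}_chd.tsv")
        sources[f"{label}_att"] = {"sumstats": f"att_{tag}_lifestyle.tsv", "prebuilt_significant": True}
        sources[f"IL1Ra_at_{label}"] = {"sumstats": f"att_{tag}_il1ra.tsv", "prebuilt_significant": True}
        attenuation_specs.append(
            {
                "lifestyle": f"{label}_att",
                "adjuster": f"IL1Ra_at_{label}",
                "outcome_label": "CHD",
                "outcome_sumstats": f"att_{tag}_chd.tsv",
            }
        )

    config = {
        "seed": seed,
        "exposure": "IL1Ra",
        "alpha_family": 0.05,
        "methods": ["ivw", "max_likelihood", "weighted_median", "egger", "presso"],
        "n_boot": 500,
        "n_sim": 500,
        "instrument_sources": sources,
        "screens": screens,
        "adjustments": adjustments,
        "mediation": mediation,
        "attenuation": attenuation_specs,
    }
    path = outdir / "study.yaml"
    path.write_text(yaml.safe_dump(config, sort_keys=False))
    return path
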