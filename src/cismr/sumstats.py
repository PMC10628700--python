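"""GWAS summary-statistics data model, text I/O, harmonization and proxy lookup.

Summary associations are the atomic unit of two-sample Mendelian
randomization: one row per variant per trait, carrying the per-allele
effect (``beta``), its standard error, and the metadata needed to align
effect alleles across studies.  This module provides

* :class:`AssociationRecord` -- a validated per-variant association,
* reading/writing of tab-delimited summary-statistic tables,
* :func:`harmonize_pair` / :func:`harmonize_multi` -- allele alignment of
  exposure and outcome tables into a :class:`HarmonizedSet`,
* :func:`resolve_proxies` -- local substitution of high-LD proxy variants
  for instruments absent from an outcome study.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AssociationRecord",
    "HarmonizedSet",
    "ProxyEntry",
    "ProxyTable",
    "ProxyResolution",
    "ReadResult",
    "CANONICAL_COLUMNS",
    "read_sumstats",
    "write_sumstats",
    "harmonize_pair",
    "harmonize_multi",
    "resolve_proxies",
]

#: canonical column order of the on-disk tab-delimited format
CANONICAL_COLUMNS = (
    "variant_id",
    "chr",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
    "trait",
)

_VALID_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _complement(allele: str) -> str:
    return allele.translate(_COMPLEMENT)[::-1] if len(allele) > 1 else allele.translate(_COMPLEMENT)


@dataclass(frozen=True)
class AssociationRecord:
    """One variant's summary association with one trait.

    ``beta`` is the additive effect per copy of ``effect_allele``, in SD
    units for continuous traits and log-odds for binary traits.  ``eaf``
    (effect-allele frequency) and ``n`` may be missing (``None``).
    """

    variant_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pvalue: float
    n: int | None = None
    trait: str = ""

    def invalid_reason(self) -> str | None:
        """Return a short tag naming the first violated invariant, or None."""
        if not self.variant_id:
            return "missing_variant_id"
        ea, oa = self.effect_allele, self.other_allele
        if not ea or not oa or not (set(ea) <= _VALID_BASES) or not (set(oa) <= _VALID_BASES):
            return "invalid_alleles"
        if ea == oa:
            return "identical_alleles"
        if not np.isfinite(self.beta):
            return "invalid_beta"
        if not np.isfinite(self.se) or self.se <= 0:
            return "invalid_se"
        if not np.isfinite(self.pvalue) or not (0 < self.pvalue <= 1):
            return "invalid_pvalue"
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            return "invalid_eaf"
        return None

    @property
    def is_palindromic(self) -> bool:
        """A/T or G/C single-base pairs whose strand is unresolvable from alleles."""
        return (
            len(self.effect_allele) == 1
            and len(self.other_allele) == 1
            and _complement(self.effect_allele) == self.other_allele
        )

    def flipped(self) -> "AssociationRecord":
        """The same association expressed on the swapped effect allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
        )


@dataclass
class HarmonizedSet:
    """Allele-aligned effect tables for a common set of instruments.

    ``exposure_betas``/``exposure_ses`` have shape (J,) for a single
    exposure or (J, K) for K exposures (multivariable MR); outcome arrays
    have shape (J,).  ``provenance`` maps every variant of the input
    intersection to exactly one flag: ``unchanged``, ``flipped``,
    ``palindromic_inferred``, ``proxy_substituted`` or ``dropped:<reason>``.
    """

    variants: list[str]
    exposure_betas: np.ndarray
    exposure_ses: np.ndarray
    outcome_betas: np.ndarray
    outcome_ses: np.ndarray
    provenance: dict[str, str] = field(default_factory=dict)
    exposure_labels: list[str] = field(default_factory=list)
    outcome_label: str = ""

    def __post_init__(self) -> None:
        self.exposure_betas = np.asarray(self.exposure_betas, dtype=float)
        self.exposure_ses = np.asarray(self.exposure_ses, dtype=float)
        self.outcome_betas = np.asarray(self.outcome_betas, dtype=float)
        self.outcome_ses = np.asarray(self.outcome_ses, dtype=float)
        j = len(self.variants)
        if len(set(self.variants)) != j:
            raise ValueError("duplicate variant in HarmonizedSet")
        for arr in (self.exposure_betas, self.exposure_ses):
            if arr.shape[0] != j:
                raise ValueError("exposure array length mismatch")
        for arr in (self.outcome_betas, self.outcome_ses):
            if arr.shape != (j,):
                raise ValueError("outcome array shape mismatch")

    @property
    def n_snps(self) -> int:
        return len(self.variants)

    @property
    def n_exposures(self) -> int:
        return 1 if self.exposure_betas.ndim == 1 else self.exposure_betas.shape[1]

    def subset(self, keep: Sequence[int]) -> "HarmonizedSet":
        keep = list(keep)
        return HarmonizedSet(
            variants=[self.variants[i] for i in keep],
            exposure_betas=self.exposure_betas[keep],
            exposure_ses=self.exposure_ses[keep],
            outcome_betas=self.outcome_betas[keep],
            outcome_ses=self.outcome_ses[keep],
            provenance={v: self.provenance.get(v, "unchanged") for v in (self.variants[i] for i in keep)},
            exposure_labels=list(self.exposure_labels),
            outcome_label=self.outcome_label,
        )


class ReadResult(NamedTuple):
    records: list[AssociationRecord]
    dropped: Counter


class ProxyEntry(NamedTuple):
    target_variant_id: str
    proxy_variant_id: str
    r2: float
    allele_mapping: dict[str, str]  # proxy allele -> target allele


@dataclass
class ProxyTable:
    """Local stand-in for an LD proxy lookup service."""

    entries: list[ProxyEntry]

    def __post_init__(self) -> None:
        for e in self.entries:
            if not (0.0 <= e.r2 <= 1.0):
                raise ValueError(f"r2 out of [0,1] for proxy {e.proxy_variant_id}")
            vals = list(e.allele_mapping.values())
            if len(set(e.allele_mapping)) != len(e.allele_mapping) or len(set(vals)) != len(vals):
                raise ValueError(f"allele_mapping not a bijection for proxy {e.proxy_variant_id}")

    @classmethod
    def from_file(cls, path) -> "ProxyTable":
        """Read a delimited proxy table.

        Columns: target_variant_id, proxy_variant_id, r2, allele_mapping
        where allele_mapping is e.g. ``A:G,T:C`` (proxy allele : target allele).
        """
        df = pd.read_csv(path, sep="\t", dtype=str)
        entries = []
        for row in df.itertuples(index=False):
            mapping = dict(pair.split(":") for pair in row.allele_mapping.split(","))
            entries.append(ProxyEntry(row.target_variant_id, row.proxy_variant_id, float(row.r2), mapping))
        return cls(entries)

    def to_file(self, path) -> None:
        rows = [
            {
                "target_variant_id": e.target_variant_id,
                "proxy_variant_id": e.proxy_variant_id,
                "r2": repr(e.r2),
                "allele_mapping": ",".join(f"{k}:{v}" for k, v in sorted(e.allele_mapping.items())),
            }
            for e in self.entries
        ]
        pd.DataFrame(rows, columns=["target_variant_id", "proxy_variant_id", "r2", "allele_mapping"]).to_csv(
            path, sep="\t", index=False
        )


class ProxyResolution(NamedTuple):
    substitutions: list[tuple[str, AssociationRecord]]
    unresolved: list[str]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_MANDATORY = ("variant_id", "effect_allele", "other_allele", "beta", "se")


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait: str | None = None,
    sep: str = "\t",
) -> ReadResult:
    """Read a delimited summary-statistics table.

    ``column_map`` maps canonical names (see :data:`CANONICAL_COLUMNS`) to the
    file's column names for non-canonical headers.  Rows violating the
    :class:`AssociationRecord` invariants are dropped and tallied; duplicate
    variant ids keep the smallest-p row (tallied as ``duplicate_id``).
    Missing mandatory columns raise ``ValueError``.
    """
    df = pd.read_csv(path, sep=sep, dtype={"variant_id": str, "chr": str}, float_precision="round_trip")
    colmap = {c: c for c in CANONICAL_COLUMNS}
    if column_map:
        colmap.update(column_map)
    for canon in _MANDATORY:
        if colmap[canon] not in df.columns:
            raise ValueError(f"header lacks mandatory column {colmap[canon]!r} (for {canon!r})")

    def get(row, canon, default=None):
        name = colmap.get(canon)
        if name is None or name not in df.columns:
            return default
        val = row[name]
        return default if pd.isna(val) else val

    dropped: Counter = Counter()
    records: list[AssociationRecord] = []
    for _, row in df.iterrows():
        eaf = get(row, "eaf")
        n = get(row, "n")
        rec = AssociationRecord(
            variant_id=str(get(row, "variant_id", "")),
            chromosome=str(get(row, "chr", "")),
            position=int(get(row, "pos", 0)),
            effect_allele=str(get(row, "effect_allele", "")).upper(),
            other_allele=str(get(row, "other_allele", "")).upper(),
            eaf=None if eaf is None else float(eaf),
            beta=float(get(row, "beta", np.nan)),
            se=float(get(row, "se", np.nan)),
            pvalue=float(get(row, "pvalue", np.nan)),
            n=None if n is None else int(n),
            trait=trait if trait is not None else str(get(row, "trait", "")),
        )
        reason = rec.invalid_reason()
        if reason is None:
            records.append(rec)
        else:
            dropped[reason] += 1

    # duplicate ids: keep smallest p, deterministic tie-break by input order
    best: dict[str, AssociationRecord] = {}
    order: list[str] = []
    for rec in records:
        prev = best.get(rec.variant_id)
        if prev is None:
            best[rec.variant_id] = rec
            order.append(rec.variant_id)
        else:
            dropped["duplicate_id"] += 1
            if rec.pvalue < prev.pvalue:
                best[rec.variant_id] = rec
    return ReadResult([best[v] for v in order], dropped)


def write_sumstats(records: Iterable[AssociationRecord], path) -> None:
    """Write records as tab-delimited text with the canonical header.

    ``read_sumstats(write_sumstats(records))`` is the identity on valid
    records; floats are serialized with ``repr`` so round-trips are exact.
    """
    rows = []
    for r in records:
        rows.append(
            {
                "variant_id": r.variant_id,
                "chr": r.chromosome,
                "pos": r.position,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": "" if r.eaf is None else repr(float(r.eaf)),
                "beta": repr(float(r.beta)),
                "se": repr(float(r.se)),
                "pvalue": repr(float(r.pvalue)),
                "n": "" if r.n is None else int(r.n),
                "trait": r.trait,
            }
        )
    pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------


def _align_outcome(
    exp: AssociationRecord,
    out: AssociationRecord,
    palindrome_policy: str,
    maf_threshold: float,
) -> tuple[AssociationRecord | None, str]:
    """Align one outcome record to the exposure's effect allele.

    Returns (aligned record or None, provenance flag).
    """
    if exp.is_palindromic:
        if not out.is_palindromic or {out.effect_allele, out.other_allele} != {
            exp.effect_allele,
            exp.other_allele,
        }:
            return None, "dropped:allele_mismatch"
        if palindrome_policy == "drop":
            return None, "dropped:palindromic"
        if palindrome_policy != "infer_by_frequency":
            raise ValueError(f"unknown palindrome policy {palindrome_policy!r}")
        if exp.eaf is None or out.eaf is None:
            return None, "dropped:ambiguous_palindrome"
        maf_e = min(exp.eaf, 1 - exp.eaf)
        maf_o = min(out.eaf, 1 - out.eaf)
        if maf_e > maf_threshold or maf_o > maf_threshold:
            return None, "dropped:ambiguous_palindrome"
        # frequencies identify the shared strand: concordant -> letters
        # comparable directly; discordant -> the outcome reports the
        # complementary strand's nominally-same letter, i.e. our other allele
        same_side = (exp.eaf < 0.5) == (out.eaf < 0.5)
        letters_match = out.effect_allele == exp.effect_allele
        # same_side XOR letters_match: either a plain allele swap or an
        # opposite-strand report; both invert beta and complement eaf
        aligned = out if same_side == letters_match else out.flipped()
        # relabel to the exposure's strand so alleles match exactly
        aligned = replace(aligned, effect_allele=exp.effect_allele, other_allele=exp.other_allele)
        return aligned, "palindromic_inferred"

    exp_pair = (exp.effect_allele, exp.other_allele)
    out_pair = (out.effect_allele, out.other_allele)
    if out_pair == exp_pair:
        return out, "unchanged"
    if out_pair == exp_pair[::-1]:
        return out.flipped(), "flipped"
    # try strand recoding (the outcome file reports the opposite strand)
    flip_pair = (_complement(out.effect_allele), _complement(out.other_allele))
    if flip_pair == exp_pair:
        return replace(out, effect_allele=flip_pair[0], other_allele=flip_pair[1]), "unchanged"
    if flip_pair == exp_pair[::-1]:
        return replace(out, effect_allele=flip_pair[0], other_allele=flip_pair[1]).flipped(), "flipped"
    return None, "dropped:allele_mismatch"


def harmonize_pair(
    exposure: Sequence[AssociationRecord],
    outcome: Sequence[AssociationRecord],
    palindrome_policy: str = "infer_by_frequency",
    maf_threshold: float = 0.42,
) -> HarmonizedSet:
    """Align outcome alleles to the exposure's effect alleles.

    Variants present in both lists are kept in exposure order.  Swapped
    alleles flip the outcome beta's sign (and complement eaf); strand flips
    (A<->T, C<->G recoding) are resolved silently; palindromic variants are
    inferred from allele frequency or dropped per ``palindrome_policy``
    (``infer_by_frequency`` or ``drop``).  Every intersection variant
    receives exactly one provenance flag.
    """
    out_by_id = {r.variant_id: r for r in outcome}
    variants: list[str] = []
    ebeta, ese, obeta, ose = [], [], [], []
    provenance: dict[str, str] = {}
    for exp in exposure:
        out = out_by_id.get(exp.variant_id)
        if out is None:
            continue
        aligned, flag = _align_outcome(exp, out, palindrome_policy, maf_threshold)
        provenance[exp.variant_id] = flag
        if aligned is None:
            continue
        variants.append(exp.variant_id)
        ebeta.append(exp.beta)
        ese.append(exp.se)
        obeta.append(aligned.beta)
        ose.append(aligned.se)
    labels = [exposure[0].trait] if exposure else []
    out_label = outcome[0].trait if outcome else ""
    return HarmonizedSet(
        variants=variants,
        exposure_betas=np.array(ebeta, dtype=float),
        exposure_ses=np.array(ese, dtype=float),
        outcome_betas=np.array(obeta, dtype=float),
        outcome_ses=np.array(ose, dtype=float),
        provenance=provenance,
        exposure_labels=labels,
        outcome_label=out_label,
    )


def harmonize_multi(
    exposures: Mapping[str, Sequence[AssociationRecord]],
    outcome: Sequence[AssociationRecord],
    palindrome_policy: str = "infer_by_frequency",
    maf_threshold: float = 0.42,
) -> HarmonizedSet:
    """Harmonize several exposures and one outcome to shared effect alleles.

    The first exposure defines the reference effect allele per variant;
    variants must be present (and reconcilable) in every table to be kept.
    Returns a :class:`HarmonizedSet` with a (J, K) exposure matrix whose
    columns follow the mapping order of ``exposures``.
    """
    labels = list(exposures)
    if not labels:
        raise ValueError("at least one exposure required")
    ref = list(exposures[labels[0]])
    aligned_cols: dict[str, dict[str, AssociationRecord]] = {labels[0]: {r.variant_id: r for r in ref}}
    provenance: dict[str, str] = {}
    for lab in labels[1:]:
        col = {}
        by_id = {r.variant_id: r for r in exposures[lab]}
        for exp in ref:
            other = by_id.get(exp.variant_id)
            if other is None:
                continue
            rec, flag = _align_outcome(exp, other, palindrome_policy, maf_threshold)
            if rec is not None:
                col[exp.variant_id] = rec
            else:
                provenance[exp.variant_id] = flag
        aligned_cols[lab] = col
    out_aligned: dict[str, AssociationRecord] = {}
    out_by_id = {r.variant_id: r for r in outcome}
    for exp in ref:
        out = out_by_id.get(exp.variant_id)
        if out is None:
            continue
        rec, flag = _align_outcome(exp, out, palindrome_policy, maf_threshold)
        if rec is not None:
            out_aligned[exp.variant_id] = rec
            provenance.setdefault(exp.variant_id, flag)
        else:
            provenance[exp.variant_id] = flag

    variants = [
        r.variant_id
        for r in ref
        if r.variant_id in out_aligned and all(r.variant_id in aligned_cols[lab] for lab in labels)
    ]
    eb = np.array([[aligned_cols[lab][v].beta for lab in labels] for v in variants], dtype=float)
    es = np.array([[aligned_cols[lab][v].se for lab in labels] for v in variants], dtype=float)
    ob = np.array([out_aligned[v].beta for v in variants], dtype=float)
    os_ = np.array([out_aligned[v].se for v in variants], dtype=float)
    return HarmonizedSet(
        variants=variants,
        exposure_betas=eb.reshape(len(variants), len(labels)),
        exposure_ses=es.reshape(len(variants), len(labels)),
        outcome_betas=ob,
        outcome_ses=os_,
        provenance={v: provenance.get(v, "unchanged") for v in variants} | provenance,
        exposure_labels=labels,
        outcome_label=outcome[0].trait if outcome else "",
    )


# ---------------------------------------------------------------------------
# Proxy substitution
# ---------------------------------------------------------------------------


def resolve_proxies(
    missing: Sequence[str],
    proxies: ProxyTable,
    outcome: Sequence[AssociationRecord],
    r2_min: float = 0.8,
) -> ProxyResolution:
    """Substitute the best available high-LD proxy for each missing variant.

    For each missing instrument the proxy with the highest r2 >= ``r2_min``
    that is present in the outcome table is chosen; its record is relabelled
    to the target variant with alleles mapped through the proxy table's
    allele mapping.  Variants without a qualifying proxy are reported as
    unresolved (not an error).
    """
    if not (0 < r2_min <= 1):
        raise ValueError("r2_min must be in (0, 1]")
    out_by_id = {r.variant_id: r for r in outcome}
    substitutions: list[tuple[str, AssociationRecord]] = []
    unresolved: list[str] = []
    for target in missing:
        candidates = [
            e
            for e in proxies.entries
            if e.target_variant_id == target and e.r2 >= r2_min and e.proxy_variant_id in out_by_id
        ]
        if not candidates:
            unresolved.append(target)
            continue
        best = max(candidates, key=lambda e: (e.r2, e.proxy_variant_id))
        rec = out_by_id[best.proxy_variant_id]
        mapping = best.allele_mapping
        if rec.effect_allele not in mapping or rec.other_allele not in mapping:
            unresolved.append(target)
            continue
        substitutions.append(
            (
                target,
                replace(
                    rec,
                    variant_id=target,
                    effect_allele=mapping[rec.effect_allele],
                    other_allele=mapping[rec.other_allele],
                ),
            )
        )
    return ProxyResolution(substitutions, unresolved)
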