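"""Genetic instrument construction for cis protein-QTL MR.

The instrument for a circulating protein is built from variants in a cis
window around the coding gene (default +/- 5 Mb), kept at genome-wide
significance (p < 5e-8), pruned to approximate linkage equilibrium by
greedy PLINK-style clumping (r2 < 0.1 within a 10,000 kb window, smallest
p retained), and scaled to a one-SD change in the exposure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .sumstats import AssociationRecord

__all__ = ["InstrumentConfig", "LDMatrix", "select_cis_significant", "clump", "scale_to_sd"]


@dataclass
class InstrumentConfig:
    """Selection parameters for a cis instrument.

    ``anchor_start``/``anchor_end`` bracket the gene body (1-based,
    inclusive); the search window extends ``window_bp`` on both sides.
    """

    anchor_chromosome: str = ""
    anchor_start: int = 0
    anchor_end: int = 0
    window_bp: int = 5_000_000
    p_threshold: float = 5e-8
    clump_r2: float = 0.1
    clump_distance_kb: float = 10_000.0

    def __post_init__(self) -> None:
        if self.window_bp < 0:
            raise ValueError("window_bp must be >= 0")
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must be in (0,1)")
        if not (0 <= self.clump_r2 <= 1):
            raise ValueError("clump_r2 must be in [0,1]")
        if self.clump_distance_kb <= 0:
            raise ValueError("clump_distance_kb must be > 0")


@dataclass
class LDMatrix:
    """Square symmetric matrix of pairwise r2 between variants."""

    variant_ids: list[str]
    r2: np.ndarray
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.variant_ids)
        if self.r2.shape != (n, n):
            raise ValueError("r2 matrix shape does not match variant list")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValueError("r2 diagonal must be 1")
        if np.any(self.r2 < 0) or np.any(self.r2 > 1):
            raise ValueError("r2 entries must lie in [0,1]")
        if not np.allclose(self.r2, self.r2.T):
            raise ValueError("r2 matrix must be symmetric")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def lookup(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    @classmethod
    def from_file(cls, path) -> "LDMatrix":
        """Read a square matrix with variant ids as header row and first column."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns), df.to_numpy(dtype=float))

    def to_file(self, path) -> None:
        pd.DataFrame(self.r2, index=self.variant_ids, columns=self.variant_ids).to_csv(path, sep="\t")

    @classmethod
    def from_triplets(cls, triplets: Sequence[tuple[str, str, float]], variant_ids: Sequence[str]) -> "LDMatrix":
        """Build from long-format (id_a, id_b, r2) entries; unlisted pairs are 0."""
        ids = list(variant_ids)
        idx = {v: i for i, v in enumerate(ids)}
        m = np.eye(len(ids))
        for a, b, r2 in triplets:
            m[idx[a], idx[b]] = m[idx[b], idx[a]] = float(r2)
        return cls(ids, m)


def select_cis_significant(
    records: Sequence[AssociationRecord], config: InstrumentConfig
) -> list[AssociationRecord]:
    """Variants on the anchor chromosome within the cis window at p < threshold.

    The window is [anchor_start - window_bp, anchor_end + window_bp],
    inclusive on both ends; the significance cut is strict (p exactly at the
    threshold is excluded).
    """
    lo = config.anchor_start - config.window_bp
    hi = config.anchor_end + config.window_bp
    return [
        r
        for r in records
        if r.chromosome == config.anchor_chromosome
        and lo <= r.position <= hi
        and r.pvalue < config.p_threshold
    ]


def clump(
    records: Sequence[AssociationRecord], ld: LDMatrix, config: InstrumentConfig
) -> list[AssociationRecord]:
    """Greedy LD clumping: retain index variants, prune their LD neighbours.

    Repeatedly takes the remaining variant with the smallest p-value (ties
    broken lexicographically by variant id) and removes every remaining
    variant with r2 >= ``clump_r2`` against it *among those within*
    ``clump_distance_kb``; pairs farther apart are never pruned.  Returns
    the retained index variants ordered by ascending p-value.
    """
    for r in records:
        if r.variant_id not in ld:
            raise KeyError(f"variant {r.variant_id!r} missing from LD matrix")
    remaining = sorted(records, key=lambda r: (r.pvalue, r.variant_id))
    retained: list[AssociationRecord] = []
    while remaining:
        index = remaining.pop(0)
        retained.append(index)
        max_bp = config.clump_distance_kb * 1000.0
        remaining = [
            r
            for r in remaining
            if not (
                r.chromosome == index.chromosome
                and abs(r.position - index.position) <= max_bp
                and ld.lookup(index.variant_id, r.variant_id) >= config.clump_r2
            )
        ]
    return retained


def scale_to_sd(records: Sequence[AssociationRecord], sd_of_trait: float) -> list[AssociationRecord]:
    """Rescale betas and SEs so effects are per one SD of the trait."""
    if not (sd_of_trait > 0):
        raise ValueError("sd_of_trait must be > 0")
    return [replace(r, beta=r.beta / sd_of_trait, se=r.se / sd_of_trait) for r in records]
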