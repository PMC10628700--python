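"""Shared fixtures: record factories and harmonized-set builders."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from cismr.sumstats import AssociationRecord, HarmonizedSet

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def make_record():
    """Factory for valid AssociationRecords with overridable fields."""

    def _make(variant_id="rs1", **kwargs):
        defaults = dict(
            variant_id=variant_id,
            chromosome="2",
            position=113_000_000,
            effect_allele="A",
            other_allele="G",
            eaf=0.3,
            beta=0.1,
            se=0.01,
            pvalue=1e-10,
            n=30_931,
            trait="exposure",
        )
        defaults.update(kwargs)
        return AssociationRecord(**defaults)

    return _make


@pytest.fixture
def make_harmonized():
    """Build a HarmonizedSet directly from effect arrays."""

    def _make(bx, sx, by, sy, labels=None):
        bx = np.asarray(bx, dtype=float)
        j = bx.shape[0]
        return HarmonizedSet(
            variants=[f"rs{i + 1}" for i in range(j)],
            exposure_betas=bx,
            exposure_ses=np.asarray(sx, dtype=float),
            outcome_betas=np.asarray(by, dtype=float),
            outcome_ses=np.asarray(sy, dtype=float),
            provenance={f"rs{i + 1}": "unchanged" for i in range(j)},
            exposure_labels=labels or ["exposure"],
            outcome_label="outcome",
        )

    return _make
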