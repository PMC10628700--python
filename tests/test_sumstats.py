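"""Summary-statistics I/O, harmonization and proxy substitution."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cismr.estimators import ivw
from cismr.sumstats import (
    AssociationRecord,
    ProxyEntry,
    ProxyTable,
    harmonize_pair,
    read_sumstats,
    resolve_proxies,
    write_sumstats,
)

ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("C", "A"), ("A", "T"), ("G", "C")]


def record_strategy(trait="exposure"):
    finite = dict(allow_nan=False, allow_infinity=False)

    def build(i, pair, eaf, beta, se, pvalue):
        return AssociationRecord(
            variant_id=f"rs{i}",
            chromosome="2",
            position=113_000_000 + i * 1000,
            effect_allele=pair[0],
            other_allele=pair[1],
            eaf=eaf,
            beta=beta,
            se=se,
            pvalue=pvalue,
            n=30_931,
            trait=trait,
        )

    return st.builds(
        build,
        i=st.integers(0, 10**6),
        pair=st.sampled_from(ALLELE_PAIRS),
        eaf=st.one_of(st.none(), st.floats(0.01, 0.99, **finite)),
        beta=st.floats(-2, 2, **finite),
        se=st.floats(1e-6, 1.0, **finite),
        pvalue=st.floats(1e-300, 1.0, exclude_min=False, **finite),
    )


class TestReadWrite:
    def test_well_formed_table_round_trips(self, tmp_path, make_record):
        records = [make_record(f"rs{i}", beta=0.1 * i - 0.1) for i in range(3)]
        path = tmp_path / "s.tsv"
        write_sumstats(records, path)
        res = read_sumstats(path)
        assert res.records == records
        assert sum(res.dropped.values()) == 0

    def test_invalid_se_row_dropped_and_tallied(self, tmp_path, make_record):
        path = tmp_path / "s.tsv"
        write_sumstats([make_record("rs1"), make_record("rs2")], path)
        text = path.read_text().replace("\t0.01\t", "\t0.0\t", 1)
        path.write_text(text)
        res = read_sumstats(path)
        assert len(res.records) == 1
        assert res.dropped == {"invalid_se": 1}

    def test_duplicate_id_keeps_smallest_p(self, tmp_path, make_record):
        records = [make_record("rs1", pvalue=1e-8), make_record("rs1", pvalue=1e-12, beta=0.5)]
        path = tmp_path / "s.tsv"
        write_sumstats(records, path)
        res = read_sumstats(path)
        assert len(res.records) == 1
        assert res.records[0].beta == 0.5
        assert res.dropped["duplicate_id"] == 1

    def test_empty_list_gives_header_only_file(self, tmp_path):
        path = tmp_path / "s.tsv"
        write_sumstats([], path)
        assert len(path.read_text().strip().splitlines()) == 1
        assert read_sumstats(path).records == []

    def test_missing_mandatory_column_raises(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("variant_id\tbeta\nrs1\t0.1\n")
        with pytest.raises(ValueError, match="mandatory"):
            read_sumstats(path)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_sumstats(tmp_path / "absent.tsv")

    def test_column_map_renames(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text(
            "SNP\tchr\tpos\tA1\tA2\teaf\tbeta\tse\tpvalue\tn\trait\n"
            "rs9\t2\t100\tA\tG\t0.2\t0.1\t0.01\t1e-9\t1000\tx\n"
        )
        res = read_sumstats(path, column_map={"variant_id": "SNP", "effect_allele": "A1", "other_allele": "A2"})
        assert res.records[0].variant_id == "rs9"
        assert res.records[0].effect_allele == "A"

    @given(st.lists(record_strategy(), max_size=40, unique_by=lambda r: r.variant_id))
    def test_round_trip_is_identity(self, tmp_path_factory, records):
        path = tmp_path_factory.mktemp("rt") / "s.tsv"
        write_sumstats(records, path)
        res = read_sumstats(path)
        assert res.records == records
        assert sum(res.dropped.values()) == 0


class TestHarmonize:
    def test_allele_swap_flips_beta(self, make_record):
        exp = [make_record("rs1", effect_allele="A", other_allele="G", beta=0.10)]
        out = [make_record("rs1", effect_allele="G", other_allele="A", beta=-0.05, trait="outcome")]
        h = harmonize_pair(exp, out)
        assert h.outcome_betas[0] == pytest.approx(0.05)
        assert h.provenance["rs1"] == "flipped"

    def test_strand_recoding_resolved(self, make_record):
        # outcome reported on the opposite strand: A/G appears as T/C
        exp = [make_record("rs1", effect_allele="A", other_allele="G", beta=0.10)]
        out = [make_record("rs1", effect_allele="T", other_allele="C", beta=0.07, trait="outcome")]
        h = harmonize_pair(exp, out)
        assert h.outcome_betas[0] == pytest.approx(0.07)
        assert h.provenance["rs1"] == "unchanged"

    def test_palindromic_inferred_from_concordant_frequencies(self, make_record):
        exp = [make_record("rs1", effect_allele="A", other_allele="T", eaf=0.10)]
        out = [make_record("rs1", effect_allele="A", other_allele="T", eaf=0.12, beta=0.07, trait="outcome")]
        h = harmonize_pair(exp, out)
        assert h.outcome_betas[0] == pytest.approx(0.07)
        assert h.provenance["rs1"] == "palindromic_inferred"

    def test_palindromic_discordant_frequencies_flip(self, make_record):
        exp = [make_record("rs1", effect_allele="A", other_allele="T", eaf=0.10)]
        out = [make_record("rs1", effect_allele="A", other_allele="T", eaf=0.88, beta=0.07, trait="outcome")]
        h = harmonize_pair(exp, out)
        assert h.outcome_betas[0] == pytest.approx(-0.07)

    def test_ambiguous_palindrome_dropped(self, make_record):
        exp = [make_record("rs1", effect_allele="A", other_allele="T", eaf=0.49)]
        out = [make_record("rs1", effect_allele="A", other_allele="T", eaf=0.50, trait="outcome")]
        h = harmonize_pair(exp, out)
        assert h.n_snps == 0
        assert h.provenance["rs1"] == "dropped:ambiguous_palindrome"

    def test_palindrome_policy_drop(self, make_record):
        exp = [make_record("rs1", effect_allele="G", other_allele="C", eaf=0.1)]
        out = [make_record("rs1", effect_allele="G", other_allele="C", eaf=0.1, trait="outcome")]
        h = harmonize_pair(exp, out, palindrome_policy="drop")
        assert h.provenance["rs1"] == "dropped:palindromic"

    def test_palindrome_missing_eaf_dropped(self, make_record):
        exp = [make_record("rs1", effect_allele="A", other_allele="T", eaf=None)]
        out = [make_record("rs1", effect_allele="A", other_allele="T", eaf=0.2, trait="outcome")]
        h = harmonize_pair(exp, out)
        assert h.provenance["rs1"] == "dropped:ambiguous_palindrome"

    def test_irreconcilable_alleles_dropped_with_flag(self, make_record):
        exp = [make_record("rs1", effect_allele="A", other_allele="G")]
        out = [make_record("rs1", effect_allele="A", other_allele="C", trait="outcome")]
        h = harmonize_pair(exp, out)
        assert h.n_snps == 0
        assert h.provenance["rs1"] == "dropped:allele_mismatch"

    def test_provenance_complete_over_intersection(self, make_record):
        exp = [
            make_record("rs1"),
            make_record("rs2", effect_allele="A", other_allele="T", eaf=0.49),
            make_record("rs3", effect_allele="T", other_allele="C"),
        ]
        out = [
            make_record("rs1", trait="o"),
            make_record("rs2", effect_allele="A", other_allele="T", eaf=0.5, trait="o"),
            make_record("rs3", effect_allele="C", other_allele="T", beta=-0.2, trait="o"),
            make_record("rs4", trait="o"),
        ]
        h = harmonize_pair(exp, out)
        dropped = [f for f in h.provenance.values() if f.startswith("dropped")]
        assert len(h.provenance) == 3  # |intersection|
        assert h.n_snps + len(dropped) == 3

    def test_harmonization_idempotent(self, make_record):
        exp = [
            make_record("rs1", effect_allele="A", other_allele="G", beta=0.1),
            make_record("rs2", effect_allele="T", other_allele="C", beta=0.2),
        ]
        out = [
            make_record("rs1", effect_allele="G", other_allele="A", beta=-0.05, trait="o"),
            make_record("rs2", effect_allele="T", other_allele="C", beta=0.04, trait="o"),
        ]
        h1 = harmonize_pair(exp, out)
        # rebuild outcome records from the aligned output and re-harmonize
        realigned = [
            AssociationRecord(
                variant_id=v,
                chromosome="2",
                position=1,
                effect_allele=e.effect_allele,
                other_allele=e.other_allele,
                eaf=e.eaf,
                beta=float(h1.outcome_betas[i]),
                se=float(h1.outcome_ses[i]),
                pvalue=0.5,
                trait="o",
            )
            for i, (v, e) in enumerate(zip(h1.variants, exp))
        ]
        h2 = harmonize_pair(exp, realigned)
        np.testing.assert_array_equal(h1.outcome_betas, h2.outcome_betas)
        assert all(flag == "unchanged" for flag in h2.provenance.values())

    def test_sign_symmetry_preserves_ivw(self, make_record):
        rng = np.random.default_rng(4)
        exp, out = [], []
        for i in range(6):
            b = rng.normal(0.3, 0.05)
            exp.append(make_record(f"rs{i}", beta=b))
            out.append(make_record(f"rs{i}", beta=0.1 * b + rng.normal(0, 0.01), trait="o"))
        flip = lambda recs: [
            AssociationRecord(**{**r.__dict__, "beta": -r.beta}) for r in recs
        ]
        e1 = ivw(harmonize_pair(exp, out))
        e2 = ivw(harmonize_pair(flip(exp), flip(out)))
        assert e1.beta == pytest.approx(e2.beta, abs=1e-12)
        assert e1.se == pytest.approx(e2.se, abs=1e-12)


class TestProxies:
    def _outcome(self, make_record):
        return [
            make_record("rs_p1", effect_allele="T", other_allele="C", beta=0.03, trait="o"),
            make_record("rs_p2", effect_allele="A", other_allele="G", beta=0.05, trait="o"),
        ]

    def test_highest_r2_proxy_chosen(self, make_record):
        table = ProxyTable(
            [
                ProxyEntry("rs_m", "rs_p1", 0.95, {"T": "A", "C": "G"}),
                ProxyEntry("rs_m", "rs_p2", 0.85, {"A": "A", "G": "G"}),
            ]
        )
        res = resolve_proxies(["rs_m"], table, self._outcome(make_record), r2_min=0.8)
        assert res.unresolved == []
        target, rec = res.substitutions[0]
        assert target == "rs_m" and rec.variant_id == "rs_m"
        assert rec.beta == pytest.approx(0.03)  # from the r2=0.95 proxy
        assert (rec.effect_allele, rec.other_allele) == ("A", "G")  # mapped alleles

    def test_below_threshold_unresolved(self, make_record):
        table = ProxyTable([ProxyEntry("rs_m", "rs_p1", 0.5, {"T": "A", "C": "G"})])
        res = resolve_proxies(["rs_m"], table, self._outcome(make_record), r2_min=0.8)
        assert res.substitutions == [] and res.unresolved == ["rs_m"]

    def test_empty_missing_list(self, make_record):
        res = resolve_proxies([], ProxyTable([]), self._outcome(make_record))
        assert res.substitutions == [] and res.unresolved == []

    def test_table_round_trip(self, tmp_path):
        table = ProxyTable([ProxyEntry("rs_m", "rs_p1", 0.95, {"T": "A", "C": "G"})])
        table.to_file(tmp_path / "p.tsv")
        back = ProxyTable.from_file(tmp_path / "p.tsv")
        assert back.entries == table.entries
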