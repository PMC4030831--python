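"""Domain extraction, pairwise/progressive alignment, identity, consensus.

The pairwise aligner is validated against exhaustive enumeration of every
global alignment for short sequences, scored by an independent function that
knows nothing about the DP recurrences.
"""

import pytest

from conftest import brute_force_global_alignments, make_msa, score_alignment

from itbkit.alignment import (
    blosum62_score,
    consensus_sequence,
    exclude_ambiguous_columns,
    extract_domain,
    family_identity_summary,
    global_align_pair,
    percent_identity,
    progressive_align,
)
from itbkit.records import DomainAnnotation, ProteinRecord


class TestExtractDomain:
    def test_cytoplasmic_tail_length(self):
        rec = ProteinRecord(id="p", sequence="A" * 768)
        ann = DomainAnnotation("p", "cytoplasmic", 724, 768)
        assert len(extract_domain(rec, ann)) == 45

    def test_single_residue(self):
        rec = ProteinRecord(id="p", sequence="ACDEF")
        ann = DomainAnnotation("p", "transmembrane", 3, 3)
        assert extract_domain(rec, ann) == "D"

    def test_out_of_bounds_rejected(self):
        rec = ProteinRecord(id="p", sequence="ACDEF")
        ann = DomainAnnotation("p", "beta_tail", 3, 9)
        with pytest.raises(ValueError, match="exceeds length"):
            extract_domain(rec, ann)

    def test_wrong_record_rejected(self):
        rec = ProteinRecord(id="p", sequence="ACDEF")
        ann = DomainAnnotation("q", "beta_tail", 1, 2)
        with pytest.raises(ValueError, match="annotation is for"):
            extract_domain(rec, ann)


class TestGlobalAlignPair:
    def test_identical_sequences_align_gapless(self):
        a, b, _ = global_align_pair("NPIYKSAV", "NPIYKSAV")
        assert a == b == "NPIYKSAV"

    def test_single_mismatch_stays_gapless(self):
        a, b, _ = global_align_pair("NPIY", "NPKY")
        assert a == "NPIY" and b == "NPKY"
        assert percent_identity(a, b) == 75.0

    def test_length_one_versus_four_introduces_three_gaps(self):
        a, b, _ = global_align_pair("A", "AAAA")
        assert a.count("-") == 3 and b.count("-") == 0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            global_align_pair("", "ACD")

    def test_optimal_against_exhaustive_enumeration(self, rng):
        """DP score equals the brute-force optimum over all alignments."""
        alphabet = "ACDEGKNPVY"
        for _ in range(40):
            a = "".join(rng.choices(alphabet, k=rng.randrange(1, 6)))
            b = "".join(rng.choices(alphabet, k=rng.randrange(1, 6)))
            ra, rb, got = global_align_pair(a, b)
            # Returned alignment scores what the DP claims.
            assert score_alignment(ra, rb, blosum62_score, 10.0, 0.5) == pytest.approx(got)
            best = max(
                score_alignment(x, y, blosum62_score, 10.0, 0.5)
                for x, y in brute_force_global_alignments(a, b)
            )
            assert got == pytest.approx(best)


class TestPercentIdentity:
    def test_gap_columns_excluded_from_denominator(self):
        assert percent_identity("NP-Y", "NPKY") == 100.0

    def test_symmetry(self, rng):
        for _ in range(50):
            n = rng.randrange(1, 12)
            a = "".join(rng.choices("ACD-", k=n))
            b = "".join(rng.choices("ACD-", k=n))
            try:
                ours = percent_identity(a, b)
            except ValueError:
                with pytest.raises(ValueError):
                    percent_identity(b, a)
                continue
            assert ours == percent_identity(b, a)
            mutual = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
            assert (ours == 100.0) == all(x == y for x, y in mutual)

    def test_no_comparable_columns_rejected(self):
        with pytest.raises(ValueError):
            percent_identity("A-", "-A")


class TestIdentitySummary:
    def test_identical_rows(self):
        msa = make_msa({"a": "NPIY", "b": "NPIY", "c": "NPIY"})
        s = family_identity_summary(msa)
        assert s["min_identity"] == s["mean_identity"] == 100.0
        assert s["conserved_fraction"] == 1.0

    def test_single_pair(self):
        msa = make_msa({"a": "NPIY", "b": "NPKY"})
        s = family_identity_summary(msa)
        assert s["min_identity"] == s["mean_identity"] == 75.0
        assert s["conserved_fraction"] == 0.75

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            family_identity_summary(make_msa({"a": "NPIY"}))


class TestConsensus:
    def test_single_row_is_itself(self):
        assert consensus_sequence(make_msa({"a": "NP-Y"})) == "NP-Y"

    def test_plurality_and_tie_rules(self):
        msa = make_msa({"a": "AAV", "b": "AVV", "c": "VA-"})
        # col0 {A,A,V} -> A; col1 {A,V,A} -> A; col2 {V,V} -> V
        assert consensus_sequence(msa) == "AAV"
        tie = make_msa({"a": "AV", "b": "VA"})
        assert consensus_sequence(tie) == "XX"

    def test_consensus_of_identical_rows_equals_row(self):
        msa = make_msa({"a": "KLLMIIHDRKEFAK", "b": "KLLMIIHDRKEFAK"})
        assert consensus_sequence(msa) == "KLLMIIHDRKEFAK"


class TestColumnFilter:
    def test_gapless_alignment_unchanged(self):
        msa = make_msa({"a": "ACDE", "b": "ACDF"})
        out = exclude_ambiguous_columns(msa, 0.5)
        assert out.rows == msa.rows
        assert out.column_map == (0, 1, 2, 3)

    def test_threshold_counts_gaps(self):
        # col1 has 2/4 gaps (> 0.25, dropped); col2 has 1/4 (kept).
        msa = make_msa({"a": "A-CE", "b": "AC-E", "c": "A-DE", "d": "ACDE"})
        out = exclude_ambiguous_columns(msa, 0.25)
        assert out.column_map == (0, 2, 3)

    def test_threshold_one_keeps_partial_columns(self):
        msa = make_msa({"a": "A-C", "b": "A-C"})
        out = exclude_ambiguous_columns(msa, 1.0)
        assert out.rows == ("A-C", "A-C")

    def test_retained_columns_keep_order(self, rng):
        for _ in range(20):
            n = rng.randrange(2, 10)
            rows = {}
            for k in range(3):
                rows[f"r{k}"] = "".join(rng.choices("AC-", k=n))
            try:
                out = exclude_ambiguous_columns(make_msa(rows), 0.4)
            except ValueError:
                continue
            assert list(out.column_map) == sorted(out.column_map)

    def test_all_columns_removed_is_error(self):
        msa = make_msa({"a": "A-", "b": "-A"})
        with pytest.raises(ValueError, match="every column"):
            exclude_ambiguous_columns(msa, 0.0)


class TestProgressiveAlign:
    def test_identical_sequences_stay_gapless(self):
        recs = [ProteinRecord(id=f"s{i}", sequence="MKVLNPIY") for i in range(4)]
        msa = progressive_align(recs)
        assert all(row == "MKVLNPIY" for row in msa.rows)

    def test_rows_reproduce_inputs_and_share_length(self):
        recs = [
            ProteinRecord(id="a", sequence="MKVLNPIYEGK"),
            ProteinRecord(id="b", sequence="MKVNPIYEGK"),
            ProteinRecord(id="c", sequence="MKVLNPIYK"),
        ]
        msa = progressive_align(recs)
        lengths = {len(r) for r in msa.rows}
        assert len(lengths) == 1
        for rec, row in zip(msa.records, msa.rows):
            assert row.replace("-", "") == rec.sequence
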