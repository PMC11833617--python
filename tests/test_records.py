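"""Record parsing, mature-peptide extraction and library statistics."""

import logging

import numpy as np
import pytest

from metavenom import records as rec
from metavenom.records import (
    MaturePeptide,
    ParentRecord,
    ProcessingFeature,
    RecordFormatError,
    collapse_by_sequence,
    cys_pair_correlation,
    extract_mature,
    length_filter,
    library_stats,
    parse_records,
    write_records,
)
from metavenom.simulate import make_parent_db


def _pep(seq, pid="p"):
    return MaturePeptide(id=pid, parent_accession=pid, sequence=seq)


def _table(tmp_path, rows):
    path = tmp_path / "records.tsv"
    header = "accession\torganism\tlineage\tsequence\tfeatures\n"
    path.write_text(header + "".join(r + "\n" for r in rows))
    return path


class TestParsing:
    def test_full_length_chain(self, tmp_path):
        path = _table(tmp_path, ["A1\torg\tPhy;Cls\tACDEF\tCHAIN:1..5"])
        (r,) = parse_records(path)
        assert r.features[0].resolved
        assert extract_mature(r)[0].sequence == "ACDEF"

    def test_out_of_range_feature_skips_record(self, tmp_path, caplog):
        path = _table(
            tmp_path,
            ["A1\torg\tPhy;Cls\tACDEF\tPEPTIDE:3..7", "A2\torg\tPhy;Cls\tACDEF\tCHAIN:1..5"],
        )
        with caplog.at_level(logging.WARNING):
            out = parse_records(path)
        assert [r.accession for r in out] == ["A2"]
        assert "line 2" in caplog.text

    def test_nonstandard_residues_rejected(self, tmp_path, caplog):
        path = _table(tmp_path, ["A1\torg\tPhy\tACDEU\t", "A2\torg\tPhy\tACDEF\t"])
        with caplog.at_level(logging.WARNING):
            out = parse_records(path)
        assert [r.accession for r in out] == ["A2"]

    def test_unresolved_coordinates_preserved(self, tmp_path):
        path = _table(tmp_path, ["A1\torg\tPhy\tACDEF\tPEPTIDE:?..5,CHAIN:1..5"])
        (r,) = parse_records(path)
        assert not r.features[0].resolved and r.features[1].resolved
        assert extract_mature(r)[0].sequence == "ACDEF"  # only the resolved one

    def test_missing_column_raises(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("accession\tsequence\nA1\tACDEF\n")
        with pytest.raises(RecordFormatError):
            parse_records(path)

    def test_duplicate_accession_skipped(self, tmp_path, caplog):
        path = _table(tmp_path, ["A1\torg\tPhy\tACDEF\t", "A1\torg\tPhy\tGHIKL\t"])
        with caplog.at_level(logging.WARNING):
            out = parse_records(path)
        assert len(out) == 1

    def test_roundtrip_byte_identical_on_synthetic_db(self, tmp_path):
        recs = make_parent_db(100, seed=3, frac_unresolved=0.2)
        p1 = tmp_path / "a.tsv"
        p2 = tmp_path / "b.tsv"
        write_records(recs, p1)
        write_records(parse_records(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert len(parse_records(p1)) == 100


class TestExtraction:
    def test_one_based_inclusive_slice(self):
        r = ParentRecord(
            "A1", "org", ("Phy",), "ACDEFGHIKLMNPQRSTVWY",
            (ProcessingFeature("PEPTIDE", 3, 7, True),),
        )
        (p,) = extract_mature(r)
        assert p.sequence == "DEFGH"
        assert p.id == "A1|3-7"

    def test_overlapping_features_both_emitted(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        r = ParentRecord(
            "A1", "org", ("Phy",), seq,
            (ProcessingFeature("CHAIN", 1, 10, True), ProcessingFeature("PEPTIDE", 5, 20, True)),
        )
        out = extract_mature(r)
        # naive-slicing oracle
        assert [p.sequence for p in out] == [seq[0:10], seq[4:20]]

    def test_no_resolved_features_yields_empty(self):
        r = ParentRecord(
            "A1", "org", ("Phy",), "ACDEF",
            (ProcessingFeature("CHAIN", None, 5, False, "?", "5"),),
        )
        assert extract_mature(r) == []

    def test_extraction_always_substring(self):
        for r in make_parent_db(50, seed=9):
            for p in extract_mature(r):
                assert p.sequence in r.sequence


class TestLengthFilter:
    def test_boundary_inclusive_at_max(self):
        peps = [_pep("A" * n, str(n)) for n in (89, 90, 91)]
        assert [p.length for p in length_filter(peps, 90)] == [89, 90]

    def test_empty_input(self):
        assert length_filter([], 90) == []

    def test_counting_on_distinct_lengths(self):
        peps = [_pep("A" * n, str(n)) for n in range(1, 201)]
        assert len(length_filter(peps, 90)) == 90

    def test_idempotence(self):
        peps = [_pep("A" * n, str(n)) for n in range(1, 120)]
        once = length_filter(peps, 90)
        assert length_filter(once, 90) == once

    def test_collapse_accumulates_parents(self):
        peps = [
            MaturePeptide("a|1-2", "a", "CC", parents=("a",)),
            MaturePeptide("b|1-2", "b", "CC", parents=("b",)),
            MaturePeptide("c|1-3", "c", "CCC", parents=("c",)),
        ]
        out = collapse_by_sequence(peps)
        assert len(out) == 2
        assert out[0].parents == ("a", "b")


class TestLibraryStats:
    def test_hand_counted_fractions(self):
        s = library_stats([_pep("AA"), _pep("CC"), _pep("CCC")])
        assert s.frac_no_cys == pytest.approx(1 / 3)
        assert s.frac_even_cys == pytest.approx(1 / 3)
        assert s.frac_odd_cys == pytest.approx(1 / 3)
        assert s.frac_ge2_cys == pytest.approx(2 / 3)
        assert s.cys_histogram == {0: 1, 2: 1, 3: 1}

    def test_identical_peptides_single_bin(self):
        s = library_stats([_pep("CCAA")] * 5)
        assert s.cys_histogram == {2: 5}

    def test_fraction_families_partition(self):
        recs = make_parent_db(500, seed=4)
        peps = [p for r in recs for p in extract_mature(r)]
        s = library_stats(peps)
        assert s.frac_no_cys + s.frac_odd_cys + s.frac_even_cys == pytest.approx(1.0, abs=1e-9)
        assert sum(s.cys_histogram.values()) == s.n_members

    def test_generator_fraction_recovery(self):
        """Cysteine-class generator targets (8% none / 22% odd / 70% even)
        are recovered within binomial error at n = 10,000."""
        recs = make_parent_db(10_000, seed=5)
        peps = [p for r in recs for p in extract_mature(r)]
        s = library_stats(peps)
        n = s.n_members
        for frac, target in [
            (s.frac_no_cys, 0.08),
            (s.frac_odd_cys, 0.22),
            (s.frac_even_cys, 0.70),
        ]:
            sigma = (target * (1 - target) / n) ** 0.5
            assert abs(frac - target) < 3 * sigma

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            library_stats([])


class TestCysPairCorrelation:
    def test_identical_counts_perfect_correlation(self):
        pairs = [(_pep("C" * k + "A"), _pep("AC" * k)) for k in (1, 2, 3, 5)]
        r, joint = cys_pair_correlation(pairs)
        assert r == pytest.approx(1.0)
        assert joint.sum() == len(pairs)

    def test_independent_counts_near_zero(self, rng):
        pairs = [
            (_pep("C" * int(rng.integers(0, 9)) + "A"), _pep("C" * int(rng.integers(0, 9)) + "A"))
            for _ in range(1000)
        ]
        r, _ = cys_pair_correlation(pairs)
        assert abs(r) < 0.1

    def test_conserved_generator_high_correlation(self):
        """Homologs generated with cysteine conservation keep their source's
        cysteine count, giving a near-perfect pair correlation."""
        from metavenom.simulate import mutate_to_identity

        recs = make_parent_db(300, seed=6)
        pairs = []
        for i, r in enumerate(recs):
            (p,) = extract_mature(r)
            hom = mutate_to_identity(p.sequence, 0.6, i, preserve_cys=True)
            pairs.append((p, _pep(hom)))
        r_coef, _ = cys_pair_correlation(pairs)
        assert r_coef > 0.9

    def test_zero_variance_flagged(self):
        pairs = [(_pep("CC"), _pep("C" * k + "A")) for k in (1, 2, 3)]
        with pytest.raises(ValueError, match="variance"):
            cys_pair_correlation(pairs)
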