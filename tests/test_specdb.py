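"""Database queries, background frequencies, and the TSV dialect."""

import numpy as np
import pytest

from kinspec.alphabet import AA20, AA_INDEX, CMGC, SERINE_THREONINE
from kinspec.errors import DatabaseFormatError, KinspecError
from kinspec.specdb import (
    PhosphositeRecord,
    SpecificityDatabase,
    background_frequencies,
    export_database,
    import_database,
    query_matching_sites,
)
from kinspec.substitution import SimilarityPolicy


def _rec(kid="K1", ktype=SERINE_THREONINE, sdr="KDESL", sub="S1", pos=10,
         hept="AAASAAA"):
    return PhosphositeRecord(kid, ktype, sdr, sub, pos, hept)


class TestRecordValidation:
    def test_wrong_heptamer_length(self):
        with pytest.raises(KinspecError, match="length 7"):
            _rec(hept="AAASAA")

    def test_centre_must_match_phospho_alphabet(self):
        with pytest.raises(KinspecError, match="phospho alphabet"):
            _rec(hept="AAAYAAA")  # Y centre on an S/T kinase
        _rec(ktype="tyrosine", hept="AAAYAAA")  # fine for a tyrosine kinase

    def test_nonstandard_residues_rejected(self):
        with pytest.raises(KinspecError, match="non-standard"):
            _rec(hept="AAXSAAA")


class TestQuery:
    def test_reflexive_match_returns_own_records(self, small_db, default_policy):
        db, truth = small_db
        for pk in truth.values():
            hits = query_matching_sites(pk.sdr, pk.kinase_type, db, default_policy)
            own = [r for r in hits if r.kinase_id == pk.kinase_id]
            assert len(own) == 50

    def test_empty_database(self, default_policy):
        db = SpecificityDatabase(records=(), sdr_length=5)
        assert query_matching_sites("KDESL", SERINE_THREONINE, db, default_policy) == []

    def test_length_mismatch_names_both_lengths(self, small_db, default_policy):
        db, _ = small_db
        with pytest.raises(KinspecError, match="3.*5|5.*3"):
            query_matching_sites("KDE", SERINE_THREONINE, db, default_policy)

    def test_kinase_types_are_separate_matching_classes(self, default_policy):
        rec = _rec(ktype=CMGC)
        db = SpecificityDatabase.from_records([rec])
        assert query_matching_sites(rec.kinase_sdr, SERINE_THREONINE, db, default_policy) == []
        assert query_matching_sites(rec.kinase_sdr, CMGC, db, default_policy) == [rec]

    def test_cutoff_zero_results_superset_of_cutoff_one(self, medium_db, blosum62):
        """Monotonicity in cutoff over 50 random queries on a 200-record db."""
        db, _ = medium_db
        rng = np.random.default_rng(0)
        p0 = SimilarityPolicy(blosum62, 0)
        p1 = SimilarityPolicy(blosum62, 1)
        for _ in range(50):
            sdr = "".join(rng.choice(list(AA20), size=db.sdr_length))
            ktype = str(rng.choice([SERINE_THREONINE, CMGC, "tyrosine"]))
            strict = query_matching_sites(sdr, ktype, db, p1)
            loose = query_matching_sites(sdr, ktype, db, p0)
            assert set(strict) <= set(loose)

    def test_query_is_deterministic_and_sorted(self, small_db, default_policy):
        db, truth = small_db
        pk = next(iter(truth.values()))
        a = query_matching_sites(pk.sdr, pk.kinase_type, db, default_policy)
        b = query_matching_sites(pk.sdr, pk.kinase_type, db, default_policy)
        assert a == b
        keys = [(r.kinase_id, r.substrate_id, r.site_position) for r in a]
        assert keys == sorted(keys)


class TestBackground:
    def test_uniform_heptamers_give_uniform_background(self):
        # heptamers cycling through all 20 residues equally often
        recs = []
        seq = AA20 * 7
        for i in range(20):
            hept = seq[i * 7 : i * 7 + 7]
            hept = hept[:3] + "S" + hept[4:]
            recs.append(_rec(sub=f"S{i}", hept=hept))
        db = SpecificityDatabase.from_records(recs)
        # not exactly uniform because of the forced S centre; build the
        # oracle by direct tally
        tally = np.zeros(20)
        for r in recs:
            for a in r.heptamer:
                tally[AA_INDEX[a]] += 1
        expected = tally / tally.sum()
        bg = background_frequencies(db, SERINE_THREONINE)
        np.testing.assert_allclose(bg.b, expected, atol=1e-12)

    def test_single_record_hand_count(self):
        db = SpecificityDatabase.from_records([_rec(hept="AAASAAA")])
        bg = background_frequencies(db, SERINE_THREONINE, floor=1e-4)
        # direct tally: A 6/7, S 1/7, 18 residues floored then renormalised
        raw = np.zeros(20)
        raw[AA_INDEX["A"]], raw[AA_INDEX["S"]] = 6 / 7, 1 / 7
        raw[raw == 0] = 1e-4
        expected = raw / raw.sum()
        np.testing.assert_allclose(bg.b, expected, atol=1e-15)

    def test_background_sums_to_one(self, small_db):
        db, _ = small_db
        for ktype in db.kinase_types():
            assert abs(background_frequencies(db, ktype).b.sum() - 1) < 1e-12

    def test_missing_type_is_an_error(self):
        db = SpecificityDatabase.from_records([_rec()])
        with pytest.raises(KinspecError, match="tyrosine"):
            background_frequencies(db, "tyrosine")


class TestTsvDialect:
    def test_round_trip(self, tmp_path, small_db):
        db, _ = small_db
        path = tmp_path / "db.tsv"
        export_database(db, path)
        back = import_database(path)
        assert back.records == db.records
        assert back.sdr_length == db.sdr_length
        assert back.provenance == db.provenance

    def test_three_record_fixture_round_trip(self, tmp_path):
        db = SpecificityDatabase.from_records(
            [_rec(sub="S1"), _rec(sub="S2", hept="RRASLPE"), _rec(sub="S3", pos=99)],
            provenance="unit fixture",
        )
        path = tmp_path / "db.tsv"
        export_database(db, path)
        assert import_database(path) == db

    def test_bad_heptamer_reports_line_number(self, tmp_path):
        path = tmp_path / "db.tsv"
        path.write_text(
            "kinase_id\tkinase_type\tkinase_sdr\tsubstrate_id\tsite_position\theptamer\n"
            "K1\tserine/threonine\tKDESL\tS1\t10\tAAASAA\n"
        )
        with pytest.raises(DatabaseFormatError, match="line 2"):
            import_database(path)

    def test_wrong_column_count_reports_line_number(self, tmp_path):
        path = tmp_path / "db.tsv"
        path.write_text(
            "kinase_id\tkinase_type\tkinase_sdr\tsubstrate_id\tsite_position\theptamer\n"
            "K1\tserine/threonine\tKDESL\n"
        )
        with pytest.raises(DatabaseFormatError, match="line 2"):
            import_database(path)

    def test_header_only_file_is_a_valid_empty_database(self, tmp_path):
        path = tmp_path / "db.tsv"
        path.write_text(
            "# kinspec specificity database; sdr_length=5\n"
            "kinase_id\tkinase_type\tkinase_sdr\tsubstrate_id\tsite_position\theptamer\n"
        )
        db = import_database(path)
        assert len(db) == 0 and db.sdr_length == 5
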