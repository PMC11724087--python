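"""Filters, eligibility, ablation and round-trip I/O for cohort data."""

import numpy as np
import pytest
import scipy.io
import scipy.sparse as sp

from phenorisk.cohort import (
    Cohort,
    ConceptVocabulary,
    EndpointCatalog,
    EventTable,
    NoConceptsError,
    RecordMatrix,
    ablate_recent,
    eligibility_mask,
    filter_concepts,
    filter_endpoints,
    read_cohort,
    write_cohort,
)


def _event_table(prior, time, event, ids=None):
    J = time.shape[1]
    return EventTable(
        endpoint_id=np.array(ids or [f"E{j}" for j in range(J)], dtype=object),
        prior_event=prior,
        time=time,
        event=event,
    )


class TestFilterConcepts:
    def test_rare_concept_dropped_at_threshold(self):
        """A concept carried by 49 individuals falls below a 50-carrier cutoff."""
        rng = np.random.default_rng(0)
        n = 600
        col_common = (rng.random(n) < 0.5).astype(np.int8)
        col_rare = np.zeros(n, dtype=np.int8)
        col_rare[:49] = 1
        X = sp.csr_matrix(np.column_stack([col_common, col_rare]))
        vocab = ConceptVocabulary(
            np.array(["common", "rare"], dtype=object),
            np.array(["condition", "drug"], dtype=object),
            np.array([int(col_common.sum()), 49]),
        )
        m2, v2 = filter_concepts(RecordMatrix(X), vocab, min_carriers=50)
        assert list(v2.concept_id) == ["common"]
        assert m2.shape == (n, 1)

    def test_identity_when_all_pass(self, toy_matrix, toy_vocab):
        m2, v2 = filter_concepts(toy_matrix, toy_vocab, min_carriers=1)
        assert m2.shape == toy_matrix.shape
        assert list(v2.concept_id) == list(toy_vocab.concept_id)

    def test_kept_set_matches_column_sums(self):
        rng = np.random.default_rng(7)
        X = sp.csr_matrix((rng.random((30, 12)) < 0.3).astype(np.int8))
        vocab = ConceptVocabulary(
            np.array([f"c{i}" for i in range(12)], dtype=object),
            np.array(["condition"] * 12, dtype=object),
            np.asarray(X.sum(axis=0)).ravel(),
        )
        sums = np.asarray(X.todense()).sum(axis=0)
        expected = [f"c{i}" for i in range(12) if sums[i] >= 4]
        _, v2 = filter_concepts(RecordMatrix(X), vocab, min_carriers=4)
        assert list(v2.concept_id) == expected

    def test_idempotent(self, small_cohort):
        _, (cohort, vocab, matrix, events, truth) = small_cohort
        m1, v1 = filter_concepts(matrix, vocab, 10)
        m2, v2 = filter_concepts(m1, v1, 10)
        assert np.array_equal(v1.concept_id, v2.concept_id)
        assert (m1.X != m2.X).nnz == 0

    def test_empty_result_raises(self, toy_matrix, toy_vocab):
        with pytest.raises(NoConceptsError):
            filter_concepts(toy_matrix, toy_vocab, min_carriers=100)

    def test_timestamps_follow_kept_columns(self, toy_matrix, toy_vocab):
        m2, _ = filter_concepts(toy_matrix, toy_vocab, min_carriers=2)
        dense_old = np.asarray(toy_matrix.X.todense())
        dense_new = np.asarray(m2.X.todense())
        assert np.array_equal(dense_new, dense_old)  # all columns have >=2 carriers
        assert np.allclose(m2.timestamps, toy_matrix.timestamps)


class TestFilterEndpoints:
    def test_threshold_boundary(self):
        """99 incident events miss a 100-event minimum; 100 make it."""
        n = 400
        prior = np.zeros((n, 2), dtype=bool)
        event = np.zeros((n, 2), dtype=bool)
        event[:99, 0] = True
        event[:100, 1] = True
        time = np.full((n, 2), 5.0)
        cat = filter_endpoints(_event_table(prior, time, event), min_incident=100)
        assert list(cat.endpoint_id) == ["E1"]

    def test_all_retained_at_minimum_one(self):
        n = 20
        event = np.ones((n, 3), dtype=bool)
        cat = filter_endpoints(
            _event_table(np.zeros((n, 3), bool), np.full((n, 3), 1.0), event), 1
        )
        assert cat.n == 3

    def test_exact_count_by_enumeration(self):
        counts = [3, 100, 250, 0, 99]
        n = 300
        event = np.zeros((n, 5), dtype=bool)
        for j, c in enumerate(counts):
            event[:c, j] = True
        cat = filter_endpoints(
            _event_table(np.zeros((n, 5), bool), np.full((n, 5), 2.0), event), 100
        )
        assert cat.n == 2
        assert list(cat.incident_count) == [100, 250]

    def test_prior_events_do_not_count_as_incident(self):
        n = 150
        event = np.zeros((n, 1), dtype=bool)
        event[:120, 0] = True
        prior = np.zeros((n, 1), dtype=bool)
        prior[:30, 0] = True  # 30 of the 120 events are in prior carriers
        table = _event_table(prior, np.full((n, 1), 3.0), event)
        assert filter_endpoints(table, 90).incident_count[0] == 90
        with pytest.raises(Exception):
            filter_endpoints(table, 91)


class TestEligibility:
    def _table(self):
        prior = np.zeros((10, 1), dtype=bool)
        prior[[0, 1, 2], 0] = True
        return _event_table(prior, np.full((10, 1), 1.0), np.zeros((10, 1), bool))

    def _cohort(self, sexes):
        return Cohort(
            individual_id=np.array([f"i{k}" for k in range(10)], dtype=object),
            age_at_recruitment=np.full(10, 50.0),
            sex=np.array(sexes, dtype=object),
            center_id=np.ones(10, dtype=int),
            recruitment_date=np.array(["2008-06-01"] * 10, dtype="datetime64[D]"),
            n_centers=1,
        )

    def test_sex_incompatibility_excludes(self):
        sexes = ["female"] * 10
        cat = EndpointCatalog(
            np.array(["E0"], dtype=object),
            np.array(["male_only"], dtype=object),
            np.array([0]),
        )
        mask = eligibility_mask(self._table(), self._cohort(sexes), "E0", cat)
        assert not mask.any()

    def test_all_eligible_without_priors(self):
        table = _event_table(
            np.zeros((10, 1), bool), np.full((10, 1), 1.0), np.zeros((10, 1), bool)
        )
        mask = eligibility_mask(table, self._cohort(["male"] * 10), "E0")
        assert mask.all()

    def test_set_arithmetic_with_overlap(self):
        """3 prior events, 2 sex-mismatches, 1 overlapping: 6 eligible."""
        sexes = ["female"] * 10
        sexes[2] = "male"  # overlaps prior-event index 2
        sexes[5] = "male"
        cat = EndpointCatalog(
            np.array(["E0"], dtype=object),
            np.array(["female_only"], dtype=object),
            np.array([0]),
        )
        mask = eligibility_mask(self._table(), self._cohort(sexes), "E0", cat)
        assert mask.sum() == 6

    def test_mask_plus_excluded_covers_cohort(self, small_cohort):
        _, (cohort, vocab, matrix, events, truth) = small_cohort
        mask = eligibility_mask(events, cohort, str(events.endpoint_id[0]))
        assert mask.sum() + (~mask).sum() == cohort.n

    def test_unknown_endpoint_raises(self):
        with pytest.raises(KeyError):
            eligibility_mask(self._table(), self._cohort(["female"] * 10), "nope")


class TestAblateRecent:
    def test_zero_window_is_identity(self, toy_matrix):
        out = ablate_recent(toy_matrix, 0.0)
        assert (out.X != toy_matrix.X).nnz == 0

    def test_infinite_window_zeroes_all(self, toy_matrix):
        out = ablate_recent(toy_matrix, np.inf)
        assert out.X.nnz == 0

    def test_brute_force_filter(self, toy_matrix):
        out = ablate_recent(toy_matrix, 2.0)
        dense = np.asarray(toy_matrix.X.todense())
        coo = toy_matrix.X.tocoo()
        expected = np.zeros_like(dense)
        for r, c, ts in zip(coo.row, coo.col, toy_matrix.timestamps):
            if ts >= 2.0:
                expected[r, c] = 1
        assert np.array_equal(np.asarray(out.X.todense()), expected)

    def test_missing_timestamps_raise(self):
        m = RecordMatrix(sp.eye(3, format="csr", dtype=np.int8))
        with pytest.raises(ValueError, match="timestamp"):
            ablate_recent(m, 1.0)


class TestRoundTrip:
    def test_lossless_round_trip(self, small_cohort, tmp_path):
        _, (cohort, vocab, matrix, events, truth) = small_cohort
        write_cohort(tmp_path / "c", cohort, vocab, matrix, events)
        c2, v2, m2, e2 = read_cohort(tmp_path / "c")
        assert np.array_equal(c2.individual_id, cohort.individual_id)
        assert np.allclose(c2.age_at_recruitment, cohort.age_at_recruitment)
        assert np.array_equal(c2.center_id, cohort.center_id)
        assert np.array_equal(v2.concept_id, vocab.concept_id)
        assert np.array_equal(v2.carrier_count, matrix.carrier_counts())
        assert (m2.X != matrix.X).nnz == 0
        assert np.allclose(m2.timestamps, matrix.timestamps)
        assert np.array_equal(e2.event, events.event)
        assert np.array_equal(e2.prior_event, events.prior_event)
        assert np.allclose(e2.time, events.time)

    def test_carrier_counts_preserved(self, small_cohort, tmp_path):
        _, (cohort, vocab, matrix, events, truth) = small_cohort
        write_cohort(tmp_path / "c", cohort, vocab, matrix, events)
        _, _, m2, _ = read_cohort(tmp_path / "c")
        assert np.array_equal(m2.carrier_counts(), matrix.carrier_counts())

    def test_nonbinary_matrix_rejected(self, tmp_path, toy_cohort):
        bad = sp.csr_matrix(np.array([[2, 0], [0, 1]], dtype=np.int8))
        with pytest.raises(ValueError, match="binary"):
            RecordMatrix(bad)
        scipy.io.mmwrite(tmp_path / "records.mtx", bad.tocoo(), field="integer")
        # a full bundle with a corrupt matrix must be rejected on read
        m_ok = RecordMatrix(sp.csr_matrix(np.array([[1, 0], [0, 1]], dtype=np.int8)))
        vocab = ConceptVocabulary(
            np.array(["a", "b"], dtype=object),
            np.array(["condition", "drug"], dtype=object),
            np.array([1, 1]),
        )
        events = EventTable(
            endpoint_id=np.array(["E0"], dtype=object),
            prior_event=np.zeros((2, 1), bool),
            time=np.full((2, 1), 1.0),
            event=np.zeros((2, 1), bool),
        )
        small = Cohort(
            individual_id=np.array(["p1", "p2"], dtype=object),
            age_at_recruitment=np.array([50.0, 60.0]),
            sex=np.array(["female", "male"], dtype=object),
            center_id=np.array([1, 1]),
            recruitment_date=np.array(["2007-01-01"] * 2, dtype="datetime64[D]"),
            n_centers=1,
        )
        write_cohort(tmp_path / "bundle", small, vocab, m_ok, events)
        scipy.io.mmwrite(tmp_path / "bundle" / "records.mtx", bad.tocoo(), field="integer")
        with pytest.raises(ValueError, match="binary"):
            read_cohort(tmp_path / "bundle")

    def test_hand_written_fixture_counts(self, tmp_path):
        """A 3-individual hand-authored bundle parses with known totals."""
        d = tmp_path / "hand"
        d.mkdir()
        (d / "cohort.tsv").write_text(
            "individual_id\tage_at_recruitment\tsex\tcenter_id\trecruitment_date\n"
            "a\t50.0\tfemale\t1\t2007-03-01\n"
            "b\t61.5\tmale\t1\t2008-07-15\n"
            "c\t44.0\tfemale\t2\t2006-11-30\n"
        )
        (d / "vocabulary.tsv").write_text(
            "concept_id\tdomain\tcarrier_count\nc1\tcondition\t2\nc2\tdrug\t1\n"
        )
        (d / "records.mtx").write_text(
            "%%MatrixMarket matrix coordinate integer general\n3 2 3\n1 1 1\n2 1 1\n2 2 1\n"
        )
        (d / "events.tsv").write_text(
            "individual_id\tendpoint_id\tprior_event\ttime\tevent\n"
            "a\tE0\t0\t4.5\t1\nb\tE0\t1\t10.0\t0\nc\tE0\t0\t10.0\t0\n"
        )
        cohort, vocab, matrix, events = read_cohort(d)
        assert cohort.n == 3
        assert list(matrix.carrier_counts()) == [2, 1]
        assert events.incident_counts().tolist() == [1]
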