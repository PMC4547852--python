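import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epint.data_model import (
    PAN,
    AlterationClass,
    AlterationMeta,
    eligible_pairs,
    filter_hypermutated,
    filter_recurrent,
    load_events,
    recurrence_threshold,
    write_events,
)

from .conftest import make_matrix


def _write_inputs(tmp_path, events_rows, meta_rows):
    events = tmp_path / "events.tsv"
    meta = tmp_path / "meta.tsv"
    pd.DataFrame(
        events_rows,
        columns=["sample_id", "alteration_id", "alteration_class", "cancer_type"],
    ).to_csv(events, sep="\t", index=False)
    pd.DataFrame(
        meta_rows,
        columns=["alteration_id", "alteration_class", "chromosome", "genes"],
    ).to_csv(meta, sep="\t", index=False)
    return events, meta


META_2 = [
    ("a1", "mutation", ".", "TP53"),
    ("a2", "CNA_loss", "9", "CDKN2A;MTAP"),
]


class TestLoadEvents:
    def test_empty_events_gives_empty_matrix(self, tmp_path):
        events, meta = _write_inputs(tmp_path, [], META_2)
        m = load_events(events, meta)
        assert m.n_samples == 0 and m.n_alterations == 0

    def test_roundtrip_preserves_incidence_and_metadata(self, tmp_path):
        rows = [
            ("s1", "a1", "mutation", "BRCA"),
            ("s1", "a2", "CNA_loss", "BRCA"),
            ("s2", "a2", "CNA_loss", "BRCA"),
        ]
        events, meta = _write_inputs(tmp_path, rows, META_2)
        m = load_events(events, meta)
        assert m.incidence.sum() == 3
        out_e, out_m = tmp_path / "out_e.tsv", tmp_path / "out_m.tsv"
        write_events(m, out_e, out_m)
        m2 = load_events(out_e, out_m)
        assert m2 == m
        assert m2.meta_of("a2").chromosome == "9"
        assert m2.meta_of("a2").genes == frozenset({"CDKN2A", "MTAP"})

    def test_unknown_alteration_in_events_is_an_error(self, tmp_path):
        rows = [("s1", "aX", "mutation", "BRCA")]
        events, meta = _write_inputs(tmp_path, rows, META_2)
        with pytest.raises(ValueError, match="aX"):
            load_events(events, meta)

    def test_duplicate_event_row_is_an_error(self, tmp_path):
        rows = [
            ("s1", "a1", "mutation", "BRCA"),
            ("s1", "a1", "mutation", "BRCA"),
        ]
        events, meta = _write_inputs(tmp_path, rows, META_2)
        with pytest.raises(ValueError, match="duplicate"):
            load_events(events, meta)

    def test_class_mismatch_is_an_error(self, tmp_path):
        rows = [("s1", "a1", "CNA_gain", "BRCA")]
        events, meta = _write_inputs(tmp_path, rows, META_2)
        with pytest.raises(ValueError, match="class"):
            load_events(events, meta)

    def test_zero_alterations_dropped_unless_requested(self, tmp_path):
        rows = [("s1", "a1", "mutation", "BRCA")]
        events, meta = _write_inputs(tmp_path, rows, META_2)
        assert load_events(events, meta).n_alterations == 1
        kept = load_events(events, meta, keep_zero_alterations=True)
        assert kept.n_alterations == 2
        assert kept.alteration_counts()[kept.alteration_loc("a2")] == 0


class TestHyperFilter:
    def test_hand_computed_iqr_threshold(self):
        # counts {2,3,4,5,100}: Q1=3, Q3=5 (linear interpolation),
        # threshold 5 + 4.5 * 2 = 14 -> only the 100-count sample excluded
        inc = np.zeros((5, 100), dtype=np.uint8)
        for i, c in enumerate([2, 3, 4, 5, 100]):
            inc[i, :c] = 1
        m = make_matrix(inc)
        filtered, report = filter_hypermutated(m)
        assert report.thresholds["global"] == pytest.approx(14.0)
        assert [e["sample_id"] for e in report.excluded_hyper_samples] == ["s4"]
        assert filtered.n_samples == 4

    def test_zero_iqr_excludes_nothing(self):
        inc = np.zeros((4, 10), dtype=np.uint8)
        inc[:, :5] = 1
        filtered, report = filter_hypermutated(make_matrix(inc))
        assert filtered.n_samples == 4
        assert report.excluded_hyper_samples == []

    def test_empty_matrix_unchanged(self):
        m = make_matrix(np.zeros((0, 0), dtype=np.uint8), cancer_types=[])
        filtered, report = filter_hypermutated(m)
        assert filtered.n_samples == 0
        assert report.excluded_hyper_samples == []

    def test_small_scope_skipped_with_warning(self):
        inc = np.ones((3, 2), dtype=np.uint8)
        with pytest.warns(UserWarning, match="fewer than 4"):
            filtered, _ = filter_hypermutated(make_matrix(inc))
        assert filtered.n_samples == 3

    def test_no_sample_at_threshold_is_removed(self):
        # threshold is exceeded strictly; a sample exactly at it stays
        inc = np.zeros((5, 20), dtype=np.uint8)
        for i, c in enumerate([2, 3, 4, 5, 14]):
            inc[i, :c] = 1
        filtered, _ = filter_hypermutated(make_matrix(inc))
        assert filtered.n_samples == 5

    def test_per_cancer_type_scope(self):
        inc = np.zeros((10, 60), dtype=np.uint8)
        counts = [2, 3, 4, 5, 50, 2, 2, 2, 2, 2]
        for i, c in enumerate(counts):
            inc[i, :c] = 1
        types = ["X"] * 5 + ["Y"] * 5
        filtered, report = filter_hypermutated(
            make_matrix(inc, cancer_types=types), scope="per_cancer_type"
        )
        assert {e["sample_id"] for e in report.excluded_hyper_samples} == {"s4"}
        assert set(report.thresholds) == {"X", "Y"}


class TestRecurrenceFilter:
    @pytest.mark.parametrize(
        "n,min_freq,threshold", [(200, 0.02, 4), (50, 0.02, 1), (100, 1.0, 100)]
    )
    def test_ceiling_rule(self, n, min_freq, threshold):
        assert recurrence_threshold(n, min_freq) == threshold

    def test_boundary_counts(self):
        inc = np.zeros((200, 2), dtype=np.uint8)
        inc[:3, 0] = 1  # 3 < ceil(0.02*200) = 4 -> dropped
        inc[:4, 1] = 1  # kept
        kept = filter_recurrent(make_matrix(inc))
        assert kept.alteration_ids == ["a1"]

    def test_min_frequency_one_keeps_only_ubiquitous(self):
        inc = np.ones((10, 2), dtype=np.uint8)
        inc[0, 1] = 0
        kept = filter_recurrent(make_matrix(inc), min_frequency=1.0)
        assert kept.alteration_ids == ["a0"]

    def test_scope_restricts_samples_and_recomputes(self):
        inc = np.zeros((100, 1), dtype=np.uint8)
        inc[:2, 0] = 1  # both carriers in type X (n=50): 2 >= ceil(1) -> kept
        types = ["X"] * 50 + ["Y"] * 50
        kept = filter_recurrent(make_matrix(inc, cancer_types=types), scope="X")
        assert kept.n_samples == 50 and kept.alteration_ids == ["a0"]

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_invalid_frequency_rejected(self, bad):
        with pytest.raises(ValueError):
            filter_recurrent(make_matrix(np.ones((4, 1), np.uint8)), bad)


class TestEligiblePairs:
    def test_same_chromosome_cna_pair_excluded(self):
        m = make_matrix(
            np.ones((4, 2), np.uint8),
            classes=[AlterationClass.CNA_LOSS, AlterationClass.CNA_GAIN],
            chromosomes=["9", "9"],
        )
        assert eligible_pairs(m) == []

    def test_mutation_cna_same_chromosome_included(self):
        m = make_matrix(
            np.ones((4, 2), np.uint8),
            classes=[AlterationClass.MUTATION, AlterationClass.CNA_LOSS],
            chromosomes=["17", "17"],
        )
        assert eligible_pairs(m) == [("a0", "a1")]

    def test_all_pairs_when_no_colocated_cnas(self):
        m = make_matrix(np.ones((4, 4), np.uint8))
        assert len(eligible_pairs(m)) == 6

    def test_missing_cna_chromosome_is_an_error(self):
        meta = AlterationMeta.__new__(AlterationMeta)
        object.__setattr__(meta, "alteration_id", "bad")
        object.__setattr__(meta, "alteration_class", AlterationClass.CNA_GAIN)
        object.__setattr__(meta, "chromosome", None)
        object.__setattr__(meta, "genes", frozenset({"g"}))
        m = make_matrix(np.ones((2, 1), np.uint8))
        m.meta[0] = meta
        with pytest.raises(ValueError, match="bad"):
            eligible_pairs(m)

    @given(st.integers(2, 6), st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_pairs_deduplicated_and_unordered(self, m_alts, seed):
        rng = np.random.default_rng(seed)
        mat = make_matrix(rng.integers(0, 2, size=(3, m_alts)))
        pairs = eligible_pairs(mat)
        canon = {tuple(sorted(p)) for p in pairs}
        assert len(canon) == len(pairs)
        assert all(a != b for a, b in pairs)
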