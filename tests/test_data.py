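"""Ingestion, listwise deletion, community maps and sample summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import symptomnet as sn
from symptomnet.data import DASS21_ITEMS, SchemaError, ValidationError


def _complete_rows(n, rng, p=21):
    return rng.integers(0, 4, size=(n, p))


class TestReadResponses:
    def test_listwise_deletion_reaches_study_sample_size(self, write_csv):
        """348 questionnaires of which 30 have a missing item leave 318."""
        rng = np.random.default_rng(0)
        values = _complete_rows(348, rng).astype(object)
        rows_with_missing = rng.choice(348, size=30, replace=False)
        for r in rows_with_missing:
            values[r, rng.integers(0, 21)] = None
        path = write_csv(values, DASS21_ITEMS)
        x = sn.read_responses(path, DASS21_ITEMS)
        assert x.n == 318
        assert x.n_dropped == 30
        assert x.ingestion_log() == {
            "n_read": 348,
            "n_dropped": 30,
            "n_retained": 318,
        }

    def test_complete_file_drops_nothing(self, write_csv):
        rng = np.random.default_rng(1)
        path = write_csv(_complete_rows(5, rng), DASS21_ITEMS)
        x = sn.read_responses(path, DASS21_ITEMS)
        assert x.n == 5 and x.n_dropped == 0

    def test_out_of_range_score_drops_row_with_warning(self, write_csv, caplog):
        rng = np.random.default_rng(2)
        values = _complete_rows(6, rng)
        values[3, 7] = 4  # outside the four-point scale
        path = write_csv(values, DASS21_ITEMS)
        with caplog.at_level("WARNING"):
            x = sn.read_responses(path, DASS21_ITEMS)
        assert x.n == 5 and x.n_dropped == 1
        assert any("out-of-range" in r.message for r in caplog.records)

    def test_strict_mode_raises_on_out_of_range(self, write_csv):
        values = _complete_rows(4, np.random.default_rng(3))
        values[0, 0] = -1
        path = write_csv(values, DASS21_ITEMS)
        with pytest.raises(ValidationError, match="out-of-range"):
            sn.read_responses(path, DASS21_ITEMS, strict=True)

    def test_non_integer_score_names_row_and_item(self, write_csv):
        values = _complete_rows(4, np.random.default_rng(4)).astype(object)
        values[2, 5] = 1.5
        path = write_csv(values, DASS21_ITEMS)
        with pytest.raises(ValidationError, match="row 2.*dass6"):
            sn.read_responses(path, DASS21_ITEMS)

    def test_missing_item_column_is_schema_error(self, write_csv):
        values = _complete_rows(4, np.random.default_rng(5), p=20)
        path = write_csv(values, DASS21_ITEMS[:20])
        with pytest.raises(SchemaError, match="dass21"):
            sn.read_responses(path, DASS21_ITEMS)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            sn.read_responses(tmp_path / "absent.csv", DASS21_ITEMS)

    def test_listwise_deletion_is_idempotent(self, write_csv, tmp_path):
        """Re-reading the retained matrix drops nothing further."""
        rng = np.random.default_rng(6)
        values = _complete_rows(40, rng).astype(object)
        for r in rng.choice(40, size=8, replace=False):
            values[r, rng.integers(0, 21)] = None
        x = sn.read_responses(write_csv(values, DASS21_ITEMS), DASS21_ITEMS)
        again_path = tmp_path / "retained.csv"
        x.to_csv(again_path)
        y = sn.read_responses(again_path, DASS21_ITEMS)
        assert y.n_dropped == 0
        assert np.array_equal(x.values, y.values)


class TestCommunityMap:
    def test_dass21_preset_is_three_by_seven(self):
        cm = sn.load_community_map("dass21")
        assert cm.communities == ("Stress", "Anxiety", "Depression")
        for c in cm.communities:
            assert len(cm.members(c)) == 7
        # the paper's numbering: items 1-7 stress, 8-14 anxiety, 15-21 depression
        assert cm.assignment["dass1"] == "Stress"
        assert cm.assignment["dass8"] == "Anxiety"
        assert cm.assignment["dass21"] == "Depression"

    def test_single_community_map_is_valid(self):
        cm = sn.CommunityMap({i: "All" for i in DASS21_ITEMS})
        assert set(cm.labels_for(DASS21_ITEMS)) == {"All"}

    def test_unassigned_item_is_schema_error(self):
        cm = sn.CommunityMap({i: "All" for i in DASS21_ITEMS[:-1]})
        with pytest.raises(SchemaError, match="dass21"):
            cm.labels_for(DASS21_ITEMS)

    def test_duplicate_assignment_in_file_is_schema_error(self, tmp_path):
        path = tmp_path / "cm.yaml"
        path.write_text("A: [x, y]\nB: [y, z]\n")
        with pytest.raises(SchemaError, match="more than one"):
            sn.load_community_map(path)

    def test_yaml_and_json_round_trip(self, tmp_path):
        ypath = tmp_path / "cm.yaml"
        ypath.write_text("Stress: [a, b]\nAnxiety: [c]\n")
        jpath = tmp_path / "cm.json"
        jpath.write_text('{"Stress": ["a", "b"], "Anxiety": ["c"]}')
        for path in (ypath, jpath):
            cm = sn.load_community_map(path)
            assert cm.assignment == {"a": "Stress", "b": "Stress", "c": "Anxiety"}


class TestSummarizeSample:
    @pytest.mark.parametrize(
        "count, n, expected",
        [
            (284, 318, 89.31),  # employment row of the study's Table 1
            (34, 318, 10.69),
            (0, 10, 0.0),
            (1, 3, 33.33),
            (1, 8, 12.5),
        ],
    )
    def test_percent_rounding(self, count, n, expected):
        s = sn.summarize_sample([("v", "a", count)], n)
        assert s.percent_of("v", "a") == expected

    def test_half_away_from_zero_rounding(self):
        # 5 / 400 = 1.25% -> printed 1.25; 1/16 = 6.25 stays 6.25;
        # 1/800 = 0.125% rounds *up* to 0.13 (not banker's 0.12)
        s = sn.summarize_sample([("v", "a", 1)], 800)
        assert s.percent_of("v", "a") == 0.13

    def test_counts_exceeding_n_rejected(self):
        with pytest.raises(ValidationError, match="exceed"):
            sn.summarize_sample([("v", "a", 200), ("v", "b", 200)], 318)

    @settings(derandomize=True, max_examples=50)
    @given(
        counts=st.lists(st.integers(min_value=0, max_value=50), min_size=1,
                        max_size=8)
    )
    def test_percents_sum_to_100_within_rounding(self, counts):
        n = sum(counts)
        if n == 0:
            return
        rows = [("v", f"c{k}", c) for k, c in enumerate(counts)]
        s = sn.summarize_sample(rows, n)
        total = s.table.percent.sum()
        assert abs(total - 100.0) <= 0.02 * len(counts) + 1e-9
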