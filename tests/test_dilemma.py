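"""Battery data model, scale scoring, screening, and aggregation."""

import numpy as np
import pandas as pd
import pytest

from moraldm import dilemma
from moraldm.dilemma import (
    CATEGORIES,
    aggregate_profile,
    aggregate_profiles,
    cronbach_alpha,
    default_battery,
    median_split,
    recode_rating,
    score_pss,
    score_social_desirability,
    screen_participants,
    validate_battery,
)


class TestRecodeRating:
    def test_threshold_exhaustive(self):
        # approval iff rating >= 4, over the whole 1..6 range
        assert [recode_rating(r) for r in range(1, 7)] == [0, 0, 0, 1, 1, 1]

    @pytest.mark.parametrize("bad", [0, 7, 3.5, -1])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            recode_rating(bad)

    def test_vectorized_matches_scalar(self, rng):
        ratings = rng.integers(1, 7, size=50)
        assert (recode_rating(ratings) == [recode_rating(r) for r in ratings]).all()


class TestScorePss:
    def test_extremes_without_reversal(self):
        assert score_pss([0] * 10, reverse_items=()) == 0
        assert score_pss([4] * 10, reverse_items=()) == 40

    def test_default_reverse_key(self):
        # four reverse-keyed items flip 4 -> 0; six stay at 4
        assert score_pss([4] * 10) == 24

    def test_pss14_range(self):
        assert score_pss([4] * 14, version=14, reverse_items=()) == 56
        assert score_pss([0] * 14, version=14) == 4 * 7

    @pytest.mark.parametrize("items", [[1] * 9, [1] * 11, [5] * 10, [-1] + [0] * 9])
    def test_invalid_items_rejected(self, items):
        with pytest.raises(ValueError):
            score_pss(items)

    def test_monotone_in_items(self, rng):
        base = rng.integers(0, 4, size=10).tolist()
        total = score_pss(base)
        for pos in range(10):
            bumped = list(base)
            bumped[pos] += 1
            delta = score_pss(bumped) - total
            if (pos + 1) in dilemma.PSS10_REVERSE_ITEMS:
                assert delta == -1
            else:
                assert delta == 1


class TestSocialDesirability:
    def test_extremes(self):
        key = [1, 0] * 6 + [1]
        assert score_social_desirability(key, key) == 13
        assert score_social_desirability([1 - k for k in key], key) == 0

    def test_partial_match_counting(self):
        key = [1] * 13
        resp = [1] * 7 + [0] * 6
        assert score_social_desirability(resp, key) == 7

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            score_social_desirability([1] * 12, [1] * 13)


class TestScreening:
    @staticmethod
    def _records(n, **overrides):
        rec = pd.DataFrame(
            {
                "participant_id": [f"P{i}" for i in range(n)],
                "acute_stress": 0,
                "attention_pass": 1,
            }
        )
        for col, vals in overrides.items():
            rec[col] = vals
        return rec

    @staticmethod
    def _responses(pids, n_items=24):
        return pd.DataFrame(
            {
                "participant_id": np.repeat(pids, n_items),
                "item_id": np.tile([f"i{j}" for j in range(n_items)], len(pids)),
            }
        )

    def test_acute_stress_flag_excludes(self):
        rec = self._records(10, acute_stress=[1, 1] + [0] * 8)
        resp = self._responses(rec["participant_id"])
        retained, log = screen_participants(rec, resp)
        assert len(retained) == 8
        assert list(log["reason"]) == ["acute_stress"] * 2

    def test_incomplete_battery_excludes(self):
        rec = self._records(2)
        resp = self._responses(rec["participant_id"])
        resp = resp.iloc[:-1]  # P1 has 23/24 items
        retained, log = screen_participants(rec, resp)
        assert retained == ["P0"]
        assert log.iloc[0].tolist() == ["P1", "incomplete"]

    def test_all_clean_all_retained(self):
        rec = self._records(5)
        retained, log = screen_participants(rec, self._responses(rec["participant_id"]))
        assert len(retained) == 5 and log.empty

    def test_first_matching_rule_wins(self):
        rec = self._records(1, acute_stress=[1], attention_pass=[0])
        retained, log = screen_participants(rec, self._responses(rec["participant_id"]))
        assert log.iloc[0]["reason"] == "acute_stress"


def _one_participant(ratings_by_cat):
    rows = []
    for cat, ratings in ratings_by_cat.items():
        for j, r in enumerate(ratings):
            rows.append({"participant_id": "P1", "item_id": f"{cat}{j}", "category": cat, "rating": r})
    return pd.DataFrame(rows)


class TestAggregateProfile:
    def test_all_accept_category(self):
        resp = _one_participant({c: [6] * 6 for c in CATEGORIES})
        prof = aggregate_profile(resp, mode="binary")
        assert prof.values["PB"] == 1.0 and prof.counts["PB"] == 6

    def test_binary_threshold_and_continuous_mean(self):
        resp = _one_participant({c: [1, 2, 3, 4, 5, 6] for c in CATEGORIES})
        assert aggregate_profile(resp, mode="binary").values["PB"] == 0.5
        assert aggregate_profile(resp, mode="continuous").values["PB"] == 3.5

    def test_empty_category_named_in_error(self):
        resp = _one_participant({c: [4] * 6 for c in ("PB", "PC", "AB")})
        with pytest.raises(ValueError, match="AC"):
            aggregate_profile(resp, mode="binary")

    def test_binary_matches_recode_mean_oracle(self, rng):
        ratings = {c: rng.integers(1, 7, size=6).tolist() for c in CATEGORIES}
        prof = aggregate_profile(_one_participant(ratings), mode="binary")
        for c in CATEGORIES:
            assert prof.values[c] == np.mean([recode_rating(r) for r in ratings[c]])

    def test_frame_aggregation_matches_single(self, rng):
        ratings = {c: rng.integers(1, 7, size=6).tolist() for c in CATEGORIES}
        resp = _one_participant(ratings)
        frame = aggregate_profiles(resp, mode="continuous")
        prof = aggregate_profile(resp, mode="continuous")
        for c in CATEGORIES:
            assert frame.loc["P1", c] == pytest.approx(prof.values[c])


class TestMedianSplit:
    def test_even_split(self):
        labels, summary = median_split(pd.Series([1, 2, 3, 4]))
        assert list(labels) == ["low", "low", "high", "high"]
        assert summary.loc["high", "N"] == 2

    def test_ties_go_low_by_default(self):
        labels, _ = median_split(pd.Series([1, 2, 2, 3]))
        assert list(labels) == ["low", "low", "low", "high"]

    def test_degenerate_all_equal(self):
        with pytest.raises(ValueError, match="degenerate"):
            median_split(pd.Series([3, 3, 3]))

    def test_partition_property(self, rng):
        scores = pd.Series(rng.integers(0, 41, size=97))
        labels, summary = median_split(scores)
        assert summary["N"].sum() == 97
        lo, hi = scores[labels == "low"], scores[labels == "high"]
        assert lo.max() <= hi.min()

    def test_group_summary_shape(self, rng):
        # median-split output carries M/SD/N per group, the reported format
        scores = pd.Series(rng.normal(26.5, 5.3, size=197).round())
        _, summary = median_split(scores)
        assert set(summary.columns) == {"M", "SD", "N"}
        assert summary["N"].sum() == 197


class TestBattery:
    def test_default_battery_valid(self):
        validate_battery(default_battery())

    def test_adjacency_violation_detected(self):
        bad = default_battery()
        bad["story_id"] = "S1"
        with pytest.raises(ValueError):
            validate_battery(bad)

    def test_cell_count_violation_detected(self):
        bad = default_battery()
        bad.loc[bad.index[0], "category"] = "PC"
        with pytest.raises(ValueError):
            validate_battery(bad)


def test_cronbach_alpha_matches_pingouin(rng):
    pg = pytest.importorskip("pingouin")
    items = rng.normal(size=(40, 10)) + rng.normal(size=(40, 1))
    ours = cronbach_alpha(items)
    theirs = pg.cronbach_alpha(pd.DataFrame(items))[0]
    assert ours == pytest.approx(theirs, abs=1e-10)
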