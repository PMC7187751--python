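"""Sequence representations, day-level majority rule, transition counts."""

import datetime as dt
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from affectflow import (
    DateWindow,
    Post,
    build_cohort,
    build_sequence,
    count_transitions,
    day_affect,
    transition_features,
    affect_frequencies,
)
from affectflow.core import SEQUENCE_SYMBOLS, UserProfile
from affectflow.sequences import all_pairs, pair_label, share_percent

symbols_st = st.lists(st.sampled_from(SEQUENCE_SYMBOLS), max_size=50)


def brute_force_pairs(symbols):
    """Independent oracle: enumerate adjacent pairs one by one and tally
    them under a string-sorted unordered key."""
    tally = Counter()
    for i in range(len(symbols) - 1):
        a, b = symbols[i], symbols[i + 1]
        tally[(min(a, b), max(a, b))] += 1
    return tally


def profile_as_string_keys(profile):
    return Counter({(min(a, b), max(a, b)): c
                    for (a, b), c in profile.counts.items() if c})


class TestDayAffect:
    @pytest.mark.parametrize("posts, expected", [
        (["+", "-", "+"], "+"),        # strict plurality
        (["+", "-"], "±"),             # equal positive and negative
        ([], "S"),                     # silent day
        (["±"], "±"),                  # single mixed post
        (["0"], "0"),
        (["±", "+"], "±"),             # mixed balances the rest
        (["0", "0", "0", "+", "-"], "±"),  # +/- tie precedes plurality
        (["0", "±"], "±"),             # tie broken by precedence
        (["+", "0"], "+"),             # remaining tie: - > + > 0 order
    ])
    def test_rule_table(self, posts, expected):
        assert day_affect(posts) == expected

    def test_plurality_first_flips_tie_rule_order(self):
        # with plurality checked first, the clear 0-majority wins before
        # the positive/negative balance rule fires
        posts = ["0", "0", "0", "+", "-"]
        assert day_affect(posts, plurality_first=True) == "0"
        assert day_affect(posts) == "±"

    def test_invalid_symbol_rejected(self):
        with pytest.raises(ValueError):
            day_affect(["+", "S"])


class TestBuildSequence:
    def test_week_with_silence_stream(self, week_posts, week_window):
        seq = build_sequence(week_posts, week_window, "post_with_silence")
        assert seq.symbols == list("+-+-+++") + ["S", "±", "0", "+", "-"]
        assert len(seq) == 12

    def test_week_without_silence_drops_the_silent_day(self, week_posts,
                                                       week_window):
        seq = build_sequence(week_posts, week_window, "post_without_silence")
        assert len(seq) == 11
        assert "S" not in seq.symbols

    def test_week_day_level(self, week_posts, week_window):
        # Monday (index 0) is excluded: its printed label in the worked
        # example contradicts the stated positive/negative balance rule
        seq = build_sequence(week_posts, week_window, "day_level")
        assert seq.symbols[1:] == ["+", "+", "S", "±", "0", "±"]
        assert len(seq) == week_window.n_days

    def test_unsorted_input_rejected(self, week_posts, week_window):
        with pytest.raises(ValueError, match="sorted"):
            build_sequence(list(reversed(week_posts)), week_window,
                           "post_with_silence")

    def test_post_outside_window_rejected(self, week_posts, week_window):
        narrow = DateWindow(week_window.start,
                            week_window.start + dt.timedelta(days=2))
        with pytest.raises(ValueError, match="outside window"):
            build_sequence(week_posts, narrow, "post_with_silence")

    @pytest.mark.parametrize("gap_days", [1, 3, 7])
    def test_consecutive_silent_days_each_get_a_token(self, gap_days):
        start = dt.date(2012, 6, 1)
        window = DateWindow(start, start + dt.timedelta(days=gap_days + 1))
        posts = [
            Post(user_id="u", created_at=dt.datetime.combine(start,
                 dt.time(9)), affect="+"),
            Post(user_id="u", created_at=dt.datetime.combine(
                window.end, dt.time(9)), affect="-"),
        ]
        seq = build_sequence(posts, window, "post_with_silence")
        assert seq.symbols == ["+"] + ["S"] * gap_days + ["-"]


class TestCountTransitions:
    @pytest.mark.parametrize("symbols, expected, total", [
        (["+", "-", "+", "+"], {("+", "-"): 2, ("+", "+"): 1}, 3),
        (["S", "S", "S"], {("S", "S"): 2}, 2),
        (["+"], {}, 0),
        ([], {}, 0),
    ])
    def test_hand_enumerated(self, symbols, expected, total):
        profile = count_transitions(symbols)
        assert profile.total == total
        nonzero = {k: v for k, v in profile.counts.items() if v}
        assert nonzero == expected

    def test_week_stream_counts(self, week_posts, week_window):
        seq = build_sequence(week_posts, week_window, "post_with_silence")
        profile = count_transitions(seq)
        nonzero = {pair_label(k): v for k, v in profile.counts.items() if v}
        assert nonzero == {"+<->-": 5, "+<->+": 2, "+<->S": 1, "±<->S": 1,
                           "±<->0": 1, "+<->0": 1}
        assert profile.total == 11

    @settings(max_examples=200, deadline=None)
    @given(symbols_st)
    def test_matches_brute_force_oracle(self, symbols):
        profile = count_transitions(symbols)
        assert profile_as_string_keys(profile) == brute_force_pairs(symbols)
        assert profile.total == max(len(symbols) - 1, 0)

    @settings(max_examples=100, deadline=None)
    @given(symbols_st)
    def test_reversal_invariance(self, symbols):
        fwd = count_transitions(symbols)
        rev = count_transitions(list(reversed(symbols)))
        assert fwd.counts == rev.counts

    @settings(max_examples=100, deadline=None)
    @given(symbols_st)
    def test_proportions_sum_to_one(self, symbols):
        profile = count_transitions(symbols)
        if profile.total > 0:
            assert sum(profile.proportions.values()) == pytest.approx(1.0)


def test_fifteen_pair_types():
    assert len(all_pairs()) == 15


class TestFeatureTables:
    def _one_user_cohort(self, affects, n_days=7):
        user = UserProfile(user_id="u1", age=25, ope=3, con=3, ext=3,
                           agr=3, neu=3, swl=4, cesd=10,
                           cesd_date=dt.date(2012, 6, 30))
        start = user.cesd_date - dt.timedelta(days=n_days - 1)
        posts = [Post(user_id="u1",
                      created_at=dt.datetime.combine(
                          start + dt.timedelta(days=i), dt.time(9)),
                      affect=a)
                 for i, a in enumerate(affects)]
        return build_cohort([user], posts, window_days=n_days)

    def test_degenerate_single_pair_feature(self):
        cohort = self._one_user_cohort(["+", "+", "+"], n_days=3)
        feats, pooled = transition_features(cohort, "post_without_silence")
        row = feats.loc["u1"]
        assert row["+<->+"] == 1.0
        assert row.drop(["+<->+", "total"]).eq(0).all()
        assert pooled["+<->+"] == 2

    def test_short_sequence_user_excluded_with_warning(self):
        cohort = self._one_user_cohort(["+"], n_days=1)
        with pytest.warns(UserWarning, match="fewer than 2"):
            feats, _ = transition_features(cohort, "post_without_silence")
        assert len(feats) == 0

    @pytest.mark.parametrize("rep", ["post_with_silence",
                                     "post_without_silence", "day_level"])
    def test_fifteen_columns_and_unit_row_sums(self, small_cohort, rep):
        feats, pooled = transition_features(small_cohort, rep)
        assert feats.shape[1] == 16  # 15 pair types + total
        props = feats.drop(columns="total")
        assert np.allclose(props.sum(axis=1), 1.0)
        # pooled counts add up to the sum of per-user totals
        assert pooled.sum() == feats["total"].sum()

    def test_day_level_sequence_spans_whole_window(self, small_cohort):
        for user, posts in small_cohort.iter_user_posts():
            seq = build_sequence(posts, small_cohort.window_for(user),
                                 "day_level")
            assert len(seq) == small_cohort.window_days


class TestAffectFrequencies:
    def test_pure_positive_user(self):
        helper = TestFeatureTables()
        cohort = helper._one_user_cohort(["+", "+", "+"], n_days=3)
        freq = affect_frequencies(cohort)
        assert freq.loc["u1", "post_share_+"] == 1.0
        assert freq.loc["u1", "day_share_+"] == 1.0

    def test_share_families_sum_to_one(self, small_cohort):
        freq = affect_frequencies(small_cohort)
        post_cols = [c for c in freq.columns if c.startswith("post_share")]
        day_cols = [c for c in freq.columns if c.startswith("day_share")]
        assert np.allclose(freq[post_cols].sum(axis=1), 1.0)
        assert np.allclose(freq[day_cols].sum(axis=1), 1.0)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            affect_frequencies(build_cohort([], []))


def test_share_percent_rounding():
    assert share_percent(1, 3) == 33
    assert share_percent(2, 3) == 67
    with pytest.raises(ValueError):
        share_percent(1, 0)
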