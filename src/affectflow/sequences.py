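"""Affect sequence representations and bidirectional transition counting.

A user's window of posts is encoded as an ordered symbol sequence in one
of three representations:

``post_with_silence``
    every post's polarity in chronological order, with a single ``S``
    token inserted at the chronological position of each calendar day on
    which the user posted nothing (so consecutive silent days produce
    ``S``/``S`` adjacencies);
``post_without_silence``
    post polarities only, silent days ignored;
``day_level``
    exactly one symbol per window day: the day's dominant affect under a
    majority rule (below), or ``S`` for a silent day.

Transitions are *bidirectional*: each adjacent symbol pair is tallied
under its unordered key ``a↔b``, giving C(5,2) + 5 = 15 transition types
over the five-symbol alphabet.

Day-level dominant affect. For the posts of one day, in order:

1. no posts → ``S``;
2. equally many positive and negative posts (and at least one of each)
   → ``±``;
3. as many mixed (``±``) posts as all other posts combined → ``±``;
4. otherwise the strict-plurality polarity; any remaining tie resolves
   by the fixed precedence ``±`` > ``-`` > ``+`` > ``0``.

Rules 2–3 are checked before plurality by default (set
``plurality_first=True`` to flip); ties that none of the stated rules
cover are broken deterministically by the precedence in rule 4.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .core import (
    AFFECT_SYMBOLS,
    Cohort,
    DateWindow,
    MIXED,
    NEGATIVE,
    NEUTRAL,
    POSITIVE,
    Post,
    SEQUENCE_SYMBOLS,
    SILENCE,
)

REPRESENTATIONS = ("post_with_silence", "post_without_silence", "day_level")

#: tie-break precedence for day-level plurality ties (highest first)
_TIE_PRECEDENCE = (MIXED, NEGATIVE, POSITIVE, NEUTRAL)


def pair_key(a: str, b: str, alphabet: Sequence[str] = SEQUENCE_SYMBOLS
             ) -> tuple[str, str]:
    """Canonical unordered key for a transition between ``a`` and ``b``,
    ordered by position in ``alphabet``."""
    if a not in alphabet or b not in alphabet:
        raise ValueError(f"symbol outside alphabet {alphabet}: {(a, b)!r}")
    return (a, b) if alphabet.index(a) <= alphabet.index(b) else (b, a)


def all_pairs(alphabet: Sequence[str] = SEQUENCE_SYMBOLS
              ) -> list[tuple[str, str]]:
    """All unordered symbol pairs (self-pairs first ordering not imposed;
    pairs follow alphabet order)."""
    out = []
    for i, a in enumerate(alphabet):
        for b in alphabet[i:]:
            out.append((a, b))
    return out


def pair_label(pair: tuple[str, str]) -> str:
    return f"{pair[0]}<->{pair[1]}"


@dataclass
class AffectSequence:
    """Ordered symbols for one user under one representation.

    ``day_index`` gives, for each symbol, the 0-based window day it
    belongs to; it is non-decreasing, and for the day-level
    representation it is simply 0..window_days-1.
    """

    user_id: str
    representation: str
    symbols: list[str]
    day_index: list[int]

    def __post_init__(self) -> None:
        if self.representation not in REPRESENTATIONS:
            raise ValueError(f"unknown representation "
                             f"{self.representation!r}")
        if len(self.symbols) != len(self.day_index):
            raise ValueError("symbols and day_index lengths differ")
        if any(b < a for a, b in zip(self.day_index, self.day_index[1:])):
            raise ValueError("day_index must be non-decreasing")
        bad = set(self.symbols) - set(SEQUENCE_SYMBOLS)
        if bad:
            raise ValueError(f"symbols outside alphabet: {sorted(bad)}")
        if self.representation == "post_without_silence" and \
                SILENCE in self.symbols:
            raise ValueError("silence token in a without-silence sequence")

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass
class TransitionProfile:
    """Bidirectional transition tallies for one sequence.

    ``counts`` maps every unordered pair of the alphabet (including
    self-pairs) to the number of adjacent occurrences; ``total`` equals
    sequence length minus one (zero for length <= 1).
    """

    user_id: str
    representation: str
    counts: dict[tuple[str, str], int]
    total: int
    alphabet: tuple[str, ...] = SEQUENCE_SYMBOLS

    @property
    def proportions(self) -> dict[tuple[str, str], float]:
        if self.total == 0:
            return {k: 0.0 for k in self.counts}
        return {k: v / self.total for k, v in self.counts.items()}

    def as_series(self, proportions: bool = True) -> pd.Series:
        src = self.proportions if proportions else self.counts
        return pd.Series({pair_label(k): src[k]
                          for k in all_pairs(self.alphabet)},
                         name=self.user_id)


def day_affect(day_posts: Sequence[str], plurality_first: bool = False) -> str:
    """Dominant affect of one day's posts (see module docstring for the
    rule order); an empty day is silence."""
    for s in day_posts:
        if s not in AFFECT_SYMBOLS:
            raise ValueError(f"invalid post polarity {s!r}")
    if not day_posts:
        return SILENCE
    counts = Counter(day_posts)

    def special_rules() -> str | None:
        # equal positive and negative presence -> mixed
        if counts[POSITIVE] == counts[NEGATIVE] > 0:
            return MIXED
        # mixed posts balancing all other posts -> mixed
        n_other = len(day_posts) - counts[MIXED]
        if counts[MIXED] > 0 and counts[MIXED] == n_other:
            return MIXED
        return None

    def plurality() -> str | None:
        top = counts.most_common()
        if len(top) == 1 or top[0][1] > top[1][1]:
            return top[0][0]
        return None

    first, second = (plurality, special_rules) if plurality_first else \
        (special_rules, plurality)
    for rule in (first, second):
        out = rule()
        if out is not None:
            return out
    # unresolved tie: deterministic precedence
    best = max(counts.values())
    tied = {s for s, c in counts.items() if c == best}
    for s in _TIE_PRECEDENCE:
        if s in tied:
            return s
    raise AssertionError("unreachable")


def _posts_by_day(posts: Sequence[Post], window: DateWindow
                  ) -> list[list[Post]]:
    buckets: list[list[Post]] = [[] for _ in range(window.n_days)]
    last = None
    for p in posts:
        if last is not None and p.created_at < last:
            raise ValueError("posts must be sorted chronologically")
        last = p.created_at
        if p.day not in window:
            raise ValueError(f"post on {p.day} outside window "
                             f"{window.start}..{window.end}")
        buckets[(p.day - window.start).days].append(p)
    return buckets


def build_sequence(posts: Sequence[Post], window: DateWindow,
                   representation: str, user_id: str | None = None,
                   plurality_first: bool = False) -> AffectSequence:
    """Encode one user's window of posts under a representation.

    Posts must be chronologically sorted and fall inside ``window``.
    """
    if representation not in REPRESENTATIONS:
        raise ValueError(f"unknown representation {representation!r}")
    uid = user_id or (posts[0].user_id if posts else "")
    buckets = _posts_by_day(posts, window)

    symbols: list[str] = []
    day_index: list[int] = []
    if representation == "day_level":
        for d, bucket in enumerate(buckets):
            symbols.append(day_affect([p.affect for p in bucket],
                                      plurality_first=plurality_first))
            day_index.append(d)
    else:
        with_silence = representation == "post_with_silence"
        for d, bucket in enumerate(buckets):
            if bucket:
                symbols.extend(p.affect for p in bucket)
                day_index.extend([d] * len(bucket))
            elif with_silence:
                symbols.append(SILENCE)
                day_index.append(d)
    return AffectSequence(user_id=uid, representation=representation,
                          symbols=symbols, day_index=day_index)


def count_transitions(seq: AffectSequence | Sequence[str],
                      alphabet: Sequence[str] = SEQUENCE_SYMBOLS,
                      user_id: str = "", representation: str = ""
                      ) -> TransitionProfile:
    """Tally adjacent symbol pairs under unordered (bidirectional) keys.

    Accepts either an :class:`AffectSequence` or a bare symbol list (for
    the latter, pass the alphabet explicitly when it is not the default
    five-symbol affect alphabet).
    """
    if isinstance(seq, AffectSequence):
        symbols = seq.symbols
        user_id = user_id or seq.user_id
        representation = representation or seq.representation
    else:
        symbols = list(seq)
    alphabet = tuple(alphabet)
    counts = {k: 0 for k in all_pairs(alphabet)}
    for a, b in zip(symbols, symbols[1:]):
        counts[pair_key(a, b, alphabet)] += 1
    return TransitionProfile(user_id=user_id, representation=representation,
                             counts=counts,
                             total=max(len(symbols) - 1, 0),
                             alphabet=alphabet)


def transition_features(cohort: Cohort, representation: str,
                        proportions: bool = True,
                        plurality_first: bool = False
                        ) -> tuple[pd.DataFrame, pd.Series]:
    """Per-user transition feature table plus pooled occurrence counts.

    Returns a (users x 15) table of transition-type proportions (or raw
    counts) with a ``total`` column, and the pooled count of each
    transition type over the whole cohort. Users with fewer than two
    symbols in the representation carry no transition and are excluded
    with a warning.
    """
    rows = {}
    totals = {}
    pooled = Counter()
    for user, posts in cohort.iter_user_posts():
        window = cohort.window_for(user)
        seq = build_sequence(posts, window, representation,
                             user_id=user.user_id,
                             plurality_first=plurality_first)
        if len(seq) < 2:
            warnings.warn(f"user {user.user_id}: fewer than 2 symbols under "
                          f"{representation}; excluded from features")
            continue
        profile = count_transitions(seq)
        rows[user.user_id] = profile.as_series(proportions=proportions)
        totals[user.user_id] = profile.total
        pooled.update(profile.counts)
    labels = [pair_label(k) for k in all_pairs()]
    table = pd.DataFrame(rows).T.reindex(columns=labels)
    table.index.name = "user_id"
    table["total"] = pd.Series(totals)
    pooled_counts = pd.Series({pair_label(k): pooled.get(k, 0)
                               for k in all_pairs()}, name="n_occ")
    return table, pooled_counts


def affect_frequencies(cohort: Cohort, plurality_first: bool = False
                       ) -> pd.DataFrame:
    """Per-user affect frequency features.

    ``post_share_<sym>``: share of the user's window posts with each of
    the four polarities (sums to 1 per user). ``day_share_<sym>``: share
    of window days whose day-level dominant affect is each of the five
    symbols, silence included (sums to 1 per user).
    """
    if cohort.n_users == 0:
        raise ValueError("empty cohort")
    rows = []
    for user, posts in cohort.iter_user_posts():
        window = cohort.window_for(user)
        day_seq = build_sequence(posts, window, "day_level",
                                 user_id=user.user_id,
                                 plurality_first=plurality_first)
        post_counts = Counter(p.affect for p in posts)
        n_posts = sum(post_counts.values())
        day_counts = Counter(day_seq.symbols)
        row = {"user_id": user.user_id}
        for s in AFFECT_SYMBOLS:
            row[f"post_share_{s}"] = (post_counts[s] / n_posts
                                      if n_posts else 0.0)
        for s in SEQUENCE_SYMBOLS:
            row[f"day_share_{s}"] = day_counts[s] / window.n_days
        rows.append(row)
    return pd.DataFrame(rows).set_index("user_id")


def pooled_affect_counts(cohort: Cohort) -> pd.Series:
    """Cohort-wide post counts per polarity (for corpus summaries)."""
    counts = Counter()
    for _, posts in cohort.iter_user_posts():
        counts.update(p.affect for p in posts)
    return pd.Series({s: counts[s] for s in AFFECT_SYMBOLS}, name="n_posts")


def share_percent(count: float, total: float) -> int:
    """A count as a whole-number percentage of a total (nearest percent)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total)
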