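"""Domain types for longitudinal posting cohorts.

The unit of analysis is a user's stream of timestamped status updates, each
carrying an affect polarity label, observed in a fixed window of calendar
days before the user completed a depression questionnaire (CES-D).

Affect polarities form a four-symbol alphabet:

    ``+``  positive valence
    ``-``  negative valence
    ``±``  mixed valence (both positive and negative present)
    ``0``  neutral (no clear valence)

A fifth derived symbol ``S`` marks a *silence day* — a calendar day in the
observation window on which the user posted nothing. ``S`` never appears on
a post; it exists only in day-indexed sequence representations.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Optional

POSITIVE = "+"
NEGATIVE = "-"
MIXED = "±"
NEUTRAL = "0"
SILENCE = "S"

#: the four polarities a single post may carry
AFFECT_SYMBOLS = (POSITIVE, NEGATIVE, MIXED, NEUTRAL)
#: full sequence alphabet, including the derived silence state
SEQUENCE_SYMBOLS = AFFECT_SYMBOLS + (SILENCE,)

ORIGINAL = "O"
NON_ORIGINAL = "N"
#: alphabet for originality sequences (post-level, with silence)
ORIGINALITY_SYMBOLS = (ORIGINAL, NON_ORIGINAL, SILENCE)

#: portable on-disk spellings of the affect polarities (``±`` does not
#: survive every CSV toolchain; ``S`` is derived and never stored)
AFFECT_TO_TOKEN = {POSITIVE: "pos", NEGATIVE: "neg", MIXED: "mix", NEUTRAL: "neu"}
TOKEN_TO_AFFECT = {v: k for k, v in AFFECT_TO_TOKEN.items()}

ORIGINALITY_GOLD_LABELS = ("original", "non_original")

#: psychometric scale columns, in canonical order
SCALE_NAMES = ("ope", "con", "ext", "agr", "neu", "swl", "cesd")

CESD_MAX = 60
#: conventional cut-off for probable depressive disorder
CESD_CUTOFF = 22


class SchemaError(ValueError):
    """An input table violates the expected schema or a field constraint."""


def parse_affect(value: str) -> str:
    """Map an on-disk affect token (or bare symbol) to its symbol.

    Accepts both the portable tokens ``pos/neg/mix/neu`` and the symbols
    themselves, so in-memory round trips are forgiving.
    """
    v = str(value).strip()
    if v in TOKEN_TO_AFFECT:
        return TOKEN_TO_AFFECT[v]
    if v in AFFECT_SYMBOLS:
        return v
    raise SchemaError(f"invalid affect label {value!r}; expected one of "
                      f"{sorted(TOKEN_TO_AFFECT)} or {list(AFFECT_SYMBOLS)}")


@dataclass
class Post:
    """One timestamped status update.

    ``created_at`` carries a calendar date and optional time-of-day; the
    calendar day is the unit of aggregation and timestamps are taken at
    face value (no timezone arithmetic).
    """

    user_id: str
    created_at: _dt.datetime
    affect: str
    text: str = ""
    language: str = "en"
    originality_gold: Optional[str] = None
    post_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.user_id:
            raise SchemaError("post user_id must be non-empty")
        if self.affect not in AFFECT_SYMBOLS:
            self.affect = parse_affect(self.affect)
        if isinstance(self.created_at, _dt.date) and not isinstance(
            self.created_at, _dt.datetime
        ):
            self.created_at = _dt.datetime.combine(self.created_at, _dt.time())
        if not isinstance(self.created_at, _dt.datetime):
            raise SchemaError(f"created_at must be a datetime, got "
                              f"{type(self.created_at).__name__}")
        if self.originality_gold is not None and (
            self.originality_gold not in ORIGINALITY_GOLD_LABELS
        ):
            raise SchemaError(
                f"originality_gold must be one of {ORIGINALITY_GOLD_LABELS}, "
                f"got {self.originality_gold!r}")

    @property
    def day(self) -> _dt.date:
        return self.created_at.date()


@dataclass
class UserProfile:
    """Psychometric scales and demographics for one user.

    Big Five (OCEAN) traits live on a 1–5 scale, satisfaction with life
    (SWL) on 1–7, and CES-D depression symptoms on 0–60 with 22 the
    conventional cut-off for probable depressive disorder.
    """

    user_id: str
    age: float
    ope: float
    con: float
    ext: float
    agr: float
    neu: float
    swl: float
    cesd: int
    cesd_date: _dt.date
    gender: str = "unknown"
    ethnicity: str = "unknown"
    living_status: str = "unknown"

    def __post_init__(self) -> None:
        if not self.user_id:
            raise SchemaError("user_id must be non-empty")
        for trait in ("ope", "con", "ext", "agr", "neu"):
            v = getattr(self, trait)
            if not (1.0 <= float(v) <= 5.0):
                raise SchemaError(f"{trait}={v} outside the 1-5 trait scale "
                                  f"for user {self.user_id}")
        if not (1.0 <= float(self.swl) <= 7.0):
            raise SchemaError(f"swl={self.swl} outside the 1-7 scale "
                              f"for user {self.user_id}")
        self.cesd = int(self.cesd)
        if not (0 <= self.cesd <= CESD_MAX):
            raise SchemaError(f"cesd={self.cesd} outside 0-{CESD_MAX} "
                              f"for user {self.user_id}")
        if isinstance(self.cesd_date, _dt.datetime):
            self.cesd_date = self.cesd_date.date()
        if not isinstance(self.cesd_date, _dt.date):
            raise SchemaError("cesd_date must be a date")

    @property
    def above_cutoff(self) -> bool:
        """True when the CES-D score meets the probable-depression cut-off."""
        return self.cesd >= CESD_CUTOFF

    def scale(self, name: str) -> float:
        if name not in SCALE_NAMES:
            raise KeyError(f"unknown scale {name!r}")
        return float(getattr(self, name))


@dataclass(frozen=True)
class DateWindow:
    """A closed interval of calendar days (both endpoints included)."""

    start: _dt.date
    end: _dt.date

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"window end {self.end} precedes start {self.start}")

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1

    def __contains__(self, day) -> bool:
        if isinstance(day, _dt.datetime):
            day = day.date()
        return self.start <= day <= self.end

    def days(self) -> Iterable[_dt.date]:
        for i in range(self.n_days):
            yield self.start + _dt.timedelta(days=i)

    @classmethod
    def ending_at(cls, end: _dt.date, n_days: int) -> "DateWindow":
        """The ``n_days``-day window whose last day is ``end``."""
        if n_days < 1:
            raise ValueError("window must span at least one day")
        return cls(end - _dt.timedelta(days=n_days - 1), end)


@dataclass
class Cohort:
    """Users plus their (chronologically sorted) posts.

    ``posts`` maps each user_id to that user's posts in ascending
    ``created_at`` order; every post's user must appear in ``users``.
    """

    users: list[UserProfile]
    posts: dict[str, list[Post]]
    window_days: int = 60

    def __post_init__(self) -> None:
        known = {u.user_id for u in self.users}
        if len(known) != len(self.users):
            raise SchemaError("duplicate user_id in cohort users")
        for uid, plist in self.posts.items():
            if uid not in known:
                raise SchemaError(f"posts present for unknown user {uid!r}")
            for a, b in zip(plist, plist[1:]):
                if b.created_at < a.created_at:
                    raise SchemaError(f"posts for user {uid!r} not sorted "
                                      "by created_at")

    def user(self, user_id: str) -> UserProfile:
        for u in self.users:
            if u.user_id == user_id:
                return u
        raise KeyError(user_id)

    def window_for(self, user: UserProfile) -> DateWindow:
        """The observation window: ``window_days`` days ending at the
        user's CES-D completion date."""
        return DateWindow.ending_at(user.cesd_date, self.window_days)

    @property
    def n_users(self) -> int:
        return len(self.users)

    @property
    def n_posts(self) -> int:
        return sum(len(p) for p in self.posts.values())

    def iter_user_posts(self):
        for u in self.users:
            yield u, self.posts.get(u.user_id, [])


def build_cohort(users: list[UserProfile], posts: Iterable[Post],
                 window_days: int = 60) -> Cohort:
    """Group posts by user, sort chronologically, and validate."""
    by_user: dict[str, list[Post]] = {u.user_id: [] for u in users}
    for p in posts:
        if p.user_id not in by_user:
            raise SchemaError(f"post for unknown user {p.user_id!r}")
        by_user[p.user_id].append(p)
    for plist in by_user.values():
        plist.sort(key=lambda p: p.created_at)
    return Cohort(users=users, posts=by_user, window_days=window_days)
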