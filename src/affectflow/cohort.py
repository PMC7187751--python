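"""Participant-selection funnel with an auditable per-stage report.

The funnel keeps users who post regularly enough for transition analysis
and restricts each survivor's posts to a fixed window of calendar days
ending at their CES-D completion date. Stages run in a fixed order:

1. ``regular_user`` — average posting rate over the user's own posting
   span at or above a threshold (default 0.3 posts/day, i.e. roughly two
   posts a week: 0.3/day over 365 days is ~110 posts/year).
2. ``recent_activity`` — at least one post in the 7 calendar days ending
   at (and including) the CES-D completion date, because the CES-D asks
   about the past week.
3. ``window_restrict`` — posts trimmed to the observation window
   (default 60 days ending at the completion date); removes nobody, but
   appears in the report so downstream counts are traceable.
4. ``min_posts`` — at least 20 posts inside the window.
5. ``adult`` — age 18 or older.
6. ``language`` — share of non-English posts in the window at most 20%;
   survivors optionally have their non-English window posts dropped from
   downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core import Cohort, DateWindow, Post, UserProfile

STAGE_NAMES = ("regular_user", "recent_activity", "window_restrict",
               "min_posts", "adult", "language")


@dataclass
class SelectionConfig:
    """Thresholds for the selection funnel; defaults follow the protocol
    described in the module docstring."""

    min_rate: float = 0.3          # posts per day over the user's span
    recent_days: int = 7           # activity window ending at cesd_date
    window_days: int = 60          # observation window length
    min_posts: int = 20            # minimum posts inside the window
    min_age: float = 18.0
    max_non_english_share: float = 0.20
    drop_non_english_posts: bool = True
    english_tag: str = "en"


@dataclass
class FilterReport:
    """Audit trail of the funnel: who entered, who survived, who was
    removed at each stage.

    Invariants: ``counts_out[i] == counts_in[i] - len(removed_ids[i])``
    and ``counts_in[i+1] == counts_out[i]``.
    """

    stage_names: list[str] = field(default_factory=list)
    counts_in: list[int] = field(default_factory=list)
    counts_out: list[int] = field(default_factory=list)
    removed_ids: list[list[str]] = field(default_factory=list)

    def add_stage(self, name: str, n_in: int, removed: list[str]) -> None:
        self.stage_names.append(name)
        self.counts_in.append(n_in)
        self.counts_out.append(n_in - len(removed))
        self.removed_ids.append(list(removed))

    def validate(self) -> None:
        for i, (n_in, n_out, rem) in enumerate(
            zip(self.counts_in, self.counts_out, self.removed_ids)
        ):
            if n_out != n_in - len(rem):
                raise ValueError(f"stage {self.stage_names[i]}: inconsistent "
                                 f"counts ({n_in} in, {len(rem)} removed, "
                                 f"{n_out} out)")
            if i + 1 < len(self.counts_in) and self.counts_in[i + 1] != n_out:
                raise ValueError(f"stage chain broken after "
                                 f"{self.stage_names[i]}")

    @property
    def n_final(self) -> int:
        return self.counts_out[-1] if self.counts_out else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "stage": self.stage_names,
            "n_in": self.counts_in,
            "n_removed": [len(r) for r in self.removed_ids],
            "n_out": self.counts_out,
        })


def posting_rate(posts: list[Post], frame: DateWindow) -> float:
    """Average posts per day inside ``frame`` (a closed day interval).

    A rate of 0.3/day corresponds to roughly 110 posts over a year, i.e.
    about two posts per week.
    """
    if frame.n_days < 1:
        raise ValueError("frame must span at least one day")
    n = sum(1 for p in posts if p.day in frame)
    return n / frame.n_days


def posting_span(posts: list[Post]) -> DateWindow | None:
    """The user's full posting span: first to last post day, inclusive."""
    if not posts:
        return None
    days = [p.day for p in posts]
    return DateWindow(min(days), max(days))


def select_cohort(
    users: list[UserProfile],
    posts: dict[str, list[Post]],
    config: SelectionConfig | None = None,
) -> tuple[Cohort, FilterReport]:
    """Run the selection funnel and return the surviving cohort plus report.

    ``posts`` maps user_id to that user's chronologically sorted posts
    (full history; the window restriction happens inside the funnel).
    Users absent from ``posts`` are treated as having no posts and drop
    out at the first stage.
    """
    cfg = config or SelectionConfig()
    report = FilterReport()
    alive: list[UserProfile] = list(users)
    windowed: dict[str, list[Post]] = {}

    # stage 1: regular users, judged over their own posting span
    removed = []
    for u in alive:
        plist = posts.get(u.user_id, [])
        span = posting_span(plist)
        rate = posting_rate(plist, span) if span is not None else 0.0
        if rate < cfg.min_rate:
            removed.append(u.user_id)
    report.add_stage("regular_user", len(alive), removed)
    alive = [u for u in alive if u.user_id not in set(removed)]

    # stage 2: at least one post in the week ending at cesd_date
    removed = []
    for u in alive:
        week = DateWindow.ending_at(u.cesd_date, cfg.recent_days)
        if not any(p.day in week for p in posts.get(u.user_id, [])):
            removed.append(u.user_id)
    report.add_stage("recent_activity", len(alive), removed)
    alive = [u for u in alive if u.user_id not in set(removed)]

    # stage 3: restrict each survivor's posts to the observation window
    for u in alive:
        window = DateWindow.ending_at(u.cesd_date, cfg.window_days)
        windowed[u.user_id] = [p for p in posts.get(u.user_id, [])
                               if p.day in window]
    report.add_stage("window_restrict", len(alive), [])

    # stage 4: enough posts in the window
    removed = [u.user_id for u in alive
               if len(windowed[u.user_id]) < cfg.min_posts]
    report.add_stage("min_posts", len(alive), removed)
    alive = [u for u in alive if u.user_id not in set(removed)]

    # stage 5: adults only
    removed = [u.user_id for u in alive if u.age < cfg.min_age]
    report.add_stage("adult", len(alive), removed)
    alive = [u for u in alive if u.user_id not in set(removed)]

    # stage 6: mostly-English posters
    removed = []
    for u in alive:
        plist = windowed[u.user_id]
        if not plist:
            continue
        share = sum(1 for p in plist if p.language != cfg.english_tag) / len(plist)
        if share > cfg.max_non_english_share:
            removed.append(u.user_id)
    report.add_stage("language", len(alive), removed)
    alive = [u for u in alive if u.user_id not in set(removed)]

    final_posts = {}
    for u in alive:
        plist = windowed[u.user_id]
        if cfg.drop_non_english_posts:
            plist = [p for p in plist if p.language == cfg.english_tag]
        final_posts[u.user_id] = plist

    report.validate()
    cohort = Cohort(users=alive, posts=final_posts,
                    window_days=cfg.window_days)
    return cohort, report
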