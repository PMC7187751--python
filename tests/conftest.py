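"""Shared fixtures: the worked-example week and small synthetic cohorts."""

from __future__ import annotations

import datetime as dt

import pytest

from affectflow import DateWindow, Post, SimulationConfig, simulate_cohort
from affectflow.core import build_cohort

#: Monday .. Sunday of the worked-example week
WEEK_MONDAY = dt.date(2012, 6, 18)

#: per-day post polarities of the worked-example week (Thursday silent)
WEEK_AFFECTS = {
    0: ["+", "-"],            # Monday
    1: ["+", "-", "+"],       # Tuesday
    2: ["+", "+"],            # Wednesday
    3: [],                    # Thursday: silence
    4: ["±"],                 # Friday
    5: ["0"],                 # Saturday
    6: ["+", "-"],            # Sunday
}

#: per-day originality labels for the worked-example week (its Monday has
#: three posts, so it is a separate post stream from the affect week)
WEEK_ORIGINALITY = {
    0: ["O", "N", "O"],
    1: ["O", "O", "N"],
    2: ["N", "N"],
    3: [],
    4: ["O"],
    5: ["O"],
    6: ["N", "N"],
}


def make_week_posts(per_day: dict[int, list[str]], user_id: str = "u1",
                    affect_fill: str = "0") -> list[Post]:
    """Posts for one week; values are affect symbols or O/N labels."""
    posts = []
    for day_offset, symbols in per_day.items():
        day = WEEK_MONDAY + dt.timedelta(days=day_offset)
        for j, sym in enumerate(symbols):
            if sym in ("O", "N"):
                affect, gold = affect_fill, (
                    "original" if sym == "O" else "non_original")
            else:
                affect, gold = sym, None
            posts.append(Post(
                user_id=user_id,
                created_at=dt.datetime.combine(day, dt.time(9 + j)),
                affect=affect, text=f"post {day_offset}-{j}",
                originality_gold=gold,
                post_id=f"{user_id}-{day_offset}-{j}"))
    return posts


@pytest.fixture
def week_window() -> DateWindow:
    return DateWindow(WEEK_MONDAY, WEEK_MONDAY + dt.timedelta(days=6))


@pytest.fixture
def week_posts() -> list[Post]:
    return make_week_posts(WEEK_AFFECTS)


@pytest.fixture
def week_originality_posts() -> list[Post]:
    return make_week_posts(WEEK_ORIGINALITY)


@pytest.fixture(scope="session")
def small_sim():
    """A 25-user simulated world shared by fast tests."""
    cfg = SimulationConfig(n_users=25, seed=7)
    users, posts, corpus, truth = simulate_cohort(cfg)
    return cfg, users, posts, corpus, truth


@pytest.fixture(scope="session")
def small_cohort(small_sim):
    _, users, posts, _, _ = small_sim
    return build_cohort(users, posts)
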