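"""Synthetic posting cohorts with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage — selection funnel, sequence encoding,
originality classification, correlation screen — can be exercised and
validated without any closed data:

* psychometric scales are drawn from a correlated multivariate normal
  (depression symptoms co-vary positively with neuroticism and
  negatively with conscientiousness, extroversion and life
  satisfaction), then mapped onto their bounded scale ranges;
* each user's posting window is a first-order Markov chain over the
  day states {+, -, ±, 0, S}; a silent day (S) emits no posts, an
  active day emits 1 + Poisson(lambda) posts whose polarity matches the
  day state with probability q (emission fidelity) and otherwise comes
  from a background polarity mix;
* personality shifts the chain on the logit scale (keeping rows
  stochastic for any effect size): by default extroversion raises
  positive persistence (+ -> +), agreeableness suppresses negative
  persistence (- -> -), and neuroticism raises positive/negative
  switching;
* each post is non-original with probability
  logistic(beta0 + beta_neu * z_neu); non-original posts copy a
  document from a generated pseudo-lyrics/quotes corpus verbatim,
  original posts get fresh token salad.

Everything is reproducible from (config, seed).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import (
    AFFECT_SYMBOLS,
    NEGATIVE,
    POSITIVE,
    Post,
    SCALE_NAMES,
    SEQUENCE_SYMBOLS,
    SILENCE,
    UserProfile,
)
from .originality import SourceDoc

_STATE_INDEX = {s: i for i, s in enumerate(SEQUENCE_SYMBOLS)}

# scale order: ope, con, ext, agr, neu, swl, cesd
_DEFAULT_TRAIT_CORR = np.array([
    # ope    con    ext    agr    neu    swl    cesd
    [1.00,  0.10,  0.20,  0.10,  0.00,  0.05,  0.00],
    [0.10,  1.00,  0.10,  0.15, -0.30,  0.30, -0.35],
    [0.20,  0.10,  1.00,  0.20, -0.30,  0.30, -0.30],
    [0.10,  0.15,  0.20,  1.00, -0.20,  0.20, -0.15],
    [0.00, -0.30, -0.30, -0.20,  1.00, -0.45,  0.55],
    [0.05,  0.30,  0.30,  0.20, -0.45,  1.00, -0.50],
    [0.00, -0.35, -0.30, -0.15,  0.55, -0.50,  1.00],
])

# nominal population means / SDs used to map latent z-scores onto the
# bounded scales (traits 1-5, SWL 1-7, CES-D 0-60); chosen to resemble a
# young, symptom-heavy social media cohort
_SCALE_MEANS = {"ope": 4.0, "con": 3.2, "ext": 3.1, "agr": 3.55,
                "neu": 3.0, "swl": 4.2, "cesd": 23.8}
_SCALE_SDS = {"ope": 0.45, "con": 0.75, "ext": 0.85, "agr": 0.68,
              "neu": 0.9, "swl": 1.4, "cesd": 11.9}
_SCALE_BOUNDS = {**{t: (1.0, 5.0) for t in ("ope", "con", "ext", "agr", "neu")},
                 "swl": (1.0, 7.0), "cesd": (0.0, 60.0)}

# base day-state chain (rows: from-state in {+, -, ±, 0, S}); silence is
# sticky so multi-day gaps occur, polarities are mildly persistent
_DEFAULT_DAY_STATE_BASE = np.array([
    # to:  +      -      ±      0      S
    [0.35, 0.12, 0.06, 0.17, 0.30],   # from +
    [0.15, 0.30, 0.07, 0.18, 0.30],   # from -
    [0.18, 0.15, 0.12, 0.20, 0.35],   # from ±
    [0.18, 0.13, 0.06, 0.33, 0.30],   # from 0
    [0.16, 0.12, 0.05, 0.15, 0.52],   # from S
])

# background polarity mix for off-state post emissions (+, -, ±, 0)
_DEFAULT_EMISSION_MIX = np.array([0.39, 0.28, 0.08, 0.24]) / 0.99

#: trait -> {(from_state, to_state): logit shift per SD of the trait}
_DEFAULT_EFFECT_SIZES = {
    "ext": {(POSITIVE, POSITIVE): 0.45},
    "agr": {(NEGATIVE, NEGATIVE): -0.42},
    "neu": {(POSITIVE, NEGATIVE): 0.60, (NEGATIVE, POSITIVE): 0.60},
}

_SYLLABLES = ["ba", "be", "bo", "da", "de", "do", "ka", "ke", "ko", "la",
              "le", "lo", "ma", "me", "mo", "na", "ne", "no", "ra", "re",
              "ro", "sa", "se", "so", "ta", "te", "to", "va", "ve", "vo"]


def _make_vocab(n_words: int, rng: np.random.Generator) -> list[str]:
    words = set()
    while len(words) < n_words:
        k = rng.integers(2, 4)
        words.add("".join(rng.choice(_SYLLABLES, size=k)))
    return sorted(words)


@dataclass
class SimulationConfig:
    """Knobs for the synthetic cohort generator (see module docstring)."""

    n_users: int = 70
    n_days: int = 60
    end_date: _dt.date = _dt.date(2012, 6, 30)
    trait_correlation: np.ndarray = field(
        default_factory=lambda: _DEFAULT_TRAIT_CORR.copy())
    day_state_base: np.ndarray = field(
        default_factory=lambda: _DEFAULT_DAY_STATE_BASE.copy())
    effect_sizes: dict = field(
        default_factory=lambda: {t: dict(v)
                                 for t, v in _DEFAULT_EFFECT_SIZES.items()})
    posts_lambda: float = 1.2        # active-day post count = 1 + Poisson
    emission_fidelity: float = 0.75  # P(post polarity == day state)
    emission_mix: np.ndarray = field(
        default_factory=lambda: _DEFAULT_EMISSION_MIX.copy())
    originality_beta: tuple[float, float] = (-2.5, 0.8)  # (beta0, beta_neu)
    corpus_size: int = 100
    keyword_site_fraction: float = 0.5
    vocab_size: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        self.trait_correlation = np.asarray(self.trait_correlation, float)
        self.day_state_base = np.asarray(self.day_state_base, float)
        self.emission_mix = np.asarray(self.emission_mix, float)
        if self.trait_correlation.shape != (7, 7):
            raise ValueError("trait_correlation must be 7x7 "
                             f"(order {SCALE_NAMES})")
        if not np.allclose(self.trait_correlation,
                           self.trait_correlation.T):
            raise ValueError("trait_correlation must be symmetric")
        if np.linalg.eigvalsh(self.trait_correlation).min() <= 1e-10:
            raise ValueError("trait_correlation must be positive definite")
        if self.day_state_base.shape != (5, 5):
            raise ValueError("day_state_base must be 5x5 over "
                             f"{SEQUENCE_SYMBOLS}")
        if (self.day_state_base < 0).any() or not np.allclose(
                self.day_state_base.sum(axis=1), 1.0):
            raise ValueError("day_state_base rows must be stochastic")
        if not (0.0 < self.emission_fidelity <= 1.0):
            raise ValueError("emission_fidelity must lie in (0, 1]")
        if self.n_days < 7:
            raise ValueError("n_days must be at least 7")
        if self.corpus_size < 1:
            raise ValueError("corpus_size must be at least 1")
        self.emission_mix = self.emission_mix / self.emission_mix.sum()
        for trait, effects in self.effect_sizes.items():
            if trait not in SCALE_NAMES:
                raise ValueError(f"unknown trait in effect_sizes: {trait!r}")
            for (a, b) in effects:
                if a not in SEQUENCE_SYMBOLS or b not in SEQUENCE_SYMBOLS:
                    raise ValueError(f"unknown state in effect on "
                                     f"{trait}: {(a, b)!r}")


@dataclass
class GroundTruth:
    """Latent quantities realized by one simulation run."""

    day_states: dict[str, list[str]]
    post_originality: dict[str, list[str]]          # O / N per post
    transition_matrices: dict[str, np.ndarray]      # per-user 5x5 chain
    non_original_prob: dict[str, float]
    config: SimulationConfig


def _z_score(user: UserProfile, scale: str) -> float:
    return (user.scale(scale) - _SCALE_MEANS[scale]) / _SCALE_SDS[scale]


def simulate_users(config: SimulationConfig,
                   seed: Optional[int] = None) -> list[UserProfile]:
    """Draw a cohort of user profiles from the correlated trait model."""
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed if seed is None else seed)
        .spawn(1)[0])
    n = config.n_users
    chol = np.linalg.cholesky(config.trait_correlation)
    z = rng.standard_normal((n, 7)) @ chol.T
    users = []
    genders = rng.choice(["female", "male"], size=n, p=[0.7, 0.3])
    ethnicities = rng.choice(["caucasian", "black", "asian", "other"],
                             size=n, p=[0.75, 0.04, 0.07, 0.14])
    living = rng.choice(["single", "with_partner", "married", "unknown"],
                        size=n, p=[0.77, 0.10, 0.07, 0.06])
    ages = np.clip(rng.normal(23.5, 6.5, size=n), 18.0, 65.0)
    for i in range(n):
        vals = {}
        for j, name in enumerate(SCALE_NAMES):
            lo, hi = _SCALE_BOUNDS[name]
            v = _SCALE_MEANS[name] + _SCALE_SDS[name] * z[i, j]
            vals[name] = float(np.clip(v, lo, hi))
        users.append(UserProfile(
            user_id=f"u{i:04d}",
            age=float(round(ages[i], 1)),
            gender=str(genders[i]), ethnicity=str(ethnicities[i]),
            living_status=str(living[i]),
            ope=vals["ope"], con=vals["con"], ext=vals["ext"],
            agr=vals["agr"], neu=vals["neu"], swl=vals["swl"],
            cesd=int(round(vals["cesd"])), cesd_date=config.end_date))
    return users


def user_transition_matrix(user: UserProfile,
                           config: SimulationConfig) -> np.ndarray:
    """The user's day-state chain: base logits shifted by standardized
    traits times the configured effect sizes, rows re-normalised."""
    logits = np.log(np.maximum(config.day_state_base, 1e-12))
    for trait, effects in config.effect_sizes.items():
        zt = _z_score(user, trait)
        for (a, b), delta in effects.items():
            logits[_STATE_INDEX[a], _STATE_INDEX[b]] += zt * delta
    mat = np.exp(logits - logits.max(axis=1, keepdims=True))
    return mat / mat.sum(axis=1, keepdims=True)


def make_reference_corpus(config: SimulationConfig,
                          seed: Optional[int] = None) -> list[SourceDoc]:
    """A seeded corpus of pseudo-lyrics/quote documents; a configurable
    fraction of sites carries a "lyrics" or "quote" keyword in its name
    and URL."""
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed if seed is None else seed)
        .spawn(3)[2])
    vocab = _make_vocab(config.vocab_size, rng)
    docs = []
    n_keyword = int(round(config.keyword_site_fraction * config.corpus_size))
    for i in range(config.corpus_size):
        words = rng.choice(vocab, size=int(rng.integers(8, 17)))
        text = " ".join(words)
        if i < n_keyword:
            kind = "lyrics" if i % 2 == 0 else "quote"
            site = f"{kind}-archive-{i:03d}"
            url = f"https://{kind}{i:03d}.example/{words[0]}"
        else:
            site = f"site-{i:03d}"
            url = f"https://pages{i:03d}.example/{words[0]}"
        docs.append(SourceDoc(doc_id=f"doc{i:04d}", text=text,
                              site_name=site, url=url))
    return docs


def simulate_posts(users: Sequence[UserProfile], config: SimulationConfig,
                   corpus: Optional[list[SourceDoc]] = None,
                   seed: Optional[int] = None
                   ) -> tuple[list[Post], GroundTruth]:
    """Simulate each user's posting window; returns the posts (sorted by
    user then time) and the latent ground truth."""
    if not users:
        raise ValueError("users must be non-empty")
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    _, posts_ss, corpus_ss = root.spawn(3)
    if corpus is None:
        corpus = make_reference_corpus(config, seed=seed)
    corpus_texts = [d.text for d in corpus]
    vocab_rng = np.random.default_rng(corpus_ss.spawn(1)[0])
    vocab = _make_vocab(config.vocab_size, vocab_rng)

    beta0, beta_neu = config.originality_beta
    start_day = config.end_date - _dt.timedelta(days=config.n_days - 1)
    all_posts: list[Post] = []
    truth = GroundTruth(day_states={}, post_originality={},
                        transition_matrices={}, non_original_prob={},
                        config=config)
    user_seeds = posts_ss.spawn(len(users))
    for user, uss in zip(users, user_seeds):
        rng = np.random.default_rng(uss)
        mat = user_transition_matrix(user, config)
        truth.transition_matrices[user.user_id] = mat
        p_nonorig = float(1.0 / (1.0 + np.exp(-(beta0 + beta_neu *
                                                _z_score(user, "neu")))))
        truth.non_original_prob[user.user_id] = p_nonorig

        state = _STATE_INDEX[SILENCE]
        for _ in range(25):                       # burn-in toward stationarity
            state = rng.choice(5, p=mat[state])
        states: list[str] = []
        originality: list[str] = []
        for d in range(config.n_days):
            state = int(rng.choice(5, p=mat[state]))
            sym = SEQUENCE_SYMBOLS[state]
            states.append(sym)
            if sym == SILENCE:
                continue
            n_posts = 1 + int(rng.poisson(config.posts_lambda))
            day = start_day + _dt.timedelta(days=d)
            for j in range(n_posts):
                if rng.random() < config.emission_fidelity:
                    affect = sym
                else:
                    affect = AFFECT_SYMBOLS[int(rng.choice(
                        4, p=config.emission_mix))]
                non_original = rng.random() < p_nonorig
                if non_original:
                    text = corpus_texts[int(rng.integers(len(corpus_texts)))]
                else:
                    words = rng.choice(vocab,
                                       size=int(rng.integers(5, 15)))
                    text = " ".join(words)
                created = _dt.datetime.combine(
                    day, _dt.time(hour=min(8 + 2 * j, 23),
                                  minute=int(rng.integers(60))))
                label = "non_original" if non_original else "original"
                originality.append("N" if non_original else "O")
                all_posts.append(Post(
                    user_id=user.user_id, created_at=created,
                    affect=affect, text=text, language="en",
                    originality_gold=label,
                    post_id=f"{user.user_id}-d{d:03d}-{j}"))
        truth.day_states[user.user_id] = states
        truth.post_originality[user.user_id] = originality
    all_posts.sort(key=lambda p: (p.user_id, p.created_at, p.post_id))
    return all_posts, truth


def simulate_cohort(config: SimulationConfig, seed: Optional[int] = None):
    """One-call generator: (users, posts, corpus, ground_truth)."""
    users = simulate_users(config, seed=seed)
    corpus = make_reference_corpus(config, seed=seed)
    posts, truth = simulate_posts(users, config, corpus=corpus, seed=seed)
    return users, posts, corpus, truth
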