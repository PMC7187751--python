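"""Near-duplicate (non-original content) detection and evaluation.

Social media users often post lyrics or quotes rather than their own
words. Such *non-original* content is detected by comparing a post
against candidate source documents with term-frequency cosine
similarity over normalised unigram tokens:

* best similarity strictly above a high threshold (default 0.96) →
  ``non_original``;
* best similarity inside the band [low, high] (default [0.92, 0.96]) AND
  the best source's url or site name contains "lyrics" or "quote"
  (case-insensitive) → ``potential`` (potentially non-original);
* otherwise ``original``.

For binary analyses, ``potential`` counts as non-original by default.

Candidate retrieval is abstracted behind :class:`SourceRetriever`; the
bundled :class:`LocalCorpusRetriever` ranks a local corpus by token
overlap, so the classifier is fully reproducible offline. Live
search-engine retrieval is deliberately out of scope.
"""

from __future__ import annotations

import math
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence

from .core import (
    Cohort,
    DateWindow,
    NON_ORIGINAL,
    ORIGINAL,
    ORIGINALITY_SYMBOLS,
    Post,
    SILENCE,
)
from .sequences import TransitionProfile, count_transitions

_URL_RE = re.compile(r"https?://\S+|www\.\S+")
_TOKEN_RE = re.compile(r"[a-z0-9']+")
_KEYWORDS = ("lyrics", "quote")


@dataclass
class SourceDoc:
    """A candidate source document (e.g. one retrieved web page)."""

    doc_id: str
    text: str
    site_name: str = ""
    url: str = ""

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError(f"source doc {self.doc_id!r} has empty text")

    @property
    def keyword_flag(self) -> bool:
        hay = (self.url + " " + self.site_name).lower()
        return any(k in hay for k in _KEYWORDS)


@dataclass
class OriginalityThresholds:
    hi: float = 0.96
    lo: float = 0.92
    potential_is_non_original: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.lo <= self.hi <= 1.0):
            raise ValueError("thresholds must satisfy 0 < lo <= hi <= 1")


@dataclass
class OriginalityResult:
    post_id: str
    best_similarity: float
    best_source: Optional[str]
    raw_label: str                 # original | potential | non_original
    binary_label: str              # O | N
    no_candidates: bool = False


def tokenize(text: str) -> list[str]:
    """Normalise to lowercase unigram tokens: URLs stripped, punctuation
    removed, whitespace collapsed."""
    text = _URL_RE.sub(" ", text.lower())
    return _TOKEN_RE.findall(text)


def text_similarity(a: str, b: str) -> float:
    """Cosine similarity of unigram term-frequency vectors.

    1.0 for identical token multisets, 0.0 for disjoint vocabularies.
    A text that is empty after normalisation yields 0.0 with a warning
    (the similarity is undefined).
    """
    ta, tb = tokenize(a), tokenize(b)
    if not ta or not tb:
        warnings.warn("text empty after normalisation; similarity "
                      "undefined, treating as 0")
        return 0.0
    ca, cb = Counter(ta), Counter(tb)
    if ca == cb:
        return 1.0
    dot = sum(ca[t] * cb[t] for t in ca.keys() & cb.keys())
    if dot == 0:
        return 0.0
    na = math.sqrt(sum(v * v for v in ca.values()))
    nb = math.sqrt(sum(v * v for v in cb.values()))
    return min(dot / (na * nb), 1.0)


class SourceRetriever(Protocol):
    """Anything that can propose candidate sources for a post text."""

    def retrieve(self, text: str, k: int = 10) -> list[SourceDoc]:
        ...


@dataclass
class LocalCorpusRetriever:
    """Rank a fixed local corpus by shared-token count (a cheap stand-in
    for a search engine's first results page)."""

    corpus: list[SourceDoc]
    k: int = 10
    _index: list[set] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self._index = [set(tokenize(d.text)) for d in self.corpus]

    def retrieve(self, text: str, k: Optional[int] = None) -> list[SourceDoc]:
        k = k or self.k
        query = set(tokenize(text))
        if not query:
            return []
        scored = []
        for doc, toks in zip(self.corpus, self._index):
            overlap = len(query & toks)
            if overlap:
                scored.append((overlap, doc))
        scored.sort(key=lambda t: (-t[0], t[1].doc_id))
        return [doc for _, doc in scored[:k]]


def classify_post(post: Post, candidates: Sequence[SourceDoc],
                  thresholds: OriginalityThresholds | None = None
                  ) -> OriginalityResult:
    """Label one post against its candidate sources.

    With no candidates the post is original by default (similarity 0,
    flagged ``no_candidates``).
    """
    th = thresholds or OriginalityThresholds()
    post_id = post.post_id or f"{post.user_id}:{post.created_at.isoformat()}"
    if not candidates:
        return OriginalityResult(post_id=post_id, best_similarity=0.0,
                                 best_source=None, raw_label="original",
                                 binary_label=ORIGINAL, no_candidates=True)
    best_sim, best_doc = -1.0, None
    for doc in candidates:
        s = text_similarity(post.text, doc.text)
        if s > best_sim:
            best_sim, best_doc = s, doc
    if best_sim > th.hi:
        raw = "non_original"
    elif th.lo <= best_sim <= th.hi and best_doc.keyword_flag:
        raw = "potential"
    else:
        raw = "original"
    if raw == "non_original":
        binary = NON_ORIGINAL
    elif raw == "potential":
        binary = NON_ORIGINAL if th.potential_is_non_original else ORIGINAL
    else:
        binary = ORIGINAL
    return OriginalityResult(post_id=post_id, best_similarity=best_sim,
                             best_source=best_doc.doc_id, raw_label=raw,
                             binary_label=binary)


def classify_cohort(cohort: Cohort, retriever: SourceRetriever,
                    thresholds: OriginalityThresholds | None = None
                    ) -> dict[str, list[OriginalityResult]]:
    """Classify every post of every cohort user; results keep post order."""
    out: dict[str, list[OriginalityResult]] = {}
    for user, posts in cohort.iter_user_posts():
        out[user.user_id] = [
            classify_post(p, retriever.retrieve(p.text), thresholds)
            for p in posts
        ]
    return out


def f_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def evaluate_classifier(predicted: Sequence[str], gold: Sequence[str],
                        positive: str = NON_ORIGINAL
                        ) -> tuple[float, float, float]:
    """Precision, recall and F1 of binary originality predictions, with
    non-original as the positive class by convention."""
    if len(predicted) != len(gold):
        raise ValueError(f"label vectors differ in length "
                         f"({len(predicted)} vs {len(gold)})")
    tp = sum(1 for p, g in zip(predicted, gold)
             if p == positive and g == positive)
    fp = sum(1 for p, g in zip(predicted, gold)
             if p == positive and g != positive)
    fn = sum(1 for p, g in zip(predicted, gold)
             if p != positive and g == positive)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return precision, recall, f_score(precision, recall)


_GOLD_TO_SYMBOL = {"original": ORIGINAL, "non_original": NON_ORIGINAL,
                   ORIGINAL: ORIGINAL, NON_ORIGINAL: NON_ORIGINAL}


def originality_sequence(posts: Sequence[Post], window: DateWindow,
                         labels: Optional[Sequence[str]] = None,
                         user_id: str = ""
                         ) -> tuple[list[str], TransitionProfile]:
    """Post-level with-silence originality stream over {O, N, S}.

    Labels come from ``labels`` (binary O/N, aligned with ``posts``) or,
    when omitted, from each post's gold originality label. One ``S``
    token marks each silent calendar day; transitions are counted over
    the 6 unordered pairs of the three-symbol alphabet.
    """
    if labels is not None and len(labels) != len(posts):
        raise ValueError("labels must align with posts")
    resolved: list[str] = []
    for i, p in enumerate(posts):
        lab = labels[i] if labels is not None else p.originality_gold
        if lab is None or lab not in _GOLD_TO_SYMBOL:
            pid = p.post_id or f"{p.user_id}:{p.created_at.isoformat()}"
            raise ValueError(f"post {pid} has no usable originality label")
        resolved.append(_GOLD_TO_SYMBOL[lab])

    # bucket by day, inserting one silence token per empty day
    symbols: list[str] = []
    per_day: dict = {}
    for p, s in zip(posts, resolved):
        if p.day not in window:
            raise ValueError(f"post on {p.day} outside window")
        per_day.setdefault(p.day, []).append(s)
    for day in window.days():
        if day in per_day:
            symbols.extend(per_day[day])
        else:
            symbols.append(SILENCE)
    profile = count_transitions(symbols, alphabet=ORIGINALITY_SYMBOLS,
                                user_id=user_id,
                                representation="post_with_silence")
    return symbols, profile
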