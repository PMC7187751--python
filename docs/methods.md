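# Methods

This note documents the models and procedures the package implements,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical conventions that matter when
reproducing results.

## Affect alphabet and sequence representations

Posts carry one of four affect polarities — positive `+`, negative `-`,
mixed `±` (both valences present), neutral `0`. A fifth symbol `S`
(silence) marks a calendar day in the observation window with no posts;
it is always derived, never stored on disk (the portable on-disk tokens
are `pos/neg/mix/neu`).

A user's window is encoded three ways:

- **post-level with silence** — post polarities in chronological order,
  with exactly one `S` token at the chronological position of each
  silent day. Consecutive silent days therefore produce S↔S adjacencies,
  which is why S↔S is a counted transition type.
- **post-level without silence** — post polarities only. The five
  S-containing pair types are structurally impossible here and are
  excluded from correlation screens of this representation.
- **day-level** — exactly one symbol per window day, regardless of
  posting gaps.

The observation window is the 60 calendar days ending at, and including,
the user's CES-D completion date. Dates are taken at face value; no
timezone arithmetic is attempted, and within-day post order follows the
timestamps (or file order where timestamps carry no time of day).

### Day-level dominant affect

For the posts of one day, rules apply in this order:

1. no posts → `S`;
2. equally many `+` and `-` posts (at least one of each) → `±`;
3. as many `±` posts as all non-`±` posts combined → `±`;
4. otherwise the strict-plurality polarity; a remaining tie resolves by
   the fixed precedence `±` > `-` > `+` > `0`.

Two genuinely open points are settled as configuration:

- *Rule order.* The balance rules (2–3) are checked before plurality, so
  a day of `0 0 0 + -` is mixed, not neutral. `plurality_first=True`
  flips this, letting a strict plurality win before the balance rules
  fire. The default follows the prose order in which the rules are
  usually stated.
- *The tie precedence* in rule 4 exists purely for determinism; mixed
  ranks first because an unresolved tie is exactly a day without a clear
  single polarity.

Worked-example caveat: in the published sample week, Monday's two posts
`+ -` are printed with day-level `-`, which contradicts both the balance
rule and the same pattern's `±` on Sunday. The implementation follows
the stated rule; the worked-example test asserts Tuesday–Sunday only and
the discrepancy is documented here rather than reproduced.

## Transition features

Adjacent symbols are tallied under unordered (bidirectional) pairs a↔b:
C(5,2) + 5 = 15 types for the affect alphabet, 6 for the originality
alphabet {O, N, S}. For a sequence of length L the counts sum to L − 1.

Per-user **proportions** of total transitions are the correlation
features (raw counts are also emitted, and pooled occurrence counts per
pair type are reported cohort-wide). Proportions were chosen because raw
counts are dominated by posting volume, which is already constrained by
the selection funnel; whether the original analysis used counts or
proportions is not stated anywhere, so this is the package's choice.
Users with fewer than two symbols in a representation carry no
transition and are excluded from the feature table with a warning.

## Selection funnel

Stages run in a fixed order, each recorded in an auditable report
(counts in/out and removed ids per stage):

1. regular user: mean posts/day ≥ 0.3 over the user's own posting span
   (first to last post, inclusive). 0.3/day ≈ 110 posts/year ≈ two a
   week. The boundary is inclusive ("twice a week *or more*"). Whether
   the original rate was computed over the full history or a fixed
   recent frame is unknowable; the span convention is ours and the frame
   is configurable.
2. recent activity: ≥ 1 post in the 7 calendar days ending at the CES-D
   completion date (the instrument asks about the past week).
3. window restriction to the 60-day observation window (a
   transformation; removes nobody, but appears in the report so
   downstream counts are traceable).
4. ≥ 20 posts in the window.
5. age ≥ 18.
6. non-English share ≤ 20% of window posts, judged from the per-post
   language tag (language identification is *not* performed; the tag is
   trusted because the original judgment was human). Survivors'
   non-English window posts are then dropped from analysis by default.

## Originality classifier

Texts are normalised to lowercase unigram tokens (URLs stripped,
punctuation removed) and compared by term-frequency cosine. Identical
token multisets score exactly 1.0. TF without IDF is the minimal reading
of "cosine similarity" between two short texts; IDF weighting or
character n-grams would need a corpus-level statistic the procedure
never mentions.

Thresholds: best similarity > 0.96 → non-original; in [0.92, 0.96] with
"lyrics"/"quote" in the best source's site name or URL → potentially
non-original; otherwise original. Both band edges are inside the band
(the high rule is strict: "> 0.96"). Potentials count as non-original in
binary analyses by default (flag-reversible; how they were tallied
originally is unstated). A post with no retrieval candidates is original
with similarity 0 and a `no-candidates` flag.

Retrieval is an interface. The shipped `LocalCorpusRetriever` ranks a
local corpus by shared-token overlap — reproducible and offline; live
search-engine retrieval is out of scope by design (result sets are
unstable and unreplayable).

## Statistics

- **Permutation correlation test.** r is the closed-form Pearson
  estimator; p = (1 + #{|r_b| ≥ |r|}) / (B + 1) over B seeded
  permutations of y, two-sided. The add-one estimator keeps p in
  [1/(B+1), 1] and never returns 0. Default B = 10,000. A permutation
  that happens to reproduce a monotone ordering ties a perfect observed
  correlation; tests must not assume the minimum p is always attained.
- **Bootstrap CI.** Percentile interval over 2,000 paired resamples by
  default (resample counts and the CI method were unstated; percentile
  is the simplest defensible default). Degenerate resamples (constant
  vectors) are redrawn with a retry guard.
- **Tiers.** p < 0.01 significant, p < 0.05 trend. No formal
  multiple-testing correction — the strict 0.01 tier *is* the
  correction policy, matching the original choice; an optional
  Benjamini–Hochberg column is available but off by default.
- **Partial correlation.** First-order formula with the t-approximation
  (t = r√((n−3)/(1−r²)) on n−3 df); a permutation variant on regression
  residuals is available behind `perm_partial_corr`.
- **Mann–Whitney.** U for the first sample with tie-corrected normal
  approximation, no continuity correction; an exhaustive-enumeration p
  is provided for oracle use at tiny n.
- **Cohen's κ** with marginal-product chance agreement; identical
  constant raters score 1, different constant raters score 0 (their
  chance agreement is 0, not 1). Average pairwise κ over a rater team is
  the plain mean over all pairs.
- **Normality.** Shapiro–Wilk, delegated to scipy.
- **Determinism.** The correlation screen spawns one child generator per
  scale×feature pair from a single seed, so results are bit-identical
  across runs and independent of traversal order.

Published confidence intervals of this kind of analysis do not always
bracket their point estimates; no attempt is made to reproduce any
specific printed interval.

## Synthetic cohort generator

The generator realises the structure the analysis assumes, with defaults
stating one fixed world:

- **Scales.** (ope, con, ext, agr, neu, swl, cesd) drawn from a
  multivariate normal with a positive-definite correlation matrix:
  neu–cesd +0.55, swl–cesd −0.50, con–cesd −0.35, ext–cesd −0.30,
  neu–swl −0.45, plus modest inter-trait structure. Latent scores map to
  scale ranges via nominal means/SDs resembling a young, symptom-heavy
  social media cohort (CES-D mean ≈ 24, SD ≈ 12; traits near 3–4 on 1–5)
  and are clipped to bounds; CES-D is generated jointly with the traits
  rather than as a response, because the mediation claim under study is
  correlational, not causal.
- **Posting.** Per user, a first-order Markov chain over day states
  {+, -, ±, 0, S}, 60 days after a 25-step burn-in. The base matrix
  makes silence sticky (S→S = 0.52; about 40% of days are silent, so
  multi-day gaps and S↔S transitions occur) and polarities mildly
  persistent. Active days emit 1 + Poisson(1.2) posts; each matches the
  day state with probability q = 0.75, otherwise drawn from a background
  polarity mix of roughly 39/28/8/24% (+/−/±/0), matching typical
  labelled-corpus shares. The two-level design (day state vs post
  emission) mirrors the mood-vs-emotion distinction behind the day/post
  duality.
- **Trait effects** act on row logits of the chain, then rows are
  re-normalised — stochasticity survives any effect size. Defaults:
  extroversion +0.45 on the +→+ logit, agreeableness −0.42 on −→−,
  neuroticism +0.60 on both +→− and −→+, per SD of the trait. These were
  calibrated once so the pipeline-recovered correlations land near the
  magnitudes such studies report (|r| ≈ 0.3: measured 0.35 / −0.34 /
  0.33 at n = 3,000) and then frozen.
- **Originality.** Each post is non-original with probability
  logistic(−2.5 + 0.8·z_neu) — a base rate near 8% rising with
  neuroticism. Non-original posts copy one document of a seeded
  pseudo-lyrics/quotes corpus verbatim (half the corpus sites carry a
  "lyrics"/"quote" keyword); original posts are fresh token salad from a
  different vocabulary.
- **Reproducibility.** Everything derives from (config, seed) through
  spawned `SeedSequence` children; a fixed seed reproduces users, posts,
  corpus, and ground truth bit-for-bit.

What the generator does **not** emulate: natural language (texts are
token salad, so the originality classifier's precision is trivially high
on synthetic data — only recall on verbatim copies is a meaningful
end-to-end check); diurnal or weekly posting rhythms; comment/like
dynamics; non-English posts or under-18 users (the funnel's language and
age stages are exercised by dedicated fixtures instead); measurement
error in the scales. A green end-to-end test therefore establishes that
the pipeline recovers the *planted correlational structure* — not that
any real population exhibits it.

## Numerical conventions and degenerate inputs

- Affect symbols are canonically ordered `+, -, ±, 0, S`; unordered pair
  keys sort by that order and print as `a<->b`.
- Constant feature or scale columns carry no correlation signal; screens
  skip them with a single warning (or raise, if configured strictly).
- `text_similarity` on a text that normalises to nothing returns 0 with
  a warning (the cosine is undefined).
- Sequences of length ≤ 1 have zero transitions; their users are
  excluded from feature tables with a warning.
- Permutation p-values can never be 0; bootstrap intervals on perfectly
  collinear data collapse to a point.
- CES-D values are integers in [0, 60]; 22 is the probable-depression
  cut-off. Traits live in [1, 5], SWL in [1, 7]; readers reject rows
  outside these ranges with row references.

## Known limitations

- The with-silence post-level stream inserts exactly one `S` per silent
  day, so a silent week contributes six S↔S transitions; alternative
  encodings (one S per gap) would change S-pair counts materially.
- The day-level majority rule's tie precedence beyond the two stated
  balance rules is an invention of necessity; flipping `plurality_first`
  changes a small number of day labels on real-shaped data.
- The classifier detects verbatim and near-verbatim copying only;
  paraphrased quotes score low cosine and pass as original.
- Partial correlation controls for one linear confounder; nonlinear
  confounding (e.g. a logistic link between trait and behaviour) leaves
  a small residual partial correlation even when the structural claim
  holds exactly.
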