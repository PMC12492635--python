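# Methods

This note documents the models and procedures implemented in `affsync`,
the parameters that matter, the decisions taken where the design was
genuinely open, and what the synthetic-data experiments do and do not
show.

## Annotation model

An *annotation tier* is a time-ordered track of segments produced by one
annotator (human or machine) for one role of one session under one
scheme. Schemes are *discrete* (fixed label set), *continuous* (numeric
values in a closed range; typically dense fixed-rate samples) or *free*
(text, e.g. transcription).

**Interval convention.** All intervals are half-open `[start, end)` in
float seconds. This makes fixed-length binning an exact partition of the
timeline: an instant on a bin boundary belongs to exactly one bin, and
back-to-back dense samples do not overlap. Timestamps serialize at
millisecond precision — upstream recognizers operate at ≥ 1 Hz, so
nothing finer carries information.

**Validation as data.** Invariants (`start < end`, label membership,
value range, confidence ∈ [0,1], intra-tier sort and non-overlap for
discrete/free tiers) are checked by `validate_tier`, which returns
violation records instead of raising, so partially corrupt machine output
can be triaged. Overlap is forbidden *within* a discrete/free tier but
free *across* tiers — parallel tracks are the normal case. The optional
per-segment confidence is stored for round-tripping and ignored by all
computation.

## Binning and ensemble fusion

The fusion grid has interval length `interval_length` (default 1.0 s);
interval *i* covers `[i·L, (i+1)·L)`. Only intervals overlapped by speech
of the target role get fused values.

- *Discrete streams* aggregate per bin by **duration-weighted mode** —
  the label holding the bin for the most time; ties break to the
  lexicographically smallest label so binning is deterministic and
  independent of segment order.
- *Continuous streams* aggregate by **time-weighted mean** over the
  covered part of the bin (uncovered time does not dilute the mean).
- *Sentiment* is attached per transcript segment; an interval shared by
  two speech segments of the same speaker receives the duration-weighted
  mean of their per-model scores.

Across the (typically three-model) ensemble:

- fused sentiment = arithmetic mean of model scores, then classified at
  ±`sentiment_threshold` (default 0.5, strict inequalities). A numeric
  mean is fused first because the classification rule tests a numeric
  inequality; a `sentiment_fusion: vote` switch instead classifies each
  model and majority-votes the classes.
- fused emotion = majority vote of model labels. A tie resolves to
  `neutral` when neutral is among the tied labels and otherwise to an
  `unclassified` sentinel — a tie never manufactures an (a)synchrony
  claim. The fused label maps to a polarity through `emotion_polarity`
  (defaults: happiness → positive; sadness, anger, fear, disgust,
  contempt → negative; surprise, neutral → neutral; fully
  config-overridable, and an unmapped label is a hard error).
- fused valence = mean of model valences, classified *high* iff
  > `valence_midpoint` (default 0.5); `valence_fusion: vote` votes
  per-model {low, high} classes instead.

Fusion is invariant under model permutation, and the sentiment class is
monotone in every individual model score.

## (A)synchrony classification

Per interval, with fused classes (sentiment_class, emotion_polarity,
valence_class):

- neutral sentiment ⇒ unclassified (no channel);
- the **emotion channel** is synchronous iff its polarity matches the
  sentiment class, asynchronous iff it opposes it, undecided for neutral
  polarity;
- the **valence channel** is asynchronous iff its class opposes the
  sentiment class (positive sentiment with low valence, negative with
  high), synchronous otherwise — it always decides;
- the reported channel is `both` when the two channels agree, the single
  deciding channel otherwise.

Two open points were closed as follows:

- **Negative-sentiment mirror rule.** The classification is stated
  symmetrically: clearly negative speech accompanied by positive
  non-verbal affect is asynchronous. The symmetric reading is the only
  one consistent with a single ±threshold governing both decision
  directions; the full 18-combination verdict table is frozen in the test
  suite.
- **Channel conflict** (emotion says synchrony, valence asynchrony or
  vice versa): the interval is recorded as two single-channel labels and
  is *denied* the `both` channel; it is surfaced as an explicit
  `conflict` summary value. Because scene selection consumes only
  `both`-channel time, conflicts can never leak into a selected scene.

## Scene building and selection

One candidate per speech segment of the target role. Within a segment,
`both`-channel time is tallied per decision; the modal decision *d* wins
and a tie drops the segment — an ambiguous scene must not enter a rating
study. Coverage = (time in both-intervals with decision *d*) / segment
duration; unclassified time counts against coverage. The alternative
reading — counting only classifiable time in the denominator — is
available as `coverage_denominator: classified`. A candidate survives iff
duration ≥ `min_scene_duration` (default 5 s) and coverage ≥
`min_both_coverage` (default 0.70).

Selection draws `n_select_per_class` (default 3) scenes per decision
class, uniformly without replacement, from one seeded NumPy generator
consumed in documented order (asynchrony pool, synchrony pool,
presentation shuffle), so a fixed seed reproduces the selection
bit-for-bit across platforms. An exhausted class returns all its
candidates plus a shortfall record.

## Sliding-window scene search

`apply_rule` slides a `window_length` (default 4 s) window in `step`
(default 1 s) increments, evaluates the predicate on the segments clipped
to the window, and merges overlapping/adjacent positive windows into
maximal segments on a machine-annotated output tier (hence output
segments never extend beyond the union of positive windows). The
smile-mirroring predicate is true when some smile onset in one tier lies
within `max_lag` (default 3 s) of an onset in the other, or when two
smiles overlap by at least `min_overlap` (default 0.5) of the shorter
one. The predicate is symmetric in the two tiers and monotone in
`max_lag`. The defaults reflect the few-second smile-response latencies
typical of dyadic interaction and are parameters, not claims.

## Agreement statistics

Tiers by multiple annotators are binned onto the interval grid and
stacked into an items × raters matrix; intervals a rater left unlabeled
are missing, and both statistics use complete-case (listwise) deletion —
the standard convention.

- **Cohen's κ** (exactly two categorical raters):
  κ = (p_o − p_e)/(1 − p_e) with chance agreement p_e from the product of
  marginal label frequencies. p_e = 1 occurs only when both raters are
  constant on the same label, where κ = 1.
- **Cronbach's α** (≥ 2 numeric raters): α = k/(k−1)·(1 − Σσ²ᵣ/σ²ₜ) with
  per-rater sample variances over items and σ²ₜ the variance of the
  per-item rater sums, all with the unbiased n−1 denominator. Zero total
  variance is an error rather than a value.

Both are cross-checked in the tests against independent routes
(scikit-learn's κ, pingouin's α, and a covariance-matrix form of α).

## Synthetic sessions

The generator emulates recognizer *outputs*: a diarized two-role
transcript whose segments carry three per-model sentiment scores, three
categorical-emotion streams and three continuous-valence streams at 1 Hz
for the target role, and per-role binary smile tiers — mirroring the
three-model ensemble cardinality per modality.

- Speech-segment durations are lognormal(μ = 1.5, σ = 0.6) seconds
  (median ≈ 4.5 s), chosen so that realistic utterances straddle the 5 s
  scene filter and both filter branches are exercised; gaps are a fraction
  of a second to ~1.5 s.
- A **planted scene** snaps its segment to the integer grid with a whole
  number of seconds *n*, so the achieved coverage is exactly
  `round(coverage·n)/n`. Planted intervals carry sentiment ±0.8 (all
  models), an emotion drawn from the matching polarity set and valence
  0.15/0.85; the remaining intervals of a planted segment get a
  neutral-polarity emotion, which can never count as both-channel time.
  Unplanted speech keeps sentiment within the neutral band, so a
  noise-free session yields exactly the qualifying planted scenes — the
  generator's consistency gate, asserted in the tests.
- **Noise** is applied after planting: per-model Gaussian jitter on
  scores and valence (`score_jitter_sd`), and per-model, per-interval
  label flips with probability ε (`label_flip_prob`): the emotion label
  is replaced by a different random label and the valence value is
  reflected across the midpoint. The ground truth records which segments
  qualify *pre-noise*.

What passing these experiments shows — and does not. Recovery and filter
exactness on synthetic sessions validate the *pipeline logic*: binning,
fusion, voting, classification, filtering and seeded selection.
The generator does not emulate correlated model errors, recognizer drift,
diarization mistakes, overlapping speech, or the base rates of real
affect; numbers obtained on it say nothing about recognizer accuracy on
recordings.

## Problem sizes and numerical choices

The default experiment sizes (400–1,000 randomized sessions for filter
exactness, 30 noise-free and 200 noisy sessions for recovery, ~12
segments per role and session) give stable Monte-Carlo estimates while
keeping the whole suite fast on a single CPU. Filter comparisons use an
absolute guard of 1e-9 against float accumulation; binning conservation
holds to the same tolerance. Degenerate inputs are errors where a value
would be meaningless (empty vote list, zero total variance, < 2 complete
rated items) and empty-but-valid results where the data is merely absent
(no speech, no candidate scenes, empty slice windows).

## Known limitations

- Sentiment is attached per transcript segment, so a very long utterance
  has constant per-model sentiment across its intervals; sub-segment
  sentiment shifts are invisible by construction.
- The conflict representation keeps single-channel (a)synchrony labels
  available, but no scene category is built from single-channel time.
- κ is the two-rater form only; multi-rater categorical agreement
  (Fleiss, Krippendorff, weighted κ) is out of scope.
- File I/O covers this package's documented dialect only; no database or
  third-party annotation-tool formats are read.
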