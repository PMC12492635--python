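# affsync

Detection of **intrapersonal affective (a)synchrony** in dyadic
interactions — moments where what a person *says* and what their face and
voice *show* diverge — from the outputs of multimodal behavior
recognizers, plus the supporting machinery such analyses need: a typed
time-anchored annotation model, a sliding-window rule engine for
dyadic events such as smile mirroring, inter-rater agreement statistics,
and a synthetic session generator with planted ground truth.

The intended users are researchers in behavioral signal processing and
digital mental health who already run speech transcription, diarization,
sentiment, facial-emotion and valence models over recorded sessions
(e.g. clinical interviews) and need a reproducible, testable way to turn
those parallel streams into scene-level annotations. No audio, video or
pretrained model is consumed here — only their outputs, as flat files.

## The method

Each speech segment of the target speaker is divided into one-second
intervals. Within an interval, each recognizer stream is aggregated to
its dominant value (duration-weighted mode for labels, time-weighted mean
for numeric streams), then fused across the model ensemble:

- **sentiment** s ∈ [−1, +1]: mean of the per-model scores, classified
  *positive* if s > 0.5, *negative* if s < −0.5, else *neutral*;
- **categorical emotion**: majority vote over the models' labels
  (ties resolve to *neutral*), mapped to a polarity
  {positive, negative, neutral};
- **valence** v ∈ [0, 1]: mean of the per-model values, *high* iff
  v > 0.5.

An interval with clearly positive sentiment accompanied by a
negative-polarity emotion and/or valence below 0.5 is **asynchronous**;
matching non-verbal affect makes it **synchronous**; clearly negative
sentiment uses the mirror rule, and neutral sentiment decides nothing.
The verdict is tracked per channel (*emotion*, *valence*, or *both* when
the two agree). A speech segment becomes a **scene** if it is at least
5 s long and *both*-classified with a uniform decision for at least 70%
of its duration; 3 scenes per decision class are then drawn with a seeded
RNG and returned in randomized presentation order. All thresholds are
config keys (`sentiment_threshold`, `valence_midpoint`,
`min_scene_duration`, `min_both_coverage`, `n_select_per_class`, …).

The package also ships Cohen's κ = (p_o − p_e)/(1 − p_e) and Cronbach's
α = k/(k−1)·(1 − Σσ²ᵣ/σ²ₜ) over annotator tiers aligned to the interval
grid, and a windowed smile-mirroring detector (onset within `max_lag`,
or overlap ≥ `min_overlap` of the shorter smile).

## Worked example

Generate a synthetic session with 4 planted synchronous and 4 planted
asynchronous scenes, then run detection:

```
$ affsync simulate --out demo/session --seed 7 --n-sync 4 --n-async 4
INFO affsync: wrote session synthetic-7 with 8 planted scenes
$ affsync detect demo/session --seed 7 --out demo/out
INFO affsync: selected 6 scenes from 8 candidates
```

`demo/out/report.json` then contains

```json
{
  "n_intervals": 94,
  "channel_tally": {"both:asynchrony": 32, "both:synchrony": 32,
                    "none:unclassified": 30},
  "n_candidates": 8,
  "candidates_by_class": {"asynchrony": 4, "synchrony": 4},
  "n_selected": 6,
  "shortfall": {"asynchrony": 0, "synchrony": 0}
}
```

94 one-second intervals of the patient's speech were fused; 64 carried a
*both*-channel verdict (the planted scenes at full coverage), 30 fell in
the neutral sentiment band. All 8 planted segments passed the 5 s / 70%
filters, and 3 per class were drawn for presentation. The selected scenes
are also written as a machine-annotated tier, `demo/out/scenes.csv`:

```
start;end;payload;confidence
2.000;10.000;synchrony;
17.000;25.000;synchrony;
29.000;37.000;synchrony;
73.000;81.000;asynchrony;
86.000;94.000;asynchrony;
101.000;109.000;asynchrony;
```

The same workflow is available as library calls
(`affsync.generate_session`, `affsync.detect_scenes`,
`affsync.select_scenes`); `affsync search` runs the smile-mirroring rule
over two tier files and `affsync agreement` computes κ/α over rater tiers.

## File formats

Tiers are semicolon-separated CSV (`start;end;payload;confidence`, UTF-8,
millisecond timestamps) with a JSON sidecar holding session, role,
annotator and scheme; transcripts are JSON lists of diarized segments
with per-model sentiment scores; configuration is YAML/JSON. See
`docs/methods.md` for the full field tables and every modeling decision.
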