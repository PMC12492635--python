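"""Bin per-model streams onto a common grid and fuse them across models.

The substrate of (a)synchrony classification is the *interval frame*: a
table with one row per fixed-length interval (index ``i`` covers
``[i*L, (i+1)*L)`` with ``L = interval_length``, default 1 s) of the
session timeline, restricted to intervals overlapped by speech of the
target role.  Each recognizer stream contributes a column; fusion then
combines the three models per modality into a single fused value and class
per interval:

* sentiment — mean of the per-model scores, thresholded at +/- the
  sentiment threshold into {negative, neutral, positive} (a "vote" mode
  that classifies each model first and majority-votes is available);
* categorical emotion — majority vote over the per-model labels, then
  mapped to a polarity {positive, negative, neutral};
* valence — mean of the per-model values, split at the midpoint into
  {low, high} (again with an optional "vote" mode).

Within a bin, a discrete stream is aggregated by duration-weighted mode
(the dominant label by time) and a continuous stream by time-weighted
mean, so irregular segment boundaries and dense fixed-rate samples are
handled identically.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .core_model import AnnotationTier, SchemeKind, TranscriptSegment
from .io_formats import PipelineConfig

__all__ = [
    "UNCLASSIFIED",
    "bin_stream",
    "majority_vote",
    "sentiment_class_of",
    "valence_class_of",
    "build_interval_frame",
    "fuse_intervals",
]

#: Sentinel returned by :func:`majority_vote` for a tie with no neutral
#: candidate; downstream classification treats it as an undecided channel.
UNCLASSIFIED = "unclassified"


def _bin_range(start: float, end: float, length: float) -> range:
    first = math.floor(start / length)
    last = math.ceil(end / length)
    return range(first, last)


def _overlap(a0: float, a1: float, b0: float, b1: float) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


def bin_stream(
    tier: AnnotationTier, interval_length: float
) -> dict[int, Union[str, float]]:
    """Aggregate one tier onto the interval grid.

    Returns ``{interval_index: value}``; bins with no overlapping segment
    are absent.  Discrete tiers aggregate by duration-weighted mode (ties
    broken toward the lexicographically smallest label, so binning is
    deterministic and order-independent); continuous tiers by time-weighted
    mean over the covered part of the bin.
    """
    if not interval_length > 0:
        raise ValueError("interval_length must be > 0")
    if tier.scheme.kind is SchemeKind.FREE:
        raise ValueError("free-text tiers cannot be binned")
    L = interval_length
    if tier.scheme.kind is SchemeKind.DISCRETE:
        weights: dict[int, Counter] = defaultdict(Counter)
        for seg in tier.segments:
            for i in _bin_range(seg.start, seg.end, L):
                dt = _overlap(seg.start, seg.end, i * L, (i + 1) * L)
                if dt > 0:
                    weights[i][str(seg.payload)] += dt
        out: dict[int, Union[str, float]] = {}
        for i, counts in weights.items():
            out[i] = min(counts, key=lambda lab: (-counts[lab], lab))
        return out
    # continuous: time-weighted mean
    num: dict[int, float] = defaultdict(float)
    den: dict[int, float] = defaultdict(float)
    for seg in tier.segments:
        for i in _bin_range(seg.start, seg.end, L):
            dt = _overlap(seg.start, seg.end, i * L, (i + 1) * L)
            if dt > 0:
                num[i] += float(seg.payload) * dt
                den[i] += dt
    return {i: num[i] / den[i] for i in den}


def majority_vote(
    votes: Sequence[str], neutral_label: str = "neutral"
) -> str:
    """Return the strictly most frequent label.

    Ties resolve to ``neutral_label`` if it is among the tied labels,
    otherwise to the :data:`UNCLASSIFIED` sentinel — a tie never
    manufactures a decided class.
    """
    if not votes:
        raise ValueError("majority_vote needs at least one vote")
    counts = Counter(votes)
    top = max(counts.values())
    tied = sorted(lab for lab, c in counts.items() if c == top)
    if len(tied) == 1:
        return tied[0]
    if neutral_label in tied:
        return neutral_label
    return UNCLASSIFIED


def sentiment_class_of(score: float, threshold: float) -> str:
    """Map a sentiment score to {negative, neutral, positive} at +/-threshold."""
    if score > threshold:
        return "positive"
    if score < -threshold:
        return "negative"
    return "neutral"


def valence_class_of(valence: float, midpoint: float) -> str:
    """Split valence at the midpoint: high iff strictly above it."""
    return "high" if valence > midpoint else "low"


def build_interval_frame(
    transcript: Sequence[TranscriptSegment],
    role: str,
    emotion_tiers: Sequence[AnnotationTier],
    valence_tiers: Sequence[AnnotationTier],
    interval_length: float = 1.0,
) -> pd.DataFrame:
    """Assemble the per-interval model table for one role.

    Rows are interval indices overlapped by at least one speech segment of
    ``role``.  Columns: ``sentiment:<model>`` (the duration-weighted mean
    of the per-segment scores of the speech overlapping the interval),
    ``emotion:<model>`` and ``valence:<model>`` from binning each stream
    tier, plus ``speech_time`` (seconds of the interval covered by the
    role's speech, used by scene building).
    """
    L = interval_length
    speech = [s for s in transcript if s.speaker == role]
    sent_num: dict[int, dict[str, float]] = defaultdict(lambda: defaultdict(float))
    sent_den: dict[int, float] = defaultdict(float)
    speech_time: dict[int, float] = defaultdict(float)
    for seg in speech:
        for i in _bin_range(seg.start, seg.end, L):
            dt = _overlap(seg.start, seg.end, i * L, (i + 1) * L)
            if dt <= 0:
                continue
            speech_time[i] += dt
            sent_den[i] += dt
            for model, score in seg.sentiment_scores.items():
                sent_num[i][model] += score * dt
    if not speech_time:
        return pd.DataFrame()

    index = sorted(speech_time)
    frame = pd.DataFrame(index=pd.Index(index, name="interval_index"))
    frame["speech_time"] = [speech_time[i] for i in index]
    models = sorted({m for seg in speech for m in seg.sentiment_scores})
    for model in models:
        frame[f"sentiment:{model}"] = [
            sent_num[i][model] / sent_den[i] if model in sent_num[i] else np.nan
            for i in index
        ]
    for tier in emotion_tiers:
        binned = bin_stream(tier, L)
        frame[f"emotion:{tier.annotator}"] = [binned.get(i) for i in index]
    for tier in valence_tiers:
        binned = bin_stream(tier, L)
        frame[f"valence:{tier.annotator}"] = [binned.get(i, np.nan) for i in index]
    return frame


def _modality_columns(frame: pd.DataFrame, modality: str) -> list[str]:
    return [c for c in frame.columns if c.startswith(modality + ":")]


def fuse_intervals(frame: pd.DataFrame, cfg: PipelineConfig) -> pd.DataFrame:
    """Fill the fused columns of an interval frame.

    Adds ``sentiment``, ``sentiment_class``, ``emotion``,
    ``emotion_polarity``, ``valence`` and ``valence_class``.  Fusion is
    invariant to model order (means and votes are symmetric).  Raises if an
    interval lacks all model values for some modality, or if a fused
    emotion label is absent from the polarity map.
    """
    if frame.empty:
        out = frame.copy()
        for col in ("sentiment", "sentiment_class", "emotion",
                    "emotion_polarity", "valence", "valence_class"):
            out[col] = pd.Series(dtype=object)
        return out

    out = frame.copy()
    sent_cols = _modality_columns(frame, "sentiment")
    emo_cols = _modality_columns(frame, "emotion")
    val_cols = _modality_columns(frame, "valence")
    for name, cols in (("sentiment", sent_cols), ("emotion", emo_cols),
                       ("valence", val_cols)):
        if not cols:
            raise ValueError(f"no {name} model columns present")

    sent_scores, sent_classes = [], []
    emotions, polarities = [], []
    valences, val_classes = [], []
    for idx, row in frame.iterrows():
        s_vals = [row[c] for c in sent_cols if pd.notna(row[c])]
        e_vals = [row[c] for c in emo_cols if row[c] is not None and pd.notna(row[c])]
        v_vals = [row[c] for c in val_cols if pd.notna(row[c])]
        for name, vals in (("sentiment", s_vals), ("emotion", e_vals),
                           ("valence", v_vals)):
            if not vals:
                raise ValueError(f"interval {idx}: no {name} model value present")

        s_mean = float(np.mean(s_vals))
        if cfg.sentiment_fusion == "mean":
            s_class = sentiment_class_of(s_mean, cfg.sentiment_threshold)
        else:
            s_class = majority_vote(
                [sentiment_class_of(v, cfg.sentiment_threshold) for v in s_vals]
            )
            if s_class == UNCLASSIFIED:
                s_class = "neutral"
        sent_scores.append(s_mean)
        sent_classes.append(s_class)

        emo = majority_vote([str(v) for v in e_vals])
        if emo == UNCLASSIFIED:
            pol = "neutral"  # tied vote with no neutral label: undecided channel
        else:
            if emo not in cfg.emotion_polarity:
                raise ValueError(f"emotion label {emo!r} absent from polarity map")
            pol = cfg.emotion_polarity[emo]
        emotions.append(emo)
        polarities.append(pol)

        v_mean = float(np.mean(v_vals))
        if cfg.valence_fusion == "mean":
            v_class = valence_class_of(v_mean, cfg.valence_midpoint)
        else:
            v_class = majority_vote(
                [valence_class_of(v, cfg.valence_midpoint) for v in v_vals],
                neutral_label="__none__",
            )
            if v_class == UNCLASSIFIED:  # even split only possible for even k
                v_class = "low"
        valences.append(v_mean)
        val_classes.append(v_class)

    out["sentiment"] = sent_scores
    out["sentiment_class"] = sent_classes
    out["emotion"] = emotions
    out["emotion_polarity"] = polarities
    out["valence"] = valences
    out["valence_class"] = val_classes
    return out
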