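"""Per-interval affective (a)synchrony classification and scene selection.

*Affective asynchrony* is a mismatch between what a speaker says and what
their face and voice show: verbal sentiment clearly positive while the
concurrent categorical emotion is negative and/or valence is low (or the
mirror image for clearly negative sentiment).  *Affective synchrony* is
their agreement.  Segments with sentiment inside the +/-0.5 neutral band
are left unclassified — no claim is made either way.

Classification runs per one-second interval on the fused frame and reports
which *channel* carries the decision:

* ``emotion`` — the categorical-emotion polarity decided alone;
* ``valence`` — the valence class decided alone;
* ``both``    — both channels decided, identically.  Only these intervals
  feed scene selection;
* a conflict (one channel says synchrony, the other asynchrony) is
  recorded as two single-channel labels and never counts as ``both``.

Scenes are speech segments at least ``min_scene_duration`` (default 5 s)
long whose ``both``-classified time with the segment's modal decision
covers at least ``min_both_coverage`` (default 70%) of their duration.
From the surviving candidates, ``n_select_per_class`` (default 3) scenes
per decision class are drawn uniformly at random with a fixed seed and
presented in randomized order.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core_model import (
    AnnotationTier,
    AnnotatorKind,
    Scheme,
    SchemeKind,
    Segment,
    TranscriptSegment,
)
from .io_formats import PipelineConfig

__all__ = [
    "Decision",
    "Channel",
    "CongruenceLabel",
    "Scene",
    "SceneSelection",
    "classify",
    "classify_frame",
    "build_scenes",
    "select_scenes",
    "scenes_to_tier",
]


class Decision(str, enum.Enum):
    SYNCHRONY = "synchrony"
    ASYNCHRONY = "asynchrony"
    UNCLASSIFIED = "unclassified"


class Channel(str, enum.Enum):
    EMOTION = "emotion"
    VALENCE = "valence"
    BOTH = "both"
    NONE = "none"
    #: The two channels decided opposite ways; reported as two
    #: single-channel labels, never as ``both``.
    CONFLICT = "conflict"


@dataclass(frozen=True)
class CongruenceLabel:
    """The (a)synchrony verdict for one interval.

    ``emotion_decision`` / ``valence_decision`` hold the per-channel
    verdicts (``None`` = channel undecided, e.g. neutral emotion polarity).
    ``channel`` summarizes which channel(s) carry the verdict and
    ``decision`` the verdict itself; on a conflict ``decision`` is
    ``UNCLASSIFIED`` at the summary level and the two single-channel
    verdicts are exposed via :meth:`single_labels`.
    """

    interval_index: int
    emotion_decision: Optional[Decision]
    valence_decision: Optional[Decision]

    @property
    def channel(self) -> Channel:
        e, v = self.emotion_decision, self.valence_decision
        if e is None and v is None:
            return Channel.NONE
        if e is not None and v is not None:
            return Channel.BOTH if e == v else Channel.CONFLICT
        return Channel.EMOTION if e is not None else Channel.VALENCE

    @property
    def decision(self) -> Decision:
        ch = self.channel
        if ch is Channel.NONE or ch is Channel.CONFLICT:
            return Decision.UNCLASSIFIED
        if ch is Channel.EMOTION:
            return self.emotion_decision  # type: ignore[return-value]
        if ch is Channel.VALENCE:
            return self.valence_decision  # type: ignore[return-value]
        return self.emotion_decision  # type: ignore[return-value]

    def single_labels(self) -> list[tuple[Channel, Decision]]:
        """All decided channels as (channel, decision) pairs."""
        out = []
        if self.emotion_decision is not None:
            out.append((Channel.EMOTION, self.emotion_decision))
        if self.valence_decision is not None:
            out.append((Channel.VALENCE, self.valence_decision))
        return out


def classify(
    sentiment_class: str,
    emotion_polarity: str,
    valence_class: str,
    interval_index: int = 0,
) -> CongruenceLabel:
    """Classify one interval from its three fused classes.

    Neutral sentiment leaves both channels undecided.  Otherwise the
    emotion channel is asynchronous iff its polarity opposes the sentiment
    class, synchronous iff it matches, undecided if the polarity is
    neutral; the valence channel is asynchronous iff its class opposes the
    sentiment class (positive sentiment with low valence, negative with
    high), synchronous otherwise.  The rule is symmetric: negating the
    sentiment class while swapping emotion polarity and valence class maps
    labels onto themselves.
    """
    if sentiment_class == "neutral":
        return CongruenceLabel(interval_index, None, None)
    if sentiment_class not in ("positive", "negative"):
        raise ValueError(f"bad sentiment class {sentiment_class!r}")

    if emotion_polarity == "neutral":
        emo: Optional[Decision] = None
    elif emotion_polarity in ("positive", "negative"):
        emo = (
            Decision.SYNCHRONY
            if emotion_polarity == sentiment_class
            else Decision.ASYNCHRONY
        )
    else:
        raise ValueError(f"bad emotion polarity {emotion_polarity!r}")

    if valence_class not in ("low", "high"):
        raise ValueError(f"bad valence class {valence_class!r}")
    valence_matches = (valence_class == "high") == (sentiment_class == "positive")
    val = Decision.SYNCHRONY if valence_matches else Decision.ASYNCHRONY
    return CongruenceLabel(interval_index, emo, val)


def classify_frame(fused: pd.DataFrame) -> dict[int, CongruenceLabel]:
    """Classify every interval of a fused frame; keys are interval indices."""
    out: dict[int, CongruenceLabel] = {}
    for idx, row in fused.iterrows():
        out[int(idx)] = classify(
            row["sentiment_class"],
            row["emotion_polarity"],
            row["valence_class"],
            interval_index=int(idx),
        )
    return out


@dataclass(frozen=True)
class Scene:
    """A speech segment that survived the duration and coverage filters."""

    session: str
    role: str
    start: float
    end: float
    decision: Decision
    both_coverage: float
    source_index: int
    text: str = ""

    @property
    def duration(self) -> float:
        return self.end - self.start

    def to_dict(self) -> dict:
        return {
            "session": self.session,
            "role": self.role,
            "start": round(self.start, 3),
            "end": round(self.end, 3),
            "duration": round(self.duration, 3),
            "decision": self.decision.value,
            "both_coverage": round(self.both_coverage, 6),
            "source_index": self.source_index,
            "text": self.text,
        }


def build_scenes(
    labels: Mapping[int, CongruenceLabel],
    transcript: Sequence[TranscriptSegment],
    cfg: PipelineConfig,
    role: str,
    session: str = "",
) -> list[Scene]:
    """Assemble candidate scenes, one per speech segment, and filter them.

    For each speech segment of ``role``: the time its intervals spend in
    channel ``both`` is tallied per decision; the modal decision ``d``
    wins, a tie drops the segment (an ambiguous scene must not enter a
    rating study).  ``both_coverage`` is (time in both-intervals with
    decision ``d``) / segment duration — unclassified time counts against
    coverage (with ``coverage_denominator: classified`` only
    non-neutral-sentiment time forms the denominator).  A candidate is
    kept iff its duration >= ``min_scene_duration`` and its coverage >=
    ``min_both_coverage``.
    """
    L = cfg.interval_length
    scenes: list[Scene] = []
    for seg_idx, seg in enumerate(transcript):
        if seg.speaker != role:
            continue
        sync_t = 0.0
        async_t = 0.0
        classified_t = 0.0
        first = math.floor(seg.start / L)
        last = math.ceil(seg.end / L)
        for i in range(first, last):
            dt = max(0.0, min(seg.end, (i + 1) * L) - max(seg.start, i * L))
            if dt <= 0:
                continue
            label = labels.get(i)
            if label is None:
                continue
            if label.channel is not Channel.NONE:
                classified_t += dt
            if label.channel is Channel.BOTH:
                if label.decision is Decision.SYNCHRONY:
                    sync_t += dt
                else:
                    async_t += dt
        duration = seg.duration
        denom = duration if cfg.coverage_denominator == "full" else classified_t
        if sync_t == async_t:
            continue  # no both-time, or tied modal decision: ambiguous
        decision = Decision.SYNCHRONY if sync_t > async_t else Decision.ASYNCHRONY
        both_t = max(sync_t, async_t)
        coverage = both_t / denom if denom > 0 else 0.0
        if duration >= cfg.min_scene_duration and coverage >= cfg.min_both_coverage:
            scenes.append(
                Scene(
                    session=session,
                    role=role,
                    start=seg.start,
                    end=seg.end,
                    decision=decision,
                    both_coverage=coverage,
                    source_index=seg_idx,
                    text=seg.text,
                )
            )
    return scenes


@dataclass
class SceneSelection:
    """The drawn scenes plus per-class shortfall bookkeeping."""

    scenes: list[Scene]
    shortfall: dict[str, int] = field(default_factory=dict)

    @property
    def has_shortfall(self) -> bool:
        return any(v > 0 for v in self.shortfall.values())


def select_scenes(
    scenes: Sequence[Scene],
    cfg: PipelineConfig,
    seed: Optional[int] = None,
) -> SceneSelection:
    """Draw ``n_select_per_class`` scenes per decision class, seeded.

    Sampling is uniform without replacement from each class with a single
    generator consumed in documented order — asynchrony class first, then
    synchrony, then the presentation shuffle — so a fixed seed gives a
    bit-reproducible selection.  A class with fewer candidates returns all
    of them and records the shortfall.
    """
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    n = cfg.n_select_per_class
    picked: list[Scene] = []
    shortfall: dict[str, int] = {}
    for decision in (Decision.ASYNCHRONY, Decision.SYNCHRONY):
        pool = [s for s in scenes if s.decision is decision]
        pool.sort(key=lambda s: (s.start, s.source_index))  # stable draw basis
        if len(pool) <= n:
            chosen = pool
            shortfall[decision.value] = n - len(pool)
        else:
            idx = rng.choice(len(pool), size=n, replace=False)
            chosen = [pool[i] for i in sorted(idx)]
            shortfall[decision.value] = 0
        picked.extend(chosen)
    order = rng.permutation(len(picked))
    return SceneSelection(scenes=[picked[i] for i in order], shortfall=shortfall)


def scenes_to_tier(
    scenes: Sequence[Scene],
    session: str,
    role: str,
    annotator: str = "affsync-detect",
) -> AnnotationTier:
    """Write scenes as a discrete machine-annotated tier."""
    scheme = Scheme(
        name="affective_congruence",
        kind=SchemeKind.DISCRETE,
        labels=("synchrony", "asynchrony"),
    )
    segments = tuple(
        Segment(start=s.start, end=s.end, payload=s.decision.value)
        for s in sorted(scenes, key=lambda s: s.start)
    )
    return AnnotationTier(
        session=session,
        role=role,
        annotator=annotator,
        annotator_kind=AnnotatorKind.MACHINE,
        scheme=scheme,
        segments=segments,
    )


def selection_report(
    selection: SceneSelection,
    candidates: Sequence[Scene],
    labels: Mapping[int, CongruenceLabel],
) -> dict:
    """JSON-ready report: per-scene details plus interval channel tallies."""
    tally: dict[str, int] = {}
    for label in labels.values():
        key = f"{label.channel.value}:{label.decision.value}"
        tally[key] = tally.get(key, 0) + 1
    return {
        "n_intervals": len(labels),
        "channel_tally": dict(sorted(tally.items())),
        "n_candidates": len(candidates),
        "candidates_by_class": {
            d.value: sum(1 for s in candidates if s.decision is d)
            for d in (Decision.ASYNCHRONY, Decision.SYNCHRONY)
        },
        "n_selected": len(selection.scenes),
        "shortfall": selection.shortfall,
        "scenes": [s.to_dict() for s in selection.scenes],
    }
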