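"""Synthetic dyadic sessions with planted (a)synchrony and mirroring.

No recordings, audio, video or pretrained recognizers are consumed
anywhere in this package; this module emulates their *outputs* — a
diarized transcript with per-model sentiment scores, three categorical-
emotion streams, three continuous-valence streams and per-role binary
smile tiers — with controllable ground truth, so every downstream stage
is testable end to end.

A :class:`SessionPlan` plants scenes into chosen speech segments of the
target role: a planted *asynchronous* segment gets clearly positive
sentiment (all models) while its emotion labels are drawn from the
negative-polarity set and its valence sits below the midpoint on the
planted fraction of one-second intervals (mirrored for a negative
sentiment sign); a planted *synchronous* segment gets matching verbal and
non-verbal affect.  Planted segments are snapped to the integer grid so
the achieved both-coverage is exactly ``round(coverage * n) / n``.
Intervals not carrying the plant get a neutral-polarity emotion, so they
can never count as both-channel time.  Noise (per-model score jitter and
per-interval label flips) is applied *after* planting; the ground truth
records which segments satisfy the duration and coverage filters
pre-noise.

Unplanted speech carries sentiment scores inside the neutral band, so a
noise-free session yields exactly the planted qualifying scenes and
nothing else — the generator's consistency gate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .agreement import RatingMatrix
from .core_model import (
    AnnotationTier,
    AnnotatorKind,
    Scheme,
    SchemeKind,
    Segment,
    TranscriptSegment,
)
from .io_formats import EMOTION_LABELS, PipelineConfig, write_tier, write_transcript

__all__ = [
    "PlantedScene",
    "SmileEvent",
    "SessionPlan",
    "SessionData",
    "generate_session",
    "write_session",
    "generate_rating_matrix",
]

SENTIMENT_MODELS = ("sent-a", "sent-b", "sent-c")
EMOTION_MODELS = ("emo-a", "emo-b", "emo-c")
VALENCE_MODELS = ("val-a", "val-b", "val-c")

_NEGATIVE_EMOTIONS = ("sadness", "anger", "fear", "disgust", "contempt")


class PlantedScene(BaseModel):
    model_config = ConfigDict(frozen=True)

    segment_index: int = Field(ge=0)  # index among the target role's segments
    decision: str  # "synchrony" | "asynchrony"
    coverage: float = Field(default=1.0, ge=0.0, le=1.0)
    duration: float = Field(default=8.0, gt=0.0)  # snapped to whole seconds
    sentiment_sign: Optional[int] = None  # +1 / -1; None draws at random

    @model_validator(mode="after")
    def _check(self) -> "PlantedScene":
        if self.decision not in ("synchrony", "asynchrony"):
            raise ValueError("decision must be synchrony or asynchrony")
        if self.sentiment_sign not in (None, 1, -1):
            raise ValueError("sentiment_sign must be +1, -1 or None")
        return self


class SmileEvent(BaseModel):
    model_config = ConfigDict(frozen=True)

    role: str
    onset: float = Field(ge=0.0)
    duration: float = Field(gt=0.0)
    mirrored: bool = False  # partner smiles back at lag ~ U(0, smile_max_lag)


class SessionPlan(BaseModel):
    """Everything that determines one synthetic session."""

    model_config = ConfigDict(extra="forbid")

    session: str = "synthetic"
    target_role: str = "patient"
    other_role: str = "therapist"
    n_segments: int = Field(default=12, ge=1)  # per role
    #: Speech-segment durations ~ lognormal(mu, sigma) seconds; the default
    #: (median ~4.5 s) straddles the 5 s scene filter so both filter
    #: branches are exercised.
    duration_lognorm_mu: float = 1.5
    duration_lognorm_sigma: float = Field(default=0.6, ge=0.0)
    gap_mean: float = Field(default=1.0, gt=0.0)
    planted_scenes: tuple[PlantedScene, ...] = ()
    #: Gaussian jitter sd added per model to sentiment scores and valence.
    score_jitter_sd: float = Field(default=0.0, ge=0.0)
    #: Per model, per one-second interval: probability that the emotion
    #: label is replaced by a different random label and that the valence
    #: value is reflected across the midpoint (a class flip).
    label_flip_prob: float = Field(default=0.0, ge=0.0, lt=1.0)
    smile_events: tuple[SmileEvent, ...] = ()
    n_smile_events: int = Field(default=4, ge=0)  # auto-generated extras
    smile_mirror_prob: float = Field(default=0.6, ge=0.0, le=1.0)
    smile_max_lag: float = Field(default=3.0, gt=0.0)
    rng_seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SessionPlan":
        if self.target_role == self.other_role:
            raise ValueError("target_role and other_role must differ")
        seen = set()
        for p in self.planted_scenes:
            if p.segment_index >= self.n_segments:
                raise ValueError(
                    f"planted segment_index {p.segment_index} >= n_segments"
                )
            if p.segment_index in seen:
                raise ValueError(f"duplicate planted segment_index {p.segment_index}")
            seen.add(p.segment_index)
        return self


@dataclass
class SessionData:
    session: str
    target_role: str
    other_role: str
    transcript: list[TranscriptSegment]
    emotion_tiers: list[AnnotationTier]
    valence_tiers: list[AnnotationTier]
    smile_tiers: dict[str, AnnotationTier]
    ground_truth: list[dict] = dc_field(default_factory=list)


def _planted_signal(decision: str, sign: int, rng: np.random.Generator) -> tuple[str, float]:
    """Base (emotion label, valence) carried by a planted both-interval."""
    nonverbal_positive = (decision == "synchrony") == (sign > 0)
    if nonverbal_positive:
        return "happiness", 0.85
    return str(rng.choice(_NEGATIVE_EMOTIONS)), 0.15


def generate_session(
    plan: SessionPlan, cfg: Optional[PipelineConfig] = None
) -> SessionData:
    """Generate one session; ``cfg`` supplies the filter thresholds that
    the ground truth is evaluated against (protocol defaults if omitted).
    """
    cfg = cfg or PipelineConfig()
    rng = np.random.default_rng(plan.rng_seed)
    planted_by_index = {p.segment_index: p for p in plan.planted_scenes}

    transcript: list[TranscriptSegment] = []
    ground_truth: list[dict] = []
    # base (label, valence) per one-second interval; filled while planting
    interval_signal: dict[int, tuple[str, float]] = {}

    t = rng.uniform(0.5, 2.0)
    for k in range(plan.n_segments):
        for role in (plan.target_role, plan.other_role):
            is_target = role == plan.target_role
            plant = planted_by_index.get(k) if is_target else None
            if plant is not None:
                start = float(np.ceil(t))
                n_sec = max(1, int(round(plant.duration)))
                end = start + n_sec
                sign = plant.sentiment_sign or int(rng.choice([1, -1]))
                base_scores = {
                    m: float(np.clip(sign * 0.8 + rng.normal(0, plan.score_jitter_sd), -1, 1))
                    for m in SENTIMENT_MODELS
                }
                k_both = int(round(plant.coverage * n_sec))
                label, valence = _planted_signal(plant.decision, sign, rng)
                c = int(start)
                for i in range(c, c + n_sec):
                    if i < c + k_both:
                        interval_signal[i] = (label, valence)
                    else:
                        # neutral-polarity filler: can never be both-channel
                        interval_signal[i] = ("surprise", 0.5)
                achieved = k_both / n_sec
                ground_truth.append(
                    {
                        "segment_index": k,
                        "transcript_index": len(transcript),
                        "start": start,
                        "end": end,
                        "decision": plant.decision,
                        "sentiment_sign": sign,
                        "coverage": achieved,
                        "qualifies": (
                            n_sec >= cfg.min_scene_duration
                            and achieved >= cfg.min_both_coverage
                        ),
                    }
                )
            else:
                start = t
                dur = float(
                    rng.lognormal(plan.duration_lognorm_mu, plan.duration_lognorm_sigma)
                )
                end = start + max(0.5, dur)
                base_scores = {
                    m: float(
                        np.clip(
                            rng.uniform(-0.3, 0.3) + rng.normal(0, plan.score_jitter_sd),
                            -1,
                            1,
                        )
                    )
                    for m in SENTIMENT_MODELS
                }
            transcript.append(
                TranscriptSegment(
                    speaker=role,
                    start=round(start, 3),
                    end=round(end, 3),
                    text=f"{role} utterance {k}",
                    sentiment_scores={m: round(s, 6) for m, s in base_scores.items()},
                )
            )
            t = end + rng.uniform(0.2, 1.5 * plan.gap_mean)

    total_end = int(np.ceil(max(s.end for s in transcript))) + 1

    emotion_scheme = Scheme(
        name="emotion", kind=SchemeKind.DISCRETE, labels=EMOTION_LABELS
    )
    valence_scheme = Scheme(
        name="valence", kind=SchemeKind.CONTINUOUS, value_range=(0.0, 1.0)
    )
    # base stream shared across models, noise independent per model
    base_stream: list[tuple[str, float]] = []
    for i in range(total_end):
        if i in interval_signal:
            base_stream.append(interval_signal[i])
        else:
            base_stream.append(
                (str(rng.choice(EMOTION_LABELS)), float(rng.uniform(0, 1)))
            )

    emotion_tiers, valence_tiers = [], []
    for m in EMOTION_MODELS:
        segs = []
        for i, (label, _) in enumerate(base_stream):
            if plan.label_flip_prob > 0 and rng.random() < plan.label_flip_prob:
                others = [lab for lab in EMOTION_LABELS if lab != label]
                label = str(rng.choice(others))
            segs.append(Segment(start=float(i), end=float(i + 1), payload=label))
        emotion_tiers.append(
            AnnotationTier(
                session=plan.session,
                role=plan.target_role,
                annotator=m,
                annotator_kind=AnnotatorKind.MACHINE,
                scheme=emotion_scheme,
                segments=tuple(segs),
            )
        )
    for m in VALENCE_MODELS:
        segs = []
        for i, (_, val) in enumerate(base_stream):
            v = val
            if plan.label_flip_prob > 0 and rng.random() < plan.label_flip_prob:
                v = 1.0 - v  # reflect across the midpoint: a class flip
            v = float(np.clip(v + rng.normal(0, plan.score_jitter_sd), 0, 1))
            segs.append(Segment(start=float(i), end=float(i + 1), payload=round(v, 6)))
        valence_tiers.append(
            AnnotationTier(
                session=plan.session,
                role=plan.target_role,
                annotator=m,
                annotator_kind=AnnotatorKind.MACHINE,
                scheme=valence_scheme,
                segments=tuple(segs),
            )
        )

    smile_tiers = _build_smile_tiers(plan, rng, total_end)
    return SessionData(
        session=plan.session,
        target_role=plan.target_role,
        other_role=plan.other_role,
        transcript=transcript,
        emotion_tiers=emotion_tiers,
        valence_tiers=valence_tiers,
        smile_tiers=smile_tiers,
        ground_truth=ground_truth,
    )


def _build_smile_tiers(
    plan: SessionPlan, rng: np.random.Generator, total_end: int
) -> dict[str, AnnotationTier]:
    roles = (plan.target_role, plan.other_role)
    events: list[SmileEvent] = list(plan.smile_events)
    for j in range(plan.n_smile_events):
        events.append(
            SmileEvent(
                role=roles[j % 2],
                onset=float(rng.uniform(0, max(1.0, total_end - 5))),
                duration=float(rng.uniform(1.0, 3.0)),
                mirrored=bool(rng.random() < plan.smile_mirror_prob),
            )
        )
    intervals: dict[str, list[tuple[float, float]]] = {r: [] for r in roles}
    for ev in events:
        if ev.role not in intervals:
            raise ValueError(f"smile event role {ev.role!r} unknown")
        intervals[ev.role].append((ev.onset, ev.onset + ev.duration))
        if ev.mirrored:
            partner = roles[1] if ev.role == roles[0] else roles[0]
            lag = float(rng.uniform(0, plan.smile_max_lag))
            dur = ev.duration * float(rng.uniform(0.8, 1.2))
            intervals[partner].append((ev.onset + lag, ev.onset + lag + dur))

    scheme = Scheme(name="smile", kind=SchemeKind.DISCRETE, labels=("smile",))
    tiers = {}
    for role in roles:
        merged: list[tuple[float, float]] = []
        for s, e in sorted(intervals[role]):
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        tiers[role] = AnnotationTier(
            session=plan.session,
            role=role,
            annotator="smile-detector",
            annotator_kind=AnnotatorKind.MACHINE,
            scheme=scheme,
            segments=tuple(
                Segment(start=round(s, 3), end=round(e, 3), payload="smile")
                for s, e in merged
            ),
        )
    return tiers


def write_session(data: SessionData, out_dir: Union[str, Path]) -> None:
    """Write a full session directory: transcript, 6 stream tiers, 2 smile
    tiers and the ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_transcript(data.transcript, out / "transcript.json")
    for tier in data.emotion_tiers:
        write_tier(tier, out / f"emotion_{tier.annotator}.csv")
    for tier in data.valence_tiers:
        write_tier(tier, out / f"valence_{tier.annotator}.csv")
    for role, tier in data.smile_tiers.items():
        write_tier(tier, out / f"smile_{role}.csv")
    meta = {
        "session": data.session,
        "target_role": data.target_role,
        "other_role": data.other_role,
        "ground_truth": data.ground_truth,
    }
    (out / "ground_truth.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def generate_rating_matrix(
    n_items: int,
    n_raters: int,
    true_scores: Optional[Sequence[float]] = None,
    rater_noise_sd: float = 0.5,
    rng_seed: int = 0,
) -> RatingMatrix:
    """Numeric rating matrix: each rater = true score + Gaussian noise.

    As ``rater_noise_sd`` tends to 0 Cronbach's alpha tends to 1; as it
    dominates the spread of the true scores, alpha tends to 0.
    """
    if n_items < 2:
        raise ValueError("n_items must be >= 2")
    if n_raters < 2:
        raise ValueError("n_raters must be >= 2")
    rng = np.random.default_rng(rng_seed)
    truth = (
        np.asarray(true_scores, dtype=float)
        if true_scores is not None
        else rng.normal(0, 1, size=n_items)
    )
    if truth.shape != (n_items,):
        raise ValueError("true_scores length must equal n_items")
    values = truth[:, None] + rng.normal(0, rater_noise_sd, size=(n_items, n_raters))
    frame = pd.DataFrame(
        values,
        index=pd.RangeIndex(n_items, name="item"),
        columns=[f"rater{j}" for j in range(n_raters)],
    )
    return RatingMatrix(values=frame)
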