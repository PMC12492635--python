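"""Typed annotation data model shared by every pipeline stage.

The central object is the :class:`AnnotationTier`: a time-ordered track of
segments produced by one annotator (human or machine) for one role in one
recorded session, under one annotation :class:`Scheme`.  Three scheme kinds
exist:

* *discrete* — segments carry a label from a predefined, ordered label set
  (e.g. the eight categorical emotions of a facial-expression recognizer);
* *continuous* — segments carry a numeric value on a bounded scale
  (e.g. valence in [0, 1]); continuous tiers are frequently dense samples
  at a fixed rate, one short segment per sample;
* *free* — segments carry arbitrary text (e.g. a transcription).

All intervals are half-open ``[start, end)`` in seconds.  This convention
makes fixed-length binning an exact partition of the timeline: a boundary
instant belongs to exactly one bin and to exactly one adjacent segment.

Domain invariants (start < end, payload type, label membership, range,
intra-tier overlap) are deliberately *not* enforced at construction time.
Machine annotators and file readers produce imperfect data; callers inspect
it with :func:`validate_tier`, which reports violations as data instead of
raising, so a session with a few bad segments can still be triaged.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Union

from pydantic import BaseModel, ConfigDict, model_validator

__all__ = [
    "SchemeKind",
    "AnnotatorKind",
    "Scheme",
    "Segment",
    "AnnotationTier",
    "TranscriptSegment",
    "Violation",
    "validate_tier",
    "slice_tier",
]


class SchemeKind(str, enum.Enum):
    DISCRETE = "discrete"
    CONTINUOUS = "continuous"
    FREE = "free"


class AnnotatorKind(str, enum.Enum):
    HUMAN = "human"
    MACHINE = "machine"


class Scheme(BaseModel):
    """An annotation scheme: what segment payloads are permitted.

    Unlike segments, schemes are configuration: a malformed scheme is a
    programming/config error, so invariants are enforced at construction.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    kind: SchemeKind
    labels: tuple[str, ...] = ()
    value_range: Optional[tuple[float, float]] = None

    @model_validator(mode="after")
    def _check_kind_fields(self) -> "Scheme":
        if self.kind is SchemeKind.DISCRETE:
            if len(self.labels) < 1:
                raise ValueError("discrete scheme needs at least one label")
            if len(set(self.labels)) != len(self.labels):
                raise ValueError("duplicate labels in discrete scheme")
            if self.value_range is not None:
                raise ValueError("discrete scheme must not carry a value_range")
        elif self.kind is SchemeKind.CONTINUOUS:
            if self.labels:
                raise ValueError("continuous scheme must not carry labels")
            if self.value_range is None:
                raise ValueError("continuous scheme needs a value_range")
            lo, hi = self.value_range
            if not lo < hi:
                raise ValueError(f"value_range must satisfy lo < hi, got [{lo}, {hi}]")
        else:  # FREE
            if self.labels or self.value_range is not None:
                raise ValueError("free scheme carries neither labels nor value_range")
        return self


Payload = Union[str, float]


class Segment(BaseModel):
    """One time-anchored annotation: ``[start, end)`` plus a payload.

    The payload is a label (discrete scheme), a numeric value (continuous)
    or text (free).  ``confidence`` is an optional fraction attached by
    machine annotators; it is stored for round-tripping but ignored by all
    downstream computation.
    """

    model_config = ConfigDict(frozen=True)

    start: float
    end: float
    payload: Payload
    confidence: Optional[float] = None

    @property
    def duration(self) -> float:
        return self.end - self.start


class AnnotationTier(BaseModel):
    session: str
    role: str
    annotator: str
    annotator_kind: AnnotatorKind = AnnotatorKind.MACHINE
    scheme: Scheme
    segments: tuple[Segment, ...] = ()

    model_config = ConfigDict(frozen=True)

    @property
    def end_time(self) -> float:
        """Largest segment end, 0.0 for an empty tier."""
        return max((s.end for s in self.segments), default=0.0)

    def with_segments(self, segments: Iterable[Segment]) -> "AnnotationTier":
        return self.model_copy(update={"segments": tuple(segments)})


class TranscriptSegment(BaseModel):
    """A diarized speech segment with per-model sentiment scores.

    ``sentiment_scores`` maps a sentiment-model name to a score in
    [-1, +1]: negative (-1) over neutral (0) to positive (+1).
    Transcripts come from upstream diarization + sentiment models and are
    expected well-formed, so invariants are enforced at construction.
    """

    model_config = ConfigDict(frozen=True)

    speaker: str
    start: float
    end: float
    text: str = ""
    sentiment_scores: dict[str, float] = {}

    @model_validator(mode="after")
    def _check(self) -> "TranscriptSegment":
        if not self.start < self.end:
            raise ValueError(f"start < end required, got [{self.start}, {self.end})")
        for model, score in self.sentiment_scores.items():
            if not -1.0 <= score <= 1.0:
                raise ValueError(
                    f"sentiment score for {model!r} out of [-1, 1]: {score}"
                )
        return self

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class Violation:
    """A broken tier invariant, reported as data.

    ``segment_index`` is the index of the offending segment, or ``None``
    for tier-level violations (ordering, overlap is attributed to the
    later segment).
    """

    segment_index: Optional[int]
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        where = "tier" if self.segment_index is None else f"segment {self.segment_index}"
        return f"{where}: {self.rule}: {self.message}"


def _payload_violations(seg: Segment, index: int, scheme: Scheme) -> list[Violation]:
    out: list[Violation] = []
    kind = scheme.kind
    if kind is SchemeKind.DISCRETE:
        if not isinstance(seg.payload, str):
            out.append(Violation(index, "payload type",
                                 f"discrete payload must be a label, got {type(seg.payload).__name__}"))
        elif seg.payload not in scheme.labels:
            out.append(Violation(index, "label membership",
                                 f"label {seg.payload!r} not in scheme {scheme.name!r}"))
    elif kind is SchemeKind.CONTINUOUS:
        if isinstance(seg.payload, bool) or not isinstance(seg.payload, (int, float)):
            out.append(Violation(index, "payload type",
                                 f"continuous payload must be numeric, got {type(seg.payload).__name__}"))
        else:
            val = float(seg.payload)
            lo, hi = scheme.value_range  # type: ignore[misc]
            if math.isnan(val):
                out.append(Violation(index, "value out of range", "value is NaN"))
            elif not lo <= val <= hi:
                out.append(Violation(index, "value out of range",
                                     f"value {val} outside [{lo}, {hi}]"))
    else:  # FREE
        if not isinstance(seg.payload, str):
            out.append(Violation(index, "payload type",
                                 f"free payload must be text, got {type(seg.payload).__name__}"))
    return out


def validate_tier(tier: AnnotationTier) -> list[Violation]:
    """Check every tier invariant; return a (possibly empty) violation list.

    Total: never raises on well-typed input.  Checked rules, per segment:
    ``start >= 0``, ``start < end``, payload matches the scheme kind
    (label membership for discrete, range for continuous), confidence in
    [0, 1] when present.  Tier level: segments sorted by start; segments
    of discrete and free tiers must not overlap (continuous tiers may be
    dense back-to-back samples, which under half-open intervals do not
    overlap anyway, so the same check applies harmlessly only to
    discrete/free).
    """
    violations: list[Violation] = []
    segs = tier.segments
    for i, seg in enumerate(segs):
        if seg.start < 0:
            violations.append(Violation(i, "start >= 0", f"start {seg.start} < 0"))
        if not seg.start < seg.end:
            violations.append(Violation(i, "start < end",
                                        f"[{seg.start}, {seg.end}) is empty or inverted"))
        violations.extend(_payload_violations(seg, i, tier.scheme))
        if seg.confidence is not None and not 0.0 <= seg.confidence <= 1.0:
            violations.append(Violation(i, "confidence in [0,1]",
                                        f"confidence {seg.confidence}"))
    for i in range(1, len(segs)):
        if segs[i].start < segs[i - 1].start:
            violations.append(Violation(i, "sorted by start",
                                        f"start {segs[i].start} before previous {segs[i - 1].start}"))
    if tier.scheme.kind in (SchemeKind.DISCRETE, SchemeKind.FREE):
        # overlap check on the start-sorted order, attributed to the later segment
        ordered = sorted(range(len(segs)), key=lambda i: (segs[i].start, segs[i].end))
        for a, b in zip(ordered, ordered[1:]):
            if segs[b].start < segs[a].end:
                violations.append(Violation(b, "no intra-tier overlap",
                                            f"segment {b} overlaps segment {a}"))
    return violations


def slice_tier(tier: AnnotationTier, t0: float, t1: float) -> AnnotationTier:
    """Restrict a tier to the half-open window ``[t0, t1)``.

    Segments intersecting the window are clipped to it; payloads are
    unchanged.  A segment touching the window only at its boundary (e.g.
    ending exactly at ``t0``) is excluded, per the half-open convention.
    An empty result is valid.
    """
    if not t0 < t1:
        raise ValueError(f"window must satisfy t0 < t1, got [{t0}, {t1})")
    out = []
    for seg in tier.segments:
        lo = max(seg.start, t0)
        hi = min(seg.end, t1)
        if lo < hi:
            if lo == seg.start and hi == seg.end:
                out.append(seg)
            else:
                out.append(seg.model_copy(update={"start": lo, "end": hi}))
    return tier.with_segments(out)
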