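"""Flat-file dialects for tiers, transcripts and the pipeline config.

Tier files are semicolon-separated CSV (semicolons keep free-text payloads
with commas unescaped) with the header ``start;end;payload;confidence`` and
a JSON sidecar ``<stem>.json`` carrying session, role, annotator and the
scheme.  Timestamps are serialized with millisecond precision; upstream
recognizers run at >= 1 Hz so nothing finer is needed.  Transcripts are a
JSON list of diarized speech segments.  The config is YAML or JSON.

Reading surfaces invariant breaches immediately, naming the offending line,
so a corrupt stream never propagates silently into the pipeline.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .core_model import (
    AnnotationTier,
    AnnotatorKind,
    Scheme,
    SchemeKind,
    Segment,
    TranscriptSegment,
    validate_tier,
)

__all__ = [
    "PipelineConfig",
    "TierFormatError",
    "DEFAULT_EMOTION_POLARITY",
    "read_tier",
    "write_tier",
    "read_transcript",
    "write_transcript",
    "read_config",
]

#: Polarity of the eight categorical emotions emitted by facial/vocal
#: emotion recognizers.  Config-overridable; "neutral" polarity emotions
#: leave the emotion channel undecided during (a)synchrony classification.
DEFAULT_EMOTION_POLARITY: dict[str, str] = {
    "happiness": "positive",
    "sadness": "negative",
    "anger": "negative",
    "fear": "negative",
    "disgust": "negative",
    "contempt": "negative",
    "surprise": "neutral",
    "neutral": "neutral",
}

EMOTION_LABELS: tuple[str, ...] = tuple(DEFAULT_EMOTION_POLARITY)


class TierFormatError(ValueError):
    """A malformed tier/transcript/config file."""


class PipelineConfig(BaseModel):
    """All tunable parameters of the (a)synchrony detection pipeline.

    Defaults encode the study protocol: one-second binning, a sentiment
    class threshold of +/-0.5, a valence midpoint of 0.5, scenes kept when
    at least 5 s long and 'both'-classified for at least 70% of their
    duration, and a random draw of 3 scenes per decision class.
    """

    model_config = ConfigDict(extra="forbid")

    interval_length: float = 1.0
    sentiment_threshold: float = 0.5
    valence_midpoint: float = 0.5
    min_scene_duration: float = 5.0
    min_both_coverage: float = 0.70
    n_select_per_class: int = 3
    rng_seed: int = 0
    emotion_polarity: dict[str, str] = dict(DEFAULT_EMOTION_POLARITY)
    #: "mean": average model sentiment scores, then threshold (default);
    #: "vote": threshold each model's score, then majority-vote the classes.
    sentiment_fusion: str = "mean"
    #: "mean": average model valences, then split at the midpoint (default);
    #: "vote": split each model's valence, then majority-vote {low, high}.
    valence_fusion: str = "mean"
    #: Denominator of the both-coverage fraction: "full" uses the whole
    #: segment duration; "classified" uses only non-neutral-sentiment time.
    coverage_denominator: str = "full"

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        if not self.interval_length > 0:
            raise ValueError("interval_length must be > 0")
        if not 0 < self.sentiment_threshold <= 1:
            raise ValueError("sentiment_threshold must be in (0, 1]")
        if not 0 < self.min_both_coverage <= 1:
            raise ValueError("min_both_coverage must be in (0, 1]")
        if self.min_scene_duration < 0:
            raise ValueError("min_scene_duration must be >= 0")
        if self.n_select_per_class < 1:
            raise ValueError("n_select_per_class must be >= 1")
        for key, allowed in (
            ("sentiment_fusion", ("mean", "vote")),
            ("valence_fusion", ("mean", "vote")),
            ("coverage_denominator", ("full", "classified")),
        ):
            if getattr(self, key) not in allowed:
                raise ValueError(f"{key} must be one of {allowed}")
        for label, pol in self.emotion_polarity.items():
            if pol not in ("positive", "negative", "neutral"):
                raise ValueError(
                    f"emotion_polarity[{label!r}] must be positive/negative/neutral"
                )
        return self


# ---------------------------------------------------------------------------
# tier files

_HEADER = "start;end;payload;confidence"


def _fmt_time(t: float) -> str:
    return f"{t:.3f}"


def _fmt_payload(payload: Union[str, float], kind: SchemeKind) -> str:
    if kind is SchemeKind.CONTINUOUS:
        return repr(float(payload))
    text = str(payload)
    if ";" in text or "\n" in text:
        raise TierFormatError("payload must not contain ';' or newlines")
    return text


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_tier(tier: AnnotationTier, path: Union[str, Path]) -> None:
    """Write a tier as semicolon CSV plus a JSON sidecar.

    Timestamps are written with millisecond precision; continuous payloads
    with full float precision (``repr``), so write -> read round-trips
    payloads exactly and timestamps to 1 ms.
    """
    path = Path(path)
    kind = tier.scheme.kind
    lines = [_HEADER]
    for seg in tier.segments:
        conf = "" if seg.confidence is None else repr(float(seg.confidence))
        lines.append(
            f"{_fmt_time(seg.start)};{_fmt_time(seg.end)};"
            f"{_fmt_payload(seg.payload, kind)};{conf}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    sidecar = {
        "session": tier.session,
        "role": tier.role,
        "annotator": tier.annotator,
        "annotator_kind": tier.annotator_kind.value,
        "scheme": {
            "name": tier.scheme.name,
            "kind": kind.value,
            "labels": list(tier.scheme.labels),
            "value_range": list(tier.scheme.value_range)
            if tier.scheme.value_range is not None
            else None,
        },
    }
    _sidecar_path(path).write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def read_tier(path: Union[str, Path], strict: bool = True) -> AnnotationTier:
    """Read a tier CSV and its JSON sidecar.

    With ``strict`` (default) any invariant breach raises
    :class:`TierFormatError` naming the first offending CSV line; with
    ``strict=False`` the tier is returned as-is for triage via
    :func:`~affsync.core_model.validate_tier`.
    """
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not path.exists():
        raise TierFormatError(f"tier file not found: {path}")
    if not sidecar_path.exists():
        raise TierFormatError(f"sidecar not found: {sidecar_path}")
    try:
        meta = json.loads(sidecar_path.read_text(encoding="utf-8"))
        scheme = Scheme(
            name=meta["scheme"]["name"],
            kind=SchemeKind(meta["scheme"]["kind"]),
            labels=tuple(meta["scheme"].get("labels") or ()),
            value_range=tuple(meta["scheme"]["value_range"])
            if meta["scheme"].get("value_range") is not None
            else None,
        )
    except (KeyError, ValueError, ValidationError) as exc:
        raise TierFormatError(f"bad sidecar {sidecar_path}: {exc}") from exc

    segments: list[Segment] = []
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].strip() != _HEADER:
        raise TierFormatError(f"{path}: missing header {_HEADER!r}")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(";")
        if len(parts) != 4:
            raise TierFormatError(f"{path}: expected 4 fields, line {lineno}")
        try:
            start, end = float(parts[0]), float(parts[1])
            payload: Union[str, float]
            payload = float(parts[2]) if scheme.kind is SchemeKind.CONTINUOUS else parts[2]
            confidence = float(parts[3]) if parts[3] != "" else None
        except ValueError as exc:
            raise TierFormatError(f"{path}: unparsable field, line {lineno}: {exc}") from exc
        segments.append(Segment(start=start, end=end, payload=payload, confidence=confidence))

    tier = AnnotationTier(
        session=meta["session"],
        role=meta["role"],
        annotator=meta["annotator"],
        annotator_kind=AnnotatorKind(meta.get("annotator_kind", "machine")),
        scheme=scheme,
        segments=tuple(segments),
    )
    if strict:
        violations = validate_tier(tier)
        if violations:
            v = violations[0]
            line = "?" if v.segment_index is None else str(v.segment_index + 2)
            raise TierFormatError(f"{path}: {v.rule}, line {line} ({v.message})")
    return tier


# ---------------------------------------------------------------------------
# transcripts


def write_transcript(segments: list[TranscriptSegment], path: Union[str, Path]) -> None:
    payload = [seg.model_dump() for seg in segments]
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def read_transcript(path: Union[str, Path]) -> list[TranscriptSegment]:
    path = Path(path)
    if not path.exists():
        raise TierFormatError(f"transcript not found: {path}")
    try:
        raw = json.loads(path.read_text(encoding="utf-8"))
        return [TranscriptSegment(**item) for item in raw]
    except (TypeError, ValueError, ValidationError) as exc:
        raise TierFormatError(f"bad transcript {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# config


def read_config(path: Optional[Union[str, Path]] = None) -> PipelineConfig:
    """Load a YAML/JSON config; missing keys take protocol defaults.

    ``None`` or an empty file yields all defaults.  Unknown keys and
    out-of-range values raise :class:`TierFormatError` naming the key.
    """
    if path is None:
        return PipelineConfig()
    path = Path(path)
    if not path.exists():
        raise TierFormatError(f"config not found: {path}")
    raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise TierFormatError(f"config {path} must be a mapping")
    try:
        return PipelineConfig(**raw)
    except ValidationError as exc:
        first = exc.errors()[0]
        key = ".".join(str(p) for p in first["loc"]) or "<root>"
        raise TierFormatError(f"bad config {path}: {key}: {first['msg']}") from exc
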