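"""In-memory detection pipeline: fuse -> classify -> build scenes.

Thin glue over :mod:`fusion` and :mod:`synchrony` for callers that hold a
transcript and stream tiers in memory (the CLI adds file I/O and seeded
selection on top).
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .core_model import AnnotationTier, TranscriptSegment
from .fusion import build_interval_frame, fuse_intervals
from .io_formats import PipelineConfig
from .synchrony import CongruenceLabel, Scene, build_scenes, classify_frame

__all__ = ["detect_scenes", "classify_session"]


def classify_session(
    transcript: Sequence[TranscriptSegment],
    role: str,
    emotion_tiers: Sequence[AnnotationTier],
    valence_tiers: Sequence[AnnotationTier],
    cfg: PipelineConfig,
) -> Mapping[int, CongruenceLabel]:
    """Per-interval (a)synchrony labels for one role of a session."""
    frame = build_interval_frame(
        transcript, role, emotion_tiers, valence_tiers, cfg.interval_length
    )
    if frame.empty:
        return {}
    return classify_frame(fuse_intervals(frame, cfg))


def detect_scenes(session_data, cfg: PipelineConfig) -> list[Scene]:
    """Candidate scenes for a generated/loaded session bundle.

    ``session_data`` is any object with ``transcript``, ``target_role``,
    ``emotion_tiers``, ``valence_tiers`` and ``session`` attributes
    (e.g. :class:`affsync.synthgen.SessionData`).
    """
    labels = classify_session(
        session_data.transcript,
        session_data.target_role,
        session_data.emotion_tiers,
        session_data.valence_tiers,
        cfg,
    )
    return build_scenes(
        labels,
        session_data.transcript,
        cfg,
        session_data.target_role,
        session=session_data.session,
    )
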