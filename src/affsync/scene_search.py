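"""Sliding-window rule engine over annotation tiers.

A :class:`WindowRule` moves a fixed-length window in fixed steps over a
pair of tiers and evaluates a predicate on the segments clipped to each
window; positive windows are merged (closure under overlap/adjacency) into
maximal scene-level segments on a new machine-annotated tier.

The shipped predicate is *smile mirroring*: within a window, one
interlocutor's smile is answered by the other's — either a smile onset in
one tier is followed within ``max_lag`` seconds by a smile onset in the
other, or their smiles overlap by at least ``min_overlap`` of the shorter
smile.  The concrete defaults (window 4 s, step 1 s, max_lag 3 s,
min_overlap 0.5) reflect the few-second smile-response latencies typical
of dyadic interaction; all four are parameters, not claims.
"""

from __future__ import annotations

from typing import Optional, Sequence

from pydantic import BaseModel, ConfigDict, model_validator

from .core_model import (
    AnnotationTier,
    AnnotatorKind,
    Scheme,
    SchemeKind,
    Segment,
    slice_tier,
    validate_tier,
)

__all__ = ["WindowRule", "mirroring_condition", "apply_rule"]


class WindowRule(BaseModel):
    model_config = ConfigDict(frozen=True)

    name: str = "smile_mirroring"
    window_length: float = 4.0
    step: float = 1.0
    condition: str = "mirroring"
    max_lag: float = 3.0
    min_overlap: float = 0.5
    output_label: str = "mirroring"

    @model_validator(mode="after")
    def _check(self) -> "WindowRule":
        if not self.window_length > 0:
            raise ValueError("window_length must be > 0")
        if not self.step > 0:
            raise ValueError("step must be > 0")
        if not self.max_lag < self.window_length:
            raise ValueError("max_lag must be < window_length")
        if not 0 < self.min_overlap <= 1:
            raise ValueError("min_overlap must be in (0, 1]")
        if self.condition != "mirroring":
            raise ValueError(f"unknown condition {self.condition!r}")
        return self


def mirroring_condition(
    window_segments_a: Sequence[Segment],
    window_segments_b: Sequence[Segment],
    max_lag: float,
    min_overlap: float,
) -> bool:
    """True iff the two clipped smile lists show mirroring in this window.

    Mirroring holds when some onset in one list lies within ``max_lag``
    seconds of an onset in the other (either direction — the predicate is
    symmetric in its tier arguments), or when a pair of smiles overlaps by
    at least ``min_overlap`` of the shorter of the two.  Inputs are the
    segments already clipped to the window.  The predicate is monotone in
    ``max_lag``: enlarging the lag never turns a positive window negative.
    """
    a = [s for s in window_segments_a if s.duration > 0]
    b = [s for s in window_segments_b if s.duration > 0]
    if not a or not b:
        return False
    for sa in a:
        for sb in b:
            if abs(sa.start - sb.start) <= max_lag:
                return True
            inter = min(sa.end, sb.end) - max(sa.start, sb.start)
            shorter = min(sa.duration, sb.duration)
            if inter > 0 and inter >= min_overlap * shorter:
                return True
    return False


def apply_rule(
    rule: WindowRule,
    tier_a: AnnotationTier,
    tier_b: AnnotationTier,
    annotator: str = "affsync-search",
) -> AnnotationTier:
    """Slide the rule's window over two tiers and emit merged hit segments.

    Windows start at ``k * step`` for k = 0, 1, ... and cover
    ``[k*step, k*step + window_length)``; the scan stops once the window
    start passes the later of the two tiers' ends.  Overlapping or
    adjacent positive windows merge into one maximal segment labeled
    ``rule.output_label``; the output tier is flagged machine-annotated.
    Output segments never extend beyond the union of positive windows.
    """
    for tier in (tier_a, tier_b):
        violations = validate_tier(tier)
        if violations:
            raise ValueError(
                f"invalid tier ({tier.role}, {tier.scheme.name}): {violations[0]}"
            )
    t_end = max(tier_a.end_time, tier_b.end_time)
    hits: list[tuple[float, float]] = []
    k = 0
    while k * rule.step < t_end:
        w0 = k * rule.step
        w1 = w0 + rule.window_length
        segs_a = slice_tier(tier_a, w0, w1).segments
        segs_b = slice_tier(tier_b, w0, w1).segments
        if mirroring_condition(segs_a, segs_b, rule.max_lag, rule.min_overlap):
            hits.append((w0, w1))
        k += 1

    merged: list[tuple[float, float]] = []
    for w0, w1 in hits:
        if merged and w0 <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], w1))
        else:
            merged.append((w0, w1))

    scheme = Scheme(
        name=rule.name,
        kind=SchemeKind.DISCRETE,
        labels=(rule.output_label,),
    )
    return AnnotationTier(
        session=tier_a.session,
        role=f"{tier_a.role}+{tier_b.role}",
        annotator=annotator,
        annotator_kind=AnnotatorKind.MACHINE,
        scheme=scheme,
        segments=tuple(
            Segment(start=w0, end=w1, payload=rule.output_label) for w0, w1 in merged
        ),
    )
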