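"""Shared fixtures and hypothesis strategies for the affsync suite."""

from __future__ import annotations

import pytest
from hypothesis import strategies as st

from affsync.core_model import (
    AnnotationTier,
    AnnotatorKind,
    Scheme,
    SchemeKind,
    Segment,
)
from affsync.io_formats import EMOTION_LABELS, PipelineConfig


@pytest.fixture
def smile_scheme() -> Scheme:
    return Scheme(name="smile", kind=SchemeKind.DISCRETE, labels=("smile",))


@pytest.fixture
def emotion_scheme() -> Scheme:
    return Scheme(name="emotion", kind=SchemeKind.DISCRETE, labels=EMOTION_LABELS)


@pytest.fixture
def valence_scheme() -> Scheme:
    return Scheme(name="valence", kind=SchemeKind.CONTINUOUS, value_range=(0.0, 1.0))


@pytest.fixture
def default_config() -> PipelineConfig:
    return PipelineConfig()


def make_tier(scheme: Scheme, segments, role: str = "patient",
              annotator: str = "m1", session: str = "s1") -> AnnotationTier:
    """Build a tier from (start, end, payload[, confidence]) tuples."""
    segs = []
    for item in segments:
        start, end, payload = item[:3]
        conf = item[3] if len(item) > 3 else None
        segs.append(Segment(start=start, end=end, payload=payload, confidence=conf))
    return AnnotationTier(
        session=session,
        role=role,
        annotator=annotator,
        annotator_kind=AnnotatorKind.MACHINE,
        scheme=scheme,
        segments=tuple(segs),
    )


# ---------------------------------------------------------------------------
# hypothesis strategies

_LABELS = ("smile", "frown", "nod")


def _ms(lo: float, hi: float) -> st.SearchStrategy[float]:
    """Timestamps on the millisecond grid, so serialization is lossless."""
    return st.integers(int(lo * 1000), int(hi * 1000)).map(lambda n: n / 1000.0)


@st.composite
def tiers(draw, kind: SchemeKind | None = None, max_segments: int = 8):
    """Random valid tiers of any scheme kind.

    Discrete/free tiers get sorted, non-overlapping segments; continuous
    tiers get sorted, possibly dense back-to-back samples.
    """
    if kind is None:
        kind = draw(st.sampled_from(list(SchemeKind)))
    if kind is SchemeKind.DISCRETE:
        scheme = Scheme(name="labels", kind=kind, labels=_LABELS)
    elif kind is SchemeKind.CONTINUOUS:
        scheme = Scheme(name="signal", kind=kind, value_range=(-2.0, 2.0))
    else:
        scheme = Scheme(name="words", kind=kind)

    n = draw(st.integers(0, max_segments))
    bounds = sorted(draw(st.lists(_ms(0, 60), min_size=2 * n, max_size=2 * n,
                                  unique=True)))
    segs = []
    for i in range(n):
        start, end = bounds[2 * i], bounds[2 * i + 1]
        if kind is SchemeKind.DISCRETE:
            payload = draw(st.sampled_from(_LABELS))
        elif kind is SchemeKind.CONTINUOUS:
            payload = draw(st.integers(-2000, 2000)) / 1000.0
        else:
            payload = draw(st.text(
                alphabet=st.characters(blacklist_characters=";\n\r",
                                       blacklist_categories=("Cs", "Cc")),
                max_size=20))
        conf = draw(st.one_of(st.none(), st.integers(0, 1000).map(lambda x: x / 1000)))
        segs.append(Segment(start=start, end=end, payload=payload, confidence=conf))
    return AnnotationTier(
        session="s1", role="patient", annotator="r1",
        annotator_kind=AnnotatorKind.HUMAN, scheme=scheme, segments=tuple(segs),
    )
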