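"""Binning, majority voting and cross-model fusion."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings

from affsync.core_model import SchemeKind, TranscriptSegment
from affsync.fusion import (
    UNCLASSIFIED,
    bin_stream,
    build_interval_frame,
    fuse_intervals,
    majority_vote,
    sentiment_class_of,
)
from affsync.io_formats import PipelineConfig

from conftest import make_tier, tiers


class TestBinStream:
    def test_full_cover_discrete(self, emotion_scheme):
        tier = make_tier(emotion_scheme, [(0.0, 2.0, "happiness")])
        assert bin_stream(tier, 1.0) == {0: "happiness", 1: "happiness"}

    def test_duration_weighted_mode(self, emotion_scheme):
        tier = make_tier(emotion_scheme, [(0.0, 0.7, "sadness"), (0.7, 1.0, "happiness")])
        assert bin_stream(tier, 1.0) == {0: "sadness"}

    def test_continuous_time_weighted_mean_vs_integration_oracle(self, valence_scheme):
        tier = make_tier(valence_scheme, [(0.0, 0.5, 0.2), (0.5, 1.0, 0.8)])
        binned = bin_stream(tier, 1.0)
        assert binned[0] == pytest.approx(0.5)

        # numeric-integration oracle on a fine grid
        dt = 1e-4
        ts = np.arange(0, 1.0, dt) + dt / 2
        vals = np.where(ts < 0.5, 0.2, 0.8)
        assert binned[0] == pytest.approx(float(vals.mean()), abs=1e-3)

    def test_uneven_continuous_coverage_normalizes_by_covered_time(self, valence_scheme):
        # only 0.25 s of bin 0 is covered, value 0.8 -> mean is 0.8, not 0.2
        tier = make_tier(valence_scheme, [(0.25, 0.5, 0.8)])
        assert bin_stream(tier, 1.0)[0] == pytest.approx(0.8)

    def test_empty_bins_absent(self, emotion_scheme):
        tier = make_tier(emotion_scheme, [(3.0, 4.0, "fear")])
        assert set(bin_stream(tier, 1.0)) == {3}

    def test_bad_interval_length(self, emotion_scheme):
        tier = make_tier(emotion_scheme, [(0, 1, "fear")])
        with pytest.raises(ValueError):
            bin_stream(tier, 0.0)

    @given(tier=tiers(kind=SchemeKind.DISCRETE))
    @settings(deadline=None, derandomize=True)
    def test_binning_conserves_labeled_time(self, tier):
        """Summed per-bin coverage equals summed segment durations."""
        L = 1.0
        covered = 0.0
        for seg in tier.segments:
            covered += seg.end - seg.start
        total = 0.0
        for i in bin_stream(tier, L):
            lo, hi = i * L, (i + 1) * L
            for seg in tier.segments:
                total += max(0.0, min(seg.end, hi) - max(seg.start, lo))
        assert total == pytest.approx(covered, abs=1e-9)


class TestMajorityVote:
    def test_strict_majority(self):
        assert majority_vote(["pos", "pos", "neg"]) == "pos"

    def test_three_way_tie_resolves_to_neutral(self):
        assert majority_vote(["pos", "neg", "neutral"]) == "neutral"

    def test_tie_without_neutral_is_unclassified(self):
        assert majority_vote(["pos", "neg"]) == UNCLASSIFIED

    def test_empty_votes_rejected(self):
        with pytest.raises(ValueError):
            majority_vote([])

    def test_all_27_three_vote_multisets_match_counting_oracle(self):
        """Exhaustive check over ordered triples from {pos, neg, neutral}."""

        def oracle(votes):
            best = max(votes.count(v) for v in votes)
            winners = {v for v in votes if votes.count(v) == best}
            if len(winners) == 1:
                return winners.pop()
            return "neutral" if "neutral" in winners else UNCLASSIFIED

        for votes in itertools.product(["pos", "neg", "neutral"], repeat=3):
            assert majority_vote(list(votes)) == oracle(list(votes)), votes


def _frame(sent_scores, emotions, valences):
    row = {"speech_time": 1.0}
    for i, s in enumerate(sent_scores):
        row[f"sentiment:m{i}"] = s
    for i, e in enumerate(emotions):
        row[f"emotion:m{i}"] = e
    for i, v in enumerate(valences):
        row[f"valence:m{i}"] = v
    return pd.DataFrame([row], index=pd.Index([0], name="interval_index"))


class TestFuseIntervals:
    def test_mean_then_threshold_positive(self, default_config):
        fused = fuse_intervals(
            _frame([0.9, 0.7, 0.8], ["happiness"] * 3, [0.8] * 3), default_config
        )
        assert fused.loc[0, "sentiment"] == pytest.approx(0.8)
        assert fused.loc[0, "sentiment_class"] == "positive"

    def test_symmetric_scores_fuse_to_neutral(self, default_config):
        fused = fuse_intervals(
            _frame([0.6, -0.6, 0.0], ["neutral"] * 3, [0.5] * 3), default_config
        )
        assert fused.loc[0, "sentiment"] == pytest.approx(0.0)
        assert fused.loc[0, "sentiment_class"] == "neutral"

    def test_emotion_vote_and_polarity(self, default_config):
        fused = fuse_intervals(
            _frame([0.0] * 3, ["sadness", "sadness", "happiness"], [0.5] * 3),
            default_config,
        )
        assert fused.loc[0, "emotion"] == "sadness"
        assert fused.loc[0, "emotion_polarity"] == "negative"

    def test_valence_mean_and_class(self, default_config):
        fused = fuse_intervals(
            _frame([0.0] * 3, ["neutral"] * 3, [0.4, 0.9, 0.8]), default_config
        )
        assert fused.loc[0, "valence"] == pytest.approx(0.7)
        assert fused.loc[0, "valence_class"] == "high"

    def test_unknown_emotion_label_names_it(self, default_config):
        with pytest.raises(ValueError, match="boredom"):
            fuse_intervals(
                _frame([0.0] * 3, ["boredom"] * 3, [0.5] * 3), default_config
            )

    def test_permutation_invariance_in_model_order(self, default_config):
        a = fuse_intervals(
            _frame([0.9, -0.2, 0.4], ["sadness", "fear", "sadness"], [0.1, 0.9, 0.3]),
            default_config,
        )
        b = fuse_intervals(
            _frame([0.4, 0.9, -0.2], ["sadness", "sadness", "fear"], [0.3, 0.1, 0.9]),
            default_config,
        )
        for col in ("sentiment", "sentiment_class", "emotion", "valence_class"):
            assert a.loc[0, col] == b.loc[0, col]

    @pytest.mark.parametrize("low,high", [(-0.9, 0.1), (0.0, 0.6), (0.3, 0.9)])
    def test_threshold_monotone_in_model_score(self, default_config, low, high):
        """Raising one model's score never moves the class toward negative."""
        order = {"negative": 0, "neutral": 1, "positive": 2}
        fa = fuse_intervals(
            _frame([low, 0.5, 0.5], ["neutral"] * 3, [0.5] * 3), default_config
        )
        fb = fuse_intervals(
            _frame([high, 0.5, 0.5], ["neutral"] * 3, [0.5] * 3), default_config
        )
        assert order[fb.loc[0, "sentiment_class"]] >= order[fa.loc[0, "sentiment_class"]]

    def test_vote_mode_thresholds_each_model_first(self):
        cfg = PipelineConfig(sentiment_fusion="vote")
        # two clearly positive models outvote one strongly negative one,
        # although the mean (0.1) would be neutral
        fused = fuse_intervals(
            _frame([0.6, 0.6, -0.9], ["neutral"] * 3, [0.5] * 3), cfg
        )
        assert fused.loc[0, "sentiment_class"] == "positive"


class TestBuildIntervalFrame:
    def test_speech_restriction_and_sentiment_spread(self, emotion_scheme, valence_scheme):
        transcript = [
            TranscriptSegment(speaker="patient", start=0.0, end=2.0, text="a",
                              sentiment_scores={"m0": 0.8}),
            TranscriptSegment(speaker="therapist", start=3.0, end=5.0, text="b",
                              sentiment_scores={"m0": -0.8}),
        ]
        emo = make_tier(emotion_scheme, [(0.0, 6.0, "happiness")])
        val = make_tier(valence_scheme, [(0.0, 6.0, 0.9)])
        frame = build_interval_frame(transcript, "patient", [emo], [val])
        assert list(frame.index) == [0, 1]
        assert frame["sentiment:m0"].tolist() == [0.8, 0.8]
        assert frame["emotion:m1"].tolist() == ["happiness", "happiness"]

    def test_interval_shared_by_two_segments_weights_by_duration(
        self, emotion_scheme, valence_scheme
    ):
        transcript = [
            TranscriptSegment(speaker="patient", start=0.0, end=0.25, text="a",
                              sentiment_scores={"m0": 1.0}),
            TranscriptSegment(speaker="patient", start=0.25, end=1.0, text="b",
                              sentiment_scores={"m0": 0.0}),
        ]
        emo = make_tier(emotion_scheme, [(0.0, 1.0, "neutral")])
        val = make_tier(valence_scheme, [(0.0, 1.0, 0.5)])
        frame = build_interval_frame(transcript, "patient", [emo], [val])
        assert frame.loc[0, "sentiment:m0"] == pytest.approx(0.25)

    def test_no_speech_gives_empty_frame(self, emotion_scheme, valence_scheme):
        emo = make_tier(emotion_scheme, [(0.0, 6.0, "happiness")])
        val = make_tier(valence_scheme, [(0.0, 6.0, 0.9)])
        assert build_interval_frame([], "patient", [emo], [val]).empty
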