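"""Episode- and wave-level affect scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from drmkit.core import (
    AffectRatings,
    EpisodeRecord,
    RespondentWave,
    SegmentReport,
    ValidationError,
    enumerate_net_affect_range,
    episode_is_unpleasant,
    episode_negative_affect,
    episode_net_affect,
    episode_positive_affect,
    score_episode_frame,
    score_wave,
    slice_full_wave,
    wave_from_frames,
)


def ratings(**kw):
    base = dict(worried=1, rushed=1, irritated_angry=1, depressed=1,
                tense_stressed=1, calm_relaxed=1, enjoyment=1)
    base.update(kw)
    return AffectRatings(**base)


def episode(start, end, r, period="morning", rid="R1", wave="test"):
    return EpisodeRecord(
        respondent_id=rid, wave=wave, period=period, start_min=start, end_min=end,
        activities=frozenset({"eating"}), companions=frozenset(), ratings=r,
    )


class TestEpisodeScores:
    @pytest.mark.parametrize(
        "kw, expected",
        [
            (dict(calm_relaxed=3, enjoyment=3), 3.0),
            (dict(calm_relaxed=1, enjoyment=3), 2.0),
            (dict(calm_relaxed=2, enjoyment=2), 2.0),
        ],
    )
    def test_positive_affect(self, kw, expected):
        assert episode_positive_affect(ratings(**kw)) == expected

    @pytest.mark.parametrize(
        "kw, expected",
        [
            ({}, 1.0),
            (dict(worried=3, rushed=3, irritated_angry=3, depressed=3, tense_stressed=3), 3.0),
            (dict(tense_stressed=3), 1.4),
        ],
    )
    def test_negative_affect(self, kw, expected):
        assert episode_negative_affect(ratings(**kw)) == pytest.approx(expected)

    def test_net_affect_endpoints_and_symmetry(self):
        assert episode_net_affect(ratings(calm_relaxed=3, enjoyment=3)) == 2.0
        all_neg = dict(worried=3, rushed=3, irritated_angry=3, depressed=3, tense_stressed=3)
        assert episode_net_affect(ratings(**all_neg)) == -2.0
        for level in (1, 2, 3):
            same = {item: level for item in
                    ("worried", "rushed", "irritated_angry", "depressed",
                     "tense_stressed", "calm_relaxed", "enjoyment")}
            assert episode_net_affect(AffectRatings(**same)) == 0.0

    def test_rating_out_of_range_names_item(self):
        with pytest.raises(ValidationError, match="enjoyment"):
            ratings(enjoyment=4)

    @pytest.mark.parametrize(
        "kw, expected",
        [
            (dict(worried=3), True),               # dominant negative
            (dict(calm_relaxed=3, worried=3), False),  # tie counts as pleasant
            ({}, False),                           # tie at floor
            (dict(worried=2, calm_relaxed=3), False),
        ],
    )
    def test_unpleasant_tie_rule(self, kw, expected):
        assert episode_is_unpleasant(ratings(**kw)) is expected

    def test_exhaustive_enumeration_attains_endpoints(self):
        lo, hi, count = enumerate_net_affect_range()
        assert (lo, hi, count) == (-2.0, 2.0, 3**7)


class TestScoreWave:
    def test_single_episode(self):
        wave = RespondentWave("R1", "test", "A",
                              episodes=[episode(480, 540, ratings(calm_relaxed=3, enjoyment=3))])
        s = score_wave(wave)
        assert s.net == 2.0
        assert s.u_index == 0.0
        assert s.total_minutes == 60

    def test_duration_weighting(self):
        r_hi = ratings(calm_relaxed=3, enjoyment=3)                      # net 2
        r_mid = ratings(calm_relaxed=2, enjoyment=3, worried=3)          # pa 2.5, na 1.4
        wave = RespondentWave(
            "R1", "test", "A",
            episodes=[episode(480, 540, r_hi), episode(540, 660, r_mid)],
        )
        s = score_wave(wave)
        expected = (60 * 2.0 + 120 * 1.1) / 180
        assert s.net == pytest.approx(expected)

    def test_u_index_share_of_time(self):
        unpleasant = ratings(worried=3)           # max neg 3 > max pos 1
        pleasant = ratings(calm_relaxed=2)
        wave = RespondentWave(
            "R1", "test", "A",
            episodes=[episode(480, 510, unpleasant), episode(510, 600, pleasant)],
        )
        assert score_wave(wave).u_index == pytest.approx(0.25)

    def test_u_index_limits(self):
        unpleasant = ratings(depressed=3)
        wave = RespondentWave("R1", "test", "A", episodes=[episode(480, 540, unpleasant)])
        assert score_wave(wave).u_index == 1.0

    def test_empty_wave_errors(self):
        with pytest.raises(ValidationError, match="no reports"):
            score_wave(RespondentWave("R1", "test", "A"))

    def test_mixed_reports_rejected(self):
        seg = SegmentReport("R1", "test", "morning", frozenset(), frozenset(), ratings())
        with pytest.raises(ValidationError):
            RespondentWave("R1", "test", "A",
                           episodes=[episode(480, 540, ratings())], segments=[seg])

    def test_incomplete_episode_dropped(self):
        wave = RespondentWave(
            "R1", "test", "A",
            episodes=[episode(480, 540, ratings(calm_relaxed=3, enjoyment=3)),
                      episode(540, 600, None)],
        )
        s = score_wave(wave)
        assert s.n_scored == 1 and s.n_dropped == 1
        assert s.net == 2.0

    def test_set_d_raw_mean_no_uindex(self):
        segs = [
            SegmentReport("R1", "test", p, frozenset({"rest"}), frozenset(), r)
            for p, r in [
                ("morning", ratings(calm_relaxed=3, enjoyment=3)),
                ("afternoon", ratings()),
                ("evening", ratings(worried=3)),
            ]
        ]
        s = score_wave(RespondentWave("R1", "test", "D", segments=segs))
        nets = [2.0, 0.0, -0.4]
        assert s.net == pytest.approx(np.mean(nets))
        assert s.u_index is None and s.total_minutes is None

    def test_set_d_equals_equal_weight_episodes(self):
        """Raw segment scoring coincides with episode scoring at equal durations."""
        blocks = [ratings(calm_relaxed=3), ratings(worried=2), ratings(enjoyment=3)]
        segs = [
            SegmentReport("R1", "test", p, frozenset({"rest"}), frozenset(), r)
            for p, r in zip(("morning", "afternoon", "evening"), blocks)
        ]
        eps = [episode(480 + 60 * i, 540 + 60 * i, r) for i, r in enumerate(blocks)]
        d_score = score_wave(RespondentWave("R1", "test", "D", segments=segs))
        e_score = score_wave(RespondentWave("R1", "test", "A", episodes=eps))
        assert d_score.net == pytest.approx(e_score.net)
        assert d_score.pa == pytest.approx(e_score.pa)
        assert d_score.na == pytest.approx(e_score.na)


@st.composite
def wave_episodes(draw):
    n = draw(st.integers(min_value=1, max_value=6))
    eps = []
    t = 360
    for _ in range(n):
        dur = draw(st.integers(min_value=2, max_value=60))
        vals = draw(st.lists(st.integers(min_value=1, max_value=3), min_size=7, max_size=7))
        items = ("worried", "rushed", "irritated_angry", "depressed",
                 "tense_stressed", "calm_relaxed", "enjoyment")
        eps.append(episode(t, t + dur, AffectRatings(**dict(zip(items, vals)))))
        t += dur
    return eps


class TestScoringInvariants:
    @settings(max_examples=60, deadline=None)
    @given(wave_episodes(), st.randoms(use_true_random=False))
    def test_reorder_invariance(self, eps, rnd):
        base = score_wave(RespondentWave("R1", "test", "A", episodes=list(eps)))
        shuffled = list(eps)
        rnd.shuffle(shuffled)
        other = score_wave(RespondentWave("R1", "test", "A", episodes=shuffled))
        assert other.net == pytest.approx(base.net)
        assert other.u_index == pytest.approx(base.u_index)

    @settings(max_examples=60, deadline=None)
    @given(wave_episodes(), st.data())
    def test_split_invariance(self, eps, data):
        """Splitting an episode into contiguous halves with the same
        ratings leaves the duration-weighted summary unchanged."""
        base = score_wave(RespondentWave("R1", "test", "A", episodes=list(eps)))
        i = data.draw(st.integers(min_value=0, max_value=len(eps) - 1))
        ep = eps[i]
        cut = data.draw(st.integers(min_value=ep.start_min + 1, max_value=ep.end_min - 1)) \
            if ep.end_min - ep.start_min > 1 else None
        if cut is None:
            return
        import dataclasses
        left = dataclasses.replace(ep, end_min=cut)
        right = dataclasses.replace(ep, start_min=cut)
        split = list(eps[:i]) + [left, right] + list(eps[i + 1:])
        other = score_wave(RespondentWave("R1", "test", "A", episodes=split))
        assert other.net == pytest.approx(base.net)
        assert other.pa == pytest.approx(base.pa)
        assert other.u_index == pytest.approx(base.u_index)

    @settings(max_examples=40, deadline=None)
    @given(wave_episodes())
    def test_summary_ranges(self, eps):
        s = score_wave(RespondentWave("R1", "test", "A", episodes=eps))
        assert 1.0 <= s.pa <= 3.0 and 1.0 <= s.na <= 3.0
        assert -2.0 <= s.net <= 2.0
        assert 0.0 <= s.u_index <= 1.0


class TestSliceFullWave:
    def _full_wave(self, eps):
        return RespondentWave("R1", "retest", "FULL", episodes=eps)

    def test_identity_when_contained(self):
        eps = [episode(480, 540, ratings()), episode(540, 700, ratings())]
        sliced = slice_full_wave(self._full_wave(eps), "morning")
        assert [(e.start_min, e.end_min) for e in sliced.episodes] == [(480, 540), (540, 700)]

    def test_straddling_episode_prorated(self):
        eps = [episode(600, 800, ratings(worried=2))]
        morning = slice_full_wave(self._full_wave(eps), "morning")
        afternoon = slice_full_wave(self._full_wave(eps), "afternoon")
        assert [(e.start_min, e.end_min) for e in morning.episodes] == [(600, 720)]
        assert [(e.start_min, e.end_min) for e in afternoon.episodes] == [(720, 800)]
        assert morning.episodes[0].ratings == eps[0].ratings

    def test_empty_slice(self):
        eps = [episode(480, 540, ratings())]
        evening = slice_full_wave(self._full_wave(eps), "evening")
        assert evening.episodes == []

    def test_non_full_wave_rejected(self):
        wave = RespondentWave("R1", "test", "A", episodes=[episode(480, 540, ratings())])
        with pytest.raises(ValidationError):
            slice_full_wave(wave, "morning")


def test_object_and_frame_scoring_agree(default_sim):
    """The typed record API and the vectorized frame path agree."""
    study = default_sim.study
    frame_scores = score_episode_frame(study.episodes).set_index(["respondent_id", "wave"])
    ids = study.episodes["respondent_id"].unique()[:8]
    for rid in ids:
        for wave in ("test", "retest"):
            rows = study.episodes.query("respondent_id == @rid and wave == @wave")
            if not len(rows):
                continue
            obj = score_wave(wave_from_frames(study, rid, wave))
            got = frame_scores.loc[(rid, wave)]
            assert obj.net == pytest.approx(got["net"])
            assert obj.u_index == pytest.approx(got["u_index"])
            assert obj.total_minutes == pytest.approx(got["total_min"])
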