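"""E_SI scoring, ICL%, contact metrics, kinematics and potency."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wormmate import (
    BehaviorTimeline,
    CentroidTrack,
    centroid_kinematics,
    compute_esi,
    compute_icl,
    contact_metrics,
    potency_fraction,
)


def _timeline(intervals, cap=120.0):
    return BehaviorTimeline(list(intervals), observation_cap=cap)


class TestComputeEsi:
    def test_immediate_prodding_with_quick_penetration_scores_199(self):
        # prodding from first contact, penetration ~1 s in
        tl = _timeline([(0.0, 1.0, "vulva_prodding"), (1.0, 1.5, "insertion")])
        res = compute_esi(tl)
        assert res.score == pytest.approx(1.0 * 1.0 * (1 + 119.0 / 120.0))
        assert round(res.score, 2) == 1.99

    def test_full_window_without_attempt_scores_zero(self):
        tl = _timeline([(0.0, 120.0, "scanning")])
        res = compute_esi(tl)
        assert res.score == 0.0
        assert not res.penetrated

    def test_hand_evaluated_mixed_timeline(self):
        # 30 s prodding, 10 s scanning, penetration at 40 s:
        # (30/40) * (1/10) * (1 + 80/120) = 0.125
        tl = _timeline(
            [
                (0.0, 30.0, "vulva_prodding"),
                (30.0, 40.0, "scanning"),
                (40.0, 40.5, "insertion"),
            ]
        )
        assert compute_esi(tl).score == pytest.approx(0.125)

    def test_durations_truncate_at_cap(self):
        tl = _timeline([(0.0, 200.0, "vulva_prodding")], cap=120.0)
        res = compute_esi(tl)
        assert res.t_prod == pytest.approx(120.0)
        assert res.t_total == pytest.approx(120.0)

    def test_no_contact_rejected(self):
        tl = _timeline([(0.0, 10.0, "off")])
        with pytest.raises(ValueError, match="contact"):
            compute_esi(tl)

    def test_zero_iff_no_prodding(self):
        with_prod = _timeline(
            [(0.0, 5.0, "scanning"), (5.0, 6.0, "vulva_prodding")]
        )
        without = _timeline([(0.0, 6.0, "scanning")])
        assert compute_esi(with_prod).score > 0
        assert compute_esi(without).score == 0.0

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        t_prod=st.floats(0.5, 60.0),
        t_nonprod=st.floats(1.0, 60.0),
        extra=st.floats(0.5, 20.0),
    )
    def test_monotone_in_prodding_and_nonproductive_time(
        self, t_prod, t_nonprod, extra
    ):
        def score(p, n):
            tl = _timeline(
                [(0.0, n, "scanning"), (n, n + p, "vulva_prodding")]
            )
            return compute_esi(tl).score

        assert score(t_prod + extra, t_nonprod) >= score(t_prod, t_nonprod)
        assert score(t_prod, t_nonprod + extra) <= score(t_prod, t_nonprod)

    def test_bonus_bounded_by_one(self):
        tl = _timeline([(0.0, 0.5, "vulva_prodding"), (0.5, 1.0, "insertion")])
        res = compute_esi(tl)
        assert 0.0 <= res.bonus <= 1.0
        assert res.score <= 2.0 * (res.t_prod / res.t_total)


class TestTimelineInvariants:
    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            _timeline([(0.0, 5.0, "scanning"), (4.0, 6.0, "vulva_prodding")])

    def test_non_terminal_insertion_rejected(self):
        with pytest.raises(ValueError, match="terminal"):
            _timeline([(0.0, 1.0, "insertion"), (1.0, 2.0, "scanning")])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="label"):
            _timeline([(0.0, 1.0, "prodding")])


class TestComputeIcl:
    def test_full_contact_is_100pct(self):
        assert compute_icl(800.0, 800.0) == 100.0

    def test_quarter_contact(self):
        assert compute_icl(250.0, 1000.0) == 25.0

    def test_zero_contact(self):
        assert compute_icl(0.0, 500.0) == 0.0

    def test_contact_exceeding_body_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            compute_icl(600.0, 500.0)


class TestContactMetrics:
    def test_single_bout_spanning_cap(self):
        m = contact_metrics(_timeline([(0.0, 120.0, "vulva_prodding")]))
        assert m.n_vulva_contacts == 1
        assert m.total_vulva_contact == 120.0
        assert m.mean_interval_between_attempts is None

    def test_interval_between_attempts(self):
        m = contact_metrics(
            _timeline(
                [
                    (0.0, 10.0, "vulva_prodding"),
                    (10.0, 30.0, "scanning"),
                    (30.0, 40.0, "vulva_prodding"),
                ]
            )
        )
        assert m.n_vulva_contacts == 2
        assert m.mean_interval_between_attempts == pytest.approx(20.0)
        assert m.cumulative_contact == pytest.approx(40.0)

    def test_empty_timeline_gives_zeros(self):
        m = contact_metrics(_timeline([]))
        assert m.n_vulva_contacts == 0
        assert m.cumulative_contact == 0.0
        assert m.average_contact == 0.0

    def test_off_gaps_split_contact_episodes(self):
        m = contact_metrics(
            _timeline(
                [
                    (0.0, 10.0, "scanning"),
                    (10.0, 20.0, "off"),
                    (20.0, 40.0, "scanning"),
                ]
            )
        )
        assert m.cumulative_contact == pytest.approx(30.0)
        assert m.average_contact == pytest.approx(15.0)


class TestCentroidKinematics:
    def test_stationary_track(self):
        track = CentroidTrack(np.arange(5.0), np.ones((5, 2)), px_per_mm=100.0)
        res = centroid_kinematics(track)
        assert res.distance_mm == 0.0
        assert np.allclose(res.velocity_mm_s, 0.0)

    def test_straight_line_constant_velocity(self):
        n = 11
        times = np.linspace(0.0, 10.0, n)
        xy = np.column_stack([np.linspace(0.0, 300.0, n), np.zeros(n)])
        res = centroid_kinematics(CentroidTrack(times, xy, px_per_mm=100.0))
        assert res.distance_mm == pytest.approx(3.0)
        assert np.allclose(res.velocity_mm_s, 0.3)

    def test_single_frame_rejected(self):
        track = CentroidTrack([0.0], [[1.0, 2.0]], px_per_mm=100.0)
        with pytest.raises(ValueError, match="two frames"):
            centroid_kinematics(track)


class TestPotencyFraction:
    def test_all_potent(self):
        assert potency_fraction([True] * 5) == (1.0, 5)

    def test_seven_of_ten(self):
        frac, n = potency_fraction(["potent"] * 7 + ["not_potent"] * 3)
        assert frac == pytest.approx(0.7)
        assert n == 10

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            potency_fraction([])
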