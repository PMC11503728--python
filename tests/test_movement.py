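import math
from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from herdmotion import (
    FrameGeometry,
    GroupPoint,
    OrderingError,
    ParameterError,
    Point2D,
    aggregate_daily,
    displacement_series,
    hourly_profile,
    normalized_distance,
)
from herdmotion.movement import daily_summary_frame

T0 = datetime(2023, 5, 13, 0, 0, 0)


def gp(i, x=None, y=None, minutes=5, n=7):
    present = x is not None
    return GroupPoint(
        frame_id=f"f{i}",
        timestamp=T0 + timedelta(minutes=i * minutes),
        point=Point2D(x, y) if present else None,
        n_pigs=n if present else 0,
    )


class TestNormalizedDistance:
    def test_full_diagonal_is_exactly_100(self):
        geom = FrameGeometry(3632, 1632)
        assert normalized_distance(Point2D(0, 0), Point2D(3632, 1632), geom) == 100.0

    def test_no_move_is_exactly_zero(self):
        geom = FrameGeometry(100, 100)
        assert normalized_distance(Point2D(5, 5), Point2D(5, 5), geom) == 0.0

    def test_three_four_five_triangle(self):
        assert normalized_distance(
            Point2D(0, 0), Point2D(3, 4), FrameGeometry(3, 4)
        ) == pytest.approx(100.0)
        assert normalized_distance(
            Point2D(0, 0), Point2D(3, 4), FrameGeometry(6, 8)
        ) == pytest.approx(50.0)

    def test_zero_dimension_rejected(self):
        with pytest.raises(ParameterError):
            FrameGeometry(0, 100)

    @given(
        x0=st.floats(0, 1000), y0=st.floats(0, 500),
        x1=st.floats(0, 1000), y1=st.floats(0, 500),
        s=st.sampled_from([0.25, 4.0, 13.7]),
    )
    def test_scale_invariance(self, x0, y0, x1, y1, s):
        """Rescaling the coordinates and the frame together leaves D
        unchanged — the design goal of normalizing by the diagonal."""
        base = normalized_distance(
            Point2D(x0, y0), Point2D(x1, y1), FrameGeometry(1000, 500)
        )
        scaled = normalized_distance(
            Point2D(x0 * s, y0 * s),
            Point2D(x1 * s, y1 * s),
            FrameGeometry(int(1000 * s), int(500 * s)),
        )
        assert abs(scaled - base) <= 1e-9 * max(base, 1.0)


class TestDisplacementSeries:
    def test_adjacent_pairs(self):
        geom = FrameGeometry(100, 100)
        diag = geom.diagonal
        track = [gp(0, 0, 0), gp(1, 0.1 * diag, 0), gp(2, 0.3 * diag, 0)]
        series = displacement_series(track, geom)
        assert [d.d_pct for d in series.displacements] == pytest.approx([10, 20])
        assert [d.dt_s for d in series.displacements] == [300, 300]

    def test_skip_policy_drops_gap_adjacent_pairs(self):
        geom = FrameGeometry(100, 100)
        track = [gp(0, 10, 10), gp(1), gp(2, 20, 20)]
        series = displacement_series(track, geom, gap_policy="skip")
        assert series.displacements == []
        assert len(series.missing) == 2

    def test_bridge_policy_spans_gap_with_accumulated_dt(self):
        geom = FrameGeometry(100, 100)
        track = [gp(0, 10, 10), gp(1), gp(2, 20, 20)]
        series = displacement_series(track, geom, gap_policy="bridge")
        assert len(series.displacements) == 1
        assert series.displacements[0].dt_s == 600.0
        assert series.missing == []

    def test_non_chronological_rejected(self):
        geom = FrameGeometry(100, 100)
        with pytest.raises(OrderingError):
            displacement_series([gp(1, 0, 0), gp(0, 1, 1)], geom)

    def test_unknown_gap_policy_rejected(self):
        with pytest.raises(ParameterError):
            displacement_series([], FrameGeometry(10, 10), gap_policy="interp")


class TestAggregation:
    def test_daily_sum(self):
        geom = FrameGeometry(100, 100)
        d = geom.diagonal
        track = [gp(0, 0, 0), gp(1, 0.10 * d, 0), gp(2, 0.30 * d, 0), gp(3, 0.35 * d, 0)]
        series = displacement_series(track, geom)
        (day,) = aggregate_daily(series)
        assert day.total_d == pytest.approx(35.0)
        assert day.n_pairs == 3
        assert day.n_missing == 0

    def test_midnight_pair_assigned_to_later_day(self):
        geom = FrameGeometry(100, 100)
        t_late = datetime(2023, 5, 13, 23, 57)
        t_next = datetime(2023, 5, 14, 0, 2)
        track = [
            GroupPoint("a", t_late, Point2D(0, 0), 7),
            GroupPoint("b", t_next, Point2D(10, 0), 7),
        ]
        series = displacement_series(track, geom)
        (day,) = aggregate_daily(series)
        assert day.day.isoformat() == "2023-05-14"

    def test_empty_series_empty_summary(self):
        series = displacement_series([], FrameGeometry(10, 10))
        assert aggregate_daily(series) == []

    def test_hourly_bins_sum_to_daily_total_exactly(self):
        geom = FrameGeometry(1000, 500)
        rng = np.random.default_rng(0)
        track = [
            gp(i, float(rng.uniform(0, 1000)), float(rng.uniform(0, 500)))
            for i in range(200)
        ]
        series = displacement_series(track, geom)
        daily = aggregate_daily(series)
        for day in daily:
            profile = hourly_profile(series, day=day.day)
            assert profile["total_d"].sum() == pytest.approx(day.total_d, rel=1e-12)
            assert profile["n_pairs"].sum() == day.n_pairs

    def test_single_pair_lands_in_its_destination_hour(self):
        geom = FrameGeometry(100, 100)
        t0 = datetime(2023, 5, 13, 8, 58)
        t1 = datetime(2023, 5, 13, 9, 3)
        track = [
            GroupPoint("a", t0, Point2D(0, 0), 7),
            GroupPoint("b", t1, Point2D(10, 0), 7),
        ]
        profile = hourly_profile(displacement_series(track, geom))
        nonzero = profile[profile["total_d"] > 0]
        assert nonzero["hour"].tolist() == [9]

    def test_uniform_cadence_fills_every_bin_equally(self):
        geom = FrameGeometry(100, 100)
        diag = geom.diagonal
        # 10% move every 5 minutes for 24h (289 frames -> 288 pairs)
        track = []
        x = 0.0
        direction = 1
        for i in range(289):
            track.append(gp(i, 50 + direction * 0.05 * diag, 50))
            direction *= -1
        series = displacement_series(track, geom)
        profile = hourly_profile(series, day=T0.date())
        # first frame is not a destination; bin 0 has 11 pairs, others 12
        expected = [11] + [12] * 23
        assert profile["n_pairs"].tolist() == expected
        assert profile["total_d"].tolist() == pytest.approx(
            [n * 10.0 for n in expected]
        )

    def test_path_at_least_net_displacement(self):
        geom = FrameGeometry(1000, 500)
        rng = np.random.default_rng(5)
        track = [
            gp(i, float(rng.uniform(0, 1000)), float(rng.uniform(0, 500)))
            for i in range(100)
        ]
        series = displacement_series(track, geom)
        net = normalized_distance(track[0].point, track[-1].point, geom)
        assert series.total_d >= net - 1e-9

    def test_summary_frame_counts_missing(self):
        geom = FrameGeometry(100, 100)
        track = [gp(0, 10, 10), gp(1), gp(2, 20, 20), gp(3, 30, 20)]
        series = displacement_series(track, geom)
        df = daily_summary_frame(series)
        assert df.loc[0, "n_pairs"] == 1
        assert df.loc[0, "n_missing"] == 2
        assert not df.loc[0, "no_data"]
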