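from decimal import Decimal

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dialcost import (
    CalibrationError,
    CrossingStatus,
    Trajectory,
    accumulated_cost,
    crossing_time,
    infer_training_duration,
    payoff_time,
    trajectory_for,
)

from conftest import D


# --- independent oracles ---------------------------------------------------


def bisect_duration(T, m, A_ref, t_ref, tol=1e-9):
    """Solve A(t_ref) = A_ref for the training duration by bisection."""
    def A(d):
        return T + m * max(0.0, t_ref - d)

    lo, hi = 0.0, t_ref
    assert A(lo) >= A_ref >= A(hi)
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if A(mid) >= A_ref:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def grid_crossing(a: Trajectory, b: Trajectory, hi=600.0, step=0.001):
    """Dense grid scan for the first sign change of A_a - A_b.

    Returns (time, sign_before) or (None, final_sign); equalities on the
    grid are ignored until a strict ordering is established.
    """
    t = np.arange(0.0, hi + step, step)

    def acc(traj):
        return float(traj.upfront) + float(traj.monthly_rate) * np.maximum(
            0.0, t - float(traj.duration_months)
        )

    f = acc(a) - acc(b)
    s = np.sign(f).astype(int)
    nz = np.nonzero(s)[0]
    if nz.size == 0:
        return None, 0
    ss = s[nz]
    flips = np.nonzero(ss[1:] != ss[:-1])[0]
    if flips.size == 0:
        return None, int(ss[0])
    k = flips[0]
    return float(t[nz[k + 1]]), int(ss[k])


def random_trajectory(rng, key="t"):
    return Trajectory(
        key,
        D(round(float(rng.uniform(0, 30000)), 2)),
        D(round(float(rng.uniform(0, 3)), 4)),
        D(round(float(rng.uniform(200, 8000)), 4)),
    )


# --- accumulated cost ------------------------------------------------------


class TestAccumulatedCost:
    def test_facility_hd_at_six_months(self, results):
        """With no training, accumulated cost is half the annual total."""
        traj = results.trajectories["in_center_hd"]
        assert abs(accumulated_cost(traj, 6) - D("33707.78")) <= D("0.05")

    def test_at_time_zero_only_the_training_outlay_has_accrued(self, results):
        for traj in results.trajectories.values():
            assert accumulated_cost(traj, 0) == traj.upfront.quantize(D("0.01"))

    def test_full_assist_home_hd_at_twelve_months(self, results):
        traj = results.trajectories["home_hd_full_assist"]
        assert abs(accumulated_cost(traj, 12) - D("47708.35")) <= D("0.50")

    def test_negative_time_rejected(self, results):
        with pytest.raises(ValueError, match=">= 0"):
            accumulated_cost(results.trajectories["capd"], -1)

    @given(
        T=st.floats(0, 1e5),
        d=st.floats(0, 12),
        m=st.floats(0, 1e4),
        t1=st.floats(0, 60),
        dt=st.floats(0, 60),
    )
    @settings(max_examples=150, derandomize=True)
    def test_non_decreasing_and_continuous_at_the_knot(self, T, d, m, t1, dt):
        traj = Trajectory("x", D(round(T, 2)), D(round(d, 4)), D(round(m, 4)))
        a1 = traj.accumulated(D(str(round(t1, 6))))
        a2 = traj.accumulated(D(str(round(t1 + dt, 6))))
        assert a2 >= a1
        # continuity at the training-duration knot
        eps = D("0.000001")
        before = traj.accumulated(max(traj.duration_months - eps, D(0)))
        after = traj.accumulated(traj.duration_months + eps)
        assert after - before <= traj.monthly_rate * 2 * eps + D("1e-12")


# --- duration calibration --------------------------------------------------


class TestInferTrainingDuration:
    @pytest.mark.parametrize(
        "T, annual, A_ref, expected",
        [
            ("25484.87", "36618.37", "33381.73", 0.412),  # conventional home HD
            ("7919.45", "36265.39", "14331.73", 0.878),   # CAPD
        ],
    )
    def test_matches_bisection_oracle(self, T, annual, A_ref, expected):
        m = D(annual) / 12
        d = infer_training_duration(D(T), m, D(A_ref), 3)
        oracle = bisect_duration(float(T), float(m), float(A_ref), 3.0)
        assert abs(float(d) - oracle) < 1e-6
        assert round(float(d), 3) == expected

    def test_fully_linear_modality_has_zero_duration(self):
        T, m = D(100), D(50)
        assert infer_training_duration(T, m, T + 3 * m, 3) == 0

    def test_reference_above_linear_maximum_is_rejected(self):
        with pytest.raises(CalibrationError, match="mod_x"):
            infer_training_duration(D(100), D(50), D(1000), 3, modality="mod_x")

    def test_reference_below_upfront_cost_is_rejected(self):
        with pytest.raises(CalibrationError, match="below the upfront"):
            infer_training_duration(D(100), D(50), D(50), 3)

    @given(
        T=st.floats(0, 5e4),
        m=st.floats(0.01, 1e4),
        d=st.floats(0, 6),
        t_extra=st.floats(0.001, 24),
    )
    @settings(max_examples=150, derandomize=True)
    def test_roundtrip_reproduces_the_reference_point(self, T, m, d, t_extra):
        """Calibrating from A(t_ref) and re-evaluating hits A_ref exactly."""
        T, m, d = D(round(T, 2)), D(str(round(m, 6))), D(str(round(d, 6)))
        t_ref = d + D(str(round(t_extra, 6)))
        traj = Trajectory("x", T, d, m)
        A_ref = traj.accumulated(t_ref)
        d_hat = infer_training_duration(T, m, A_ref, t_ref)
        assert Trajectory("x", T, d_hat, m).accumulated(t_ref) == A_ref
        assert abs(d_hat - d) < D("1e-15")


# --- crossing solver -------------------------------------------------------


class TestCrossingTime:
    def test_upfront_investment_recouped_at_twelve_months(self):
        a = Trajectory("a", D(1200), D(0), D(100))
        b = Trajectory("b", D(0), D(0), D(200))
        res = crossing_time(a, b)
        assert res.status is CrossingStatus.CROSSES_AT
        assert res.time_months == 12
        assert res.cheaper_before == "b"
        assert res.cheaper_after == "a"

    def test_identical_trajectories(self):
        a = Trajectory("a", D(10), D(1), D(5))
        b = Trajectory("b", D(10), D(1), D(5))
        assert crossing_time(a, b).status is CrossingStatus.IDENTICAL

    def test_conventional_home_hd_crosses_facility_hd(self, results):
        res = results.crossing("home_hd_conventional", "in_center_hd")
        assert res.status is CrossingStatus.CROSSES_AT
        assert res.time_months.quantize(D("0.01")) == D("9.44")
        assert res.cheaper_before == "in_center_hd"
        assert res.cheaper_after == "home_hd_conventional"

    def test_costlier_stream_with_no_investment_never_crosses(self):
        a = Trajectory("a", D(100), D(0), D(300))
        b = Trajectory("b", D(0), D(0), D(200))
        res = crossing_time(a, b)
        assert res.status is CrossingStatus.ALWAYS_COSTLIER

    def test_equal_start_diverging_is_not_a_crossing(self):
        a = Trajectory("a", D(0), D(0), D(100))
        b = Trajectory("b", D(0), D(0), D(200))
        res = crossing_time(a, b)
        assert res.status is CrossingStatus.ALWAYS_CHEAPER

    def test_touch_without_sign_change_is_not_a_crossing(self):
        # a starts above, meets b exactly at the knot, then rises again
        a = Trajectory("a", D(100), D(1), D(300))
        b = Trajectory("b", D(0), D(0), D(100))  # equal at t=1: 100 == 100
        res = crossing_time(a, b)
        assert res.status is CrossingStatus.ALWAYS_COSTLIER

    def test_agrees_with_dense_grid_scan(self):
        rng = np.random.default_rng(20190707)
        n_checked = 0
        for _ in range(300):
            a = random_trajectory(rng, "a")
            b = random_trajectory(rng, "b")
            res = crossing_time(a, b)
            t_grid, sign_before = grid_crossing(a, b)
            if res.status is CrossingStatus.CROSSES_AT and float(res.time_months) <= 599:
                assert t_grid is not None
                assert abs(float(res.time_months) - t_grid) <= 0.002
                n_checked += 1
            elif res.status is CrossingStatus.ALWAYS_COSTLIER:
                assert t_grid is None and sign_before >= 0
            elif res.status is CrossingStatus.ALWAYS_CHEAPER:
                assert t_grid is None and sign_before <= 0
        assert n_checked > 100  # the draw produces plenty of true crossings


# --- graduation payoff -----------------------------------------------------


class TestPayoffTime:
    def test_complete_care_to_self_care_home_hd(self, book, rates):
        months = payoff_time(
            book["home_hd_complete_care"], book["home_hd_conventional"], rates
        )
        assert months.quantize(D("0.01")) == D("10.89")
        assert months < 12

    def test_full_assist_to_self_care_ccpd(self, book, rates):
        months = payoff_time(book["ccpd_full_assist"], book["ccpd"], rates)
        assert months.quantize(D("0.01")) == D("3.45")
        assert months < 12

    def test_free_training_pays_off_immediately(self, book, rates):
        months = payoff_time(book["ccpd_full_assist"], book["in_center_hd"], rates)
        assert months == 0  # comparator trains nobody

    def test_graduating_to_a_costlier_modality_never_pays_off(self, book, rates):
        with pytest.raises(ValueError, match="never pays off"):
            payoff_time(book["ccpd"], book["ccpd_full_assist"], rates)


class TestTrajectoryFor:
    def test_comparator_is_a_pure_maintenance_stream(self, book, rates, results):
        from dialcost import annual_maintenance_total

        traj = results.trajectories["in_center_hd"]
        assert traj.upfront == 0
        assert traj.duration_months == 0
        annual = annual_maintenance_total(book["in_center_hd"].maintenance, rates)
        assert traj.monthly_rate * 12 == annual

    def test_training_profile_needs_duration_or_calibration(self):
        from dialcost import TrainingProfile

        with pytest.raises(ValueError, match="duration_months or a calibration"):
            TrainingProfile((), duration_months=None, calibration=None)
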