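"""Accumulated-cost trajectories, duration calibration and break-even solving.

Each modality's cost stream is modelled as a one-time training outlay ``T``
at therapy start, a training period of ``d`` months during which no
maintenance accrues, and a constant maintenance rate ``m`` per month
thereafter:

    A(t) = T + m * max(0, t - d)

A(t) is continuous, non-decreasing and piecewise linear with a single knot
at ``d``.  Cost neutrality between two modalities is the first time their
accumulated costs cross; because both curves are piecewise linear the
crossing is solved exactly, segment by segment, in decimal arithmetic.

No discounting is applied: the horizons of interest are short (months to a
few years) and the model compares undiscounted cash streams.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal
from enum import Enum
from typing import Optional, TYPE_CHECKING

from .costbook import (
    Modality,
    OverheadRates,
    annual_maintenance_total,
    as_money,
    training_total,
)

__all__ = [
    "Trajectory",
    "CrossingStatus",
    "CrossingResult",
    "CalibrationError",
    "accumulated_cost",
    "infer_training_duration",
    "crossing_time",
    "payoff_time",
    "trajectory_for",
]

_ZERO = Decimal("0")
_TWELVE = Decimal("12")


def _as_months(t) -> Decimal:
    if isinstance(t, Decimal):
        return t
    if isinstance(t, float):
        return Decimal(str(t))
    return Decimal(t)


class CalibrationError(ValueError):
    """A training duration cannot be recovered from its reference point."""


@dataclass(frozen=True)
class Trajectory:
    """Piecewise-linear accumulated-cost curve for one modality."""

    modality_key: str
    upfront: Decimal          # training outlay T at t = 0
    duration_months: Decimal  # training duration d
    monthly_rate: Decimal     # maintenance rate m per month

    def __post_init__(self):
        object.__setattr__(self, "upfront", as_money(self.upfront))
        object.__setattr__(self, "duration_months", _as_months(self.duration_months))
        m = self.monthly_rate
        m = Decimal(str(m)) if isinstance(m, float) else Decimal(m)
        object.__setattr__(self, "monthly_rate", m)
        if self.upfront < 0 or self.duration_months < 0 or self.monthly_rate < 0:
            raise ValueError(f"trajectory {self.modality_key!r}: T, d, m must all be >= 0")

    def _accumulated(self, t: Decimal) -> Decimal:
        elapsed = t - self.duration_months
        if elapsed < 0:
            elapsed = _ZERO
        return self.upfront + self.monthly_rate * elapsed

    def accumulated(self, t) -> Decimal:
        """Accumulated cost at month ``t`` (exact, unrounded)."""
        t = _as_months(t)
        if t < 0:
            raise ValueError(f"time must be >= 0 months, got {t}")
        return self._accumulated(t)


def accumulated_cost(traj: Trajectory, t) -> Decimal:
    """Accumulated cost ``T + m*max(0, t - d)`` at month ``t``, to the cent."""
    from .costbook import round_cents

    return round_cents(traj.accumulated(t))


def infer_training_duration(T, m, A_ref, t_ref, modality: str = "") -> Decimal:
    """Training duration that makes the trajectory hit a reference point.

    Solves ``A(t_ref) = A_ref`` for ``d``, giving ``d = (T + m*t_ref -
    A_ref) / m``.  The solution is unique whenever ``A_ref > T`` (the
    reference lies on the accruing branch of the curve).

    Raises
    ------
    CalibrationError
        If ``A_ref`` exceeds ``T + m*t_ref`` (would imply a negative
        duration) or falls below ``T`` (no duration can reproduce a
        reference under the upfront cost).
    """
    T = as_money(T)
    m = _as_months(m)
    A_ref = as_money(A_ref)
    t_ref = _as_months(t_ref)
    label = f" for {modality!r}" if modality else ""
    if m <= 0:
        raise CalibrationError(f"monthly rate must be > 0 to calibrate{label}")
    ceiling = T + m * t_ref
    if A_ref > ceiling:
        raise CalibrationError(
            f"inconsistent calibration{label}: reference accumulated cost {A_ref} at "
            f"{t_ref} months exceeds the zero-duration maximum {ceiling}"
        )
    if A_ref < T:
        raise CalibrationError(
            f"inconsistent calibration{label}: reference accumulated cost {A_ref} is "
            f"below the upfront training cost {T}"
        )
    return (ceiling - A_ref) / m


def trajectory_for(modality: Modality, rates: OverheadRates) -> Trajectory:
    """Build a modality's trajectory from its cost profiles.

    ``T`` is the training total, ``m`` the annual maintenance total divided
    by 12, and ``d`` either the configured duration or the duration
    calibrated from the training profile's reference point.
    """
    T = training_total(modality.training, rates)
    m = annual_maintenance_total(modality.maintenance, rates) / _TWELVE
    if modality.training.duration_months is not None:
        d = modality.training.duration_months
    else:
        ref = modality.training.calibration
        if ref is None:
            raise CalibrationError(
                f"modality {modality.name!r} has neither a training duration nor a "
                "calibration reference"
            )
        d = infer_training_duration(T, m, ref.accumulated, ref.at_months, modality.name)
    return Trajectory(modality.name, T, d, m)


class CrossingStatus(str, Enum):
    CROSSES_AT = "crosses_at"
    ALWAYS_CHEAPER = "always_cheaper"
    ALWAYS_COSTLIER = "always_costlier"
    IDENTICAL = "identical"


@dataclass(frozen=True)
class CrossingResult:
    """Outcome of comparing two accumulated-cost trajectories.

    Statuses are from the first trajectory's perspective: ``always_cheaper``
    means its accumulated cost never exceeds the other's (and is lower
    somewhere).  ``time_months`` is present only for ``crosses_at``.
    """

    status: CrossingStatus
    time_months: Optional[Decimal] = None
    cheaper_before: Optional[str] = None
    cheaper_after: Optional[str] = None

    def __post_init__(self):
        if self.status is CrossingStatus.CROSSES_AT:
            if self.time_months is None or self.time_months < 0:
                raise ValueError("crosses_at requires time_months >= 0")


def _sign(x: Decimal) -> int:
    return (x > 0) - (x < 0)


def crossing_time(a: Trajectory, b: Trajectory) -> CrossingResult:
    """Earliest time the sign of ``A_a(t) - A_b(t)`` changes.

    Both curves are piecewise linear with knots at their training
    durations, so the difference is solved exactly on the segments
    delimited by {0, d_a, d_b}.  Starting equal at t=0 and then diverging
    is not a crossing; a curve that touches the other and returns to the
    same side is not a crossing either.  When the curves coincide over a
    segment and the ordering flips after it, the crossing is reported at
    the start of the coincident stretch (the infimum time at which the
    ordering changes).
    """
    same = (
        a.upfront == b.upfront
        and a.duration_months == b.duration_months
        and a.monthly_rate == b.monthly_rate
    )
    if same:
        return CrossingResult(CrossingStatus.IDENTICAL)

    def crossed(t: Decimal, sign_before: int) -> CrossingResult:
        cheaper_before, cheaper_after = (
            (a.modality_key, b.modality_key)
            if sign_before < 0
            else (b.modality_key, a.modality_key)
        )
        return CrossingResult(CrossingStatus.CROSSES_AT, t, cheaper_before, cheaper_after)

    knots = sorted({_ZERO, a.duration_months, b.duration_months})
    segments = [(knots[i], knots[i + 1] if i + 1 < len(knots) else None) for i in range(len(knots))]

    prev = 0            # last established nonzero sign of the difference
    zero_since = None   # start of the current run of exact ties
    for t0, t1 in segments:
        f0 = a._accumulated(t0) - b._accumulated(t0)
        slope = (a.monthly_rate if t0 >= a.duration_months else _ZERO) - (
            b.monthly_rate if t0 >= b.duration_months else _ZERO
        )
        sg0 = _sign(f0)
        if sg0 == 0:
            if zero_since is None:
                zero_since = t0
        else:
            if prev and sg0 != prev:
                return crossed(zero_since if zero_since is not None else t0, prev)
            prev = sg0
            zero_since = None
        if slope == 0:
            continue  # sign at t0 persists across the segment
        if sg0 == 0:
            # leaves the tie immediately; new sign is the slope's
            ssg = _sign(slope)
            if prev and ssg != prev:
                return crossed(zero_since, prev)
            prev = ssg
            zero_since = None
            continue
        root = t0 - f0 / slope
        if root > t0 and (t1 is None or root < t1):
            # transversal crossing strictly inside the segment
            return crossed(root, sg0)
        # a root exactly at t1 surfaces as a tie at the next segment start

    if prev > 0:
        return CrossingResult(
            CrossingStatus.ALWAYS_COSTLIER, cheaper_before=b.modality_key
        )
    if prev < 0:
        return CrossingResult(
            CrossingStatus.ALWAYS_CHEAPER, cheaper_before=a.modality_key
        )
    return CrossingResult(CrossingStatus.IDENTICAL)


def payoff_time(from_m: Modality, to_m: Modality, rates: OverheadRates) -> Decimal:
    """Months to recoup a cheaper modality's training cost after switching.

    A patient graduating from ``from_m`` to ``to_m`` invests ``to_m``'s
    training total and saves the maintenance differential each month; the
    payoff time is ``T_to / ((M_from - M_to) / 12)``.
    """
    m_from = annual_maintenance_total(from_m.maintenance, rates)
    m_to = annual_maintenance_total(to_m.maintenance, rates)
    diff = m_from - m_to
    if diff <= 0:
        raise ValueError(
            f"graduating {from_m.name!r} -> {to_m.name!r} never pays off: "
            f"maintenance differential {diff} per year is not positive"
        )
    T_to = training_total(to_m.training, rates)
    return T_to / (diff / _TWELVE)
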