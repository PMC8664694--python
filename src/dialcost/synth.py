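"""Random cost books with generator-side ground truth.

The generator emulates the structure of a real program cost book — a few
direct-HR lines that attract payroll overheads, an adjunct HR line that
does not, non-HR lines, a one-time training outlay and a training-duration
offset — purely so every stage of the engine can be property-tested
against values computed independently at generation time.  Draws are
uniform over the configured intervals; no claim of realism beyond the
structure is intended.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal
from typing import Dict, Tuple

import numpy as np

from .costbook import (
    AssistanceLevel,
    CalibrationRef,
    Category,
    CostBook,
    CostLine,
    MaintenanceProfile,
    Modality,
    OverheadRates,
    TrainingProfile,
    round_cents,
)

__all__ = ["SynthSpec", "GroundTruth", "random_costbook"]

_CENT = Decimal("0.01")


def _interval(name, lo, hi, allow_equal=True):
    if lo < 0 or hi < lo or (not allow_equal and hi == lo):
        raise ValueError(f"{name}: degenerate interval ({lo}, {hi})")


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the random cost-book generator.

    The comparator is generated last as a single-line modality whose
    monthly maintenance rate sits a random premium above the cheapest
    generated modality, so crossings against it exist and are non-trivial.
    """

    seed: int = 0
    n_modalities: int = 4
    n_hr_lines_range: Tuple[int, int] = (2, 5)
    hr_line_range: Tuple[float, float] = (500.0, 20000.0)
    non_hr_line_range: Tuple[float, float] = (100.0, 15000.0)
    training_range: Tuple[float, float] = (0.0, 25000.0)
    duration_range: Tuple[float, float] = (0.0, 2.0)
    rates: OverheadRates = field(default_factory=OverheadRates)
    comparator_rate_premium: Tuple[float, float] = (0.05, 0.8)

    def __post_init__(self):
        if self.n_modalities < 1:
            raise ValueError("n_modalities must be >= 1")
        _interval("n_hr_lines_range", *self.n_hr_lines_range)
        _interval("hr_line_range", *self.hr_line_range)
        _interval("non_hr_line_range", *self.non_hr_line_range)
        _interval("training_range", *self.training_range)
        _interval("duration_range", *self.duration_range)
        _interval("comparator_rate_premium", *self.comparator_rate_premium)


@dataclass(frozen=True)
class GroundTruth:
    """Expected quantities recorded while a modality was generated.

    Computed by straight-line arithmetic on the drawn numbers, not by the
    cost-book engine, so they serve as an independent oracle.
    """

    maintenance_total: Decimal
    training_total: Decimal
    upfront: Decimal
    duration_months: Decimal
    monthly_rate: Decimal

    def accumulated(self, t: float) -> float:
        """Oracle accumulated cost (float straight-line evaluation)."""
        return float(self.upfront) + float(self.monthly_rate) * max(
            0.0, float(t) - float(self.duration_months)
        )


def _draw_cents(rng, lo, hi) -> Decimal:
    return round_cents(Decimal(str(float(rng.uniform(lo, hi)))))


def random_costbook(spec: SynthSpec) -> Tuple[CostBook, Dict[str, GroundTruth]]:
    """Generate a reproducible random cost book and its ground truth.

    The same seed always yields the same book.  Each non-comparator
    modality gets direct-HR lines, one overhead-exempt adjunct line, two
    non-HR lines, a single training line and a training duration encoded as
    a calibration reference (so the calibration path is exercised); the
    ground truth records the exact totals and trajectory parameters.
    """
    rng = np.random.default_rng(spec.seed)
    b = spec.rates.benefit_rate
    v = spec.rates.vacation_relief_rate

    modalities: Dict[str, Modality] = {}
    truth: Dict[str, GroundTruth] = {}
    t_ref = Decimal(str(spec.duration_range[1] + 1.0))

    for i in range(spec.n_modalities):
        name = f"modality_{i:02d}"
        n_hr = int(rng.integers(spec.n_hr_lines_range[0], spec.n_hr_lines_range[1] + 1))
        hr_amounts = [_draw_cents(rng, *spec.hr_line_range) for _ in range(n_hr)]
        adjunct = _draw_cents(rng, *spec.non_hr_line_range)
        non_hr = [_draw_cents(rng, *spec.non_hr_line_range) for _ in range(2)]
        training_sub = _draw_cents(rng, *spec.training_range)
        duration = Decimal(str(round(float(rng.uniform(*spec.duration_range)), 6)))

        # independent straight-line ground truth
        hr_base = sum(hr_amounts, Decimal("0"))
        maintenance_total = (
            hr_base
            + adjunct
            + sum(non_hr, Decimal("0"))
            + round_cents(b * hr_base)
            + round_cents(v * hr_base)
        )
        training_total = (
            training_sub + round_cents(b * training_sub) + round_cents(v * training_sub)
        )
        monthly = maintenance_total / 12
        a_ref = training_total + monthly * (t_ref - duration)
        truth[name] = GroundTruth(
            maintenance_total, training_total, training_total, duration, monthly
        )

        lines = [
            CostLine(f"Staff role {j}", Category.DIRECT_HR, amt)
            for j, amt in enumerate(hr_amounts)
        ]
        lines.append(CostLine("Mileage and communications", Category.HR_ADJUNCT, adjunct))
        lines.append(CostLine("Medical supplies", Category.SUPPLIES_MEDICAL, non_hr[0]))
        lines.append(CostLine("Capital", Category.CAPITAL, non_hr[1]))
        maintenance = MaintenanceProfile(name, AssistanceLevel.SELF_CARE, Decimal(3), tuple(lines))
        training_lines = (
            (CostLine("Training nurse", Category.DIRECT_HR, training_sub),)
            if training_sub > 0
            else ()
        )
        training = TrainingProfile(
            training_lines,
            duration_months=None,
            calibration=CalibrationRef(a_ref, t_ref),
        )
        modalities[name] = Modality(maintenance, training)

    # comparator: no training, monthly rate a premium above the cheapest
    cheapest = min(gt.monthly_rate for gt in truth.values())
    premium = Decimal(str(float(rng.uniform(*spec.comparator_rate_premium))))
    comp_annual = round_cents(cheapest * (1 + premium) * 12)
    comp_line = CostLine("Facility care", Category.SUPPLIES_OTHER, comp_annual)
    modalities["comparator"] = Modality(
        MaintenanceProfile("comparator", AssistanceLevel.IN_CENTER, Decimal(3), (comp_line,)),
        TrainingProfile((), Decimal(0)),
    )
    truth["comparator"] = GroundTruth(
        comp_annual, Decimal("0"), Decimal("0"), Decimal("0"), comp_annual / 12
    )

    return CostBook(modalities, spec.rates, comparator="comparator"), truth
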