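"""Comparative analyses over a cost book.

Covers the downstream questions the cost model exists to answer: how much a
health system saves per year when a patient graduates from assisted to
self-care dialysis, how many months of therapy each home modality needs
before it undercuts facility-based care (with one-way sensitivity on the
facility cost), and what happens to a modality's cost structure when the
treatment schedule or the staffing model changes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import Decimal
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .costbook import (
    CostBook,
    MaintenanceProfile,
    Modality,
    OverheadRates,
    annual_maintenance_total,
    round_cents,
    scale_line,
)
from .trajectory import (
    CalibrationError,
    CrossingResult,
    Trajectory,
    crossing_time,
    trajectory_for,
)

__all__ = [
    "NeutralityRow",
    "FrequencyChange",
    "StaffSubstitution",
    "ScenarioSpec",
    "graduation_savings",
    "neutrality_table",
    "apply_scenario",
]


def graduation_savings(
    assisted: Modality, self_care: Modality, rates: OverheadRates
) -> Decimal:
    """Annual maintenance saving when a patient moves to self-care.

    The difference of the two annual maintenance totals, training excluded
    (graduation training is a one-time cost handled by
    :func:`dialcost.trajectory.payoff_time`).  Negative values mean the
    nominally assisted modality is actually cheaper to run.
    """
    return annual_maintenance_total(assisted.maintenance, rates) - annual_maintenance_total(
        self_care.maintenance, rates
    )


@dataclass(frozen=True)
class NeutralityRow:
    """One evaluated modality's cost-neutrality results vs the comparator."""

    evaluated: str
    comparator: str
    base_result: CrossingResult
    sensitivity_results: Dict[Decimal, CrossingResult]


def _as_factor(x) -> Decimal:
    f = Decimal(str(x)) if isinstance(x, float) else Decimal(x)
    if f <= 0:
        raise ValueError(f"sensitivity scale factor must be > 0, got {f}")
    return f


def neutrality_table(
    book: CostBook, scale_factors: Sequence = ()
) -> List[NeutralityRow]:
    """Cost-neutrality times of every modality against the comparator.

    For each non-comparator modality the base crossing is computed, plus
    one crossing per scale factor in which the comparator's monthly
    maintenance rate is multiplied by the factor (one-way sensitivity on
    the facility cost; the evaluated modality is left untouched, and the
    comparator carries no training cost to scale).
    """
    factors = [_as_factor(f) for f in scale_factors]
    comparator = trajectory_for(book[book.comparator], book.rates)

    missing = []
    trajectories: Dict[str, Trajectory] = {}
    for key in book.evaluated:
        try:
            trajectories[key] = trajectory_for(book[key], book.rates)
        except CalibrationError:
            missing.append(key)
    if missing:
        raise CalibrationError(
            "no training duration available (configured or calibrated) for: "
            + ", ".join(sorted(missing))
        )

    rows = []
    for key, traj in trajectories.items():
        sens = {}
        for f in factors:
            scaled = replace(comparator, monthly_rate=comparator.monthly_rate * f)
            sens[f] = crossing_time(traj, scaled)
        rows.append(NeutralityRow(key, book.comparator, crossing_time(traj, comparator), sens))
    return rows


@dataclass(frozen=True)
class FrequencyChange:
    """Change the treatment schedule to ``new_treatments_per_week``.

    Frequency-scaled lines (consumables, per-run charges, per-visit
    assistance staffing) are multiplied by the frequency ratio; fixed costs
    are unchanged.
    """

    new_treatments_per_week: Decimal

    def __post_init__(self):
        tpw = self.new_treatments_per_week
        tpw = Decimal(str(tpw)) if isinstance(tpw, float) else Decimal(tpw)
        if tpw <= 0:
            raise ValueError("new_treatments_per_week must be > 0")
        object.__setattr__(self, "new_treatments_per_week", tpw)


@dataclass(frozen=True)
class StaffSubstitution:
    """Replace staffing roles with cheaper (or costlier) ones.

    ``role_map`` pairs existing line labels with their replacement labels;
    each mapped line's amount is multiplied by ``wage_ratio`` (e.g. the
    health-care-aide to licensed-practical-nurse wage ratio, < 1 for a
    cost-saving substitution).  Overheads re-derive automatically because
    they are computed from the lines downstream.
    """

    role_map: Tuple[Tuple[str, str], ...]
    wage_ratio: Decimal

    def __post_init__(self):
        ratio = self.wage_ratio
        ratio = Decimal(str(ratio)) if isinstance(ratio, float) else Decimal(ratio)
        if ratio <= 0:
            raise ValueError("wage_ratio must be > 0")
        object.__setattr__(self, "wage_ratio", ratio)
        object.__setattr__(self, "role_map", tuple((str(a), str(b)) for a, b in self.role_map))


ScenarioSpec = Union[FrequencyChange, StaffSubstitution]


def apply_scenario(profile: MaintenanceProfile, spec: ScenarioSpec) -> MaintenanceProfile:
    """Return a new maintenance profile under a what-if scenario.

    The result is an ordinary profile: feeding it back through the cost
    book totals re-derives overheads on the adjusted lines.
    """
    if isinstance(spec, FrequencyChange):
        ratio = spec.new_treatments_per_week / profile.treatments_per_week
        lines = tuple(
            scale_line(l, ratio) if l.frequency_scaled else l for l in profile.lines
        )
        return replace(
            profile, treatments_per_week=spec.new_treatments_per_week, lines=lines
        )
    if isinstance(spec, StaffSubstitution):
        mapping = dict(spec.role_map)
        labels = {l.label for l in profile.lines}
        unknown = sorted(set(mapping) - labels)
        if unknown:
            raise ValueError(
                f"{profile.modality_name}: no such staffing line(s): {', '.join(unknown)}"
            )
        lines = tuple(
            scale_line(l, spec.wage_ratio, label=mapping[l.label])
            if l.label in mapping
            else l
            for l in profile.lines
        )
        return replace(profile, lines=lines)
    raise TypeError(f"unknown scenario spec: {spec!r}")
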