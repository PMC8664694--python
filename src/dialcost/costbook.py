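"""Cost books: per-modality line-item cost structures and derived totals.

A cost book describes each dialysis modality as a list of labelled annual
cost lines (staffing, supplies, drugs, equipment, capital, ...) plus a
one-time training cost structure.  Payroll overheads — employee benefits and
vacation/relief coverage — are not entered as lines; they are derived by
applying fixed multipliers to the direct human-resources subtotal, the way
hospital cost accounting reports them.  All amounts are per patient-year in
a single currency (the packaged data set uses real 2019 Canadian dollars)
and are held as :class:`decimal.Decimal` at cent precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from decimal import Decimal, InvalidOperation, ROUND_HALF_UP
from enum import Enum
from typing import Iterable, Mapping, Optional, Tuple

__all__ = [
    "Category",
    "AssistanceLevel",
    "CostLine",
    "OverheadRates",
    "MaintenanceProfile",
    "CalibrationRef",
    "TrainingProfile",
    "Modality",
    "CostBook",
    "as_money",
    "round_cents",
    "round_dollars",
    "derived_overheads",
    "annual_maintenance_total",
    "training_total",
]

_CENT = Decimal("0.01")
_DOLLAR = Decimal("1")


def as_money(value) -> Decimal:
    """Coerce a number or numeric string to a Decimal currency amount.

    Floats are converted through ``str`` so that ``19594.00`` becomes the
    decimal 19594.00 and not its binary approximation.
    """
    if isinstance(value, Decimal):
        return value
    if isinstance(value, float):
        return Decimal(str(value))
    try:
        return Decimal(value)
    except (InvalidOperation, TypeError, ValueError) as exc:
        raise ValueError(f"not a currency amount: {value!r}") from exc


def round_cents(value: Decimal) -> Decimal:
    """Round half-up to cent precision (the convention of payroll tables)."""
    return value.quantize(_CENT, rounding=ROUND_HALF_UP)


def round_dollars(value: Decimal) -> Decimal:
    """Round half-up to whole currency units, for text-style reporting."""
    return value.quantize(_DOLLAR, rounding=ROUND_HALF_UP)


class Category(str, Enum):
    """Cost-line category; drives overhead and scenario behaviour."""

    DIRECT_HR = "direct_hr"
    HR_ADJUNCT = "hr_adjunct"
    SUPPLIES_MEDICAL = "supplies_medical"
    SUPPLIES_OTHER = "supplies_other"
    DRUGS = "drugs"
    EQUIPMENT = "equipment"
    SUNDRY = "sundry"
    UTILITIES_OVERHEAD = "utilities_overhead"
    WATER = "water"
    CAPITAL = "capital"
    IN_CENTER_RUNS = "in_center_runs"


#: Categories whose cost scales with the number of treatments per week by
#: default (consumables and per-run charges).  Direct-HR lines for visiting
#: assistance staff also scale, but that is a per-line choice made in the
#: cost book, not a category default.
FREQUENCY_SCALED_CATEGORIES = frozenset(
    {Category.SUPPLIES_MEDICAL, Category.WATER, Category.IN_CENTER_RUNS}
)


class AssistanceLevel(str, Enum):
    SELF_CARE = "self_care"
    PARTIAL_ASSIST = "partial_assist"
    FULL_ASSIST = "full_assist"
    COMPLETE_CARE = "complete_care"
    IN_CENTER = "in_center"


@dataclass(frozen=True)
class CostLine:
    """One labelled annual cost item.

    Parameters
    ----------
    label : str
        Free-text row label, e.g. ``"Registered nurse"``.
    category : Category
        Determines whether the line feeds the payroll-overhead base
        (``direct_hr`` only) and its default scenario behaviour.
    annual_amount : Decimal
        Non-negative cost per patient-year, cent precision.
    frequency_scaled : bool, optional
        Whether the line scales with treatments per week in frequency
        scenarios.  Defaults by category (consumables and per-run charges
        scale; fixed costs do not); assistance-staff lines are typically
        flagged True explicitly.
    """

    label: str
    category: Category
    annual_amount: Decimal
    frequency_scaled: Optional[bool] = None

    def __post_init__(self):
        object.__setattr__(self, "category", Category(self.category))
        amount = as_money(self.annual_amount)
        if amount < 0:
            raise ValueError(f"cost line {self.label!r}: amount must be >= 0, got {amount}")
        if -amount.as_tuple().exponent > 2:
            raise ValueError(
                f"cost line {self.label!r}: amount {amount} has sub-cent precision"
            )
        object.__setattr__(self, "annual_amount", amount)
        if self.frequency_scaled is None:
            object.__setattr__(
                self, "frequency_scaled", self.category in FREQUENCY_SCALED_CATEGORIES
            )

    @property
    def multiplier_base(self) -> bool:
        """True iff the line enters the benefits/vacation multiplier base.

        Only direct human-resources lines do.  Adjunct HR expenditures
        (mileage, communications, parking) are wage-adjacent but carry no
        payroll overhead.
        """
        return self.category is Category.DIRECT_HR


@dataclass(frozen=True)
class OverheadRates:
    """Payroll overhead multipliers applied to the direct-HR subtotal.

    ``benefit_rate`` covers employer-paid benefits; ``vacation_relief_rate``
    covers vacation entitlements and relief staffing.  Both are dimensionless
    fractions in [0, 1).
    """

    benefit_rate: Decimal = Decimal("0.2015")
    vacation_relief_rate: Decimal = Decimal("0.1962")

    def __post_init__(self):
        for name in ("benefit_rate", "vacation_relief_rate"):
            value = getattr(self, name)
            if isinstance(value, float):
                value = Decimal(str(value))
            else:
                value = Decimal(value)
            if not (0 <= value < 1):
                raise ValueError(f"{name} must lie in [0, 1), got {value}")
            object.__setattr__(self, name, value)


def _check_unique_labels(lines: Iterable[CostLine], context: str) -> None:
    seen = set()
    for line in lines:
        if line.label in seen:
            raise ValueError(f"{context}: duplicate line label {line.label!r}")
        seen.add(line.label)


@dataclass(frozen=True)
class MaintenanceProfile:
    """A modality's recurring cost structure.

    ``treatments_per_week`` is the scheduled treatment frequency (3 for
    thrice-weekly hemodialysis, 7 for daily cycler peritoneal dialysis) and
    is the reference point for frequency scenarios.
    """

    modality_name: str
    assistance_level: AssistanceLevel
    treatments_per_week: Decimal
    lines: Tuple[CostLine, ...]

    def __post_init__(self):
        object.__setattr__(self, "assistance_level", AssistanceLevel(self.assistance_level))
        tpw = self.treatments_per_week
        tpw = Decimal(str(tpw)) if isinstance(tpw, float) else Decimal(tpw)
        if tpw <= 0:
            raise ValueError(f"{self.modality_name}: treatments_per_week must be > 0")
        object.__setattr__(self, "treatments_per_week", tpw)
        object.__setattr__(self, "lines", tuple(self.lines))
        _check_unique_labels(self.lines, self.modality_name)


@dataclass(frozen=True)
class CalibrationRef:
    """Reference point used to calibrate a training duration.

    The duration is chosen so that the modality's accumulated cost at
    ``at_months`` equals ``accumulated`` (see
    :func:`dialcost.trajectory.infer_training_duration`).
    """

    accumulated: Decimal
    at_months: Decimal

    def __post_init__(self):
        object.__setattr__(self, "accumulated", as_money(self.accumulated))
        at = self.at_months
        at = Decimal(str(at)) if isinstance(at, float) else Decimal(at)
        if at <= 0:
            raise ValueError("calibration reference time must be > 0 months")
        object.__setattr__(self, "at_months", at)


@dataclass(frozen=True)
class TrainingProfile:
    """A modality's one-time training cost structure.

    Training is delivered by staff, so every line is ``direct_hr`` and the
    same payroll overheads apply.  ``duration_months`` is the time from
    therapy start during which the patient trains and no maintenance cost
    accrues; if None, a :class:`CalibrationRef` must be supplied and the
    duration is fitted from it.
    """

    lines: Tuple[CostLine, ...] = ()
    duration_months: Optional[Decimal] = None
    calibration: Optional[CalibrationRef] = None

    def __post_init__(self):
        object.__setattr__(self, "lines", tuple(self.lines))
        _check_unique_labels(self.lines, "training")
        for line in self.lines:
            if line.category is not Category.DIRECT_HR:
                raise ValueError(
                    f"training line {line.label!r}: must be direct_hr, got {line.category.value}"
                )
        if self.duration_months is not None:
            d = self.duration_months
            d = Decimal(str(d)) if isinstance(d, float) else Decimal(d)
            if d < 0:
                raise ValueError("training duration must be >= 0 months")
            object.__setattr__(self, "duration_months", d)
        elif self.calibration is None:
            raise ValueError("training profile needs duration_months or a calibration reference")


@dataclass(frozen=True)
class Modality:
    """A dialysis modality: recurring maintenance plus one-time training."""

    maintenance: MaintenanceProfile
    training: TrainingProfile = field(default_factory=TrainingProfile)

    @property
    def name(self) -> str:
        return self.maintenance.modality_name


@dataclass(frozen=True)
class CostBook:
    """The full model input: modalities keyed by name, overhead rates and
    the comparator modality (facility-based care, by default in-center HD).
    """

    modalities: Mapping[str, Modality]
    rates: OverheadRates = field(default_factory=OverheadRates)
    comparator: str = "in_center_hd"

    def __post_init__(self):
        object.__setattr__(self, "modalities", dict(self.modalities))
        if self.comparator not in self.modalities:
            raise ValueError(f"comparator modality {self.comparator!r} not in cost book")

    def __getitem__(self, key: str) -> Modality:
        return self.modalities[key]

    def keys(self):
        return self.modalities.keys()

    @property
    def evaluated(self) -> Tuple[str, ...]:
        """Modality keys other than the comparator, in book order."""
        return tuple(k for k in self.modalities if k != self.comparator)


# ---------------------------------------------------------------------------
# Operations


def derived_overheads(
    lines: Iterable[CostLine], rates: OverheadRates
) -> Tuple[Decimal, Decimal]:
    """Benefits and vacation/relief amounts derived from direct-HR lines.

    Each is the corresponding rate times the direct-HR subtotal, rounded
    half-up to cents (matching how the derived rows appear in cost tables).
    Adjunct HR lines are excluded from the base.  An empty collection yields
    (0.00, 0.00).
    """
    base = sum((l.annual_amount for l in lines if l.multiplier_base), Decimal("0"))
    return (
        round_cents(rates.benefit_rate * base),
        round_cents(rates.vacation_relief_rate * base),
    )


def annual_maintenance_total(profile: MaintenanceProfile, rates: OverheadRates) -> Decimal:
    """Annual per-patient maintenance cost: all lines plus derived overheads."""
    benefits, vacation = derived_overheads(profile.lines, rates)
    return sum((l.annual_amount for l in profile.lines), Decimal("0")) + benefits + vacation


def training_total(profile: TrainingProfile, rates: OverheadRates) -> Decimal:
    """One-time training cost: direct-HR subtotal grossed up by overheads.

    Assembled as subtotal + round(b×subtotal) + round(v×subtotal), i.e. the
    derived rows are rounded to cents individually before summing.
    """
    subtotal = sum((l.annual_amount for l in profile.lines), Decimal("0"))
    benefits, vacation = derived_overheads(profile.lines, rates)
    return subtotal + benefits + vacation


def scale_line(line: CostLine, factor: Decimal, label: Optional[str] = None) -> CostLine:
    """Return a copy of ``line`` with its amount scaled (rounded to cents)."""
    return replace(
        line,
        label=line.label if label is None else label,
        annual_amount=round_cents(line.annual_amount * factor),
    )
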