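"""Model/Results interface over a cost book.

:class:`CostMinimizationModel` wraps a :class:`~dialcost.costbook.CostBook`;
``fit()`` derives every quantity the model reports — per-modality annual
maintenance and training totals with payroll overheads, accumulated-cost
trajectories (calibrating any training durations specified by reference
points), accumulated costs at the requested horizons, and the
cost-neutrality table with one-way sensitivity on the comparator — and
returns a :class:`CostMinimizationResults` carrying them.
"""

from __future__ import annotations

from decimal import Decimal
from typing import Dict, Optional, Sequence

import pandas as pd

from .costbook import (
    CostBook,
    Modality,
    annual_maintenance_total,
    derived_overheads,
    round_cents,
    round_dollars,
    training_total,
)
from .trajectory import (
    CrossingResult,
    CrossingStatus,
    Trajectory,
    accumulated_cost,
    crossing_time,
    payoff_time,
    trajectory_for,
)
from .analyses import (
    NeutralityRow,
    ScenarioSpec,
    apply_scenario,
    graduation_savings,
    neutrality_table,
)

__all__ = ["CostMinimizationModel", "CostMinimizationResults"]

_DEFAULT_TIMEPOINTS = (Decimal(3), Decimal(6), Decimal(12))
_DEFAULT_FACTORS = (Decimal("0.75"), Decimal("1.25"))


def _fmt_months(result: CrossingResult) -> str:
    """Render a crossing result the way neutrality tables print it."""
    if result.status is CrossingStatus.CROSSES_AT:
        return str(result.time_months.quantize(Decimal("0.01")))
    if result.status is CrossingStatus.ALWAYS_COSTLIER:
        return "comparator always less costly"
    if result.status is CrossingStatus.ALWAYS_CHEAPER:
        return "comparator always more costly"
    return "identical"


class CostMinimizationModel:
    """Deterministic cost-minimization model for dialysis modalities.

    Parameters
    ----------
    book : CostBook
        Modalities, overhead rates and the comparator.
    timepoints : sequence of months, optional
        Horizons at which accumulated costs are reported (default 3, 6, 12).
    sensitivity_factors : sequence of positive scale factors, optional
        One-way sensitivity factors applied to the comparator's monthly
        maintenance rate in the neutrality table (default 0.75 and 1.25,
        i.e. facility cost varied by +/-25%).
    """

    def __init__(
        self,
        book: CostBook,
        timepoints: Sequence = _DEFAULT_TIMEPOINTS,
        sensitivity_factors: Sequence = _DEFAULT_FACTORS,
    ):
        self.book = book
        self.timepoints = tuple(
            Decimal(str(t)) if isinstance(t, float) else Decimal(t) for t in timepoints
        )
        self.sensitivity_factors = tuple(
            Decimal(str(f)) if isinstance(f, float) else Decimal(f)
            for f in sensitivity_factors
        )

    @classmethod
    def from_config(cls, path, **kwargs) -> "CostMinimizationModel":
        """Build a model from a YAML/JSON cost-book configuration file."""
        from .io import load_costbook

        return cls(load_costbook(path), **kwargs)

    def fit(self) -> "CostMinimizationResults":
        """Derive totals, calibrate trajectories and solve cost neutrality."""
        book = self.book
        trajectories = {
            key: trajectory_for(mod, book.rates) for key, mod in book.modalities.items()
        }
        return CostMinimizationResults(self, trajectories)


class CostMinimizationResults:
    """Fitted quantities of a :class:`CostMinimizationModel`.

    Attributes
    ----------
    trajectories : dict of str -> Trajectory
        Calibrated accumulated-cost curves per modality.
    maintenance_totals : pandas.Series
        Annual per-patient maintenance cost (float, currency/year).
    training_totals : pandas.Series
        One-time training cost per modality (float, currency).
    durations : pandas.Series
        Training durations in months (calibrated where configured so).
    """

    def __init__(self, model: CostMinimizationModel, trajectories: Dict[str, Trajectory]):
        self.model = model
        self.book = model.book
        self.trajectories = trajectories
        keys = list(self.book.modalities)
        self.maintenance_totals = pd.Series(
            {k: float(annual_maintenance_total(self.book[k].maintenance, self.book.rates)) for k in keys},
            name="annual_maintenance",
        )
        self.training_totals = pd.Series(
            {k: float(training_total(self.book[k].training, self.book.rates)) for k in keys},
            name="training_total",
        )
        self.durations = pd.Series(
            {k: float(trajectories[k].duration_months) for k in keys},
            name="training_duration_months",
        )

    # -- tables -----------------------------------------------------------

    def maintenance_table(self) -> pd.DataFrame:
        """Line-item maintenance costs per modality with derived overheads.

        Mirrors a program cost table: one column per modality, line labels
        as rows, then derived Benefits and Vacation/relief rows and the
        annual total.
        """
        book = self.book
        columns = {}
        for key, mod in book.modalities.items():
            col = {l.label: float(l.annual_amount) for l in mod.maintenance.lines}
            benefits, vacation = derived_overheads(mod.maintenance.lines, book.rates)
            col["Benefits"] = float(benefits)
            col["Vacation and relief"] = float(vacation)
            col["Total"] = float(annual_maintenance_total(mod.maintenance, book.rates))
            columns[key] = col
        return pd.DataFrame(columns).fillna(0.0)

    def training_table(self) -> pd.DataFrame:
        """Training cost lines per modality with overheads and totals."""
        book = self.book
        columns = {}
        for key, mod in book.modalities.items():
            col = {l.label: float(l.annual_amount) for l in mod.training.lines}
            benefits, vacation = derived_overheads(mod.training.lines, book.rates)
            col["Benefits"] = float(benefits)
            col["Relief hours and vacation"] = float(vacation)
            col["Total"] = float(training_total(mod.training, book.rates))
            columns[key] = col
        return pd.DataFrame(columns).fillna(0.0)

    def accumulated(self, timepoints: Optional[Sequence] = None) -> pd.DataFrame:
        """Accumulated cost per modality at the given months (rows=months)."""
        times = self.model.timepoints if timepoints is None else [
            Decimal(str(t)) if isinstance(t, float) else Decimal(t) for t in timepoints
        ]
        data = {
            key: [float(accumulated_cost(traj, t)) for t in times]
            for key, traj in self.trajectories.items()
        }
        return pd.DataFrame(data, index=[float(t) for t in times]).rename_axis("months")

    def neutrality(self, scale_factors: Optional[Sequence] = None) -> pd.DataFrame:
        """Cost-neutrality table vs the comparator, months to two decimals.

        Crossing times appear as numbers-as-text; dominance appears as
        explanatory text, following the convention of published neutrality
        tables.
        """
        factors = (
            self.model.sensitivity_factors if scale_factors is None else scale_factors
        )
        rows = self.neutrality_rows(factors)
        records = []
        for row in rows:
            rec = {
                "evaluated": row.evaluated,
                "comparator": row.comparator,
                "months": _fmt_months(row.base_result),
            }
            for f, res in row.sensitivity_results.items():
                rec[f"months_x{f}"] = _fmt_months(res)
            records.append(rec)
        return pd.DataFrame.from_records(records)

    def neutrality_rows(self, scale_factors: Optional[Sequence] = None):
        """Structured neutrality results (list of :class:`NeutralityRow`)."""
        factors = (
            self.model.sensitivity_factors if scale_factors is None else scale_factors
        )
        return neutrality_table(self.book, factors)

    # -- scalar analyses --------------------------------------------------

    def graduation_savings(self, assisted: str, self_care: str) -> Decimal:
        """Annual maintenance saving of graduating to self-care (currency)."""
        return graduation_savings(
            self.book[assisted], self.book[self_care], self.book.rates
        )

    def payoff_time(self, from_key: str, to_key: str) -> Decimal:
        """Months to recoup the target modality's training via lower
        maintenance after switching."""
        return payoff_time(self.book[from_key], self.book[to_key], self.book.rates)

    def crossing(self, a: str, b: str) -> CrossingResult:
        """Crossing of two fitted modality trajectories."""
        return crossing_time(self.trajectories[a], self.trajectories[b])

    def scenario(self, spec: ScenarioSpec, modalities: Optional[Sequence[str]] = None) -> pd.DataFrame:
        """Annual maintenance totals before/after a what-if scenario.

        Applies the scenario to each selected modality's maintenance
        profile and re-derives totals (overheads included) on the adjusted
        lines.
        """
        keys = list(self.book.modalities) if modalities is None else list(modalities)
        records = []
        for key in keys:
            base = annual_maintenance_total(self.book[key].maintenance, self.book.rates)
            adjusted_profile = apply_scenario(self.book[key].maintenance, spec)
            adjusted = annual_maintenance_total(adjusted_profile, self.book.rates)
            records.append(
                {
                    "modality": key,
                    "annual_maintenance": float(base),
                    "annual_maintenance_scenario": float(adjusted),
                    "delta": float(adjusted - base),
                }
            )
        return pd.DataFrame.from_records(records).set_index("modality")

    # -- presentation -----------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary: totals, durations and the neutrality table."""
        book = self.book
        head = pd.DataFrame(
            {
                "maintenance/yr": self.maintenance_totals.map(lambda v: f"{v:,.2f}"),
                "training": self.training_totals.map(lambda v: f"{v:,.2f}"),
                "train months": self.durations.map(lambda v: f"{v:.3f}"),
            }
        )
        parts = [
            "Cost-minimization model",
            f"comparator: {book.comparator}   "
            f"overheads: benefits {book.rates.benefit_rate}, "
            f"vacation/relief {book.rates.vacation_relief_rate}",
            "",
            head.to_string(),
            "",
            "Months of therapy to cost neutrality vs comparator:",
            self.neutrality().to_string(index=False),
        ]
        return "\n".join(parts)

    def plot_accumulated(self, modalities: Optional[Sequence[str]] = None, horizon=12, ax=None):
        """Plot accumulated-cost curves over [0, horizon] months."""
        import matplotlib.pyplot as plt
        import numpy as np

        if ax is None:
            _, ax = plt.subplots()
        keys = list(self.trajectories) if modalities is None else list(modalities)
        t = np.linspace(0.0, float(horizon), 241)
        for key in keys:
            traj = self.trajectories[key]
            a = float(traj.upfront) + float(traj.monthly_rate) * np.maximum(
                0.0, t - float(traj.duration_months)
            )
            ax.plot(t, a, label=key)
        ax.set_xlabel("months of therapy")
        ax.set_ylabel("accumulated cost")
        ax.legend(fontsize="small")
        return ax
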