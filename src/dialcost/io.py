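"""Reading, validating and writing cost-book configurations; CSV export.

The configuration is a structured-text file (YAML or JSON, detected by
extension) with the shape::

    schema_version: 1
    rates: {benefit_rate: "0.2015", vacation_relief_rate: "0.1962"}
    comparator: in_center_hd
    modalities:
      - name: in_center_hd
        assistance_level: in_center
        treatments_per_week: 3
        maintenance:
          - {label: Registered nurse, category: direct_hr, amount: "19594.00"}
        training:
          duration_months: 0
          lines: []

A modality that trains patients before maintenance starts may instead give
``duration_months: calibrate`` plus ``calibration: {accumulated: "...",
at_months: 3}``; the duration is then fitted so the accumulated cost hits
the reference point.  Amounts are decimal strings or numbers with at most
two fraction digits; the decimal separator is always a dot and thousands
separators are rejected.

Validation collects every problem before failing, so a bad file reports all
its errors at once with field context.
"""

from __future__ import annotations

import json
from decimal import Decimal, InvalidOperation
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
import yaml

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
)
from .trajectory import CalibrationError, trajectory_for

__all__ = [
    "SCHEMA_VERSION",
    "CostBookValidationError",
    "load_costbook",
    "dump_costbook",
    "export_tables",
]

SCHEMA_VERSION = 1

_KNOWN_TOP = {"schema_version", "rates", "comparator", "modalities"}
_KNOWN_MODALITY = {
    "name",
    "display_name",
    "assistance_level",
    "treatments_per_week",
    "maintenance",
    "training",
}
_KNOWN_LINE = {"label", "category", "amount", "frequency_scaled"}
_KNOWN_TRAINING = {"lines", "duration_months", "calibration"}


class CostBookValidationError(ValueError):
    """Raised with the full list of configuration problems."""

    def __init__(self, errors: List[str]):
        self.errors = list(errors)
        super().__init__("invalid cost book:\n" + "\n".join(f"  - {e}" for e in self.errors))


def _parse_amount(raw, where: str, errors: List[str]) -> Optional[Decimal]:
    if isinstance(raw, bool) or raw is None:
        errors.append(f"{where}: amount must be a number or decimal string, got {raw!r}")
        return None
    text = str(raw)
    if "," in text or "_" in text or " " in text.strip():
        errors.append(f"{where}: thousands separators are not accepted: {raw!r}")
        return None
    try:
        value = Decimal(text)
    except InvalidOperation:
        errors.append(f"{where}: cannot parse amount {raw!r}")
        return None
    if value < 0:
        errors.append(f"{where}: amount must be non-negative, got {value}")
        return None
    if -value.as_tuple().exponent > 2:
        errors.append(f"{where}: amount {value} has more than 2 fraction digits")
        return None
    return value


def _parse_line(raw, where: str, errors: List[str], warn) -> Optional[CostLine]:
    if not isinstance(raw, dict):
        errors.append(f"{where}: expected a mapping, got {type(raw).__name__}")
        return None
    for key in set(raw) - _KNOWN_LINE:
        warn(f"{where}: unknown key {key!r} ignored")
    label = raw.get("label")
    if not label:
        errors.append(f"{where}: missing label")
        return None
    where = f"{where} ({label})"
    try:
        category = Category(raw.get("category"))
    except ValueError:
        errors.append(
            f"{where}: unknown category {raw.get('category')!r}; expected one of "
            + ", ".join(c.value for c in Category)
        )
        return None
    amount = _parse_amount(raw.get("amount"), where, errors)
    if amount is None:
        return None
    try:
        return CostLine(str(label), category, amount, raw.get("frequency_scaled"))
    except ValueError as exc:
        errors.append(f"{where}: {exc}")
        return None


def _parse_modality(raw, idx: int, errors: List[str], warn) -> Optional[Modality]:
    where = f"modalities[{idx}]"
    if not isinstance(raw, dict):
        errors.append(f"{where}: expected a mapping")
        return None
    name = raw.get("name")
    if not name:
        errors.append(f"{where}: missing name")
        return None
    where = f"modality {name!r}"
    for key in set(raw) - _KNOWN_MODALITY:
        warn(f"{where}: unknown key {key!r} ignored")
    local: List[str] = []

    try:
        level = AssistanceLevel(raw.get("assistance_level"))
    except ValueError:
        local.append(
            f"{where}: unknown assistance_level {raw.get('assistance_level')!r}"
        )
        level = None

    maintenance_lines = []
    raw_lines = raw.get("maintenance", [])
    if not isinstance(raw_lines, list):
        local.append(f"{where}: maintenance must be a list of lines")
        raw_lines = []
    for i, raw_line in enumerate(raw_lines):
        line = _parse_line(raw_line, f"{where}.maintenance[{i}]", local, warn)
        if line is not None:
            maintenance_lines.append(line)

    training_raw = raw.get("training") or {}
    if not isinstance(training_raw, dict):
        local.append(f"{where}: training must be a mapping")
        training_raw = {}
    for key in set(training_raw) - _KNOWN_TRAINING:
        warn(f"{where}.training: unknown key {key!r} ignored")
    training_lines = []
    for i, raw_line in enumerate(training_raw.get("lines") or []):
        line = _parse_line(raw_line, f"{where}.training.lines[{i}]", local, warn)
        if line is not None:
            training_lines.append(line)

    duration = training_raw.get("duration_months", 0)
    calibration = None
    if isinstance(duration, str) and duration.strip().lower() == "calibrate":
        duration = None
        raw_cal = training_raw.get("calibration")
        if not isinstance(raw_cal, dict):
            local.append(f"{where}.training: duration 'calibrate' needs a calibration mapping")
        else:
            acc = _parse_amount(
                raw_cal.get("accumulated"), f"{where}.training.calibration", local
            )
            at = raw_cal.get("at_months")
            try:
                at = Decimal(str(at))
            except (InvalidOperation, TypeError):
                local.append(f"{where}.training.calibration: bad at_months {at!r}")
                at = None
            if acc is not None and at is not None:
                try:
                    calibration = CalibrationRef(acc, at)
                except ValueError as exc:
                    local.append(f"{where}.training.calibration: {exc}")

    if local:
        errors.extend(local)
        return None
    try:
        maintenance = MaintenanceProfile(
            str(name), level, Decimal(str(raw.get("treatments_per_week", 3))), tuple(maintenance_lines)
        )
        training = TrainingProfile(tuple(training_lines), duration, calibration)
        return Modality(maintenance, training)
    except (ValueError, InvalidOperation) as exc:
        errors.append(f"{where}: {exc}")
        return None


def load_costbook(path, warn=None) -> CostBook:
    """Load and validate a cost-book configuration file.

    Calibrated training durations are resolved eagerly so an unresolvable
    reference point fails here, naming the modality.  ``warn`` (callable
    taking a message) receives non-fatal notices such as unknown keys;
    by default they go to ``logging``.
    """
    import logging

    if warn is None:
        warn = logging.getLogger(__name__).warning
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise CostBookValidationError(["top level must be a mapping"])

    errors: List[str] = []
    for key in set(raw) - _KNOWN_TOP:
        warn(f"unknown top-level key {key!r} ignored")
    version = raw.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        warn(f"schema_version {version!r} differs from supported {SCHEMA_VERSION}; proceeding")

    rates_raw = raw.get("rates") or {}
    try:
        rates = OverheadRates(
            Decimal(str(rates_raw.get("benefit_rate", "0.2015"))),
            Decimal(str(rates_raw.get("vacation_relief_rate", "0.1962"))),
        )
    except (ValueError, InvalidOperation) as exc:
        errors.append(f"rates: {exc}")
        rates = OverheadRates()

    modalities: Dict[str, Modality] = {}
    raw_modalities = raw.get("modalities")
    if not isinstance(raw_modalities, list) or not raw_modalities:
        errors.append("modalities: at least one modality block is required")
        raw_modalities = []
    for idx, raw_mod in enumerate(raw_modalities):
        mod = _parse_modality(raw_mod, idx, errors, warn)
        if mod is not None:
            if mod.name in modalities:
                errors.append(f"duplicate modality name {mod.name!r}")
            else:
                modalities[mod.name] = mod

    comparator = raw.get("comparator")
    if not comparator:
        errors.append("missing comparator key")
    elif comparator not in modalities:
        errors.append(f"comparator {comparator!r} is not a defined modality")

    if errors:
        raise CostBookValidationError(errors)

    book = CostBook(modalities, rates, str(comparator))
    # resolve calibrated durations now so inconsistent references fail at load
    for key, mod in book.modalities.items():
        if mod.training.duration_months is None:
            try:
                trajectory_for(mod, book.rates)
            except CalibrationError as exc:
                errors.append(str(exc))
    if errors:
        raise CostBookValidationError(errors)
    return book


def dump_costbook(book: CostBook, path) -> Path:
    """Write a cost book back to YAML (or JSON by extension).

    Round-trips with :func:`load_costbook`: amounts are emitted as decimal
    strings with two fraction digits and calibration references are
    preserved rather than baked into resolved durations.
    """
    def line_dict(line: CostLine) -> dict:
        return {
            "label": line.label,
            "category": line.category.value,
            "amount": str(line.annual_amount),
            "frequency_scaled": line.frequency_scaled,
        }

    doc = {
        "schema_version": SCHEMA_VERSION,
        "rates": {
            "benefit_rate": str(book.rates.benefit_rate),
            "vacation_relief_rate": str(book.rates.vacation_relief_rate),
        },
        "comparator": book.comparator,
        "modalities": [],
    }
    for key, mod in book.modalities.items():
        training: dict = {"lines": [line_dict(l) for l in mod.training.lines]}
        if mod.training.duration_months is not None:
            training["duration_months"] = str(mod.training.duration_months)
        else:
            ref = mod.training.calibration
            training["duration_months"] = "calibrate"
            training["calibration"] = {
                "accumulated": str(ref.accumulated),
                "at_months": str(ref.at_months),
            }
        doc["modalities"].append(
            {
                "name": key,
                "assistance_level": mod.maintenance.assistance_level.value,
                "treatments_per_week": str(mod.maintenance.treatments_per_week),
                "maintenance": [line_dict(l) for l in mod.maintenance.lines],
                "training": training,
            }
        )
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(doc, indent=2), encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")
    return path


def export_tables(
    book: CostBook,
    out_dir,
    timepoints: Sequence = (3, 6, 12),
    scale_factors: Sequence = (),
) -> Dict[str, Path]:
    """Write the model's result tables as CSV files.

    Produces ``maintenance.csv`` (line items, derived overheads, totals per
    modality), ``training.csv``, ``accumulated.csv`` (accumulated cost at
    the requested months) and ``neutrality.csv`` (months to cost neutrality
    vs the comparator, with one sensitivity column per scale factor).
    UTF-8, two-decimal amounts, dominance statuses as text.
    """
    from .model import CostMinimizationModel

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    res = CostMinimizationModel(
        book, timepoints=timepoints, sensitivity_factors=scale_factors
    ).fit()

    paths = {}

    def write(name: str, frame: pd.DataFrame, index_label=None, float_format="%.2f"):
        p = out_dir / name
        frame.to_csv(p, index_label=index_label, float_format=float_format, encoding="utf-8")
        paths[name] = p

    write("maintenance.csv", res.maintenance_table(), index_label="line")
    write("training.csv", res.training_table(), index_label="line")
    write("accumulated.csv", res.accumulated(), index_label="months")
    neutrality = res.neutrality().set_index("evaluated")
    write("neutrality.csv", neutrality, index_label="evaluated")
    return paths
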