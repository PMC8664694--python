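"""Packaged cost books."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .costbook import CostBook
from .io import load_costbook

__all__ = ["manitoba_2019", "manitoba_2019_path"]


def manitoba_2019_path():
    """Path-like handle to the packaged Manitoba 2019 cost-book file."""
    return resources.files(__package__) / "data" / "manitoba_2019.yaml"


def manitoba_2019() -> CostBook:
    """The Manitoba single-payer dialysis cost book (2019 Canadian dollars).

    Nine modalities — in-center HD (the comparator, no training cost),
    self-care CAPD/CCPD, conventional home HD, and the assisted home HD and
    CCPD variants — with line-item maintenance and training costs, payroll
    overhead rates, and training durations calibrated from accumulated
    costs at 3 months of therapy.
    """
    with resources.as_file(manitoba_2019_path()) as path:
        return load_costbook(Path(path))
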