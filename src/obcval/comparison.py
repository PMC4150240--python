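"""Comparison (severity) score: ADOS-2 totals mapped to a 1-10 scale.

Subjects are separated into cells by age band and verbal level; within each
cell the ADOS-2 total is looked up in a monotone table.  A score of 1 means
minimal-to-no evidence of autism-related symptoms and 10 a high level of
impairment.  The calibrated published tables are proprietary instrument
content, so the package ships a synthetic default table (linear decile
binning of totals within each cell) that preserves the structural contract —
range 1-10, monotone in total, age-by-verbal-level cells — without
reproducing any published calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .config import VERBAL_LEVELS
from .sheets import ValidationError


@dataclass(frozen=True)
class ComparisonCell:
    age_lo: float
    age_hi: float  # half-open band [age_lo, age_hi)
    verbal_level: str
    mapping: dict[int, int]

    def __post_init__(self) -> None:
        if self.verbal_level not in VERBAL_LEVELS:
            raise ValidationError(f"unknown verbal level {self.verbal_level!r}")
        if not (self.age_lo < self.age_hi):
            raise ValidationError(
                f"empty age band [{self.age_lo}, {self.age_hi})")
        object.__setattr__(self, "mapping", {int(k): int(v) for k, v in self.mapping.items()})
        last = None
        for total in sorted(self.mapping):
            score = self.mapping[total]
            if not 1 <= score <= 10:
                raise ValidationError(
                    f"comparison score {score} for total {total} outside 1..10")
            if last is not None and score < last:
                raise ValidationError(
                    f"comparison mapping decreases at total {total}")
            last = score

    def contains(self, age_years: float, verbal_level: str) -> bool:
        return (self.verbal_level == verbal_level
                and self.age_lo <= age_years < self.age_hi)


@dataclass
class ComparisonTable:
    cells: list[ComparisonCell] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cells = list(self.cells)
        for level in VERBAL_LEVELS:
            bands = sorted((c.age_lo, c.age_hi) for c in self.cells
                           if c.verbal_level == level)
            for (lo1, hi1), (lo2, hi2) in zip(bands, bands[1:]):
                if lo2 < hi1:
                    raise ValidationError(
                        f"overlapping age bands [{lo1},{hi1}) and [{lo2},{hi2}) "
                        f"for verbal level {level!r}")

    def lookup_cell(self, age_years: float, verbal_level: str) -> ComparisonCell:
        for cell in self.cells:
            if cell.contains(age_years, verbal_level):
                return cell
        raise ValidationError(
            f"age {age_years} / verbal level {verbal_level!r} outside all "
            f"configured comparison-table cells")


def comparison_score(total: int, age_years: float, verbal_level: str,
                     table: ComparisonTable) -> int:
    """Look up the 1-10 comparison score for an ADOS-2 total."""
    cell = table.lookup_cell(age_years, verbal_level)
    if total not in cell.mapping:
        raise ValidationError(
            f"total {total} outside the mapped domain of the comparison cell "
            f"[{cell.age_lo},{cell.age_hi})/{cell.verbal_level}")
    return cell.mapping[total]


def load_comparison_table(path) -> ComparisonTable:
    """Load and validate a comparison table from YAML.

    Expected layout::

        cells:
          - {age_lo: 0.0, age_hi: 5.0, verbal_level: some_words,
             map: {0: 1, 1: 1, ...}}
    """
    with open(path, encoding="utf-8") as handle:
        data = yaml.safe_load(handle) or {}
    cells = []
    for raw in data.get("cells", []):
        cells.append(ComparisonCell(
            age_lo=float(raw["age_lo"]),
            age_hi=float(raw["age_hi"]),
            verbal_level=str(raw["verbal_level"]),
            mapping=raw["map"],
        ))
    return ComparisonTable(cells=cells)


def save_comparison_table(table: ComparisonTable, path) -> None:
    data = {"cells": [
        {"age_lo": c.age_lo, "age_hi": c.age_hi, "verbal_level": c.verbal_level,
         "map": dict(sorted(c.mapping.items()))}
        for c in table.cells]}
    with open(path, "w", encoding="utf-8") as handle:
        yaml.safe_dump(data, handle, sort_keys=False)


def default_comparison_table(max_total: int = 28, age_lo: float = 0.0,
                             age_hi: float = 21.0,
                             band_split: float = 5.0) -> ComparisonTable:
    """Synthetic default table: linear decile binning of totals per cell.

    Two age bands per verbal level ([age_lo, band_split) and
    [band_split, age_hi)) with an identical linear mapping, so the table
    exercises the cell machinery while remaining self-evidently uncalibrated.
    """
    mapping = {t: 1 + (t * 10) // (max_total + 1) for t in range(max_total + 1)}
    cells = [
        ComparisonCell(lo, hi, level, dict(mapping))
        for level in VERBAL_LEVELS
        for lo, hi in ((age_lo, band_split), (band_split, age_hi))
    ]
    return ComparisonTable(cells=cells)
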