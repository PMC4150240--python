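"""Data model and I/O for ADOS Module 1 score sheets and cohorts.

A Module 1 score sheet records 29 ordinal item codes for one child, plus
demographics and (optionally) a best-estimate clinical diagnosis.  Raw item
codes live in {0, 1, 2, 3, 7, 8}: 0-3 grade increasing abnormality, 7 marks
an abnormality of a different kind and 8 means the item was not applicable.
All scoring algorithms operate on *recoded* codes in {0, 1, 2} (3 -> 2,
7/8 -> 0).

Cohorts round-trip losslessly through a plain CSV dialect (one row per
subject; one column per item id; blank clinical_dx means missing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

# Standard Module 1 item lettering: 8 A-items (language/communication),
# 12 B-items (reciprocal social interaction), 2 C-items (play),
# 4 D-items (stereotyped behaviors), 3 E-items (other abnormal behaviors).
ITEM_IDS: tuple[str, ...] = (
    tuple(f"A{i}" for i in range(1, 9))
    + tuple(f"B{i}" for i in range(1, 13))
    + tuple(f"C{i}" for i in range(1, 3))
    + tuple(f"D{i}" for i in range(1, 5))
    + tuple(f"E{i}" for i in range(1, 4))
)
assert len(ITEM_IDS) == 29

RAW_CODES = frozenset({0, 1, 2, 3, 7, 8})
GENDERS = ("male", "female", "unknown")
DX_LABELS = ("spectrum", "non_spectrum")

SPECTRUM = "spectrum"
NON_SPECTRUM = "non_spectrum"


class ValidationError(ValueError):
    """A score sheet, cohort or configuration violated an invariant."""


def recode_item(raw_code: int, *, special_recode: Mapping[int, int] | None = None,
                three_recode: Mapping[int, int] | None = None) -> int:
    """Map a raw item code to the algorithm code used by every instrument.

    Default mapping: 3 -> 2, 7 -> 0, 8 -> 0, and 0/1/2 pass through, so the
    result is always in {0, 1, 2}.  The special-code mapping is overridable
    because 7/8 handling is a scoring convention, not part of the published
    cutoff rules.
    """
    if raw_code not in RAW_CODES:
        raise ValidationError(f"raw item code {raw_code!r} not in {sorted(RAW_CODES)}")
    special = {7: 0, 8: 0} if special_recode is None else dict(special_recode)
    threes = {3: 2} if three_recode is None else dict(three_recode)
    if raw_code in special:
        return special[raw_code]
    if raw_code in threes:
        return threes[raw_code]
    return raw_code


@dataclass(frozen=True)
class ScoreSheet:
    """One subject's Module 1 item codes plus demographics.

    ``items`` must contain exactly the 29 Module 1 item ids, each with a raw
    code in {0, 1, 2, 3, 7, 8}.  ``clinical_dx`` is the external best-estimate
    clinical label where one exists.
    """

    subject_id: str
    age_years: float
    gender: str
    items: Mapping[str, int]
    clinical_dx: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise ValidationError("subject_id must be a non-empty string")
        if not (self.age_years >= 0):
            raise ValidationError(
                f"subject {self.subject_id}: age_years must be >= 0, got {self.age_years}")
        if self.gender not in GENDERS:
            raise ValidationError(
                f"subject {self.subject_id}: gender {self.gender!r} not in {GENDERS}")
        if self.clinical_dx is not None and self.clinical_dx not in DX_LABELS:
            raise ValidationError(
                f"subject {self.subject_id}: clinical_dx {self.clinical_dx!r} "
                f"not in {DX_LABELS} or missing")
        missing = set(ITEM_IDS) - set(self.items)
        extra = set(self.items) - set(ITEM_IDS)
        if missing or extra:
            raise ValidationError(
                f"subject {self.subject_id}: items must cover exactly the 29 "
                f"Module 1 ids (missing={sorted(missing)}, unknown={sorted(extra)})")
        for item_id in ITEM_IDS:
            code = self.items[item_id]
            if code not in RAW_CODES:
                raise ValidationError(
                    f"subject {self.subject_id}, item {item_id}: code {code!r} "
                    f"not in {sorted(RAW_CODES)}")
        object.__setattr__(self, "items", dict(self.items))

    def recoded(self, item_id: str) -> int:
        return recode_item(self.items[item_id])


@dataclass
class Cohort:
    """An ordered collection of score sheets with unique subject ids."""

    sheets: list[ScoreSheet] = field(default_factory=list)
    source_tag: str = ""

    def __post_init__(self) -> None:
        self.sheets = list(self.sheets)
        seen: set[str] = set()
        for sheet in self.sheets:
            if sheet.subject_id in seen:
                raise ValidationError(f"duplicate subject_id {sheet.subject_id!r}")
            seen.add(sheet.subject_id)

    def __len__(self) -> int:
        return len(self.sheets)

    def __iter__(self):
        return iter(self.sheets)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return self.sheets == other.sheets and self.source_tag == other.source_tag


_META_COLUMNS = ("subject_id", "age_years", "gender", "clinical_dx")


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as UTF-8 CSV in the dialect :func:`read_cohort` accepts."""
    rows = []
    for sheet in cohort:
        row: dict[str, object] = {
            "subject_id": sheet.subject_id,
            "age_years": repr(float(sheet.age_years)),
            "gender": sheet.gender,
            "clinical_dx": sheet.clinical_dx or "",
        }
        for item_id in ITEM_IDS:
            row[item_id] = sheet.items[item_id]
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(_META_COLUMNS) + list(ITEM_IDS))
    frame.to_csv(path, index=False)


def read_cohort(path, *, source_tag: str | None = None,
                missing_as_zero: bool = False) -> Cohort:
    """Read a cohort CSV, validating every cell.

    Blank ``clinical_dx`` cells mean the clinical label is missing.  Blank
    item cells are a hard error unless ``missing_as_zero`` is set, in which
    case each imputed cell is logged as a warning (the study design assumes
    complete score sheets, so imputation is strictly opt-in).
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for column in list(_META_COLUMNS) + list(ITEM_IDS):
        if column not in frame.columns:
            raise ValidationError(f"{path}: missing required column {column!r}")
    sheets = []
    for row_idx, row in enumerate(frame.itertuples(index=False), start=2):
        record = dict(zip(frame.columns, row))
        items: dict[str, int] = {}
        for item_id in ITEM_IDS:
            cell = record[item_id].strip()
            if cell == "":
                if missing_as_zero:
                    logger.warning(
                        "%s line %d: imputing missing item %s as 0 for subject %s",
                        path, row_idx, item_id, record["subject_id"])
                    items[item_id] = 0
                    continue
                raise ValidationError(
                    f"{path} line {row_idx}, column {item_id}: missing item code "
                    f"for subject {record['subject_id']!r}")
            try:
                code = int(cell)
            except ValueError:
                raise ValidationError(
                    f"{path} line {row_idx}, column {item_id}: "
                    f"non-integer code {cell!r}") from None
            if code not in RAW_CODES:
                raise ValidationError(
                    f"{path} line {row_idx}, column {item_id}: code {code} "
                    f"not in {sorted(RAW_CODES)}")
            items[item_id] = code
        try:
            age = float(record["age_years"]) if record["age_years"].strip() else -1.0
        except ValueError:
            raise ValidationError(
                f"{path} line {row_idx}, column age_years: "
                f"non-numeric value {record['age_years']!r}") from None
        dx = record["clinical_dx"].strip() or None
        try:
            sheets.append(ScoreSheet(
                subject_id=record["subject_id"],
                age_years=age,
                gender=record["gender"].strip(),
                items=items,
                clinical_dx=dx,
            ))
        except ValidationError as exc:
            raise ValidationError(f"{path} line {row_idx}: {exc}") from None
    tag = source_tag if source_tag is not None else str(path)
    return Cohort(sheets=sheets, source_tag=tag)
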