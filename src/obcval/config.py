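"""Instrument configuration: algorithm item lists and classification cutoffs.

The published cutoff rules are public (and baked in as defaults), but the
assignment of the 29 Module 1 items to algorithm domains is proprietary
instrument content.  The defaults below are structural placeholders chosen to
satisfy the known counts — 16 algorithm items shared across instruments, a
social + communication subset for ADOS-G, verbal-level-specific social-affect
and restricted/repetitive-behavior lists for the revised algorithm — and must
be overridden with the licensed item assignments before use on real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import yaml

from .sheets import ITEM_IDS, ValidationError, recode_item

SOME_WORDS = "some_words"
FEW_TO_NO_WORDS = "few_to_no_words"
VERBAL_LEVELS = (SOME_WORDS, FEW_TO_NO_WORDS)

# Placeholder domain assignments (see module docstring).
DEFAULT_ADOSG_SOCIAL = ("B1", "B2", "B5", "B8", "B9", "B10", "B11")
DEFAULT_ADOSG_COMM = ("A2", "A5", "A7", "A8")
DEFAULT_ADOS2_SA = {
    SOME_WORDS: ("A2", "A7", "A8", "B1", "B2", "B5", "B9", "B10", "B11", "B12"),
    FEW_TO_NO_WORDS: ("A2", "A4", "A8", "B1", "B2", "B3", "B5", "B9", "B10", "B12"),
}
DEFAULT_ADOS2_RRB = {
    SOME_WORDS: ("A3", "D1", "D2", "D4"),
    FEW_TO_NO_WORDS: ("A3", "D1", "D2", "D4"),
}

# The eight behaviors the observation-based classifier evaluates, mapped to
# plausible Module 1 item ids (display name -> item id).
DEFAULT_OBC_FEATURES: tuple[tuple[str, str], ...] = (
    ("frequency of vocalization directed to others", "A2"),
    ("eye contact", "B1"),
    ("social smile", "B2"),
    ("shared enjoyment in interaction", "B5"),
    ("showing", "B9"),
    ("initiation of joint attention", "B10"),
    ("functional play with objects", "C1"),
    ("imagination/creativity", "C2"),
)


@dataclass
class AlgorithmConfig:
    """Item lists, recode maps and cutoffs for every instrument.

    Cutoff semantics (all inclusive minima):

    * ADOS-G autism: social >= 7 and communication >= 4 and total >= 12;
      autism spectrum: social >= 4 and communication >= 2 and total >= 7.
    * ADOS-2 ("some words"): total >= 12 autism, >= 8 autism spectrum;
      ("few to no words"): total >= 16 autism, >= 11 autism spectrum.
    * Verbal level: "few to no words" iff the raw code of ``verbal_item``
      (A1, overall level of non-echoed language) is >= ``fewno_words_min_code``.
    """

    adosg_social_items: tuple[str, ...] = DEFAULT_ADOSG_SOCIAL
    adosg_comm_items: tuple[str, ...] = DEFAULT_ADOSG_COMM
    ados2_sa_items: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_ADOS2_SA.items()})
    ados2_rrb_items: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_ADOS2_RRB.items()})
    verbal_item: str = "A1"
    fewno_words_min_code: int = 3
    adosg_autism_cutoffs: Mapping[str, int] = field(
        default_factory=lambda: {"social": 7, "comm": 4, "total": 12})
    adosg_spectrum_cutoffs: Mapping[str, int] = field(
        default_factory=lambda: {"social": 4, "comm": 2, "total": 7})
    ados2_autism_cutoff: Mapping[str, int] = field(
        default_factory=lambda: {SOME_WORDS: 12, FEW_TO_NO_WORDS: 16})
    ados2_spectrum_cutoff: Mapping[str, int] = field(
        default_factory=lambda: {SOME_WORDS: 8, FEW_TO_NO_WORDS: 11})
    special_code_recode: Mapping[int, int] = field(
        default_factory=lambda: {7: 0, 8: 0})
    three_recode: Mapping[int, int] = field(default_factory=lambda: {3: 2})
    obc_features: tuple[tuple[str, str], ...] = DEFAULT_OBC_FEATURES
    low_confidence_threshold: float = 2.0
    class_sign: int = -1  # negative score means spectrum
    borderline_margin: int = 1

    def __post_init__(self) -> None:
        self.adosg_social_items = tuple(self.adosg_social_items)
        self.adosg_comm_items = tuple(self.adosg_comm_items)
        self.ados2_sa_items = {k: tuple(v) for k, v in dict(self.ados2_sa_items).items()}
        self.ados2_rrb_items = {k: tuple(v) for k, v in dict(self.ados2_rrb_items).items()}
        self.obc_features = tuple((str(n), str(i)) for n, i in self.obc_features)
        valid = set(ITEM_IDS)

        def check_items(name, ids):
            unknown = set(ids) - valid
            if unknown:
                raise ValidationError(f"{name}: unknown item ids {sorted(unknown)}")
            if len(set(ids)) != len(tuple(ids)):
                raise ValidationError(f"{name}: duplicate item ids")

        check_items("adosg_social_items", self.adosg_social_items)
        check_items("adosg_comm_items", self.adosg_comm_items)
        if set(self.adosg_social_items) & set(self.adosg_comm_items):
            raise ValidationError("ADOS-G social and communication item lists overlap")
        for level in VERBAL_LEVELS:
            if level not in self.ados2_sa_items or level not in self.ados2_rrb_items:
                raise ValidationError(f"ADOS-2 item lists missing verbal level {level!r}")
            check_items(f"ados2_sa_items[{level}]", self.ados2_sa_items[level])
            check_items(f"ados2_rrb_items[{level}]", self.ados2_rrb_items[level])
            if set(self.ados2_sa_items[level]) & set(self.ados2_rrb_items[level]):
                raise ValidationError(f"ADOS-2 SA and RRB lists overlap at {level!r}")
        if self.verbal_item not in valid:
            raise ValidationError(f"verbal_item {self.verbal_item!r} unknown")
        for name, cuts in (("adosg", (self.adosg_spectrum_cutoffs, self.adosg_autism_cutoffs)),):
            spectrum, autism = cuts
            for key in ("social", "comm", "total"):
                if spectrum[key] <= 0 or autism[key] <= 0:
                    raise ValidationError(f"{name} cutoffs must be positive")
                if spectrum[key] > autism[key]:
                    raise ValidationError(
                        f"{name} spectrum cutoff {key} exceeds autism cutoff")
        for level in VERBAL_LEVELS:
            if self.ados2_spectrum_cutoff[level] <= 0:
                raise ValidationError("ADOS-2 cutoffs must be positive")
            if self.ados2_spectrum_cutoff[level] > self.ados2_autism_cutoff[level]:
                raise ValidationError("ADOS-2 spectrum cutoff exceeds autism cutoff")
        if len(self.obc_features) != 8:
            raise ValidationError("obc_features must list exactly 8 behaviors")
        check_items("obc_features", [i for _, i in self.obc_features])
        if self.low_confidence_threshold < 0:
            raise ValidationError("low_confidence_threshold must be >= 0")
        if self.class_sign not in (-1, 1):
            raise ValidationError("class_sign must be -1 or +1")

    # -- recode -------------------------------------------------------------

    def recode(self, raw_code: int) -> int:
        return recode_item(raw_code, special_recode=self.special_code_recode,
                           three_recode=self.three_recode)

    @property
    def obc_item_ids(self) -> tuple[str, ...]:
        return tuple(i for _, i in self.obc_features)

    # -- YAML ---------------------------------------------------------------

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["ados2_sa_items"] = {k: list(v) for k, v in self.ados2_sa_items.items()}
        data["ados2_rrb_items"] = {k: list(v) for k, v in self.ados2_rrb_items.items()}
        data["adosg_social_items"] = list(self.adosg_social_items)
        data["adosg_comm_items"] = list(self.adosg_comm_items)
        data["obc_features"] = [list(pair) for pair in self.obc_features]
        with open(path, "w", encoding="utf-8") as handle:
            yaml.safe_dump(data, handle, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "AlgorithmConfig":
        with open(path, encoding="utf-8") as handle:
            data = yaml.safe_load(handle) or {}
        if "obc_features" in data:
            data["obc_features"] = tuple(tuple(pair) for pair in data["obc_features"])
        for key in ("special_code_recode", "three_recode"):
            if key in data:
                data[key] = {int(k): int(v) for k, v in data[key].items()}
        return cls(**data)


def default_config() -> AlgorithmConfig:
    """The fully populated default configuration."""
    return AlgorithmConfig()
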