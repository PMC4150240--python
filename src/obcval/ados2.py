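"""ADOS-2 Module 1 algorithm: verbal-level branching and dual cutoff sets.

The revised algorithm first assigns a verbal level from the overall level of
non-echoed language (item A1): a raw code at or above
``fewno_words_min_code`` (default 3) means "few to no words", otherwise
"some words".  Social-affect and restricted/repetitive-behavior domain scores
are sums of recoded codes over verbal-level-specific item lists, and the
classification cutoffs apply to their total:

* some words:       total >= 12 autism, total >= 8 autism spectrum;
* few to no words:  total >= 16 autism, total >= 11 autism spectrum.

Item revisions between instrument editions that branched former code-2
behaviors into a new code 3 are absorbed by the shared 3 -> 2 recode, so no
item-version switch is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

from .ados_g import AUTISM, AUTISM_SPECTRUM, CLASSIFICATIONS, _domain_sum
from .config import AlgorithmConfig, FEW_TO_NO_WORDS, SOME_WORDS, VERBAL_LEVELS, default_config
from .sheets import NON_SPECTRUM, ScoreSheet, ValidationError


@dataclass(frozen=True)
class Ados2Result:
    verbal_level: str
    sa_score: int
    rrb_score: int
    total: int
    classification: str

    def __post_init__(self) -> None:
        if self.verbal_level not in VERBAL_LEVELS:
            raise ValidationError(f"unknown verbal level {self.verbal_level!r}")
        if self.total != self.sa_score + self.rrb_score:
            raise ValidationError("total must equal sa + rrb")
        if self.classification not in CLASSIFICATIONS:
            raise ValidationError(f"unknown classification {self.classification!r}")


def verbal_level(sheet: ScoreSheet, config: AlgorithmConfig | None = None) -> str:
    """Assign the verbal level from the raw code of the configured A1 item."""
    config = config or default_config()
    if config.verbal_item not in sheet.items:
        raise ValidationError(
            f"subject {sheet.subject_id}: verbal item {config.verbal_item!r} absent")
    raw = sheet.items[config.verbal_item]
    return FEW_TO_NO_WORDS if raw >= config.fewno_words_min_code else SOME_WORDS


def classify_ados2(total: int, level: str, config: AlgorithmConfig | None = None) -> str:
    """Apply the verbal-level-specific cutoffs to an ADOS-2 total."""
    config = config or default_config()
    if level not in VERBAL_LEVELS:
        raise ValidationError(f"unknown verbal level {level!r}")
    if total >= config.ados2_autism_cutoff[level]:
        return AUTISM
    if total >= config.ados2_spectrum_cutoff[level]:
        return AUTISM_SPECTRUM
    return NON_SPECTRUM


def score_ados2(sheet: ScoreSheet, config: AlgorithmConfig | None = None) -> Ados2Result:
    """Score one sheet with the ADOS-2 Module 1 algorithm."""
    config = config or default_config()
    level = verbal_level(sheet, config)
    sa = _domain_sum(sheet, config.ados2_sa_items[level], config)
    rrb = _domain_sum(sheet, config.ados2_rrb_items[level], config)
    total = sa + rrb
    return Ados2Result(
        verbal_level=level,
        sa_score=sa,
        rrb_score=rrb,
        total=total,
        classification=classify_ados2(total, level, config),
    )
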