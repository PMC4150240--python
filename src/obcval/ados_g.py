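"""ADOS-G Module 1 diagnostic algorithm.

Domain scores are sums of recoded item codes over the configured social and
communication item lists.  Classification is three-way:

* autism: social >= 7, communication >= 4 and social+communication >= 12;
* autism spectrum: social >= 4, communication >= 2 and total >= 7;
* otherwise non-spectrum.

``binarize`` collapses autism and autism spectrum into a single "spectrum"
outcome, the positive class used throughout the evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import AlgorithmConfig, default_config
from .sheets import NON_SPECTRUM, SPECTRUM, ScoreSheet, ValidationError

AUTISM = "autism"
AUTISM_SPECTRUM = "autism_spectrum"
CLASSIFICATIONS = (AUTISM, AUTISM_SPECTRUM, NON_SPECTRUM)


@dataclass(frozen=True)
class AdosGResult:
    social_score: int
    communication_score: int
    total: int
    classification: str

    def __post_init__(self) -> None:
        if self.total != self.social_score + self.communication_score:
            raise ValidationError("total must equal social + communication")
        if self.classification not in CLASSIFICATIONS:
            raise ValidationError(f"unknown classification {self.classification!r}")


def classify_ados_g(social: int, comm: int, config: AlgorithmConfig | None = None) -> str:
    """Apply the ADOS-G cutoff rules to a (social, communication) score pair."""
    config = config or default_config()
    total = social + comm
    aut = config.adosg_autism_cutoffs
    spec = config.adosg_spectrum_cutoffs
    if social >= aut["social"] and comm >= aut["comm"] and total >= aut["total"]:
        return AUTISM
    if social >= spec["social"] and comm >= spec["comm"] and total >= spec["total"]:
        return AUTISM_SPECTRUM
    return NON_SPECTRUM


def _domain_sum(sheet: ScoreSheet, item_ids, config: AlgorithmConfig) -> int:
    total = 0
    for item_id in item_ids:
        if item_id not in sheet.items:
            raise ValidationError(
                f"subject {sheet.subject_id}: configured item {item_id!r} absent")
        total += config.recode(sheet.items[item_id])
    return total


def score_ados_g(sheet: ScoreSheet, config: AlgorithmConfig | None = None) -> AdosGResult:
    """Score one sheet with the ADOS-G Module 1 algorithm."""
    config = config or default_config()
    social = _domain_sum(sheet, config.adosg_social_items, config)
    comm = _domain_sum(sheet, config.adosg_comm_items, config)
    return AdosGResult(
        social_score=social,
        communication_score=comm,
        total=social + comm,
        classification=classify_ados_g(social, comm, config),
    )


def binarize(classification: str) -> str:
    """Collapse the three-way label to spectrum vs non-spectrum."""
    if classification in (AUTISM, AUTISM_SPECTRUM):
        return SPECTRUM
    if classification == NON_SPECTRUM:
        return NON_SPECTRUM
    raise ValidationError(f"unknown classification {classification!r}")
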