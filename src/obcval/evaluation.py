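"""Head-to-head agreement evaluation between classifiers.

Everything here treats *spectrum* as the positive class: sensitivity is the
fraction of reference-spectrum subjects the test classifier also calls
spectrum, specificity the fraction of reference-non-spectrum subjects called
non-spectrum, and PPV/NPV the predictive values of the test classifier's
calls.  Metrics with a zero denominator are reported as missing (``None``),
never as 0.  Displayed metrics are rounded half-up to three decimals; full
precision is retained internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .ados2 import Ados2Result
from .ados_g import AdosGResult
from .adtree import OBCResult
from .config import AlgorithmConfig, default_config
from .sheets import Cohort, NON_SPECTRUM, SPECTRUM, ValidationError

_BINARY = (SPECTRUM, NON_SPECTRUM)


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts; rows = test classifier, columns = reference; positive = spectrum."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def confusion_matrix(test_labels: Sequence[str],
                     reference_labels: Sequence[str]) -> ConfusionMatrix:
    """Tally (test, reference) binary label pairs."""
    if len(test_labels) != len(reference_labels):
        raise ValidationError(
            f"label sequences differ in length ({len(test_labels)} vs {len(reference_labels)})")
    counts = {(t, r): 0 for t in _BINARY for r in _BINARY}
    for t, r in zip(test_labels, reference_labels):
        if t not in _BINARY or r not in _BINARY:
            raise ValidationError(f"non-binary label pair ({t!r}, {r!r})")
        counts[(t, r)] += 1
    return ConfusionMatrix(
        tp=counts[(SPECTRUM, SPECTRUM)],
        fn=counts[(NON_SPECTRUM, SPECTRUM)],
        fp=counts[(SPECTRUM, NON_SPECTRUM)],
        tn=counts[(NON_SPECTRUM, NON_SPECTRUM)],
    )


def round_half_up(value: float, digits: int = 3) -> float:
    """Decimal half-up rounding (0.0005 -> 0.001), as printed report tables use."""
    quantum = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MetricsReport:
    """The five agreement metrics derived from a confusion matrix.

    Each metric is a proportion in [0, 1] or ``None`` when its denominator is
    zero.  ``display()`` renders the half-up 3-decimal form used in report
    tables.
    """

    sensitivity: Optional[float]
    specificity: Optional[float]
    accuracy: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    n: int
    reference_name: str = ""

    def display(self) -> dict[str, Optional[float]]:
        return {
            name: (None if value is None else round_half_up(value))
            for name, value in (
                ("sensitivity", self.sensitivity), ("specificity", self.specificity),
                ("accuracy", self.accuracy), ("ppv", self.ppv), ("npv", self.npv))
        }


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def metrics(cm: ConfusionMatrix, reference_name: str = "") -> MetricsReport:
    """Sensitivity, specificity, accuracy, PPV and NPV of a confusion matrix."""
    return MetricsReport(
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        accuracy=_ratio(cm.tp + cm.tn, cm.n),
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        n=cm.n,
        reference_name=reference_name,
    )


def spearman_r(x: Sequence[float], y: Sequence[float]) -> Optional[float]:
    """Spearman rank correlation with average ranks for ties.

    Returns ``None`` when either ranked sequence has zero variance (the
    correlation is undefined).  Requires n >= 3.
    """
    if len(x) != len(y):
        raise ValidationError(f"sequences differ in length ({len(x)} vs {len(y)})")
    if len(x) < 3:
        raise ValidationError("spearman_r requires n >= 3")
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if np.all(xv == xv[0]) or np.all(yv == yv[0]):
        return None
    rho = stats.spearmanr(xv, yv).statistic
    return None if np.isnan(rho) else float(rho)


# ---------------------------------------------------------------------------
# Misclassification audit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AuditEntry:
    subject_id: str
    obc_class: str
    obc_score: float
    low_confidence: bool
    reference_class: str
    borderline: bool
    criteria_met: int


@dataclass(frozen=True)
class AuditReport:
    entries: tuple[AuditEntry, ...]
    n_compared: int

    @property
    def n_disagreements(self) -> int:
        return len(self.entries)

    @property
    def frac_low_confidence(self) -> Optional[float]:
        if not self.entries:
            return None
        return sum(e.low_confidence for e in self.entries) / len(self.entries)


def _adosg_audit(res: AdosGResult, margin: int,
                 config: AlgorithmConfig) -> tuple[bool, int]:
    cuts = config.adosg_spectrum_cutoffs
    scores = {"social": res.social_score, "comm": res.communication_score,
              "total": res.total}
    borderline = any(abs(scores[k] - cuts[k]) <= margin for k in cuts)
    met = sum(scores[k] >= cuts[k] for k in cuts)
    return borderline, met


def _ados2_audit(res: Ados2Result, margin: int,
                 config: AlgorithmConfig) -> tuple[bool, int]:
    cut = config.ados2_spectrum_cutoff[res.verbal_level]
    return abs(res.total - cut) <= margin, int(res.total >= cut)


def misclassification_breakdown(
        cohort: Cohort,
        obc_results: Sequence[OBCResult],
        reference_results: Sequence[AdosGResult | Ados2Result],
        config: AlgorithmConfig | None = None) -> AuditReport:
    """Audit the subjects on which the OBC and the reference instrument disagree.

    For every disagreeing subject the report flags whether the reference
    scores are *borderline* (within ``config.borderline_margin`` of a
    governing spectrum cutoff), how many of the reference's spectrum criteria
    the subject meets (three for ADOS-G: social, communication and total
    cutoffs; one for ADOS-2: the verbal-level total cutoff), and whether the
    OBC call was low confidence.
    """
    config = config or default_config()
    sheets = list(cohort)
    if not (len(sheets) == len(obc_results) == len(reference_results)):
        raise ValidationError("cohort, OBC results and reference results must align")
    from .ados_g import binarize  # local import avoids a cycle at module load

    entries = []
    for sheet, obc, ref in zip(sheets, obc_results, reference_results):
        ref_label = binarize(ref.classification)
        if obc.predicted_class == ref_label:
            continue
        if isinstance(ref, AdosGResult):
            borderline, met = _adosg_audit(ref, config.borderline_margin, config)
        elif isinstance(ref, Ados2Result):
            borderline, met = _ados2_audit(ref, config.borderline_margin, config)
        else:
            raise ValidationError(f"unsupported reference result {type(ref).__name__}")
        entries.append(AuditEntry(
            subject_id=sheet.subject_id,
            obc_class=obc.predicted_class,
            obc_score=obc.score,
            low_confidence=obc.low_confidence,
            reference_class=ref_label,
            borderline=borderline,
            criteria_met=met,
        ))
    return AuditReport(entries=tuple(entries), n_compared=len(sheets))
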