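"""Confusion matrices, agreement metrics, Spearman correlation and audits."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from obcval import (Cohort, ConfusionMatrix, ValidationError, confusion_matrix,
                    metrics, misclassification_breakdown, round_half_up,
                    spearman_r)
from obcval.ados2 import Ados2Result
from obcval.ados_g import AdosGResult
from obcval.adtree import OBCResult
from obcval.sheets import NON_SPECTRUM, SPECTRUM

from conftest import make_sheet

S, N = SPECTRUM, NON_SPECTRUM


class TestConfusionMatrix:
    def test_perfect_agreement(self):
        cm = confusion_matrix([S, N], [S, N])
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (1, 0, 0, 1)

    def test_all_false_positive(self):
        cm = confusion_matrix([S] * 5, [N] * 5)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (0, 0, 5, 0)

    def test_matches_brute_force_tally_on_random_pairs(self):
        rng = np.random.default_rng(42)
        test = [S if x else N for x in rng.integers(0, 2, 50)]
        ref = [S if x else N for x in rng.integers(0, 2, 50)]
        cm = confusion_matrix(test, ref)
        pairs = list(zip(test, ref))
        assert cm.tp == pairs.count((S, S))
        assert cm.fn == pairs.count((N, S))
        assert cm.fp == pairs.count((S, N))
        assert cm.tn == pairs.count((N, N))
        assert cm.n == 50

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="length"):
            confusion_matrix([S], [S, N])

    def test_non_binary_label_rejected(self):
        with pytest.raises(ValidationError, match="non-binary"):
            confusion_matrix(["autism"], [S])


class TestMetrics:
    def test_perfect_classifier_all_ones(self):
        report = metrics(ConfusionMatrix(tp=10, fn=0, fp=0, tn=5))
        assert report.display() == {"sensitivity": 1.0, "specificity": 1.0,
                                    "accuracy": 1.0, "ppv": 1.0, "npv": 1.0}

    def test_zero_denominator_reported_missing_not_zero(self):
        report = metrics(ConfusionMatrix(tp=0, fn=0, fp=3, tn=2))
        assert report.sensitivity is None  # no reference-positive subjects
        assert report.specificity == pytest.approx(0.4)
        report2 = metrics(ConfusionMatrix(tp=0, fn=0, fp=0, tn=0))
        assert report2.accuracy is None

    def test_full_precision_retained_internally(self):
        report = metrics(ConfusionMatrix(tp=2280, fn=53, fp=64, tn=219))
        assert report.sensitivity == pytest.approx(2280 / 2333)
        assert report.display()["sensitivity"] == 0.977

    @pytest.mark.parametrize("value,expected", [
        (0.0005, 0.001),   # half rounds up, not to even
        (0.9745, 0.975),
        (0.8045, 0.805),
        (0.123449, 0.123),
    ])
    def test_half_up_rounding(self, value, expected):
        assert round_half_up(value) == expected


class TestSpearman:
    def test_monotone_increasing_is_one(self):
        assert spearman_r([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)

    def test_monotone_decreasing_is_minus_one(self):
        assert spearman_r([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_tied_ranks_match_manual_average_rank_oracle(self):
        # ranks of (1,2,2,4) are (1, 2.5, 2.5, 4); of (1,3,2,4) are (1,3,2,4);
        # Pearson of those rank vectors is 4.5/sqrt(4.5*5) = 3/sqrt(10)
        assert spearman_r([1, 2, 2, 4], [1, 3, 2, 4]) == pytest.approx(3 / 10 ** 0.5)

    def test_self_correlation_is_one(self):
        assert spearman_r([3, 1, 4, 1, 5], [3, 1, 4, 1, 5]) == pytest.approx(1.0)

    def test_zero_variance_is_missing(self):
        assert spearman_r([1, 1, 1], [1, 2, 3]) is None

    def test_short_input_rejected(self):
        with pytest.raises(ValidationError, match="n >= 3"):
            spearman_r([1, 2], [1, 2])

    @given(data=st.lists(st.tuples(st.integers(0, 20), st.integers(0, 20)),
                         min_size=4, max_size=30),
           scale=st.integers(1, 5), shift=st.integers(-10, 10))
    def test_invariant_under_strictly_monotone_transform(self, data, scale, shift):
        x = [a for a, _ in data]
        y = [b for _, b in data]
        base = spearman_r(x, y)
        transformed = spearman_r([scale * v ** 3 + shift for v in x], y)
        if base is None:
            assert transformed is None
        else:
            assert transformed == pytest.approx(base)


def _adosg(social, comm):
    from obcval import classify_ados_g
    return AdosGResult(social, comm, social + comm, classify_ados_g(social, comm))


def _obc(score):
    return OBCResult(score=score, predicted_class=S if score < 0 else N,
                     low_confidence=abs(score) < 2)


class TestAudit:
    def test_perfect_agreement_is_empty(self, config):
        cohort = Cohort([make_sheet("A"), make_sheet("B")])
        obc = [_obc(3.0), _obc(-3.0)]
        refs = [_adosg(0, 0), _adosg(8, 6)]
        audit = misclassification_breakdown(cohort, obc, refs, config)
        assert audit.n_disagreements == 0
        assert audit.frac_low_confidence is None

    def test_borderline_spectrum_case_flags_all_three_criteria(self, config):
        # reference sits exactly on the spectrum cutoffs (4, 2, total 7)
        cohort = Cohort([make_sheet("A")])
        audit = misclassification_breakdown(
            cohort, [_obc(+1.0)], [_adosg(4, 3)], config)
        entry = audit.entries[0]
        assert entry.reference_class == S and entry.obc_class == N
        assert entry.borderline
        assert entry.criteria_met == 3

    def test_low_confidence_flagged_in_disagreement_set(self, config):
        cohort = Cohort([make_sheet("A")])
        audit = misclassification_breakdown(
            cohort, [_obc(-0.4)], [_adosg(0, 0)], config)
        assert audit.entries[0].low_confidence
        assert audit.frac_low_confidence == 1.0

    def test_ados2_reference_uses_total_cutoff(self, config):
        cohort = Cohort([make_sheet("A")])
        ref = Ados2Result("some_words", 7, 0, 7, "non_spectrum")
        audit = misclassification_breakdown(cohort, [_obc(-2.5)], [ref], config)
        entry = audit.entries[0]
        assert entry.borderline          # total 7 is within 1 of the cutoff 8
        assert entry.criteria_met == 0
        assert not entry.low_confidence

    def test_misaligned_inputs_rejected(self, config):
        cohort = Cohort([make_sheet("A")])
        with pytest.raises(ValidationError, match="align"):
            misclassification_breakdown(cohort, [], [_adosg(0, 0)], config)
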