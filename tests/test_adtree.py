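"""Alternating decision tree: prediction semantics, boosting, persistence."""

from __future__ import annotations

import math

import numpy as np
import pytest

from obcval import (ADTreeModel, CohortParams, ObcFeatureSet, Rule,
                    ValidationError, generate_cohort, load_model, predict_obc,
                    save_model, score_sheet, train_adtree)
from obcval.adtree import EPS, THRESHOLDS
from obcval.sheets import NON_SPECTRUM, SPECTRUM

from conftest import make_sheet, random_cohort

FEATURES = ObcFeatureSet()  # A2, B1, B2, B5, B9, B10, C1, C2


def make_separable_sheets(n_per_class=100, item="B1"):
    """Sheets where one feature alone separates the classes perfectly."""
    sheets, labels = [], []
    for i in range(n_per_class):
        sheets.append(make_sheet(f"P{i}", **{item: 2}))
        labels.append(SPECTRUM)
        sheets.append(make_sheet(f"N{i}", **{item: 0}))
        labels.append(NON_SPECTRUM)
    return sheets, labels


class TestPrediction:
    def test_root_only_model_is_constant(self, zero_sheet):
        model = ADTreeModel(root_value=0.3)
        assert score_sheet(model, zero_sheet) == pytest.approx(0.3)
        assert score_sheet(model, make_sheet(B1=3, C2=2)) == pytest.approx(0.3)

    def test_hand_built_path_sum(self, config):
        # eye contact (B1) gates the tree; social smile (B2) nested under true
        model = ADTreeModel(
            root_value=0.2,
            rules=(
                Rule(None, "B1", 1, -1.5, +0.4),
                Rule((0, True), "B2", 2, -0.9, +0.1),
            ))
        sheet = make_sheet(B1=2, B2=2)
        result = predict_obc(model, sheet, config)
        assert result.score == pytest.approx(0.2 - 1.5 - 0.9)
        assert result.predicted_class == SPECTRUM
        assert not result.low_confidence

    def test_unreached_precondition_contributes_nothing(self):
        model = ADTreeModel(
            root_value=0.0,
            rules=(
                Rule(None, "B1", 1, -1.0, +1.0),
                Rule((0, True), "B2", 1, -5.0, -5.0),
            ))
        # B1 = 0 takes rule 0's false branch, so rule 1 never fires
        assert score_sheet(model, make_sheet(B1=0, B2=2)) == pytest.approx(1.0)

    def test_scores_near_zero_are_low_confidence(self, config):
        for value, low in ((1.9, True), (-1.9, True), (2.0, False), (-2.5, False)):
            result = predict_obc(ADTreeModel(root_value=value), make_sheet(), config)
            assert result.low_confidence is low

    def test_zero_score_is_non_spectrum_and_low_confidence(self, config):
        result = predict_obc(ADTreeModel(root_value=0.0), make_sheet(), config)
        assert result.predicted_class == NON_SPECTRUM
        assert result.low_confidence

    def test_prediction_depends_only_on_feature_items(self):
        model = ADTreeModel(root_value=0.1, rules=(Rule(None, "B1", 1, -1.0, 1.0),))
        a = make_sheet(B1=2, D1=0, E3=0)
        b = make_sheet(B1=2, D1=3, E3=2)  # differ only in non-feature items
        assert score_sheet(model, a) == score_sheet(model, b)

    def test_missing_feature_item_rejected(self):
        model = ADTreeModel(root_value=0.0)
        sheet = make_sheet()
        object.__setattr__(sheet, "items",
                           {k: v for k, v in sheet.items.items() if k != "B1"})
        with pytest.raises(ValidationError, match="B1"):
            score_sheet(model, sheet)


class TestTraining:
    def test_zero_rounds_balanced_classes_gives_zero_root(self):
        sheets, labels = make_separable_sheets(50)
        model = train_adtree(sheets, labels, FEATURES, rounds=0)
        assert model.rules == ()
        assert model.root_value == pytest.approx(0.0)

    def test_perfect_separator_found_in_one_round(self):
        sheets, labels = make_separable_sheets(100, item="B1")
        model = train_adtree(sheets, labels, FEATURES, rounds=1)
        assert len(model.rules) == 1
        rule = model.rules[0]
        assert rule.item_id == "B1"
        predictions = [predict_obc(model, s).predicted_class for s in sheets]
        assert predictions == labels  # training accuracy 1.0

    def test_one_round_matches_exhaustive_stump_search(self):
        """The chosen stump minimises Z over all 8 x 3 candidates (brute force)."""
        cohort, labels, _theta = generate_cohort(CohortParams(n=300, seed=5))
        config_items = FEATURES.item_ids
        X = np.array([[min(2, s.items[i]) if s.items[i] not in (7, 8) else 0
                       for i in config_items] for s in cohort])
        y = np.array([-1.0 if lab == "spectrum" else 1.0 for lab in labels])
        w = np.ones(len(y))
        root = 0.5 * math.log((w[y > 0].sum() + EPS) / (w[y < 0].sum() + EPS))
        w = w * np.exp(-y * root)
        best = None
        for f, item in enumerate(config_items):
            for t in THRESHOLDS:
                c = X[:, f] >= t
                z = 2.0 * (math.sqrt(w[c & (y > 0)].sum() * w[c & (y < 0)].sum())
                           + math.sqrt(w[~c & (y > 0)].sum() * w[~c & (y < 0)].sum()))
                if best is None or (z, f, t) < best:
                    best = (z, f, t)
        model = train_adtree(cohort, labels, FEATURES, rounds=1)
        assert model.rules[0].item_id == config_items[best[1]]
        assert model.rules[0].threshold == best[2]
        assert model.root_value == pytest.approx(root)

    def test_boosting_loss_bound_non_increasing(self):
        cohort, labels, _theta = generate_cohort(CohortParams(n=500, seed=3))
        model = train_adtree(cohort, labels, FEATURES, rounds=8)
        losses = model.train_loss
        assert len(losses) == 8
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))

    def test_single_class_input_rejected(self):
        sheets, _ = make_separable_sheets(5)
        with pytest.raises(ValidationError, match="each class"):
            train_adtree(sheets, [SPECTRUM] * len(sheets), FEATURES, rounds=1)

    def test_label_alignment_enforced(self):
        sheets, labels = make_separable_sheets(5)
        with pytest.raises(ValidationError, match="align"):
            train_adtree(sheets, labels[:-1], FEATURES, rounds=1)

    def test_deterministic_given_input_order(self):
        cohort, labels, _theta = generate_cohort(CohortParams(n=400, seed=11))
        m1 = train_adtree(cohort, labels, FEATURES, rounds=4)
        m2 = train_adtree(cohort, labels, FEATURES, rounds=4)
        assert m1 == m2

    def test_agrees_with_sklearn_stump_on_separable_data(self):
        """Independent cross-check: a depth-1 sklearn tree picks the same split."""
        sklearn = pytest.importorskip("sklearn.tree")
        sheets, labels = make_separable_sheets(60, item="B5")
        X = [[s.items[i] for i in FEATURES.item_ids] for s in sheets]
        y = [1 if lab == SPECTRUM else 0 for lab in labels]
        stump = sklearn.DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, y)
        model = train_adtree(sheets, labels, FEATURES, rounds=1)
        assert FEATURES.item_ids[stump.tree_.feature[0]] == "B5"
        assert model.rules[0].item_id == "B5"
        assert stump.score(X, y) == 1.0


class TestPersistence:
    def test_round_trip_identity(self, tmp_path):
        cohort, labels, _theta = generate_cohort(CohortParams(n=300, seed=9))
        model = train_adtree(cohort, labels, FEATURES, rounds=3)
        path = tmp_path / "m.json"
        save_model(model, path)
        assert load_model(path) == model

    def test_truncated_file_is_schema_error(self, tmp_path):
        cohort, labels, _theta = generate_cohort(CohortParams(n=100, seed=9))
        model = train_adtree(cohort, labels, FEATURES, rounds=1)
        path = tmp_path / "m.json"
        save_model(model, path)
        path.write_text(path.read_text()[:40])
        with pytest.raises(ValidationError, match="malformed"):
            load_model(path)

    def test_version_mismatch_rejected(self, tmp_path):
        path = tmp_path / "m.json"
        path.write_text('{"version": 99}')
        with pytest.raises(ValidationError, match="version"):
            load_model(path)

    def test_shipped_demo_model_predicts_identically_after_round_trip(self, tmp_path):
        from obcval import shipped_demo_model
        model = shipped_demo_model()
        path = tmp_path / "m.json"
        save_model(model, path)
        reloaded = load_model(path)
        for sheet in random_cohort(100, seed=21):
            assert score_sheet(reloaded, sheet) == score_sheet(model, sheet)
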