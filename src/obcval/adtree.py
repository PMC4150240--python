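"""Alternating decision tree (ADTree) classifier over eight observed behaviors.

An ADTree is a boosted ensemble of decision stumps arranged in a tree of
alternating prediction and splitter nodes.  The model's output for a sheet is
the *sum* of the prediction values along every root-to-leaf path whose
conditions the sheet satisfies — a signed real score.  The sign encodes the
predicted class (negative means spectrum under the default orientation) and
the magnitude encodes confidence: scores near zero are low-confidence calls.

Training follows the canonical boosting formulation:

* instance weights start at 1;
* every prediction value is a smoothed log-odds
  ``0.5 * ln((W_plus + eps) / (W_minus + eps))`` with ``eps = 1``;
* each round adds the (precondition, stump condition) pair minimising

  ``Z = 2 * [sqrt(W+(p & c) W-(p & c)) + sqrt(W+(p & ~c) W-(p & ~c))] + W(~p)``

  where ``p`` ranges over the root and both branches of every existing rule
  and ``c`` over ``item >= t`` conditions on recoded codes with
  ``t in {1, 2, 3}``;
* weights of instances reaching the new rule are multiplied by
  ``exp(-y * value)`` for the branch value they receive.

Ties in the stump search are broken toward the lowest (precondition index,
feature order, threshold) tuple, making training deterministic given the
input order.  Because the candidate set contains a vacuous stump (threshold
3 is never met by a recoded code), the total instance weight — the
exponential-loss bound on training error — never increases across rounds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .config import AlgorithmConfig, DEFAULT_OBC_FEATURES, default_config
from .sheets import Cohort, NON_SPECTRUM, SPECTRUM, ScoreSheet, ValidationError

MODEL_FORMAT_VERSION = 1
EPS = 1.0  # smoothing constant in every log-odds prediction value
THRESHOLDS = (1, 2, 3)


@dataclass(frozen=True)
class FeatureSet:
    """An ordered list of (display name, score-sheet item id) features."""

    features: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "features",
                           tuple((str(n), str(i)) for n, i in self.features))
        if not self.features:
            raise ValidationError("feature set must not be empty")
        ids = self.item_ids
        if len(set(ids)) != len(ids):
            raise ValidationError("feature item ids must be unique")

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(i for _, i in self.features)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.features)


class ObcFeatureSet(FeatureSet):
    """The ordered eight behaviors the observation-based classifier evaluates."""

    def __init__(self, features: Iterable[tuple[str, str]] = DEFAULT_OBC_FEATURES):
        super().__init__(tuple(features))
        if len(self.features) != 8:
            raise ValidationError("an OBC feature set has exactly 8 behaviors")


@dataclass(frozen=True)
class Rule:
    """One splitter node: a stump gated by a precondition.

    ``precondition`` is ``None`` for the root, otherwise ``(rule_index,
    branch)`` referencing the true/false branch of an earlier rule.
    ``value_true``/``value_false`` are the prediction values added when the
    condition ``recoded(item_id) >= threshold`` holds / fails.
    """

    precondition: Optional[tuple[int, bool]]
    item_id: str
    threshold: int
    value_true: float
    value_false: float

    def __post_init__(self) -> None:
        if self.threshold not in THRESHOLDS:
            raise ValidationError(f"stump threshold {self.threshold} not in {THRESHOLDS}")
        if not (math.isfinite(self.value_true) and math.isfinite(self.value_false)):
            raise ValidationError("rule prediction values must be finite")


@dataclass(frozen=True)
class ADTreeModel:
    root_value: float
    rules: tuple[Rule, ...] = ()
    class_sign: int = -1  # sign of the score that means spectrum
    feature_set: FeatureSet = field(default_factory=ObcFeatureSet)
    train_loss: tuple[float, ...] = ()  # per-round exponential-loss bound

    def __post_init__(self) -> None:
        if not math.isfinite(self.root_value):
            raise ValidationError("root_value must be finite")
        if self.class_sign not in (-1, 1):
            raise ValidationError("class_sign must be -1 or +1")
        item_ids = set(self.feature_set.item_ids)
        for idx, rule in enumerate(self.rules):
            if rule.item_id not in item_ids:
                raise ValidationError(
                    f"rule {idx}: item {rule.item_id!r} not in the feature set")
            if rule.precondition is not None:
                parent, _branch = rule.precondition
                if not 0 <= parent < idx:
                    raise ValidationError(
                        f"rule {idx}: precondition must reference an earlier rule")


@dataclass(frozen=True)
class OBCResult:
    score: float
    predicted_class: str
    low_confidence: bool


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def _as_feature_set(features) -> FeatureSet:
    if isinstance(features, FeatureSet):
        return features
    pairs = []
    for entry in features:
        if isinstance(entry, str):
            pairs.append((entry, entry))
        else:
            pairs.append(tuple(entry))
    if len(pairs) == 8:
        return ObcFeatureSet(tuple(pairs))
    return FeatureSet(tuple(pairs))


def _feature_codes(sheet: ScoreSheet, feature_set: FeatureSet,
                   config: AlgorithmConfig) -> list[int]:
    codes = []
    for item_id in feature_set.item_ids:
        if item_id not in sheet.items:
            raise ValidationError(
                f"subject {sheet.subject_id}: feature item {item_id!r} absent")
        codes.append(config.recode(sheet.items[item_id]))
    return codes


def score_sheet(model: ADTreeModel, sheet: ScoreSheet,
                config: AlgorithmConfig | None = None) -> float:
    """The signed ADTree score: sum of values along all satisfied paths."""
    config = config or default_config()
    codes = dict(zip(model.feature_set.item_ids,
                     _feature_codes(sheet, model.feature_set, config)))
    score = model.root_value
    # satisfied[i] == whether rule i's condition held, None if unreachable
    satisfied: list[Optional[bool]] = []
    for rule in model.rules:
        if rule.precondition is None:
            reachable = True
        else:
            parent, branch = rule.precondition
            reachable = satisfied[parent] is not None and satisfied[parent] == branch
        if not reachable:
            satisfied.append(None)
            continue
        holds = codes[rule.item_id] >= rule.threshold
        satisfied.append(holds)
        score += rule.value_true if holds else rule.value_false
    return score


def predict_obc(model: ADTreeModel, sheet: ScoreSheet,
                config: AlgorithmConfig | None = None) -> OBCResult:
    """Classify one sheet: class from the score's sign, confidence from |score|.

    A score of exactly zero is classified non-spectrum and flagged low
    confidence.
    """
    config = config or default_config()
    value = score_sheet(model, sheet, config)
    spectrum = (value > 0) if model.class_sign > 0 else (value < 0)
    return OBCResult(
        score=value,
        predicted_class=SPECTRUM if spectrum else NON_SPECTRUM,
        low_confidence=abs(value) < config.low_confidence_threshold,
    )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _log_odds(w_plus: float, w_minus: float) -> float:
    return 0.5 * math.log((w_plus + EPS) / (w_minus + EPS))


def train_adtree(cohort: Cohort | Sequence[ScoreSheet], labels: Sequence[str],
                 features: FeatureSet | Sequence | None = None, rounds: int = 8,
                 config: AlgorithmConfig | None = None) -> ADTreeModel:
    """Train an alternating decision tree by boosting.

    Parameters
    ----------
    cohort
        Training sheets (order matters only for tie-breaking).
    labels
        Binary reference labels, "spectrum"/"non_spectrum", aligned with the
        sheets; both classes must be present.
    features
        The 8-behavior feature set; defaults to the standard one.
    rounds
        Number of splitter nodes to add (``rounds = 0`` gives a root-only
        model).
    """
    config = config or default_config()
    features = (_as_feature_set(features) if features is not None
                else ObcFeatureSet(config.obc_features))
    sheets = list(cohort)
    if len(sheets) != len(labels):
        raise ValidationError("labels must align one-to-one with sheets")
    if rounds < 0:
        raise ValidationError("rounds must be >= 0")
    label_set = set(labels)
    if not label_set <= {SPECTRUM, NON_SPECTRUM}:
        raise ValidationError(f"labels must be binary spectrum/non_spectrum, got {label_set}")
    if len(label_set) < 2:
        raise ValidationError("training requires at least one example of each class")

    n = len(sheets)
    n_features = len(features.item_ids)
    X = np.array([_feature_codes(s, features, config) for s in sheets], dtype=np.int64)
    # y = +1 for the class on the positive-score side; with the default
    # orientation (class_sign = -1) spectrum sheets carry y = -1.
    sign = config.class_sign
    y = np.array([sign if lab == SPECTRUM else -sign for lab in labels], dtype=np.float64)

    w = np.ones(n, dtype=np.float64)
    pos = y > 0

    root_value = _log_odds(w[pos].sum(), w[~pos].sum())
    w = w * np.exp(-y * root_value)

    # condition masks for every (feature, threshold) candidate
    cond_masks = {(f, t): X[:, f] >= t for f in range(n_features) for t in THRESHOLDS}

    # precondition masks; index 0 is the root, then two per rule (true, false)
    precond_masks: list[np.ndarray] = [np.ones(n, dtype=bool)]
    precond_refs: list[Optional[tuple[int, bool]]] = [None]

    rules: list[Rule] = []
    losses: list[float] = []
    total0 = float(n)

    for _ in range(rounds):
        best = None  # (Z, precond_idx, feature, threshold)
        for p_idx, p_mask in enumerate(precond_masks):
            w_p_pos = float(w[p_mask & pos].sum())
            w_p_neg = float(w[p_mask & ~pos].sum())
            w_not_p = float(w.sum()) - w_p_pos - w_p_neg
            for f in range(n_features):
                for t in THRESHOLDS:
                    c = cond_masks[(f, t)]
                    wc_pos = float(w[p_mask & c & pos].sum())
                    wc_neg = float(w[p_mask & c & ~pos].sum())
                    z = (2.0 * (math.sqrt(wc_pos * wc_neg)
                                + math.sqrt((w_p_pos - wc_pos) * (w_p_neg - wc_neg)))
                         + w_not_p)
                    key = (z, p_idx, f, t)
                    if best is None or key < best:
                        best = key
        assert best is not None
        _, p_idx, f, t = best
        p_mask = precond_masks[p_idx]
        c = cond_masks[(f, t)]
        in_true = p_mask & c
        in_false = p_mask & ~c
        value_true = _log_odds(float(w[in_true & pos].sum()), float(w[in_true & ~pos].sum()))
        value_false = _log_odds(float(w[in_false & pos].sum()), float(w[in_false & ~pos].sum()))
        rule = Rule(
            precondition=precond_refs[p_idx],
            item_id=features.item_ids[f],
            threshold=t,
            value_true=value_true,
            value_false=value_false,
        )
        rule_idx = len(rules)
        rules.append(rule)
        w = np.where(in_true, w * math.exp(-value_true) ** y, w)
        # exp(-y*v) written as exp(-v)**y keeps the vectorised form exact
        w = np.where(in_false, w * math.exp(-value_false) ** y, w)
        precond_masks.extend([in_true, in_false])
        precond_refs.extend([(rule_idx, True), (rule_idx, False)])
        losses.append(float(w.sum()) / total0)

    return ADTreeModel(
        root_value=root_value,
        rules=tuple(rules),
        class_sign=sign,
        feature_set=features,
        train_loss=tuple(losses),
    )


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_model(model: ADTreeModel, path) -> None:
    """Serialise a model to JSON (lossless round-trip)."""
    data = {
        "version": MODEL_FORMAT_VERSION,
        "class_sign": model.class_sign,
        "root_value": model.root_value,
        "features": [list(pair) for pair in model.feature_set.features],
        "rules": [
            {
                "precondition": (None if r.precondition is None
                                 else {"rule": r.precondition[0], "branch": r.precondition[1]}),
                "item": r.item_id,
                "threshold": r.threshold,
                "value_true": r.value_true,
                "value_false": r.value_false,
            }
            for r in model.rules
        ],
        "train_loss": list(model.train_loss),
    }
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(data, handle, indent=1, sort_keys=True)
        handle.write("\n")


def load_model(path) -> ADTreeModel:
    """Load a model from JSON, checking the format version and schema."""
    try:
        with open(path, encoding="utf-8") as handle:
            data = json.load(handle)
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{path}: malformed model file ({exc})") from None
    if not isinstance(data, dict) or data.get("version") != MODEL_FORMAT_VERSION:
        raise ValidationError(
            f"{path}: unsupported model format version {data.get('version') if isinstance(data, dict) else data!r}")
    try:
        rules = tuple(
            Rule(
                precondition=(None if r["precondition"] is None
                              else (int(r["precondition"]["rule"]), bool(r["precondition"]["branch"]))),
                item_id=r["item"],
                threshold=int(r["threshold"]),
                value_true=float(r["value_true"]),
                value_false=float(r["value_false"]),
            )
            for r in data["rules"]
        )
        return ADTreeModel(
            root_value=float(data["root_value"]),
            rules=rules,
            class_sign=int(data["class_sign"]),
            feature_set=_as_feature_set([tuple(p) for p in data["features"]]),
            train_loss=tuple(float(x) for x in data.get("train_loss", ())),
        )
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"{path}: model schema mismatch ({exc!r})") from None
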