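"""End-to-end validation: score a cohort with every instrument, train (or
load) the classifier on a disjoint split, and report agreement.

The validation design mirrors a head-to-head evaluation of a short classifier
against two reference scoring algorithms and an external clinical label:

1. obtain a cohort (generated synthetically or loaded from CSV);
2. either evaluate a supplied pre-trained model on the whole cohort
   (the mode analogous to validating an externally trained classifier), or
   split the cohort by a seeded shuffle, train the tree on one half using
   ADOS-G-derived binary labels, and evaluate on the held-out half — training
   and evaluation subjects never overlap;
3. score every evaluation sheet with ADOS-G, ADOS-2, the comparison score
   and the classifier;
4. report three confusion matrices (classifier vs ADOS-G, vs ADOS-2, vs
   clinical diagnosis where available), the five agreement metrics for each,
   Spearman correlations of the classifier score against the two instrument
   totals and the comparison score, and the misclassification audits.

Reports are plain dictionaries of JSON-serialisable values; regeneration from
the same seed and configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .ados2 import score_ados2
from .ados_g import binarize, score_ados_g
from .adtree import ADTreeModel, ObcFeatureSet, predict_obc, train_adtree
from .comparison import ComparisonTable, comparison_score, default_comparison_table
from .config import AlgorithmConfig, default_config
from .evaluation import (confusion_matrix, metrics, misclassification_breakdown,
                         spearman_r)
from .sheets import Cohort, ValidationError
from .synthetic import CohortParams, generate_cohort

logger = logging.getLogger(__name__)


def config_hash(config: AlgorithmConfig) -> str:
    """Stable short digest of a configuration, for report provenance."""
    from dataclasses import asdict
    canonical = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def split_cohort(cohort: Cohort, train_fraction: float, seed: int) -> tuple[list[int], list[int]]:
    """Disjoint train/eval index split by a seeded shuffle."""
    if not 0.0 < train_fraction < 1.0:
        raise ValidationError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cohort))
    n_train = int(round(len(cohort) * train_fraction))
    train_idx = sorted(int(i) for i in order[:n_train])
    eval_idx = sorted(int(i) for i in order[n_train:])
    if set(train_idx) & set(eval_idx):
        raise ValidationError("train and eval splits overlap")
    return train_idx, eval_idx


def _metrics_block(cm, name):
    report = metrics(cm, reference_name=name)
    return {
        "confusion": {"tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn},
        "n": report.n,
        "metrics": {k: v for k, v in report.display().items()},
        "metrics_full": {
            "sensitivity": report.sensitivity, "specificity": report.specificity,
            "accuracy": report.accuracy, "ppv": report.ppv, "npv": report.npv,
        },
    }


def _audit_block(audit):
    return {
        "n_compared": audit.n_compared,
        "n_disagreements": audit.n_disagreements,
        "frac_low_confidence": audit.frac_low_confidence,
        "entries": [
            {"subject_id": e.subject_id, "obc_class": e.obc_class,
             "obc_score": e.obc_score, "low_confidence": e.low_confidence,
             "reference_class": e.reference_class, "borderline": e.borderline,
             "criteria_met": e.criteria_met}
            for e in audit.entries
        ],
    }


def run_validation(params: CohortParams | None = None, *,
                   cohort: Cohort | None = None,
                   config: AlgorithmConfig | None = None,
                   table: ComparisonTable | None = None,
                   model: ADTreeModel | None = None,
                   rounds: int = 8,
                   train_fraction: float = 0.5,
                   seed: int | None = None,
                   out_dir: str | Path | None = None) -> dict:
    """Run the full validation and return the report dictionary.

    Exactly one of ``params``/``cohort`` supplies the data.  With ``model``
    given, the whole cohort is evaluation data; otherwise a model is trained
    on a seeded ``train_fraction`` split against ADOS-G-derived labels and
    evaluated on the remainder.  ``seed`` drives the split shuffle (defaults
    to ``params.seed`` when generating).
    """
    config = config or default_config()
    table = table or default_comparison_table()
    if (params is None) == (cohort is None):
        raise ValidationError("supply exactly one of params or cohort")
    if params is not None:
        cohort, _true_labels, _theta = generate_cohort(params)
        if seed is None:
            seed = params.seed
    if seed is None:
        seed = 0
    logger.info("cohort: %d sheets (%s)", len(cohort), cohort.source_tag)

    if model is None:
        train_idx, eval_idx = split_cohort(cohort, train_fraction, seed)
        train_sheets = [cohort.sheets[i] for i in train_idx]
        train_labels = [binarize(score_ados_g(s, config).classification)
                        for s in train_sheets]
        model = train_adtree(train_sheets, train_labels,
                             ObcFeatureSet(config.obc_features),
                             rounds=rounds, config=config)
        eval_sheets = [cohort.sheets[i] for i in eval_idx]
        mode = "train_eval_split"
        logger.info("trained %d-rule tree on %d sheets; evaluating on %d",
                    len(model.rules), len(train_sheets), len(eval_sheets))
    else:
        train_idx, eval_idx = [], list(range(len(cohort)))
        eval_sheets = list(cohort.sheets)
        mode = "pretrained_model"
        logger.info("evaluating supplied model on all %d sheets", len(eval_sheets))

    eval_cohort = Cohort(sheets=eval_sheets, source_tag=cohort.source_tag)
    adosg = [score_ados_g(s, config) for s in eval_sheets]
    ados2 = [score_ados2(s, config) for s in eval_sheets]
    cs = [comparison_score(r.total, s.age_years, r.verbal_level, table)
          for s, r in zip(eval_sheets, ados2)]
    obc = [predict_obc(model, s, config) for s in eval_sheets]

    obc_labels = [r.predicted_class for r in obc]
    adosg_labels = [binarize(r.classification) for r in adosg]
    ados2_labels = [binarize(r.classification) for r in ados2]

    blocks = {
        "obc_vs_adosg": _metrics_block(confusion_matrix(obc_labels, adosg_labels),
                                       "ados_g"),
        "obc_vs_ados2": _metrics_block(confusion_matrix(obc_labels, ados2_labels),
                                       "ados_2"),
    }
    dx_pairs = [(o, s.clinical_dx) for o, s in zip(obc_labels, eval_sheets)
                if s.clinical_dx is not None]
    if dx_pairs:
        blocks["obc_vs_clinical"] = _metrics_block(
            confusion_matrix([p[0] for p in dx_pairs], [p[1] for p in dx_pairs]),
            "clinical_dx")

    scores = [r.score for r in obc]
    correlations = {
        "obc_vs_adosg_total": spearman_r(scores, [r.total for r in adosg]),
        "obc_vs_ados2_total": spearman_r(scores, [r.total for r in ados2]),
        "obc_vs_comparison_score": spearman_r(scores, cs),
    }

    audits = {
        "vs_adosg": _audit_block(misclassification_breakdown(eval_cohort, obc, adosg, config)),
        "vs_ados2": _audit_block(misclassification_breakdown(eval_cohort, obc, ados2, config)),
    }

    report = {
        "provenance": {
            "package_version": __version__,
            "seed": int(seed),
            "config_hash": config_hash(config),
            "mode": mode,
            "n_cohort": len(cohort),
            "n_train": len(train_idx),
            "n_eval": len(eval_sheets),
            "rounds": int(rounds),
        },
        "comparisons": blocks,
        "spearman": correlations,
        "audits": audits,
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_report(report, out_dir / "report.json")
        per_subject_table(eval_sheets, adosg, ados2, cs, obc).to_csv(
            out_dir / "per_subject.csv", index=False)
        with open(out_dir / "summary.txt", "w", encoding="utf-8") as handle:
            handle.write(summarize(report))
    return report


def per_subject_table(sheets, adosg, ados2, cs, obc) -> pd.DataFrame:
    """Per-subject results: every score, classification and flag."""
    rows = []
    for s, g, a2, c, o in zip(sheets, adosg, ados2, cs, obc):
        rows.append({
            "subject_id": s.subject_id,
            "age_years": s.age_years,
            "gender": s.gender,
            "clinical_dx": s.clinical_dx or "",
            "adosg_social": g.social_score,
            "adosg_comm": g.communication_score,
            "adosg_total": g.total,
            "adosg_class": g.classification,
            "adosg_binary": binarize(g.classification),
            "ados2_verbal_level": a2.verbal_level,
            "ados2_sa": a2.sa_score,
            "ados2_rrb": a2.rrb_score,
            "ados2_total": a2.total,
            "ados2_class": a2.classification,
            "ados2_binary": binarize(a2.classification),
            "comparison_score": c,
            "obc_score": o.score,
            "obc_class": o.predicted_class,
            "obc_low_confidence": o.low_confidence,
        })
    return pd.DataFrame(rows)


def write_report(report: dict, path) -> None:
    """Write a report JSON with stable key order and formatting."""
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(report, handle, indent=2, sort_keys=True, allow_nan=False)
        handle.write("\n")


def summarize(report: dict) -> str:
    """Human-readable one-page summary of a validation report."""
    lines = []
    prov = report["provenance"]
    lines.append(f"Validation report (seed={prov['seed']}, mode={prov['mode']}, "
                 f"n_eval={prov['n_eval']})")
    for name, block in report["comparisons"].items():
        m = block["metrics"]
        cm = block["confusion"]
        lines.append(f"  {name}: n={block['n']} "
                     f"tp={cm['tp']} fn={cm['fn']} fp={cm['fp']} tn={cm['tn']}")
        lines.append("    " + "  ".join(
            f"{k}={'NA' if v is None else f'{v:.3f}'}" for k, v in m.items()))
    lines.append("  Spearman correlations (classifier score vs):")
    for name, rho in report["spearman"].items():
        lines.append(f"    {name}: {'NA' if rho is None else f'{rho:+.3f}'}")
    for name, audit in report["audits"].items():
        frac = audit["frac_low_confidence"]
        lines.append(f"  audit {name}: {audit['n_disagreements']} disagreements "
                     f"of {audit['n_compared']}; low-confidence fraction "
                     f"{'NA' if frac is None else f'{frac:.2f}'}")
    return "\n".join(lines) + "\n"
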