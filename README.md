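# obcval

Validation machinery for a **short observation-based autism classifier**
against the full-length ADOS Module 1 scoring algorithms.

Autism is diagnosed behaviorally, most often with the Autism Diagnostic
Observation Schedule (ADOS): a clinician-administered exam whose Module 1
(for children with little or no language) records 29 ordinal item codes
across 10 activities and takes 60–90 minutes. A machine-learned classifier
that evaluates only 8 of those behaviors can, in principle, triage children
far faster — but it has to be validated head-to-head against the instruments
it abbreviates. This package implements that validation end-to-end for
researchers in autism phenotyping and screening-test methodology:

* **ADOS-G algorithm** — social + communication domain scores from recoded
  item codes (3→2, special codes 7/8→0); autism iff social ≥ 7, communication
  ≥ 4 and total ≥ 12; autism spectrum iff social ≥ 4, communication ≥ 2 and
  total ≥ 7; else non-spectrum.
* **ADOS-2 algorithm** — verbal level from item A1 (code ≥ 3 → "few to no
  words"), social-affect + restricted/repetitive-behavior total, with cutoffs
  8/12 (some words) or 11/16 (few to no words) for spectrum/autism.
* **Comparison score** — the ADOS-2 total mapped to a 1–10 severity scale
  within age-by-verbal-level cells (the shipped table is synthetic; the
  published calibration is licensed instrument content).
* **Observation-based classifier (OBC)** — an alternating decision tree
  (ADTree) over 8 behaviors, trained by boosting. Its prediction is the sum
  of log-odds values along all satisfied root-to-leaf paths: a signed score
  whose sign is the class (negative = spectrum) and whose magnitude is
  confidence; |score| < 2 flags a low-confidence call.
* **Evaluation** — confusion matrices with spectrum as the positive class,
  sensitivity / specificity / accuracy / PPV / NPV (half-up rounded to 3
  decimals for display), Spearman rank correlations of the OBC score against
  instrument totals, and a borderline-case audit of every disagreement.
* **Synthetic cohorts** — real score-sheet repositories are
  access-controlled, so a seeded generator emulates their structure (≈89%
  spectrum, age ≈ 6.2 ± 4.3 years, graded-response item codes driven by a
  latent severity) to make every stage testable and reproducible.

## Worked example

```python
from obcval import CohortParams, run_validation, summarize

report = run_validation(CohortParams(n=2616, seed=1), rounds=8)
print(summarize(report))
```

```
Validation report (seed=1, mode=train_eval_split, n_eval=1308)
  obc_vs_adosg: n=1308 tp=1143 fn=14 fp=52 tn=99
    sensitivity=0.988  specificity=0.656  accuracy=0.950  ppv=0.956  npv=0.876
  obc_vs_ados2: n=1308 tp=1165 fn=21 fp=30 tn=92
    sensitivity=0.982  specificity=0.754  accuracy=0.961  ppv=0.975  npv=0.814
  obc_vs_clinical: n=1308 tp=1144 fn=23 fp=51 tn=90
    sensitivity=0.980  specificity=0.638  accuracy=0.943  ppv=0.957  npv=0.796
  Spearman correlations (classifier score vs):
    obc_vs_adosg_total: -0.770
    obc_vs_ados2_total: -0.751
    obc_vs_comparison_score: -0.744
  audit vs_adosg: 66 disagreements of 1308; low-confidence fraction 0.92
  audit vs_ados2: 51 disagreements of 1308; low-confidence fraction 0.84
```

Reading this: a cohort of 2616 synthetic sheets was split in half; an 8-rule
ADTree trained on one half (against ADOS-G-derived labels) was evaluated on
the other. The tree recovers the reference classifications with ~98%
sensitivity and 66–75% specificity, its signed score tracks both instrument
totals and the severity scale (strongly negative rank correlations — more
negative score, more severe presentation), and ~9 in 10 of its
misclassifications carry the low-confidence flag that would route a child to
full assessment.

The `examples/` directory walks each capability separately (generation,
instrument scoring, training, agreement evaluation, full pipeline), and the
same stages are exposed as a thin CLI:

```sh
obcval generate --n 2616 --seed 1 --out cohort.csv
obcval run-all --n 2616 --seed 1 --out results/
```

**On real data:** the cutoff rules are published, but the assignment of the
29 items to algorithm domains is proprietary instrument content. The shipped
item lists are structural placeholders with the correct counts; override
them (and the comparison table) via `AlgorithmConfig` / YAML before scoring
licensed score sheets.

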