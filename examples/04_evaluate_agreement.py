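"""Compare classifier calls against a reference instrument.

Builds the 2x2 confusion matrix (spectrum = positive class), derives the five
agreement metrics, correlates the signed score with the instrument total, and
audits the disagreements for borderline reference scores and low-confidence
classifier calls.
"""

from obcval import (CohortParams, binarize, confusion_matrix, generate_cohort,
                    metrics, misclassification_breakdown, predict_obc,
                    score_ados_g, spearman_r, train_adtree)

cohort, _, _ = generate_cohort(CohortParams(n=1500, seed=19))
adosg = [score_ados_g(s) for s in cohort]
labels = [binarize(r.classification) for r in adosg]

train_n = 750
model = train_adtree(cohort.sheets[:train_n], labels[:train_n], rounds=8)

eval_sheets = cohort.sheets[train_n:]
obc = [predict_obc(model, s) for s in eval_sheets]
cm = confusion_matrix([r.predicted_class for r in obc], labels[train_n:])
report = metrics(cm, reference_name="ados_g")

print(f"confusion (vs ADOS-G): tp={cm.tp} fn={cm.fn} fp={cm.fp} tn={cm.tn}")
print("metrics:", report.display())
rho = spearman_r([r.score for r in obc], [r.total for r in adosg[train_n:]])
print(f"Spearman score-vs-total: {rho:+.3f} (negative: lower score = more severe)")

from obcval import Cohort
audit = misclassification_breakdown(
    Cohort(eval_sheets), obc, adosg[train_n:])
print(f"audit: {audit.n_disagreements} disagreements of {audit.n_compared}; "
      f"{audit.frac_low_confidence:.0%} were low-confidence calls")
borderline = sum(e.borderline for e in audit.entries)
print(f"  {borderline} of them had borderline reference scores "
      f"(within 1 point of a spectrum cutoff)")
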