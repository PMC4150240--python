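"""Train the 8-behavior alternating decision tree and read its signed scores.

The classifier is trained by boosting against ADOS-G-derived spectrum /
non-spectrum labels.  Its output is a signed score: negative means spectrum,
positive non-spectrum, and |score| < 2 flags a low-confidence call that
warrants full assessment.
"""

from obcval import (CohortParams, binarize, generate_cohort, predict_obc,
                    save_model, score_ados_g, train_adtree)

cohort, _, _ = generate_cohort(CohortParams(n=1000, seed=11))
labels = [binarize(score_ados_g(s).classification) for s in cohort]

model = train_adtree(cohort, labels, rounds=8)
print(f"root prediction {model.root_value:+.3f}; {len(model.rules)} rules:")
for i, rule in enumerate(model.rules):
    gate = "root" if rule.precondition is None else \
        f"rule {rule.precondition[0]} {'true' if rule.precondition[1] else 'false'}"
    print(f"  {i}: under {gate}: {rule.item_id} >= {rule.threshold} ? "
          f"{rule.value_true:+.3f} : {rule.value_false:+.3f}")

for sheet in cohort.sheets[:5]:
    r = predict_obc(model, sheet)
    flag = " (low confidence)" if r.low_confidence else ""
    print(f"{sheet.subject_id}: score {r.score:+.2f} -> {r.predicted_class}{flag}")

save_model(model, "scratch_model.json")
print("saved scratch_model.json")
# Each rule adds its true/false value for every sheet that reaches it; the
# final score is the sum over all satisfied paths plus the root value.
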