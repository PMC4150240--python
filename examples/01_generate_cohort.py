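"""Generate a synthetic score-sheet cohort and inspect its structure.

The generator emulates the statistical shape of archival Module 1 score-sheet
collections: ~89% spectrum, ages ~6.2 +/- 4.3 years, 77% male, and 29 ordinal
item codes driven by one latent severity per child.
"""

import numpy as np

from obcval import CohortParams, generate_cohort, write_cohort

params = CohortParams(n=1000, seed=42)
cohort, true_labels, theta = generate_cohort(params)

n_spectrum = true_labels.count("spectrum")
ages = [s.age_years for s in cohort]
print(f"cohort: {len(cohort)} sheets, {n_spectrum} spectrum "
      f"({n_spectrum / len(cohort):.1%})")
print(f"age: mean {np.mean(ages):.2f} sd {np.std(ages):.2f} years")
print(f"latent severity: spectrum mean {np.mean([t for t, l in zip(theta, true_labels) if l == 'spectrum']):+.2f}, "
      f"control mean {np.mean([t for t, l in zip(theta, true_labels) if l == 'non_spectrum']):+.2f}")

first = cohort.sheets[0]
print(f"first sheet {first.subject_id}: A1={first.items['A1']} "
      f"B1={first.items['B1']} C2={first.items['C2']} dx={first.clinical_dx}")

write_cohort(cohort, "scratch_cohort.csv")
print("wrote scratch_cohort.csv (one row per subject, one column per item)")
# The class mix and severity separation are what make every downstream score
# (instrument totals, classifier output) covary, as the validation assumes.
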