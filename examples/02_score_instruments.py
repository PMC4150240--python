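"""Score sheets with the ADOS-G and ADOS-2 algorithms and the severity score.

Shows the two cutoff systems side by side on the same child, plus the 1-10
comparison score looked up in the (synthetic) age-by-verbal-level table.
"""

from obcval import (CohortParams, comparison_score, default_comparison_table,
                    generate_cohort, score_ados2, score_ados_g)

cohort, _, _ = generate_cohort(CohortParams(n=5, seed=7))
table = default_comparison_table()

for sheet in cohort:
    g = score_ados_g(sheet)
    a2 = score_ados2(sheet)
    cs = comparison_score(a2.total, sheet.age_years, a2.verbal_level, table)
    print(f"{sheet.subject_id}: ADOS-G social={g.social_score} "
          f"comm={g.communication_score} total={g.total} -> {g.classification}")
    print(f"          ADOS-2 [{a2.verbal_level}] SA={a2.sa_score} "
          f"RRB={a2.rrb_score} total={a2.total} -> {a2.classification}; "
          f"comparison score {cs}/10")
# ADOS-G classifies from two domain scores plus their total; ADOS-2 applies a
# single total cutoff that depends on the child's verbal level, and the
# comparison score restates that total as 1 (minimal) .. 10 (high impairment).
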