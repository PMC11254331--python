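"""Select a cohort by its initial grade and summarise where it ended up.

Mirrors the interactive cohort-explorer workflow: choose an arm, a
symptom term, the severity at the initial cycle, and a time window; get
back the trajectory matrix, a plain-language final-state statement, and
the grade-duration table (how each grade's occurrences spread over the
cycles — counted in patient-cycle cells, so a patient at grade 3 in two
cycles contributes two grade-3 cases).
"""

import toxflow as tf

table = tf.simulate_trial(tf.preset("b35-ae"), n_per_arm=400,
                          term="arthralgia", seed=7)
query = tf.CohortQuery(arm="anastrozole", term="arthralgia",
                       initial_level="3", start_stage="6 mo", end_stage="30 mo")
cohort = tf.select_cohort(table, query)
print(f"{cohort.n_patients} patients had grade 3 arthralgia at 6 months "
      "on anastrozole\n")

display = cohort.map_states(tf.CTCAE_DISPLAY_MAP, tf.ctcae_display_scale())
summary = tf.final_state_summary(display)
print(summary.statement)
print("(percents use the initial cohort size as denominator and are "
      "rounded half away from zero — they may not sum to exactly 100)\n")

print("grade duration — share of each grade's occurrences per cycle:")
for grade, dist in tf.grade_duration(display).items():
    row = ", ".join(f"{stage}: {pct}%" for stage, pct in dist.items())
    print(f"  grade {grade}: {row}")
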