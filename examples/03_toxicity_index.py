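"""The Toxicity Index: a single number for a whole toxicity profile.

With grades sorted descending w(1) >= w(2) >= ..., the index is
TI = sum_i w(i) / prod_{j<i} (1 + w(j)). Its integer part is the worst
grade; the fractional part encodes how toxic the rest of the course was,
so profiles with the same maximum grade are still ordered sensibly and
the value always stays in [max grade, max grade + 1) — below 6 for CTCAE.
"""

import toxflow as tf

profiles = {
    "one bad cycle      [3]": [3],
    "bad then moderate  [3, 2]": [3, 2],
    "two bad cycles     [3, 3, 2]": [3, 3, 2],
    "relentless grade 5 [5, 5, 5, 5]": [5, 5, 5, 5],
}
for label, grades in profiles.items():
    print(f"{label}: TI = {tf.toxicity_index(grades):.5f}")

print("\ncohort TI distribution for grade-3 starters (synthetic trial):")
table = tf.simulate_trial(tf.preset("b35-ae"), n_per_arm=400,
                          term="arthralgia", seed=7)
query = tf.CohortQuery("anastrozole", "arthralgia", "3", "6 mo", "30 mo")
cohort = tf.select_cohort(table, query)
ti = tf.cohort_ti_summary(cohort)
print(f"  n = {len(ti.values)}, mean = {ti.mean:.2f} (sd {ti.sd:.2f}), "
      f"median = {ti.median:.2f} [{ti.q1:.2f}-{ti.q3:.2f}]")
print("  every value is >= 3 (the cohort's entry grade) and < 6:",
      all(3 <= v < 6 for v in ti.values))
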