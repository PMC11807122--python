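"""Simulate a small behavioral cohort and run the full behavioral analysis.

Builds schedules and condition-calibrated synthetic responses for 12
subjects, filters RT outliers, and runs the 2x2 repeated-measures ANOVA
(probe symmetry x cognitive load) on accuracy with Greenhouse-Geisser
correction and generalized eta-squared, plus Bonferroni pairwise
contrasts.
"""

import pandas as pd

from symwm import behavior_stats as bs
from symwm import synth_behavior as sb
from symwm.schedule import build_schedule, compute_layout
from symwm.stimuli import generate_stimulus_set

stimulus_set = generate_stimulus_set(7)
layout = compute_layout()
profile = sb.default_profile()

tables = []
for s in range(12):
    schedule = build_schedule(100 + s, stimulus_set)
    records = sb.simulate_responses(profile, schedule, 200 + s,
                                    subject_id=f"sub-{s + 1:02d}")
    tables.append(bs.build_trial_table(schedule, records, layout))
table = pd.concat(tables, ignore_index=True)
table["acc"] = table["correct"] * 100.0

anova = bs.rm_anova(table, "acc", ["symmetry", "load"])
print("Accuracy RM-ANOVA (12 simulated subjects, 288 trials each):")
print(anova[["effect", "F", "df_num", "df_den", "p_gg", "ges"]]
      .to_string(index=False, float_format=lambda v: f"{v:.4g}"))

pairs = bs.pairwise_comparisons(table, "acc", ["symmetry", "load"])
print("\nBonferroni pairwise accuracy contrasts (percentage points):")
print(pairs[["contrast", "m_difference", "t", "df", "p_adjusted"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("\n-> load dominates accuracy; the symmetry advantage grows under "
      "high load (the planted interaction), matching the generator's "
      "condition probabilities.")
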