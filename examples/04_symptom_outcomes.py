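"""Relate learning trajectories to symptom change and baseline cognition.

Builds the composite anxiety/depression/general indices from the
questionnaire panel, runs the between-cluster ANOVAs on the pre-post
change scores (Tukey HSD follow-ups at a Bonferroni-shrunk alpha),
within-cluster paired t-tests, and the baseline predictor screen.
"""

import pandas as pd

import wmtraj as wt

cohort = wt.simulate_cohort(wt.CohortConfig(rng_seed=1))
part = wt.fit(cohort.matrix, 3, restarts=20, rng_seed=1)
index_table = wt.build_index_table(cohort.panels)

print("between-cluster ANOVAs on change scores (positive = improvement):")
outcomes = wt.outcome_analysis(part, index_table)
for name, entry in outcomes.items():
    a = entry["anova"]
    print(f"  {name:<18} F({a.df_between},{a.df_within}) = {a.F:.3f}, "
          f"p = {a.p:.4f}, eta2 = {a.eta2:.3f}")

anx = outcomes["anxiety_change"]
print("\nTukey HSD for anxiety change (alpha = 0.05/3):")
print(anx["tukey"].pairs.round(4).to_string(index=False))

if "paired_t" in anx:
    print("\nwithin-cluster pre-post anxiety t-tests:")
    for c, t in anx["paired_t"].items():
        print(f"  cluster {c}: t({t.df}) = {t.t:.3f}, p = {t.p:.4f}, "
              f"d = {t.cohens_d:.3f}")

pre_cols = [c for c in index_table.columns if c.endswith("_pre")]
screen = wt.predictor_screen(
    part,
    cohort.baseline.set_index("participant_id").join(index_table[pre_cols]),
    predictors=["age", "gender", "cdt_pre", "flanker_pre",
                "anxiety_pre", "depression_pre"],
)
print("\nbaseline predictor screen (uncorrected, exploratory):")
print(screen.table().round(4).to_string())

print("\nOnly the saturating high-baseline cluster shows a within-group "
      "anxiety reduction, and only the cognitive baselines (working-memory "
      "capacity, flanker interference) separate the clusters - demographics "
      "and baseline symptoms do not.")
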