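"""Does the learning trajectory mediate cognition -> anxiety improvement?

Fits the path model  CDT -> cluster -> anxiety change  by
full-information maximum likelihood (partially observed batteries
contribute their marginal likelihood), reports standardized paths with
delta-method and bootstrap intervals for the indirect effect, and
compares the model to an independence baseline.
"""

import pandas as pd

import wmtraj as wt

cohort = wt.simulate_cohort(wt.CohortConfig(rng_seed=1))
part = wt.fit(cohort.matrix, 3, restarts=20, rng_seed=1)
index_table = wt.build_index_table(cohort.panels)

fit = wt.fit_mediation(
    cohort.baseline.set_index("participant_id")["cdt_pre"],
    pd.Series(part.assignments, dtype=float),
    index_table["anxiety_change"],
    missing_policy="fiml",
)

print(f"cases used (FIML): {fit.n_used}")
for name, est in (("a  (CDT -> cluster)", fit.a),
                  ("b  (cluster -> anxiety)", fit.b),
                  ("c' (direct CDT -> anxiety)", fit.c_prime)):
    print(f"  {name:<28} beta = {est.coef:+.3f}, SE = {est.se:.3f}, "
          f"Z = {est.z:+.2f}, p = {est.p:.4f}")

est, (lo, hi) = wt.indirect_effect_test(fit, method="delta")
print(f"\nindirect effect a*b = {est:.3f}, delta 95% CI [{lo:.3f}, {hi:.3f}]")
est, (lo, hi) = wt.indirect_effect_test(fit, method="bootstrap",
                                        n_boot=200, rng_seed=1)
print(f"bootstrap 95% CI [{lo:.3f}, {hi:.3f}] (200 resamples)")

stat, df, p = fit.chi2_vs_baseline
print(f"\nmodel vs independence baseline: chi2({df}) = {stat:.2f}, p = {p:.4g}")

print("\nA positive a and b with a null direct path c' is the mediation "
      "signature: higher baseline working-memory capacity predicts landing "
      "in a better learning trajectory, which in turn carries the anxiety "
      "improvement.")
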