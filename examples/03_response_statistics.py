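"""Univariate response analysis: Welch's t-test with Hedges' g.

Simulates a cohort whose response depends on FDG uptake in medullary
concordant lesions (responders lower), then tests each feature.
"""

from dualpet import SynthConfig, generate_cohort, cohort_feature_table, welch_test

table = cohort_feature_table(generate_cohort(
    SynthConfig(n_patients=120, seed=11), render=False))
resp = table["response"] == 1

for feature in ("SUVmean[FDG medullary concordant]",
                "SUVmean[FDG extramedullary concordant]",
                "MTV[FDG medullary discordant]"):
    r = welch_test(table.loc[resp, feature], table.loc[~resp, feature])
    print(f"{feature}")
    print(f"  mean diff (resp - nonresp) = {r.mean_diff:+.2f} "
          f"[{r.ci95[0]:+.2f}, {r.ci95[1]:+.2f}], p = {r.p_two_sided:.4f}")
    print(f"  Hedges g = {r.hedges_g:+.2f} [{r.g_ci95[0]:+.2f}, {r.g_ci95[1]:+.2f}] "
          f"(n = {r.n_x}/{r.n_y})")

print("\nA negative g on the planted FDG-uptake features means responders "
      "show lower uptake; the third feature carries no planted response "
      "effect and should hover near zero.")
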