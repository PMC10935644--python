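"""Cross-sectional models: functional scores vs PET-based Braak stage.

Fits the covariate-adjusted linear models of each functional instrument
on the simplified stage groups (reference: group 0), plus the one-way
ANOVA with Tukey post-hocs, on one synthetic cohort. Betas are in
outcome-SD units; the expected qualitative pattern is FAQ/ECog effects
emerging at III-IV and CDR-SB-F only at V-VI.
"""

import braakadl as ba

cfg = ba.SyntheticConfig(seed=42)
staged = ba.stage_cohort(
    ba.generate_cohort(cfg), ba.estimate_thresholds(ba.generate_reference(cfg))
)
base = staged.baseline()

for instr, label in [("faq", "FAQ"), ("ecog", "ECog"), ("cdrsbf", "CDR-SB-F")]:
    res = ba.fit_stage_model(base, instr)
    print(f"\n{label}: adjusted R^2 = {res.adj_r2:.2f}, n = {res.n_used}")
    print(res.terms.round(3).to_string())

gc = ba.compare_groups(base, "faq")
print(f"\nFAQ one-way ANOVA: F = {gc.anova_f:.1f}, p = {gc.anova_p:.2g}")
print("Tukey HSD adjusted p-values:")
print(gc.pairwise.round(4).to_string(index=False))

print("\nDescriptive table (per stage group):")
print(ba.describe_cohort(base).round(3).to_string(index=False))
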