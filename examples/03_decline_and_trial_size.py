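"""Annual functional decline by baseline stage, and trial sample sizes.

Computes per-participant annual score changes, excludes 2.5-SD outliers,
models the z-scored rates on baseline stage group, then asks: how many
participants per arm would a trial need to detect a 25% slowing of the
mean decline at 80% power, recruiting at each stage group?
"""

import pandas as pd

import braakadl as ba

cfg = ba.SyntheticConfig(seed=42)
staged = ba.stage_cohort(
    ba.generate_cohort(cfg), ba.estimate_thresholds(ba.generate_reference(cfg))
)
base = staged.baseline()
rates = ba.compute_annual_changes(staged)
m = rates.merge(base[["id", "stage_group", "age", "sex", "abeta_suvr"]], on="id")
print(f"{len(m)} participants with a follow-up visit "
      f"(mean interval {m['followup_years'].mean():.2f} y)")

res = ba.fit_change_model(m, "faq")
print("\nAnnual FAQ change on baseline stage (z-scored rate):")
print(res.terms.round(3).to_string())

# trial planning from the observed per-group decline of the FAQ
keep = ~ba.flag_outliers(m["rate_faq"].to_numpy())
print("\nObserved FAQ decline by baseline stage (points/year, outliers excluded):")
print(m[keep].groupby("stage_group")["rate_faq"].agg(["mean", "std"]).round(2).to_string())
print("A near-zero mean decline makes a fixed fractional slowing nearly")
print("undetectable, which is what drives early-stage sample sizes upward.")
sizes = {}
for group in ("I-II", "III-IV", "V-VI"):
    r = m.loc[keep & (m["stage_group"] == group), "rate_faq"].dropna()
    sizes[group] = ba.required_sample_size(r.mean(), r.std(ddof=1))
print("\nPer-arm n for a 25% slowing of FAQ decline (alpha 0.05, power 0.80):")
table = pd.DataFrame({"faq": sizes})
print(table.to_string())
out = ba.inflation_ratios(table)
print(f"Recruiting earlier-stage participants inflates recruitment "
      f"{out['min_ratio']:.2f}-{out['max_ratio']:.2f}x vs stages V-VI.")

n = sizes["V-VI"]
r = m.loc[keep & (m["stage_group"] == "V-VI"), "rate_faq"].dropna()
power = ba.simulate_power(n, r.mean(), r.std(ddof=1), reps=2000, seed=1)
print(f"Monte-Carlo check at V-VI (n = {n}/arm): empirical power {100*power:.1f}%")
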