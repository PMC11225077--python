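"""Synthetic model inputs: stand-in life table and age-risk profiles.

The analysis needs a national life table and age-resolved event risks
that are not published alongside the model inputs.  This script builds
the Gompertz stand-in life table (calibrated to 42 remaining years of
life expectancy at age 35) and the linear age expansion of the published
event-risk ranges, and prints a few rows of each.
"""

import polypill_cea as pc

spec = pc.calibrate_gompertz(target_life_expectancy=42.0, doubling_years=8.0)
lt = pc.generate_life_table(spec)
print(f"Gompertz hazard at 35: {spec.hazard_at_start:.5f}/yr, doubling every "
      f"{spec.doubling_years:g} years")
print(f"life expectancy at 35: {lt.life_expectancy(35):.2f} years")
print("\nannual death probability q(x):")
for age in (35, 50, 65, 80, 95, 100):
    print(f"  age {age:3d}: {lt.q(age):.5f}")

params = pc.load_base_case()
prof = pc.generate_risk_profiles(params).set_index("age")
print("\nannual event risks (selected ages):")
print(prof.loc[[35, 50, 65, 85, 100]].round(4).to_string())
print(
    "\nStroke and heart-failure risks are constant; MI, angina and PVD\n"
    "risks rise linearly from their lower to upper published bound between\n"
    "ages 35 and 85 and stay clamped at the upper bound thereafter."
)
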