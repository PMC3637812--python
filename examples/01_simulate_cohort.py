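"""Simulate a synthetic colonoscopy cohort with a known latent indication.

The generator emulates a two-city cohort: each patient has a true (latent)
screening/non-screening indication, three imperfect indicators of it, and a
claims history whose code frequencies depend on the true indication.
"""

import coloscreen as cs

config = cs.SyntheticConfig.default()   # n = 1,230, prevalence 0.46
truth, indicators, claims = cs.generate_cohort(config)

print(f"patients: {len(truth)}, claims rows: {len(claims)}")
print(f"true screening fraction:        {truth['latent_indication'].mean():.3f}")
print(f"endoscopist says screening:     {indicators['endoscopist'].mean():.3f}")
print(f"patient indication 1 screening: {indicators['patient_1'].mean():.3f}")
print(f"patient indication 2 screening: {indicators['patient_2'].mean():.3f}")
print(claims.head(5).to_string(index=False))

# The indicator marginals sit near the observed study frequencies
# (46.8% / 51.0% / 38.9%) because sensitivity/specificity defaults are
# calibrated against them; the truth column is what no real study observes.
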