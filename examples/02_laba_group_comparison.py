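"""Cohort-level comparison: does LABA maintenance therapy raise heart rate?

Simulates a cohort in which LABA users carry a constant +0.8 bpm offset,
then runs the patient-first hourly comparison: each person-time segment is
reduced to a 24-hour profile before group averaging, so heavy wearers do
not dominate.  The printed overall difference should land near the
injected 0.8 bpm; the pooled-minute CI is near-degenerate at this data
volume while the patient bootstrap gives an honest interval.
"""

import numpy as np

from inhalerhr import GeneratorConfig, simulate_cohort
from inhalerhr import filter_low_wear, split_laba_person_time, hourly_patient_means
from inhalerhr import hourly_group_curve, overall_group_difference

config = GeneratorConfig(
    n_patients=30, days_per_patient=40, laba_offset_bpm=0.8, laba_fraction=0.7,
    saba_kernel=None, rng_seed=7,
)
bundle = simulate_cohort(config)

kept, removal = filter_low_wear(bundle)
print(f"wear filter kept {len(kept)}/{len(bundle)} patients")

segments = split_laba_person_time(kept)
profiles = [hourly_patient_means(s) for s in segments if len(s.hr)]
curve = hourly_group_curve(profiles)
result = overall_group_difference(profiles, segments, seed=7)

print("\nhour  LABA   no-LABA  difference (bpm)")
for h in (3, 9, 15, 21):
    row = curve.table.loc[h]
    print(f"  {h:02d}  {row.laba_mean:6.2f} {row.non_laba_mean:8.2f} {row.difference:8.2f}")

print(f"\noverall difference (patient-first): {result.difference:.3f} bpm")
print(f"pooled-minute 95% CI:   [{result.pooled_ci[0]:.3f}, {result.pooled_ci[1]:.3f}]")
print(f"patient bootstrap 95% CI: [{result.bootstrap_ci[0]:.3f}, {result.bootstrap_ci[1]:.3f}]")
# The injected offset is 0.8 bpm -- well under the 5 bpm threshold usually
# taken as clinically relevant for sustained heart-rate change.
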