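"""The drug-effect kernel and the night-wear calibration, in isolation.

Shows the two closed-form building blocks of the generator: the piecewise
reliever kernel built from threshold-crossing landmarks, and the solver
that converts a target nighttime data share into a wear probability.
"""

import numpy as np

from inhalerhr import saba_landmark_kernel, build_kernel, night_retention_for_fraction

kernel = saba_landmark_kernel()
print("reliever heart-rate kernel (landmark construction):")
print(f"  ramp starts:        -{kernel.onset_lead_min:.2f} min")
print(f"  5 bpm crossing:     -17 min  -> kernel(-17) = {kernel(np.array([-17.0]))[0]:.3f}")
print(f"  actuation minute:    kernel(0)   = {kernel(np.array([0.0]))[0]:.3f} bpm")
print(f"  peak:                kernel(9)   = {kernel(np.array([9.0]))[0]:.3f} bpm")
print(f"  return anchor:       kernel(138) = {kernel(np.array([138.0]))[0]:.3f} bpm")
print(f"  decay rate:          {kernel.decay_rate:.6f} per min "
      "(solved so the decay hits the threshold at the return anchor)")

series = build_kernel(kernel)
print(f"  grid: {series.index[0]}..{series.index[-1]} min, "
      f"area {series.sum():.0f} bpm*min")

print("\nnight-wear calibration (share of minutes in 00:00-06:00):")
for target in (0.10, 0.187, 0.25):
    p = night_retention_for_fraction(target, day_retention=1.0)
    print(f"  target {100 * target:5.1f}%  ->  night retention p = {p:.3f}")
# With uniform wear the night share caps at 25% (6 of 24 hours); 18.7%
# corresponds to wearing the device about 69% of night hours.
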