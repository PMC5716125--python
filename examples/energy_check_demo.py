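"""Beam-energy consistency from the step-wedge signal levels.

Builds the six signal levels (air + five steps) for a range of beam
qualities, fits the exponential depth-dose model, and prints the recovered
D20/D10 ratio next to the generating one — the same consistency index a
physicist would trend to catch target wear (energy drifting low) before it
becomes clinically relevant.
"""

import numpy as np

import stepwedge as sw

wedge = sw.StepWedgeSpec()
depths = np.concatenate([[0.0], sw.water_equivalent_depths(wedge)])

print("water-equivalent depths (mm):", np.round(depths, 1))
print()
print("true D20/D10   recovered   difference (%)")
for true_ratio in (0.536, 0.520, 0.519, 0.514, 0.499):
    mu = -np.log(true_ratio) / 100.0          # effective attenuation per mm water
    rng = np.random.default_rng(int(true_ratio * 1e4))
    levels = np.exp(-mu * depths) * (1.0 + 2e-4 * rng.standard_normal(depths.size))
    fit = sw.fit_pdd_exponential(levels, depths)
    diff = sw.percent_ratio_difference(fit.d20_d10, true_ratio)
    print(f"   {true_ratio:.3f}        {fit.d20_d10:.4f}       {diff:+.2f}")
print()
print("Differences of a few hundredths of a percent reflect the level noise;")
print("the clinical action tolerance on this beam-quality index is 1%.")
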