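"""Abutment check of an interrupted and completed delivery.

Interrupts a simulated step-wedge delivery mid-slope, resumes it with a
deliberate couch-position error, and estimates that error by registering the
completion's time profile against the straight-line continuation of the
interrupted profile.  Positive = overlap (dose peak), negative = gap (dose
dip); about 8% local dose error per millimetre of mismatch.
"""

import stepwedge as sw

geom = sw.MachineGeometry()

print("induced (mm)   estimated (mm)   approx. dose error at abutment")
for induced in (-1.0, -0.5, 0.0, 0.5, 1.0):
    scenario = sw.SimulationScenario(seed=99)
    fraction = sw.slope_interrupt_fraction(scenario, slope_index=2, within=0.45)
    first, second, _ = sw.simulate_completion_pair(scenario, fraction, induced)

    profile_1 = sw.extract_time_profile(sw.output_correct(first))
    profile_2 = sw.extract_time_profile(sw.output_correct(second))
    result = sw.estimate_abutment_shift(profile_1, profile_2, geom, refine=False)
    dose = sw.abutment_dose_perturbation(result.shift_mm)
    kind = "peak" if dose > 0 else ("dip" if dose < 0 else "none")
    print(f"   {induced:+.1f}          {result.shift_mm:+.2f}            "
          f"{abs(dose):.0f}% {kind}")

print()
print("A mismatch of 0.5 mm (about 4% local dose error) is the action level;")
print("the estimator resolves single projections, i.e. ~0.03 mm of couch travel.")
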