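"""Estimator-validation suites: induced deviations recovered in simulation.

Each suite reproduces one induced-deviation design on simulated
acquisitions — couch-speed factors −2..+2% in 0.5% steps, slit widths
9.7..11.1 mm in 0.2 mm steps, lateral wedge offsets −3..+3 mm in 1 mm
steps, beam-quality ratios spanning 0.499..0.536, and completion mismatches
−1..+1 mm — runs the full estimation chain on each scenario, and summarises
the recovery error.  All scenario noise is the nominal detector noise of
0.5% (1 SD); seeds are derived deterministically from a single base seed.

These functions back both the acceptance checks and the package's own
regression tests.
"""

from __future__ import annotations

import numpy as np

from .acquisition import (
    extract_time_profile,
    extract_transverse_profiles,
    output_correct,
)
from .completion import estimate_abutment_shift
from .geometry import (
    MachineGeometry,
    StepWedgeSpec,
    channels_to_isocenter_mm,
    water_equivalent_depths,
)
from .simulate import (
    SimulationScenario,
    simulate_acquisition,
    simulate_completion_pair,
    slope_interrupt_fraction,
)
from .timeprofile import couch_speed_deviation, field_width, fit_schematic_profile
from .transverse import analyze_centers, fit_pdd_exponential

#: Beam-quality ratios spanning the induced-energy validation range.
ENERGY_RATIOS = (0.536, 0.520, 0.519, 0.514, 0.499)


def _scenario_seed(base_seed: int, index: int) -> int:
    return (1000 * base_seed + index) % (2**31 - 1)


def _fitted_scenario(scn: SimulationScenario, restarts: int, fit_seed: int):
    acq, truth = simulate_acquisition(scn)
    acq = output_correct(acq)
    profile = extract_time_profile(acq)
    fit = fit_schematic_profile(
        profile, scn.geom, scn.wedge, restarts=restarts, seed=fit_seed
    )
    return acq, truth, fit


def couch_speed_suite(seed: int = 1, restarts: int = 10) -> dict:
    """Recover couch-speed deviations of −2..+2% (0.5% steps, 9 scenarios).

    Returns per-scenario errors (measured − induced deviation, in %) and
    their mean absolute value.
    """
    factors = 1.0 + np.arange(-2.0, 2.01, 0.5) / 100.0
    geom, wedge = MachineGeometry(), StepWedgeSpec()
    errors = []
    for i, f in enumerate(factors, start=1):
        scn = SimulationScenario(
            geom=geom, wedge=wedge, couch_speed_factor=float(f),
            seed=_scenario_seed(seed, i),
        )
        _, _, fit = _fitted_scenario(scn, restarts, fit_seed=i)
        measured, _ = couch_speed_deviation(fit, geom, wedge)
        errors.append(measured - 100.0 * (f - 1.0))
    errors = np.array(errors)
    return {
        "induced_pct": (100.0 * (factors - 1.0)).tolist(),
        "errors_pct": errors.tolist(),
        "mean_abs_error_pct": float(np.mean(np.abs(errors))),
        "n": int(factors.size),
    }


def field_width_suite(seed: int = 1, restarts: int = 10) -> dict:
    """Recover slit widths 9.7..11.1 mm (0.2 mm steps, 8 scenarios).

    Returns per-scenario errors (estimated − true width, mm) and their SD.
    """
    widths = np.arange(9.7, 11.11, 0.2)
    geom, wedge = MachineGeometry(), StepWedgeSpec()
    errors = []
    for i, w in enumerate(widths, start=1):
        scn = SimulationScenario(
            geom=geom, wedge=wedge, field_width_mm=float(w),
            seed=_scenario_seed(seed, 100 + i),
        )
        _, _, fit = _fitted_scenario(scn, restarts, fit_seed=i)
        errors.append(field_width(fit, geom) - w)
    errors = np.array(errors)
    return {
        "true_width_mm": widths.tolist(),
        "errors_mm": errors.tolist(),
        "sd_error_mm": float(errors.std(ddof=1)),
        "n": int(widths.size),
    }


def sagittal_laser_suite(seed: int = 1, restarts: int = 10) -> dict:
    """Recover lateral wedge offsets −3..+3 mm (1 mm steps, 7 scenarios).

    Each offset is recovered as the mean modified-Gaussian center of the
    five air-normalised step profiles relative to the detector-center dip,
    back-projected to isocenter.  Returns errors and their SD.
    """
    offsets = np.arange(-3.0, 3.01, 1.0)
    geom, wedge = MachineGeometry(), StepWedgeSpec()
    errors = []
    for i, off in enumerate(offsets, start=1):
        scn = SimulationScenario(
            geom=geom, wedge=wedge, lateral_offset_mm=float(off),
            seed=_scenario_seed(seed, 200 + i),
        )
        acq, _, fit = _fitted_scenario(scn, restarts, fit_seed=i)
        profiles = extract_transverse_profiles(acq, fit)
        centers = analyze_centers(profiles, geom, restarts=restarts, seed=i)
        recovered = channels_to_isocenter_mm(
            centers.sagittal_laser_channel - centers.detector_center_channel, geom
        )
        errors.append(recovered - off)
    errors = np.array(errors)
    return {
        "induced_offset_mm": offsets.tolist(),
        "errors_mm": errors.tolist(),
        "sd_error_mm": float(errors.std(ddof=1)),
        "n": int(offsets.size),
    }


def energy_suite(seed: int = 1, restarts: int = 10) -> dict:
    """Recover D20/D10 ratios spanning 0.499..0.536 (5 scenarios).

    Acquisitions are simulated at the matching effective attenuation
    coefficients, the schematic fit extracts the six levels, the exponential
    PDD fit yields the measured ratio.  Returns absolute relative errors (%)
    and their mean.
    """
    geom, wedge = MachineGeometry(), StepWedgeSpec()
    depths = np.concatenate([[0.0], water_equivalent_depths(wedge)])
    errors = []
    for i, ratio in enumerate(ENERGY_RATIOS, start=1):
        mu = -np.log(ratio) / 100.0
        scn = SimulationScenario(
            geom=geom, wedge=wedge, mu_eff_per_mm=float(mu),
            seed=_scenario_seed(seed, 300 + i),
        )
        _, _, fit = _fitted_scenario(scn, restarts, fit_seed=i)
        pdd = fit_pdd_exponential(fit.s[:6], depths)
        errors.append(100.0 * (pdd.d20_d10 / ratio - 1.0))
    errors = np.array(errors)
    return {
        "true_ratio": list(ENERGY_RATIOS),
        "errors_pct": errors.tolist(),
        "mean_abs_error_pct": float(np.mean(np.abs(errors))),
        "n": len(ENERGY_RATIOS),
    }


def abutment_suite(seed: int = 1, seeds_per_mismatch: int = 3) -> dict:
    """Recover completion mismatches −1, −0.5, 0, +0.5, +1 mm.

    Each mismatch is simulated ``seeds_per_mismatch`` times and estimated by
    the integer-projection SSE registration.  Returns recovery errors
    (estimated − induced, mm) and their SD.
    """
    mismatches = (-1.0, -0.5, 0.0, 0.5, 1.0)
    geom, wedge = MachineGeometry(), StepWedgeSpec()
    errors = []
    run = 0
    for m in mismatches:
        for _ in range(seeds_per_mismatch):
            run += 1
            scn = SimulationScenario(
                geom=geom, wedge=wedge, seed=_scenario_seed(seed, 400 + run)
            )
            frac = slope_interrupt_fraction(scn, slope_index=2, within=0.45)
            first, second, _ = simulate_completion_pair(scn, frac, m)
            p1 = extract_time_profile(output_correct(first))
            p2 = extract_time_profile(output_correct(second))
            result = estimate_abutment_shift(p1, p2, geom, refine=False)
            errors.append(result.shift_mm - m)
    errors = np.array(errors)
    return {
        "induced_mm": list(mismatches),
        "errors_mm": errors.tolist(),
        "sd_error_mm": float(errors.std(ddof=1)),
        "n": int(errors.size),
    }
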