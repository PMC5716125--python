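"""Synthetic detector acquisitions with known ground truth.

The simulator emulates the static-gantry step-wedge delivery: a 10 mm slit
beam, couch moving at 1 mm/s, the five-step aluminum wedge traversing the
beam thin end first while the 640-channel MVCT detector records.  It is the
fixture generator for every estimator in this package — each machine
parameter the QA method measures (couch speed, field width, beam energy via
the effective attenuation coefficient, lateral/longitudinal setup offsets,
abutment mismatch) is a scenario field, and the exact generating values are
returned alongside the acquisition.

Longitudinal model: the slit of width *w* integrates transmission as the
wedge moves at speed *v*; each level transmits ``exp(-mu * depth_k)`` and a
level boundary crossing the slit produces a linear ramp of duration ``w/v``,
reproducing the 7-flat/6-slope schematic shape.  Transverse model: a broad
modified-Gaussian air profile with a narrow multiplicative dip at the
channel opposing the focus; the wedge attenuates a lateral window of its
physical width (back-projected to channels) with short smoothed edges.
Output fluctuations enter as a common multiplicative factor on detector and
monitor signals so that monitor correction can undo them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .acquisition import DetectorAcquisition
from .errors import SimulationError
from .geometry import (
    MachineGeometry,
    StepWedgeSpec,
    isocenter_mm_to_channels,
    water_equivalent_depths,
)
from .timeprofile import _KNOT_LEVEL

#: Default effective attenuation coefficient (per mm of water).  Chosen to
#: give D20/D10 ≈ 0.519, the mid-range beam-quality ratio of a flattening-
#: filter-free 6 MV tomotherapy beam under normal injector settings.
DEFAULT_MU_PER_MM = -np.log(0.519) / 100.0

#: Relative depth of the septa-alignment dip at the detector center channel
#: and its Gaussian width in channels.  The real dip shape is not published;
#: this notch is a synthetic stand-in sized so center-channel detection works
#: without modelling detector physics (flagged in truth records).
DIP_AMPLITUDE = 0.05
DIP_SIGMA_CHANNELS = 3.0


@dataclass(frozen=True)
class ReferencePDD:
    """Reference percentage-depth-dose curve, normalised to 100 at 50 mm.

    Stands in for the water-tank PDD measured at commissioning: an exact
    exponential, so closed-form checks exist.
    """

    depth_mm: np.ndarray
    dose_rel: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "depth_mm", np.asarray(self.depth_mm, dtype=float))
        object.__setattr__(self, "dose_rel", np.asarray(self.dose_rel, dtype=float))
        if self.depth_mm.shape != self.dose_rel.shape or self.depth_mm.ndim != 1:
            raise SimulationError("depth and dose grids must be matching vectors")
        d50 = float(np.interp(50.0, self.depth_mm, self.dose_rel))
        if abs(d50 - 100.0) > 1e-6:
            raise SimulationError("reference PDD must be normalised to 100 at 50 mm")
        beyond = self.dose_rel[self.depth_mm >= 50.0]
        if np.any(np.diff(beyond) >= 0):
            raise SimulationError("reference PDD must decrease beyond 50 mm depth")

    @property
    def d20_d10(self) -> float:
        """Ratio of PDD values at 200 mm and 100 mm depth."""
        return float(
            np.interp(200.0, self.depth_mm, self.dose_rel)
            / np.interp(100.0, self.depth_mm, self.dose_rel)
        )


def make_reference_pdd(
    mu_eff_per_mm: float, depth_mm: np.ndarray | None = None
) -> ReferencePDD:
    """Exponential reference PDD: ``dose(d) = 100 * exp(-mu * (d - 50))``."""
    if mu_eff_per_mm <= 0:
        raise SimulationError("mu_eff_per_mm must be positive")
    if depth_mm is None:
        depth_mm = np.arange(0.0, 301.0, 1.0)
    dose = 100.0 * np.exp(-mu_eff_per_mm * (np.asarray(depth_mm, float) - 50.0))
    return ReferencePDD(depth_mm=depth_mm, dose_rel=dose)


@dataclass(frozen=True)
class SimulationScenario:
    """Ground-truth machine state for one simulated acquisition.

    Defaults are the nominal study conditions: 300 s beam-on at 30 Hz,
    nominal couch speed and 10 mm slit, wedge entering the beam 40 s into
    the acquisition (expected p1 = 1200), detector noise 0.5% (1 SD,
    multiplicative per reading) and a 1% sinusoidal output ripple.
    """

    geom: MachineGeometry = field(default_factory=MachineGeometry)
    wedge: StepWedgeSpec = field(default_factory=StepWedgeSpec)
    couch_speed_factor: float = 1.0
    field_width_mm: float = 10.0
    mu_eff_per_mm: float = DEFAULT_MU_PER_MM
    lateral_offset_mm: float = 0.0
    longitudinal_offset_mm: float = 0.0
    noise_rel: float = 0.005
    output_ripple: tuple[float, float] = (0.01, 10.0)  # (relative amplitude, period s)
    wedge_entry_s: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.9 < self.couch_speed_factor < 1.1:
            raise SimulationError("couch_speed_factor must lie in (0.9, 1.1)")
        if not 5.0 < self.field_width_mm < 15.0:
            raise SimulationError("field_width_mm must lie in (5, 15)")
        if self.noise_rel < 0:
            raise SimulationError("noise_rel must be non-negative")
        if self.mu_eff_per_mm <= 0:
            raise SimulationError("mu_eff_per_mm must be positive")
        if self.seed is None:
            raise SimulationError("seed must be set")


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _position_knots(scn: SimulationScenario) -> tuple[np.ndarray, np.ndarray]:
    """Transmission vs wedge position: knot positions (mm past slit entry)
    and the seven flat levels [air, step1..5, air]."""
    depths = water_equivalent_depths(scn.wedge)
    levels = np.concatenate([[1.0], np.exp(-scn.mu_eff_per_mm * depths), [1.0]])
    bounds = scn.wedge.boundary_positions_mm  # 6 boundaries 0..150
    knots = np.empty(12)
    knots[0::2] = bounds
    knots[1::2] = bounds + scn.field_width_mm
    return knots, levels


def _transmission_at_position(scn: SimulationScenario, xi: np.ndarray) -> np.ndarray:
    """Longitudinal transmission for wedge travel coordinate ``xi`` (mm)."""
    knots, levels = _position_knots(scn)
    return np.interp(xi, knots, levels[_KNOT_LEVEL])


def _air_profile(scn: SimulationScenario) -> tuple[np.ndarray, float]:
    """Transverse air profile over all channels and the detector-center
    channel (where the septa-alignment dip sits)."""
    g = scn.geom
    x = np.arange(g.n_channels, dtype=float)
    center = (g.n_channels - 1) / 2.0
    broad = 0.05 + np.exp(-0.5 * (np.abs(x - center) / 150.0) ** 4.0)
    dip = 1.0 - DIP_AMPLITUDE * np.exp(-0.5 * ((x - center) / DIP_SIGMA_CHANNELS) ** 2)
    return broad * dip, center


def _wedge_window(scn: SimulationScenario) -> np.ndarray:
    """Per-channel lateral coverage of the wedge (0 outside, 1 under it),
    with 2-channel linear edge smoothing."""
    g = scn.geom
    x = np.arange(g.n_channels, dtype=float)
    center = (g.n_channels - 1) / 2.0 + isocenter_mm_to_channels(
        scn.lateral_offset_mm, g
    )
    half = isocenter_mm_to_channels(scn.wedge.width_mm / 2.0, g)
    return np.clip((half - np.abs(x - center)) / 2.0 + 0.5, 0.0, 1.0)


def _output_factor(scn: SimulationScenario, t: np.ndarray, rng) -> np.ndarray:
    amp, period = scn.output_ripple
    out = 1.0 + amp * np.sin(2.0 * np.pi * t / period)
    # The monitor chamber integrates the whole beam, so its own noise is an
    # order of magnitude below single-channel noise.
    out_monitor = out * (1.0 + (scn.noise_rel / 10.0) * rng.standard_normal(t.size))
    return out, out_monitor


def _assemble(
    scn: SimulationScenario,
    transmission: np.ndarray,
    t: np.ndarray,
    rng,
    row_scale: np.ndarray | None = None,
) -> DetectorAcquisition:
    """Build a noisy acquisition from a longitudinal transmission trace."""
    air, _ = _air_profile(scn)
    window = _wedge_window(scn)
    factor = (1.0 - window[None, :]) + window[None, :] * transmission[:, None]
    signal = air[None, :] * factor
    if row_scale is not None:
        signal = signal * row_scale[:, None]
    out, out_monitor = _output_factor(scn, t, rng)
    signal = signal * out[:, None]
    if scn.noise_rel > 0:
        signal = signal * (1.0 + scn.noise_rel * rng.standard_normal(signal.shape))
    np.clip(signal, 0.0, None, out=signal)
    return DetectorAcquisition(
        signal=signal,
        monitor=out_monitor,
        dt_s=scn.geom.dt_s,
        meta={"machine_id": "SIM", "procedure": "stepwedge", "seed": scn.seed},
    )


def _truth(scn: SimulationScenario) -> dict:
    g = scn.geom
    v = g.couch_speed_mm_s * scn.couch_speed_factor
    t_enter = scn.wedge_entry_s + scn.longitudinal_offset_mm / v
    knots, levels = _position_knots(scn)
    p_true = (t_enter + knots / v) / g.dt_s
    return {
        "scenario": {
            k: v_
            for k, v_ in asdict(scn).items()
            if k not in ("geom", "wedge")
        },
        "couch_speed_mm_s": v,
        "wedge_entry_s": t_enter,
        "p_projections": p_true.tolist(),
        "levels": levels.tolist(),
        "detector_center_channel": (g.n_channels - 1) / 2.0,
        "wedge_center_channel": (g.n_channels - 1) / 2.0
        + isocenter_mm_to_channels(scn.lateral_offset_mm, g),
        "d20_d10": float(np.exp(-100.0 * scn.mu_eff_per_mm)),
        "dip_is_synthetic_standin": True,
    }


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def simulate_acquisition(
    scn: SimulationScenario,
) -> tuple[DetectorAcquisition, dict]:
    """Simulate one full step-wedge acquisition.

    Returns the acquisition and a ground-truth record holding every scenario
    field plus the exact transition coordinates and levels.
    """
    g = scn.geom
    truth = _truth(scn)
    v = truth["couch_speed_mm_s"]
    t_enter = truth["wedge_entry_s"]
    end_of_wedge = t_enter + (scn.wedge.length_mm + scn.field_width_mm) / v
    if t_enter <= 1.0 or end_of_wedge >= g.acquisition_s - 1.0:
        raise SimulationError(
            "wedge travel inconsistent with acquisition duration: wedge spans "
            f"{t_enter:.1f}..{end_of_wedge:.1f} s of a {g.acquisition_s:.0f} s beam"
        )
    n = g.n_projections
    t = np.arange(n) * g.dt_s
    xi = (t - t_enter) * v
    transmission = _transmission_at_position(scn, xi)
    rng = np.random.default_rng(scn.seed)
    acq = _assemble(scn, transmission, t, rng)
    return acq, truth


def slope_interrupt_fraction(
    scn: SimulationScenario, slope_index: int = 2, within: float = 0.45
) -> float:
    """Fraction of the acquisition at which to interrupt so that the beam is
    ``within`` of the way down slope ``slope_index`` (0..5)."""
    truth = _truth(scn)
    v = truth["couch_speed_mm_s"]
    xi = scn.wedge.boundary_positions_mm[slope_index] + within * scn.field_width_mm
    return float((truth["wedge_entry_s"] + xi / v) / scn.geom.acquisition_s)


def simulate_completion_pair(
    scn: SimulationScenario,
    interrupt_fraction: float,
    induced_mismatch_mm: float = 0.0,
    closed_leaf_s: float = 10.0,
    leak_fraction: float = 0.01,
) -> tuple[DetectorAcquisition, DetectorAcquisition, dict]:
    """Simulate an interrupted acquisition and its machine-generated completion.

    The first acquisition stops at ``interrupt_fraction`` of the beam-on
    time, which must fall on a slope of the time profile.  The second starts
    with a ``closed_leaf_s`` flat segment at leakage level (the system
    stabilising output with all leaves closed), shows the brief all-leaves
    transient dip shortly after resuming, and then continues the delivery
    with the couch start position offset by ``induced_mismatch_mm``
    (positive = overlap: material re-irradiated; negative = gap).
    """
    if abs(induced_mismatch_mm) > 2.0:
        raise SimulationError("|induced_mismatch_mm| must not exceed 2 mm")
    g = scn.geom
    truth = _truth(scn)
    v = truth["couch_speed_mm_s"]
    t_enter = truth["wedge_entry_s"]
    t_int = interrupt_fraction * g.acquisition_s
    xi_int = (t_int - t_enter) * v

    knots, _ = _position_knots(scn)
    on_slope = False
    for j in range(0, 12, 2):
        lo, hi = knots[j], knots[j + 1]
        margin = 0.02 * (hi - lo)
        if lo + margin < xi_int < hi - margin:
            on_slope = True
            break
    if not on_slope:
        raise SimulationError(
            "must interrupt on slope: the chosen interruption point falls on a "
            "flat segment of the time profile"
        )

    rng = np.random.default_rng(scn.seed)
    n1 = int(np.floor(t_int / g.dt_s))
    t1 = np.arange(n1) * g.dt_s
    xi1 = (t1 - t_enter) * v
    first = _assemble(scn, _transmission_at_position(scn, xi1), t1, rng)

    # Second acquisition: closed-leaf flat, then the remainder of the wedge.
    rng2 = np.random.default_rng(scn.seed + 1)
    remaining_s = (scn.wedge.length_mm + scn.field_width_mm - xi_int) / v + 10.0
    n2 = int(np.ceil((closed_leaf_s + remaining_s) / g.dt_s))
    i_open = int(round(closed_leaf_s / g.dt_s))
    t2 = np.arange(n2) * g.dt_s
    idx = np.arange(n2)
    xi2 = xi_int - induced_mismatch_mm + (idx - i_open) * v * g.dt_s
    trans2 = _transmission_at_position(scn, xi2)
    row_scale = np.ones(n2)
    row_scale[:i_open] = leak_fraction
    trans2[:i_open] = 1.0  # closed leaves: leakage is position-independent
    # All-leaves-closed transient ~0.5 s after resumption (3 projections).
    dip_at = i_open + int(round(0.5 / g.dt_s))
    row_scale[dip_at : dip_at + 3] = leak_fraction
    second = _assemble(scn, trans2, t2, rng2, row_scale=row_scale)
    second.meta["procedure"] = "completion"

    truth.update(
        {
            "interrupt_projection": n1,
            "interrupt_time_s": t_int,
            "interrupt_position_mm": xi_int,
            "reopen_projection": i_open,
            "induced_mismatch_mm": induced_mismatch_mm,
            "closed_leaf_s": closed_leaf_s,
        }
    )
    return first, second, truth
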