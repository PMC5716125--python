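"""Machine and phantom geometry: constants, invariants and unit conversions.

Every other module works in three coordinate systems:

* **channels** — lateral index on the 640-cavity MVCT arc (0-based, may be
  fractional),
* **projections** — time samples of the detector stream (0-based, fractional
  for fitted transition coordinates),
* **millimetres at isocenter** — the physical scale QA tolerances are
  written in.

The conversions between them are a single back-projection factor SAD/SDD for
channels and ``dt * couch_speed`` for projections.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError

#: Sampling interval of the down-sampled (10:1) detector stream, in seconds.
#: 300 s of beam-on time at this rate gives 9000 projections.
DT_30HZ = 1.0 / 30.0

#: Rounded "time per projection" conventionally used when quoting projection
#: counts in millimetres (8 projections -> 0.2 mm at 1 mm/s).  Exposed
#: separately from :data:`DT_30HZ`; an analysis uses one or the other, never
#: a silent mix.
DT_30MS = 0.030


@dataclass(frozen=True)
class MachineGeometry:
    """Fixed geometry and nominal delivery parameters of the treatment unit.

    Defaults describe a Hi-Art-style helical tomotherapy machine operated in
    the static-gantry step-wedge procedure: 1 cm slit, 1 mm/s couch,
    300 s beam-on.
    """

    sad_cm: float = 85.0
    sdd_cm: float = 142.0
    detector_radius_cm: float = 110.0
    n_channels: int = 640
    channel_pitch_mm: float = 1.2
    channel_length_mm: float = 42.0
    dt_s: float = DT_30HZ
    couch_speed_mm_s: float = 1.0
    field_width_mm: float = 10.0
    acquisition_s: float = 300.0

    def __post_init__(self) -> None:
        positive = {
            "sad_cm": self.sad_cm,
            "sdd_cm": self.sdd_cm,
            "detector_radius_cm": self.detector_radius_cm,
            "n_channels": self.n_channels,
            "channel_pitch_mm": self.channel_pitch_mm,
            "channel_length_mm": self.channel_length_mm,
            "dt_s": self.dt_s,
            "couch_speed_mm_s": self.couch_speed_mm_s,
            "field_width_mm": self.field_width_mm,
            "acquisition_s": self.acquisition_s,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ConfigError(f"{name} must be strictly positive, got {value!r}")
        if not self.sad_cm < self.sdd_cm:
            raise ConfigError("sad_cm must be smaller than sdd_cm")
        if self.n_channels % 2 != 0:
            raise ConfigError("n_channels must be even")

    @property
    def magnification(self) -> float:
        """Detector-plane magnification SDD/SAD (≈1.67)."""
        return self.sdd_cm / self.sad_cm

    @property
    def n_projections(self) -> int:
        """Number of projections in one nominal acquisition."""
        return round(self.acquisition_s / self.dt_s)


@dataclass(frozen=True)
class StepWedgeSpec:
    """The five-step aluminum wedge phantom.

    The wedge is traversed thin end first; each level presents a known
    water-equivalent depth obtained from the aluminum thickness and the bulk
    density ratio (water density taken as 1).
    """

    step_lengths_mm: tuple[float, ...] = (29.9, 30.0, 30.0, 30.0, 30.1)
    step_thicknesses_mm: tuple[float, ...] = (19.5, 39.0, 58.5, 78.0, 97.6)
    density_g_cm3: float = 2.69
    width_mm: float = 69.7
    travel_mm: float = 200.0

    def __post_init__(self) -> None:
        if len(self.step_lengths_mm) != 5 or len(self.step_thicknesses_mm) != 5:
            raise ConfigError("the wedge has exactly five steps")
        if any(v <= 0 for v in self.step_lengths_mm + self.step_thicknesses_mm):
            raise ConfigError("step lengths and thicknesses must be positive")
        if np.any(np.diff(self.step_thicknesses_mm) <= 0):
            raise ConfigError("step thicknesses must be strictly increasing")
        if abs(sum(self.step_lengths_mm) - 150.0) > 1e-9:
            raise ConfigError("step lengths must sum to 150 mm")
        if not self.density_g_cm3 > 1:
            raise ConfigError("density_g_cm3 must exceed 1 (denser than water)")
        if self.width_mm <= 0 or self.travel_mm <= 0:
            raise ConfigError("width_mm and travel_mm must be positive")

    @property
    def length_mm(self) -> float:
        return float(sum(self.step_lengths_mm))

    @property
    def boundary_positions_mm(self) -> np.ndarray:
        """Longitudinal positions of the six level boundaries (0 .. 150 mm),
        measured from the thin leading edge."""
        return np.concatenate([[0.0], np.cumsum(self.step_lengths_mm)])


def water_equivalent_depths(wedge: StepWedgeSpec) -> np.ndarray:
    """Water-equivalent depth of each step, in mm of water.

    Aluminum thickness is scaled by the bulk density ratio (19.5 mm of
    aluminum at 2.69 g/cm^3 ≈ 52.5 mm of water).  No energy-dependent
    stopping-power correction is applied.
    """
    return np.asarray(wedge.step_thicknesses_mm, dtype=float) * wedge.density_g_cm3


def channels_to_isocenter_mm(delta_channels: float, geom: MachineGeometry) -> float:
    """Back-project a lateral distance in detector channels to isocenter mm.

    Linear in its argument; sign is preserved.  One 1.2 mm channel maps to
    ≈0.72 mm at isocenter.
    """
    return delta_channels * geom.channel_pitch_mm * geom.sad_cm / geom.sdd_cm


def isocenter_mm_to_channels(delta_mm: float, geom: MachineGeometry) -> float:
    """Inverse of :func:`channels_to_isocenter_mm`."""
    return delta_mm * geom.sdd_cm / (geom.sad_cm * geom.channel_pitch_mm)


def projections_to_mm(n_projections: float, dt_s: float, couch_speed_mm_s: float) -> float:
    """Convert a projection count to millimetres of couch travel."""
    if dt_s <= 0 or couch_speed_mm_s <= 0:
        raise ValueError("dt_s and couch_speed_mm_s must be positive")
    return n_projections * dt_s * couch_speed_mm_s


def mm_to_projections(mm: float, dt_s: float, couch_speed_mm_s: float) -> float:
    """Inverse of :func:`projections_to_mm`."""
    if dt_s <= 0 or couch_speed_mm_s <= 0:
        raise ValueError("dt_s and couch_speed_mm_s must be positive")
    return mm / (dt_s * couch_speed_mm_s)


# ---------------------------------------------------------------------------
# machine.json configuration
# ---------------------------------------------------------------------------

def load_machine_config(path) -> tuple[MachineGeometry, StepWedgeSpec]:
    """Load a ``machine.json`` config holding geometry and wedge fields.

    The file is a JSON object with optional ``"machine"`` and ``"wedge"``
    sub-objects; omitted fields fall back to the defaults above.  Unknown
    keys are rejected.
    """
    try:
        with open(path, "r", encoding="utf-8") as fh:
            raw = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot read machine config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("machine config must be a JSON object")
    unknown = set(raw) - {"machine", "wedge"}
    if unknown:
        raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")

    def build(cls, section):
        data = raw.get(section, {})
        if not isinstance(data, dict):
            raise ConfigError(f"config section {section!r} must be an object")
        allowed = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - allowed
        if bad:
            raise ConfigError(f"unknown keys in {section!r}: {sorted(bad)}")
        for key in ("step_lengths_mm", "step_thicknesses_mm"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    return build(MachineGeometry, "machine"), build(StepWedgeSpec, "wedge")


def save_machine_config(path, geom: MachineGeometry, wedge: StepWedgeSpec) -> None:
    """Write geometry and wedge to a ``machine.json`` file."""
    payload = {"machine": dataclasses.asdict(geom), "wedge": dataclasses.asdict(wedge)}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
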