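"""Full QA runs: orchestration, tolerance flags, and the trend ledger.

``run_stepwedge_qa`` executes the whole chain — output correction, schematic
time-profile fit, couch/field/laser metrics, transverse-profile fits, the
two PDD routes — and flags every metric against a tolerance set.  Reports
serialise to JSON and append to a JSON-lines trend ledger from which
per-metric means and standard deviations are summarised.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from .acquisition import (
    DetectorAcquisition,
    extract_time_profile,
    extract_transverse_profiles,
    output_correct,
    read_acquisition,
)
from .errors import StepWedgeError
from .geometry import MachineGeometry, StepWedgeSpec, water_equivalent_depths
from .timeprofile import compute_metrics, fit_schematic_profile
from .transverse import analyze_centers, energy_consistency, fit_pdd_exponential


@dataclass(frozen=True)
class ToleranceSet:
    """Action tolerances per metric; values within 80% of tolerance pass,
    within tolerance warn, beyond it fail."""

    couch_speed_pct: float = 1.0
    step_length_pct: float = 1.0
    energy_ratio_pct: float = 1.0
    field_width_mm: float = 0.2
    laser_mm: float = 1.0
    abutment_mm: float = 0.5

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"tolerance {f.name} must be positive")


@dataclass
class QAReport:
    """All metrics of one QA run with per-metric pass/warn/fail flags."""

    machine_id: str
    timestamp: str
    metrics: dict
    flags: dict
    references: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "QAReport":
        return cls(**data)

    @classmethod
    def from_json(cls, text: str) -> "QAReport":
        return cls.from_dict(json.loads(text))

    @property
    def passed(self) -> bool:
        return not any(v == "fail" for v in self.flags.values())


def _flag(value: float, tolerance: float) -> str:
    a = abs(value)
    if a <= 0.8 * tolerance:
        return "pass"
    if a <= tolerance:
        return "warn"
    return "fail"


def run_stepwedge_qa(
    acquisition: DetectorAcquisition | str | Path,
    geom: MachineGeometry | None = None,
    wedge: StepWedgeSpec | None = None,
    tolerances: ToleranceSet | None = None,
    reference_p1: float | None = None,
    reference_pdd=None,
    machine_id: str | None = None,
    seed: int = 0,
    restarts: int = 10,
) -> QAReport:
    """Run the complete step-wedge analysis on one acquisition.

    Deterministic for a fixed ``seed`` (which drives the fit restarts).
    Raw 300 Hz acquisitions (dt < 10 ms) are down-sampled 10:1 first.
    """
    geom = geom or MachineGeometry()
    wedge = wedge or StepWedgeSpec()
    tolerances = tolerances or ToleranceSet()

    stage = "load"
    try:
        if not isinstance(acquisition, DetectorAcquisition):
            acquisition = read_acquisition(acquisition)
        if acquisition.dt_s < 0.01:
            from .acquisition import downsample_10to1

            acquisition = downsample_10to1(acquisition)
        stage = "output correction"
        acq = output_correct(acquisition)

        stage = "schematic time-profile fit"
        profile = extract_time_profile(acq)
        fit = fit_schematic_profile(profile, geom, wedge, restarts=restarts, seed=seed)

        stage = "transverse analysis"
        profiles = extract_transverse_profiles(acq, fit)
        centers = analyze_centers(profiles, geom, restarts=restarts, seed=seed)

        # Re-anchor the time profile on the measured detector center channel
        # if it differs from the geometric middle used initially.
        center_channel = int(round(centers.detector_center_channel))
        if center_channel != profile.channel_index:
            stage = "schematic refit on center channel"
            profile = extract_time_profile(acq, center_channel)
            fit = fit_schematic_profile(
                profile, geom, wedge, restarts=restarts, seed=seed
            )

        stage = "time-profile metrics"
        tp_metrics = compute_metrics(fit, geom, wedge, reference_p1=reference_p1)

        stage = "PDD fit"
        depths = np.concatenate([[0.0], water_equivalent_depths(wedge)])
        pdd_time = fit_pdd_exponential(fit.s[:6], depths)
        # Second route: transmission at the wedge center from the transverse
        # normalised profiles (ratio air -> step at each fitted center).
        trans_levels = [1.0]
        air_vals = profiles[0].values
        for sp in profiles[1:]:
            c = int(round(centers.sagittal_laser_channel))
            trans_levels.append(float(sp.values[c] / air_vals[c]))
        pdd_transverse = fit_pdd_exponential(np.asarray(trans_levels), depths)
        agreement_pct = 100.0 * (pdd_time.d20_d10 / pdd_transverse.d20_d10 - 1.0)

        energy_dev = (
            energy_consistency(pdd_time, reference_pdd)
            if reference_pdd is not None
            else None
        )
    except StepWedgeError as exc:
        exc.add_note(f"QA stage: {stage}")
        raise

    metrics = {
        "couch_speed_dev_pct": tp_metrics.couch_speed_dev_pct,
        "couch_speed_per_step_dev_pct": list(tp_metrics.per_step_dev_pct),
        "step_lengths_mm": list(tp_metrics.step_lengths_mm),
        "field_width_mm": tp_metrics.field_width_mm,
        "field_width_dev_mm": tp_metrics.field_width_mm - geom.field_width_mm,
        "transverse_laser_offset_mm": tp_metrics.transverse_laser_offset_mm,
        "detector_center_channel": centers.detector_center_channel,
        "sagittal_laser_channel": centers.sagittal_laser_channel,
        "beam_center_channel": centers.beam_center_channel,
        "sagittal_laser_offset_mm": centers.pairwise_offsets_mm["laser_vs_beam"],
        "couch_walk_mm": centers.couch_walk_mm,
        "d20_d10_time": pdd_time.d20_d10,
        "d20_d10_transverse": pdd_transverse.d20_d10,
        "d20_d10_route_agreement_pct": agreement_pct,
        "energy_dev_pct": energy_dev,
        "p1_projection": float(fit.p[0]),
        "fit_r2": fit.r2,
    }

    flags = {
        "couch_speed": _flag(metrics["couch_speed_dev_pct"], tolerances.couch_speed_pct),
        "couch_speed_uniformity": _flag(
            max(abs(v) for v in metrics["couch_speed_per_step_dev_pct"]),
            tolerances.step_length_pct,
        ),
        "field_width": _flag(metrics["field_width_dev_mm"], tolerances.field_width_mm),
        "sagittal_laser": _flag(metrics["sagittal_laser_offset_mm"], tolerances.laser_mm),
        "transverse_laser": (
            _flag(metrics["transverse_laser_offset_mm"], tolerances.laser_mm)
            if metrics["transverse_laser_offset_mm"] is not None
            else "no-reference"
        ),
        "energy": (
            _flag(energy_dev, tolerances.energy_ratio_pct)
            if energy_dev is not None
            else "no-reference"
        ),
    }

    return QAReport(
        machine_id=machine_id or str(acq.meta.get("machine_id", "unknown")),
        timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        metrics=metrics,
        flags=flags,
        references={
            "reference_p1": reference_p1,
            "reference_d20_d10": (
                reference_pdd.d20_d10 if reference_pdd is not None else None
            ),
            "tolerances": dataclasses.asdict(tolerances),
            "seed": seed,
        },
        meta={"dt_s": acq.dt_s, "n_projections": acq.n_projections},
    )


# ---------------------------------------------------------------------------
# trend ledger
# ---------------------------------------------------------------------------

def append_trend(report: QAReport, ledger_path) -> None:
    """Append one report to a JSON-lines trend ledger (one report per line)."""
    with open(ledger_path, "a", encoding="utf-8") as fh:
        fh.write(report.to_json() + "\n")


def trend_summary(ledger_path) -> dict:
    """Per-metric mean and 1 SD over the ledger, plus out-of-tolerance counts.

    Corrupt lines are skipped with a warning and counted.
    """
    path = Path(ledger_path)
    reports: list[QAReport] = []
    skipped = 0
    if path.exists():
        with open(path, "r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    reports.append(QAReport.from_json(line))
                except (json.JSONDecodeError, TypeError) as exc:
                    skipped += 1
                    warnings.warn(
                        f"skipping corrupt ledger line {lineno}: {exc}", stacklevel=2
                    )
    summary: dict = {"n_reports": len(reports), "n_skipped": skipped, "metrics": {}, "fail_counts": {}}
    if not reports:
        return summary

    scalar_keys = sorted(
        k
        for k in reports[0].metrics
        if isinstance(reports[0].metrics[k], (int, float))
        and reports[0].metrics[k] is not None
    )
    for key in scalar_keys:
        values = np.array(
            [
                r.metrics[key]
                for r in reports
                if isinstance(r.metrics.get(key), (int, float))
                and r.metrics[key] is not None
                and math.isfinite(r.metrics[key])
            ],
            dtype=float,
        )
        if values.size == 0:
            continue
        summary["metrics"][key] = {
            "n": int(values.size),
            "mean": float(values.mean()),
            "sd": float(values.std(ddof=1)) if values.size > 1 else 0.0,
        }
    for r in reports:
        for name, flag in r.flags.items():
            if flag == "fail":
                summary["fail_counts"][name] = summary["fail_counts"].get(name, 0) + 1
    return summary
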