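"""Detector acquisitions: file dialect, down-sampling, output correction,
profile extraction.

The on-machine data format is proprietary, so acquisitions are stored in an
open dialect: a CSV table with header ``projection,monitor,ch0000..chNNNN``
(one row per projection, file order defines time) plus a JSON sidecar
``<name>.meta.json`` carrying ``dt_s`` and free-form metadata.  The pair
round-trips losslessly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .errors import (
    AcquisitionFormatError,
    MonitorSignalError,
    SegmentTooShortError,
)
from .geometry import DT_30HZ, MachineGeometry

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .timeprofile import SchematicProfileFit


@dataclass
class DetectorAcquisition:
    """One detector acquisition: projections x channels signal matrix,
    per-projection monitor-chamber signal, time base and metadata."""

    signal: np.ndarray
    monitor: np.ndarray
    dt_s: float = DT_30HZ
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.monitor = np.asarray(self.monitor, dtype=float)
        if self.signal.ndim != 2:
            raise AcquisitionFormatError("signal must be a 2-D matrix")
        if self.monitor.ndim != 1 or self.monitor.shape[0] != self.signal.shape[0]:
            raise AcquisitionFormatError(
                "monitor length must equal the number of signal rows "
                f"({self.monitor.shape[0]} vs {self.signal.shape[0]})"
            )
        if self.dt_s <= 0:
            raise AcquisitionFormatError("dt_s must be positive")
        neg = np.argwhere(self.signal < 0)
        if neg.size:
            r, c = neg[0]
            raise AcquisitionFormatError(f"negative signal at row {r}, channel {c}")

    @property
    def n_projections(self) -> int:
        return self.signal.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[1]


@dataclass
class TimeProfile:
    """Output-corrected signal course of a single channel over time."""

    values: np.ndarray
    channel_index: int
    dt_s: float = DT_30HZ

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise AcquisitionFormatError("time profile contains non-finite values")
        if self.values.size <= 100:
            raise AcquisitionFormatError("time profile must be longer than 100 projections")


@dataclass
class TransverseProfile:
    """Per-channel signal averaged over the projections of one flat segment."""

    values: np.ndarray
    label: str
    projections_averaged: tuple[int, int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise AcquisitionFormatError("transverse profile contains non-finite values")


# ---------------------------------------------------------------------------
# file dialect
# ---------------------------------------------------------------------------

def _meta_path(path: Path) -> Path:
    return path.with_suffix("").with_name(path.with_suffix("").name + ".meta.json")


def write_acquisition(acq: DetectorAcquisition, path) -> None:
    """Write the CSV + JSON-sidecar pair.  Values round-trip bit-identically."""
    path = Path(path)
    frame = pd.DataFrame(
        acq.signal, columns=[f"ch{c:04d}" for c in range(acq.n_channels)]
    )
    frame.insert(0, "monitor", acq.monitor)
    frame.insert(0, "projection", np.arange(acq.n_projections))
    # pandas' default float writer emits the shortest round-trip repr, which
    # is lossless for float64 and much faster than printf-style formatting
    frame.to_csv(path, index=False)
    with open(_meta_path(path), "w", encoding="utf-8") as fh:
        json.dump({"dt_s": acq.dt_s, "meta": acq.meta}, fh, indent=2, default=str)
        fh.write("\n")


def read_acquisition(path, expected_channels: int | None = 640) -> DetectorAcquisition:
    """Read an acquisition written by :func:`write_acquisition`.

    ``expected_channels`` guards against truncated files (pass ``None`` for
    non-standard detector sizes).
    """
    path = Path(path)
    if not path.exists():
        raise AcquisitionFormatError(f"no such acquisition file: {path}")
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError, ValueError) as exc:
        raise AcquisitionFormatError(f"malformed acquisition file {path}: {exc}") from exc
    cols = list(frame.columns)
    if len(cols) < 3 or cols[0] != "projection" or cols[1] != "monitor":
        raise AcquisitionFormatError(
            "malformed header: expected 'projection,monitor,ch0000..'"
        )
    chan_cols = cols[2:]
    expected = [f"ch{c:04d}" for c in range(len(chan_cols))]
    if chan_cols != expected:
        raise AcquisitionFormatError(
            f"channel count/order mismatch: {len(chan_cols)} channel columns "
            "do not form a contiguous ch0000.. sequence"
        )
    if expected_channels is not None and len(chan_cols) != expected_channels:
        raise AcquisitionFormatError(
            f"channel count mismatch: file has {len(chan_cols)} channels, "
            f"expected {expected_channels}"
        )
    if frame.isna().to_numpy().any():
        row = int(np.argwhere(frame.isna().to_numpy())[0, 0])
        raise AcquisitionFormatError(f"row-length mismatch or missing value at row {row}")
    meta_file = _meta_path(path)
    if not meta_file.exists():
        raise AcquisitionFormatError(f"missing metadata sidecar {meta_file}")
    with open(meta_file, "r", encoding="utf-8") as fh:
        sidecar = json.load(fh)
    return DetectorAcquisition(
        signal=frame[chan_cols].to_numpy(dtype=float),
        monitor=frame["monitor"].to_numpy(dtype=float),
        dt_s=float(sidecar.get("dt_s", DT_30HZ)),
        meta=dict(sidecar.get("meta", {})),
    )


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def downsample_10to1(acq: DetectorAcquisition) -> DetectorAcquisition:
    """Average 10 consecutive projections into one (signal and monitor alike).

    This is the 300 Hz -> 30 Hz reduction applied to the raw stream.  A
    trailing remainder (row count not divisible by 10) is dropped with a
    warning; fewer than 10 rows is an error.
    """
    n = acq.n_projections
    if n < 10:
        raise AcquisitionFormatError("need at least 10 projections to down-sample 10:1")
    keep = (n // 10) * 10
    if keep != n:
        warnings.warn(
            f"dropping trailing {n - keep} projections not filling a 10-block",
            stacklevel=2,
        )
    signal = acq.signal[:keep].reshape(-1, 10, acq.n_channels).mean(axis=1)
    monitor = acq.monitor[:keep].reshape(-1, 10).mean(axis=1)
    return DetectorAcquisition(
        signal=signal, monitor=monitor, dt_s=acq.dt_s * 10, meta=dict(acq.meta)
    )


def beam_on_mask(monitor: np.ndarray) -> np.ndarray:
    """Projections considered beam-on: monitor above 10% of its 95th percentile."""
    monitor = np.asarray(monitor, dtype=float)
    return monitor > 0.1 * np.percentile(monitor, 95)


def output_correct(acq: DetectorAcquisition) -> DetectorAcquisition:
    """Correct detector readings for machine-output fluctuations.

    Each beam-on row is divided by its monitor reading and rescaled by the
    beam-on monitor mean, so constant output leaves the signal unchanged.
    Beam-off rows are zeroed.  The monitor vector is replaced by its mean,
    which makes the operation idempotent.
    """
    mask = beam_on_mask(acq.monitor)
    if not mask.any():
        raise MonitorSignalError("no beam-on projections found")
    first, last = np.nonzero(mask)[0][[0, -1]]
    span = acq.monitor[first : last + 1]
    if np.any(span <= 0):
        bad = first + int(np.nonzero(span <= 0)[0][0])
        raise MonitorSignalError(
            f"monitor signal non-positive at projection {bad} inside the beam-on segment"
        )
    mean = float(acq.monitor[mask].mean())
    signal = np.zeros_like(acq.signal)
    signal[mask] = acq.signal[mask] * (mean / acq.monitor[mask, None])
    monitor = np.full_like(acq.monitor, mean)
    meta = dict(acq.meta)
    meta["output_corrected"] = True
    return DetectorAcquisition(signal=signal, monitor=monitor, dt_s=acq.dt_s, meta=meta)


# ---------------------------------------------------------------------------
# profile extraction
# ---------------------------------------------------------------------------

def extract_time_profile(
    acq: DetectorAcquisition, channel_index: int | None = None
) -> TimeProfile:
    """Return one channel's column as a :class:`TimeProfile`.

    Default channel: ``meta['center_channel']`` (typically set after a
    transverse analysis located the detector center), falling back to the
    geometric middle of the array.
    """
    if channel_index is None:
        channel_index = int(round(acq.meta.get("center_channel", acq.n_channels // 2)))
    if not 0 <= channel_index < acq.n_channels:
        raise IndexError(
            f"channel index {channel_index} out of range 0..{acq.n_channels - 1}"
        )
    return TimeProfile(
        values=acq.signal[:, channel_index],
        channel_index=int(channel_index),
        dt_s=acq.dt_s,
    )


def extract_transverse_profiles(
    acq: DetectorAcquisition,
    fit: "SchematicProfileFit",
    margin_fraction: float = 0.1,
    min_segment: int = 20,
) -> list[TransverseProfile]:
    """Average detector rows over each flat segment of the fitted time profile.

    Returns six profiles: air (before the wedge enters) plus one per step.
    Only rows strictly inside each flat interval are used, with a guard
    margin of ``margin_fraction`` of the segment length on each side, so no
    sloped projection contributes.
    """
    p = np.asarray(fit.p, dtype=float)
    segments = [("air", 0.0, p[0])]
    for k in range(1, 6):
        segments.append((f"step{k}", p[2 * k - 1], p[2 * k]))

    profiles = []
    for label, lo, hi in segments:
        if hi - lo < min_segment:
            raise SegmentTooShortError(
                f"segment too short: flat '{label}' spans {hi - lo:.1f} projections "
                f"(< {min_segment})"
            )
        m = margin_fraction * (hi - lo)
        start = int(np.ceil(lo + m))
        stop = int(np.floor(hi - m)) + 1
        start = max(start, 0)
        stop = min(stop, acq.n_projections)
        if stop - start < 1:
            raise SegmentTooShortError(
                f"segment too short: no rows strictly inside flat '{label}'"
            )
        profiles.append(
            TransverseProfile(
                values=acq.signal[start:stop].mean(axis=0),
                label=label,
                projections_averaged=(start, stop),
            )
        )
    return profiles
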