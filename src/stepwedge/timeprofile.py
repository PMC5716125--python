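"""Schematic step-wedge time-profile model and the metrics derived from it.

The output-corrected signal of one central detector channel, recorded while
the wedge traverses the slit beam, is modelled by a piecewise-linear curve of
seven flat and six sloped straight lines.  It is characterised by 19
parameters: twelve transition coordinates ``p1..p12`` (real-valued, 0-based
projection numbers) and seven signal levels ``s1..s7`` (air, the five steps,
trailing air).  The transition coordinates carry all timing information:

* couch speed and its uniformity (slope-start to slope-start spacings),
* longitudinal field width (``p2 - p1``, one boundary crossing the slit),
* transverse-laser/couch-start position (``p1`` against a reference).

Fitting minimises the summed squared residual with a seeded multi-start
Nelder-Mead simplex.  Because the model is linear in the seven levels for
fixed transitions, the simplex searches only the twelve transition
coordinates while the levels are solved exactly by linear least squares at
every evaluation (a variable-projection formulation of the same objective);
the resulting fit reports all 19 parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from ._optim import multistart_nelder_mead, r_squared
from .acquisition import TimeProfile
from .errors import FitQualityError, NoStepStructureError, StepWedgeError
from .geometry import MachineGeometry, StepWedgeSpec

#: Level index attached to each of the twelve transition knots: the model
#: value at knot j is ``s[_KNOT_LEVEL[j]]``.
_KNOT_LEVEL = np.array([0, 1, 1, 2, 2, 3, 3, 4, 4, 5, 5, 6])


@dataclass
class SchematicProfileFit:
    """The fitted 19-parameter schematic profile."""

    p: np.ndarray  # 12 transition coordinates, strictly increasing (projections)
    s: np.ndarray  # 7 flat levels (arbitrary units)
    sse: float
    r2: float
    n_restarts_used: int

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if self.p.shape != (12,) or self.s.shape != (7,):
            raise ValueError("expected 12 transition coordinates and 7 levels")
        if np.any(np.diff(self.p) <= 0):
            raise ValueError("transition coordinates must be strictly increasing")
        if not 0.0 <= self.r2 <= 1.0:
            raise ValueError("r2 must lie in [0, 1]")


@dataclass
class StepWedgeMetrics:
    """Couch, field-width and laser metrics derived from one schematic fit."""

    couch_speed_dev_pct: float
    per_step_dev_pct: tuple[float, ...]
    step_lengths_mm: tuple[float, ...]
    field_width_mm: float
    transverse_laser_offset_mm: float | None = None


def evaluate_schematic(p, s, t) -> np.ndarray:
    """Evaluate the 7-flat/6-slope piecewise-linear model on grid ``t``.

    Flat value ``s1`` before ``p1``, ``s7`` after ``p12``; linear
    interpolation on every slope.
    """
    p = np.asarray(p, dtype=float)
    s = np.asarray(s, dtype=float)
    if p.shape != (12,) or s.shape != (7,):
        raise ValueError("expected 12 transition coordinates and 7 levels")
    if np.any(np.diff(p) <= 0):
        raise ValueError("transition coordinates must be strictly increasing")
    return np.interp(t, p, s[_KNOT_LEVEL])


class _SchematicObjective:
    """Weighted SSE of the schematic model against a profile on grid 0..n-1.

    Detector noise is multiplicative (sigma proportional to the signal), so
    the maximum-likelihood objective weights each residual by 1/signal^2;
    the weights come from a smoothed copy of the data, floored at 10% of
    its median, and make the objective invariant to overall profile scale.

    Linear-in-levels structure is exploited: for a candidate transition
    vector the weighted normal equations of the 7 levels are assembled
    segment-wise from prefix sums (no dense design matrix), solved, and the
    exact weighted SSE returned.  Cost is O(slope samples) per evaluation.
    """

    def __init__(self, y: np.ndarray):
        self.y = np.asarray(y, dtype=float)
        self.n = self.y.size
        smooth = uniform_filter1d(self.y, size=31, mode="nearest")
        floor = 0.1 * max(float(np.median(smooth)), 1e-300)
        self.w = 1.0 / np.maximum(smooth, floor) ** 2
        wy = self.w * self.y
        self._cum_w = np.concatenate([[0.0], np.cumsum(self.w)])
        self._cum_wy = np.concatenate([[0.0], np.cumsum(wy)])
        self._ytwy = float(np.sum(wy * self.y))
        self._t = np.arange(self.n, dtype=float)
        self._eye = np.eye(7)

    def levels_for(self, p: np.ndarray) -> tuple[np.ndarray, float]:
        """Optimal levels and weighted SSE for sorted transitions ``p``."""
        n = self.n
        y = self.y
        ata = np.zeros((7, 7))
        aty = np.zeros(7)
        cuts = np.clip(np.ceil(p), 0, n).astype(int)
        bounds = np.concatenate([[0], cuts, [n]])
        for j in range(13):
            lo, hi = bounds[j], bounds[j + 1]
            if hi <= lo:
                continue
            if j == 0:
                l0 = l1 = 0
            elif j == 12:
                l0 = l1 = 6
            else:
                l0, l1 = _KNOT_LEVEL[j - 1], _KNOT_LEVEL[j]
            if l0 == l1:  # flat segment
                ata[l0, l0] += self._cum_w[hi] - self._cum_w[lo]
                aty[l0] += self._cum_wy[hi] - self._cum_wy[lo]
            else:  # slope segment between knots j-1 and j
                denom = p[j] - p[j - 1]
                idx = np.arange(lo, hi)
                alpha = (idx - p[j - 1]) / denom if denom > 1e-12 else np.full(hi - lo, 0.5)
                w0 = 1.0 - alpha
                wseg = self.w[lo:hi]
                seg = wseg * y[lo:hi]
                ata[l0, l0] += float(w0 @ (wseg * w0))
                ata[l1, l1] += float(alpha @ (wseg * alpha))
                cross = float(w0 @ (wseg * alpha))
                ata[l0, l1] += cross
                ata[l1, l0] += cross
                aty[l0] += float(w0 @ seg)
                aty[l1] += float(alpha @ seg)
        reg = 1e-10 * max(float(ata.diagonal().max()), 1.0)
        try:
            s = np.linalg.solve(ata + reg * self._eye, aty)
        except np.linalg.LinAlgError:
            return np.full(7, np.nan), np.inf
        sse = self._ytwy - 2.0 * float(s @ aty) + float(s @ ata @ s)
        if sse > 1e-8 * self._ytwy:
            return s, sse
        # Near a perfect fit the closed form cancels catastrophically;
        # recompute the weighted SSE from the residuals directly.
        r = y - np.interp(self._t, p, s[_KNOT_LEVEL])
        return s, float(np.sum(self.w * r * r))

    def unweighted_sse(self, p: np.ndarray, s: np.ndarray) -> float:
        """Plain SSE of the model, for the R^2 quality gate."""
        r = self.y - np.interp(self._t, p, s[_KNOT_LEVEL])
        return float(r @ r)

    def __call__(self, p_vec: np.ndarray) -> float:
        p = np.sort(np.asarray(p_vec, dtype=float))
        return self.levels_for(p)[1]


def _initial_transitions(
    y: np.ndarray, geom: MachineGeometry, wedge: StepWedgeSpec
) -> np.ndarray:
    """Nominal-geometry initial guess for p1..p12 from the first signal drop."""
    n = y.size
    sm = uniform_filter1d(y, size=15, mode="nearest")
    air = float(np.median(sm[: max(30, n // 25)]))
    if air <= 0 or (air - sm.min()) < 0.3 * air:
        raise NoStepStructureError(
            "no step structure: profile lacks the expected signal drop"
        )
    below = np.nonzero(sm < 0.95 * air)[0]
    if below.size == 0:
        raise NoStepStructureError("no step structure: no transition detected")
    crossing = int(below[0])

    v = geom.couch_speed_mm_s
    slope_proj = geom.field_width_mm / v / geom.dt_s
    # Estimate where on the first slope the 95% crossing sits from the level
    # after the slope, then walk back to the slope start.
    t1_idx = min(crossing + int(slope_proj), n - 1)
    t1 = np.clip(sm[t1_idx] / air, 0.05, 0.95)
    alpha = np.clip(0.05 / (1.0 - t1), 0.0, 1.0)
    p1 = crossing - alpha * slope_proj

    starts = p1 + wedge.boundary_positions_mm / v / geom.dt_s  # 6 slope starts
    p = np.empty(12)
    p[0::2] = starts
    p[1::2] = starts + slope_proj
    if p[-1] > n - 2:
        raise NoStepStructureError(
            "no step structure: profile does not cover the full wedge"
        )
    return p


def fit_schematic_profile(
    profile: TimeProfile,
    geom: MachineGeometry,
    wedge: StepWedgeSpec,
    restarts: int = 10,
    seed: int = 0,
    init_window: float = 50.0,
) -> SchematicProfileFit:
    """Fit the 19-parameter schematic profile to a time profile.

    For each restart the whole transition vector is shifted by an offset
    drawn uniformly from ``±init_window`` projections around the detected
    first signal drop; the best of the restarts is polished and returned.
    Fits with R^2 <= 0.99 are rejected with :class:`FitQualityError`.
    """
    y = np.asarray(profile.values, dtype=float)
    if np.ptp(y) <= 0:
        raise NoStepStructureError("no step structure: profile is constant")
    obj = _SchematicObjective(y)
    p_init = _initial_transitions(y, geom, wedge)

    rng = np.random.default_rng(seed)
    offsets = rng.uniform(-init_window, init_window, size=restarts)
    starts = [p_init + off for off in offsets]

    p_best, _, used = multistart_nelder_mead(obj, starts)
    p_best = np.sort(p_best)
    s_best, _ = obj.levels_for(p_best)
    # quality is reported on the plain (unweighted) residuals
    sse = obj.unweighted_sse(p_best, s_best)
    r2 = r_squared(sse, y)

    try:
        fit = SchematicProfileFit(
            p=p_best, s=s_best, sse=sse, r2=r2, n_restarts_used=used
        )
    except ValueError as exc:
        raise FitQualityError(f"degenerate schematic fit: {exc}") from exc
    if np.any(np.diff(fit.s[1:6]) >= 0):
        raise FitQualityError(
            "fitted step levels are not strictly decreasing", fit=fit
        )
    if r2 <= 0.99:
        raise FitQualityError(f"schematic fit quality too low (R^2={r2:.4f})", fit=fit)
    # Sanity flag (not an error): trailing level should return to the air level.
    resid_sd = np.sqrt(sse / y.size)
    fit_s7_consistent = abs(fit.s[6] - fit.s[0]) <= max(3 * resid_sd, 1e-6 * abs(fit.s[0]))
    if not fit_s7_consistent:
        import warnings

        warnings.warn(
            "trailing level s7 deviates from the leading air level s1 by more "
            "than 3 residual SDs",
            stacklevel=2,
        )
    return fit


# ---------------------------------------------------------------------------
# derived metrics
# ---------------------------------------------------------------------------

def step_lengths(fit: SchematicProfileFit, geom: MachineGeometry) -> np.ndarray:
    """Apparent length of each step in mm: slope-start to next-slope-start
    spacing times ``dt`` times the nominal couch speed (independent of slit
    width)."""
    p = fit.p
    spans = p[2::2] - p[0:-2:2]  # p3-p1, p5-p3, ..., p11-p9
    return spans * geom.dt_s * geom.couch_speed_mm_s


def field_width(fit: SchematicProfileFit, geom: MachineGeometry) -> float:
    """Longitudinal slit width at isocenter: ``(p2 - p1) * dt * couch_speed``."""
    return float((fit.p[1] - fit.p[0]) * geom.dt_s * geom.couch_speed_mm_s)


def couch_speed_deviation(
    fit: SchematicProfileFit, geom: MachineGeometry, wedge: StepWedgeSpec
) -> tuple[float, np.ndarray]:
    """Overall and per-step couch-speed deviation in percent.

    Overall: the wedge length (150 mm) divided by the measured traversal
    time ``(p11 - p1) * dt`` gives the actual speed, compared against
    nominal.  Per-step: measured apparent step lengths against the physical
    step lengths.
    """
    travel_s = (fit.p[10] - fit.p[0]) * geom.dt_s
    measured_speed = wedge.length_mm / travel_s
    overall = 100.0 * (measured_speed / geom.couch_speed_mm_s - 1.0)
    lengths = step_lengths(fit, geom)
    per_step = 100.0 * (lengths / np.asarray(wedge.step_lengths_mm) - 1.0)
    return float(overall), per_step


def transverse_laser_offset(
    fit: SchematicProfileFit, reference_p1: float, geom: MachineGeometry
) -> float:
    """Longitudinal (transverse-laser) offset in mm against a calibration run.

    Positive means the wedge entered the beam late, i.e. it was set up
    shifted away from the gantry.  ``reference_p1`` must come from a
    calibration acquisition with identical ``dt`` and couch speed.
    """
    if reference_p1 is None:
        raise StepWedgeError("transverse-laser check requires a reference p1")
    return float((fit.p[0] - reference_p1) * geom.dt_s * geom.couch_speed_mm_s)


def compute_metrics(
    fit: SchematicProfileFit,
    geom: MachineGeometry,
    wedge: StepWedgeSpec,
    reference_p1: float | None = None,
) -> StepWedgeMetrics:
    """Bundle all time-profile metrics for one fit."""
    overall, per_step = couch_speed_deviation(fit, geom, wedge)
    lengths = step_lengths(fit, geom)
    laser = (
        transverse_laser_offset(fit, reference_p1, geom)
        if reference_p1 is not None
        else None
    )
    return StepWedgeMetrics(
        couch_speed_dev_pct=overall,
        per_step_dev_pct=tuple(float(v) for v in per_step),
        step_lengths_mm=tuple(float(v) for v in lengths),
        field_width_mm=field_width(fit, geom),
        transverse_laser_offset_mm=laser,
    )
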