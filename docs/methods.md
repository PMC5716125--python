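# Methods

This note documents the models, estimators, numerical choices and
limitations of the `stepwedge` package: a filmless constancy-QA method for
helical tomotherapy that derives couch, collimation, laser, beam-energy and
abutment metrics from the on-board MVCT detector signals recorded while a
five-step aluminum wedge phantom traverses a static 1 cm slit beam.

## 1. Measurement model

### 1.1 Geometry

The machine is described by `MachineGeometry`: SAD 85 cm, SDD 142 cm at the
detector center, 640 xenon channels of 1.2 mm lateral pitch and 42 mm
longitudinal cavity length, detector arc radius 110 cm. A lateral distance
of Δ channels back-projects to isocenter as

    Δx_iso = Δ · 1.2 mm · SAD/SDD  ≈ Δ · 0.72 mm,

the only divergence correction applied anywhere (modelling the septa
geometry in 3-D is out of scope). Longitudinal distances come from time:
n projections correspond to `n · dt · v` millimetres of couch travel at
couch speed `v` (nominally 1 mm/s).

Two time bases coexist in the field's conventions and are both exposed:
`DT_30HZ = 1/30 s` (the 10:1 down-sampled detector stream; 300 s of beam-on
gives 9000 projections) and `DT_30MS = 0.030 s` (the rounded per-projection
time used when quoting projection counts in mm, e.g. 8 projections →
0.2 mm). An analysis uses one base throughout, never a mixture; the
acquisition's own `dt_s` governs all fitted quantities.

### 1.2 Phantom

`StepWedgeSpec`: five aluminum steps of lengths 29.9/30.0/30.0/30.0/30.1 mm
(150 mm total) and thicknesses 19.5/39.0/58.5/78.0/97.6 mm, density
2.69 g/cm³, width 69.7 mm. Water-equivalent depths are thickness × density
(water density 1): 52.5, 104.9, 157.4, 209.8, 262.5 mm. No energy-dependent
stopping-power correction is applied — the bulk density ratio is what the
printed depths imply, and the method only trends a *ratio* of depth doses,
so a fixed scaling convention cancels.

### 1.3 The schematic time profile

The output-corrected signal of one central detector channel versus time is
modelled as seven flat and six sloped straight lines with 19 parameters:
transition coordinates p1..p12 (real-valued projection numbers, strictly
increasing) and levels s1..s7 (air, steps 1–5, trailing air). Each slope is
one wedge-level boundary crossing the slit: its duration is w/v (slit width
over couch speed), which is what makes p2−p1 a field-width measurement and
the slope-start spacings p1–p3, p3–p5, … step-length measurements.

Derived metrics:

* couch speed: `v_meas = 150 mm / ((p11 − p1)·dt)`, reported as percent
  deviation from nominal; per-step deviations from the five slope-start
  spacings check speed uniformity;
* field width at isocenter: `(p2 − p1)·dt·v`;
* transverse-laser (longitudinal setup) offset: `(p1 − p1_ref)·dt·v`
  against a calibration acquisition; positive = wedge entered late;
* beam energy: exponential fit of levels s1..s6 (§1.5).

### 1.4 Transverse profiles and the three centers

Per-channel signals averaged over the interior of each flat segment (10%
guard margins so no sloped projection contributes) give six transverse
profiles: air plus one per step. Their central part is fitted with the
modified Gaussian

    y(x) = y0 + a · exp(−½ (|x − x0| / b)^c),

whose exponent c interpolates between a Gaussian (c = 2) and a hard-edged
top hat (c large). Three centers result:

* **detector center** — the dip the septa alignment imprints on the air
  profile (the channel opposing the focus), fitted over ±40 channels around
  the strongest narrow local minimum;
* **sagittal-laser position** — mean x0 of the five step profiles
  normalised to air, each fitted over the contiguous region with
  transmission < 0.9; the spread of the five centers (back-projected to mm)
  flags couch walk when it exceeds 1 mm;
* **beam center** — midpoint of the two flank inflections of the air
  profile, located where centred second differences of the 5-channel
  smoothed profile cross zero.

On an aligned machine all three coincide; pairwise differences at isocenter
are the laser/beam alignment metrics.

### 1.5 Depth dose and beam-quality index

The six levels (air at depth 0 plus the five steps at their
water-equivalent depths) follow `s(d) = s0·exp(−μ_eff·d)` closely over
50–260 mm. The fit is linear least squares on log-levels — stable, with a
closed-form slope usable as a cross-check. The percentage depth dose is
normalised to 100 at 50 mm and the beam-quality index is

    D20/D10 = PDD(200 mm)/PDD(100 mm) = exp(−100·μ_eff),

compared against the commissioning water-tank curve as a percent
difference. The trailing level s7 is excluded (it re-measures air); it is
instead checked against s1 as a sanity flag. A second, independent route
builds the same six levels from the transverse profiles (step/air ratio at
the wedge center); both routes agree to well under 0.5% in simulation and
their difference is reported as a self-consistency metric.

### 1.6 Completion / abutment

A delivery interrupted while the time profile is on a slope is resumed by
the machine as an automatically generated completion. The completion's
profile starts with ≈10 s of closed-leaf leakage while output and couch
stabilise, then a brief all-leaves-closed transient shortly after
resumption; both are data artifacts, detected (sustained rise to the
interrupted profile's final level ±20%, then a level-band mask) and
excluded rather than modelled. The mismatch estimate registers the first
100 usable completion samples against the straight-line continuation of the
interrupted profile's final slope: an exhaustive integer shift search over
±100 projections minimising the summed squared difference, optionally
refined below one projection by a parabola through the three SSE values
around the minimum (off when reproducing integer-projection readings).
Sign convention: positive = overlap (couch restarted early → dose peak),
negative = gap (→ dip). A linear penumbra model converts the mismatch to a
local dose error of ≈8% per millimetre (|shift| ≤ 2 mm).

The straight-line continuation is valid because the junction is on a slope
by construction and |mismatch| ≤ 2 mm ≪ the 10 s slope duration; the
registration window is kept inside the slope by interrupting near
mid-slope.

## 2. Fitting

Both profile models are fitted by seeded multi-start Nelder–Mead simplex
minimisation of the summed squared residual, with the best restart polished
by repeated fresh simplexes until the objective stops improving (relative
improvement below 1e-12). Restart tolerances: `xatol` 1e-3 projections
(schematic) / 1e-5 (modified Gaussian), relative SSE tolerance 1e-10,
at most 20 000 evaluations per restart.

*Schematic fit.* Because detector noise is multiplicative, the objective is
a weighted SSE with weights 1/(smoothed signal)² — the maximum-likelihood
form, which also makes the objective invariant to overall profile scale;
fit quality (R²) is still reported on plain residuals. The model is linear
in the seven levels for fixed transitions, so the simplex searches only
p1..p12 while s1..s7 are solved exactly by weighted linear least squares at
every evaluation (variable projection of the same objective); the normal
equations are assembled segment-wise from prefix sums, keeping one
evaluation at ~0.05 ms for a 9000-projection profile. Near a perfect fit
the closed-form SSE cancels catastrophically, so once it falls below 1e-8
of the weighted signal energy the SSE is recomputed directly from
residuals.
Candidate transition vectors are sorted before evaluation, which keeps the
search unconstrained while guaranteeing a valid model. Initialisation
detects the first signal drop below 95% of the air level and places the
remaining transitions at their nominal spacings; each of the 10 restarts
shifts the whole vector by a uniform draw from ±50 projections. Fits with
R² ≤ 0.99 (about the profile mean) are rejected with the fit attached for
inspection; non-monotone step levels are likewise rejected.

*Modified-Gaussian fit.* The ten restarts walk a clean grid of two base
parameterizations — a narrow dip on a background (baseline from the window
edges, centroid center) and a flat-bottomed transmission window (baseline
at the far extreme, center and width from the half-depth crossings) —
crossed with shape exponents c ∈ {2, 4, 8, 32, 128}; restarts beyond the
grid re-visit it with the center jittered ±10 channels. Width and shape are
searched in log-space (the usable c spans two orders of magnitude and
multiplicative steps keep the simplex conditioned); plain jittered restarts
from a single base were found to miss the narrow (b, c) basin of the
near-top-hat profiles. R² ≤ 0.99 is rejected.

## 3. The simulator

`simulate_acquisition` generates the full projections × channels matrix for
a scenario with known ground truth; it is the fixture generator for every
estimator and the package's master oracle (with zero noise, every estimator
must recover its scenario parameter to 1e-6 relative — tested).

* **Longitudinal**: transmission is the 7-flat/6-slope schematic itself,
  evaluated in couch-position coordinates — level k transmits
  `exp(−μ_eff · d_k)`, boundaries crossing the slit produce linear ramps of
  w/v. Real penumbra S-shapes are deliberately not modelled (the schematic
  model is the generative truth).
* **Transverse**: the air profile is a broad modified Gaussian (b = 150
  channels, c = 4, 5% pedestal) times a narrow central dip (5% deep,
  σ = 3 channels) at the channel opposing the focus; the real dip's shape
  is unpublished, so this notch is a synthetic stand-in sized only for
  center detection and flagged as such in truth records. The wedge
  attenuates a lateral window of its physical 69.7 mm width back-projected
  to channels, centred at the lateral offset, with 2-channel linear edge
  smoothing.
* **Output and noise**: the monitor and all detector rows share a
  multiplicative output factor 1 + ripple (default 1% amplitude, 10 s
  period — a typical magnitude for output wobble the monitor correction
  must remove); detector readings carry independent multiplicative
  Gaussian noise (default 0.5% — a realistic per-channel, per-projection
  SNR for a xenon MVCT channel at 30 Hz); the monitor carries one tenth of
  the detector noise, as it integrates the whole beam. All randomness comes
  from one integer seed; acquisitions are bit-reproducible.
* **Defaults** are the nominal study conditions: 300 s beam-on at 30 Hz,
  wedge entering the beam 40 s in (expected p1 = 1200), nominal couch
  speed and 10 mm slit, μ_eff chosen so D20/D10 ≈ 0.519 (mid-range for a
  flattening-filter-free 6 MV beam).

What the simulator does **not** emulate — detector energy response, scatter
beyond the fixed dip, penumbra shape, gantry-angle effects, helical
delivery — bounds what passing tests show: they validate the estimators
against the stated signal model, not against all detector physics. The
agreement of the two independent PDD routes and the monitor-correction
round trip are internal consistency checks that would also hold on real
data.

`simulate_completion_pair` interrupts a scenario at a chosen fraction of
the beam-on time (which must land on a slope), and produces the completion
with a 10 s closed-leaf lead-in at 1% leakage, the 3-projection transient
dip 0.5 s after reopening, and the couch restart offset by the induced
mismatch. The deliberate systematic gap some machines exhibit at
resumption is *not* built in — it is machine behaviour, not algorithm
behaviour — but can be injected via the induced mismatch.

## 4. Tolerances and reporting

`ToleranceSet` defaults: couch speed 1%, per-step length 1%, beam-quality
ratio 1%, field width 0.2 mm (a 0.2 mm change of the 10 mm slit moves the
delivered dose by roughly ±2%), lasers 1 mm, abutment 0.5 mm. Metrics
within 80% of tolerance pass, within tolerance warn, beyond it fail; the
80% warn boundary is this package's choice. Reports serialise to JSON and
append to a JSON-lines trend ledger (append-only, diff-able, no database);
corrupt ledger lines are skipped, warned about and counted.

## 5. Numerical and design choices

* 0-based, real-valued projection and channel coordinates everywhere; the
  p1..p12 naming is kept for the fitted parameters.
* Output correction divides each beam-on projection by its monitor reading
  (rescaled by the beam-on mean); beam-on means monitor above 10% of its
  95th percentile, beam-off rows are zeroed, and the operation is
  idempotent. A smoothed correction was considered and rejected — division
  is exact for the multiplicative model the monitor chamber measures.
* Down-sampling 300→30 Hz is a strict 10:1 block mean over signal and
  monitor alike; a trailing partial block is dropped with a warning.
* The acquisition dialect is CSV (`projection,monitor,ch0000..ch0639`)
  plus a JSON sidecar for `dt_s` and metadata: diff-able, language-neutral,
  lossless (shortest round-trip float representation).
* The time-profile channel is the detector-center channel found by the
  transverse analysis, rounded to the nearest integer (fallback: the
  geometric middle); the analysis refits automatically when the two differ.
* Second-difference smoothing window 5 channels: the smallest window that
  suppressed seeded noise in pilot property tests while biasing the
  inflection by < 0.1 channel.
* Exponential PDD fitted on log-levels with equal weights (multiplicative
  noise of constant relative size is homoscedastic in the log domain).

## 6. Problem sizes

Validation statistics are computed at the delivery's native size — 9000
projections × 640 channels per acquisition — over the full induced-deviation
designs: 9 couch-speed, 8 field-width, 7 lateral-offset, 5 beam-quality and
15 completion scenarios, one seeded noisy realisation each (three per
completion mismatch). One schematic fit takes a few seconds; the whole
validation battery runs in a few minutes on one core.

At the default noise level the single-channel field-width estimate has an
intrinsic standard deviation of ≈0.03 mm: a numerically computed
Cramér–Rao bound for the p2−p1 span of the free 19-parameter model puts
the floor at 0.030 mm, and the fitted estimator sits within ~10% of it
(weighted and unweighted objectives are indistinguishable here). Width
precision beyond that comes from trending over sessions, not from a single
acquisition.

## 7. Known limitations

* Constancy, not absolute dosimetry: every metric is relative to a
  reference (calibration p1, commissioning PDD, nominal speed/width).
* The 8%/mm abutment dose model is a linear approximation from penumbra
  overlap, valid only for |shift| ≤ 2 mm.
* Laser checks cover the sagittal and transverse lasers; the coronal
  (height) laser is not measurable at gantry 0° with useful sensitivity.
* Output (machine dose rate) is not measured — the monitor chamber is used
  to *remove* output variations, not to audit them.
* Helical delivery, gantry-synchrony and MVCT image quality are outside the
  method's scope.
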