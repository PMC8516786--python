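# Methods

## The optical eye model

The simulator isolates the *optical* component of the pupil-size artefact:
the part caused purely by corneal refraction, assuming a perfectly circular
pupil whose center is fixed on the optic axis. Everything lives in the
horizontal plane — the eye has one rotational degree of freedom about a
fixed rotation center, the cornea is a circular (or elliptical) arc, the
pupil is a chord, and the camera is an ideal pinhole projecting onto a 1-D
image line. Eye translation, the crystalline lens, corneal thickness and
3-D entrance-pupil effects are deliberately outside the model.

Geometry (all lengths mm, config-exposed, Le Grand-style reduced eye):

| parameter | default | meaning |
|---|---|---|
| `corneal_radius` | 7.8 | radius of the spherical corneal surface |
| `n_outside` / `n_inside` | 1.0 / 1.336 | air / aqueous refractive indices |
| `pupil_plane_depth` | 3.6 | corneal apex → pupil plane |
| `rotation_center_offset` | 13.5 | corneal apex → eye rotation center |
| `limbus_radius` | 5.85 | transverse extent of the modelled corneal cap |
| `pinhole_distance` | 530 | rotation center → camera pinhole (53 cm) |
| `image_plane_distance` | 25 | arbitrary image scale (cancelled by the LUT) |

The elliptical variant (`ellipsoidal_variant`) replaces the circular arc by
a prolate conic with semi-axes (10.43, 8.97) mm — apical radius of
curvature b²/a ≈ 7.7 mm, asphericity Q ≈ −0.26, the textbook aspheric
cornea — with the apex on the optic axis and no pupil decentration, so it
drops into every operation unchanged. Setting both semi-axes to the
spherical radius reproduces the spherical model to 1e−9, which is tested.

Sign conventions: viewing angle θ is positive when the gaze point is right
of the camera from the participant's perspective; deviations are apparent
minus true orientation. Image positions are mirror-corrected so they
increase with θ.

### Ray solve

For a pupil-perimeter point P (pupil center ± d/2 in the rotated pupil
plane), the solver finds the corneal surface parameter φ whose refracted
ray passes through the pinhole. The signed miss distance of the refracted
ray at the pinhole is evaluated on a 721-point coarse grid over the corneal
cap; the sign-change bracket nearest the global |miss| minimum is then
narrowed by 64 vectorized bisection steps (interval ≪ 1e−15 rad). The
solved point must leave a residual miss below 1e−10 mm or the trace is
flagged. Bisection was chosen over bracket-free methods because the
geometry guarantees a single root over the cap for all states of interest
and bisection is unconditionally robust there; a secant polish would add
nothing at this tolerance. Candidate surface points where the ray would
travel backwards through the surface, hit total internal reflection, or
head away from the camera are excluded before bracketing.

Two independent cross-checks guard the solver: (a) a dense-grid
"zoom" search (four passes of 801 points, resolution < 1e−9 rad) that
shares only the forward miss evaluation, agreeing to ≤ 1e−6 rad on 100
random states; and (b) during development the whole forward trace was
validated to ~1e−14 image units against a backward trace (camera → cornea →
pupil plane) built on `scipy.optimize.brentq`.

### Calibration lookup table

The LUT records the perceived pupil center (mean of the two perimeter-ray
image positions) while the eye rotates from −20° to +20° in 0.001° steps at
the 4 mm calibration pupil — 40001 entries, checked strictly monotone.
Inversion is linear interpolation; at this grid density higher-order
interpolation changes nothing above 1e−9°, so linearity is preferred for
monotonicity. Deviation nulls at θ = 0 and d = d_cal are verified to twice
the grid step.

### Direction of the simulated artefact

With these (anatomically standard) parameters the simulated PSA slope
*increases* with viewing angle — negative at −12°, positive at +12°, about
±0.023 °/mm — and the elliptical variant behaves the same way. This is the
direction predicted by the published three-dimensional entrance-pupil
models (Fedtke and colleagues' peripheral entrance-pupil work; Aguirre's
model eye). Empirical measurements of the viewing-direction-dependent PSA
consistently report the *opposite* direction (slope decreasing with
viewing angle) and magnitudes one to two orders larger; the package's
simulation reproduces the magnitude order of existing simulations but, like
those published models, not the empirical direction. A parameter scan
showed the sign is robust over corneal radius 7–9.5 mm, pupil depth
≥ 2.7 mm, rotation-center offset 11–15 mm, camera distance 0.2–1 m and
n_inside 1.2–1.45; only an anatomically implausible pupil plane almost
touching the cornea flips it. The discrepancy between refraction-only
models and measurement is a genuine open question, and the package reports
its computed slopes rather than forcing a direction.

## PSA quantification

The pipeline is: velocity filter → median centering → decile curve → line
fit.

* **Velocity filter.** Pupil velocity is a difference of window means: the
  mean over the 20 ms after a sample minus the mean over the 20 ms before
  it, divided by the (w+1)-sample separation of the window centers. This is
  exact for linear ramps and attenuates high frequencies with a closed-form
  factor that the tests verify against the analytic derivative of the
  0.125 Hz stimulus sinusoid. Samples with velocity strictly greater than
  mean + 2 SD (statistics over defined velocities only; population SD) are
  invalidated, then every run of missing data is widened by 20 ms (rounded
  to whole samples) on each side — in that order. A degenerate SD = 0 trace
  removes nothing (strict inequality). The pre-padding "core" mask and the
  threshold are stored on the filtered trace so that re-filtering is a
  no-op (idempotence).
* **Decile curve.** x-values are the empirical 2nd–8th deciles of pupil
  size (linear-interpolation quantiles); each y-value is the mean deviation
  of samples whose pupil lies in the half-decile band
  [Q((k−0.5)/10), Q((k+0.5)/10)), so every sample between Q(0.15) and
  Q(0.85) contributes exactly once. Band means are not exactly the deciles
  for a non-uniform pupil distribution, so the seven-point fit carries a
  small systematic term (≈0.3% of the slope for a sinusoidally driven
  pupil); for a uniform pupil sweep with band edges on order statistics the
  recovery is exact to machine precision, and both behaviours are tested.
* **Slope.** Unweighted least squares through the seven points; °/mm.
  `PSAResults` adds residual-based standard errors of slope and intercept.
* **Foreshortening.** A pupil viewed at angle α off-axis is foreshortened
  by cos α; the helper returns 1/cos α and the percent underestimation
  (1 − cos α)·100 — 2.2% at 12°.

Pupil-size units: the decile curve requires millimetres; `convert_pupil_units`
applies an offline-calibrated linear ratio and tags the trace. A possible
square-root transform for area-based trackers is out of scope — the ratio
is assumed linear in diameter.

## Gaze pipeline

Thresholds are manual per recording (as in practice): dark pixels
(< threshold) form pupil candidates, bright pixels (> threshold) CR
candidates, labelled with 8-connectivity. Screening uses pixel area
(defaults 50–20000 px² pupil, 4–400 px² CR), fitted-ellipse axis ratio
(≤ 2) and fill fraction (area / fitted-ellipse area ≥ 0.6); the defaults
are package choices, config-exposed. Centers are binary (unweighted)
centers of mass. Of the CR candidates the three lowest in the image
(largest y; ties broken by x) are averaged; frames with fewer are flagged
invalid. The p-CR vector maps to gaze by a per-axis least-squares fit over
the six quadratic terms (1, x, y, x², xy, y²); ten calibration points are
typical, six non-degenerate ones are the minimum, and a rank check rejects
degenerate designs (e.g. collinear targets, or targets on two vertical
levels only, which make y² collinear with y). 10-bit input is right-shifted
to 8-bit before processing.

## Synthetic data

The trace generator reproduces the *statistical structure* of a PSA trial:
pupil(t) = 4 + 1.5 sin(2π·0.125·t) mm over 160 s at 1000 Hz, horizontal
deviation = offset + slope·(pupil − 4 mm) + N(0, 0.1°), blinks as
Poisson-scheduled 150 ms gaps (12/min by default) flanked by 1 mm linear
pupil ramps at 15 mm/s — steep enough to trip the 2-SD filter, with
configurable steepness so threshold crossing is controllable in tests. It
deliberately does **not** model pupillary latency and constriction/dilation
asymmetry, hippus, drift, or the physiological pupil-center shift: the
decile-curve statistic depends only on the joint (pupil, deviation)
distribution, so an in-phase sinusoid suffices for validating the
estimator. Passing tests therefore demonstrate correctness of the
*pipeline*, not that real eyes have linear artefacts. Defaults give ≈5%
post-filter data loss; the recovery study (below) uses 16 blinks/min for
≈6–10% loss.

The image renderer draws a 4×-supersampled dark pupil disk on a mid-grey
iris with Gaussian-profile specular CR spots that peak at `cr_gray`
regardless of background (so spots over the pupil stay bright, as real
glints do), plus optional Gaussian pixel noise; six spots in two rows of
three emulate a six-LED illuminator. Ground truth stores exact sub-pixel
geometry. Eyelids, eyelashes and off-axis pupil ellipticity are not
rendered.

## Problem sizes and numerical tolerances

The test suite uses a 0.02° LUT for most optics tests and the full 0.001°
grid in the end-to-end acceptance checks; the slope-recovery study uses 50
trials of 160 s at 1000 Hz with slopes drawn uniformly from ±0.7 °/mm
(mean absolute error ≈ 0.001 °/mm, bound 0.02); solver/brute-force
agreement is required at 1e−6 rad (observed ≈ 1e−10); pupil centers must be
recovered within 0.2 px on rendered frames (observed ≈ 0.05 px) and exact
quadratic calibrations must round-trip below 1e−9 (observed ≈ 1e−14).

## Known limitations

* The refraction model is 2-D; tangential (vertical) effects and the
  three-dimensional entrance-pupil geometry are not captured.
* The corneal reflection is not ray-traced; the LUT maps pupil-center
  position directly to orientation, which matches the pupil-only definition
  of the optical artefact (the CR is formed by front-surface reflection and
  is unaffected by refraction).
* Simulated artefact magnitudes are one to two orders below empirical
  slopes, and the simulated direction follows refraction-only optics (see
  above); neither should be read as a prediction of measured artefacts.
* The velocity-filter kernel is a difference of window means; other
  differentiators would shift the threshold statistics slightly.
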