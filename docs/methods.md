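# Methods

## Geometry and observables

A chase is a pair of synchronized 3D position series (pursuer, target) at a
nominal 190 Hz. All angles are reported in degrees, azimuths in (−180°,
180°] (counter-clockwise positive, 0° along +x), elevations in [−90°, 90°].

* **Heading** θ_P: spherical angles of the line of flight. The displacement
  ending at frame *i* defines the heading *at* frame *i*. This convention is
  deliberate: under the explicit-Euler flight model used throughout (heading
  updated before the position step), the step *i−1 → i* is flown with the
  frame-*i* heading, so measurement is the exact inverse of simulation.
  With the opposite (forward) attribution, gains recovered from simulated
  chases carry a systematic bias of order kp·Δt_frame (~14% at kp = 26 s⁻¹),
  purely from the half-frame bookkeeping mismatch. For real continuous
  motion the choice is a half-frame convention absorbed by the fitted delay.
  Frames with no displacement carry the last valid heading and are flagged.
* **Bearing** θ_A: spherical angles of the pursuer→target line.
* **Error angle** θ_E = θ_A − θ_P per plane, azimuth wrapped.
* The vertical plane uses the pursuer's cumulative horizontal path length
  x′ as abscissa; the vertical heading is atan2(Δz, horizontal step), so
  plotting z against x′ matches the planar geometry.
* Target angular size ρ = 2·atan(r_target / R_A), r_target = 4 mm.

## Smoothing and differentiation

5 mm tracking noise at 190 Hz makes frame-to-frame headings meaningless
(the noise is comparable to the ~6 mm per-frame displacement), so the
identification pipeline (`track_observables`) smooths **positions** with a
Savitzky–Golay filter before extracting angles, then smooths each angle
series again before central-difference differentiation (one-sided at the
ends, azimuths unwrapped first).

Defaults: position window 25 frames (~132 ms), order 2; rate window 7
frames (~37 ms), order 2. These were calibrated once by generative
recovery (`recovery_experiment`): across a grid of window pairs on
noisy chases generated by known BP and PN controllers, 25/7 recovers the BP
gain within ~4%, its 2-frame delay exactly, and the PN constant within ~2%,
at two generator seeds. Narrower position windows leave correlated noise
(θ_E and Ω_P share the pursuer-position noise through θ_P) that inflates
gains and drags delay estimates toward zero; wider rate windows push delay
estimates late. Both windows are per-call parameters; `compute_rates` on
its own defaults to a 5-frame window. Savitzky–Golay filters are zero-phase,
so the smoothing does not shift the fitted delays.

Spectral analyses (the 24 Hz modulation check) use *raw* differentiation
instead: heavy polynomial smoothing has oscillating stop-band sidelobes
that distort power ratios between neighbouring bands, while raw
differentiation of white position noise gives a flat, honest floor.

## Conditioning: the close-range mask

When the in-plane pursuer–target separation approaches the noise scale, the
bearing geometry degenerates: a near-overhead pass can sweep the horizontal
bearing by >100° per frame (aliased beyond recovery), and millimetre noise
dominates the angles. Identification therefore drops frames whose in-plane
range is below 5 cm (≈10× the tracking SD), dilated by a 12-frame guard
band so delayed/smoothed neighbours of such frames are excluded too. A
single unmasked overhead pass was enough to destroy an otherwise R > 0.99
pooled proportional-navigation fit. The floor and guard are parameters of
`identify_controllers`; `min_range=0` disables masking.

## Lag-scan fits

For each candidate delay (default 0–50 ms at frame resolution, anchored at
zero so integer-frame delays are exact; negative delays available for lead
analysis; sub-frame steps available via `delay_step`), the input series is
shifted by interpolation, an OLS line is fitted over the valid overlap of
all pooled chases, and the fit with maximum |R| wins; ties break toward the
smallest delay (parsimony). Pooling is frame-weighted across chases; a
per-chase route is available by fitting chases individually. Fits with
R ≥ 0.7 are flagged as accepted candidate laws. Delays with fewer than 10
overlapping pairs are skipped.

Expected small biases, measured on noise-free synthetic data: the central
difference used for measured rates sits half a frame late relative to the
simulator's backward difference, so proportional-navigation delay estimates
read about one frame long; gains are unaffected at the optimum because both
sides of the regression pass through identical linear filters.

## Simulators

Explicit Euler at the track's frame interval, matching the 190 Hz data
cadence; a refinement test confirms O(Δt) convergence. Delayed inputs are
linearly interpolated in the input history and held at their initial value
for t < delay. Capture: distance below 10 mm (8 mm dummy plus tracking SD),
configurable.

Three entry points:

* `simulate_planar` — one plane, scripted target path.
* `simulate_coupled` — one 3D state; yaw and pitch controllers drive a
  single velocity vector (pitch clamped at ±89°). Used by the generator.
* `simulate_3d(mode="decoupled")` — the replay-evaluation construction:
  horizontal sim in (x, y); vertical sim in (x′, z) with the target placed
  at x′_measured + horizontal range, which preserves the vertical bearing
  of the 3D geometry when the simulated pursuer tracks the measured x′.
  This planar-abscissa construction is this package's own choice; whether
  the original analysis used it or a full 3D state is not documented
  anywhere we know of, and the coupled mode exists to quantify the
  difference (they agree to ~mm on near-planar chases).

Speed policies: replay of the measured per-frame speed (the step ending at
frame k+1 is driven by the frame-k command, mirroring the Euler update),
constant, or the angular-size law s = ρ·S_v·e^(−ρ/ρ*) + S_g for ρ > 0.5°
(else S_g). The angular-size gains default to placeholders (S_g = 0.3 m/s,
S_v = 0.05 m/s/deg, ρ* = 20°) — the primary sources cite them from earlier
work without printing values — and must be set explicitly for quantitative
use.

## Replay evaluation and grid search

ε is the mean point-to-point distance between measured and simulated
pursuer positions, per plane; the vertical version compares each
trajectory's *own* cumulative x′ (a consequence of the x′ construction; a
simulated pursuer that backtracks in the plane would make its x-coordinate
and path length diverge, which the mild vertical controllers here do not
produce). Grid searches simulate every chase at every grid point with speed
replay and the plane's identified delay, average ε across chases, and
report the argmin; failed grid points are recorded as missing and excluded
with a warning. Default grids cover kp ∈ [0, 60] s⁻¹ step 1, N ∈ [0, 8],
β ∈ [−45°, 45°] step 1°. When a grid search runs on noisy measured tracks,
the tracks are position-smoothed first — replay speed differenced from raw
noisy positions is unusable (±1.3 m/s per frame at 5 mm noise).

The bias convention is Ω_P = kp·(θ_E + β): a controller that holds the
target 23° above the horizon has β = −23°, and reports quote the held
angle −β where that is the natural quantity.

Strategy comparison: one-way ANOVA on per-chase mean ε with a Tukey-style
pairwise follow-up (conventions: n.s. above p = 0.05, *** below 0.001);
the type-I error rate of the pipeline is verified by simulation in the
test suite.

## Synthetic data

The generator reproduces the study conditions: 0.50 × 0.50 × 0.70 m arena,
190 Hz, an 8 mm dummy target at constant altitude, and i.i.d. isotropic
Gaussian position noise of SD 5 mm on both protagonists (only the marginal
SD of the original reconstruction error is documented, so independence is
assumed). Target kinds: line; circle at 1 m/s (radius 0.15 m); "spring"
(y-translation plus rotation about a vertical axis), with translational
speed constrained to [0, 1.5] m/s — including the rotational contribution —
and rotation rate to [360, 1300]°/s. Defaults: spring, 0.2 m/s translation,
720°/s rotation, 0.10 m arm (peak target speed 1.46 m/s). An optional
24 Hz sinusoidal speed modulation (relative amplitude, default off; 0.1 in
the rejection test — only its presence, not its size, is documented)
emulates the actuation artefact of circular dummy runs.

The virtual fly starts uniformly in the arena (≥10 cm from the target),
initially headed at the target with 10° Gaussian jitter, and flies the
horizontal and vertical controllers closed-loop at constant 1.2 m/s
(measured blowfly chases cluster near 1–1.5 m/s). Horizon 2 s; chases that
do not capture are kept and flagged. Chases shorter than 60 frames
(immediate captures from lucky spawns) are redrawn with a fresh seed when a
fixed-size set is requested. Everything is deterministic under the spec's
seed.

What the generator does *not* emulate — and hence what recovery tests do
not probe: body/head orientation (the simulated heading is exactly the
velocity direction; real flies side-slip and saccade), correlated or
outlier tracking noise, chase initiation and abandonment, aerodynamics and
banked turns.

## Numerical choices and edge cases

* Azimuth wrap to (−180°, 180°]; unwrap before differentiation and inside
  the simulators (incremental continuous bearing).
* r = 0 in circular statistics: mean direction undefined, flagged, σ = ∞;
  the circular SD is σ = √(−2 ln r) (the standard directional-statistics
  definition; the arc-based alternative is not used). Rose-plot bins are
  5° wide.
* Degenerate lag-fit inputs (zero variance) score R = 0 rather than NaN.
* Trajectory files: plain delimited text with header `t,xp,yp,zp,xt,yt,zt`;
  units and column remapping via a YAML sidecar dialect; NaN rows dropped
  (logged), interpolated, or the file rejected, per dialect. Time steps
  must sit within 5% of an integer multiple of the nominal frame interval
  (dropped rows leave integer gaps); jittered recordings can be
  regularised with `resample_uniform`.
* The pure-pursuit capture guarantee holds for a point capture only with
  unbounded curvature; with a proportional command the turn radius is
  v/(kp·|θ_E|), so the property test uses kp = 30 s⁻¹ and a 2 cm catch
  zone.

## Known limitations

* Identification assumes pooled frames are exchangeable; per-chase
  heterogeneity is visible only through the per-chase fitting route.
* The close-range mask and smoothing windows are calibrated on the
  generator's noise model; grossly different noise (e.g. heavy-tailed
  tracking failures) would need recalibration.
* The vertical replay construction shares the measured pursuer's x′ with
  the simulated fly; ε_V therefore under-penalises errors in horizontal
  pacing that cancel in path length.
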