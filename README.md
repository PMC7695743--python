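# pursuitkin

Kinematic analysis of aerial pursuit trajectories: which steering law is a
chasing animal flying?

Male blowflies chase moving targets (females, or an actuated dummy) with
trajectory corrections in the 10-millisecond range. Given synchronized 3D
position tracks of a pursuer and a target, `pursuitkin` extracts the angular
observables of pursuit, identifies the steering control law behind them, and
selects among candidate controllers by replaying each one against the
measured chases.

## The model

Two lines organise the geometry. The **line of flight** (LOF) joins
consecutive pursuer positions; its azimuth/elevation angles are the heading
angles θ_P. The **line of sight** (LOS) joins pursuer to target; its angles
are the bearing angles θ_A. The egocentric position of the target — the
*error angle* — is their difference, per plane:

    θ_E = θ_A − θ_P

Candidate steering laws map a delayed angular input onto the commanded
heading rate Ω_P (deg/s):

| strategy                     | law                                            |
|------------------------------|------------------------------------------------|
| pure pursuit (PP)            | Ω_P(t) = kp·θ_E(t−Δt), bias β = 0              |
| biased pursuit (BP)          | Ω_P(t) = kp·[θ_E(t−Δt) + β]                    |
| proportional navigation (PN) | Ω_P(t) = N·Ω_A(t−Δt)                           |
| mixed pursuit (MP)           | kp·[θ_E(t−Δt₁) + β] + N·Ω_A(t−Δt₂)             |

PP tracks (the pursuer converges into the target's wake), BP with a non-zero
bias intercepts, PN holds the bearing constant. The toolkit identifies gains
and sensorimotor delays by lag-scanned least-squares fits of Ω_P against
each candidate input, and scores whole controllers by the mean
point-to-point distance ε between measured and re-simulated trajectories,
with the model fly flying at the measured speed (speed replay).

A first-class synthetic-data generator produces closed-loop virtual-fly
chases with known ground-truth controllers, the arena geometry, dummy-target
kinematics (circle at 1 m/s; "spring" paths combining translation and
rotation), 190 Hz sampling, and 5 mm Gaussian tracking noise — so the whole
pipeline is testable by parameter recovery.

## Worked example

Generate ten noisy chases flown by a known biased-pursuit controller
(kp = 26 s⁻¹, two-frame delay), then recover it:

```python
import numpy as np
from pursuitkin import (
    SyntheticSpec, ControllerSpec, track_observables, identify_controllers,
    smooth_track, grid_search,
)
from pursuitkin.synthetic import _generate_set

truth = ControllerSpec(strategy="BP", kp=26.0, beta=0.0, dt1=2 / 190)
chases = _generate_set(SyntheticSpec(controller=truth, seed=1, noise_sd=0.005), 10)

obs = [track_observables(c) for c in chases]
fits = identify_controllers([a for a, _ in obs], [r for _, r in obs], plane="horizontal")
for name, f in fits.items():
    flag = " *" if f.accepted else ""
    print(f"{name:8s} gain={f.gain:7.2f}  delay={f.delay*1e3:5.1f} ms  R={f.r:+.3f}{flag}")

gs = grid_search([smooth_track(c, 25) for c in chases], "BP", "horizontal",
                 grid={"kp": np.arange(0, 61, 1.0)}, dt1=fits["theta_E"].delay)
print(f"grid-search optimum: kp = {gs.best_params['kp']:.0f} 1/s "
      f"(mean eps = {gs.best_eps*1e3:.1f} mm)")
```

Output:

```
theta_E  gain=  27.06  delay= 10.5 ms  R=+0.863 *
theta_A  gain=  -0.32  delay= 47.4 ms  R=-0.077
omega_E  gain=  -0.82  delay=  0.0 ms  R=-0.616
omega_A  gain=   0.95  delay= 36.8 ms  R=+0.776 *
grid-search optimum: kp = 26 1/s (mean eps = 2.5 mm)
```

Reading it: the error-angle fit (`theta_E`, starred at R ≥ 0.7) recovers the
generating gain within ~4% and the 10.5 ms delay exactly; the bearing-rate
fit (`omega_A`) also correlates — closed-loop pursuit data always show such
cross-correlations, which is why the replay grid search decides between
whole controllers: ε bottoms out at kp = 26 s⁻¹, the generating value, with
a 2.5 mm mean trajectory error (half the tracking noise).

A `pursuitkin` command-line tool wraps the same pipeline
(`pursuitkin synth | angles | stats | fit | gridsearch | simulate | recover`).

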