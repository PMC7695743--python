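"""Synthetic chases with known ground-truth controllers.

Emulates the experimental conditions of the chase arena: a dummy target on a
circular path at 1 m/s or on a "spring-shaped" path (translation along y
plus rotation about the vertical axis, forward speed within [0, 1.5] m/s and
rotation rate within [360, 1300] deg/s), a virtual fly flying a closed-loop
pursuit controller inside a 0.50 x 0.50 x 0.70 m arena at 190 frames/s, and
i.i.d. isotropic Gaussian position noise of SD 5 mm on both protagonists
(the reconstruction accuracy of the stereo rig being emulated).  Circular
targets can carry a 24 Hz sinusoidal speed modulation, an artefact of the
dummy actuation that the identification pipeline must be robust to.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .evaluation import grid_search
from .kinematics import smooth_track, track_observables
from .models import (
    BLOWFLY_HORIZONTAL,
    BLOWFLY_VERTICAL,
    ControllerSpec,
    SpeedPolicy,
    simulate_coupled,
)
from .system_id import identify_controllers
from .track import PursuitTrack

__all__ = ["SyntheticSpec", "gen_target", "gen_chase", "recovery_experiment"]

ARENA = (0.50, 0.50, 0.70)          # meters
SPRING_SPEED_RANGE = (0.0, 1.5)     # m/s, translational
SPRING_ROTATION_RANGE = (360.0, 1300.0)  # deg/s


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic chase.

    Target kinds: ``line`` (constant velocity), ``circle`` (1 m/s on a
    0.15 m radius by default), ``spring`` (y-translation plus rotation about
    a vertical axis).  The spring invariants — translational speed within
    [0, 1.5] m/s and rotation rate within [360, 1300] deg/s — are enforced.
    """

    kind: Literal["line", "circle", "spring"] = "spring"
    speed: float = 0.2                  # m/s: line speed / spring translation speed
    rotation_rate: float = 720.0        # deg/s, spring rotation about vertical axis
    rotation_radius: float = 0.10       # m, spring arm
    circle_radius: float = 0.15         # m
    circle_speed: float = 1.0           # m/s, tangential
    arena: tuple[float, float, float] = ARENA
    controller: ControllerSpec = BLOWFLY_HORIZONTAL
    v_controller: ControllerSpec = field(
        default_factory=lambda: replace(BLOWFLY_VERTICAL, plane="vertical")
    )
    policy: SpeedPolicy = SpeedPolicy(mode="constant", s_const=1.2)
    noise_sd: float = 0.005             # m
    frame_rate: float = 190.0
    duration: float = 2.0               # s
    seed: int = 0
    modulation_24hz: float = 0.0        # relative speed-modulation amplitude
    capture_radius: float = 0.010       # m
    heading_jitter_sd: float = 10.0     # deg, initial-heading jitter

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.kind == "spring":
            lo, hi = SPRING_SPEED_RANGE
            if not lo <= self.speed <= hi:
                raise ValueError(f"spring translation speed must be within {SPRING_SPEED_RANGE}")
            lo, hi = SPRING_ROTATION_RANGE
            if not lo <= self.rotation_rate <= hi:
                raise ValueError(f"spring rotation rate must be within {SPRING_ROTATION_RANGE}")
            peak = self.speed + self.rotation_radius * math.radians(self.rotation_rate)
            if peak > SPRING_SPEED_RANGE[1] + 1e-9:
                raise ValueError(
                    f"spring peak target speed {peak:.2f} m/s exceeds {SPRING_SPEED_RANGE[1]} m/s; "
                    "reduce speed, rotation_rate or rotation_radius"
                )
        if self.kind not in ("line", "circle", "spring"):
            raise ValueError(f"unknown target kind {self.kind!r}")


def _speed_phase(spec: SyntheticSpec, times: np.ndarray) -> np.ndarray:
    """Integral of the (optionally 24 Hz modulated) speed multiplier."""
    if spec.modulation_24hz == 0.0:
        return times.copy()
    w = 2.0 * math.pi * 24.0
    # integral of 1 + a sin(w t)
    return times + spec.modulation_24hz * (1.0 - np.cos(w * times)) / w


def gen_target(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free ideal target path sampled at ``frame_rate``.

    Returns ``(times, target_xyz)``.  The target flies at constant altitude
    (the dummy's z was never varied); the 24 Hz modulation, when enabled,
    multiplies the translational speed by ``1 + a sin(2 pi 24 t)``.
    """
    n = int(round(spec.duration * spec.frame_rate)) + 1
    times = np.arange(n) / spec.frame_rate
    ax, ay, az = spec.arena
    cx, cy, z0 = ax / 2.0, ay / 2.0, az / 2.0
    s_t = _speed_phase(spec, times)  # effective elapsed distance-time

    if spec.kind == "line":
        xyz = np.column_stack(
            [
                np.full(n, cx - ax / 4.0) + spec.speed * s_t,
                np.full(n, cy),
                np.full(n, z0),
            ]
        )
    elif spec.kind == "circle":
        omega = spec.circle_speed / spec.circle_radius  # rad/s
        phase = omega * s_t
        xyz = np.column_stack(
            [
                cx + spec.circle_radius * np.cos(phase),
                cy + spec.circle_radius * np.sin(phase),
                np.full(n, z0),
            ]
        )
    else:  # spring
        omega = math.radians(spec.rotation_rate)
        phase = omega * s_t
        y0 = cy - spec.speed * spec.duration / 2.0
        xyz = np.column_stack(
            [
                cx + spec.rotation_radius * np.cos(phase),
                y0 + spec.speed * s_t + spec.rotation_radius * np.sin(phase),
                np.full(n, z0),
            ]
        )
    return times, xyz


def gen_chase(spec: SyntheticSpec) -> tuple[PursuitTrack, dict]:
    """Closed-loop virtual-fly chase with measurement noise.

    The fly starts at a seeded uniform position inside the arena (10 cm
    margin from the target's start), initially headed at the target with
    seeded Gaussian jitter, and flies the spec's horizontal and vertical
    controllers.  Gaussian position noise of ``noise_sd`` is added
    independently to both protagonists.

    Returns the noisy track and a ground-truth dict with the generating
    controllers, the noise-free track and the capture outcome.
    """
    rng = np.random.default_rng(spec.seed)
    times, target = gen_target(spec)
    ax, ay, az = spec.arena

    for _ in range(100):
        start = rng.uniform([0.05, 0.05, 0.05], [ax - 0.05, ay - 0.05, az - 0.05])
        if np.linalg.norm(start - target[0]) > 0.10:
            break
    los = target[0] - start
    head_h = math.degrees(math.atan2(los[1], los[0])) + rng.normal(0.0, spec.heading_jitter_sd)
    head_v = math.degrees(math.atan2(los[2], math.hypot(los[0], los[1]))) + rng.normal(
        0.0, spec.heading_jitter_sd
    )

    sim = simulate_coupled(
        times,
        target,
        spec.controller,
        spec.v_controller,
        spec.policy,
        init_pos=start,
        init_heading_h=head_h,
        init_heading_v=head_v,
        capture_radius=spec.capture_radius,
    )
    m = len(sim)
    clean = PursuitTrack(
        time=sim.time,
        pursuer_xyz=sim.positions,
        target_xyz=target[:m],
        chase_id=f"synth-{spec.kind}-{spec.seed}",
        frame_rate=spec.frame_rate,
    )
    noisy = clean
    if spec.noise_sd > 0:
        noisy = clean.with_positions(
            clean.pursuer_xyz + rng.normal(0.0, spec.noise_sd, (m, 3)),
            clean.target_xyz + rng.normal(0.0, spec.noise_sd, (m, 3)),
        )
    truth = {
        "controller": spec.controller,
        "v_controller": spec.v_controller,
        "policy": spec.policy,
        "clean_track": clean,
        "captured": sim.captured,
        "capture_time": sim.capture_time,
        "sim": sim,
    }
    return noisy, truth


def _generate_set(spec: SyntheticSpec, n_chases: int, min_frames: int = 60) -> list[PursuitTrack]:
    """n seeded chases; ones truncated early by capture are re-drawn."""
    chases = []
    sub = 0
    while len(chases) < n_chases:
        track, truth = gen_chase(replace(spec, seed=spec.seed + 1000 * len(chases) + sub))
        if len(track) >= min_frames:
            chases.append(track)
        else:
            sub += 1
            if sub > 50:
                raise RuntimeError("could not generate enough sufficiently long chases")
    return chases


def recovery_experiment(
    n_chases: int,
    spec: SyntheticSpec,
    noise_levels: Sequence[float] = (0.0, 0.005),
    position_window: int = 25,
    rate_window: int = 7,
    do_grid: bool = False,
    kp_grid: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Bias/RMSE of recovered controller parameters versus ground truth.

    For each noise level, generates ``n_chases`` seeded chases, runs the
    identification pipeline (position smoothing, angles, rates, pooled
    lag-scan fits) and reports the recovered horizontal gain and delay (and,
    for PN generators, the navigation constant) against the generating
    values.  With ``do_grid`` the replay grid search over ``kp_grid`` is run
    as well and its argmin reported.
    """
    if n_chases < 1:
        raise ValueError("need at least one chase")
    h = spec.controller
    is_pn = h.strategy == "PN"
    true_gain = h.N if is_pn else h.kp
    true_delay = h.dt2 if is_pn else h.dt1
    fit_key = "omega_A" if is_pn else "theta_E"

    rows = []
    for noise in noise_levels:
        chases = _generate_set(replace(spec, noise_sd=noise), n_chases)
        obs = [
            track_observables(
                c,
                position_window=(position_window if noise > 0 else 0),
                rate_window=rate_window,
            )
            for c in chases
        ]
        fits = identify_controllers(
            [a for a, _ in obs], [r for _, r in obs], plane="horizontal"
        )
        fit = fits[fit_key]
        row = {
            "noise_sd": noise,
            "strategy": h.strategy,
            "true_gain": true_gain,
            "gain_hat": fit.gain,
            "gain_bias": fit.gain - true_gain,
            "gain_rel_err": (fit.gain - true_gain) / true_gain if true_gain else np.nan,
            "true_delay": true_delay,
            "delay_hat": fit.delay,
            "delay_err_frames": (fit.delay - true_delay) * spec.frame_rate,
            "R": fit.r,
            "n_frames": fit.n,
        }
        if do_grid:
            grid_vals = (
                np.asarray(kp_grid, dtype=float)
                if kp_grid is not None
                else np.arange(0.0, 61.0, 1.0)
            )
            # replay simulation needs de-noised speed and initial conditions
            sim_chases = (
                [smooth_track(c, position_window) for c in chases]
                if (noise > 0 and position_window)
                else chases
            )
            gs = grid_search(
                sim_chases,
                strategy="BP" if not is_pn else "PN",
                plane="horizontal",
                grid={"N" if is_pn else "kp": grid_vals},
                dt1=fit.delay if not is_pn else 0.0,
                dt2=fit.delay if is_pn else 0.0,
                fixed={"beta": h.beta},
            )
            row["grid_argmin"] = gs.best_params["N" if is_pn else "kp"]
            row["grid_eps"] = gs.best_eps
        rows.append(row)
    return pd.DataFrame(rows)
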