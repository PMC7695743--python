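"""Closed-loop kinematic pursuit simulators.

A virtual fly steers by one of four laws, each turning an angular input into
a commanded heading rate (degrees/s):

===================  =========================================================
pure pursuit (PP)    ``Omega_P = kp * theta_E(t - dt1)``            (beta = 0)
biased pursuit (BP)  ``Omega_P = kp * [theta_E(t - dt1) + beta]``
prop. nav. (PN)      ``Omega_P = N * Omega_A(t - dt2)``
mixed pursuit (MP)   ``Omega_P = kp * [theta_E(t - dt1) + beta]
                     + N * Omega_A(t - dt2)``
===================  =========================================================

PP and BP optionally add a derivative term ``kd * Omega_E(t - dt1)``
(``kd = 0`` disables it, the default).  Forward speed comes from a
:class:`SpeedPolicy`: replay of a measured speed profile, a constant, or the
angular-size law

    s = S_g                                         if rho <= 0.5 deg
    s = rho(t-dt) * S_v * exp(-rho(t-dt)/rho*) + S_g   otherwise

State is integrated by explicit Euler at the target track's frame interval;
delayed inputs are linearly interpolated in the input history and held at
their initial value for times earlier than the delay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .kinematics import DEFAULT_TARGET_DIAMETER, compute_x_prime, wrap_azimuth
from .track import PursuitTrack

__all__ = [
    "ControllerSpec",
    "SpeedPolicy",
    "SimResult",
    "Decoupled3DResult",
    "steering_command",
    "speed_command",
    "simulate_planar",
    "simulate_coupled",
    "simulate_3d",
    "horizontal_plane_setup",
    "vertical_plane_setup",
]

DEFAULT_CAPTURE_RADIUS = 0.010  # m: 8 mm dummy plus tracking SD

Strategy = Literal["PP", "BP", "PN", "MP"]


@dataclass(frozen=True)
class ControllerSpec:
    """Parameters of one steering law in one plane.

    ``kp`` in 1/s, ``beta`` in degrees, ``N`` and ``kd`` unitless, delays in
    seconds: ``dt1`` on the error-angle path, ``dt2`` on the bearing-rate
    path.
    """

    strategy: Strategy = "BP"
    kp: float = 0.0
    kd: float = 0.0
    beta: float = 0.0
    N: float = 0.0
    dt1: float = 0.0
    dt2: float = 0.0
    plane: Literal["horizontal", "vertical"] = "horizontal"

    def __post_init__(self) -> None:
        if self.strategy not in ("PP", "BP", "PN", "MP"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.kp < 0:
            raise ValueError("kp must be non-negative")
        if self.dt1 < 0 or self.dt2 < 0:
            raise ValueError("delays must be non-negative")
        if self.strategy == "PP" and self.beta != 0.0:
            raise ValueError("pure pursuit requires beta = 0")
        if self.strategy == "PN" and self.kp != 0.0:
            raise ValueError("proportional navigation uses no error-angle gain (kp = 0)")

    @property
    def max_delay(self) -> float:
        return max(self.dt1, self.dt2)


# Fitted horizontal / vertical biased-pursuit controllers of the blowfly
# (kp in 1/s, delay in s, beta in degrees).
BLOWFLY_HORIZONTAL = ControllerSpec(strategy="BP", kp=26.0, beta=0.0, dt1=0.010, plane="horizontal")
BLOWFLY_VERTICAL = ControllerSpec(strategy="BP", kp=10.0, beta=-23.0, dt1=0.021, plane="vertical")


@dataclass(frozen=True)
class SpeedPolicy:
    """Forward-speed law for the virtual fly.

    ``replay`` uses a measured per-frame speed profile (supplied by the
    simulator or via ``replay_speed``); ``constant`` holds ``s_const``;
    ``boeddeker`` applies the angular-size law with gains ``S_g`` (m/s),
    ``S_v`` (m/s per degree), ``rho_star`` (degrees) and delay ``dt``.
    The Boeddeker gains default to documented placeholders and should be set
    explicitly for quantitative use.
    """

    mode: Literal["replay", "constant", "boeddeker"] = "constant"
    s_const: float = 1.2
    S_g: float = 0.3
    S_v: float = 0.05
    rho_star: float = 20.0
    dt: float = 0.0
    replay_speed: np.ndarray | None = None
    target_diameter: float = DEFAULT_TARGET_DIAMETER

    def __post_init__(self) -> None:
        if self.mode not in ("replay", "constant", "boeddeker"):
            raise ValueError(f"unknown speed mode {self.mode!r}")
        if self.mode == "boeddeker" and not (
            self.S_g > 0 and self.S_v > 0 and self.rho_star > 0
        ):
            raise ValueError("boeddeker mode needs positive S_g, S_v, rho_star")


def steering_command(
    spec: ControllerSpec,
    theta_e_delayed: float,
    omega_a_delayed: float,
    omega_e_delayed: float = 0.0,
) -> float:
    """Heading-rate command (deg/s) for already-delayed inputs (deg, deg/s)."""
    if spec.strategy in ("PP", "BP"):
        cmd = spec.kp * (theta_e_delayed + spec.beta)
        if spec.kd:
            cmd += spec.kd * omega_e_delayed
        return cmd
    if spec.strategy == "PN":
        return spec.N * omega_a_delayed
    # MP: both paths, each with its own (already applied) delay
    return spec.kp * (theta_e_delayed + spec.beta) + spec.N * omega_a_delayed


def speed_command(policy: SpeedPolicy, rho_delayed: float = 0.0, replay_speed: float = 0.0) -> float:
    """Forward speed (m/s) under the policy; ``rho_delayed`` in degrees."""
    if policy.mode == "replay":
        return replay_speed
    if policy.mode == "constant":
        return policy.s_const
    if rho_delayed <= 0.0:
        raise ValueError("boeddeker mode needs a positive angular size")
    if rho_delayed <= 0.5:
        return policy.S_g
    return rho_delayed * policy.S_v * math.exp(-rho_delayed / policy.rho_star) + policy.S_g


@dataclass(frozen=True)
class SimResult:
    """Output of one closed-loop simulation (planar or 3D)."""

    time: np.ndarray
    positions: np.ndarray          # (n, 2) planar or (n, 3)
    headings: np.ndarray           # (n,) planar azimuth or (n, 2) az/elev, deg
    diagnostics: pd.DataFrame      # per-frame controller inputs/outputs
    captured: bool
    capture_time: float | None
    frame_rate: float
    target_positions: np.ndarray = None

    def __len__(self) -> int:
        return self.time.size

    def to_track(self, chase_id: str = "sim") -> PursuitTrack:
        """Simulated chase as a PursuitTrack (planar runs get z = 0)."""
        pur = self.positions
        tar = self.target_positions
        if pur.shape[1] == 2:
            pur = np.column_stack([pur, np.zeros(len(pur))])
            tar = np.column_stack([tar, np.zeros(len(tar))])
        return PursuitTrack(
            time=self.time, pursuer_xyz=pur, target_xyz=tar,
            chase_id=chase_id, frame_rate=self.frame_rate,
        )


@dataclass(frozen=True)
class Decoupled3DResult:
    """Paired horizontal (x, y) and vertical (x', z) replay simulations."""

    horizontal: SimResult
    vertical: SimResult


class _DelayedSeries:
    """Growing per-frame history with interpolated lookback in frames."""

    __slots__ = ("values", "n")

    def __init__(self, horizon: int):
        self.values = np.empty(horizon)
        self.n = 0

    def push(self, v: float) -> None:
        self.values[self.n] = v
        self.n += 1

    def delayed(self, delay_frames: float) -> float:
        # query at (current frame index) - delay; hold initial value before t0
        idx = (self.n - 1) - delay_frames
        if idx <= 0.0:
            return self.values[0]
        lo = int(idx)
        frac = idx - lo
        if frac == 0.0 or lo + 1 >= self.n:
            return self.values[lo]
        return (1.0 - frac) * self.values[lo] + frac * self.values[lo + 1]


def _check_uniform(times: np.ndarray, rel_tol: float = 1e-6) -> float:
    dt = np.diff(times)
    if dt.size == 0 or dt[0] <= 0:
        raise ValueError("need at least two strictly increasing time stamps")
    if np.abs(dt / dt[0] - 1.0).max() > 1e-3:
        raise ValueError("simulation requires a uniform time base")
    return float(np.mean(dt))


def simulate_planar(
    times: np.ndarray,
    target_xy: np.ndarray,
    spec: ControllerSpec,
    policy: SpeedPolicy,
    init_pos: Sequence[float],
    init_heading: float,
    capture_radius: float = DEFAULT_CAPTURE_RADIUS,
) -> SimResult:
    """Simulate a planar pursuit against a scripted target path.

    ``times`` must be uniform; ``target_xy`` is ``(n, 2)``.  The pursuer
    starts at ``init_pos`` with heading ``init_heading`` (degrees).  Each
    frame: record state, measure the angular inputs, apply the (delayed)
    steering law, then Euler-update heading and position.  The run stops at
    capture (``distance < capture_radius``) or at the end of the target
    track.
    """
    times = np.asarray(times, dtype=float)
    target_xy = np.asarray(target_xy, dtype=float)
    n = times.size
    dt = _check_uniform(times)
    rate = 1.0 / dt
    max_delay = max(spec.max_delay, policy.dt if policy.mode == "boeddeker" else 0.0)
    if max_delay >= times[-1] - times[0]:
        raise ValueError("controller delay exceeds the simulation horizon")
    if policy.mode == "replay":
        if policy.replay_speed is None or len(policy.replay_speed) < n:
            raise ValueError("replay mode requires a replay_speed series covering the horizon")

    x, y = float(init_pos[0]), float(init_pos[1])
    heading = float(init_heading)
    d1f, d2f, drf = spec.dt1 * rate, spec.dt2 * rate, policy.dt * rate

    th_e_hist = _DelayedSeries(n)
    om_a_hist = _DelayedSeries(n)
    om_e_hist = _DelayedSeries(n)
    rho_hist = _DelayedSeries(n)

    pos = np.empty((n, 2))
    head = np.empty(n)
    rec = {k: np.empty(n) for k in
           ("theta_E", "omega_A", "theta_E_used", "omega_A_used", "omega_P", "speed", "range")}
    captured = False
    capture_time = None
    prev_th_a = prev_th_a_cont = None
    prev_th_e = prev_th_e_cont = None
    r_half = policy.target_diameter / 2.0

    k = 0
    for k in range(n):
        pos[k] = (x, y)
        head[k] = heading
        dx, dy = target_xy[k, 0] - x, target_xy[k, 1] - y
        r = math.hypot(dx, dy)
        rec["range"][k] = r

        th_a = math.degrees(math.atan2(dy, dx))
        if prev_th_a is None:
            th_a_cont = th_a
            om_a = 0.0
        else:
            th_a_cont = prev_th_a_cont + wrap_azimuth(th_a - prev_th_a)
            om_a = (th_a_cont - prev_th_a_cont) * rate
        prev_th_a, prev_th_a_cont = th_a, th_a_cont

        th_e = wrap_azimuth(th_a - heading)
        if prev_th_e is None:
            th_e_cont = th_e
            om_e = 0.0
        else:
            th_e_cont = prev_th_e_cont + wrap_azimuth(th_e - prev_th_e)
            om_e = (th_e_cont - prev_th_e_cont) * rate
        prev_th_e, prev_th_e_cont = th_e, th_e_cont

        rho = 2.0 * math.degrees(math.atan2(r_half, r)) if r > 0 else 180.0
        th_e_hist.push(th_e)
        om_a_hist.push(om_a)
        om_e_hist.push(om_e)
        rho_hist.push(rho)

        th_e_d = th_e_hist.delayed(d1f)
        om_a_d = om_a_hist.delayed(d2f)
        om_e_d = om_e_hist.delayed(d1f)
        omega_p = steering_command(spec, th_e_d, om_a_d, om_e_d)
        speed = speed_command(
            policy,
            rho_delayed=rho_hist.delayed(drf),
            replay_speed=policy.replay_speed[k] if policy.mode == "replay" else 0.0,
        )
        rec["theta_E"][k] = th_e
        rec["omega_A"][k] = om_a
        rec["theta_E_used"][k] = th_e_d
        rec["omega_A_used"][k] = om_a_d
        rec["omega_P"][k] = omega_p
        rec["speed"][k] = speed

        if r < capture_radius:
            captured = True
            capture_time = float(times[k])
            break

        heading += omega_p * dt
        hr = math.radians(heading)
        x += speed * dt * math.cos(hr)
        y += speed * dt * math.sin(hr)

    m = k + 1
    diag = pd.DataFrame({key: v[:m] for key, v in rec.items()})
    diag.insert(0, "t", times[:m])
    return SimResult(
        time=times[:m].copy(),
        positions=pos[:m],
        headings=head[:m],
        diagnostics=diag,
        captured=captured,
        capture_time=capture_time,
        frame_rate=rate,
        target_positions=target_xy[:m].copy(),
    )


def simulate_coupled(
    times: np.ndarray,
    target_xyz: np.ndarray,
    h_spec: ControllerSpec,
    v_spec: ControllerSpec,
    policy: SpeedPolicy,
    init_pos: Sequence[float],
    init_heading_h: float,
    init_heading_v: float,
    capture_radius: float = DEFAULT_CAPTURE_RADIUS,
) -> SimResult:
    """Single-state 3D pursuit: yaw and pitch controllers drive one velocity.

    The horizontal controller receives ``theta_EH``/``Omega_AH``, the
    vertical one ``theta_EV``/``Omega_AV`` (elevation against horizontal
    range).  Velocity is ``s * (cos(el) cos(az), cos(el) sin(az), sin(el))``;
    pitch is clamped to [-89, 89] degrees.  Capture tests 3D distance.
    """
    times = np.asarray(times, dtype=float)
    target_xyz = np.asarray(target_xyz, dtype=float)
    n = times.size
    dt = _check_uniform(times)
    rate = 1.0 / dt
    for s in (h_spec, v_spec):
        if s.max_delay >= times[-1] - times[0]:
            raise ValueError("controller delay exceeds the simulation horizon")
    if policy.mode == "replay" and (policy.replay_speed is None or len(policy.replay_speed) < n):
        raise ValueError("replay mode requires a replay_speed series covering the horizon")

    x, y, z = (float(v) for v in init_pos)
    az, el = float(init_heading_h), float(init_heading_v)
    histories = {
        "th_eh": _DelayedSeries(n), "om_ah": _DelayedSeries(n), "om_eh": _DelayedSeries(n),
        "th_ev": _DelayedSeries(n), "om_av": _DelayedSeries(n), "om_ev": _DelayedSeries(n),
        "rho": _DelayedSeries(n),
    }
    pos = np.empty((n, 3))
    head = np.empty((n, 2))
    rec = {k: np.empty(n) for k in
           ("theta_EH", "theta_EV", "omega_AH", "omega_AV", "omega_PH", "omega_PV",
            "speed", "range")}
    captured = False
    capture_time = None
    prev = {}
    r_half = policy.target_diameter / 2.0
    rateH, rateV = rate, rate

    k = 0
    for k in range(n):
        pos[k] = (x, y, z)
        head[k] = (az, el)
        dx, dy, dz = target_xyz[k, 0] - x, target_xyz[k, 1] - y, target_xyz[k, 2] - z
        rh = math.hypot(dx, dy)
        r3 = math.hypot(rh, dz)
        rec["range"][k] = r3

        th_ah = math.degrees(math.atan2(dy, dx))
        th_av = math.degrees(math.atan2(dz, rh))
        if "th_ah" not in prev:
            th_ah_cont, om_ah = th_ah, 0.0
            om_av = 0.0
        else:
            th_ah_cont = prev["th_ah_cont"] + wrap_azimuth(th_ah - prev["th_ah"])
            om_ah = (th_ah_cont - prev["th_ah_cont"]) * rateH
            om_av = (th_av - prev["th_av"]) * rateV
        prev.update(th_ah=th_ah, th_ah_cont=th_ah_cont, th_av=th_av)

        th_eh = wrap_azimuth(th_ah - az)
        th_ev = th_av - el
        if "th_eh" not in prev:
            th_eh_cont, om_eh = th_eh, 0.0
            om_ev = 0.0
        else:
            th_eh_cont = prev["th_eh_cont"] + wrap_azimuth(th_eh - prev["th_eh"])
            om_eh = (th_eh_cont - prev["th_eh_cont"]) * rateH
            om_ev = (th_ev - prev["th_ev"]) * rateV
        prev.update(th_eh=th_eh, th_eh_cont=th_eh_cont, th_ev=th_ev)

        rho = 2.0 * math.degrees(math.atan2(r_half, r3)) if r3 > 0 else 180.0
        h = histories
        h["th_eh"].push(th_eh); h["om_ah"].push(om_ah); h["om_eh"].push(om_eh)
        h["th_ev"].push(th_ev); h["om_av"].push(om_av); h["om_ev"].push(om_ev)
        h["rho"].push(rho)

        om_ph = steering_command(
            h_spec,
            h["th_eh"].delayed(h_spec.dt1 * rate),
            h["om_ah"].delayed(h_spec.dt2 * rate),
            h["om_eh"].delayed(h_spec.dt1 * rate),
        )
        om_pv = steering_command(
            v_spec,
            h["th_ev"].delayed(v_spec.dt1 * rate),
            h["om_av"].delayed(v_spec.dt2 * rate),
            h["om_ev"].delayed(v_spec.dt1 * rate),
        )
        speed = speed_command(
            policy,
            rho_delayed=h["rho"].delayed(policy.dt * rate),
            replay_speed=policy.replay_speed[k] if policy.mode == "replay" else 0.0,
        )
        rec["theta_EH"][k] = th_eh
        rec["theta_EV"][k] = th_ev
        rec["omega_AH"][k] = om_ah
        rec["omega_AV"][k] = om_av
        rec["omega_PH"][k] = om_ph
        rec["omega_PV"][k] = om_pv
        rec["speed"][k] = speed

        if r3 < capture_radius:
            captured = True
            capture_time = float(times[k])
            break

        az += om_ph * dt
        el = max(-89.0, min(89.0, el + om_pv * dt))
        azr, elr = math.radians(az), math.radians(el)
        ce = math.cos(elr)
        x += speed * dt * ce * math.cos(azr)
        y += speed * dt * ce * math.sin(azr)
        z += speed * dt * math.sin(elr)

    m = k + 1
    diag = pd.DataFrame({key: v[:m] for key, v in rec.items()})
    diag.insert(0, "t", times[:m])
    return SimResult(
        time=times[:m].copy(),
        positions=pos[:m],
        headings=head[:m],
        diagnostics=diag,
        captured=captured,
        capture_time=capture_time,
        frame_rate=rate,
        target_positions=target_xyz[:m].copy(),
    )


def _initial_heading(points: np.ndarray, planar: bool = True) -> float:
    """Heading (deg) from the first frames with non-zero displacement."""
    for i in range(len(points) - 1):
        d = points[i + 1] - points[i]
        if np.linalg.norm(d) > 1e-12:
            return math.degrees(math.atan2(d[1], d[0]))
    raise ValueError("no displacement to define an initial heading")


def _step_speed(points: np.ndarray, dt: float) -> np.ndarray:
    """Per-frame replay speed; entry k drives the step k -> k+1."""
    steps = np.linalg.norm(np.diff(points, axis=0), axis=1) / dt
    return np.append(steps, steps[-1])


def horizontal_plane_setup(track: PursuitTrack) -> dict:
    """Replay ingredients for a horizontal (x, y) simulation of a chase."""
    pur = track.pursuer_xyz[:, :2]
    return {
        "times": track.time,
        "target_xy": track.target_xyz[:, :2],
        "init_pos": pur[0],
        "init_heading": _initial_heading(pur),
        "replay_speed": _step_speed(pur, track.dt),
        "measured_xy": pur,
    }


def vertical_plane_setup(track: PursuitTrack) -> dict:
    """Replay ingredients for a vertical (x', z) simulation of a chase.

    The abscissa is the pursuer's cumulative horizontal path length x'.  The
    target is placed at ``x'_P(t) + horizontal range(t)`` so that the
    vertical bearing angle of the planar construction equals the 3D
    elevation bearing when the simulated pursuer tracks the measured x'.
    """
    xp = compute_x_prime(track)
    hrange = np.hypot(
        track.target_xyz[:, 0] - track.pursuer_xyz[:, 0],
        track.target_xyz[:, 1] - track.pursuer_xyz[:, 1],
    )
    pur = np.column_stack([xp, track.pursuer_xyz[:, 2]])
    return {
        "times": track.time,
        "target_xy": np.column_stack([xp + hrange, track.target_xyz[:, 2]]),
        "init_pos": pur[0],
        "init_heading": _initial_heading(pur),
        "replay_speed": _step_speed(pur, track.dt),
        "measured_xy": pur,
    }


def simulate_3d(
    target_track: PursuitTrack,
    h_spec: ControllerSpec,
    v_spec: ControllerSpec,
    policy: SpeedPolicy | None = None,
    mode: Literal["decoupled", "coupled"] = "decoupled",
    capture_radius: float = DEFAULT_CAPTURE_RADIUS,
) -> SimResult | Decoupled3DResult:
    """Simulate a 3D chase against a measured track.

    ``decoupled`` (paper-faithful) runs the horizontal controller in (x, y)
    and the vertical controller in (x', z), each with its own replay speed
    from the measured pursuer.  ``coupled`` integrates one 3D state driven by
    both controllers.  Initial conditions come from the first measured
    frames.
    """
    if policy is None:
        policy = SpeedPolicy(mode="replay")
    if mode == "coupled":
        pur = target_track.pursuer_xyz
        rp = policy
        if rp.mode == "replay" and rp.replay_speed is None:
            rp = replace(rp, replay_speed=_step_speed(pur, target_track.dt))
        d0 = pur[1] - pur[0]
        return simulate_coupled(
            target_track.time,
            target_track.target_xyz,
            h_spec,
            v_spec,
            rp,
            init_pos=pur[0],
            init_heading_h=_initial_heading(pur[:, :2]),
            init_heading_v=math.degrees(
                math.atan2(d0[2], math.hypot(d0[0], d0[1]))
            ),
            capture_radius=capture_radius,
        )
    if mode != "decoupled":
        raise ValueError(f"unknown mode {mode!r}")

    results = {}
    for plane, spec, setup in (
        ("horizontal", h_spec, horizontal_plane_setup(target_track)),
        ("vertical", v_spec, vertical_plane_setup(target_track)),
    ):
        pol = policy
        if pol.mode == "replay":
            pol = replace(pol, replay_speed=setup["replay_speed"])
        results[plane] = simulate_planar(
            setup["times"],
            setup["target_xy"],
            spec,
            pol,
            init_pos=setup["init_pos"],
            init_heading=setup["init_heading"],
            capture_radius=capture_radius,
        )
    return Decoupled3DResult(horizontal=results["horizontal"], vertical=results["vertical"])
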