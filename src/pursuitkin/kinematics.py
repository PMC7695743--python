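"""Angular observables of a chase.

Two lines organise the geometry of pursuit.  The line of flight (LOF) joins
consecutive pursuer positions — it is the direction of the velocity vector —
and its spherical angles are the heading angles ``theta_P``.  The line of
sight (LOS) joins pursuer to target; its angles are the bearing angles
``theta_A``.  The egocentric position of the target, the error (or target
heading) angle, is their difference::

    theta_E = theta_A - theta_P        (per plane, azimuth wrapped)

Each angle splits into a horizontal component (azimuth in the external frame,
counter-clockwise positive, 0 deg along +x, range (-180, 180]) and a vertical
component (elevation, range [-90, 90]).  The vertical plane uses the
pursuer's cumulative horizontal path length ``x'`` as abscissa, so the
vertical heading is ``atan2(dz, horizontal displacement)``.

Angles are reported in degrees everywhere; rates in degrees per second.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .track import PursuitTrack

__all__ = [
    "AngleSeries",
    "RateSeries",
    "Saccade",
    "wrap_azimuth",
    "smooth_track",
    "compute_angles",
    "compute_x_prime",
    "compute_rates",
    "track_observables",
    "extract_saccades",
]

DEFAULT_TARGET_DIAMETER = 0.008  # meters; 8 mm dummy sphere


def wrap_azimuth(angle_deg):
    """Wrap angles in degrees to the interval (-180, 180]."""
    a = np.asarray(angle_deg, dtype=float)
    wrapped = a - 360.0 * np.floor((a + 180.0) / 360.0)
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    return wrapped if wrapped.ndim else float(wrapped)


@dataclass(frozen=True)
class AngleSeries:
    """Per-frame angular observables of one chase (degrees, meters, m/s)."""

    time: np.ndarray
    theta_ph: np.ndarray     # pursuer heading, azimuth
    theta_pv: np.ndarray     # pursuer heading, elevation
    theta_ah: np.ndarray     # bearing, azimuth
    theta_av: np.ndarray     # bearing, elevation
    theta_eh: np.ndarray     # error angle, azimuth (wrapped)
    theta_ev: np.ndarray     # error angle, elevation
    r_a: np.ndarray          # pursuer-target distance
    r_p: np.ndarray          # pursuer speed
    x_prime: np.ndarray      # cumulative horizontal path length
    rho: np.ndarray          # target angular size, degrees
    frame_rate: float
    heading_held: np.ndarray = field(default=None)  # frames with carried heading
    chase_id: str = "chase"

    def __len__(self) -> int:
        return self.time.size

    def angle(self, name: str) -> np.ndarray:
        return getattr(self, f"theta_{name.lower()}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.time,
                "theta_PH": self.theta_ph,
                "theta_PV": self.theta_pv,
                "theta_AH": self.theta_ah,
                "theta_AV": self.theta_av,
                "theta_EH": self.theta_eh,
                "theta_EV": self.theta_ev,
                "R_A": self.r_a,
                "R_P": self.r_p,
                "x_prime": self.x_prime,
                "rho": self.rho,
            }
        )


@dataclass(frozen=True)
class RateSeries:
    """First temporal derivatives of the six pursuit angles (deg/s)."""

    time: np.ndarray
    omega_ph: np.ndarray
    omega_pv: np.ndarray
    omega_ah: np.ndarray
    omega_av: np.ndarray
    omega_eh: np.ndarray
    omega_ev: np.ndarray
    frame_rate: float
    chase_id: str = "chase"

    def __len__(self) -> int:
        return self.time.size

    def rate(self, name: str) -> np.ndarray:
        return getattr(self, f"omega_{name.lower()}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.time,
                "omega_PH": self.omega_ph,
                "omega_PV": self.omega_pv,
                "omega_AH": self.omega_ah,
                "omega_AV": self.omega_av,
                "omega_EH": self.omega_eh,
                "omega_EV": self.omega_ev,
            }
        )


@dataclass(frozen=True)
class Saccade:
    """A supra-threshold yaw-rate event with its speed-dip timing."""

    t_start: float
    t_end: float
    t_peak: float
    peak_rate: float        # deg/s, signed
    t_speed_min: float
    speed_min: float        # m/s
    lead: float             # t_peak - t_speed_min, seconds (>0: dip precedes turn)


def smooth_track(track: PursuitTrack, window: int = 11, polyorder: int = 2) -> PursuitTrack:
    """Savitzky-Golay smooth both position series of a track.

    Tracking noise of a few millimeters makes frame-to-frame headings
    meaningless; smoothing positions before angle extraction is the standard
    remedy.  ``window`` is in frames and must be odd and <= track length.
    """
    n = len(track)
    if window > n:
        raise ValueError(f"smoothing window {window} exceeds track length {n}")
    if window % 2 == 0:
        raise ValueError("window must be odd")
    pur = savgol_filter(track.pursuer_xyz, window, polyorder, axis=0, mode="interp")
    tar = savgol_filter(track.target_xyz, window, polyorder, axis=0, mode="interp")
    return track.with_positions(pur, tar)


def compute_x_prime(track: PursuitTrack) -> np.ndarray:
    """Cumulative horizontal path length of the pursuer; 0 at the first frame."""
    d = np.diff(track.pursuer_xyz[:, :2], axis=0)
    steps = np.hypot(d[:, 0], d[:, 1])
    return np.concatenate([[0.0], np.cumsum(steps)])


def compute_angles(
    track: PursuitTrack,
    target_diameter: float = DEFAULT_TARGET_DIAMETER,
    mirror: bool = False,
    stationary_eps: float = 1e-9,
) -> AngleSeries:
    """Extract heading, bearing and error angles from a chase.

    The heading at frame ``i`` comes from the displacement ``i-1 -> i`` (the
    step *ending* at frame ``i``: under an explicit-Euler flight model the
    heading is updated before the step, so that displacement was flown with
    the frame-``i`` heading); the first frame carries the following heading.
    Frames with displacement below ``stationary_eps`` (stationary pursuer,
    heading undefined) carry the last valid heading and are flagged in
    ``heading_held``.

    ``mirror`` reflects the scene about the x-z plane (y -> -y) before any
    computation — the preprocessing used to normalise chases to a common
    target rotation direction.

    ``target_diameter > 0`` (meters) sets the angular size
    ``rho = 2 atan(radius / R_A)``.
    """
    if target_diameter <= 0:
        raise ValueError("target_diameter must be positive")
    pur = track.pursuer_xyz.copy()
    tar = track.target_xyz.copy()
    if mirror:
        pur[:, 1] *= -1.0
        tar[:, 1] *= -1.0

    n = len(track)
    disp = np.diff(pur, axis=0)
    horiz = np.hypot(disp[:, 0], disp[:, 1])
    norm = np.linalg.norm(disp, axis=1)

    theta_ph = np.empty(n)
    theta_pv = np.empty(n)
    held = np.zeros(n, dtype=bool)
    held[0] = True  # frame 0 has no incoming step; backfilled below
    last = None
    for i in range(1, n):
        j = i - 1  # displacement ending at frame i
        if norm[j] > stationary_eps:
            last = (
                math.degrees(math.atan2(disp[j, 1], disp[j, 0])),
                math.degrees(math.atan2(disp[j, 2], horiz[j])),
            )
            theta_ph[i], theta_pv[i] = last
        else:
            held[i] = True
            if last is not None:
                theta_ph[i], theta_pv[i] = last
    # leading undefined frames: backfill from the first valid heading
    first_valid = np.flatnonzero(~held)
    if first_valid.size == 0:
        raise ValueError("pursuer never moves; heading undefined everywhere")
    fv = first_valid[0]
    theta_ph[:fv] = theta_ph[fv]
    theta_pv[:fv] = theta_pv[fv]

    los = tar - pur
    horiz_los = np.hypot(los[:, 0], los[:, 1])
    theta_ah = np.degrees(np.arctan2(los[:, 1], los[:, 0]))
    theta_av = np.degrees(np.arctan2(los[:, 2], horiz_los))
    r_a = np.linalg.norm(los, axis=1)

    dt = np.diff(track.time)
    r_p = np.empty(n)
    r_p[1:] = norm / dt  # speed of the step ending at each frame
    r_p[0] = r_p[1]

    theta_eh = wrap_azimuth(theta_ah - theta_ph)
    theta_ev = theta_av - theta_pv
    rho = 2.0 * np.degrees(np.arctan2(target_diameter / 2.0, r_a))

    return AngleSeries(
        time=track.time.copy(),
        theta_ph=theta_ph,
        theta_pv=theta_pv,
        theta_ah=theta_ah,
        theta_av=theta_av,
        theta_eh=theta_eh,
        theta_ev=theta_ev,
        r_a=r_a,
        r_p=r_p,
        x_prime=compute_x_prime(track),
        rho=rho,
        frame_rate=track.frame_rate,
        heading_held=held,
        chase_id=track.chase_id,
    )


def _differentiate(series: np.ndarray, time: np.ndarray, window: int, polyorder: int) -> np.ndarray:
    if window and window > 1:
        if window % 2 == 0:
            raise ValueError("smoothing window must be odd")
        if series.size < window:
            raise ValueError(f"series of length {series.size} shorter than window {window}")
        series = savgol_filter(series, window, polyorder, mode="interp")
    return np.gradient(series, time)


def compute_rates(
    angles: AngleSeries,
    window: int = 5,
    polyorder: int = 2,
    uniform_rel_tol: float = 1e-3,
) -> RateSeries:
    """Differentiate the angle series into angular velocities.

    Azimuth series are unwrapped before differentiation so that +/-180 deg
    crossings do not produce spikes.  Each series is optionally
    Savitzky-Golay smoothed (``window`` frames, ``polyorder``; ``window=0``
    disables) and then differentiated with central differences, one-sided at
    the ends.  Requires a uniform time base.
    """
    dtv = np.diff(angles.time)
    if np.abs(dtv * angles.frame_rate - 1.0).max() > uniform_rel_tol:
        raise ValueError("compute_rates requires a uniform time base; resample first")

    t = angles.time
    ph = np.unwrap(angles.theta_ph, period=360.0)
    ah = np.unwrap(angles.theta_ah, period=360.0)
    eh = np.unwrap(angles.theta_eh, period=360.0)

    omega_ph = _differentiate(ph, t, window, polyorder)
    omega_ah = _differentiate(ah, t, window, polyorder)
    omega_eh = _differentiate(eh, t, window, polyorder)
    omega_pv = _differentiate(angles.theta_pv, t, window, polyorder)
    omega_av = _differentiate(angles.theta_av, t, window, polyorder)
    omega_ev = _differentiate(angles.theta_ev, t, window, polyorder)

    return RateSeries(
        time=t.copy(),
        omega_ph=omega_ph,
        omega_pv=omega_pv,
        omega_ah=omega_ah,
        omega_av=omega_av,
        omega_eh=omega_eh,
        omega_ev=omega_ev,
        frame_rate=angles.frame_rate,
        chase_id=angles.chase_id,
    )


def track_observables(
    track: PursuitTrack,
    position_window: int = 25,
    position_polyorder: int = 2,
    rate_window: int = 7,
    rate_polyorder: int = 2,
    target_diameter: float = DEFAULT_TARGET_DIAMETER,
    mirror: bool = False,
) -> tuple[AngleSeries, RateSeries]:
    """Standard pipeline from a (possibly noisy) track to angles and rates.

    Positions are Savitzky-Golay smoothed first (``position_window=0``
    disables, for noise-free simulated tracks), then angles are extracted and
    differentiated.
    """
    if position_window:
        track = smooth_track(track, position_window, position_polyorder)
    angles = compute_angles(track, target_diameter=target_diameter, mirror=mirror)
    rates = compute_rates(angles, window=rate_window, polyorder=rate_polyorder)
    return angles, rates


def extract_saccades(
    rates: RateSeries,
    speed: np.ndarray,
    threshold: float = 1500.0,
    speed_search_before: float = 0.05,
) -> list[Saccade]:
    """Detect body saccades: contiguous runs of ``|omega_PH| >= threshold``.

    For each event the signed peak yaw rate and its time are reported along
    with the forward-speed minimum found between ``speed_search_before``
    seconds before the event start and the event end — saccadic turns are
    coordinated with a brief deceleration that may precede the rotation.
    Default threshold 1500 deg/s.
    """
    speed = np.asarray(speed, dtype=float)
    if speed.shape != rates.time.shape:
        raise ValueError("speed series must align with the rate series")
    above = np.abs(rates.omega_ph) >= threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(above.size)

    events = []
    t = rates.time
    for s, e in zip(starts, ends):
        seg = rates.omega_ph[s:e]
        ipk = s + int(np.argmax(np.abs(seg)))
        w0 = int(np.searchsorted(t, t[s] - speed_search_before))
        imin = w0 + int(np.argmin(speed[w0:e]))
        events.append(
            Saccade(
                t_start=float(t[s]),
                t_end=float(t[e - 1]),
                t_peak=float(t[ipk]),
                peak_rate=float(rates.omega_ph[ipk]),
                t_speed_min=float(t[imin]),
                speed_min=float(speed[imin]),
                lead=float(t[ipk] - t[imin]),
            )
        )
    return events
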