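"""Control-law identification by lag-scanned linear fits.

Candidate steering laws predict the commanded heading rate ``Omega_P`` from a
delayed angular input (``theta_E`` for pursuit laws, ``Omega_A`` for
proportional navigation).  For each trial delay the input is shifted forward
in time (linear interpolation for sub-frame delays), an ordinary
least-squares line ``y = gain * x + intercept`` is fitted over the valid
overlap, and the Pearson correlation recorded; the reported fit is the one
maximising ``|R|``, ties broken toward the smallest delay.  Fits are pooled
over frames across chases.

A fit with ``R >= 0.7`` is flagged as an accepted candidate law.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .kinematics import AngleSeries, RateSeries

__all__ = [
    "LagFit",
    "LagScanRegressor",
    "lag_scan_fit",
    "identify_controllers",
    "speed_relations",
    "ACCEPT_R",
]

ACCEPT_R = 0.7
DEFAULT_MAX_DELAY = 0.050  # seconds: 0-50 ms scan


@dataclass(frozen=True)
class LagFit:
    """Best lagged linear fit ``y(t) = gain * x(t - delay) + intercept``."""

    gain: float
    intercept: float
    delay: float           # seconds
    r: float               # signed Pearson correlation at the best delay
    n: int                 # paired samples in the winning fit
    delays: np.ndarray     # scanned delays, seconds
    r_by_delay: np.ndarray

    @property
    def accepted(self) -> bool:
        return abs(self.r) >= ACCEPT_R

    def to_dict(self) -> dict:
        return {
            "gain": self.gain,
            "intercept": self.intercept,
            "delay": self.delay,
            "R": self.r,
            "n": self.n,
            "accepted": self.accepted,
        }


def _as_series_list(x) -> list[np.ndarray]:
    if isinstance(x, np.ndarray) and x.ndim == 1:
        return [np.asarray(x, dtype=float)]
    if isinstance(x, (list, tuple)):
        return [np.asarray(s, dtype=float) for s in x]
    return [np.asarray(x, dtype=float).ravel()]


def _shift_series(x: np.ndarray, delay_frames: float) -> tuple[np.ndarray, slice]:
    """``x(t - delay)`` sampled on the original grid, with its valid slice.

    Positive delays look back in time; negative delays (lead analysis) look
    forward.  Sub-frame shifts are linearly interpolated.
    """
    n = x.size
    idx = np.arange(n) - delay_frames
    lo = int(np.ceil(max(0.0, delay_frames)))
    hi = n - int(np.ceil(max(0.0, -delay_frames)))
    shifted = np.interp(idx, np.arange(n), x)
    return shifted, slice(lo, hi)


class LagScanRegressor(RegressorMixin, BaseEstimator):
    """Scikit-learn style estimator for the lag-scanned linear fit.

    Parameters
    ----------
    max_delay :
        Upper end of the scanned delay range, seconds.
    min_delay :
        Lower end; negative values allow the input to *lead* the output.
    delay_step :
        Scan step in seconds; defaults to one frame (``1 / frame_rate``).
    frame_rate :
        Sampling rate of the series, Hz.
    min_overlap :
        Delays with fewer valid pairs are skipped; if all are skipped the
        fit fails.

    Attributes (after ``fit``)
    --------------------------
    gain_, intercept_, delay_, r_, n_ : winning fit parameters.
    delays_, r_by_delay_ : the full scan.
    """

    def __init__(
        self,
        max_delay: float = DEFAULT_MAX_DELAY,
        min_delay: float = 0.0,
        delay_step: float | None = None,
        frame_rate: float = 190.0,
        min_overlap: int = 10,
    ):
        self.max_delay = max_delay
        self.min_delay = min_delay
        self.delay_step = delay_step
        self.frame_rate = frame_rate
        self.min_overlap = min_overlap

    def _delay_grid(self) -> np.ndarray:
        step = self.delay_step if self.delay_step is not None else 1.0 / self.frame_rate
        if step <= 0:
            raise ValueError("delay_step must be positive")
        # anchor the grid at zero so integer-frame delays are hit exactly
        lo = int(np.ceil(self.min_delay / step - 1e-9))
        hi = int(np.floor(self.max_delay / step + 1e-9))
        if hi < lo:
            raise ValueError("empty delay grid")
        return step * np.arange(lo, hi + 1)

    def fit(self, X, y, mask=None):
        """Fit on one series pair or on lists of per-chase series (pooled).

        ``mask`` (optional, same layout as ``y``) marks frames to keep —
        used to drop ill-conditioned frames, e.g. where the target is so
        close that angular observables are dominated by tracking noise.
        """
        xs = _as_series_list(X)
        ys = _as_series_list(y)
        if len(xs) != len(ys) or any(a.size != b.size for a, b in zip(xs, ys)):
            raise ValueError("x and y must pair up chase by chase with equal lengths")
        if mask is None:
            masks = [np.ones(s.size, dtype=bool) for s in ys]
        else:
            masks = [np.asarray(m, dtype=bool) for m in _as_series_list(mask)]
        delays = self._delay_grid()
        results = []
        for d in delays:
            pooled_x, pooled_y = [], []
            for xi, yi, mi in zip(xs, ys, masks):
                shifted, valid = _shift_series(xi, d * self.frame_rate)
                keep = mi[valid]
                pooled_x.append(shifted[valid][keep])
                pooled_y.append(yi[valid][keep])
            px = np.concatenate(pooled_x)
            py = np.concatenate(pooled_y)
            if px.size < self.min_overlap or px.size < 3:
                continue
            if np.ptp(px) == 0 or np.ptp(py) == 0:
                # degenerate: correlation undefined; treat as no relation
                results.append((d, 0.0, 0.0, float(py.mean()), px.size))
                continue
            res = stats.linregress(px, py)
            results.append((d, float(res.rvalue), float(res.slope), float(res.intercept), px.size))
        if not results:
            raise ValueError("no delay had enough overlapping samples")
        r_abs = np.array([abs(r[1]) for r in results])
        best = results[int(np.argmax(r_abs))]  # argmax returns first max: smallest delay wins ties
        self.delays_ = np.array([r[0] for r in results])
        self.r_by_delay_ = np.array([r[1] for r in results])
        self.delay_, self.r_, self.gain_, self.intercept_, self.n_ = best
        return self

    def predict(self, X):
        """Predict y from an already delay-aligned input series."""
        x = np.asarray(X, dtype=float).ravel()
        return self.gain_ * x + self.intercept_

    def as_lagfit(self) -> LagFit:
        return LagFit(
            gain=self.gain_,
            intercept=self.intercept_,
            delay=self.delay_,
            r=self.r_,
            n=self.n_,
            delays=self.delays_,
            r_by_delay=self.r_by_delay_,
        )


def lag_scan_fit(
    x,
    y,
    delays: Sequence[float] | None = None,
    frame_rate: float = 190.0,
    min_overlap: int = 10,
) -> LagFit:
    """Functional wrapper over :class:`LagScanRegressor`.

    ``delays`` may be an explicit list of scan delays in seconds (uniform
    spacing assumed) or None for the default 0-50 ms frame-resolution scan.
    """
    if delays is None:
        est = LagScanRegressor(frame_rate=frame_rate, min_overlap=min_overlap)
    else:
        delays = np.asarray(delays, dtype=float)
        if delays.size < 1:
            raise ValueError("empty delay grid")
        step = delays[1] - delays[0] if delays.size > 1 else None
        est = LagScanRegressor(
            max_delay=float(delays[-1]),
            min_delay=float(delays[0]),
            delay_step=None if step is None else float(step),
            frame_rate=frame_rate,
            min_overlap=min_overlap,
        )
    return est.fit(x, y).as_lagfit()


def _range_mask(angles: AngleSeries, plane: str, min_range: float, guard: int) -> np.ndarray:
    """Keep-mask excluding low in-plane-range frames plus a guard band."""
    from scipy.ndimage import binary_dilation

    if plane == "horizontal":
        in_plane = angles.r_a * np.cos(np.deg2rad(angles.theta_av))
    else:
        in_plane = angles.r_a
    bad = in_plane < min_range
    if guard > 0 and bad.any():
        bad = binary_dilation(bad, iterations=guard)
    return ~bad


_PLANE_SUFFIX = {"horizontal": "h", "vertical": "v"}
CANDIDATE_INPUTS = ("theta_E", "theta_A", "omega_E", "omega_A")


def identify_controllers(
    angles: AngleSeries | Iterable[AngleSeries],
    rates: RateSeries | Iterable[RateSeries],
    plane: str = "horizontal",
    max_delay: float = DEFAULT_MAX_DELAY,
    delay_step: float | None = None,
    min_range: float = 0.05,
    mask_guard: int = 12,
) -> dict[str, LagFit]:
    """Lag-scan fits of ``Omega_P`` against each candidate steering input.

    Pools frames across chases and returns one :class:`LagFit` per input in
    ``theta_E, theta_A, omega_E, omega_A`` for the requested plane.  The
    ``accepted`` flag on each fit marks ``R >= 0.7``.

    Frames where the pursuer-target separation *in the fitted plane* drops
    below ``min_range`` (meters) are excluded, together with a guard band of
    ``mask_guard`` frames around them: near-zero in-plane range makes the
    bearing geometry ill-conditioned (angular rates alias and tracking noise
    dominates), and the guard keeps delayed/smoothed neighbours of such
    frames out of the fit (``min_range=0`` disables).
    """
    if plane not in _PLANE_SUFFIX:
        raise ValueError("plane must be 'horizontal' or 'vertical'")
    sfx = _PLANE_SUFFIX[plane]
    angles_list = [angles] if isinstance(angles, AngleSeries) else list(angles)
    rates_list = [rates] if isinstance(rates, RateSeries) else list(rates)
    if len(angles_list) != len(rates_list):
        raise ValueError("need matching angle and rate series per chase")
    frame_rate = rates_list[0].frame_rate

    y = [r.rate(f"p{sfx}") for r in rates_list]
    inputs = {
        "theta_E": [a.angle(f"e{sfx}") for a in angles_list],
        "theta_A": [a.angle(f"a{sfx}") for a in angles_list],
        "omega_E": [r.rate(f"e{sfx}") for r in rates_list],
        "omega_A": [r.rate(f"a{sfx}") for r in rates_list],
    }
    masks = (
        [_range_mask(a, plane, min_range, mask_guard) for a in angles_list]
        if min_range > 0
        else None
    )
    out = {}
    for name, xs in inputs.items():
        est = LagScanRegressor(max_delay=max_delay, delay_step=delay_step, frame_rate=frame_rate)
        out[name] = est.fit(xs, y, mask=masks).as_lagfit()
    return out


def speed_relations(
    angles: AngleSeries | Iterable[AngleSeries],
    rates: RateSeries | Iterable[RateSeries],
    speed: np.ndarray | Iterable[np.ndarray] | None = None,
    max_delay: float = DEFAULT_MAX_DELAY,
    min_delay: float | None = None,
) -> dict[str, LagFit]:
    """Lagged fits of horizontal forward speed against steering covariates.

    Fits speed against ``|Omega_PH|`` (the saccade/speed coupling; negative
    delays allowed so a speed change may *lead* the turn), ``theta_EH``,
    ``Omega_EH`` and the target angular size ``rho``.  ``speed`` defaults to
    the ``R_P`` series carried by the angles.
    """
    angles_list = [angles] if isinstance(angles, AngleSeries) else list(angles)
    rates_list = [rates] if isinstance(rates, RateSeries) else list(rates)
    if speed is None:
        speeds = [a.r_p for a in angles_list]
    elif isinstance(speed, np.ndarray):
        speeds = [speed]
    else:
        speeds = [np.asarray(s, dtype=float) for s in speed]
    frame_rate = rates_list[0].frame_rate
    lo = -max_delay if min_delay is None else min_delay

    inputs = {
        "abs_omega_PH": [np.abs(r.omega_ph) for r in rates_list],
        "theta_EH": [a.theta_eh for a in angles_list],
        "omega_EH": [r.omega_eh for r in rates_list],
        "rho": [a.rho for a in angles_list],
    }
    out = {}
    for name, xs in inputs.items():
        est = LagScanRegressor(
            max_delay=max_delay,
            min_delay=lo if name == "abs_omega_PH" else 0.0,
            frame_rate=frame_rate,
        )
        out[name] = est.fit(xs, speeds).as_lagfit()
    return out


def fits_to_frame(fits: dict[str, LagFit]) -> pd.DataFrame:
    return pd.DataFrame({k: f.to_dict() for k, f in fits.items()}).T
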