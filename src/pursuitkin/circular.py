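"""Circular statistics of pursuit angles.

Angular distributions are summarised by the mean resultant vector: the
vector average of unit vectors pointing along each sample angle.  Its
direction is the angular mean ``mu`` and its length ``r`` in [0, 1] measures
concentration — 0 for a uniform distribution, 1 when all samples coincide.
The angular standard deviation used here is the circular SD
``sigma = sqrt(-2 ln r)``, the standard directional-statistics choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .kinematics import AngleSeries, wrap_azimuth

__all__ = ["CircularSummary", "mean_vector", "summarize_pursuit_angles", "POOLED_ANGLES"]

POOLED_ANGLES = ("ph", "ah", "eh", "pv", "av", "ev")


@dataclass(frozen=True)
class CircularSummary:
    """Mean vector, circular SD and 5-degree binned counts of an angular sample."""

    mu: float            # mean angle, degrees; NaN when undefined (r = 0)
    r_len: float         # mean resultant length in [0, 1]
    sigma: float         # circular SD, degrees; inf at r = 0
    n: int
    bins: np.ndarray     # counts per bin, sums to n
    bin_edges: np.ndarray
    mu_defined: bool = True

    def to_dict(self) -> dict:
        return {
            "mu": self.mu,
            "r_len": self.r_len,
            "sigma": self.sigma,
            "n": self.n,
            "mu_defined": self.mu_defined,
        }


def mean_vector(
    angles_deg: Sequence[float] | np.ndarray,
    bin_width: float = 5.0,
    r_tol: float = 1e-12,
) -> CircularSummary:
    """Summarise a sample of angles (degrees) by its mean resultant vector.

    Raises on empty input.  When the resultant length is (numerically) zero
    the mean direction is undefined: ``mu`` is NaN and ``mu_defined`` False.
    """
    a = np.ravel(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        raise ValueError("mean_vector needs at least one angle")
    if not np.isfinite(a).all():
        raise ValueError("non-finite angles")
    rad = np.deg2rad(a)
    c = np.cos(rad).mean()
    s = np.sin(rad).mean()
    r = float(np.hypot(c, s))
    defined = r > r_tol
    mu = float(np.rad2deg(np.arctan2(s, c))) if defined else float("nan")
    sigma = float(np.rad2deg(np.sqrt(-2.0 * np.log(r)))) if r > 0 else float("inf")

    edges = np.arange(-180.0, 180.0 + bin_width / 2, bin_width)
    counts, _ = np.histogram(wrap_azimuth_for_binning(a), bins=edges)
    return CircularSummary(
        mu=mu, r_len=r, sigma=sigma, n=a.size, bins=counts, bin_edges=edges, mu_defined=defined
    )


def wrap_azimuth_for_binning(a: np.ndarray) -> np.ndarray:
    # histogram over [-180, 180): map the closed upper endpoint onto -180
    w = np.asarray(wrap_azimuth(a), dtype=float)
    return np.where(w == 180.0, -180.0, w)


def summarize_pursuit_angles(
    angles: AngleSeries | Iterable[AngleSeries],
    bin_width: float = 5.0,
) -> dict[str, CircularSummary]:
    """One circular summary per pursuit angle, pooling frames across chases.

    Returns a dict keyed ``ph, ah, eh, pv, av, ev``; every frame of every
    chase counts once (frame-weighted pooling).
    """
    if isinstance(angles, AngleSeries):
        angles = [angles]
    series_list = list(angles)
    if not series_list:
        raise ValueError("no angle series given")
    out = {}
    for key in POOLED_ANGLES:
        pooled = np.concatenate([s.angle(key) for s in series_list])
        out[key] = mean_vector(pooled, bin_width=bin_width)
    return out


def summaries_to_frame(summaries: dict[str, CircularSummary]) -> pd.DataFrame:
    return pd.DataFrame({k: v.to_dict() for k, v in summaries.items()}).T
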