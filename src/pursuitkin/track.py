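"""Trajectory containers and delimited-text I/O.

A chase is a pair of synchronized 3D position time series: the pursuer (a male
fly) and the target (an actuated dummy).  Everything downstream — angle
extraction, controller identification, replay simulation — consumes the
:class:`PursuitTrack` defined here.  Units are meters and seconds throughout;
the nominal acquisition rate of the videography rig this format mirrors is
190 frames per second.

File dialect
------------
Tracks are stored as plain delimited text with the header
``t,xp,yp,zp,xt,yt,zt``.  Non-default delimiters, unit declarations (``ms``
time, ``mm`` lengths) and column remapping live in a small YAML sidecar/dict
passed as ``dialect`` so that the reader never guesses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PursuitTrack",
    "TrackFormatError",
    "TrackValidationError",
    "read_track",
    "write_track",
    "write_tracks",
    "resample_uniform",
]

logger = logging.getLogger(__name__)

DEFAULT_FRAME_RATE = 190.0
_CANONICAL_COLUMNS = ("t", "xp", "yp", "zp", "xt", "yt", "zt")


class TrackFormatError(ValueError):
    """Raised when a trajectory file cannot be parsed under its dialect."""


class TrackValidationError(ValueError):
    """Raised when parsed data violate the track contract."""


@dataclass(frozen=True)
class PursuitTrack:
    """Synchronized pursuer/target 3D position time series.

    Parameters
    ----------
    time :
        Sample times in seconds, strictly increasing, length ``n >= 3``.
    pursuer_xyz, target_xyz :
        ``(n, 3)`` position arrays in meters.
    chase_id :
        Free-form label used in filenames and reports.
    frame_rate :
        Nominal acquisition rate in Hz; the time base need not be exactly
        uniform (see :func:`resample_uniform`).
    """

    time: np.ndarray
    pursuer_xyz: np.ndarray
    target_xyz: np.ndarray
    chase_id: str = "chase"
    frame_rate: float = DEFAULT_FRAME_RATE

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        pur = np.asarray(self.pursuer_xyz, dtype=float)
        tar = np.asarray(self.target_xyz, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "pursuer_xyz", pur)
        object.__setattr__(self, "target_xyz", tar)
        if time.ndim != 1 or pur.shape != (time.size, 3) or tar.shape != (time.size, 3):
            raise TrackValidationError(
                f"shape mismatch: time {time.shape}, pursuer {pur.shape}, target {tar.shape}"
            )
        if time.size < 3:
            raise TrackValidationError(f"track needs >= 3 frames, got {time.size}")
        if not (np.isfinite(time).all() and np.isfinite(pur).all() and np.isfinite(tar).all()):
            raise TrackValidationError("non-finite values in track")
        if not (np.diff(time) > 0).all():
            raise TrackValidationError("time must be strictly increasing")
        if not self.frame_rate > 0:
            raise TrackValidationError("frame_rate must be positive")

    def __len__(self) -> int:
        return self.time.size

    @property
    def dt(self) -> float:
        """Nominal frame interval in seconds."""
        return 1.0 / self.frame_rate

    def max_dt_deviation(self) -> float:
        """Largest relative deviation of the time step from 1/frame_rate."""
        return float(np.abs(np.diff(self.time) * self.frame_rate - 1.0).max())

    def is_uniform(self, rel_tol: float = 1e-6) -> bool:
        return self.max_dt_deviation() <= rel_tol

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.time,
                "xp": self.pursuer_xyz[:, 0],
                "yp": self.pursuer_xyz[:, 1],
                "zp": self.pursuer_xyz[:, 2],
                "xt": self.target_xyz[:, 0],
                "yt": self.target_xyz[:, 1],
                "zt": self.target_xyz[:, 2],
            }
        )

    def with_positions(
        self, pursuer_xyz: np.ndarray, target_xyz: np.ndarray | None = None
    ) -> "PursuitTrack":
        return replace(
            self,
            pursuer_xyz=pursuer_xyz,
            target_xyz=self.target_xyz if target_xyz is None else target_xyz,
        )


@dataclass(frozen=True)
class Dialect:
    """Declared file conventions; all readers go through this."""

    delimiter: str = ","
    time_unit: str = "s"        # "s" | "ms"
    length_unit: str = "m"      # "m" | "mm" | "cm"
    columns: Mapping[str, str] = field(default_factory=dict)  # canonical -> file header
    nan_policy: str = "drop"    # "drop" | "interpolate" | "reject"
    frame_rate: float = DEFAULT_FRAME_RATE
    dt_rel_tol: float = 0.05    # reject file if time step deviates more than this

    _TIME_SCALE = {"s": 1.0, "ms": 1e-3}
    _LENGTH_SCALE = {"m": 1.0, "cm": 1e-2, "mm": 1e-3}

    @classmethod
    def from_spec(cls, spec: "Dialect | Mapping | str | Path | None") -> "Dialect":
        if spec is None:
            return cls()
        if isinstance(spec, cls):
            return spec
        if isinstance(spec, (str, Path)):
            with open(spec) as fh:
                spec = yaml.safe_load(fh) or {}
        return cls(**dict(spec))

    def time_scale(self) -> float:
        try:
            return self._TIME_SCALE[self.time_unit]
        except KeyError:
            raise TrackFormatError(f"unknown time unit {self.time_unit!r}") from None

    def length_scale(self) -> float:
        try:
            return self._LENGTH_SCALE[self.length_unit]
        except KeyError:
            raise TrackFormatError(f"unknown length unit {self.length_unit!r}") from None


def read_track(
    path: str | Path,
    dialect: Dialect | Mapping | str | Path | None = None,
    chase_id: str | None = None,
) -> PursuitTrack:
    """Read a delimited trajectory file into a validated :class:`PursuitTrack`.

    The ``dialect`` declares delimiter, units, column mapping and the NaN
    policy (``drop`` incomplete rows with a logged count, ``interpolate``
    them linearly in time, or ``reject`` the whole file).  Times are
    converted to seconds and coordinates to meters before validation; a file
    whose time step strays from ``1/frame_rate`` by more than
    ``dt_rel_tol`` (relative) is rejected.
    """
    path = Path(path)
    dia = Dialect.from_spec(dialect)
    if not path.exists():
        raise FileNotFoundError(path)

    header_comment = _read_header_comment(path)
    df = pd.read_csv(path, sep=dia.delimiter, comment="#", skipinitialspace=True)
    rename = {v: k for k, v in dia.columns.items()}
    df = df.rename(columns=rename)
    missing = [c for c in _CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrackFormatError(f"{path}: missing columns {missing}")
    df = df[list(_CANONICAL_COLUMNS)].astype(float)

    bad = df.isna().any(axis=1)
    if bad.any():
        if dia.nan_policy == "reject":
            raise TrackValidationError(f"{path}: {int(bad.sum())} rows with NaN (policy=reject)")
        if dia.nan_policy == "drop":
            logger.info("%s: dropping %d NaN rows", path, int(bad.sum()))
            df = df.loc[~bad]
        elif dia.nan_policy == "interpolate":
            logger.info("%s: interpolating %d NaN rows", path, int(bad.sum()))
            df = df.set_index("t").interpolate(method="index", limit_direction="both")
            df = df.reset_index()
        else:
            raise TrackFormatError(f"unknown nan_policy {dia.nan_policy!r}")

    time = df["t"].to_numpy() * dia.time_scale()
    scale = dia.length_scale()
    pur = df[["xp", "yp", "zp"]].to_numpy() * scale
    tar = df[["xt", "yt", "zt"]].to_numpy() * scale

    track = PursuitTrack(
        time=time,
        pursuer_xyz=pur,
        target_xyz=tar,
        chase_id=chase_id or header_comment or path.stem,
        frame_rate=dia.frame_rate,
    )
    # dropped rows leave gaps at integer multiples of the nominal step;
    # only the residual from the nearest multiple counts as jitter
    steps = np.diff(track.time) * dia.frame_rate
    dev = float(np.abs(steps - np.maximum(np.round(steps), 1.0)).max())
    if dev > dia.dt_rel_tol:
        raise TrackValidationError(
            f"{path}: time step deviates from 1/{dia.frame_rate} Hz by {dev:.3g} "
            f"(tolerance {dia.dt_rel_tol}); resample or fix the dialect"
        )
    return track


def _read_header_comment(path: Path) -> str | None:
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("#") and "chase_id:" in first:
        return first.split("chase_id:", 1)[1].strip()
    return None


def write_track(track: PursuitTrack, path: str | Path, delimiter: str = ",") -> Path:
    """Write a track as delimited text; round-trips through :func:`read_track`."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# chase_id: {track.chase_id}\n")
        track.to_frame().to_csv(fh, sep=delimiter, index=False, float_format="%.12g")
    return path


def write_tracks(tracks: Iterable[PursuitTrack], directory: str | Path) -> list[Path]:
    """Write one file per chase, named after its ``chase_id``."""
    directory = Path(directory)
    return [write_track(t, directory / f"{t.chase_id}.csv") for t in tracks]


def resample_uniform(track: PursuitTrack, rate: float | None = None) -> PursuitTrack:
    """Linearly interpolate a track onto a uniform grid spanning its time range.

    ``rate`` defaults to the track's nominal frame rate.  Already-uniform
    tracks at the same rate pass through unchanged up to floating point.
    """
    if rate is None:
        rate = track.frame_rate
    if rate <= 0:
        raise ValueError("rate must be positive")
    t0, t1 = track.time[0], track.time[-1]
    n = int(np.floor((t1 - t0) * rate + 1e-9)) + 1
    new_t = t0 + np.arange(n) / rate
    pur = np.column_stack([np.interp(new_t, track.time, track.pursuer_xyz[:, i]) for i in range(3)])
    tar = np.column_stack([np.interp(new_t, track.time, track.target_xyz[:, i]) for i in range(3)])
    return PursuitTrack(
        time=new_t,
        pursuer_xyz=pur,
        target_xyz=tar,
        chase_id=track.chase_id,
        frame_rate=float(rate),
    )
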