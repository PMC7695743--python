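"""Replay-based evaluation of candidate steering controllers.

A candidate controller is scored by re-simulating each measured chase with
the model fly flying at the measured speed (speed replay) and measuring the
mean point-to-point distance between measured and simulated pursuer
positions:

    eps_H = mean_k sqrt((x_hat_k - x_k)^2 + (y_hat_k - y_k)^2)
    eps_V = mean_k sqrt((x'_hat_k - x'_k)^2 + (z_hat_k - z_k)^2)

where x' is each trajectory's own cumulative horizontal path length.  A grid
search over controller gains yields an error surface whose argmin is the
best-fitting parameter set; strategies are compared by one-way ANOVA on
per-chase errors with Tukey pairwise follow-up.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .kinematics import compute_x_prime
from .models import (
    DEFAULT_CAPTURE_RADIUS,
    ControllerSpec,
    SpeedPolicy,
    horizontal_plane_setup,
    simulate_planar,
    vertical_plane_setup,
)
from .track import PursuitTrack

__all__ = [
    "ErrorScore",
    "GridSearchResult",
    "ControllerGridSearch",
    "trajectory_error",
    "grid_search",
    "compare_strategies",
    "StrategyComparison",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ErrorScore:
    """Per-plane mean trajectory errors of one simulated chase (meters)."""

    eps_h: float
    eps_v: float
    per_frame_h: np.ndarray
    per_frame_v: np.ndarray
    chase_id: str = "chase"


def _planar_error(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d = a - b
    return np.hypot(d[:, 0], d[:, 1])


def trajectory_error(measured: PursuitTrack, simulated: PursuitTrack) -> ErrorScore:
    """Eps metrics between a measured chase and a simulation on its time base."""
    if len(measured) != len(simulated):
        raise ValueError(
            f"length mismatch: measured {len(measured)} vs simulated {len(simulated)} frames"
        )
    per_h = _planar_error(measured.pursuer_xyz[:, :2], simulated.pursuer_xyz[:, :2])
    vm = np.column_stack([compute_x_prime(measured), measured.pursuer_xyz[:, 2]])
    vs = np.column_stack([compute_x_prime(simulated), simulated.pursuer_xyz[:, 2]])
    per_v = _planar_error(vm, vs)
    return ErrorScore(
        eps_h=float(per_h.mean()),
        eps_v=float(per_v.mean()),
        per_frame_h=per_h,
        per_frame_v=per_v,
        chase_id=measured.chase_id,
    )


@dataclass(frozen=True)
class GridSearchResult:
    """Error surface of a controller family over its parameter grid."""

    axes: dict[str, np.ndarray]         # axis name -> grid values
    surface: np.ndarray                 # mean eps over chases, shaped by axes
    per_chase: np.ndarray               # (*surface.shape, n_chases)
    best_params: dict[str, float]
    best_eps: float
    strategy: str
    plane: str

    def to_frame(self) -> pd.DataFrame:
        names = list(self.axes)
        rows = []
        for idx in np.ndindex(self.surface.shape):
            row = {n: self.axes[n][i] for n, i in zip(names, idx)}
            row["eps"] = self.surface[idx]
            rows.append(row)
        return pd.DataFrame(rows)


class ControllerGridSearch(BaseEstimator):
    """Grid search over steering-law gains by replay simulation.

    Scanned axes are whichever of ``kp_grid``, ``N_grid``, ``beta_grid`` are
    not None (relevant to ``strategy``); the other parameters are held at
    ``kp``/``N``/``beta``.  Delays ``dt1``/``dt2`` are the plane's
    identified sensorimotor delays and are not scanned.

    After ``fit(chases)``: ``surface_``, ``axes_``, ``per_chase_``,
    ``best_params_``, ``best_eps_``, ``result_``.
    """

    def __init__(
        self,
        strategy: str = "BP",
        plane: str = "horizontal",
        kp_grid: Sequence[float] | None = None,
        N_grid: Sequence[float] | None = None,
        beta_grid: Sequence[float] | None = None,
        kp: float = 0.0,
        N: float = 0.0,
        beta: float = 0.0,
        kd: float = 0.0,
        dt1: float = 0.0,
        dt2: float = 0.0,
        capture_radius: float = DEFAULT_CAPTURE_RADIUS,
    ):
        self.strategy = strategy
        self.plane = plane
        self.kp_grid = kp_grid
        self.N_grid = N_grid
        self.beta_grid = beta_grid
        self.kp = kp
        self.N = N
        self.beta = beta
        self.kd = kd
        self.dt1 = dt1
        self.dt2 = dt2
        self.capture_radius = capture_radius

    def _axes(self) -> dict[str, np.ndarray]:
        axes = {}
        for name, grid in (("kp", self.kp_grid), ("N", self.N_grid), ("beta", self.beta_grid)):
            if grid is not None:
                axes[name] = np.asarray(grid, dtype=float)
        if not axes:
            raise ValueError("no grid axis given")
        return axes

    def _spec(self, point: Mapping[str, float]) -> ControllerSpec:
        params = {"kp": self.kp, "N": self.N, "beta": self.beta}
        params.update(point)
        return ControllerSpec(
            strategy=self.strategy,
            kp=params["kp"] if self.strategy != "PN" else 0.0,
            N=params["N"],
            beta=params["beta"],
            kd=self.kd,
            dt1=self.dt1,
            dt2=self.dt2,
            plane=self.plane,
        )

    def fit(self, chases: Iterable[PursuitTrack], y=None):
        chases = list(chases)
        if not chases:
            raise ValueError("need at least one chase")
        if self.plane == "horizontal":
            setups = [horizontal_plane_setup(c) for c in chases]
        elif self.plane == "vertical":
            setups = [vertical_plane_setup(c) for c in chases]
        else:
            raise ValueError("plane must be 'horizontal' or 'vertical'")

        axes = self._axes()
        names = list(axes)
        shape = tuple(len(v) for v in axes.values())
        per_chase = np.full(shape + (len(chases),), np.nan)

        for idx in itertools.product(*(range(len(v)) for v in axes.values())):
            point = {n: float(axes[n][i]) for n, i in zip(names, idx)}
            spec = self._spec(point)
            for j, setup in enumerate(setups):
                try:
                    sim = simulate_planar(
                        setup["times"],
                        setup["target_xy"],
                        spec,
                        SpeedPolicy(mode="replay", replay_speed=setup["replay_speed"]),
                        init_pos=setup["init_pos"],
                        init_heading=setup["init_heading"],
                        capture_radius=self.capture_radius,
                    )
                except Exception:  # noqa: BLE001 - surface point recorded as missing
                    logger.warning(
                        "simulation failed at %s for chase %s", point, chases[j].chase_id
                    )
                    continue
                m = len(sim)
                per_chase[idx + (j,)] = _planar_error(
                    sim.positions, setup["measured_xy"][:m]
                ).mean()

        with np.errstate(invalid="ignore"):
            surface = np.nanmean(per_chase, axis=-1)
        if np.isnan(surface).all():
            raise ValueError("every grid point failed to simulate")
        best_idx = np.unravel_index(np.nanargmin(surface), surface.shape)
        best = {n: float(axes[n][i]) for n, i in zip(names, best_idx)}

        self.axes_ = axes
        self.surface_ = surface
        self.per_chase_ = per_chase
        self.best_params_ = best
        self.best_eps_ = float(surface[best_idx])
        self.result_ = GridSearchResult(
            axes=axes,
            surface=surface,
            per_chase=per_chase,
            best_params=best,
            best_eps=self.best_eps_,
            strategy=self.strategy,
            plane=self.plane,
        )
        return self

    def per_chase_at_best(self) -> np.ndarray:
        idx = tuple(
            int(np.flatnonzero(self.axes_[n] == v)[0]) for n, v in self.best_params_.items()
        )
        return self.per_chase_[idx]


def grid_search(
    chases: Iterable[PursuitTrack],
    strategy: str,
    plane: str,
    grid: Mapping[str, Sequence[float]],
    dt1: float = 0.0,
    dt2: float = 0.0,
    fixed: Mapping[str, float] | None = None,
    capture_radius: float = DEFAULT_CAPTURE_RADIUS,
) -> GridSearchResult:
    """Functional wrapper over :class:`ControllerGridSearch`.

    ``grid`` maps axis names (``kp``, ``N``, ``beta``) to value lists;
    ``fixed`` pins the non-scanned parameters.
    """
    fixed = dict(fixed or {})
    est = ControllerGridSearch(
        strategy=strategy,
        plane=plane,
        kp_grid=grid.get("kp"),
        N_grid=grid.get("N"),
        beta_grid=grid.get("beta"),
        kp=fixed.get("kp", 0.0),
        N=fixed.get("N", 0.0),
        beta=fixed.get("beta", 0.0),
        kd=fixed.get("kd", 0.0),
        dt1=dt1,
        dt2=dt2,
        capture_radius=capture_radius,
    )
    return est.fit(chases).result_


@dataclass(frozen=True)
class StrategyComparison:
    """One-way ANOVA across strategies plus Tukey pairwise comparisons."""

    f_stat: float
    p_value: float
    pairwise: pd.DataFrame   # columns: group1, group2, meandiff, p_adj, significant
    group_means: dict[str, float]

    def significance(self, alpha: float = 0.05, strong: float = 0.001) -> str:
        if self.p_value < strong:
            return "***"
        return "n.s." if self.p_value > alpha else "*"


def compare_strategies(
    scores: Mapping[str, Sequence[float]], pairwise: bool = True
) -> StrategyComparison:
    """Compare per-chase eps scores across >= 2 strategies.

    Scores should be paired (same chases per strategy); each group needs at
    least 3 observations.  Significance conventions: ``n.s.`` above 0.05,
    ``***`` below 0.001.  ``pairwise=False`` skips the Tukey follow-up.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in scores.items()}
    if len(groups) < 2:
        raise ValueError("need at least two strategies")
    for k, v in groups.items():
        if v.size < 3:
            raise ValueError(f"strategy {k!r} has fewer than 3 observations")

    f_stat, p_value = stats.f_oneway(*groups.values())
    if not np.isfinite(f_stat):
        # all groups identical with zero within-group variance
        f_stat, p_value = 0.0, 1.0

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate(list(groups.values()))
    labels = np.concatenate([[k] * v.size for k, v in groups.items()])
    if not pairwise:
        pairwise_df = pd.DataFrame(
            columns=["group1", "group2", "meandiff", "p_adj", "significant"]
        )
        return StrategyComparison(
            f_stat=float(f_stat),
            p_value=float(p_value),
            pairwise=pairwise_df,
            group_means={k: float(v.mean()) for k, v in groups.items()},
        )
    if np.ptp(values) == 0:
        pairs = list(itertools.combinations(groups, 2))
        pairwise_df = pd.DataFrame(
            {
                "group1": [a for a, _ in pairs],
                "group2": [b for _, b in pairs],
                "meandiff": 0.0,
                "p_adj": 1.0,
                "significant": False,
            }
        )
    else:
        tk = pairwise_tukeyhsd(values, labels)
        pairwise_df = pd.DataFrame(
            tk.summary().data[1:], columns=[c.strip() for c in tk.summary().data[0]]
        ).rename(columns={"p-adj": "p_adj", "reject": "significant"})
    return StrategyComparison(
        f_stat=float(f_stat),
        p_value=float(p_value),
        pairwise=pairwise_df,
        group_means={k: float(v.mean()) for k, v in groups.items()},
    )
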