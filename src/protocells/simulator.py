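"""Trajectory driver, survival classification and summary statistics."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import dynamics
from .schedule import ScheduleParams, TimeGrid, build_grid
from .dynamics import InitialDensities, ModelParams, PostState, PreState

__all__ = [
    "Trajectory",
    "SummaryStats",
    "run",
    "classify_survival",
    "summarize",
    "MEAN_MODES",
]

#: Averaging conventions: "<protocell phase>_<nutrient phase>".  Protocell
#: densities can be taken just after ("post") or just before ("pre") the
#: competition; nutrient pools just before the competition ("pre") or as the
#: unconsumed remainder free + hidden ("post").
MEAN_MODES = ("post_pre", "pre_pre", "post_post", "pre_post")


@dataclass(frozen=True)
class Trajectory:
    """Time-indexed record of the simulation: one pre/post state pair per
    modeling time point, plus the grid that produced them."""

    grid: TimeGrid
    pre: tuple[PreState, ...]
    post: tuple[PostState, ...]

    def __post_init__(self) -> None:
        if not (len(self.pre) == len(self.post) == len(self.grid)):
            raise ValueError("trajectory length must equal grid length")

    @property
    def times(self) -> np.ndarray:
        return self.grid.times

    @property
    def qtilde(self) -> np.ndarray:
        """(n, 3, 2) pre-competition class densities."""
        return np.stack([p.qtilde for p in self.pre])

    @property
    def qt(self) -> np.ndarray:
        """(n, 3, 2) post-competition class densities."""
        return np.stack([p.qt for p in self.post])

    @property
    def pools_pre(self) -> np.ndarray:
        """(n, 3) nutrient pools just before the competition."""
        return np.stack([p.pools for p in self.pre])

    @property
    def free(self) -> np.ndarray:
        return np.stack([p.free for p in self.post])

    @property
    def hidden(self) -> np.ndarray:
        return np.stack([p.hidden for p in self.post])

    def species_series(self, s: int, *, phase: str = "post") -> np.ndarray:
        """Total density of species ``s`` (young + old) at every point."""
        arr = self.qt if phase == "post" else self.qtilde
        return arr[:, s, :].sum(axis=1)

    def total_series(self, *, phase: str = "post") -> np.ndarray:
        """Overall protocell density QT = QT0 + QT1 + QT2."""
        arr = self.qt if phase == "post" else self.qtilde
        return arr.sum(axis=(1, 2))

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {
            "time": self.times,
            "case": np.array([self.grid.case(i).label for i in range(len(self.grid))]),
        }
        ages = ("young", "old")
        for s in range(3):
            for a in (0, 1):
                cols[f"Qtilde_T{s}{ages[a]}"] = self.qtilde[:, s, a]
        for s in range(3):
            for a in (0, 1):
                cols[f"QT{s}{ages[a]}"] = self.qt[:, s, a]
        for n, name in enumerate(dynamics.NUTRIENT_NAMES):
            cols[f"Q{name}_pre"] = self.pools_pre[:, n]
        for n, name in enumerate(dynamics.NUTRIENT_NAMES):
            cols[f"Q{name}_free"] = self.free[:, n]
        for n, name in enumerate(dynamics.NUTRIENT_NAMES):
            cols[f"Q{name}_hidden"] = self.hidden[:, n]
        for s in range(3):
            cols[f"QT{s}"] = self.species_series(s)
        cols["QT"] = self.total_series()
        return pd.DataFrame(cols)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def run(
    schedule: ScheduleParams,
    model: ModelParams,
    inits: InitialDensities,
    *,
    return_parental_nutrients: bool = False,
) -> Trajectory:
    """Run the deterministic model over the whole time grid."""
    grid = build_grid(schedule)
    pres: list[PreState] = []
    posts: list[PostState] = []
    for i in range(len(grid)):
        pre, post = dynamics.step(
            posts, grid, i, model, inits,
            return_parental_nutrients=return_parental_nutrients,
        )
        pres.append(pre)
        posts.append(post)
    return Trajectory(grid=grid, pre=tuple(pres), post=tuple(posts))


def classify_survival(
    traj: Trajectory,
    species: int,
    epsilon: float = 1e-9,
) -> tuple[bool, Optional[float]]:
    """Whether ``species`` is extinct at the end of the run, and when it fell.

    The species is extinct iff its total post-competition density at its
    final operation time is at most ``epsilon``.  The extinction time is the
    first operation time from which the density stays at or below ``epsilon``
    for the rest of the run (``None`` for survivors).
    """
    op_idx = np.nonzero(traj.grid.active[:, species])[0]
    if len(op_idx) == 0:
        # Species never operates inside the horizon; it is absent throughout.
        extinct = float(traj.qt[:, species, :].sum(axis=1).max(initial=0.0)) <= epsilon
        return extinct, (0.0 if extinct else None)
    totals = traj.qt[op_idx, species, :].sum(axis=1)
    if totals[-1] > epsilon:
        return False, None
    alive = np.nonzero(totals > epsilon)[0]
    first_dead = 0 if len(alive) == 0 else int(alive[-1]) + 1
    return True, float(traj.times[op_idx[first_dead]])


@dataclass(frozen=True)
class SummaryStats:
    """Time-point averages over a window plus per-species survival outcome."""

    mean_QT: float
    mean_QT0: float
    mean_QT1: float
    mean_QT2: float
    mean_Qx: float
    mean_Qx1: float
    mean_Qx2: float
    extinct: tuple[bool, bool, bool]
    extinction_time: tuple[Optional[float], Optional[float], Optional[float]]
    window: tuple[float, float]
    mean_mode: str
    n_points: int

    def to_dict(self) -> dict:
        return {
            "mean_QT": self.mean_QT,
            "mean_QT0": self.mean_QT0,
            "mean_QT1": self.mean_QT1,
            "mean_QT2": self.mean_QT2,
            "mean_Qx": self.mean_Qx,
            "mean_Qx1": self.mean_Qx1,
            "mean_Qx2": self.mean_Qx2,
            "extinct": list(self.extinct),
            "extinction_time": list(self.extinction_time),
            "window": list(self.window),
            "mean_mode": self.mean_mode,
            "n_points": self.n_points,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def summarize(
    traj: Trajectory,
    window: Optional[tuple[float, float]] = None,
    *,
    epsilon: float = 1e-9,
    mean_mode: str = "post_pre",
) -> SummaryStats:
    """Compute time-point means over ``window`` and survival outcomes.

    The default convention averages post-competition protocell densities and
    pre-competition nutrient pools over every modeling time point in the
    window (the full horizon when ``window`` is omitted).
    """
    if mean_mode not in MEAN_MODES:
        raise ValueError(f"mean_mode must be one of {MEAN_MODES}, got {mean_mode!r}")
    if window is None:
        window = (0.0, float(traj.grid.params.horizon))
    lo, hi = window
    mask = (traj.times >= lo) & (traj.times <= hi)
    if not mask.any():
        raise ValueError(f"window {window} contains no modeling time points")

    cell_phase, pool_phase = mean_mode.split("_")
    cells = traj.qt if cell_phase == "post" else traj.qtilde
    pools = traj.pools_pre if pool_phase == "pre" else traj.free + traj.hidden

    cells = cells[mask]
    pools = pools[mask]
    per_species = cells.sum(axis=2).mean(axis=0)
    pool_means = pools.mean(axis=0)

    surv = [classify_survival(traj, s, epsilon) for s in range(3)]
    return SummaryStats(
        mean_QT=float(per_species.sum()),
        mean_QT0=float(per_species[0]),
        mean_QT1=float(per_species[1]),
        mean_QT2=float(per_species[2]),
        mean_Qx=float(pool_means[0]),
        mean_Qx1=float(pool_means[1]),
        mean_Qx2=float(pool_means[2]),
        extinct=tuple(s[0] for s in surv),
        extinction_time=tuple(s[1] for s in surv),
        window=(float(lo), float(hi)),
        mean_mode=mean_mode,
        n_points=int(mask.sum()),
    )
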