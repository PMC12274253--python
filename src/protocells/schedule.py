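"""Operation-time scheduling for the three-species protocell ecosystem.

Each protocell species reproduces on its own arithmetic clock: species ``s``
operates at times ``t_s0 + k*tau_s`` (k = 0, 1, 2, ...).  The ecosystem is
advanced over the *modeling time points* — the sorted union of the three
operation-time sequences — and at each point only the species for which the
point is an operation time ("active" species) compete for nutrients.

Because reproduction times may be mutually incommensurable (e.g. pi/2 and
1.7), every operation time is computed directly as ``t_s0 + k*tau_s`` rather
than by cumulative summation, and two candidate times are merged into one
grid point only when they agree to a relative tolerance.  This keeps the grid
exact over long horizons: incommensurable clocks never spuriously collide,
while genuinely coincident times (commensurable clocks) always do.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "SPECIES_NAMES",
    "CASE_LABELS",
    "ConfigurationError",
    "ScheduleParams",
    "TimeGrid",
    "OperationCase",
    "build_grid",
    "last_op_index",
    "classify_case",
]

#: Species indices: 0 = generalist T0, 1 = specialist T1, 2 = specialist T2.
SPECIES_NAMES = ("T0", "T1", "T2")

#: Roman-numeral operation-case label for each nonempty active-species set.
#: The simulator keys all behaviour on the active set itself; the labels are
#: bookkeeping for trajectory output.
CASE_LABELS: dict[frozenset[int], str] = {
    frozenset({0}): "I",
    frozenset({1}): "II",
    frozenset({2}): "III",
    frozenset({0, 1}): "IV",
    frozenset({0, 2}): "V",
    frozenset({1, 2}): "VI",
    frozenset({0, 1, 2}): "VII",
}


class ConfigurationError(ValueError):
    """A model/schedule parameter violates its constraints."""


def _merge_tol(t: float) -> float:
    # Two candidate times within this distance are the same grid point.
    return 1e-9 * max(1.0, abs(t))


@dataclass(frozen=True)
class ScheduleParams:
    """Reproduction clocks of the three species and the studied interval.

    Parameters
    ----------
    tau0, tau1, tau2
        Reproduction (cycle) times of the generalist T0 and the specialists
        T1, T2; strictly positive, mutually incommensurable values allowed.
    t00, t10, t20
        Initial operation times.  At least one must be 0 so that the first
        modeling time point of the ecosystem is t = 0.
    horizon
        End of the studied time interval (closed: points with t <= horizon
        belong to the grid).
    """

    tau0: float
    tau1: float
    tau2: float
    t00: float = 0.0
    t10: float = 0.0
    t20: float = 0.0
    horizon: float = 200.0

    def __post_init__(self) -> None:
        problems = []
        for name in ("tau0", "tau1", "tau2"):
            if not getattr(self, name) > 0:
                problems.append(f"{name} must be strictly positive, got {getattr(self, name)!r}")
        for name in ("t00", "t10", "t20"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be non-negative, got {getattr(self, name)!r}")
        if min(self.t00, self.t10, self.t20) > _merge_tol(0.0):
            problems.append(
                "at least one of t00, t10, t20 must be 0 "
                f"(got {self.t00!r}, {self.t10!r}, {self.t20!r})"
            )
        if not self.horizon > 0:
            problems.append(f"horizon must be positive, got {self.horizon!r}")
        if problems:
            raise ConfigurationError("; ".join(problems))

    @property
    def taus(self) -> tuple[float, float, float]:
        return (self.tau0, self.tau1, self.tau2)

    @property
    def starts(self) -> tuple[float, float, float]:
        return (self.t00, self.t10, self.t20)


@dataclass(frozen=True)
class OperationCase:
    """Operation case at one modeling time point: label + active species."""

    label: str
    active_set: frozenset[int]


@dataclass(frozen=True)
class TimeGrid:
    """The modeling time points and their per-species operation structure.

    Attributes
    ----------
    times
        Strictly increasing array of modeling time points, ``times[0] == 0``.
    active
        Boolean array of shape ``(n, 3)``: ``active[i, s]`` is True iff
        ``times[i]`` is an operation time point of species ``s``.
    prev_op
        Integer array of shape ``(n, 3)``: index of the latest operation time
        point of species ``s`` that is ``<= times[i]``; ``-1`` where the
        species has not yet operated (t < t_s0).  This realizes the
        "last operation time" lookback sequences of the model.
    """

    times: np.ndarray
    active: np.ndarray
    prev_op: np.ndarray
    params: ScheduleParams

    def __len__(self) -> int:
        return len(self.times)

    def active_set(self, i: int) -> frozenset[int]:
        return frozenset(int(s) for s in np.nonzero(self.active[i])[0])

    def case(self, i: int) -> OperationCase:
        return classify_case(self.active_set(i))

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: index, time, per-species activity, case label."""
        return pd.DataFrame(
            {
                "index": np.arange(len(self)),
                "time": self.times,
                "active_T0": self.active[:, 0],
                "active_T1": self.active[:, 1],
                "active_T2": self.active[:, 2],
                "case_label": [self.case(i).label for i in range(len(self))],
            }
        )


def build_grid(params: ScheduleParams) -> TimeGrid:
    """Construct the modeling time grid from the three operation sequences.

    Every operation time is generated directly as ``t_s0 + k*tau_s`` (no
    cumulative drift) and candidate times from different species are merged
    into a single grid point when they coincide within the relative merge
    tolerance.
    """
    candidates: list[tuple[float, int]] = []
    for s, (t0, tau) in enumerate(zip(params.starts, params.taus)):
        if t0 > params.horizon + _merge_tol(params.horizon):
            continue  # species never appears inside the studied interval
        kmax = int(np.floor((params.horizon - t0) / tau + 1e-12))
        ks = np.arange(kmax + 1)
        ts = t0 + ks * tau
        ts = ts[ts <= params.horizon + _merge_tol(params.horizon)]
        candidates.extend((float(t), s) for t in ts)
    if not candidates:
        raise ConfigurationError("no operation time points fall inside the horizon")
    candidates.sort(key=lambda c: c[0])

    times: list[float] = []
    active_rows: list[list[bool]] = []
    for t, s in candidates:
        if times and t - times[-1] <= _merge_tol(t):
            active_rows[-1][s] = True
        else:
            times.append(t)
            active_rows.append([False, False, False])
            active_rows[-1][s] = True

    times_arr = np.asarray(times, dtype=float)
    active_arr = np.asarray(active_rows, dtype=bool)

    n = len(times_arr)
    prev = np.full((n, 3), -1, dtype=np.int64)
    last = [-1, -1, -1]
    for i in range(n):
        for s in range(3):
            if active_arr[i, s]:
                last[s] = i
            prev[i, s] = last[s]

    times_arr.setflags(write=False)
    active_arr.setflags(write=False)
    prev.setflags(write=False)
    return TimeGrid(times=times_arr, active=active_arr, prev_op=prev, params=params)


def last_op_index(grid: TimeGrid, species: int, i: int) -> Optional[int]:
    """Index of the latest operation time point of ``species`` at or before
    ``times[i]``, or ``None`` if the species has not operated yet."""
    if not 0 <= i < len(grid):
        raise IndexError(f"time-point index {i} out of range [0, {len(grid)})")
    if species not in (0, 1, 2):
        raise ValueError(f"species must be 0, 1 or 2, got {species!r}")
    j = int(grid.prev_op[i, species])
    return None if j < 0 else j


def classify_case(active_set: Iterable[int]) -> OperationCase:
    """Map a nonempty active-species set to its operation-case label."""
    key = frozenset(int(s) for s in active_set)
    if not key:
        raise RuntimeError("empty active set: every grid point must be an operation time of some species")
    try:
        return OperationCase(label=CASE_LABELS[key], active_set=key)
    except KeyError:
        raise ValueError(f"invalid species set {sorted(key)}") from None
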