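"""Single-time-point state transition of the protocell competition model.

State layout
------------
Protocell class densities are ``(3, 2)`` arrays indexed ``[species, age]``
with species 0 = generalist T0, 1 = specialist T1, 2 = specialist T2 and age
0 = young (first cycle), 1 = old (second cycle).  Nutrient pools are ``(3,)``
arrays in the order ``(x, x1, x2)``.

Model rules
-----------
At an operation time point, a protocell must absorb one unit of every
nutrient it does not already carry from its parent:

* young T0 carries x1 and x2 from its parent, so it demands only x;
* young T1 carries x1, so it demands x and x2;
* young T2 carries x2, so it demands x and x1;
* every old protocell demands all of x, x1 and x2.

A survivor produces one offspring (pre-supplied with the species' own
product(s)) and releases one unit of each produced nutrient to the
environment at the species' *next* operation time: T0 releases x1 and x2,
T1 releases x1, T2 releases x2.  A protocell that fails to obtain its full
demand set dies; whatever it had absorbed becomes "hidden" nutrient that
re-enters the environment at the next modeling time point.

When a nutrient pool cannot satisfy total demand, the demanders share it
uniformly at random; the model computes with expected values, which makes
the share exactly proportional.  The competition operator below therefore
multiplies every class density by the product of its per-nutrient success
fractions ``f_n = min(Q_n / D_n, 1)`` — a single formula that covers every
combination of active species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .schedule import ConfigurationError, TimeGrid, _merge_tol

__all__ = [
    "NUTRIENT_NAMES",
    "YOUNG",
    "OLD",
    "DEMAND",
    "RELEASE",
    "PARENT_SUPPLY",
    "ModelParams",
    "InitialDensities",
    "PreState",
    "PostState",
    "pre_competition",
    "resolve_competition",
    "step",
]

NUTRIENT_NAMES = ("x", "x1", "x2")
YOUNG, OLD = 0, 1

#: DEMAND[s, a, n] — class (s, a) must absorb nutrient n at an operation time.
DEMAND = np.array(
    [
        [[1, 0, 0], [1, 1, 1]],  # T0: young needs x; old needs x, x1, x2
        [[1, 0, 1], [1, 1, 1]],  # T1: young needs x, x2
        [[1, 1, 0], [1, 1, 1]],  # T2: young needs x, x1
    ],
    dtype=bool,
)
DEMAND.setflags(write=False)

#: RELEASE[s, n] — a surviving protocell of species s releases one unit of n
#: to the environment (credited at the species' next operation time).
RELEASE = np.array([[0, 1, 1], [0, 1, 0], [0, 0, 1]], dtype=bool)
RELEASE.setflags(write=False)

#: Nutrients a parent packs into its offspring: identical to what it releases.
PARENT_SUPPLY = RELEASE


def _as_class_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (3, 2):
        raise ConfigurationError(f"{name} must have shape (3, 2) [species, age], got {arr.shape}")
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ConfigurationError(f"{name} must be finite and non-negative")
    arr.setflags(write=False)
    return arr


def _as_pool_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (3,):
        raise ConfigurationError(f"{name} must have shape (3,) [x, x1, x2], got {arr.shape}")
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ConfigurationError(f"{name} must be finite and non-negative")
    arr.setflags(write=False)
    return arr


@dataclass(frozen=True)
class ModelParams:
    """Environmental nutrient rates (density units per time unit).

    Positive values mean the environment produces the nutrient, negative
    values mean it decays, independently of the protocells.
    """

    b: float
    b1: float
    b2: float

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.b, self.b1, self.b2])):
            raise ConfigurationError("rates b, b1, b2 must be finite")

    @property
    def rates(self) -> np.ndarray:
        return np.array([self.b, self.b1, self.b2], dtype=float)


@dataclass(frozen=True)
class InitialDensities:
    """Initial class densities ``qt[(3, 2)]`` and nutrient pools ``pools[(3,)]``."""

    qt: np.ndarray
    pools: np.ndarray

    def __init__(self, qt, pools) -> None:
        object.__setattr__(self, "qt", _as_class_array(qt, "initial class densities"))
        object.__setattr__(self, "pools", _as_pool_array(pools, "initial nutrient pools"))


@dataclass(frozen=True)
class PreState:
    """Densities just before the competition at one modeling time point."""

    qtilde: np.ndarray  # (3, 2) class densities
    pools: np.ndarray  # (3,) environmental nutrient pools

    def __init__(self, qtilde, pools) -> None:
        object.__setattr__(self, "qtilde", _as_class_array(qtilde, "pre-competition densities"))
        object.__setattr__(self, "pools", _as_pool_array(pools, "pre-competition pools"))


@dataclass(frozen=True)
class PostState:
    """Densities just after the competition: survivors, free and hidden pools.

    ``free[n]`` is the surplus of nutrient n not absorbed by anyone;
    ``hidden[n]`` is the amount absorbed by protocells that nevertheless died,
    released back to the environment at the next modeling time point.
    """

    qt: np.ndarray  # (3, 2) surviving class densities
    free: np.ndarray  # (3,)
    hidden: np.ndarray  # (3,)

    def __init__(self, qt, free, hidden) -> None:
        object.__setattr__(self, "qt", _as_class_array(qt, "post-competition densities"))
        object.__setattr__(self, "free", _as_pool_array(free, "free pools"))
        object.__setattr__(self, "hidden", _as_pool_array(hidden, "hidden pools"))

    def species_total(self, s: int) -> float:
        return float(self.qt[s].sum())


def pre_competition(
    history: Sequence[PostState],
    grid: TimeGrid,
    i: int,
    params: ModelParams,
    inits: InitialDensities,
) -> PreState:
    """Densities just before the competition at grid index ``i``.

    ``history`` holds the post-competition states of all earlier indices
    (``history[j]`` belongs to ``grid.times[j]``; only entries at ``i - 1``
    and at each species' previous operation index are consulted).

    The update generalizes uniformly over the active set:

    * nutrient pools receive the previous point's free + hidden amounts, the
      environmental rate integrated over the elapsed time, and — for each
      species operating now and past its first operation — one unit of each
      produced nutrient per survivor of its previous operation time; negative
      totals are clamped to zero;
    * an operating species' young density is the total survivor count of its
      previous operation time (each survivor produced one offspring) and its
      old density is the surviving-young count (they aged; surviving old died
      after reproducing);
    * non-operating species are carried over unchanged, and are zero before
      their first operation time.
    """
    if not 0 <= i < len(grid):
        raise IndexError(f"time-point index {i} out of range [0, {len(grid)})")
    if len(history) < i:
        raise ValueError(f"history of length {len(history)} cannot support index {i}")

    t_i = float(grid.times[i])
    tol = _merge_tol(t_i)

    if i == 0:
        qtilde = np.zeros((3, 2))
        for s in range(3):
            if grid.active[0, s]:  # t_s0 == 0
                qtilde[s] = inits.qt[s]
        return PreState(qtilde=qtilde, pools=inits.pools.copy())

    prev = history[i - 1]
    dt = t_i - float(grid.times[i - 1])

    pools = prev.free + prev.hidden + params.rates * dt
    qtilde = np.zeros((3, 2))
    for s in range(3):
        start = grid.params.starts[s]
        if grid.active[i, s]:
            if abs(t_i - start) <= tol:  # first operation time of s
                qtilde[s] = inits.qt[s]
            else:
                j = int(grid.prev_op[i - 1, s])  # last operation strictly before t_i
                survivors = history[j].qt[s]
                qtilde[s, YOUNG] = survivors.sum()
                qtilde[s, OLD] = survivors[YOUNG]
                pools = pools + survivors.sum() * RELEASE[s]
        elif t_i < start - tol:
            pass  # species not yet present: stays zero
        else:
            qtilde[s] = prev.qt[s]

    return PreState(qtilde=qtilde, pools=np.maximum(pools, 0.0))


def resolve_competition(
    pre: PreState,
    active: Iterable[int],
    *,
    return_parental_nutrients: bool = False,
) -> PostState:
    """Resolve the competition for nutrients at one modeling time point.

    For each nutrient n, total demand ``D_n`` sums the pre-competition
    densities of the active classes requiring n, and the success fraction is
    ``f_n = min(Q_n / D_n, 1)`` (1 when nothing demands n).  A class survives
    with density ``qtilde * prod(f_n over its demand set)``; inactive classes
    pass through unchanged.  Free and hidden pools follow by bookkeeping:
    ``free = max(Q - D, 0)`` and ``hidden = min(Q, D) - consumed``.

    With ``return_parental_nutrients`` the parent-supplied units carried by
    young protocells that die are also credited to the hidden pools (strict
    mass conservation); the default follows the model's printed bookkeeping,
    which returns only environmentally absorbed units.
    """
    active_set = frozenset(int(s) for s in active)
    if not active_set:
        raise RuntimeError("empty active set passed to resolve_competition")
    if not active_set <= {0, 1, 2}:
        raise ValueError(f"invalid species in active set: {sorted(active_set)}")

    qtilde = pre.qtilde
    pools = pre.pools

    active_mask = np.zeros((3, 1), dtype=bool)
    for s in active_set:
        active_mask[s, 0] = True

    # (3, 2, 3) competitor densities broadcast over the demand table
    competing = DEMAND * (qtilde * active_mask)[:, :, None]
    total_demand = competing.sum(axis=(0, 1))  # D_n

    fractions = np.ones(3)
    nz = total_demand > 0
    with np.errstate(over="ignore"):  # pool/demand may overflow; min() fixes it
        fractions[nz] = np.minimum(pools[nz] / total_demand[nz], 1.0)

    qt = qtilde.copy()
    for s in active_set:
        for a in (YOUNG, OLD):
            qt[s, a] = qtilde[s, a] * np.prod(fractions[DEMAND[s, a]])

    consumed = ((qt * active_mask)[:, :, None] * DEMAND).sum(axis=(0, 1))
    free = np.maximum(pools - total_demand, 0.0)
    hidden = np.maximum(np.minimum(pools, total_demand) - consumed, 0.0)

    if return_parental_nutrients:
        for s in active_set:
            lost_young = qtilde[s, YOUNG] - qt[s, YOUNG]
            hidden = hidden + lost_young * PARENT_SUPPLY[s]

    return PostState(qt=qt, free=free, hidden=hidden)


def step(
    history: Sequence[PostState],
    grid: TimeGrid,
    i: int,
    params: ModelParams,
    inits: InitialDensities,
    *,
    return_parental_nutrients: bool = False,
) -> tuple[PreState, PostState]:
    """One full modeling time point: pre-competition update + competition."""
    pre = pre_competition(history, grid, i, params, inits)
    post = resolve_competition(
        pre, grid.active_set(i), return_parental_nutrients=return_parental_nutrients
    )
    return pre, post
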