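"""Generalist-only equilibrium of the model and its local stability.

When both specialists are extinct, the specialists' clocks tick at
``tau1 = tau2 = tau0 / 2`` and the nutrient pools x1, x2 grow without bound
(each surviving generalist releases one unit of both per cycle while only the
old generalists consume them).  Under the resulting abundance of x1 and x2,
composing the two per-time-point transitions of one full generalist cycle
yields an autonomous three-variable map on

    ``(X, u, v)`` = (pre-competition x pool,
                     pre-competition young density,
                     pre-competition old density)

at successive generalist operation times:

    f  = min(X / (u + v), 1)          success fraction for x (1 if u+v = 0)
    X' = max(X - (u + v), 0) + b*tau0
    u' = f * (u + v)                  every survivor leaves one offspring
    v' = f * u                        surviving young become old

Its fixed point in the scarce regime is ``(b*tau0, b*tau0, phi*b*tau0)`` with
``phi = (sqrt(5) - 1) / 2``; the corresponding post-competition survivor
densities are ``QT01* = phi * b * tau0`` and ``QT02* = (1 - phi) * b * tau0``,
so the young:old ratio is the golden ratio ``(1 + sqrt(5)) / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "PHI",
    "ContractedState",
    "EquilibriumResult",
    "contracted_map",
    "closed_form_equilibrium",
    "numerical_fixed_point",
    "survivors_at",
    "stability",
    "equilibrium_report",
]

#: The reciprocal golden ratio (sqrt(5) - 1) / 2 = 0.618...
PHI = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class ContractedState:
    """State of the time-contracted generalist cycle (pre-competition)."""

    X: float  # nutrient-x pool
    u: float  # young-generalist density
    v: float  # old-generalist density

    def __post_init__(self) -> None:
        if min(self.X, self.u, self.v) < 0 or not all(
            np.isfinite([self.X, self.u, self.v])
        ):
            raise ValueError(f"contracted state must be finite and non-negative, got {self}")

    def as_array(self) -> np.ndarray:
        return np.array([self.X, self.u, self.v], dtype=float)


@dataclass(frozen=True)
class EquilibriumResult:
    """Equilibrium values, Jacobian spectrum and stability verdict."""

    Qx_star: float
    QT01_star: float
    QT02_star: float
    eigenvalues: Optional[np.ndarray] = None
    stable: Optional[bool] = None

    def to_dict(self) -> dict:
        d = {
            "Qx_star": self.Qx_star,
            "QT01_star": self.QT01_star,
            "QT02_star": self.QT02_star,
        }
        if self.eigenvalues is not None:
            d["eigenvalue_moduli"] = sorted(abs(complex(l)) for l in self.eigenvalues)
            d["stable"] = bool(self.stable)
        return d


def _map_array(state: np.ndarray, b: float, tau0: float) -> np.ndarray:
    X, u, v = state
    total = u + v
    f = 1.0 if total == 0.0 else min(X / total, 1.0)
    y = f * u
    o = f * v
    return np.array([max(X - total, 0.0) + b * tau0, y + o, y])


def contracted_map(state: ContractedState, b: float, tau0: float = 1.0) -> ContractedState:
    """One full generalist cycle of the time-contracted model."""
    if b <= 0:
        raise ValueError(f"inflow rate b must be positive, got {b!r}")
    if tau0 <= 0:
        raise ValueError(f"tau0 must be positive, got {tau0!r}")
    X2, u2, v2 = _map_array(state.as_array(), b, tau0)
    return ContractedState(X=float(X2), u=float(u2), v=float(v2))


def closed_form_equilibrium(b: float, tau0: float = 1.0) -> EquilibriumResult:
    """Closed-form equilibrium values (no stability information).

    ``Qx_star`` is the pre-competition x pool at generalist operation times;
    ``QT01_star`` and ``QT02_star`` are the post-competition young/old
    survivor densities.  Everything scales linearly with ``b * tau0``.
    """
    if b <= 0:
        raise ValueError(f"equilibrium formula requires positive inflow b, got {b!r}")
    if tau0 <= 0:
        raise ValueError(f"tau0 must be positive, got {tau0!r}")
    scale = b * tau0
    return EquilibriumResult(
        Qx_star=scale,
        QT01_star=PHI * scale,
        QT02_star=(1.0 - PHI) * scale,
    )


def numerical_fixed_point(
    b: float,
    tau0: float = 1.0,
    initial_guess: Optional[ContractedState] = None,
    *,
    rtol: float = 1e-12,
    max_iter: int = 100_000,
) -> ContractedState:
    """Fixed point of the contracted map by direct iteration.

    Converges to ``(b*tau0, b*tau0, phi*b*tau0)`` from any start in a
    neighbourhood of the scarce regime (the map is a local contraction
    there).  Raises ``RuntimeError`` with diagnostics on non-convergence.
    """
    if b <= 0 or tau0 <= 0:
        raise ValueError("b and tau0 must be positive")
    scale = b * tau0
    if initial_guess is None:
        initial_guess = ContractedState(X=scale, u=0.75 * scale, v=0.5 * scale)
    state = initial_guess.as_array()
    for k in range(max_iter):
        nxt = _map_array(state, b, tau0)
        if np.max(np.abs(nxt - state)) <= rtol * scale:
            return ContractedState(X=float(nxt[0]), u=float(nxt[1]), v=float(nxt[2]))
        state = nxt
    raise RuntimeError(
        f"fixed-point iteration did not converge in {max_iter} iterations "
        f"(last state {state}, last step {np.max(np.abs(nxt - state)):.3e}, "
        f"tolerance {rtol * scale:.3e})"
    )


def survivors_at(state: ContractedState) -> tuple[float, float]:
    """Post-competition (young, old) survivor densities at a contracted state."""
    total = state.u + state.v
    f = 1.0 if total == 0.0 else min(state.X / total, 1.0)
    return f * state.u, f * state.v


def stability(b: float, tau0: float = 1.0) -> EquilibriumResult:
    """Jacobian eigenvalues of the contracted map at the fixed point.

    The Jacobian is differentiated numerically (central differences with a
    step scaled to ``b * tau0``).  The fixed point lies strictly inside the
    scarce branch — ``u* + v* = (1 + phi) * b * tau0 > b * tau0 = X*`` — so no
    clamp kink is crossed by the difference stencil.  The equilibrium is
    locally asymptotically stable iff every eigenvalue modulus is below 1;
    by degree-1 homogeneity of the scarce-branch map the spectrum does not
    depend on ``b``.
    """
    cf = closed_form_equilibrium(b, tau0)
    scale = b * tau0
    fp = np.array([scale, scale, PHI * scale])
    h = 1e-6 * scale
    jac = np.empty((3, 3))
    for j in range(3):
        hi, lo = fp.copy(), fp.copy()
        hi[j] += h
        lo[j] -= h
        jac[:, j] = (_map_array(hi, b, tau0) - _map_array(lo, b, tau0)) / (2 * h)
    eigenvalues = np.linalg.eigvals(jac)
    return EquilibriumResult(
        Qx_star=cf.Qx_star,
        QT01_star=cf.QT01_star,
        QT02_star=cf.QT02_star,
        eigenvalues=eigenvalues,
        stable=bool(np.max(np.abs(eigenvalues)) < 1.0),
    )


def equilibrium_report(
    b: float,
    tau0: float = 1.0,
    b1: Optional[float] = None,
    b2: Optional[float] = None,
) -> dict:
    """Full equilibrium analysis as a JSON-serializable dictionary.

    Reports the closed-form and numerically iterated fixed point, the
    Jacobian spectrum with the stability verdict, and — when the x1/x2
    environmental rates are supplied — a self-consistency check of the
    abundance assumption: at the fixed point each generalist cycle feeds
    ``QT0* + b_k * tau0`` units of nutrient k into the environment while the
    old generalists consume only ``QT02*``, so the pools grow without bound
    whenever the net balance is positive.
    """
    result = stability(b, tau0)
    fp = numerical_fixed_point(b, tau0)
    young, old = survivors_at(fp)
    report = {
        "b": b,
        "tau0": tau0,
        "closed_form": result.to_dict(),
        "numerical_fixed_point": {
            "Qx_star": fp.X,
            "pre_young": fp.u,
            "pre_old": fp.v,
            "QT01_star": young,
            "QT02_star": old,
        },
        "golden_ratio_young_to_old": young / old,
    }
    qt0_star = result.QT01_star + result.QT02_star
    for name, rate in (("x1", b1), ("x2", b2)):
        if rate is not None:
            net = qt0_star + rate * tau0 - result.QT02_star
            report[f"abundance_check_{name}"] = {
                "per_cycle_input": qt0_star + rate * tau0,
                "per_cycle_consumption": result.QT02_star,
                "net_growth": net,
                "unbounded_growth": bool(net > 0),
            }
    return report
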