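"""Run configuration: schema, validation, presets and (de)serialization.

A run configuration is a nested mapping with four blocks::

    schedule: tau0, tau1, tau2, t00, t10, t20, horizon
    model:    b, b1, b2
    init:     qt0_young, qt0_old, qt1_young, qt1_old, qt2_young, qt2_old,
              qx, qx1, qx2
    options:  epsilon, mean_mode, return_parental_nutrients

Numeric fields may be given as expression strings such as ``"pi/2"`` or
``"pi/2 * pi/4 + 0.2"``; they are evaluated to full double precision at load
time, because the grid structure depends on exact incommensurability of the
reproduction times (a decimal truncation of pi/2 would make the clocks
commensurable and change the grid).
"""

from __future__ import annotations

import ast
import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Optional

import yaml

from .dynamics import InitialDensities, ModelParams
from .schedule import ConfigurationError, ScheduleParams
from .simulator import MEAN_MODES

__all__ = [
    "RunOptions",
    "RunConfig",
    "load_config",
    "config_from_dict",
    "preset",
    "preset_names",
    "PRESETS",
]

_SCHEDULE_KEYS = {"tau0", "tau1", "tau2", "t00", "t10", "t20", "horizon"}
_SCHEDULE_DEFAULTS = {"t00": 0.0, "t10": 0.0, "t20": 0.0, "horizon": 200.0}
_MODEL_KEYS = {"b", "b1", "b2"}
_INIT_KEYS = {
    "qt0_young", "qt0_old", "qt1_young", "qt1_old", "qt2_young", "qt2_old",
    "qx", "qx1", "qx2",
}
_OPTION_KEYS = {"epsilon", "mean_mode", "return_parental_nutrients"}

_ALLOWED_NODES = (
    ast.Expression, ast.BinOp, ast.UnaryOp, ast.Constant, ast.Name,
    ast.Add, ast.Sub, ast.Mult, ast.Div, ast.Pow, ast.USub, ast.UAdd,
    ast.Call, ast.Load,
)
_EVAL_NAMES = {"pi": math.pi, "e": math.e, "sqrt": math.sqrt}


def _eval_number(value: Any, where: str) -> float:
    """Evaluate a numeric field: plain number or restricted arithmetic
    expression over +, -, *, /, **, pi, e and sqrt."""
    if isinstance(value, bool):
        raise ConfigurationError(f"{where}: expected a number, got boolean {value!r}")
    if isinstance(value, (int, float)):
        return float(value)
    if not isinstance(value, str):
        raise ConfigurationError(f"{where}: expected a number or expression string, got {value!r}")
    try:
        tree = ast.parse(value, mode="eval")
        for node in ast.walk(tree):
            if not isinstance(node, _ALLOWED_NODES):
                raise ValueError(f"disallowed syntax: {type(node).__name__}")
            if isinstance(node, ast.Name) and node.id not in _EVAL_NAMES:
                raise ValueError(f"unknown name {node.id!r}")
            if isinstance(node, ast.Call):
                if not (isinstance(node.func, ast.Name) and node.func.id == "sqrt"):
                    raise ValueError("only sqrt(...) calls are allowed")
        return float(eval(compile(tree, "<config>", "eval"), {"__builtins__": {}}, _EVAL_NAMES))
    except (SyntaxError, ValueError, TypeError, ZeroDivisionError) as exc:
        raise ConfigurationError(f"{where}: cannot evaluate {value!r} ({exc})") from None


@dataclass(frozen=True)
class RunOptions:
    """Behavioural knobs that do not belong to the model itself."""

    epsilon: float = 1e-9
    mean_mode: str = "post_pre"
    return_parental_nutrients: bool = False

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ConfigurationError(f"epsilon must be non-negative, got {self.epsilon!r}")
        if self.mean_mode not in MEAN_MODES:
            raise ConfigurationError(
                f"mean_mode must be one of {MEAN_MODES}, got {self.mean_mode!r}"
            )


@dataclass(frozen=True)
class RunConfig:
    """Validated aggregate of everything a single run needs."""

    schedule: ScheduleParams
    model: ModelParams
    init: InitialDensities
    options: RunOptions = field(default_factory=RunOptions)

    def to_dict(self) -> dict:
        s, m, i, o = self.schedule, self.model, self.init, self.options
        return {
            "schedule": {
                "tau0": s.tau0, "tau1": s.tau1, "tau2": s.tau2,
                "t00": s.t00, "t10": s.t10, "t20": s.t20, "horizon": s.horizon,
            },
            "model": {"b": m.b, "b1": m.b1, "b2": m.b2},
            "init": {
                "qt0_young": float(i.qt[0, 0]), "qt0_old": float(i.qt[0, 1]),
                "qt1_young": float(i.qt[1, 0]), "qt1_old": float(i.qt[1, 1]),
                "qt2_young": float(i.qt[2, 0]), "qt2_old": float(i.qt[2, 1]),
                "qx": float(i.pools[0]), "qx1": float(i.pools[1]), "qx2": float(i.pools[2]),
            },
            "options": {
                "epsilon": o.epsilon,
                "mean_mode": o.mean_mode,
                "return_parental_nutrients": o.return_parental_nutrients,
            },
        }


def _check_keys(block: Mapping, allowed: set, required: set, where: str, problems: list) -> None:
    unknown = set(block) - allowed
    if unknown:
        problems.append(f"{where}: unknown key(s) {sorted(unknown)}")
    missing = required - set(block)
    if missing:
        problems.append(f"{where}: missing required key(s) {sorted(missing)}")


def config_from_dict(data: Mapping[str, Any]) -> RunConfig:
    """Build a validated :class:`RunConfig`; report *all* violations at once."""
    problems: list[str] = []
    if not isinstance(data, Mapping):
        raise ConfigurationError(f"configuration must be a mapping, got {type(data).__name__}")
    unknown_blocks = set(data) - {"schedule", "model", "init", "options"}
    if unknown_blocks:
        problems.append(f"unknown block(s) {sorted(unknown_blocks)}")

    sched_block = dict(data.get("schedule") or {})
    model_block = dict(data.get("model") or {})
    init_block = dict(data.get("init") or {})
    opt_block = dict(data.get("options") or {})

    _check_keys(sched_block, _SCHEDULE_KEYS, {"tau0", "tau1", "tau2"}, "schedule", problems)
    _check_keys(model_block, _MODEL_KEYS, _MODEL_KEYS, "model", problems)
    _check_keys(init_block, _INIT_KEYS, set(), "init", problems)
    _check_keys(opt_block, _OPTION_KEYS, set(), "options", problems)
    if problems:
        raise ConfigurationError("; ".join(problems))

    def num(block, key, where, default=None):
        if key not in block:
            return default
        try:
            return _eval_number(block[key], f"{where}.{key}")
        except ConfigurationError as exc:
            problems.append(str(exc))
            return default

    sched_kwargs = {k: num(sched_block, k, "schedule", _SCHEDULE_DEFAULTS.get(k))
                    for k in _SCHEDULE_KEYS if k in sched_block or k in _SCHEDULE_DEFAULTS}
    model_kwargs = {k: num(model_block, k, "model") for k in sorted(_MODEL_KEYS & set(model_block))}
    init_vals = {k: num(init_block, k, "init", 0.0) for k in _INIT_KEYS}

    if problems:
        raise ConfigurationError("; ".join(problems))

    errors: list[str] = []
    schedule = model = init = options = None
    try:
        schedule = ScheduleParams(**sched_kwargs)
    except ConfigurationError as exc:
        errors.append(f"schedule: {exc}")
    try:
        model = ModelParams(**model_kwargs)
    except (ConfigurationError, TypeError) as exc:
        errors.append(f"model: {exc}")
    try:
        init = InitialDensities(
            qt=[[init_vals["qt0_young"], init_vals["qt0_old"]],
                [init_vals["qt1_young"], init_vals["qt1_old"]],
                [init_vals["qt2_young"], init_vals["qt2_old"]]],
            pools=[init_vals["qx"], init_vals["qx1"], init_vals["qx2"]],
        )
    except ConfigurationError as exc:
        errors.append(f"init: {exc}")
    try:
        options = RunOptions(
            epsilon=float(opt_block.get("epsilon", 1e-9)),
            mean_mode=str(opt_block.get("mean_mode", "post_pre")),
            return_parental_nutrients=bool(opt_block.get("return_parental_nutrients", False)),
        )
    except ConfigurationError as exc:
        errors.append(f"options: {exc}")
    if errors:
        raise ConfigurationError("; ".join(errors))
    return RunConfig(schedule=schedule, model=model, init=init, options=options)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        raise ConfigurationError(f"configuration file {path} is empty")
    return config_from_dict(data)


# ---------------------------------------------------------------------------
# Experiment presets: the published computer-experiment configurations.
# Reproduction times involving pi are stored as expression strings so that
# the clocks stay exactly incommensurable in double precision.
# ---------------------------------------------------------------------------

_TAU_IRRATIONAL = {"tau0": "pi/2", "tau1": "pi/2 * pi/4 + 0.2", "tau2": 1.7}
_TAU_COMMENSURABLE = {"tau0": 1.0, "tau1": 0.5, "tau2": 0.5}


def _cfg(taus, b, b1, b2, qt0, qt1, qt2, pools):
    return {
        "schedule": dict(taus, t00=0, t10=0, t20=0, horizon=200),
        "model": {"b": b, "b1": b1, "b2": b2},
        "init": {
            "qt0_young": qt0, "qt0_old": qt0,
            "qt1_young": qt1, "qt1_old": qt1,
            "qt2_young": qt2, "qt2_old": qt2,
            "qx": pools[0], "qx1": pools[1], "qx2": pools[2],
        },
    }


PRESETS: dict[str, dict] = {
    # Survival of T1 vs its own initial density (incommensurable clocks)
    "fig3_init40": _cfg(_TAU_IRRATIONAL, 20000, -1000, -1000, 100, 40, 1000, (10000, 10000, 100000)),
    "fig3_init50": _cfg(_TAU_IRRATIONAL, 20000, -1000, -1000, 100, 50, 1000, (10000, 10000, 100000)),
    "fig3_init200": _cfg(_TAU_IRRATIONAL, 20000, -1000, -1000, 100, 200, 1000, (10000, 10000, 100000)),
    # Keystone role of the generalist
    "fig4_init1000": _cfg(_TAU_IRRATIONAL, 20000, -500, -500, 1000, 1000, 1000, (10000, 10000, 100000)),
    "fig4_init100": _cfg(_TAU_IRRATIONAL, 20000, -500, -500, 100, 1000, 1000, (10000, 10000, 100000)),
    "fig4_init0": _cfg(_TAU_IRRATIONAL, 20000, -500, -500, 0, 1000, 1000, (10000, 10000, 100000)),
    # Survival of T1 vs its initial density (commensurable clocks)
    "fig5_init50": _cfg(_TAU_COMMENSURABLE, 20000, -500, -500, 100, 50, 1000, (10000, 10000, 100000)),
    "fig5_init60": _cfg(_TAU_COMMENSURABLE, 20000, -500, -500, 100, 60, 1000, (10000, 10000, 100000)),
    "fig5_init21000": _cfg(_TAU_COMMENSURABLE, 20000, -500, -500, 100, 21000, 1000, (10000, 10000, 100000)),
    # Survival anomaly of T2 vs the nutrient decay rates
    "fig6_b900": _cfg(_TAU_IRRATIONAL, 20000, -900, -900, 1000, 1000, 1000, (10000, 10000, 10000)),
    "fig6_b1000": _cfg(_TAU_IRRATIONAL, 20000, -1000, -1000, 1000, 1000, 1000, (10000, 10000, 10000)),
    "fig6_b1500": _cfg(_TAU_IRRATIONAL, 20000, -1500, -1500, 1000, 1000, 1000, (10000, 10000, 10000)),
    # Overall density controlled by the x inflow rate b
    "fig7_b10000": _cfg(_TAU_IRRATIONAL, 10000, -500, -500, 1000, 1000, 1000, (10000, 10000, 100000)),
    "fig7_b20000": _cfg(_TAU_IRRATIONAL, 20000, -500, -500, 1000, 1000, 1000, (10000, 10000, 100000)),
    "fig7_b30000": _cfg(_TAU_IRRATIONAL, 30000, -500, -500, 1000, 1000, 1000, (10000, 10000, 100000)),
    # Generalist-only equilibrium regime (same run as fig5_init50)
    "equilibrium_b20000": _cfg(_TAU_COMMENSURABLE, 20000, -500, -500, 100, 50, 1000, (10000, 10000, 100000)),
}


def preset_names() -> list[str]:
    return sorted(PRESETS)


def preset(name: str) -> RunConfig:
    """The validated configuration of a named published experiment."""
    try:
        data = PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {', '.join(preset_names())}"
        ) from None
    return config_from_dict(data)
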