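"""Named parameter fixtures, scenario configuration files, and orchestration.

Two reference parameter sets are shipped as fixtures:

* ``setA`` — weak contact rates; R0 = 0.0786 < 1, dissemination dies out
  and the system settles at the information-free equilibrium.
* ``setB`` — strong within-group contact; R0 = 208.281 > 1, the system
  converges to an interior information-existence equilibrium.

Scenario files are TOML (JSON accepted) with the model rates as top-level
keys plus ``[init]``, ``[time]``, and optional ``[sigmas]`` / ``[control]``
tables; unknown keys are rejected with their key path.
``run_full_report`` chains the other modules — reproduction number,
equilibria, threshold criteria, and optional simulations — into one
deterministic, seed-stamped report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import criteria as _criteria
from .model_core import (
    EquilibriumPoint,
    EquilibriumSolverError,
    ModelParameters,
    StateVector,
    ValidationError,
    basic_reproduction_number,
    find_endemic_equilibrium,
    information_free_equilibrium,
    simulate_ode,
)
from .optimal_control import (
    ControlProblem,
    compare_control_strategies,
    forward_backward_sweep,
)
from .stochastic_sim import NoiseIntensities, ensemble_summary

__all__ = [
    "Scenario",
    "ControlSettings",
    "RunReport",
    "ScenarioError",
    "FIXTURES",
    "set_a",
    "set_b",
    "load_scenario",
    "save_scenario",
    "run_full_report",
]

logger = logging.getLogger("crossinfo")

_PARAM_KEYS = ("B1", "B2", "mu",
               "alpha11", "alpha12", "alpha21", "alpha22",
               "beta11", "beta12", "beta21", "beta22",
               "gamma11", "gamma12", "gamma21", "gamma22")
_SIGMA_KEYS = tuple(f"sigma{i}" for i in range(1, 9))
_INIT_KEYS = ("S1", "I1", "M1", "M2", "R1", "S2", "I2", "M3", "M4", "R2")
_TIME_KEYS = ("t_end", "dt")
_CONTROL_KEYS = ("c1", "c2", "c3", "c4", "t_f", "n_grid")
_TOP_KEYS = set(_PARAM_KEYS) | {"name", "seed", "init", "time", "sigmas",
                                "control"}


class ScenarioError(ValueError):
    """A scenario file violates the schema; the message carries key paths."""


@dataclass(frozen=True)
class ControlSettings:
    """Cost weights, horizon, and grid for the optimal-control stage."""

    c1: float = 1.0
    c2: float = 1.0
    c3: float = 1.0
    c4: float = 1.0
    t_f: float = 50.0
    n_grid: int = 1001

    def to_dict(self) -> dict:
        return {"c1": self.c1, "c2": self.c2, "c3": self.c3, "c4": self.c4,
                "t_f": self.t_f, "n_grid": self.n_grid}


@dataclass(frozen=True)
class Scenario:
    """A complete, validated run configuration."""

    name: str
    params: ModelParameters
    sigmas: NoiseIntensities
    init: StateVector
    t_end: float = 1000.0
    dt: float = 0.01
    control: Optional[ControlSettings] = None
    seed: int = 1

    def __post_init__(self):
        if self.t_end <= 0 or self.dt <= 0:
            raise ScenarioError("time.t_end and time.dt must be positive")

    def control_problem(self) -> ControlProblem:
        if self.control is None:
            raise ScenarioError(f"scenario {self.name!r} has no control table")
        c = self.control
        return ControlProblem(
            params=self.params, c1=c.c1, c2=c.c2, c3=c.c3, c4=c.c4,
            t_f=c.t_f, n_grid=c.n_grid, sigmas=self.sigmas,
            init=(self.init.S1, self.init.S2, self.init.I1, self.init.I2))

    def to_dict(self) -> dict:
        d: dict = {"name": self.name, "seed": self.seed}
        d.update(self.params.to_dict())
        d["sigmas"] = self.sigmas.to_dict()
        d["init"] = self.init.to_dict()
        d["time"] = {"t_end": self.t_end, "dt": self.dt}
        if self.control is not None:
            d["control"] = self.control.to_dict()
        return d

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _default_init() -> StateVector:
    # the reference runs start every compartment at 0.5 except the
    # susceptibles at 10; every report records the initial state used
    return StateVector(S1=10.0, I1=0.5, M1=0.5, M2=0.5, R1=0.5,
                       S2=10.0, I2=0.5, M3=0.5, M4=0.5, R2=0.5)


def set_a() -> Scenario:
    """Sub-threshold fixture: R0 = 0.0786 < 1."""
    params = ModelParameters(
        B1=1.0, B2=1.0, mu=0.1,
        alpha11=0.003, alpha12=0.002, alpha21=0.003, alpha22=0.005,
        beta11=0.002, beta12=0.004, beta21=0.005, beta22=0.003,
        gamma11=0.002, gamma12=0.003, gamma21=0.005, gamma22=0.003)
    return Scenario(name="setA", params=params,
                    sigmas=NoiseIntensities.uniform(1e-4),
                    init=_default_init())


def set_b() -> Scenario:
    """Super-threshold fixture: R0 = 208.281 > 1, interior equilibrium."""
    params = ModelParameters(
        B1=1.0, B2=1.0, mu=0.1,
        alpha11=0.2, alpha12=0.003, alpha21=0.005, alpha22=0.3,
        beta11=0.02, beta12=0.04, beta21=0.05, beta22=0.03,
        gamma11=0.02, gamma12=0.03, gamma21=0.05, gamma22=0.03)
    return Scenario(name="setB", params=params,
                    sigmas=NoiseIntensities.uniform(1e-4),
                    init=_default_init(),
                    control=ControlSettings())


FIXTURES = {"setA": set_a, "setB": set_b}


def _require_number(d: dict, key: str, path: str) -> float:
    if key not in d:
        raise ScenarioError(f"missing key {path}{key}")
    v = d[key]
    if isinstance(v, bool) or not isinstance(v, (int, float)):
        raise ScenarioError(f"{path}{key} must be a number, got {v!r}")
    return float(v)


def _check_unknown(d: dict, allowed, path: str) -> None:
    unknown = set(d) - set(allowed)
    if unknown:
        names = ", ".join(sorted(f"{path}{k}" for k in unknown))
        raise ScenarioError(f"unknown keys: {names}")


def _scenario_from_dict(raw: dict, name_hint: str) -> Scenario:
    _check_unknown(raw, _TOP_KEYS, "")
    try:
        params = ModelParameters(
            **{k: _require_number(raw, k, "") for k in _PARAM_KEYS})
        init_raw = raw.get("init")
        if init_raw is None:
            init = _default_init()
        else:
            _check_unknown(init_raw, _INIT_KEYS, "init.")
            init = StateVector(
                **{k: _require_number(init_raw, k, "init.")
                   for k in _INIT_KEYS})
        time_raw = raw.get("time", {})
        _check_unknown(time_raw, _TIME_KEYS, "time.")
        t_end = float(time_raw.get("t_end", 1000.0))
        dt = float(time_raw.get("dt", 0.01))
        sigmas_raw = raw.get("sigmas", {})
        _check_unknown(sigmas_raw, _SIGMA_KEYS, "sigmas.")
        sigmas = NoiseIntensities(**{k: float(sigmas_raw.get(k, 0.0))
                                     for k in _SIGMA_KEYS})
    except ValidationError as exc:
        raise ScenarioError(str(exc)) from exc
    control = None
    if "control" in raw:
        ctl = raw["control"]
        _check_unknown(ctl, _CONTROL_KEYS, "control.")
        control = ControlSettings(
            c1=float(ctl.get("c1", 1.0)), c2=float(ctl.get("c2", 1.0)),
            c3=float(ctl.get("c3", 1.0)), c4=float(ctl.get("c4", 1.0)),
            t_f=float(ctl.get("t_f", 50.0)),
            n_grid=int(ctl.get("n_grid", 1001)))
    try:
        return Scenario(name=str(raw.get("name", name_hint)), params=params,
                        sigmas=sigmas, init=init, t_end=t_end, dt=dt,
                        control=control, seed=int(raw.get("seed", 1)))
    except ValidationError as exc:
        raise ScenarioError(str(exc)) from exc


def load_scenario(source) -> Scenario:
    """Load a scenario from a fixture name or a TOML/JSON file path."""
    if isinstance(source, str) and source in FIXTURES:
        return FIXTURES[source]()
    path = Path(source)
    if not path.exists():
        raise ScenarioError(
            f"{source!r} is neither a known fixture "
            f"({', '.join(sorted(FIXTURES))}) nor an existing file")
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text())
    else:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    if not isinstance(raw, dict):
        raise ScenarioError("scenario file must hold a table/object at top level")
    return _scenario_from_dict(raw, name_hint=path.stem)


def _toml_value(v) -> str:
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, int):
        return str(v)
    return repr(float(v))


def save_scenario(scenario: Scenario, path) -> None:
    """Write a scenario to TOML or JSON (chosen by file suffix), losslessly."""
    path = Path(path)
    d = scenario.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=2) + "\n")
        return
    lines = [f"name = {_toml_value(d['name'])}", f"seed = {d['seed']}"]
    lines += [f"{k} = {_toml_value(d[k])}" for k in _PARAM_KEYS]
    for table in ("sigmas", "init", "time", "control"):
        if table in d:
            lines.append(f"\n[{table}]")
            lines += [f"{k} = {_toml_value(v)}" for k, v in d[table].items()]
    path.write_text("\n".join(lines) + "\n")


@dataclass
class RunReport:
    """Aggregated output of one scenario run; every number is traceable to
    exactly one operation of the underlying modules."""

    scenario_name: str
    scenario_hash: str
    seed: int
    R0: float
    information_free: EquilibriumPoint
    endemic: Optional[EquilibriumPoint]
    extinction: Optional[_criteria.ExtinctionReport]
    stationary: Optional[_criteria.StationaryReport]
    ode_final_state: Optional[dict]
    sde_summary: Optional[dict]
    control_comparison: Optional[dict]
    initial_state: dict
    errors: dict = field(default_factory=dict)
    version: str = ""

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario_name,
            "scenario_hash": self.scenario_hash,
            "seed": self.seed,
            "version": self.version,
            "R0": self.R0,
            "information_free": self.information_free.to_dict(),
            "endemic": self.endemic.to_dict() if self.endemic else None,
            "extinction": self.extinction.to_dict() if self.extinction else None,
            "stationary": self.stationary.to_dict() if self.stationary else None,
            "ode_final_state": self.ode_final_state,
            "sde_summary": self.sde_summary,
            "control_comparison": self.control_comparison,
            "initial_state": self.initial_state,
            "errors": self.errors,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def run_full_report(
    scenario: Scenario,
    *,
    run_ode: bool = True,
    run_sde: bool = False,
    run_control: bool = False,
    n_reps: int = 100,
    seed: Optional[int] = None,
) -> RunReport:
    """Compute reproduction number, equilibria, criteria, and optional
    simulations for one scenario.

    Stage failures are caught and recorded in ``errors`` under the stage
    name; the partial report is still returned.  Given identical seeds the
    report is deterministic.
    """
    from . import __version__

    seed = scenario.seed if seed is None else seed
    p = scenario.params
    r0 = basic_reproduction_number(p)
    e0 = information_free_equilibrium(p)
    errors: dict = {}
    logger.info("report stage=r0 scenario=%s hash=%s R0=%.6g",
                scenario.name, scenario.content_hash(), r0)

    endemic = None
    if r0 > 1:
        try:
            endemic = find_endemic_equilibrium(p)
        except EquilibriumSolverError as exc:
            errors["endemic"] = str(exc)

    extinction = None
    try:
        extinction = _criteria.extinction_thresholds(p, scenario.sigmas)
    except Exception as exc:  # pragma: no cover - defensive
        errors["extinction"] = str(exc)

    stationary = None
    if endemic is not None and not endemic.boundary:
        try:
            stationary = _criteria.stationary_condition(p, scenario.sigmas,
                                                        endemic)
        except ValidationError as exc:
            errors["stationary"] = str(exc)

    ode_final = None
    if run_ode:
        try:
            traj = simulate_ode(p, scenario.init, scenario.t_end, scenario.dt,
                                record_every=10_000)
            ode_final = dict(zip(
                ("S1", "I1", "M1", "M2", "R1", "S2", "I2", "M3", "M4", "R2"),
                map(float, traj.final_state)))
            logger.info("report stage=ode scenario=%s t_end=%g",
                        scenario.name, scenario.t_end)
        except Exception as exc:
            errors["ode"] = str(exc)

    sde_summary = None
    if run_sde:
        try:
            summ = ensemble_summary(p, scenario.sigmas, scenario.init,
                                    scenario.t_end, scenario.dt,
                                    n_reps=n_reps, base_seed=seed)
            sde_summary = summ.to_dict()
            logger.info("report stage=sde scenario=%s n_reps=%d base_seed=%d",
                        scenario.name, n_reps, seed)
        except Exception as exc:
            errors["sde"] = str(exc)

    control_cmp = None
    if run_control:
        try:
            problem = scenario.control_problem()
            solution = forward_backward_sweep(problem)
            cmp_report = compare_control_strategies(problem, solution,
                                                    n_reps=n_reps,
                                                    base_seed=seed)
            control_cmp = {"solution": solution.to_dict(),
                           "comparison": cmp_report.to_dict()}
            logger.info("report stage=control scenario=%s converged=%s J=%.6g",
                        scenario.name, solution.converged, solution.objective)
        except Exception as exc:
            errors["control"] = str(exc)

    return RunReport(
        scenario_name=scenario.name,
        scenario_hash=scenario.content_hash(),
        seed=seed,
        R0=r0,
        information_free=e0,
        endemic=endemic,
        extinction=extinction,
        stationary=stationary,
        ode_final_state=ode_final,
        sde_summary=sde_summary,
        control_comparison=control_cmp,
        initial_state=scenario.init.to_dict(),
        errors=errors,
        version=__version__,
    )
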