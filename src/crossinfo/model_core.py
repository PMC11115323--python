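"""Deterministic core of the two-group cross-dissemination model.

The population of an open virtual community is split into ten compartments:
two susceptible ("easy-to-adopt") classes S1, S2, two disseminator classes
I1, I2 (one per piece of information), four mutant/variation classes
M1, M2, M3, M4 (strong believers and information-fusion groups), and two
removed/escaping classes R1, R2.  Susceptibles of each group contact
disseminators of their own information at rates alpha11, alpha22 and of the
other information at the cross rates alpha12, alpha21; disseminators mutate
at rates beta, mutants are removed at rates gamma, and everyone leaves the
system at the per-capita rate mu while B1, B2 individuals per unit time
enter.

This module holds the parameter/state data model, the deterministic vector
field, a classical fourth-order Runge-Kutta integrator, the closed-form
basic reproduction number, and both equilibria (information-free and
information-existence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "STATE_FIELDS",
    "ModelParameters",
    "StateVector",
    "Trajectory",
    "EquilibriumPoint",
    "ValidationError",
    "IntegrationError",
    "EquilibriumSolverError",
    "deterministic_rhs",
    "basic_reproduction_number",
    "information_free_equilibrium",
    "find_endemic_equilibrium",
    "simulate_ode",
]

#: Canonical compartment ordering used by every array-valued interface.
STATE_FIELDS = ("S1", "I1", "M1", "M2", "R1", "S2", "I2", "M3", "M4", "R2")

#: Tolerance below which a slightly negative density is treated as zero
#: (Runge-Kutta undershoot); anything more negative is a hard error.
NEGATIVITY_TOL = 1e-9


class ValidationError(ValueError):
    """Invalid parameters, state, or mismatched inputs."""


class IntegrationError(RuntimeError):
    """Deterministic integration produced a non-finite or negative state."""

    def __init__(self, message: str, time: float | None = None):
        super().__init__(message)
        self.time = time


class EquilibriumSolverError(RuntimeError):
    """Root finding for the endemic equilibrium failed to converge."""

    def __init__(self, message: str, last_iterate: np.ndarray | None = None):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass(frozen=True)
class ModelParameters:
    """All deterministic rates of the ten-compartment system.

    Parameters
    ----------
    B1, B2 : float
        Inflow of new individuals per unit time into group 1 / group 2.
    mu : float
        Per-capita rate of leaving the system (1/time).
    alpha11, alpha12 : float
        Contact rates of group-1 susceptibles with disseminators of
        information 1 and information 2 (cross contact), each in (0, 1].
    alpha21, alpha22 : float
        Contact rates of group-2 susceptibles with disseminators of
        information 1 (cross contact) and information 2, each in (0, 1].
    beta11, beta12 : float
        Mutation rates I1 -> M1 (strong belief) and I1 -> M2 (fusion).
    beta21, beta22 : float
        Mutation rates I2 -> M3 (fusion) and I2 -> M4 (strong belief).
    gamma11, gamma12, gamma21, gamma22 : float
        Removal rates M1 -> R1, M2 -> R1, M3 -> R2, M4 -> R2.
    """

    B1: float
    B2: float
    mu: float
    alpha11: float
    alpha12: float
    alpha21: float
    alpha22: float
    beta11: float
    beta12: float
    beta21: float
    beta22: float
    gamma11: float
    gamma12: float
    gamma21: float
    gamma22: float

    def __post_init__(self):
        for name in ("B1", "B2", "mu", "gamma11", "gamma12", "gamma21", "gamma22"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be positive and finite, got {v!r}")
        for name in ("alpha11", "alpha12", "alpha21", "alpha22",
                     "beta11", "beta12", "beta21", "beta22"):
            v = getattr(self, name)
            if not (np.isfinite(v) and 0 < v <= 1):
                raise ValidationError(f"{name} must lie in (0, 1], got {v!r}")

    @property
    def k1(self) -> float:
        """Total exit rate from I1: beta11 + beta12 + mu."""
        return self.beta11 + self.beta12 + self.mu

    @property
    def k2(self) -> float:
        """Total exit rate from I2: beta21 + beta22 + mu."""
        return self.beta21 + self.beta22 + self.mu

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(**d)


@dataclass(frozen=True)
class StateVector:
    """Densities of the ten compartments; all nonnegative."""

    S1: float
    I1: float
    M1: float
    M2: float
    R1: float
    S2: float
    I2: float
    M3: float
    M4: float
    R2: float

    def __post_init__(self):
        for name in STATE_FIELDS:
            v = getattr(self, name)
            if not np.isfinite(v) or v < -NEGATIVITY_TOL:
                raise ValidationError(f"compartment {name} must be >= 0, got {v!r}")

    @property
    def N(self) -> float:
        """Total population: exact sum of the ten compartments."""
        return float(sum(getattr(self, name) for name in STATE_FIELDS))

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in STATE_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "StateVector":
        y = np.asarray(y, dtype=float)
        if y.shape != (10,):
            raise ValidationError(f"state array must have shape (10,), got {y.shape}")
        return cls(**dict(zip(STATE_FIELDS, map(float, y))))

    def to_dict(self) -> dict:
        return {name: getattr(self, name) for name in STATE_FIELDS}

    @classmethod
    def from_dict(cls, d: dict) -> "StateVector":
        return cls(**d)


@dataclass
class Trajectory:
    """States on a strictly increasing time grid plus provenance metadata."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), 10), columns in STATE_FIELDS order
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be a strictly increasing 1-d grid")
        if self.states.shape != (self.times.size, 10):
            raise ValidationError(
                f"states shape {self.states.shape} does not match grid of "
                f"{self.times.size} points")

    def __len__(self) -> int:
        return self.times.size

    def column(self, name: str) -> np.ndarray:
        return self.states[:, STATE_FIELDS.index(name)]

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_FIELDS))
        df.insert(0, "t", self.times)
        return df

    def to_csv(self, path) -> None:
        """Write ``t,S1,I1,M1,M2,R1,S2,I2,M3,M4,R2`` at full float precision."""
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, metadata: dict | None = None) -> "Trajectory":
        df = pd.read_csv(path)
        return cls(df["t"].to_numpy(), df[list(STATE_FIELDS)].to_numpy(),
                   metadata or {})


@dataclass
class EquilibriumPoint:
    """A fixed point of the deterministic system.

    ``boundary`` marks convergence to the information-free manifold
    (I1 or I2 numerically zero) rather than an interior point.
    """

    S1: float
    I1: float
    M1: float
    M2: float
    R1: float
    S2: float
    I2: float
    M3: float
    M4: float
    R2: float
    residual_norm: float = 0.0
    boundary: bool = False

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in STATE_FIELDS], dtype=float)

    @property
    def core(self) -> tuple[float, float, float, float]:
        """The transmission-active block (S1*, S2*, I1*, I2*)."""
        return (self.S1, self.S2, self.I1, self.I2)

    def to_dict(self) -> dict:
        d = {name: getattr(self, name) for name in STATE_FIELDS}
        d["residual_norm"] = self.residual_norm
        d["boundary"] = self.boundary
        return d


def _as_state_array(state) -> np.ndarray:
    if isinstance(state, StateVector):
        return state.to_array()
    if isinstance(state, EquilibriumPoint):
        return state.to_array()
    y = np.asarray(state, dtype=float)
    if y.shape[-1] != 10:
        raise ValidationError(f"state must have 10 components, got shape {y.shape}")
    return y


def deterministic_rhs(state, params: ModelParameters) -> np.ndarray:
    """Time derivatives of the ten compartments.

    Accepts a :class:`StateVector` or an array whose last axis has length 10
    (vectorised over leading axes).  The component sum is always
    ``B1 + B2 - mu * N``: every contact, mutation, and removal term moves
    mass between compartments and cancels pairwise.
    """
    y = _as_state_array(state)
    if np.any(~np.isfinite(y)) or np.any(y < -NEGATIVITY_TOL):
        raise ValidationError("state contains negative or non-finite components")
    return _rhs_array(y, params)


def _rhs_array(y: np.ndarray, p: ModelParameters) -> np.ndarray:
    """Unchecked vectorised vector field; last axis is the compartment axis."""
    S1, I1, M1, M2, R1 = y[..., 0], y[..., 1], y[..., 2], y[..., 3], y[..., 4]
    S2, I2, M3, M4, R2 = y[..., 5], y[..., 6], y[..., 7], y[..., 8], y[..., 9]
    c11 = p.alpha11 * S1 * I1
    c12 = p.alpha12 * S1 * I2
    c21 = p.alpha21 * S2 * I1
    c22 = p.alpha22 * S2 * I2
    out = np.empty_like(y)
    out[..., 0] = p.B1 - c11 - c12 - p.mu * S1
    out[..., 1] = c11 + c12 - p.k1 * I1
    out[..., 2] = p.beta11 * I1 - (p.gamma11 + p.mu) * M1
    out[..., 3] = p.beta12 * I1 - (p.gamma12 + p.mu) * M2
    out[..., 4] = p.gamma11 * M1 + p.gamma12 * M2 - p.mu * R1
    out[..., 5] = p.B2 - c21 - c22 - p.mu * S2
    out[..., 6] = c21 + c22 - p.k2 * I2
    out[..., 7] = p.beta21 * I2 - (p.gamma21 + p.mu) * M3
    out[..., 8] = p.beta22 * I2 - (p.gamma22 + p.mu) * M4
    out[..., 9] = p.gamma21 * M3 + p.gamma22 * M4 - p.mu * R2
    return out


def basic_reproduction_number(params: ModelParameters) -> float:
    """Closed-form basic reproduction number R0.

    R0 = B1*B2*(alpha11*alpha22 - alpha12*alpha21)
         / (mu^2 * (beta11+beta12+mu) * (beta21+beta22+mu)).

    The value is returned signed: it is negative exactly when the cross
    contact product alpha12*alpha21 exceeds the within-group product
    alpha11*alpha22.  R0 < 1 predicts decay of dissemination; R0 > 1
    persistence.
    """
    p = params
    num = p.B1 * p.B2 * (p.alpha11 * p.alpha22 - p.alpha12 * p.alpha21)
    return num / (p.mu ** 2 * p.k1 * p.k2)


def information_free_equilibrium(params: ModelParameters) -> EquilibriumPoint:
    """The dissemination-free fixed point: S1 = B1/mu, S2 = B2/mu, rest 0."""
    return EquilibriumPoint(
        S1=params.B1 / params.mu, I1=0.0, M1=0.0, M2=0.0, R1=0.0,
        S2=params.B2 / params.mu, I2=0.0, M3=0.0, M4=0.0, R2=0.0,
        residual_norm=0.0, boundary=True)


def _induced_tail(params: ModelParameters, I1: float, I2: float):
    """Mutant and removed equilibrium values induced by (I1*, I2*)."""
    p = params
    M1 = p.beta11 * I1 / (p.gamma11 + p.mu)
    M2 = p.beta12 * I1 / (p.gamma12 + p.mu)
    M3 = p.beta21 * I2 / (p.gamma21 + p.mu)
    M4 = p.beta22 * I2 / (p.gamma22 + p.mu)
    R1 = (p.gamma11 * M1 + p.gamma12 * M2) / p.mu
    R2 = (p.gamma21 * M3 + p.gamma22 * M4) / p.mu
    return M1, M2, M3, M4, R1, R2


def _core_residual(x: np.ndarray, p: ModelParameters) -> np.ndarray:
    """Residual of the (S1, I1, S2, I2) subsystem at a candidate point."""
    S1, I1, S2, I2 = x
    f1 = p.B1 - p.alpha11 * S1 * I1 - p.alpha12 * S1 * I2 - p.mu * S1
    f2 = p.alpha11 * S1 * I1 + p.alpha12 * S1 * I2 - p.k1 * I1
    f3 = p.B2 - p.alpha21 * S2 * I1 - p.alpha22 * S2 * I2 - p.mu * S2
    f4 = p.alpha21 * S2 * I1 + p.alpha22 * S2 * I2 - p.k2 * I2
    return np.array([f1, f2, f3, f4])


def default_initial_state() -> StateVector:
    """Generic positive start: susceptibles at 10, everything else at 0.5."""
    return StateVector(S1=10.0, I1=0.5, M1=0.5, M2=0.5, R1=0.5,
                       S2=10.0, I2=0.5, M3=0.5, M4=0.5, R2=0.5)


def find_endemic_equilibrium(
    params: ModelParameters,
    tolerance: float = 1e-9,
    initial_guess: Optional[Sequence[float]] = None,
    boundary_tol: float = 1e-6,
) -> EquilibriumPoint:
    """Locate the information-existence equilibrium E*.

    The four-dimensional algebraic system for (S1, I1, S2, I2) (the full
    vector field with the mutant and removed compartments eliminated) is
    solved with a hybrid Powell root finder; the remaining compartments
    follow exactly as M* = beta I*/(gamma+mu) and R* = gamma M*/mu.

    Parameters
    ----------
    tolerance : float
        Maximum absolute residual of the full ten-component vector field
        accepted at the returned point.
    initial_guess : sequence of 4 floats, optional
        (S1, I1, S2, I2) starting point.  Default: the state reached by
        integrating the deterministic system from a generic positive start
        to t = 500 — robust and self-validating.
    boundary_tol : float
        I* below this value flags the result as a boundary (information-free)
        equilibrium.

    Raises
    ------
    EquilibriumSolverError
        If the root finder does not converge to the requested residual;
        the exception carries the last iterate.
    """
    if initial_guess is None:
        traj = simulate_ode(params, default_initial_state(), t_end=500.0, dt=0.05,
                            record_every=10_000)
        y = traj.final_state
        x0 = np.array([y[0], y[1], y[5], y[6]])
    else:
        x0 = np.asarray(initial_guess, dtype=float)
        if x0.shape != (4,):
            raise ValidationError("initial_guess must be (S1, I1, S2, I2)")

    sol = optimize.root(_core_residual, x0, args=(params,), method="hybr",
                        tol=1e-13)
    x = sol.x
    # tiny negative roundoff on a boundary root is clamped before assembly
    x = np.where(np.abs(x) < boundary_tol, np.maximum(x, 0.0), x)
    if np.any(x < 0):
        raise EquilibriumSolverError(
            f"root finder converged to a negative point {x}", last_iterate=sol.x)
    S1, I1, S2, I2 = x
    M1, M2, M3, M4, R1, R2 = _induced_tail(params, I1, I2)
    point = np.array([S1, I1, M1, M2, R1, S2, I2, M3, M4, R2])
    residual = float(np.max(np.abs(_rhs_array(point, params))))
    if not sol.success or residual > tolerance:
        raise EquilibriumSolverError(
            f"equilibrium solver failed (residual {residual:.3e}): {sol.message}",
            last_iterate=sol.x)
    boundary = bool(I1 < boundary_tol or I2 < boundary_tol)
    return EquilibriumPoint(S1=S1, I1=I1, M1=M1, M2=M2, R1=R1,
                            S2=S2, I2=I2, M3=M3, M4=M4, R2=R2,
                            residual_norm=residual, boundary=boundary)


def rk4_step(y: np.ndarray, dt: float, params: ModelParameters) -> np.ndarray:
    """One classical fourth-order Runge-Kutta step (vectorised)."""
    k1 = _rhs_array(y, params)
    k2 = _rhs_array(y + 0.5 * dt * k1, params)
    k3 = _rhs_array(y + 0.5 * dt * k2, params)
    k4 = _rhs_array(y + dt * k3, params)
    return y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def simulate_ode(
    params: ModelParameters,
    init: StateVector | Sequence[float],
    t_end: float,
    dt: float = 0.01,
    record_every: int = 1,
) -> Trajectory:
    """Integrate the deterministic system with classical RK4 on a fixed grid.

    Parameters
    ----------
    record_every : int
        Keep every ``record_every``-th grid point (the initial and final
        states are always kept).

    Notes
    -----
    The continuous system preserves positivity, so the integrator does not
    clamp: a state component dipping below ``-1e-9`` (or going non-finite)
    raises :class:`IntegrationError` with the offending time instead of
    being silently repaired.
    """
    if dt <= 0 or t_end <= 0:
        raise ValidationError("dt and t_end must be positive")
    y = _as_state_array(init).astype(float).copy()
    if np.any(y < -NEGATIVITY_TOL):
        raise ValidationError("initial state must be nonnegative")
    n_steps = int(round(t_end / dt))
    rec_idx = list(range(0, n_steps + 1, record_every))
    if rec_idx[-1] != n_steps:
        rec_idx.append(n_steps)
    times = np.array([i * dt for i in rec_idx])
    states = np.empty((len(rec_idx), 10))
    states[0] = y
    pos = 1
    for i in range(1, n_steps + 1):
        with np.errstate(over="ignore", invalid="ignore"):
            y = rk4_step(y, dt, params)
        if not np.all(np.isfinite(y)):
            raise IntegrationError(f"non-finite state at t={i * dt:g}", time=i * dt)
        if np.any(y < -NEGATIVITY_TOL):
            raise IntegrationError(
                f"negative state at t={i * dt:g}: min={y.min():.3e}", time=i * dt)
        if pos < len(rec_idx) and i == rec_idx[pos]:
            states[pos] = y
            pos += 1
    return Trajectory(times, states, metadata={
        "scheme": "rk4", "dt": dt, "t_end": t_end,
        "params": params.to_dict()})
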