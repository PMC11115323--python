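"""Optimal control of the contact rates by a forward-backward sweep.

The four contact rates become time-dependent controls
alpha11(t), alpha12(t), alpha21(t), alpha22(t) in [0, 1], chosen to
maximise cumulative dissemination net of quadratic effort,

    J = int_0^tf [ I1 + I2 - c1/2 a11^2 - c2/2 a12^2
                              - c3/2 a21^2 - c4/2 a22^2 ] dt,

subject to the four-compartment state system in (S1, S2, I1, I2) (the
mutant and removed classes do not feed back on transmission and are
excluded).  Pontryagin's principle yields adjoint variables
delta1..delta4 with zero terminal values and the projected control law

    a11* = clip((delta1 - delta3) S1 I1 / c1, 0, 1)    (and symmetrically),

which the forward-backward sweep iterates to a fixed point: forward RK4
state integration with the current controls, backward RK4 adjoint
integration from delta(tf) = 0, projected control update with convex
relaxation.

The adjoint system of the stochastic problem is a backward SDE whose
second (diffusion-adjoint) components are unspecified; this module uses
the standard certainty-equivalence treatment — diffusion adjoints
identically zero and deterministic backward integration along the forward
path.  The forward path in the sweep is deterministic by default; the
resulting control paths can then be evaluated on the stochastic state
system via :func:`compare_control_strategies`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model_core import ModelParameters, ValidationError
from .stochastic_sim import NoiseIntensities, _damping_factor

__all__ = [
    "ControlProblem",
    "ControlSolution",
    "ControlComparison",
    "CONTROL_NAMES",
    "evaluate_objective",
    "adjoint_rhs",
    "control_update",
    "forward_states",
    "backward_adjoints",
    "forward_backward_sweep",
    "best_constant_control",
    "compare_control_strategies",
]

#: Control ordering used by every (n, 4) control array.
CONTROL_NAMES = ("alpha11", "alpha12", "alpha21", "alpha22")

#: State ordering of the reduced control system.
CONTROL_STATE = ("S1", "S2", "I1", "I2")


@dataclass(frozen=True)
class ControlProblem:
    """The control problem: dynamics, cost weights, horizon, and grid.

    ``init`` is (S1, S2, I1, I2) at t = 0; ``n_grid`` is the number of grid
    points on [0, t_f] (so the step is t_f / (n_grid - 1)).  ``sigmas``
    enters only the stochastic evaluation of a solution, never the sweep.
    """

    params: ModelParameters
    c1: float
    c2: float
    c3: float
    c4: float
    t_f: float
    init: tuple[float, float, float, float]
    n_grid: int = 1001
    sigmas: NoiseIntensities = field(default_factory=NoiseIntensities)

    def __post_init__(self):
        for name in ("c1", "c2", "c3", "c4"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        if not self.t_f > 0:
            raise ValidationError("t_f must be positive")
        if self.n_grid < 2:
            raise ValidationError("n_grid must be at least 2")
        if len(self.init) != 4 or any(v < 0 for v in self.init):
            raise ValidationError("init must be four nonnegative values")

    @property
    def weights(self) -> np.ndarray:
        return np.array([self.c1, self.c2, self.c3, self.c4])

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(0.0, self.t_f, self.n_grid)

    @property
    def baseline_controls(self) -> np.ndarray:
        """Constant controls at the uncontrolled parameter values."""
        p = self.params
        u = np.array([p.alpha11, p.alpha12, p.alpha21, p.alpha22])
        return np.tile(u, (self.n_grid, 1))


@dataclass
class ControlSolution:
    """Output of the forward-backward sweep."""

    grid: np.ndarray
    controls: np.ndarray   # (n, 4) in CONTROL_NAMES order, each in [0, 1]
    states: np.ndarray     # (n, 4) in CONTROL_STATE order
    adjoints: np.ndarray   # (n, 4), adjoints[-1] == 0
    objective: float
    iterations: int
    converged: bool
    final_change: float

    def to_dict(self) -> dict:
        return {"grid": self.grid.tolist(),
                "controls": {name: self.controls[:, i].tolist()
                             for i, name in enumerate(CONTROL_NAMES)},
                "states": {name: self.states[:, i].tolist()
                           for i, name in enumerate(CONTROL_STATE)},
                "adjoints": {f"delta{i+1}": self.adjoints[:, i].tolist()
                             for i in range(4)},
                "objective": self.objective,
                "iterations": self.iterations,
                "converged": self.converged,
                "final_change": self.final_change}


def _state_rhs(x: np.ndarray, u: np.ndarray, p: ModelParameters) -> np.ndarray:
    """Controlled state dynamics; x, u broadcast over leading axes."""
    S1, S2, I1, I2 = x[..., 0], x[..., 1], x[..., 2], x[..., 3]
    a11, a12, a21, a22 = u[..., 0], u[..., 1], u[..., 2], u[..., 3]
    f1 = a11 * S1 * I1 + a12 * S1 * I2
    f2 = a21 * S2 * I1 + a22 * S2 * I2
    out = np.empty_like(x)
    out[..., 0] = p.B1 - f1 - p.mu * S1
    out[..., 1] = p.B2 - f2 - p.mu * S2
    out[..., 2] = f1 - p.k1 * I1
    out[..., 3] = f2 - p.k2 * I2
    return out


def adjoint_rhs(state, adjoint, controls_at_t, params: ModelParameters,
                sigmas: Optional[NoiseIntensities] = None) -> np.ndarray:
    """Drift of the adjoint system with zero diffusion adjoints.

    d delta1/dt = (delta1-delta3)(a11 I1 + a12 I2) + delta1 mu
    d delta2/dt = (delta2-delta4)(a21 I1 + a22 I2) + delta2 mu
    d delta3/dt = 1 + (delta1-delta3) a11 S1 + (delta2-delta4) a21 S2
                    + delta3 (beta11+beta12+mu)
    d delta4/dt = 1 + (delta1-delta3) a12 S1 + (delta2-delta4) a22 S2
                    + delta4 (beta21+beta22+mu)

    ``sigmas`` is accepted for signature compatibility; under the
    certainty-equivalence treatment the noise intensities do not enter.
    """
    x = np.asarray(state, dtype=float)
    d = np.asarray(adjoint, dtype=float)
    u = np.asarray(controls_at_t, dtype=float)
    S1, S2, I1, I2 = x[..., 0], x[..., 1], x[..., 2], x[..., 3]
    d1, d2, d3, d4 = d[..., 0], d[..., 1], d[..., 2], d[..., 3]
    a11, a12, a21, a22 = u[..., 0], u[..., 1], u[..., 2], u[..., 3]
    g1 = d1 - d3
    g2 = d2 - d4
    out = np.empty_like(d)
    out[..., 0] = g1 * (a11 * I1 + a12 * I2) + d1 * params.mu
    out[..., 1] = g2 * (a21 * I1 + a22 * I2) + d2 * params.mu
    out[..., 2] = 1.0 + g1 * a11 * S1 + g2 * a21 * S2 + d3 * params.k1
    out[..., 3] = 1.0 + g1 * a12 * S1 + g2 * a22 * S2 + d4 * params.k2
    return out


def control_update(state, adjoint, weights) -> np.ndarray:
    """Projected control law: elementwise in [0, 1].

    a11 = clip((d1-d3) S1 I1 / c1), a12 = clip((d1-d3) S1 I2 / c2),
    a21 = clip((d2-d4) S2 I1 / c3), a22 = clip((d2-d4) S2 I2 / c4).
    """
    x = np.asarray(state, dtype=float)
    d = np.asarray(adjoint, dtype=float)
    c = np.asarray(weights, dtype=float)
    S1, S2, I1, I2 = x[..., 0], x[..., 1], x[..., 2], x[..., 3]
    g1 = d[..., 0] - d[..., 2]
    g2 = d[..., 1] - d[..., 3]
    raw = np.stack([g1 * S1 * I1 / c[0], g1 * S1 * I2 / c[1],
                    g2 * S2 * I1 / c[2], g2 * S2 * I2 / c[3]], axis=-1)
    return np.clip(raw, 0.0, 1.0)


def evaluate_objective(states, controls, weights, grid) -> float:
    """Composite-trapezoid value of the objective J."""
    x = np.asarray(states, dtype=float)
    u = np.asarray(controls, dtype=float)
    t = np.asarray(grid, dtype=float)
    c = np.asarray(weights, dtype=float)
    if x.shape[0] != t.size or u.shape[0] != t.size:
        raise ValidationError("states, controls, and grid must share a grid")
    integrand = x[..., 2] + x[..., 3] - 0.5 * (u ** 2 @ c)
    return float(np.trapezoid(integrand, t, axis=0))


def forward_states(problem: ControlProblem, controls: np.ndarray) -> np.ndarray:
    """RK4 integration of the controlled state system along the grid.

    Controls are given at the grid nodes; half-step values use the mean of
    the adjacent nodes.
    """
    p = problem.params
    n = problem.n_grid
    h = problem.t_f / (n - 1)
    x = np.empty((n, 4) if controls.ndim == 2 else
                 (n,) + controls.shape[1:], dtype=float)
    x[0] = np.asarray(problem.init, dtype=float)
    for i in range(n - 1):
        u0, u1 = controls[i], controls[i + 1]
        um = 0.5 * (u0 + u1)
        k1 = _state_rhs(x[i], u0, p)
        k2 = _state_rhs(x[i] + 0.5 * h * k1, um, p)
        k3 = _state_rhs(x[i] + 0.5 * h * k2, um, p)
        k4 = _state_rhs(x[i] + h * k3, u1, p)
        x[i + 1] = x[i] + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    if not np.all(np.isfinite(x)):
        raise ValidationError("divergent state in forward integration")
    return x


def backward_adjoints(problem: ControlProblem, states: np.ndarray,
                      controls: np.ndarray) -> np.ndarray:
    """RK4 integration of the adjoint system backwards from delta(t_f) = 0."""
    p = problem.params
    n = problem.n_grid
    h = problem.t_f / (n - 1)
    d = np.zeros_like(states)
    for i in range(n - 1, 0, -1):
        x1, x0 = states[i], states[i - 1]
        u1, u0 = controls[i], controls[i - 1]
        xm, um = 0.5 * (x0 + x1), 0.5 * (u0 + u1)
        k1 = adjoint_rhs(x1, d[i], u1, p)
        k2 = adjoint_rhs(xm, d[i] - 0.5 * h * k1, um, p)
        k3 = adjoint_rhs(xm, d[i] - 0.5 * h * k2, um, p)
        k4 = adjoint_rhs(x0, d[i] - h * k3, u0, p)
        d[i - 1] = d[i] - (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return d


def forward_backward_sweep(
    problem: ControlProblem,
    relaxation: float = 0.5,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> ControlSolution:
    """Iterate the forward-backward sweep to a fixed point of the control law.

    Starting from the constant uncontrolled baseline, each iteration runs
    the forward state integration, the backward adjoint integration, and
    the projected control update blended with the previous controls as
    ``new = (1 - w) old + w proposed``.  Iteration stops when the maximum
    relative control change drops below ``tol``.  Non-convergence returns
    the last iterate with ``converged=False`` rather than raising.
    """
    if not (0 < relaxation <= 1):
        raise ValidationError("relaxation must lie in (0, 1]")
    c = problem.weights
    u = problem.baseline_controls
    change = math.inf
    it = 0
    states = adjoints = None
    for it in range(1, max_iter + 1):
        states = forward_states(problem, u)
        adjoints = backward_adjoints(problem, states, u)
        proposed = control_update(states, adjoints, c)
        new = (1.0 - relaxation) * u + relaxation * proposed
        # the terminal value is known exactly: zero adjoints project to zero
        new[-1] = proposed[-1]
        change = float(np.max(np.abs(new - u)) / (1.0 + np.max(np.abs(new))))
        u = new
        if change < tol:
            break
    states = forward_states(problem, u)
    adjoints = backward_adjoints(problem, states, u)
    J = evaluate_objective(states, u, c, problem.grid)
    return ControlSolution(grid=problem.grid, controls=u, states=states,
                           adjoints=adjoints, objective=J, iterations=it,
                           converged=change < tol, final_change=change)


def best_constant_control(problem: ControlProblem,
                          resolution: float = 0.1) -> tuple[np.ndarray, float]:
    """Brute-force search over constant admissible controls.

    Evaluates J for every constant control vector on a ``resolution``-spaced
    grid of [0, 1]^4 (all candidates integrated simultaneously) and returns
    the best vector and its objective.  Serves as an independent lower
    bound for the sweep's objective.
    """
    levels = np.round(np.arange(0.0, 1.0 + resolution / 2, resolution), 12)
    cand = np.array(list(itertools.product(levels, repeat=4)))
    n_cand = cand.shape[0]
    p = problem.params
    n = problem.n_grid
    h = problem.t_f / (n - 1)
    x = np.tile(np.asarray(problem.init, dtype=float), (n_cand, 1))
    t = problem.grid
    # trapezoid accumulation of int (I1 + I2) dt without storing paths
    acc = 0.5 * (x[:, 2] + x[:, 3])
    for _ in range(n - 1):
        k1 = _state_rhs(x, cand, p)
        k2 = _state_rhs(x + 0.5 * h * k1, cand, p)
        k3 = _state_rhs(x + 0.5 * h * k2, cand, p)
        k4 = _state_rhs(x + h * k3, cand, p)
        x = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        acc += x[:, 2] + x[:, 3]
    acc -= 0.5 * (x[:, 2] + x[:, 3])
    J = acc * h - 0.5 * problem.t_f * (cand ** 2 @ problem.weights)
    best = int(np.argmax(J))
    return cand[best], float(J[best])


@dataclass
class ControlComparison:
    """Paired stochastic comparison of constant vs optimal control."""

    times: np.ndarray
    mean_constant: np.ndarray   # (n, 4) mean state paths under constant control
    mean_optimal: np.ndarray    # (n, 4) under the sweep's control paths
    J_constant: float
    J_optimal: float
    J_constant_se: float
    J_optimal_se: float
    per_replicate_J: dict       # {"constant": array, "optimal": array}
    n_reps: int
    base_seed: int

    def mean_column(self, arm: str, name: str) -> np.ndarray:
        arr = self.mean_constant if arm == "constant" else self.mean_optimal
        return arr[:, CONTROL_STATE.index(name)]

    def to_dict(self) -> dict:
        return {"times": self.times.tolist(),
                "mean_constant": {n: self.mean_constant[:, i].tolist()
                                  for i, n in enumerate(CONTROL_STATE)},
                "mean_optimal": {n: self.mean_optimal[:, i].tolist()
                                 for i, n in enumerate(CONTROL_STATE)},
                "J_constant": self.J_constant, "J_optimal": self.J_optimal,
                "J_constant_se": self.J_constant_se,
                "J_optimal_se": self.J_optimal_se,
                "n_reps": self.n_reps, "base_seed": self.base_seed}


def _simulate_controlled_sde(problem: ControlProblem, controls: np.ndarray,
                             dW: np.ndarray) -> np.ndarray:
    """Euler-Maruyama paths of the stochastic state system.

    ``controls`` has shape (n_grid, 4); ``dW`` has shape
    (n_grid - 1, n_reps, 4) holding increments of W1..W4.  Returns states of
    shape (n_grid, n_reps, 4); negatives are truncated to zero.
    """
    p = problem.params
    s = problem.sigmas
    n, n_reps = controls.shape[0], dW.shape[1]
    h = problem.t_f / (n - 1)
    x = np.tile(np.asarray(problem.init, dtype=float), (n_reps, 1))
    out = np.empty((n, n_reps, 4))
    out[0] = x
    for i in range(n - 1):
        S1, S2, I1, I2 = x[:, 0], x[:, 1], x[:, 2], x[:, 3]
        b1 = s.sigma1 * S1 * I1 * dW[i, :, 0] + s.sigma2 * S1 * I2 * dW[i, :, 1]
        b2 = s.sigma3 * S2 * I1 * dW[i, :, 2] + s.sigma4 * S2 * I2 * dW[i, :, 3]
        after_drift = x + _state_rhs(x, controls[i], p) * h
        g = np.stack([-b1, -b2, b1, b2], axis=-1)
        x = after_drift + _damping_factor(after_drift, g)[:, None] * g
        x = np.maximum(x, 0.0)
        out[i + 1] = x
    if not np.all(np.isfinite(out)):
        raise ValidationError("divergent state in stochastic comparison")
    return out


def compare_control_strategies(
    problem: ControlProblem,
    solution: ControlSolution,
    n_reps: int = 200,
    base_seed: int = 0,
) -> ControlComparison:
    """Simulate the stochastic state system under both control strategies.

    Replicate r of each arm uses the Brownian increments of seed
    ``base_seed + r`` — the comparison is pairwise coupled, so arm
    differences are not masked by between-path noise.  Reports mean state
    paths and the Monte-Carlo objective for the constant baseline and the
    optimal control paths.
    """
    if solution.controls.shape != (problem.n_grid, 4):
        raise ValidationError("solution grid does not match problem grid")
    n = problem.n_grid
    h = problem.t_f / (n - 1)
    sq = math.sqrt(h)
    dW = np.empty((n - 1, n_reps, 4))
    for r in range(n_reps):
        rng = np.random.default_rng(base_seed + r)
        dW[:, r, :] = rng.standard_normal((n - 1, 4)) * sq
    arms = {}
    for name, controls in (("constant", problem.baseline_controls),
                           ("optimal", solution.controls)):
        paths = _simulate_controlled_sde(problem, controls, dW)
        Js = np.array([evaluate_objective(paths[:, r, :], controls,
                                          problem.weights, problem.grid)
                       for r in range(n_reps)])
        arms[name] = (paths.mean(axis=1), Js)
    mean_c, J_c = arms["constant"]
    mean_o, J_o = arms["optimal"]
    return ControlComparison(
        times=problem.grid,
        mean_constant=mean_c, mean_optimal=mean_o,
        J_constant=float(J_c.mean()), J_optimal=float(J_o.mean()),
        J_constant_se=float(J_c.std(ddof=1) / math.sqrt(n_reps)) if n_reps > 1 else 0.0,
        J_optimal_se=float(J_o.std(ddof=1) / math.sqrt(n_reps)) if n_reps > 1 else 0.0,
        per_replicate_J={"constant": J_c, "optimal": J_o},
        n_reps=n_reps, base_seed=base_seed)
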