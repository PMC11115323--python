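"""Euler-Maruyama simulation of the Ito SDE system.

White Gaussian noise perturbs the four contact rates and four mutation
rates: alpha_ij -> alpha_ij + sigma_k dW_k/dt and beta_ij -> beta_ij +
sigma_k dW_k/dt with eight independent Brownian motions.  Substituting into
the deterministic system yields an Ito SDE in which every diffusion term
appears twice with opposite signs (mass leaving one compartment enters
another), so the diffusion contributions across the ten compartments sum to
exactly zero at every step.  The two removed compartments R1, R2 carry no
diffusion — the stochastic system perturbs only the eight transmission /
mutation equations — and keep their deterministic drift.

Positivity holds for the continuous-time solution but not for the
Euler-Maruyama discretisation.  Two safeguards are applied at every step:

1. *Boundary noise damping.*  The step's diffusion vector is scaled by the
   largest factor theta in [0, 1] for which no compartment goes negative.
   Scaling the whole vector preserves the pairwise flux cancellation, so
   the total population still obeys its exact balance law
   dN = (B1 + B2 - mu N) dt along every path and remains bounded.  Plain
   one-sided truncation lacks this property: clamping a source compartment
   at zero while its partner keeps the full flux injects mass and makes
   the scheme explosive under strong noise.  Away from the boundary
   theta = 1 and the update is the textbook Euler-Maruyama step.
2. *Truncation backstop.*  Anything still negative after damping (drift
   undershoot, roundoff) is truncated to zero and counted; the count is
   part of every trajectory's metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional, Sequence

import numpy as np

from .model_core import (
    NEGATIVITY_TOL,
    STATE_FIELDS,
    ModelParameters,
    StateVector,
    Trajectory,
    ValidationError,
    _as_state_array,
    _rhs_array,
    simulate_ode,
)

__all__ = [
    "NoiseIntensities",
    "EnsemblePaths",
    "EnsembleSummary",
    "SimulationError",
    "em_step",
    "diffusion_increment",
    "simulate_sde",
    "simulate_ensemble",
    "ensemble_summary",
]

#: Parameter bound to each diffusion intensity, in order sigma1..sigma8.
SIGMA_BINDINGS = ("alpha11", "alpha12", "alpha21", "alpha22",
                  "beta11", "beta12", "beta21", "beta22")

#: Compartments that carry diffusion (R1 and R2 do not).
NOISY_COMPARTMENTS = ("S1", "I1", "M1", "M2", "S2", "I2", "M3", "M4")

_CHUNK_STEPS = 1024  # Brownian increments drawn per replicate per chunk


class SimulationError(RuntimeError):
    """Stochastic integration produced a non-finite state."""

    def __init__(self, message: str, step: int | None = None,
                 replicate: int | None = None):
        super().__init__(message)
        self.step = step
        self.replicate = replicate


@dataclass(frozen=True)
class NoiseIntensities:
    """The eight diffusion intensities sigma1..sigma8 (all >= 0).

    Binding order is fixed: sigma1 -> alpha11, sigma2 -> alpha12,
    sigma3 -> alpha21, sigma4 -> alpha22, sigma5 -> beta11,
    sigma6 -> beta12, sigma7 -> beta21, sigma8 -> beta22.
    """

    sigma1: float = 0.0
    sigma2: float = 0.0
    sigma3: float = 0.0
    sigma4: float = 0.0
    sigma5: float = 0.0
    sigma6: float = 0.0
    sigma7: float = 0.0
    sigma8: float = 0.0

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not (np.isfinite(v) and v >= 0):
                raise ValidationError(f"{f.name} must be >= 0, got {v!r}")

    @classmethod
    def uniform(cls, sigma: float) -> "NoiseIntensities":
        """All eight intensities equal to ``sigma``."""
        return cls(*([float(sigma)] * 8))

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=float)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseIntensities":
        return cls(**d)


def diffusion_increment(y: np.ndarray, sigmas: np.ndarray,
                        dW: np.ndarray) -> np.ndarray:
    """Diffusion contribution of one step, before truncation.

    ``y`` has shape (..., 10), ``dW`` shape (..., 8).  The eight elementary
    noise fluxes are

        a1 = sigma1*S1*I1*dW1   (S1 <-> I1)     a5 = sigma5*I1*dW5 (I1 <-> M1)
        a2 = sigma2*S1*I2*dW2   (S1 <-> I1)     a6 = sigma6*I1*dW6 (I1 <-> M2)
        a3 = sigma3*S2*I1*dW3   (S2 <-> I2)     a7 = sigma7*I2*dW7 (I2 <-> M3)
        a4 = sigma4*S2*I2*dW4   (S2 <-> I2)     a8 = sigma8*I2*dW8 (I2 <-> M4)

    each entering its source with a minus sign and its target with a plus
    sign, so the ten components of the result sum to exactly zero.
    """
    S1, I1 = y[..., 0], y[..., 1]
    S2, I2 = y[..., 5], y[..., 6]
    a1 = sigmas[0] * S1 * I1 * dW[..., 0]
    a2 = sigmas[1] * S1 * I2 * dW[..., 1]
    a3 = sigmas[2] * S2 * I1 * dW[..., 2]
    a4 = sigmas[3] * S2 * I2 * dW[..., 3]
    a5 = sigmas[4] * I1 * dW[..., 4]
    a6 = sigmas[5] * I1 * dW[..., 5]
    a7 = sigmas[6] * I2 * dW[..., 6]
    a8 = sigmas[7] * I2 * dW[..., 7]
    out = np.zeros_like(y)
    out[..., 0] = -a1 - a2
    out[..., 1] = a1 + a2 - a5 - a6
    out[..., 2] = a5
    out[..., 3] = a6
    out[..., 5] = -a3 - a4
    out[..., 6] = a3 + a4 - a7 - a8
    out[..., 7] = a7
    out[..., 8] = a8
    return out


def _damping_factor(after_drift: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Largest theta in [0, 1] with ``after_drift + theta * g >= 0``.

    ``after_drift`` is the state plus the drift increment, ``g`` the raw
    diffusion increment; both have the compartment axis last.  Returns
    theta with the compartment axis reduced away.
    """
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        ratio = np.where(g < 0, after_drift / np.where(g < 0, -g, 1.0), np.inf)
    return np.clip(ratio.min(axis=-1), 0.0, 1.0)


def em_step(state, params: ModelParameters, sigmas: NoiseIntensities,
            dt: float, increments) -> tuple[np.ndarray, int]:
    """One Euler-Maruyama update with boundary noise damping.

    Parameters
    ----------
    increments : array-like, shape (..., 8)
        Brownian increments Delta W_i for this step (mean 0, variance dt),
        supplied externally for testability.

    Returns
    -------
    (new_state, n_truncated)
        The updated state with any remaining negative components truncated
        to zero, and the number of components that were truncated.
    """
    if dt <= 0:
        raise ValidationError("dt must be positive")
    y = _as_state_array(state)
    dW = np.asarray(increments, dtype=float)
    if dW.shape[-1] != 8:
        raise ValidationError(f"increments must have 8 components, got {dW.shape}")
    s = sigmas.to_array()
    after_drift = y + _rhs_array(y, params) * dt
    g = diffusion_increment(y, s, dW)
    theta = _damping_factor(after_drift, g)
    new = after_drift + np.expand_dims(theta, -1) * g
    if not np.all(np.isfinite(new)):
        raise SimulationError("non-finite state after Euler-Maruyama step")
    neg = new < 0
    n_trunc = int(np.count_nonzero(neg))
    if n_trunc:
        new = np.where(neg, 0.0, new)
    return new, n_trunc


def _record_grid(n_steps: int, record_every: int) -> np.ndarray:
    idx = np.arange(0, n_steps + 1, record_every)
    if idx[-1] != n_steps:
        idx = np.append(idx, n_steps)
    return idx


@dataclass
class EnsemblePaths:
    """Raw recorded paths of a replicate ensemble.

    ``states`` has shape (n_recorded_times, n_reps, 10).
    """

    times: np.ndarray
    states: np.ndarray
    truncation_counts: np.ndarray  # per replicate
    seeds: np.ndarray
    dt: float

    def trajectory(self, r: int) -> Trajectory:
        return Trajectory(self.times, self.states[:, r, :], metadata={
            "scheme": "euler-maruyama", "dt": self.dt,
            "seed": int(self.seeds[r]),
            "truncation_events": int(self.truncation_counts[r])})

    def trajectories(self) -> list[Trajectory]:
        return [self.trajectory(r) for r in range(self.states.shape[1])]

    def column(self, name: str) -> np.ndarray:
        """Recorded paths of one compartment, shape (n_times, n_reps)."""
        return self.states[:, :, STATE_FIELDS.index(name)]


def simulate_ensemble(
    params: ModelParameters,
    sigmas: NoiseIntensities,
    init: StateVector | Sequence[float],
    t_end: float,
    dt: float,
    seeds: Sequence[int],
    record_every: int = 1,
) -> EnsemblePaths:
    """Simulate one Euler-Maruyama path per seed, vectorised across seeds.

    Replicate ``r`` uses ``numpy.random.default_rng(seeds[r])`` for its
    Brownian increments and is bit-identical to a single
    :func:`simulate_sde` run with the same seed, independent of how many
    replicates are simulated together.
    """
    if dt <= 0 or t_end <= 0:
        raise ValidationError("dt and t_end must be positive")
    y0 = _as_state_array(init).astype(float)
    if np.any(y0 < -NEGATIVITY_TOL):
        raise ValidationError("initial state must be nonnegative")
    seeds = np.asarray(seeds, dtype=np.int64)
    n_reps = seeds.size
    n_steps = int(round(t_end / dt))
    rec_idx = _record_grid(n_steps, record_every)
    times = rec_idx * dt
    s = sigmas.to_array()
    sqdt = np.sqrt(dt)

    y = np.tile(np.maximum(y0, 0.0), (n_reps, 1))
    states = np.empty((rec_idx.size, n_reps, 10))
    states[0] = y
    trunc = np.zeros(n_reps, dtype=np.int64)
    rngs = [np.random.default_rng(int(sd)) for sd in seeds]

    pos = 1
    step = 0
    while step < n_steps:
        m = min(_CHUNK_STEPS, n_steps - step)
        # chunked draws are stream-sequential, so the per-replicate stream
        # does not depend on the chunk size
        dW = np.stack([rng.standard_normal((m, 8)) for rng in rngs], axis=1)
        dW *= sqdt
        for j in range(m):
            after_drift = y + _rhs_array(y, params) * dt
            g = diffusion_increment(y, s, dW[j])
            y = after_drift + _damping_factor(after_drift, g)[:, None] * g
            neg = y < 0
            if neg.any():
                trunc += np.count_nonzero(neg, axis=1)
                y[neg] = 0.0
            step += 1
            if pos < rec_idx.size and step == rec_idx[pos]:
                if not np.all(np.isfinite(y)):
                    bad = int(np.argwhere(~np.isfinite(y))[0, 0])
                    raise SimulationError(
                        f"non-finite state at step {step} (replicate {bad})",
                        step=step, replicate=bad)
                states[pos] = y
                pos += 1
    return EnsemblePaths(times=times, states=states, truncation_counts=trunc,
                         seeds=seeds, dt=dt)


def simulate_sde(
    params: ModelParameters,
    sigmas: NoiseIntensities,
    init: StateVector | Sequence[float],
    t_end: float,
    dt: float = 0.01,
    seed: int = 0,
    record_every: int = 1,
) -> Trajectory:
    """One seeded Euler-Maruyama path of the stochastic system.

    The same seed (with identical parameters, intensities, initial state,
    and grid) reproduces the trajectory bit for bit.  The number of
    negative-truncation events is reported in ``metadata``.
    """
    ens = simulate_ensemble(params, sigmas, init, t_end, dt, [seed],
                            record_every=record_every)
    return ens.trajectory(0)


@dataclass
class EnsembleSummary:
    """Per-time summaries and endpoint histograms of a replicate ensemble."""

    times: np.ndarray
    mean: np.ndarray            # (n_times, 10)
    sd: np.ndarray              # (n_times, 10)
    quantiles: dict             # level -> (n_times, 10)
    histograms: dict            # compartment -> (bin_edges, counts), endpoint
    truncation_counts: np.ndarray
    n_reps: int
    base_seed: int
    deterministic: Trajectory = None  # reference path on the same grid

    def mean_column(self, name: str) -> np.ndarray:
        return self.mean[:, STATE_FIELDS.index(name)]

    def sd_column(self, name: str) -> np.ndarray:
        return self.sd[:, STATE_FIELDS.index(name)]

    def to_dict(self) -> dict:
        return {
            "times": self.times.tolist(),
            "mean": {c: self.mean[:, i].tolist()
                     for i, c in enumerate(STATE_FIELDS)},
            "sd": {c: self.sd[:, i].tolist()
                   for i, c in enumerate(STATE_FIELDS)},
            "quantiles": {str(q): {c: arr[:, i].tolist()
                                   for i, c in enumerate(STATE_FIELDS)}
                          for q, arr in self.quantiles.items()},
            "histograms": {c: {"bin_edges": e.tolist(), "counts": n.tolist()}
                           for c, (e, n) in self.histograms.items()},
            "truncation_counts": self.truncation_counts.tolist(),
            "n_reps": self.n_reps,
            "base_seed": self.base_seed,
            "deterministic": {c: self.deterministic.column(c).tolist()
                              for c in STATE_FIELDS}
                             if self.deterministic is not None else None,
        }


def ensemble_summary(
    params: ModelParameters,
    sigmas: NoiseIntensities,
    init: StateVector | Sequence[float],
    t_end: float,
    dt: float,
    n_reps: int,
    base_seed: int,
    quantile_levels: Sequence[float] = (0.05, 0.25, 0.5, 0.75, 0.95),
    n_bins: int = 30,
    record_every: Optional[int] = None,
    paths: Optional[EnsemblePaths] = None,
) -> EnsembleSummary:
    """Monte-Carlo ensemble with per-time summaries and endpoint histograms.

    Replicate ``r`` uses seed ``base_seed + r``.  Histograms cover the
    endpoint values of the eight compartments that carry diffusion, with
    ``n_bins`` equal-width bins over the ensemble endpoint range; a
    deterministic reference path on the same recorded grid is included for
    comparison plots and tables.  Precomputed ``paths`` may be passed to
    summarise an existing ensemble without re-simulating.
    """
    if n_reps < 2:
        raise ValidationError("n_reps must be >= 2")
    if record_every is None:
        record_every = max(1, int(round(0.5 / dt)))
    if paths is None:
        seeds = base_seed + np.arange(n_reps)
        paths = simulate_ensemble(params, sigmas, init, t_end, dt, seeds,
                                  record_every=record_every)
    mean = paths.states.mean(axis=1)
    sd = paths.states.std(axis=1, ddof=1)
    quants = {q: np.quantile(paths.states, q, axis=1) for q in quantile_levels}
    hists = {}
    endpoint = paths.states[-1]  # (n_reps, 10)
    for name in NOISY_COMPARTMENTS:
        vals = endpoint[:, STATE_FIELDS.index(name)]
        lo, hi = float(vals.min()), float(vals.max())
        if hi <= lo:  # degenerate range: a single bin around the value
            lo, hi = lo - 0.5, hi + 0.5
        counts, edges = np.histogram(vals, bins=n_bins, range=(lo, hi))
        hists[name] = (edges, counts)
    det = simulate_ode(params, np.maximum(_as_state_array(init), 0.0),
                       t_end, dt, record_every=record_every)
    return EnsembleSummary(times=paths.times, mean=mean, sd=sd,
                           quantiles=quants, histograms=hists,
                           truncation_counts=paths.truncation_counts,
                           n_reps=n_reps, base_seed=base_seed,
                           deterministic=det)
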