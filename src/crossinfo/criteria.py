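"""Analytic threshold criteria for the stochastic system, and empirical checks.

Two closed-form verdicts are implemented:

* **Extinction.**  limsup ln I1(t)/t <= G1 almost surely, with

      G1 = alpha11^2/(2 sigma1^2) + alpha12^2/(2 sigma2^2)
           - (beta11 + beta12 + mu + sigma5^2/2 + sigma6^2/2)

  and symmetrically G2 for I2 (alpha21, alpha22, sigma3, sigma4, sigma7,
  sigma8, beta21, beta22).  G1 < 0 and G2 < 0 imply both disseminator
  densities tend to zero exponentially a.s. — strong enough noise kills
  the dissemination.

* **Stationary distribution.**  With E* = (S1*, S2*, I1*, I2*) the interior
  equilibrium of the deterministic system, define

      Gamma = sigma1^2 S1*^2 I1* + sigma2^2 S1*^2 I2*^2
              + sigma3^2 S2*^2 I1*^2
              + (sigma5^2 + sigma6^2)(I1*/2 + 2 I1*^2)
              + (sigma7^2 + sigma8^2)(I2*/2 + 2 I2*^2)
      xi1 = 2 mu - sigma1^2 I1*          xi2 = 2 mu - sigma4^2 I2*
      xi3 = 2 (beta11 + beta12 + mu - sigma5^2 - sigma6^2)
      xi4 = 2 (beta21 + beta22 + mu - sigma7^2 - sigma8^2)

  If 0 < Gamma < min(xi1 S1*^2, xi2 S2*^2, xi3 I1*^2, xi4 I2*^2) a unique
  stationary distribution exists, the solution is ergodic, and the
  time-averaged xi-weighted mean-square deviation from E* is bounded by
  Gamma.  The mutant compartments play no role in this criterion.

The ``gamma_variant="plus_sigma4"`` switch adds a sigma4^2 S2*^2 I2* term to
Gamma; the two published forms of the constant differ by exactly this term
and the default follows the theorem statement (the smaller, stricter
constant).  Empirical diagnostics estimate the log-slope ln I(t)/t and the
Eq-style weighted mean-square deviation from ensembles produced by
:mod:`crossinfo.stochastic_sim`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .model_core import (
    EquilibriumPoint,
    ModelParameters,
    Trajectory,
    ValidationError,
)
from .stochastic_sim import NoiseIntensities

__all__ = [
    "ExtinctionReport",
    "StationaryReport",
    "LogSlopeReport",
    "DeviationEstimate",
    "extinction_g",
    "extinction_thresholds",
    "stationary_condition",
    "log_slope_diagnostic",
    "mean_square_deviation",
]


@dataclass(frozen=True)
class ExtinctionReport:
    """Extinction thresholds G1, G2 and their verdicts (G < 0 => extinct)."""

    G1: float
    G2: float
    extinct1: bool
    extinct2: bool
    sigma_zero_flag1: bool = False  # G1 is +inf because sigma1 or sigma2 = 0
    sigma_zero_flag2: bool = False

    def to_dict(self) -> dict:
        return {"G1": self.G1, "G2": self.G2,
                "extinct1": self.extinct1, "extinct2": self.extinct2,
                "sigma_zero_flag1": self.sigma_zero_flag1,
                "sigma_zero_flag2": self.sigma_zero_flag2}


@dataclass(frozen=True)
class StationaryReport:
    """The stationary-distribution sufficient condition at an interior E*."""

    Gamma: float
    xi1: float
    xi2: float
    xi3: float
    xi4: float
    bound: float            # min(xi1 S1*^2, xi2 S2*^2, xi3 I1*^2, xi4 I2*^2)
    satisfied: bool         # 0 < Gamma < bound (and all xi > 0)
    equilibrium: EquilibriumPoint
    gamma_variant: str = "theorem"

    @property
    def xi(self) -> tuple[float, float, float, float]:
        return (self.xi1, self.xi2, self.xi3, self.xi4)

    def to_dict(self) -> dict:
        return {"Gamma": self.Gamma, "xi1": self.xi1, "xi2": self.xi2,
                "xi3": self.xi3, "xi4": self.xi4, "bound": self.bound,
                "satisfied": self.satisfied,
                "gamma_variant": self.gamma_variant,
                "equilibrium": self.equilibrium.to_dict()}


def extinction_g(alpha_a: float, alpha_b: float, exit_rate: float,
                 sigma_a: float, sigma_b: float,
                 sigma_c: float, sigma_d: float) -> tuple[float, bool]:
    """One extinction threshold value.

    G = alpha_a^2/(2 sigma_a^2) + alpha_b^2/(2 sigma_b^2)
        - (exit_rate + sigma_c^2/2 + sigma_d^2/2)

    where ``exit_rate`` is beta + beta' + mu for the relevant group.  A zero
    contact rate contributes 0 regardless of its sigma; a zero sigma under a
    positive contact rate makes the term (and G) +inf — the deterministic
    limit has no noise-driven extinction mechanism — and sets the flag.
    """
    flagged = False

    def term(alpha: float, sigma: float) -> float:
        nonlocal flagged
        if alpha == 0:
            return 0.0
        if sigma == 0:
            flagged = True
            return math.inf
        return alpha ** 2 / (2.0 * sigma ** 2)

    g = (term(alpha_a, sigma_a) + term(alpha_b, sigma_b)
         - (exit_rate + 0.5 * sigma_c ** 2 + 0.5 * sigma_d ** 2))
    return g, flagged


def extinction_thresholds(params: ModelParameters,
                          sigmas: NoiseIntensities) -> ExtinctionReport:
    """Closed-form extinction thresholds for both disseminator classes."""
    g1, f1 = extinction_g(params.alpha11, params.alpha12, params.k1,
                          sigmas.sigma1, sigmas.sigma2,
                          sigmas.sigma5, sigmas.sigma6)
    g2, f2 = extinction_g(params.alpha21, params.alpha22, params.k2,
                          sigmas.sigma3, sigmas.sigma4,
                          sigmas.sigma7, sigmas.sigma8)
    return ExtinctionReport(G1=g1, G2=g2, extinct1=g1 < 0, extinct2=g2 < 0,
                            sigma_zero_flag1=f1, sigma_zero_flag2=f2)


def stationary_condition(
    params: ModelParameters,
    sigmas: NoiseIntensities,
    equilibrium: EquilibriumPoint,
    gamma_variant: str = "theorem",
) -> StationaryReport:
    """Evaluate the stationary-distribution sufficient condition at E*.

    Parameters
    ----------
    equilibrium : EquilibriumPoint
        Must be interior (I1*, I2* > 0); a boundary equilibrium raises.
    gamma_variant : {"theorem", "plus_sigma4"}
        "plus_sigma4" adds the sigma4^2 S2*^2 I2* term to Gamma for
        sensitivity checking (see module docstring).

    Negative xi values are reported as computed but force
    ``satisfied=False``.
    """
    if gamma_variant not in ("theorem", "plus_sigma4"):
        raise ValidationError(f"unknown gamma_variant {gamma_variant!r}")
    if equilibrium.boundary or equilibrium.I1 <= 0 or equilibrium.I2 <= 0:
        raise ValidationError(
            "stationary condition requires an interior equilibrium "
            "(I1*, I2* > 0)")
    S1, S2 = equilibrium.S1, equilibrium.S2
    I1, I2 = equilibrium.I1, equilibrium.I2
    s = sigmas
    gamma = (s.sigma1 ** 2 * S1 ** 2 * I1
             + s.sigma2 ** 2 * S1 ** 2 * I2 ** 2
             + s.sigma3 ** 2 * S2 ** 2 * I1 ** 2
             + (s.sigma5 ** 2 + s.sigma6 ** 2) * (0.5 * I1 + 2.0 * I1 ** 2)
             + (s.sigma7 ** 2 + s.sigma8 ** 2) * (0.5 * I2 + 2.0 * I2 ** 2))
    if gamma_variant == "plus_sigma4":
        gamma += s.sigma4 ** 2 * S2 ** 2 * I2
    xi1 = 2.0 * params.mu - s.sigma1 ** 2 * I1
    xi2 = 2.0 * params.mu - s.sigma4 ** 2 * I2
    xi3 = 2.0 * (params.beta11 + params.beta12 + params.mu
                 - s.sigma5 ** 2 - s.sigma6 ** 2)
    xi4 = 2.0 * (params.beta21 + params.beta22 + params.mu
                 - s.sigma7 ** 2 - s.sigma8 ** 2)
    bound = min(xi1 * S1 ** 2, xi2 * S2 ** 2, xi3 * I1 ** 2, xi4 * I2 ** 2)
    ok = (0.0 < gamma < bound) and min(xi1, xi2, xi3, xi4) > 0
    return StationaryReport(Gamma=gamma, xi1=xi1, xi2=xi2, xi3=xi3, xi4=xi4,
                            bound=bound, satisfied=ok, equilibrium=equilibrium,
                            gamma_variant=gamma_variant)


@dataclass
class LogSlopeReport:
    """Empirical estimate of sup ln I(t)/t over an ensemble."""

    estimate: Optional[float]      # max over positive replicates; None if none
    per_replicate: np.ndarray      # ln I(t*)/t* for replicates with I > 0
    n_excluded: int                # replicates truncated to zero at t*
    degenerate: bool               # all replicates hit zero
    time: float                    # the evaluation time t*


def log_slope_diagnostic(
    trajectories: Iterable[Trajectory],
    compartment: str = "I1",
    window: Optional[tuple[float, float]] = None,
    at: str = "window_end",
) -> LogSlopeReport:
    """Estimate limsup ln I(t)/t from simulated trajectories.

    With ``at="window_end"`` each replicate contributes ln I(t*)/t* at the
    last grid time inside ``window`` (default: the final time); replicates
    whose density is zero there (truncation or floating-point underflow of
    an exponentially decaying path) are excluded and counted.  With
    ``at="last_positive"`` each replicate is instead evaluated at its own
    last grid time with I > 0, so paths that decay below the smallest
    representable double — which respect any exponential bound a fortiori —
    still contribute their steepest observable slope.  If every replicate is
    excluded the estimate is degenerate and the bound is trivially
    respected.
    """
    if compartment not in ("I1", "I2"):
        raise ValidationError("compartment must be 'I1' or 'I2'")
    if at not in ("window_end", "last_positive"):
        raise ValidationError("at must be 'window_end' or 'last_positive'")
    values = []
    n_excluded = 0
    t_star = None
    for traj in trajectories:
        t = traj.times
        if window is not None:
            mask = (t >= window[0]) & (t <= window[1])
            if not mask.any():
                raise ValidationError("window contains no grid points")
            idx_all = np.nonzero(mask)[0]
        else:
            idx_all = np.arange(t.size)
        col = traj.column(compartment)
        if at == "window_end":
            idx = idx_all[-1]
            if col[idx] <= 0:
                n_excluded += 1
                t_star = float(t[idx])
                continue
        else:
            pos = idx_all[(col[idx_all] > 0) & (t[idx_all] > 0)]
            if pos.size == 0:
                n_excluded += 1
                continue
            idx = pos[-1]
        t_star = float(t[idx])
        if t_star <= 0:
            raise ValidationError("evaluation time must be positive")
        values.append(math.log(col[idx]) / t_star)
    values = np.asarray(values)
    degenerate = values.size == 0
    return LogSlopeReport(
        estimate=None if degenerate else float(values.max()),
        per_replicate=values, n_excluded=n_excluded,
        degenerate=degenerate, time=t_star if t_star is not None else math.nan)


@dataclass
class DeviationEstimate:
    """Monte-Carlo estimate of the time-averaged weighted square deviation."""

    estimate: float
    standard_error: float
    per_replicate: np.ndarray
    window: tuple[float, float]


def mean_square_deviation(
    trajectories: Sequence[Trajectory],
    equilibrium: EquilibriumPoint,
    report: StationaryReport,
    window: Optional[tuple[float, float]] = None,
) -> DeviationEstimate:
    """Estimate (1/t) E int [xi1 (S1-S1*)^2 + xi2 (S2-S2*)^2
    + xi3 (I1-I1*)^2 + xi4 (I2-I2*)^2] du over the trajectory window.

    When the stationary condition holds this quantity is bounded by Gamma;
    the estimate is returned with its Monte-Carlo standard error so the
    bound can be tested with sampling slack.  All trajectories must share
    one time grid.
    """
    trajectories = list(trajectories)
    if not trajectories:
        raise ValidationError("at least one trajectory required")
    t0 = trajectories[0].times
    for traj in trajectories[1:]:
        if traj.times.shape != t0.shape or not np.array_equal(traj.times, t0):
            raise ValidationError("trajectories must share a common time grid")
    if window is None:
        window = (float(t0[0]), float(t0[-1]))
    mask = (t0 >= window[0]) & (t0 <= window[1])
    if np.count_nonzero(mask) < 2:
        raise ValidationError("window must contain at least two grid points")
    t = t0[mask]
    span = t[-1] - t[0]
    xi1, xi2, xi3, xi4 = report.xi
    e = equilibrium
    per_rep = np.empty(len(trajectories))
    for r, traj in enumerate(trajectories):
        y = traj.states[mask]
        integrand = (xi1 * (y[:, 0] - e.S1) ** 2
                     + xi2 * (y[:, 5] - e.S2) ** 2
                     + xi3 * (y[:, 1] - e.I1) ** 2
                     + xi4 * (y[:, 6] - e.I2) ** 2)
        per_rep[r] = np.trapezoid(integrand, t) / span
    se = per_rep.std(ddof=1) / math.sqrt(len(per_rep)) if len(per_rep) > 1 else 0.0
    return DeviationEstimate(estimate=float(per_rep.mean()),
                             standard_error=float(se),
                             per_replicate=per_rep,
                             window=(float(t[0]), float(t[-1])))
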