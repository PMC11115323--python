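# Methods

## The model

`crossinfo` simulates and analyses a ten-compartment model of two pieces of
information spreading simultaneously through two groups of an open
population.  Each group `k` has susceptibles `Sk` and disseminators `Ik`;
disseminators mutate into variant compartments (`M1`, `M4`: strong believers
of the original information; `M2`, `M3`: fusion of both), which are removed
into `R1`, `R2`.  New individuals enter at rates `B1`, `B2` and everyone
leaves at per-capita rate `mu`.  The deterministic dynamics are

    S1' = B1 - a11 S1 I1 - a12 S1 I2 - mu S1
    I1' = a11 S1 I1 + a12 S1 I2 - (b11 + b12 + mu) I1
    M1' = b11 I1 - (g11 + mu) M1        M2' = b12 I1 - (g12 + mu) M2
    R1' = g11 M1 + g12 M2 - mu R1

and symmetrically for group 2 (`a21`, `a22`, `b21`, `b22`, `g21`, `g22`).
`a11`, `a22` are within-group contact rates, `a12`, `a21` cross-group
("cross-dissemination") rates; all contact and mutation rates lie in
(0, 1].  Summing the ten equations gives the exact balance
`N' = B1 + B2 - mu N`, used throughout as a structural invariant.

The basic reproduction number is the closed form

    R0 = B1 B2 (a11 a22 - a12 a21) / (mu^2 (b11+b12+mu)(b21+b22+mu)).

It is returned signed: when cross contact dominates (`a12 a21 > a11 a22`)
the formula is negative, which the criteria report flags rather than
clamps.  `R0 < 1` sends the system to the information-free equilibrium
`(B1/mu, 0, ..., B2/mu, 0, ...)`; `R0 > 1` to an interior equilibrium E*.

E* has no closed form.  `find_endemic_equilibrium` solves the
four-dimensional `(S1, I1, S2, I2)` subsystem with a hybrid Powell root
finder, seeds it by default with the state reached after integrating to
t = 500 (robust and self-validating: the long-time integration and the
root must agree), and reconstructs the remaining compartments exactly via
`M* = b I*/(g + mu)`, `R* = g M*/mu`.  The residual of the full
ten-component field at the returned point is reported
(`residual_norm`, default tolerance 1e-9); a root with `I* < 1e-6` is
flagged `boundary` rather than treated as interior.

Deterministic integration uses classical fixed-step RK4 (default
dt = 0.01).  States are not clamped: the continuous system preserves
positivity, so an undershoot below -1e-9 raises an error instead of being
silently repaired.

## Stochastic dynamics

Environmental uncertainty perturbs the four contact and four mutation
rates with independent white noises: `a11 -> a11 + s1 dW1/dt`, ...,
`b22 -> b22 + s8 dW8/dt`.  The resulting Ito system carries each noise as
an antisymmetric flux between exactly two compartments (e.g.
`-s1 S1 I1 dW1` in S1 appears as `+s1 S1 I1 dW1` in I1); the removed
compartments carry no diffusion.  Paths are generated by Euler-Maruyama
with two boundary safeguards:

* **Boundary noise damping.**  Each step's diffusion vector is scaled by
  the largest factor `theta` in [0, 1] that keeps every compartment
  nonnegative.  Because the whole vector is scaled, the pairwise flux
  cancellation — and with it the exact balance law for N — survives, so
  the scheme cannot explode: N is bounded by `max(N0, (B1+B2)/mu)` along
  every path.  One-sided truncation alone lacks this property: clamping a
  source compartment at zero while its exchange partner keeps the full
  flux injects mass, and under strong noise that ratchet drives the
  discretisation to overflow.  Away from the boundary `theta = 1` and the
  update is the textbook EM step.
* **Truncation backstop.**  Residual negatives (drift undershoot,
  roundoff) are truncated to zero and counted; counts are reported in
  trajectory metadata as a discretisation-stress diagnostic.

Reproducibility: replicate `r` of an ensemble uses
`numpy.random.default_rng(base_seed + r)`; increments are drawn in step
chunks, which is stream-equivalent to drawing them all at once, so an
ensemble member is bit-identical to a single-path run with the same seed.

Step sizes must resolve the multiplicative noise: the scheme is faithful
when `sigma * S * sqrt(dt)` is well below 1.  The default dt = 0.01 is
ample for the weak-noise regimes (sigma around 1e-4); the strong-noise
extinction experiments use dt = 1e-3.

## Threshold criteria

Extinction: `limsup ln Ik(t)/t <= Gk` almost surely, with

    G1 = a11^2/(2 s1^2) + a12^2/(2 s2^2) - (b11 + b12 + mu + s5^2/2 + s6^2/2)

and symmetrically G2.  `G1 < 0` and `G2 < 0` imply exponential extinction
of both disseminator classes.  A zero contact rate contributes 0; a zero
sigma under a positive contact rate yields +inf with a flag (the
deterministic limit has no noise-driven extinction mechanism).  G is
strictly decreasing in each of its sigma^2 arguments, tested by finite
differences.

Stationary distribution: at an interior E*, with

    Gamma = s1^2 S1*^2 I1* + s2^2 S1*^2 I2*^2 + s3^2 S2*^2 I1*^2
            + (s5^2+s6^2)(I1*/2 + 2 I1*^2) + (s7^2+s8^2)(I2*/2 + 2 I2*^2)
    xi1 = 2 mu - s1^2 I1*              xi2 = 2 mu - s4^2 I2*
    xi3 = 2(b11 + b12 + mu - s5^2 - s6^2)
    xi4 = 2(b21 + b22 + mu - s7^2 - s8^2)

the condition `0 < Gamma < min(xi1 S1*^2, xi2 S2*^2, xi3 I1*^2, xi4 I2*^2)`
is sufficient for an ergodic stationary distribution, and the time-averaged
xi-weighted mean-square deviation of `(S1, S2, I1, I2)` from E* is bounded
by Gamma.  The mutant compartments do not enter this criterion.  Two
published forms of the constant differ by a `s4^2 S2*^2 I2*` term; the
default follows the stricter theorem-statement form and
`gamma_variant="plus_sigma4"` switches the larger one in for sensitivity
checks.

Empirical diagnostics close the loop with simulation.  The log-slope
diagnostic estimates `sup ln I(t)/t` over an ensemble; because a decaying
path's density underflows double precision long before large horizons
(the realised decay rate near the recovered susceptible level `S = B/mu`
is about `-sigma^2 S^2 / 2`, typically far steeper than G), the
`at="last_positive"` mode evaluates each replicate at its last positive
grid time.  The mean-square-deviation estimator integrates the weighted
squared deviations by the trapezoid rule per replicate and reports the
ensemble mean with its standard error.

Checking the deviation bound at a finite horizon requires starting the
ensemble at E*: the underlying Lyapunov inequality gives
`(1/t) E int <= Gamma + Theta(X0)/t` with `Theta(E*) = 0`, so from E* the
bound holds at every t, while from a generic start the transient term
dominates the (tiny) Gamma until impractically large horizons.

### A degenerate boundary of the cross-noise system

The cross-contact diffusions `s2 S1 I2 dW2` (into I1) and `s3 S2 I1 dW3`
(into I2) have amplitudes that do not vanish with the compartment they
feed.  At the `I1 = 0` boundary this noise keeps injecting mass, so with
strong cross intensities the dissemination is repeatedly re-excited — in
any positivity-preserving discretisation, and arguably in the continuous
system, whose global-positivity argument is silent on exactly this
degenerate boundary.  The packaged extinction experiment therefore places
the strong noise on the within-group rates, whose flux is proportional to
I and genuinely dies with it (sigma = (0.45, 0.02, 0.02, 0.7, 0, 0, 0, 0)
for the super-threshold rate set, giving G1 = -0.050, G2 = -0.057): under
that configuration all replicates are extinct by t = 1000 and the
log-slope bound holds with a wide margin.  The closed-form arithmetic of
G at the fully-noisy configuration (G1 = -0.1399955 at s1 = s2 = 1,
s5 = s6 = 0) is asserted separately as a formula check.

## Optimal control

The four contact rates become controls `a_ij(t)` in [0, 1], chosen to
maximise

    J = int_0^tf [ I1 + I2 - c1/2 a11^2 - c2/2 a12^2
                             - c3/2 a21^2 - c4/2 a22^2 ] dt

subject to the reduced `(S1, S2, I1, I2)` state system (the mutant and
removed classes do not feed back on transmission).  Pontryagin's principle
gives adjoints `d1..d4` with `d(tf) = 0` and the projected law
`a11* = clip((d1 - d3) S1 I1 / c1, 0, 1)` (symmetrically for the rest).
The adjoint system of the stochastic problem is a backward SDE whose
diffusion-adjoint components the theory leaves unconstructed; the solver
uses the standard certainty-equivalence treatment — those components set
to zero, deterministic backward integration along a deterministic forward
path — and the resulting control paths are then *evaluated* on the
stochastic state system in a pairwise-coupled comparison (identical
Brownian increments for the controlled and baseline arms).

The forward-backward sweep iterates forward RK4, backward RK4 and the
projected update with convex relaxation `new = (1 - w) old + w proposed`
(defaults w = 0.5, tolerance 1e-4 on the relative control change, at most
200 iterations, 1001-point grid).  The terminal control values are set to
the exact projection of the zero terminal adjoints, i.e. zero.  Two
oracles guard the solver: a brute-force grid search over constant
admissible controls (vectorised over all candidates) that the sweep must
beat within 1%, and the fixed-point property that one further sweep
iteration moves a converged solution by less than the tolerance.

Convention note: the objective is maximised while the Hamiltonian is
written in minimisation form (`-I1 - I2 + ...`); the implemented adjoint
drift and control law are the internally consistent pair that follows
from that convention.

## Reference scenarios and what the tests show

Two packaged parameter sets drive all experiments: `setA`
(weak contact, R0 = 0.0786) and `setB` (strong within-group contact,
R0 = 208.281); both use B1 = B2 = 1, mu = 0.1.  No initial compartment
values are canonical for these rates, so the fixtures start all
compartments at 0.5 with susceptibles at 10, and every report records the
initial state used.  Default noise intensities are 1e-4 throughout.

Problem sizes used by the test-suite experiments: 100-200 replicates,
horizons t = 1000-2000, dt = 0.01 for weak noise and 1e-3 for the
extinction scenario, states recorded every 0.5-1 time units.  These sizes
put three-standard-error Monte-Carlo slack well below the effects under
test.

The simulator generates its own data; nothing is fitted to external
observations.  Passing tests therefore demonstrate internal consistency —
scheme correctness, agreement between closed-form criteria and simulated
dynamics, dominance of the computed control — not that the model describes
any real information-spread dataset.  Real systems have network structure,
non-Gaussian and correlated shocks, and time-varying rates, all outside
this model class (as are Markov regime switching and Levy-jump noise
mechanisms).

## Known limitations

* Euler-Maruyama is strong order 1/2; no Milstein or higher-order scheme
  is provided, and step sizes must be chosen with `sigma S sqrt(dt) << 1`.
* The boundary damping is a discretisation device: near-degenerate states
  it reduces effective noise, which matters only in regimes (strong cross
  noise at the extinction boundary) where the continuous model itself is
  delicate.
* The sweep solves the certainty-equivalent control problem; no genuine
  backward-SDE solver (regression or deep-BSDE) is attempted.
* Jacobian-based stability classification of equilibria is not included;
  verdicts rest on the printed threshold quantities and simulation.
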