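# Methods

## Model

The S2EIR system tracks five population densities `(S, E1, E2, I, R)` in an
open system: immigration `B` into `S`, removal `mu` from every compartment,
and mass-action contact `alpha * S * I` between easy adopters and
transmitters. A fraction `m` of transmitters are authoritative "super
transmitters"; their influence is modelled by boosting the flow into the
strongly-receptive hesitant class `E1` to `alpha * (1+m) * S * I`, while
ordinary contacts feed the weakly-receptive carrier class `E2` at
`alpha * S * I`. `E1` adopts (`beta`), drifts to `E2` (`epsilon`) or drops
out (`gamma1`); `E2` drops out (`gamma2`); transmitters stop at `lam`.

Structural identities used throughout, and asserted in tests:

- mass balance: the field components sum to `B - mu*N`, `N = S+E1+E2+I+R`;
- the region `{x >= 0, N <= B/mu}` is positively invariant;
- `R0 = sqrt(B*alpha*beta*(1+m) / (mu*k1*k2))` with
  `k1 = beta+gamma1+epsilon+mu`, `k2 = lam+mu`, is the spectral radius of
  the next-generation matrix `F V^-1` on the `(E1, I)` block. The radical
  is genuine: `F V^-1` is anti-diagonal, so its spectral radius is the
  geometric mean of the two transmission pathways' gains. Both worked
  scenario values (0.681, 1.275) and the equilibrium relation
  `S* = B/(mu*R0^2)` confirm it.

### Parameters

| name | meaning | units | worked-scenario values |
|------|---------|-------|------------------------|
| B | immigration rate | indiv/time | 1 (set_A–C), 5 (set_D) |
| alpha | contact rate | 1/time | 0.2–0.8 |
| m | super-transmitter proportion | – | 0.3 (baseline 0.1 in control scenarios) |
| beta | adoption rate E1→I | 1/time | 0.6 (0.06–0.1 as control baseline) |
| epsilon | drift E1→E2 | 1/time | 0.2 |
| gamma1, gamma2 | drop-out rates | 1/time | 0.5, 0.7 |
| mu | removal rate | 1/time | 0.2–0.3 |
| lam | recovery rate I→R | 1/time | 0.2–0.4 |

`m` lies in `(0, 1]` for the uncontrolled model; when promoted to a control
the closed interval `[0, 1]` is admissible (`m_as_control` flag). The name
`lam` avoids Python's reserved `lambda`.

## Equilibria and stability

The information-free equilibrium is `E0 = (B/mu, 0, 0, 0, 0)`. For
`R0 > 1` the positive equilibrium is returned in closed form
(`S* = B/(mu R0^2)`, `I* = mu(R0^2-1)/(alpha(2+m))`, ...); the `R*`
component is not part of the standard closed-form set and is derived from
the steady-state balance of `R`: `R* = (lam*I* + gamma1*E1* +
gamma2*E2*)/mu`. Every returned equilibrium carries `max|rhs|` as a
residual diagnostic and is rejected above `1e-9`.

The Jacobian at `E0` has eigenvalues `-mu` (twice), `-(gamma2+mu)` and the
roots of `h^2 + (k1+k2)h + (1-R0^2)k1k2`. That quadratic's discriminant is
`(k1+k2)^2 - 4(1-R0^2)k1k2 >= (k1+k2)^2 - 4k1k2 >= 0` by AM–GM whenever
`R0 <= 1` (and trivially positive otherwise), so the spectrum at `E0` is
always real — there is no oscillatory approach to extinction in this model.

At `E*`, eliminating the two trivially stable directions leaves a cubic
whose coefficients are computed in the printed `R0`-form
(`a2 = k1+k2+mu*R0^2`, etc.); tests verify that its roots together with
`{-mu, -(gamma2+mu)}` reproduce the full numeric 5x5 spectrum.

Stability classification reports four boolean flags, each the *literal*
hypothesis of one sufficient condition:

- local stability of `E0`: `R0 < 1`;
- global stability of `E0`: `B*alpha*(2+m) <= mu^2`;
- local stability of `E*`: `R0 > 1` together with the auxiliary condition
  `mu^2*R0^4 > alpha*beta*(1+m)`;
- global stability of `E*`: `R0 > 1`.

Flags say "condition holds", never "system proven stable". Two gaps are
worth knowing: the global-E0 condition is much stricter than `R0 < 1` and
fails for the extinction worked scenario (0.46 > 0.09) even though
trajectories do converge to `E0` there; and the auxiliary local-E* proof
condition fails for the persistence worked scenario (0.238 < 0.39) even
though all four Routh–Hurwitz inequalities hold at its `E*`. Both gaps are
reported as-is. A condition within `1e-12` of its threshold is reported as
`None` (inconclusive): Routh–Hurwitz logic is strict-inequality logic, and
a boolean answer at the boundary would overstate what was checked.

## Integration

Classical fixed-step RK4, default `dt = 0.01`; horizons `tf = 50` for
control scenarios and `tf = 200` for asymptotic checks. Controls are
piecewise-constant per step (left grid value at substeps). States are not
clipped at zero: positivity is a property of the model, so a component
below `-1e-9` aborts integration as an integrator error rather than being
masked.

The adjoint system is integrated backward on the same grid. The adjoint
field needs `S` and `I` between grid nodes; these are reconstructed by
cubic Hermite interpolation using the model field at the nodes. Linear
interpolation would cap the backward scheme at second order; with Hermite
the measured Richardson order of the coupled forward–backward computation
is ~4.1 (forward alone ~4.05).

## Optimal control

`m(t)` and `beta(t)` in `[0,1]` maximise
`J = int_0^tf [E1 + I - (c1/2)m^2 - (c2/2)beta^2] dt`. The Hamiltonian is
implemented in the equivalent minimisation form (`-E1 - I + ...`); the
bound-constraint multipliers are eliminated by projection, which reproduces
the standard three-case analysis exactly. The adjoint system has zero
terminal conditions, and `delta5' = mu*delta5` makes the `R`-costate
identically zero.

The forward–backward sweep iterates: forward state RK4, backward adjoint
RK4, pointwise projected control update, relaxation
`u <- (1-w)u_old + w*u_new`. Defaults: `w = 0.5`, `tol = 1e-4` on the L1
relative change of controls and states, `max_iter = 200`, controls
initialised at zero. Non-convergence returns `converged=False` with the
change history instead of raising. A converged solution is a fixed point:
one extra sweep moves the controls by less than `10*tol`, which the suite
asserts.

Unprinted scenario settings are fixed once as package defaults: initial
state `(2, 0.5, 0.5, 0.5, 0.5)` (a small informed seed in a mostly
susceptible population inside the invariant region), `c1 = c2 = 1`,
`tf = 50`. The "middle" strategy is both controls constant at 0.5
(configurable); "single" strategies sweep one control with the other pinned
at its baseline; constant-strategy baselines are `m0 = 0.1` with
`beta0 = 0.1` (moderate scenario) or `beta0 = 0.06` (high-immigration
scenario). All strategy-comparison claims are orderings, not curve
reproductions, because the orderings are robust to these choices while the
curves are not.

### Comparing strategies on a finite horizon

With zero terminal adjoints the optimal controls necessarily roll off to
zero as `t -> tf`, so the tail of a finite-horizon optimal trajectory
reverts toward uncontrolled dynamics — a transversality boundary layer,
not a property of the steady regime. Settled-behaviour comparisons
(largest transmitter density, smallest carrier density under optimal
control) therefore use the plateau window `[0.4*tf, 0.9*tf]`: after the
initial transient, before the roll-off layer. Whole-horizon integrals are
used where the claim is cumulative (time-integrated `I`).

## Sensitivity

`dR0/dm` and `dR0/dbeta` are implemented twice — the full quotient-rule
expressions and the simplified forms `R0/(2(1+m))` and
`R0*(gamma1+epsilon+mu)/(2*beta*k1)` — and asserted equal at every call;
the suite additionally checks both against central finite differences of
`R0` (h = 1e-6, relative tolerance 1e-6, 1000 random draws). Both are
strictly positive on the whole valid domain: more authority and more
acceptance always widen transmission. The `(m, beta)` surface of `R0` is
discretely monotone along both axes with its maximum at `(1, 1)`.

## Synthetic scenarios and what tests do not show

There is no external data: the four bundled parameter sets are the worked
numerical scenarios, and random-draw property tests sample rates uniformly
from `[0.05, 1]` (B from `[0.1, 5]`). Passing tests therefore demonstrate
internal mathematical consistency — closed forms vs. numeric spectra,
analytic derivatives vs. finite differences, sweep fixed points vs. the
maximum principle — not that the model describes any particular empirical
information-transmission process. Mass-action contact, homogeneous mixing,
constant rates and a well-mixed (non-network) population are modelling
assumptions inherited with the model.

## Known limitations

- Fixed-step RK4 only; no adaptive or stiff integration (the model is
  non-stiff in the studied regimes).
- The FBSM is a first-order fixed-point method: convergence is not
  guaranteed for extreme weight/horizon combinations; the relaxation weight
  mitigates but does not eliminate oscillation.
- Stability flags evaluate printed sufficient conditions; no bifurcation
  continuation or center-manifold analysis at `R0 = 1`.
- Global sensitivity over all nine parameters is out of scope; only the
  two control parameters are analysed.
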