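"""Pontryagin optimal control of the super-transmitter fraction and adoption rate.

The proportion of super transmitters ``m`` and the adoption rate ``beta``
are promoted to time-varying controls ``m(t), beta(t)`` in [0, 1].  The
objective rewards circulating information while penalising control effort:

    J(m, beta) = int_0^tf [ E1 + I - (c1/2) m^2 - (c2/2) beta^2 ] dt,

maximised over the admissible set.  The Pontryagin optimality system couples
the state equations (forward, given initial data) with the adjoint
equations (backward, zero terminal conditions) through the projected
control laws

    m*(t)    = clip( (delta1 - delta2) * alpha * S * I / c1, 0, 1 )
    beta*(t) = clip( (delta2 - delta4) * E1 / c2, 0, 1 )

and is solved here by the forward-backward sweep method (FBSM) with
relaxed control updates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .integrate import Trajectory, integrate_adjoint_backward, integrate_forward
from .model import ControlPair, InvalidInputError, ModelParameters, rhs

__all__ = [
    "OCProblem",
    "OCSolution",
    "StrategyResult",
    "objective",
    "control_update",
    "hamiltonian",
    "forward_backward_sweep",
    "compare_strategies",
    "plateau_mean",
    "DEFAULT_INITIAL_STATE",
    "STRATEGY_NAMES",
    "PLATEAU_WINDOW",
]

#: fractional window of the horizon used when comparing strategies'
#: settled behaviour: after the initial transient, before the
#: transversality boundary layer in which optimal controls roll off to
#: zero (zero terminal adjoints force u*(tf) = 0, so the very end of a
#: finite-horizon optimal trajectory reverts toward uncontrolled dynamics)
PLATEAU_WINDOW = (0.4, 0.9)

#: default initial compartment densities for control scenarios
DEFAULT_INITIAL_STATE = (2.0, 0.5, 0.5, 0.5, 0.5)

STRATEGY_NAMES = ("optimal", "middle", "single_m", "single_beta", "constant")


@dataclass(frozen=True)
class OCProblem:
    """A discretised optimal-control problem.

    ``params.m`` and ``params.beta`` double as the baseline constants used
    by the uncontrolled / constant-control comparison strategies.  ``c1``
    and ``c2`` weight the quadratic effort costs of ``m(t)`` and
    ``beta(t)``; ``relaxation`` damps the sweep's control updates
    (``u <- (1-w) u_old + w u_new``); convergence is declared when the
    largest relative change of controls and states between sweeps drops
    below ``tol``.
    """

    params: ModelParameters
    initial: tuple[float, ...] = DEFAULT_INITIAL_STATE
    tf: float = 50.0
    dt: float = 0.01
    c1: float = 1.0
    c2: float = 1.0
    relaxation: float = 0.5
    tol: float = 1e-4
    max_iter: int = 200

    def __post_init__(self) -> None:
        if self.c1 <= 0 or self.c2 <= 0:
            raise InvalidInputError("weight coefficients c1, c2 must be > 0")
        if not (0.0 < self.relaxation <= 1.0):
            raise InvalidInputError("relaxation weight must lie in (0, 1]")
        if self.tol <= 0 or self.max_iter < 1:
            raise InvalidInputError("need tol > 0 and max_iter >= 1")


@dataclass(frozen=True)
class OCSolution:
    """FBSM output: aligned state/adjoint/control trajectories plus diagnostics."""

    state_traj: Trajectory
    adjoint_traj: np.ndarray
    control_traj: np.ndarray
    J: float
    iterations: int
    converged: bool
    history: list = field(default_factory=list)
    fixed_point_residual: float = float("nan")


@dataclass(frozen=True)
class StrategyResult:
    """One strategy's trajectory and objective in a comparison run."""

    name: str
    trajectory: Trajectory
    J: float
    solution: OCSolution | None = None


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def objective(traj: Trajectory, c1: float, c2: float) -> float:
    """Composite-trapezoid evaluation of J on the trajectory's own grid."""
    if traj.controls is None:
        raise InvalidInputError("objective requires a trajectory carrying controls")
    E1 = traj.states[:, 1]
    I = traj.states[:, 3]
    m = traj.controls[:, 0]
    b = traj.controls[:, 1]
    integrand = E1 + I - 0.5 * c1 * m * m - 0.5 * c2 * b * b
    return float(np.trapezoid(integrand, traj.times))


def control_update(
    state, adjoint, params: ModelParameters, c1: float, c2: float
) -> ControlPair:
    """Projected pointwise maximiser of the Hamiltonian.

    The unconstrained stationary values ``(delta1-delta2)*alpha*S*I/c1`` and
    ``(delta2-delta4)*E1/c2`` are clipped to the admissible interval [0, 1];
    the clipping reproduces exactly the case analysis that eliminates the
    bound-constraint multipliers.
    """
    S, E1, _, I, _ = np.asarray(state, dtype=float)
    d1, d2, _, d4, _ = np.asarray(adjoint, dtype=float)
    m_star = min(1.0, max(0.0, (d1 - d2) * params.alpha * S * I / c1))
    beta_star = min(1.0, max(0.0, (d2 - d4) * E1 / c2))
    return ControlPair(m_star, beta_star)


def hamiltonian(
    state,
    adjoint,
    control: ControlPair | tuple[float, float],
    params: ModelParameters,
    c1: float = 1.0,
    c2: float = 1.0,
) -> float:
    """Pontryagin Hamiltonian (minimisation form, bound multipliers omitted).

    ``H = -E1 - I + (c1/2) m^2 + (c2/2) beta^2 + delta . f(x, u)``.  At an
    interior optimal control, dH/dm = c1*m - (delta1-delta2)*alpha*S*I = 0
    and dH/dbeta = c2*beta - (delta2-delta4)*E1 = 0.
    """
    x = np.asarray(state, dtype=float)
    d = np.asarray(adjoint, dtype=float)
    if isinstance(control, ControlPair):
        m_t, beta_t = control.m_t, control.beta_t
    else:
        m_t, beta_t = control
    running = -x[1] - x[3] + 0.5 * c1 * m_t * m_t + 0.5 * c2 * beta_t * beta_t
    return float(running + d @ rhs(x, params, (m_t, beta_t)))


# ---------------------------------------------------------------------------
# forward-backward sweep
# ---------------------------------------------------------------------------

def _rel_change(new: np.ndarray, old: np.ndarray) -> float:
    """L1 relative change, Lenhart-style: ||new-old|| / max(||new||, eps)."""
    denom = max(float(np.abs(new).sum()), 1e-12)
    return float(np.abs(new - old).sum()) / denom


def forward_backward_sweep(
    problem: OCProblem,
    optimize: Sequence[str] = ("m", "beta"),
    fixed_controls: tuple[float, float] | None = None,
) -> OCSolution:
    """Solve the optimality system by relaxed forward-backward sweeps.

    Each iteration integrates the state system forward under the current
    control schedule, the adjoint system backward under the zero terminal
    condition, applies the projected control laws pointwise, and relaxes.
    ``optimize`` restricts which controls are updated (the other is pinned
    to its baseline from ``fixed_controls`` or ``problem.params``), which
    implements the single-control strategies.

    Never raises on non-convergence: exceeding ``max_iter`` returns
    ``converged=False`` with the per-iteration change history intact so
    callers can diagnose.
    """
    params = problem.params.with_controls_admissible()
    n = int(round(problem.tf / problem.dt))
    baseline = fixed_controls if fixed_controls is not None else (
        problem.params.m, problem.params.beta)
    update_m = "m" in optimize
    update_beta = "beta" in optimize

    u = np.zeros((n + 1, 2))
    if not update_m:
        u[:, 0] = baseline[0]
    if not update_beta:
        u[:, 1] = baseline[1]

    w = problem.relaxation
    history: list[float] = []
    states_prev: np.ndarray | None = None
    converged = False
    iterations = 0

    for iterations in range(1, problem.max_iter + 1):
        traj = integrate_forward(params, problem.initial, problem.tf,
                                 problem.dt, controls=u)
        adj = integrate_adjoint_backward(params, traj)

        u_new = u.copy()
        d1 = adj[:, 0]
        d2 = adj[:, 1]
        d4 = adj[:, 3]
        S = traj.states[:, 0]
        E1 = traj.states[:, 1]
        I = traj.states[:, 3]
        if update_m:
            u_new[:, 0] = np.clip((d1 - d2) * params.alpha * S * I / problem.c1,
                                  0.0, 1.0)
        if update_beta:
            u_new[:, 1] = np.clip((d2 - d4) * E1 / problem.c2, 0.0, 1.0)

        u_relaxed = (1.0 - w) * u + w * u_new
        change = _rel_change(u_relaxed, u)
        if states_prev is not None:
            change = max(change, _rel_change(traj.states, states_prev))
        history.append(change)
        u = u_relaxed
        states_prev = traj.states
        if change < problem.tol:
            converged = True
            break

    # evaluate the returned schedule on its own trajectory
    traj = integrate_forward(params, problem.initial, problem.tf, problem.dt,
                             controls=u)
    adj = integrate_adjoint_backward(params, traj)
    u_star = u.copy()
    if update_m:
        u_star[:, 0] = np.clip(
            (adj[:, 0] - adj[:, 1]) * params.alpha
            * traj.states[:, 0] * traj.states[:, 3] / problem.c1, 0.0, 1.0)
    if update_beta:
        u_star[:, 1] = np.clip(
            (adj[:, 1] - adj[:, 3]) * traj.states[:, 1] / problem.c2, 0.0, 1.0)
    residual = float(np.max(np.abs(u - u_star)))

    return OCSolution(
        state_traj=traj,
        adjoint_traj=adj,
        control_traj=u,
        J=objective(traj, problem.c1, problem.c2),
        iterations=iterations,
        converged=converged,
        history=history,
        fixed_point_residual=residual,
    )


# ---------------------------------------------------------------------------
# strategy comparison
# ---------------------------------------------------------------------------

def plateau_mean(
    traj: Trajectory,
    component: str,
    window: tuple[float, float] = PLATEAU_WINDOW,
) -> float:
    """Mean of one compartment over the settled fraction of the horizon."""
    t = traj.times
    lo, hi = window[0] * t[-1], window[1] * t[-1]
    mask = (t >= lo) & (t <= hi)
    return float(traj.component(component)[mask].mean())

def _constant_run(problem: OCProblem, m0: float, beta0: float) -> Trajectory:
    params = problem.params.with_controls_admissible()
    return integrate_forward(params, problem.initial, problem.tf, problem.dt,
                             controls=(m0, beta0))


def compare_strategies(
    problem: OCProblem,
    strategy_set: Sequence = STRATEGY_NAMES,
    middle: tuple[float, float] = (0.5, 0.5),
) -> Mapping[str, StrategyResult]:
    """Run a set of control strategies on identical initial data and horizon.

    Strategies: ``optimal`` (full sweep over both controls), ``single_m`` /
    ``single_beta`` (sweep over one control, the other pinned at its
    baseline from ``problem.params``), ``middle`` (both controls constant at
    ``middle``, 0.5 by default), ``constant`` (both at the baselines), or a
    ``("constant", m0, beta0)`` tuple for an explicit constant pair.
    """
    results: dict[str, StrategyResult] = {}
    for strat in strategy_set:
        if isinstance(strat, tuple) and strat and strat[0] == "constant":
            name = f"constant({strat[1]:g},{strat[2]:g})"
            traj = _constant_run(problem, float(strat[1]), float(strat[2]))
            results[name] = StrategyResult(name, traj,
                                           objective(traj, problem.c1, problem.c2))
            continue
        if strat == "optimal":
            sol = forward_backward_sweep(problem)
            results[strat] = StrategyResult(strat, sol.state_traj, sol.J, sol)
        elif strat == "single_m":
            sol = forward_backward_sweep(problem, optimize=("m",))
            results[strat] = StrategyResult(strat, sol.state_traj, sol.J, sol)
        elif strat == "single_beta":
            sol = forward_backward_sweep(problem, optimize=("beta",))
            results[strat] = StrategyResult(strat, sol.state_traj, sol.J, sol)
        elif strat == "middle":
            traj = _constant_run(problem, *middle)
            results[strat] = StrategyResult(strat, traj,
                                            objective(traj, problem.c1, problem.c2))
        elif strat == "constant":
            traj = _constant_run(problem, problem.params.m, problem.params.beta)
            results[strat] = StrategyResult(strat, traj,
                                            objective(traj, problem.c1, problem.c2))
        else:
            raise InvalidInputError(f"unknown strategy {strat!r}")
    return results
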