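"""Core S2EIR model: parameters, state, vector field, Lyapunov diagnostics.

The S2EIR model describes contact-based information transmission in an open
population with two "hesitant" compartments.  Easy adopters S are contacted
by transmitters I at rate ``alpha``; a fraction ``m`` of transmitters are
authoritative "super transmitters" that boost the effective contact rate into
the strongly-receptive hesitant class E1 to ``alpha*(1+m)``, while ordinary
contacts feed the weakly-receptive "asymptomatic carrier" class E2 at rate
``alpha``.  E1 individuals adopt and start transmitting at rate ``beta``,
drift to E2 at rate ``epsilon``, or drop out to R at rate ``gamma1``; E2
drops out at ``gamma2``; transmitters recover (stop transmitting) at
``lam``; every compartment is subject to removal at ``mu`` and the system
receives immigrants at rate ``B``.

State ordering throughout the package is ``(S, E1, E2, I, R)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ModelParameters",
    "ControlPair",
    "InvalidInputError",
    "rhs",
    "total_population",
    "lyapunov_L",
    "lyapunov_W",
]

#: absolute tolerance below which a trajectory component is considered to
#: have left the positive orthant (an integration error, not a model state)
POSITIVITY_TOL = 1e-9


class InvalidInputError(ValueError):
    """Raised when a state, parameter set or control violates its domain."""


# ---------------------------------------------------------------------------
# parameters and controls
# ---------------------------------------------------------------------------

#: rate parameters that must be strictly positive
_POSITIVE_FIELDS = ("B", "alpha", "beta", "epsilon", "gamma1", "gamma2", "mu", "lam")


@dataclass(frozen=True)
class ModelParameters:
    """The nine rate/proportion constants of the S2EIR system.

    Parameters
    ----------
    B : float
        Immigration rate into the susceptible class (individuals / time).
    alpha : float
        Transmission contact rate (1 / time).
    m : float
        Proportion of super transmitters.  In the uncontrolled model this is
        a constant in ``(0, 1]``; when the proportion is promoted to a
        control variable the closed interval ``[0, 1]`` is admissible, which
        is signalled with ``m_as_control=True``.
    beta : float
        Adoption rate E1 -> I (1 / time).
    epsilon : float
        Drift rate E1 -> E2 (1 / time).
    gamma1, gamma2 : float
        Drop-out rates E1 -> R and E2 -> R (1 / time).
    mu : float
        Removal rate acting on every compartment (1 / time).
    lam : float
        Recovery rate I -> R (1 / time).  Named ``lam`` because ``lambda``
        is reserved in Python; it is the model's λ.
    m_as_control : bool
        If true, ``m`` (and ``beta``) are treated as baseline values for a
        control problem and ``m = 0`` is admissible.
    """

    B: float
    alpha: float
    m: float
    beta: float
    epsilon: float
    gamma1: float
    gamma2: float
    mu: float
    lam: float
    m_as_control: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        problems = []
        for name in _POSITIVE_FIELDS:
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0.0:
                problems.append(f"{name} must be finite and > 0, got {value!r}")
        lo_open = not self.m_as_control
        if not np.isfinite(self.m) or self.m > 1.0 or self.m < 0.0 or (
            lo_open and self.m == 0.0
        ):
            interval = "(0, 1]" if lo_open else "[0, 1]"
            problems.append(f"m must lie in {interval}, got {self.m!r}")
        if problems:
            raise InvalidInputError("; ".join(problems))

    # frequently used aggregates ------------------------------------------------
    @property
    def k1(self) -> float:
        """Total outflow rate from E1: ``beta + gamma1 + epsilon + mu``."""
        return self.beta + self.gamma1 + self.epsilon + self.mu

    @property
    def k2(self) -> float:
        """Total outflow rate from I: ``lam + mu``."""
        return self.lam + self.mu

    def with_controls_admissible(self) -> "ModelParameters":
        """Return a copy flagged for the control regime (``m`` in [0, 1])."""
        return replace(self, m_as_control=True)


@dataclass(frozen=True)
class ControlPair:
    """A point value of the control pair ``(m(t), beta(t))``, each in [0, 1]."""

    m_t: float
    beta_t: float

    def __post_init__(self) -> None:
        for name, v in (("m_t", self.m_t), ("beta_t", self.beta_t)):
            if not np.isfinite(v) or not (0.0 <= v <= 1.0):
                raise InvalidInputError(f"{name} must lie in [0, 1], got {v!r}")

    @classmethod
    def from_params(cls, params: ModelParameters) -> "ControlPair":
        """Degenerate constant control reproducing the uncontrolled system."""
        return cls(params.m, params.beta)


# ---------------------------------------------------------------------------
# vector field
# ---------------------------------------------------------------------------

def _as_state(state: Sequence[float]) -> np.ndarray:
    arr = np.asarray(state, dtype=float)
    if arr.shape != (5,):
        raise InvalidInputError(f"state must have 5 components, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"state must be finite, got {arr!r}")
    return arr


def total_population(state: Sequence[float]) -> float:
    """N = S + E1 + E2 + I + R."""
    return float(np.sum(_as_state(state)))


def rhs(
    state: Sequence[float],
    params: ModelParameters,
    control: ControlPair | tuple[float, float] | None = None,
) -> np.ndarray:
    """Evaluate the S2EIR vector field at ``state``.

    With ``control=None`` the constant parameters ``(params.m, params.beta)``
    are used, which is the uncontrolled system; a :class:`ControlPair` (or a
    plain ``(m_t, beta_t)`` tuple, useful inside integrators) substitutes
    time-varying controls into the same field.

    Returns
    -------
    numpy.ndarray
        ``(dS, dE1, dE2, dI, dR)``.  The components always sum to
        ``B - mu * N`` (mass balance), an algebraic identity of the model.
    """
    S, E1, E2, I, R = _as_state(state)
    if control is None:
        m_t, beta_t = params.m, params.beta
    elif isinstance(control, ControlPair):
        m_t, beta_t = control.m_t, control.beta_t
    else:
        m_t, beta_t = control

    a, mu = params.alpha, params.mu
    super_flow = a * (1.0 + m_t) * S * I   # S -> E1, boosted by super transmitters
    plain_flow = a * S * I                 # S -> E2, ordinary contacts

    dS = params.B - super_flow - plain_flow - mu * S
    dE1 = super_flow - (beta_t + params.gamma1 + params.epsilon + mu) * E1
    dE2 = plain_flow + params.epsilon * E1 - (params.gamma2 + mu) * E2
    dI = beta_t * E1 - (params.lam + mu) * I
    dR = params.lam * I + params.gamma1 * E1 + params.gamma2 * E2 - mu * R
    return np.array([dS, dE1, dE2, dI, dR])


# ---------------------------------------------------------------------------
# Lyapunov diagnostics
# ---------------------------------------------------------------------------

def lyapunov_L(state: Sequence[float]) -> float:
    """Information mass ``L = E1 + E2 + I + R``.

    When ``B*alpha*(2+m) <= mu**2`` this is a Lyapunov function for the
    information-free equilibrium: along trajectories inside the invariant
    region ``N <= B/mu`` its derivative satisfies
    ``L' <= [alpha*(2+m)*S - mu]*I - mu*(E1+E2+R) <= 0``.
    """
    arr = _as_state(state)
    return float(arr[1:].sum())


def lyapunov_W(state: Sequence[float], eq_state: Sequence[float]) -> float:
    """Squared total deviation from an equilibrium.

    ``W = [(S-S*) + (E1-E1*) + (E2-E2*) + (I-I*) + (R-R*)]**2``, i.e. the
    squared deviation of the total population from its equilibrium value.
    Along any trajectory ``W' = -2*mu*(N - N*)**2 <= 0``, which drives the
    global-stability argument for the information-existence equilibrium.
    Deviations of opposite sign in different compartments cancel inside the
    square; only the population total matters.
    """
    eq = getattr(eq_state, "state", eq_state)  # accept an EquilibriumPoint
    diff = total_population(state) - total_population(eq)
    return float(diff * diff)
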