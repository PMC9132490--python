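"""Equilibria, basic reproduction number and stability classification.

The threshold quantity is the basic reproduction number

    R0 = sqrt( B*alpha*beta*(1+m) / (mu*(beta+gamma1+epsilon+mu)*(lam+mu)) ),

the spectral radius of the next-generation matrix F V^-1 built from the two
transmission-related compartments (E1, I) and evaluated at the
information-free equilibrium S = B/mu.  For R0 < 1 the information-free
equilibrium E0 = (B/mu, 0, 0, 0, 0) is locally asymptotically stable; for
R0 > 1 a unique positive information-existence equilibrium E* exists in
closed form and the classical sufficient conditions (Routh-Hurwitz on the
reduced cubic, Lyapunov arguments) for its stability can be evaluated.

Every theorem flag reported here is "the printed sufficient condition
holds", evaluated literally — never a stronger claim of stability.
Conditions within ``BOUNDARY_TOL`` of their threshold are reported as
``None`` (inconclusive), because Routh-Hurwitz logic is strict-inequality
logic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ControlPair, InvalidInputError, ModelParameters, rhs

__all__ = [
    "EquilibriumPoint",
    "StabilityReport",
    "NoSuchEquilibriumError",
    "next_generation_matrices",
    "basic_reproduction_number",
    "information_free_equilibrium",
    "information_existence_equilibrium",
    "jacobian",
    "eigenvalues_at_E0",
    "routh_hurwitz",
    "classify_stability",
]

#: a theorem condition closer than this to its threshold is inconclusive
BOUNDARY_TOL = 1e-12

#: maximum rhs residual accepted for a returned equilibrium
RESIDUAL_TOL = 1e-9


class NoSuchEquilibriumError(ValueError):
    """The requested equilibrium does not exist for these parameters."""


@dataclass(frozen=True)
class EquilibriumPoint:
    """An equilibrium of the S2EIR system with a residual diagnostic.

    ``residual`` is ``max|rhs|`` at the returned state — a direct numerical
    check that the closed-form expressions solve the steady-state equations.
    """

    kind: str  # "information_free" | "information_existence"
    state: np.ndarray
    residual: float


@dataclass(frozen=True)
class StabilityReport:
    """R0, characteristic-polynomial data and theorem-condition flags.

    Flags are ``True``/``False`` for a condition that clearly holds/fails
    and ``None`` when it sits within :data:`BOUNDARY_TOL` of its threshold.
    ``a3..a0`` and ``hurwitz_margin`` (``a2*a1 - a3*a0``) are only defined
    when R0 > 1 and are ``None`` otherwise.
    """

    R0: float
    a3: float | None
    a2: float | None
    a1: float | None
    a0: float | None
    hurwitz_margin: float | None
    lambda01: complex
    lambda02: complex
    lambda03: complex
    lambda04: complex
    lambda05: complex
    thm31_local_E0: bool | None
    thm32_global_E0: bool | None
    thm33_local_Estar: bool | None
    thm34_global_Estar: bool | None

    def to_dict(self) -> dict:
        def _num(v):
            if v is None:
                return None
            if isinstance(v, complex):
                return {"re": v.real, "im": v.imag}
            return float(v)

        return {
            "R0": self.R0,
            "a3": _num(self.a3),
            "a2": _num(self.a2),
            "a1": _num(self.a1),
            "a0": _num(self.a0),
            "hurwitz_margin": _num(self.hurwitz_margin),
            "eigenvalues_E0": [
                _num(getattr(self, f"lambda0{i}")) for i in range(1, 6)
            ],
            "thm31_local_E0": self.thm31_local_E0,
            "thm32_global_E0": self.thm32_global_E0,
            "thm33_local_Estar": self.thm33_local_Estar,
            "thm34_global_Estar": self.thm34_global_Estar,
        }


def _strict(value: float, threshold: float = 0.0, sense: str = ">") -> bool | None:
    """Strict comparison with an inconclusive band around the threshold."""
    if abs(value - threshold) < BOUNDARY_TOL:
        return None
    return value > threshold if sense == ">" else value < threshold


# ---------------------------------------------------------------------------
# next-generation matrix and R0
# ---------------------------------------------------------------------------

def next_generation_matrices(
    params: ModelParameters, S_at_dfe: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Infection matrix F and transition matrix V on the (E1, I) block.

    Linearising the new-transmission and transition flows at the
    information-free equilibrium (``S = B/mu`` unless overridden) gives

        F = [[0, alpha*(1+m)*S], [beta, 0]],
        V = diag(beta+gamma1+epsilon+mu, lam+mu).
    """
    S = params.B / params.mu if S_at_dfe is None else float(S_at_dfe)
    if S <= 0:
        raise InvalidInputError(f"S at the disease-free equilibrium must be > 0, got {S}")
    F = np.array([[0.0, params.alpha * (1.0 + params.m) * S], [params.beta, 0.0]])
    V = np.diag([params.k1, params.k2])
    return F, V


def basic_reproduction_number(params: ModelParameters) -> float:
    """Spectral radius of F V^-1 at S = B/mu, in closed form.

    F V^-1 is anti-diagonal, so its spectral radius is the geometric mean of
    the off-diagonal entries:
    ``sqrt(B*alpha*beta*(1+m) / (mu*k1*k2))``.
    """
    return float(
        np.sqrt(
            params.B
            * params.alpha
            * params.beta
            * (1.0 + params.m)
            / (params.mu * params.k1 * params.k2)
        )
    )


# ---------------------------------------------------------------------------
# equilibria
# ---------------------------------------------------------------------------

def information_free_equilibrium(params: ModelParameters) -> EquilibriumPoint:
    """E0 = (B/mu, 0, 0, 0, 0); always exists."""
    state = np.array([params.B / params.mu, 0.0, 0.0, 0.0, 0.0])
    residual = float(np.max(np.abs(rhs(state, params))))
    return EquilibriumPoint("information_free", state, residual)


def information_existence_equilibrium(params: ModelParameters) -> EquilibriumPoint:
    """Closed-form positive equilibrium E*; requires R0 > 1.

    With ``k1 = beta+gamma1+epsilon+mu``, ``k2 = lam+mu``:

        S*  = B / (mu * R0^2)
        E1* = B*(1+m)*(R0^2 - 1) / ((2+m)*k1*R0^2)
        E2* = B*(R0^2 - 1)*(k1 + epsilon*(1+m)) / ((2+m)*(gamma2+mu)*k1*R0^2)
        I*  = mu*(R0^2 - 1) / (alpha*(2+m))
        R*  = (lam*I* + gamma1*E1* + gamma2*E2*) / mu

    R* follows from the steady-state balance of the R compartment.
    """
    R0 = basic_reproduction_number(params)
    if R0 <= 1.0:
        raise NoSuchEquilibriumError(
            f"information-existence equilibrium requires R0 > 1, got R0 = {R0:.6g}"
        )
    R0sq = R0 * R0
    two_m = 2.0 + params.m
    k1 = params.k1
    excess = R0sq - 1.0

    S = params.B / (params.mu * R0sq)
    E1 = params.B * (1.0 + params.m) * excess / (two_m * k1 * R0sq)
    E2 = (
        params.B
        * excess
        * (k1 + params.epsilon * (1.0 + params.m))
        / (two_m * (params.gamma2 + params.mu) * k1 * R0sq)
    )
    I = params.mu * excess / (params.alpha * two_m)
    R = (params.lam * I + params.gamma1 * E1 + params.gamma2 * E2) / params.mu

    state = np.array([S, E1, E2, I, R])
    residual = float(np.max(np.abs(rhs(state, params))))
    if residual >= RESIDUAL_TOL:
        raise InvalidInputError(
            f"closed-form equilibrium residual {residual:.3g} exceeds {RESIDUAL_TOL}"
        )
    return EquilibriumPoint("information_existence", state, residual)


# ---------------------------------------------------------------------------
# Jacobian and spectra
# ---------------------------------------------------------------------------

def jacobian(
    params: ModelParameters,
    state,
    control: ControlPair | tuple[float, float] | None = None,
) -> np.ndarray:
    """Analytic 5x5 Jacobian of the vector field at ``state``.

    State ordering (S, E1, E2, I, R).  At E0 the matrix reduces to the
    block-triangular form whose nontrivial part is the 2x2 (E1, I) block;
    at E* it carries the extra -alpha*(2+m)*I* terms in the first column.
    """
    S, _, _, I, _ = np.asarray(state, dtype=float)
    if control is None:
        m_t, beta_t = params.m, params.beta
    elif isinstance(control, ControlPair):
        m_t, beta_t = control.m_t, control.beta_t
    else:
        m_t, beta_t = control
    a, mu = params.alpha, params.mu
    k1 = beta_t + params.gamma1 + params.epsilon + mu
    J = np.zeros((5, 5))
    J[0, 0] = -a * (2.0 + m_t) * I - mu
    J[0, 3] = -a * (2.0 + m_t) * S
    J[1, 0] = a * (1.0 + m_t) * I
    J[1, 1] = -k1
    J[1, 3] = a * (1.0 + m_t) * S
    J[2, 0] = a * I
    J[2, 1] = params.epsilon
    J[2, 2] = -(params.gamma2 + mu)
    J[2, 3] = a * S
    J[3, 1] = beta_t
    J[3, 3] = -params.k2
    J[4, 1] = params.gamma1
    J[4, 2] = params.gamma2
    J[4, 3] = params.lam
    J[4, 4] = -mu
    return J


def eigenvalues_at_E0(params: ModelParameters) -> np.ndarray:
    """Closed-form spectrum of the Jacobian at the information-free equilibrium.

    Three eigenvalues are immediate: -mu (twice) and -(gamma2+mu).  The
    remaining pair solves the quadratic of the (E1, I) block,

        h^2 + (k1+k2) h + (1 - R0^2) k1 k2 = 0,

    giving ``(-(k1+k2) +/- sqrt((k1+k2)^2 - 4*(1-R0^2)*k1*k2)) / 2``.
    Both have negative real part exactly when R0 < 1.
    """
    k1, k2 = params.k1, params.k2
    R0 = basic_reproduction_number(params)
    trace = k1 + k2
    disc = trace * trace - 4.0 * (1.0 - R0 * R0) * k1 * k2
    sqrt_disc = np.sqrt(complex(disc))
    lam04 = (-trace + sqrt_disc) / 2.0
    lam05 = (-trace - sqrt_disc) / 2.0
    return np.array(
        [-params.mu, -params.mu, -(params.gamma2 + params.mu), lam04, lam05],
        dtype=complex,
    )


def routh_hurwitz(params: ModelParameters) -> dict[str, float]:
    """Coefficients of the reduced cubic at E* and the Hurwitz margin.

    Eliminating the two trivially stable directions (-mu and -(gamma2+mu))
    at the information-existence equilibrium leaves a cubic
    ``a3 h^3 + a2 h^2 + a1 h + a0`` with

        a3 = 1
        a2 = k1 + k2 + mu*R0^2
        a1 = k1*k2 + (k1+k2)*mu*R0^2 - B*alpha*beta*(1+m)/(mu*R0^2)
        a0 = k1*k2*mu*R0^2 - B*alpha*beta*(1+m)/R0^2

    and Hurwitz margin ``a2*a1 - a3*a0``.  All roots of the cubic have
    negative real part iff a2, a1, a0 > 0 and the margin is > 0.
    Only defined for R0 > 1.
    """
    R0 = basic_reproduction_number(params)
    if R0 <= 1.0:
        raise NoSuchEquilibriumError(
            f"Routh-Hurwitz analysis of E* requires R0 > 1, got R0 = {R0:.6g}"
        )
    k1, k2, mu = params.k1, params.k2, params.mu
    R0sq = R0 * R0
    babm = params.B * params.alpha * params.beta * (1.0 + params.m)
    s = k1 + k2
    a3 = 1.0
    a2 = s + mu * R0sq
    a1 = k1 * k2 + s * mu * R0sq - babm / (mu * R0sq)
    a0 = k1 * k2 * mu * R0sq - babm / R0sq
    margin = (
        k1 * k2 * s
        + s * s * mu * R0sq
        + s * mu * mu * R0sq * R0sq
        + babm / R0sq
        - babm * s / (mu * R0sq)
        - babm
    )
    return {"a3": a3, "a2": a2, "a1": a1, "a0": a0, "hurwitz_margin": margin}


def classify_stability(params: ModelParameters) -> StabilityReport:
    """Evaluate every theorem hypothesis literally and assemble the report.

    - local stability of E0: R0 < 1
    - global stability of E0: B*alpha*(2+m) <= mu^2
    - local stability of E*: R0 > 1 together with the auxiliary proof
      condition mu^2*R0^4 > alpha*beta*(1+m)
    - global stability of E*: R0 > 1
    """
    R0 = basic_reproduction_number(params)
    eig = eigenvalues_at_E0(params)

    thm31 = _strict(R0, 1.0, "<")
    thm32 = _strict(
        params.mu**2 - params.B * params.alpha * (2.0 + params.m), 0.0, ">"
    )
    # Thm 3.2's condition is non-strict (<=); boundary still inconclusive
    r0_above = _strict(R0, 1.0, ">")
    aux = _strict(
        params.mu**2 * R0**4 - params.alpha * params.beta * (1.0 + params.m),
        0.0,
        ">",
    )
    if r0_above is None or (r0_above and aux is None):
        thm33 = None
    else:
        thm33 = bool(r0_above and aux)
    thm34 = r0_above

    if r0_above:
        rh = routh_hurwitz(params)
    else:
        rh = {k: None for k in ("a3", "a2", "a1", "a0", "hurwitz_margin")}

    return StabilityReport(
        R0=R0,
        a3=rh["a3"],
        a2=rh["a2"],
        a1=rh["a1"],
        a0=rh["a0"],
        hurwitz_margin=rh["hurwitz_margin"],
        lambda01=complex(eig[0]),
        lambda02=complex(eig[1]),
        lambda03=complex(eig[2]),
        lambda04=complex(eig[3]),
        lambda05=complex(eig[4]),
        thm31_local_E0=thm31,
        thm32_global_E0=thm32,
        thm33_local_Estar=thm33,
        thm34_global_Estar=thm34,
    )
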