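"""Sensitivity of the basic reproduction number to the control parameters.

Both partial derivatives of R0 = sqrt(B*alpha*beta*(1+m) / (mu*k1*k2))
with respect to the super-transmitter proportion m and the adoption rate
beta are strictly positive: more authoritative transmitters and higher
individual acceptance both widen the transmission range.  Each derivative
is implemented twice — the full quotient-rule expression and an
algebraically simplified closed form — and the two are asserted to agree at
every call, which guards against transcription slips; the test suite
additionally checks both against central finite differences of R0 itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import InvalidInputError, ModelParameters
from .stability import basic_reproduction_number

__all__ = ["SensitivityGrid", "dR0_dm", "dR0_dbeta", "sensitivity_surface"]

_AGREE_RTOL = 1e-9


@dataclass(frozen=True)
class SensitivityGrid:
    """R0 and its partial derivatives tabulated over an (m, beta) grid.

    ``R0_surface[i, j]`` corresponds to ``m_values[i]``, ``beta_values[j]``.
    """

    m_values: np.ndarray
    beta_values: np.ndarray
    R0_surface: np.ndarray
    dR0_dm_surface: np.ndarray
    dR0_dbeta_surface: np.ndarray


def _uv(params: ModelParameters) -> tuple[float, float]:
    """Numerator and denominator of R0^2."""
    u = params.B * params.alpha * params.beta * (1.0 + params.m)
    v = params.mu * params.k1 * params.k2
    return u, v


def dR0_dm(params: ModelParameters) -> float:
    """dR0/dm = B*alpha*beta / (2*sqrt(u*v)), equivalently R0 / (2*(1+m))."""
    u, v = _uv(params)
    full = params.B * params.alpha * params.beta / (2.0 * np.sqrt(u * v))
    simplified = basic_reproduction_number(params) / (2.0 * (1.0 + params.m))
    if not np.isclose(full, simplified, rtol=_AGREE_RTOL):
        raise AssertionError(
            f"dR0/dm forms disagree: {full!r} vs {simplified!r}"
        )
    return float(simplified)


def dR0_dbeta(params: ModelParameters) -> float:
    """dR0/dbeta via the quotient rule, equivalently
    R0*(gamma1+epsilon+mu) / (2*beta*k1).

    The quotient-rule numerator is B*alpha*(1+m)*mu*(gamma1+epsilon+mu)*k2:
    raising beta feeds I faster but also shortens the E1 residence time, and
    only the (gamma1+epsilon+mu) part of the E1 outflow survives the
    cancellation, so the derivative decays to zero as beta grows.
    """
    u, v = _uv(params)
    g = params.gamma1 + params.epsilon + params.mu
    num = params.B * params.alpha * (1.0 + params.m) * params.mu * g * params.k2
    full = num / (2.0 * v * np.sqrt(u * v))
    simplified = (
        basic_reproduction_number(params) * g / (2.0 * params.beta * params.k1)
    )
    if not np.isclose(full, simplified, rtol=_AGREE_RTOL):
        raise AssertionError(
            f"dR0/dbeta forms disagree: {full!r} vs {simplified!r}"
        )
    return float(simplified)


def sensitivity_surface(
    params: ModelParameters, m_grid, beta_grid
) -> SensitivityGrid:
    """Evaluate R0 and its (m, beta) gradient over a rectangular grid.

    The surface is strictly increasing along both axes for any valid
    parameter set, with its maximum at ``(m, beta) = (1, 1)``.
    """
    m_values = np.atleast_1d(np.asarray(m_grid, dtype=float))
    beta_values = np.atleast_1d(np.asarray(beta_grid, dtype=float))
    if m_values.size == 0 or beta_values.size == 0:
        raise InvalidInputError("sensitivity grid must be non-empty")
    for name, vals in (("m", m_values), ("beta", beta_values)):
        if np.any(vals <= 0.0) or np.any(vals > 1.0):
            raise InvalidInputError(f"{name} grid values must lie in (0, 1]")

    from dataclasses import replace

    shape = (m_values.size, beta_values.size)
    R0 = np.empty(shape)
    dm = np.empty(shape)
    db = np.empty(shape)
    for i, m in enumerate(m_values):
        for j, b in enumerate(beta_values):
            p = replace(params, m=float(m), beta=float(b))
            R0[i, j] = basic_reproduction_number(p)
            dm[i, j] = dR0_dm(p)
            db[i, j] = dR0_dbeta(p)
    return SensitivityGrid(m_values, beta_values, R0, dm, db)
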