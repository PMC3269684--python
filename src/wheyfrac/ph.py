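"""Empirical pH model of CO2-saturated WPI solutions.

Dissolved CO2 forms carbonic acid; at saturation the pH of a WPI solution is
well described by an empirical fit

    pH = s * ln(P_psi) + f(C)

with s = -0.25 pH units per ln(psi) and f a cubic in the WPI concentration C
(wt%), calibrated at 60 degC over 0.5-13.8 MPa and extrapolated in pressure.
The fit is concentration-valid for C = 1-28 wt%.  This is an empirical
correlation, not a carbonic-acid speciation model.

Pressures are accepted in MPa and converted internally (1 MPa = 145.038 psi).
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

from .errors import UnreachablePHError, ValidationError
from .types import round_half_away

logger = logging.getLogger(__name__)

#: Unit conversion applied to all pressures before taking the logarithm.
PSI_PER_MPA = 145.038

#: Maximum modelled operating pressure, MPa.
P_MAX_MPA = 34.0


@dataclass(frozen=True)
class PHModelParams:
    """Calibrated coefficients: slope of ln(P_psi) and cubic in C (high to low)."""

    slope: float = -0.25
    poly_coeffs: tuple[float, float, float, float] = (3.73e-5, -2.59e-3, 7.33e-2, 6.16)

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValidationError("slope must be negative (pH falls with pressure)")


DEFAULT_PARAMS = PHModelParams()


def _warn_concentration(C_wpi: float) -> None:
    if C_wpi < 0:
        raise ValidationError(f"C_wpi must be non-negative, got {C_wpi}")
    if not (1.0 <= C_wpi <= 28.0):
        warnings.warn(
            f"C_wpi={C_wpi} wt% outside the 1-28 wt% calibration range",
            stacklevel=3,
        )


def f_of_c(C_wpi: float, params: PHModelParams = DEFAULT_PARAMS) -> float:
    """Concentration term f(C): cubic in WPI concentration (wt%)."""
    _warn_concentration(C_wpi)
    a3, a2, a1, a0 = params.poly_coeffs
    return ((a3 * C_wpi + a2) * C_wpi + a1) * C_wpi + a0


def ph_at(
    P: float,
    C_wpi: float,
    T: float = 60.0,
    params: PHModelParams = DEFAULT_PARAMS,
) -> float:
    """Equilibrium pH of a CO2-saturated WPI solution at ``P`` MPa, ``C`` wt%.

    ``T`` is accepted for interface symmetry but unused: the correlation was
    calibrated at 60 degC and carries no temperature term.  Returns the full-
    precision value; use :func:`ph_rounded` for the 1-decimal convention of
    the experiment table.
    """
    if P <= 0:
        raise ValidationError(f"P must be positive, got {P} MPa")
    if T != 60.0:
        logger.info("pH model is calibrated at 60 degC; T=%s has no effect", T)
    return params.slope * math.log(P * PSI_PER_MPA) + f_of_c(C_wpi, params)


def ph_rounded(P: float, C_wpi: float, T: float = 60.0,
               params: PHModelParams = DEFAULT_PARAMS) -> float:
    """pH rounded to 1 decimal, ties away from zero (reported-table convention)."""
    return round_half_away(ph_at(P, C_wpi, T, params), 1)


def pressure_for_ph(
    target_ph: float,
    C_wpi: float,
    params: PHModelParams = DEFAULT_PARAMS,
    p_max: float = P_MAX_MPA,
) -> float:
    """Closed-form inversion: pressure (MPa) giving ``target_ph`` at ``C_wpi``.

    Raises :class:`UnreachablePHError` when no pressure in (0, ``p_max``]
    attains the target, reporting the attainable pH range.
    """
    ln_p_psi = (target_ph - f_of_c(C_wpi, params)) / params.slope
    P = math.exp(ln_p_psi) / PSI_PER_MPA
    if 0.0 < P <= p_max * (1.0 + 1e-12):
        return min(P, p_max)  # absorb exp/log round-off at the boundary
    if not (0.0 < P <= p_max):
        ph_min = ph_at(p_max, C_wpi, params=params)
        raise UnreachablePHError(
            f"pH {target_ph} unreachable at C={C_wpi} wt%: attainable range is "
            f"[{ph_min:.3f}, inf) for P in (0, {p_max}] MPa"
        )
    return P
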