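"""De-foaming tank sizing, foam regime and centrifuge selection.

On depressurization the CO2-saturated liquor leaves the reactor as a dense
foam (density ~0.1 kg/L below 14 MPa).  The de-foaming tank must hold the
incoming foam while its liquid drains, so its minimum working volume is the
foam volumetric inflow divided by the drainage rate:

    V_tank = (W_liq / 60) / (d_foam * r_drainage)      [L, with W_liq kg/h]

The corresponding liquid residence time is the tank volume over the liquid
volumetric flow, which reduces to t_s = d_liq / (r_drainage * d_foam).
A literal transcription of the source relation (d_foam / d_liq in the
numerator) is dimensionally inconsistent with its own reported 25-minute
result and is kept only behind ``literal=True`` for comparison.
"""
from __future__ import annotations

from dataclasses import dataclass

from .errors import UnsupportedConcentrationError, ValidationError
from .types import FoamProperties


@dataclass(frozen=True)
class TankSpec:
    """De-foaming tank design point."""

    V_tank: float      # working volume, L
    t_s: float         # liquid residence time, min
    W_liq: float       # liquid mass inflow, kg/h
    regime: str        # 'foamed' or 'collapsed'


def foam_regime(P: float, foam: FoamProperties = FoamProperties()) -> str:
    """Foam regime at extraction: 'foamed' at or below the collapse pressure.

    Above ~14 MPa the foam self-collapses during extraction (excess shear and
    cell size), so no stable foam reaches the tank.  A de-foaming tank is
    nonetheless always present in the plant design and costing.
    """
    if P <= 0:
        raise ValidationError("P must be positive")
    return "foamed" if P <= foam.collapse_pressure else "collapsed"


def defoaming_tank_volume(W_liq: float, foam: FoamProperties = FoamProperties()) -> float:
    """Minimum de-foaming tank volume (L) for a liquid inflow of ``W_liq`` kg/h."""
    if W_liq <= 0:
        raise ValidationError("W_liq must be positive")
    return (W_liq / 60.0) / (foam.d_foam * foam.r_drainage)


def residence_time(foam: FoamProperties = FoamProperties(),
                   literal: bool = False) -> float:
    """Liquid residence time (min) of the minimum-volume de-foaming tank.

    ``literal=True`` evaluates the inconsistent as-published form
    (1/r) * (d_foam/d_liq) instead of the volume-over-flow identity.
    """
    if literal:
        return (1.0 / foam.r_drainage) * (foam.d_foam / foam.d_liq)
    return foam.d_liq / (foam.r_drainage * foam.d_foam)


def tank_spec(W_liq: float, P: float,
              foam: FoamProperties = FoamProperties()) -> TankSpec:
    """Size the de-foaming tank for one operating point."""
    return TankSpec(
        V_tank=defoaming_tank_volume(W_liq, foam),
        t_s=residence_time(foam),
        W_liq=W_liq,
        regime=foam_regime(P, foam),
    )


def select_centrifuge_g(C_wpi: float) -> float:
    """Design centrifugal force (multiples of g) for solid/liquid separation.

    Solid compaction of the precipitate plateaus by 8000-10,000 g for 5% and
    10% WPI feeds; 10,000 g is returned as the design point.  Above 10% no
    compaction plateau was reached up to 20,000 g, so no supported selection
    exists and an error is raised.
    """
    if C_wpi <= 0:
        raise ValidationError("C_wpi must be positive")
    if C_wpi > 10.0:
        raise UnsupportedConcentrationError(
            f"no validated centrifuge force for C_wpi={C_wpi} wt%: compaction "
            "showed no plateau up to 20,000 g above 10 wt%"
        )
    return 10_000.0
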