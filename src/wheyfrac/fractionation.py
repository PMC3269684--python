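"""Recovery and purity arithmetic plus lookup/interpolation over the grid.

The central identity: the recovery of protein k in the dry precipitate is

    rec_k = x_k,agg * Y / x_k,wpi

where x_k,agg is its mass fraction in the dry solid, Y the solid yield (mass
precipitate per mass WPI powder) and x_k,wpi its mass fraction in the feed
powder.  The selectivity of the separation is summarised by the purity
ratio rec_alpha / rec_beta (both on the solid side): larger means more
selective alpha-lactalbumin precipitation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import LinearNDInterpolator

from .errors import (ExtrapolationError, NoMatchingConditionError,
                     ValidationError)
from .types import (PROTEINS, FractionationOutcome, WPIComposition,
                    WPI_ASSAY)


@dataclass(frozen=True)
class PurityReport:
    """Product-quality summary of one fractionation condition."""

    alpha_purity: float          # alpha-LA mass fraction of the dry solid
    alpha_recovery: float        # solid-side
    beta_recovery_liquid: float
    gmp_recovery_liquid: float
    purity_ratio: float
    solid_yield: float


def recovery_from_composition(x_k_agg: float, Y: float, x_k_wpi: float) -> float:
    """Recovery of a protein in the solid fraction from composition and yield.

    Values marginally above 1 (by <= 0.02, from rounding of the inputs) are
    clipped with a warning; larger excesses raise.
    """
    if x_k_wpi == 0:
        raise ValidationError("species absent from feed (x_k_wpi = 0)")
    for name, v in (("x_k_agg", x_k_agg), ("Y", Y), ("x_k_wpi", x_k_wpi)):
        if not (0.0 < v <= 1.0):
            raise ValidationError(f"{name} must be in (0, 1], got {v}")
    rec = x_k_agg * Y / x_k_wpi
    if rec > 1.0:
        if rec <= 1.02:
            warnings.warn(f"recovery {rec:.4f} > 1 clipped to 1", stacklevel=2)
            return 1.0
        raise ValidationError(f"recovery {rec:.4f} exceeds 1 beyond rounding slack")
    return rec


def purity_ratio(rec_alpha: float, rec_beta_solid: float) -> float:
    """Selectivity ratio rec_alpha / rec_beta, both on the solid side."""
    if rec_beta_solid <= 0:
        raise ValidationError("rec_beta_solid must be positive")
    return rec_alpha / rec_beta_solid


def purity_report(outcome: FractionationOutcome,
                  comp: WPIComposition = WPI_ASSAY) -> PurityReport:
    """Assemble a :class:`PurityReport`, back-filling recoveries if needed."""
    o = fill_derived_recoveries(outcome, comp)
    return PurityReport(
        alpha_purity=o.solid_composition["alpha_la"],
        alpha_recovery=o.recovery_solid["alpha_la"],
        beta_recovery_liquid=1.0 - o.recovery_solid["beta_lg"],
        gmp_recovery_liquid=1.0 - o.recovery_solid["gmp"],
        purity_ratio=purity_ratio(o.recovery_solid["alpha_la"],
                                  o.recovery_solid["beta_lg"]),
        solid_yield=o.solid_yield,
    )


def fill_derived_recoveries(
    outcome: FractionationOutcome,
    comp: WPIComposition = WPI_ASSAY,
) -> FractionationOutcome:
    """Back-fill missing solid recoveries from composition and yield.

    Species whose recovery was not measured but whose solid composition is
    known get rec = x_agg * Y / x_wpi, and are listed in ``derived_fields``.
    """
    if outcome.solid_yield is None:
        return outcome
    rec = dict(outcome.recovery_solid)
    derived = list(outcome.derived_fields)
    for k in PROTEINS:
        if k in rec or k not in outcome.solid_composition:
            continue
        rec[k] = recovery_from_composition(
            outcome.solid_composition[k], outcome.solid_yield,
            comp.species_fraction(k),
        )
        derived.append(f"recovery_solid.{k}")
    if rec == outcome.recovery_solid:
        return outcome
    return replace(outcome, recovery_solid=rec, derived_fields=tuple(derived))


def lookup_outcome(
    T: float, C_wpi: float, P: float,
    table: list[FractionationOutcome],
    comp: WPIComposition = WPI_ASSAY,
) -> FractionationOutcome:
    """Exact-condition lookup (|dT| <= 0.5, |dC| <= 0.5, |dP| <= 0.2).

    Missing recoveries of the matched row are back-filled via the recovery
    identity and flagged as derived.
    """
    for o in table:
        if abs(o.T - T) <= 0.5 and abs(o.C_wpi - C_wpi) <= 0.5 and abs(o.P - P) <= 0.2:
            return fill_derived_recoveries(o, comp)
    raise NoMatchingConditionError(
        f"no experimental condition within tolerance of (T={T}, C={C_wpi}, "
        f"P={P}); consider interpolate_outcome for off-grid queries"
    )


# ---------------------------------------------------------------------------
# Interpolation over the irregular (T, C, P) grid

_FIELDS = ("ph", "solid_yield")


def _outcome_scalars(o: FractionationOutcome) -> dict[str, float]:
    vals = {"ph": o.ph, "solid_yield": o.solid_yield}
    for k in PROTEINS:
        vals[f"x_{k}"] = o.solid_composition.get(k)
        vals[f"rec_{k}"] = o.recovery_solid.get(k)
    return vals


def _plane_interpolators(table, comp):
    """Per-C_wpi-plane 2D linear interpolators in (T, ln P), per field."""
    filled = [fill_derived_recoveries(o, comp) for o in table]
    planes: dict[float, list[FractionationOutcome]] = {}
    for o in filled:
        planes.setdefault(o.C_wpi, []).append(o)
    out = {}
    for c, rows in planes.items():
        pts = np.array([[o.T, np.log(o.P)] for o in rows])
        fields: dict[str, LinearNDInterpolator] = {}
        scalars = [_outcome_scalars(o) for o in rows]
        for name in scalars[0]:
            vals = [s[name] for s in scalars]
            if any(v is None for v in vals):
                continue
            fields[name] = LinearNDInterpolator(pts, np.asarray(vals, float))
        out[c] = fields
    return out


def _eval_plane(fields, T: float, P: float) -> dict[str, float]:
    q = np.array([[T, np.log(P)]])
    vals = {}
    for name, itp in fields.items():
        v = float(itp(q)[0])
        if np.isnan(v):
            raise ExtrapolationError(
                f"(T={T}, P={P}) outside the experimental hull of this "
                "concentration plane; extrapolation is refused"
            )
        vals[name] = v
    return vals


def interpolate_outcome(
    T: float, C_wpi: float, P: float,
    table: list[FractionationOutcome],
    comp: WPIComposition = WPI_ASSAY,
) -> FractionationOutcome:
    """Per-field multilinear interpolation over the experimental grid.

    Interpolates linearly within each WPI-concentration plane over (T, ln P)
    and linearly across the bracketing concentration planes; exact at grid
    nodes.  Queries outside the hull raise :class:`ExtrapolationError` —
    never silent extrapolation.  The result is flagged ``interpolated``.
    """
    planes = _plane_interpolators(table, comp)
    cs = sorted(planes)
    if not (cs[0] <= C_wpi <= cs[-1]):
        raise ExtrapolationError(
            f"C_wpi={C_wpi} outside the covered range [{cs[0]}, {cs[-1]}] wt%"
        )
    if C_wpi in planes:
        vals = _eval_plane(planes[C_wpi], T, P)
    else:
        c_lo = max(c for c in cs if c < C_wpi)
        c_hi = min(c for c in cs if c > C_wpi)
        lo = _eval_plane(planes[c_lo], T, P)
        hi = _eval_plane(planes[c_hi], T, P)
        w = (C_wpi - c_lo) / (c_hi - c_lo)
        vals = {k: (1 - w) * lo[k] + w * hi[k] for k in lo if k in hi}
    comp_vals = {k: vals[f"x_{k}"] for k in PROTEINS if f"x_{k}" in vals}
    rec_vals = {k: vals[f"rec_{k}"] for k in PROTEINS if f"rec_{k}" in vals}
    return FractionationOutcome(
        T=T, C_wpi=C_wpi, P=P,
        ph=vals.get("ph"),
        solid_yield=vals.get("solid_yield"),
        solid_composition=comp_vals,
        recovery_solid=rec_vals,
        interpolated=True,
    )
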