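"""Domain types for the semi-continuous sCO2 whey-protein fractionation model.

The process treats a whey protein isolate (WPI) solution with supercritical
CO2: dissolved CO2 forms carbonic acid, lowers pH, and selectively
precipitates alpha-lactalbumin (with most minor whey proteins) while
beta-lactoglobulin and glycomacropeptide stay mostly soluble.  These types
carry the operating conditions, material compositions and experimental
outcomes that every downstream stage (pH, mass balance, sizing, costing)
consumes.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .errors import SolubilityRangeError, ValidationError

#: Protein species tracked individually through the flow-sheet.
PROTEINS: tuple[str, ...] = ("alpha_la", "beta_lg", "gmp", "minor")

#: Dissolved non-protein solids (follow the water phase in the centrifuge).
SOLUTES: tuple[str, ...] = ("minerals", "lactose")

#: All species appearing in a material stream, in canonical order.
SPECIES: tuple[str, ...] = ("water",) + SOLUTES + PROTEINS + ("co2",)


def _check_fraction(name: str, value: float, lo: float = 0.0, hi: float = 1.0) -> None:
    if not (lo <= value <= hi):
        raise ValidationError(f"{name} must be in [{lo}, {hi}], got {value}")


@dataclass(frozen=True)
class ProcessConditions:
    """Operating scenario: temperature, CO2 pressure, feed concentration and rate.

    Parameters
    ----------
    T : float
        Reactor temperature, degrees C.  55-80 is accepted; outside the
        experimentally covered 60-65 band a warning is emitted.
    P : float
        CO2 pressure, MPa.  Bounded by the 34 MPa maximum working pressure
        of the modelled reactor.
    C_wpi : float
        WPI concentration, wt% (mass WPI per mass solution, 1-28).
    feed_rate : float
        Total solution mass flow, kg/h.
    residence_time : float
        Reactor hold time, h.  All experimental outcomes were obtained at
        2 h; other values are rejected downstream rather than rescaled.
    """

    T: float
    P: float
    C_wpi: float
    feed_rate: float
    residence_time: float = 2.0

    def __post_init__(self) -> None:
        if not (55.0 <= self.T <= 80.0):
            raise ValidationError(f"T={self.T} degC outside permitted 55-80 range")
        if not (60.0 <= self.T <= 65.0):
            warnings.warn(
                f"T={self.T} degC outside the experimentally covered 60-65 band",
                stacklevel=2,
            )
        if not (0.0 < self.P <= 34.0):
            raise ValidationError(f"P={self.P} MPa outside (0, 34]")
        if not (1.0 <= self.C_wpi <= 28.0):
            raise ValidationError(
                f"C_wpi={self.C_wpi} wt% outside the 1-28 wt% validity range"
            )
        if self.feed_rate <= 0:
            raise ValidationError("feed_rate must be positive")
        if self.residence_time <= 0:
            raise ValidationError("residence_time must be positive")

    @property
    def wpi_rate(self) -> float:
        """WPI powder mass flow, kg/h."""
        return self.feed_rate * self.C_wpi / 100.0


@dataclass(frozen=True)
class WPIComposition:
    """Composition of the WPI powder feeding the process.

    ``protein_split`` gives the mass fraction of each protein class within
    total protein; powder-basis species fractions are
    ``protein_fraction * protein_split[k]``.
    """

    protein_fraction: float
    protein_split: dict[str, float]
    minerals_fraction: float
    lactose_fraction: float
    moisture_fraction: float

    def __post_init__(self) -> None:
        for name in ("protein_fraction", "minerals_fraction",
                     "lactose_fraction", "moisture_fraction"):
            _check_fraction(name, getattr(self, name))
        total = (self.protein_fraction + self.minerals_fraction
                 + self.lactose_fraction + self.moisture_fraction)
        if total > 1.0 + 1e-9:
            raise ValidationError(f"powder fractions sum to {total} > 1")
        if set(self.protein_split) != set(PROTEINS):
            raise ValidationError(f"protein_split must cover {PROTEINS}")
        s = sum(self.protein_split.values())
        if abs(s - 1.0) > 1e-9:
            raise ValidationError(f"protein_split sums to {s}, expected 1")

    def species_fraction(self, species: str, basis: str = "powder") -> float:
        """Mass fraction of a protein species on ``powder`` or ``protein`` basis."""
        if species not in PROTEINS:
            raise ValidationError(f"unknown protein species {species!r}")
        if basis == "powder":
            return self.protein_fraction * self.protein_split[species]
        if basis == "protein":
            return self.protein_split[species]
        raise ValidationError(f"basis must be 'powder' or 'protein', got {basis!r}")


#: Protein class split of the commercial WPI feed (fraction of total protein).
PROTEIN_SPLIT: dict[str, float] = {
    "beta_lg": 0.55,
    "alpha_la": 0.20,
    "gmp": 0.18,
    "minor": 0.07,
}

#: Assay profile of the WPI powder (90.1% protein, 2.9% ash, 3.6% moisture;
#: balance lactose/fat left unassigned).  Default basis for recovery math.
WPI_ASSAY = WPIComposition(
    protein_fraction=0.901,
    protein_split=PROTEIN_SPLIT,
    minerals_fraction=0.029,
    lactose_fraction=0.0,
    moisture_fraction=0.036,
)

#: Profile calibrated to close the reference stream table (90.0% protein,
#: 2.0% minerals, 1.0% lactose, 7.0% moisture).  Default for flow-sheets.
#: The assay and calibrated profiles disagree; both are kept, neither is
#: "corrected" (see docs/methods.md).
WPI_FLOWSHEET = WPIComposition(
    protein_fraction=0.90,
    protein_split=PROTEIN_SPLIT,
    minerals_fraction=0.02,
    lactose_fraction=0.01,
    moisture_fraction=0.07,
)


@dataclass(frozen=True)
class FractionationOutcome:
    """One fractionation experiment: yield, compositions and recoveries.

    ``recovery_solid`` maps each protein species to the fraction of its feed
    mass ending in the solid (precipitate) fraction; missing entries mean the
    value was not measured.  ``derived_fields`` records which entries were
    back-filled from the composition identity rec = x_agg * Y / x_wpi rather
    than measured directly.
    """

    T: float
    C_wpi: float
    P: float
    ph: float | None = None
    solid_yield: float | None = None
    solid_composition: dict[str, float] = field(default_factory=dict)
    recovery_solid: dict[str, float] = field(default_factory=dict)
    replicate_sd: dict[str, float] = field(default_factory=dict)
    derived_fields: tuple[str, ...] = ()
    interpolated: bool = False

    def __post_init__(self) -> None:
        if self.solid_yield is not None:
            _check_fraction("solid_yield", self.solid_yield)
        for k, v in self.recovery_solid.items():
            _check_fraction(f"recovery_solid[{k}]", v)
        if self.solid_composition:
            s = sum(self.solid_composition.values())
            if abs(s - 1.0) > 0.02:
                raise ValidationError(
                    f"solid composition sums to {s:.4f}, outside 1 +/- 0.02"
                )

    def recovery_liquid(self, species: str) -> float:
        """Complement recovery in the soluble fraction (1 - solid recovery)."""
        return 1.0 - self.recovery_solid[species]


@dataclass(frozen=True)
class FoamProperties:
    """Lumped properties of the CO2/whey-protein foam formed on depressurization.

    Defaults are the measured constants for 3-14 MPa operation: foam density
    ~0.1 kg/L and drainage rate ~0.4 L liquid per minute per L of initial
    liquid; above ``collapse_pressure`` the foam self-collapses during
    extraction.
    """

    d_foam: float = 0.1          # kg/L
    r_drainage: float = 0.4      # 1/min
    d_liq: float = 1.0           # kg/L, dilute aqueous solution
    collapse_pressure: float = 14.0  # MPa

    def __post_init__(self) -> None:
        if self.d_foam <= 0 or self.r_drainage <= 0 or self.d_liq <= 0:
            raise ValidationError("foam parameters must be positive")
        if self.d_foam >= self.d_liq:
            raise ValidationError("foam density must be below liquid density")


@dataclass(frozen=True)
class CO2SolubilityTable:
    """Piecewise-linear CO2 solubility in the WPI feed, kg CO2 per kg solution.

    Anchored on the two in-model operating points: 47 kg/h dissolved per
    907 kg/h feed at 8.3 MPa and 103.26 kg/h per 907 kg/h at 31 MPa.
    Queries outside the covered pressure span raise rather than extrapolate.
    """

    points: tuple[tuple[float, float], ...] = (
        (8.3, 47.0 / 907.0),
        (31.0, 103.26 / 907.0),
    )

    def __post_init__(self) -> None:
        ps = [p for p, _ in self.points]
        ss = [s for _, s in self.points]
        if len(self.points) < 2:
            raise ValidationError("solubility table needs at least two points")
        if any(s <= 0 for s in ss):
            raise ValidationError("solubility must be strictly positive")
        if sorted(ps) != ps or any(b < a for a, b in zip(ss, ss[1:])):
            raise ValidationError(
                "solubility must be monotone non-decreasing in pressure"
            )

    @property
    def p_min(self) -> float:
        return self.points[0][0]

    @property
    def p_max(self) -> float:
        return self.points[-1][0]

    def dissolved_ratio(self, P: float) -> float:
        """Dissolved CO2 mass per mass of feed solution at pressure ``P`` MPa."""
        if not (self.p_min <= P <= self.p_max):
            raise SolubilityRangeError(
                f"P={P} MPa outside solubility table span "
                f"[{self.p_min}, {self.p_max}] MPa"
            )
        for (p0, s0), (p1, s1) in zip(self.points, self.points[1:]):
            if p0 <= P <= p1:
                if p1 == p0:
                    return s0
                return s0 + (s1 - s0) * (P - p0) / (p1 - p0)
        raise AssertionError("unreachable")  # pragma: no cover


@dataclass(frozen=True)
class EquipmentUnit:
    """One priced unit of the equipment catalog."""

    tag: str
    description: str
    specification: str
    cost_kusd: float
    section: str  # 'reaction' or 'separation'

    def __post_init__(self) -> None:
        if self.cost_kusd < 0:
            raise ValidationError(f"{self.tag}: cost must be >= 0")
        if self.section not in ("reaction", "separation"):
            raise ValidationError(f"{self.tag}: unknown section {self.section!r}")


@dataclass(frozen=True)
class EquipmentCatalog:
    """Priced equipment list plus a lump 'unlisted equipment' allowance."""

    units: tuple[EquipmentUnit, ...]
    unlisted_kusd: float = 0.0

    def __post_init__(self) -> None:
        if self.unlisted_kusd < 0:
            raise ValidationError("unlisted equipment cost must be >= 0")
        tags = [u.tag for u in self.units]
        if len(set(tags)) != len(tags):
            raise ValidationError("equipment tags must be unique")

    @property
    def total_kusd(self) -> float:
        return sum(u.cost_kusd for u in self.units) + self.unlisted_kusd

    def section_kusd(self, section: str) -> float:
        """Listed-equipment cost of one section (excludes the unlisted lump)."""
        return sum(u.cost_kusd for u in self.units if u.section == section)

    def unit(self, tag: str) -> EquipmentUnit:
        for u in self.units:
            if u.tag == tag:
                return u
        raise KeyError(tag)


@dataclass(frozen=True)
class EconomicModel:
    """Schedule, rates and annualization parameters of the cost model.

    Defaults: 22 production h/day plus 2 maintenance h/day, 250 days/yr,
    two operators per shift at $45/h, maintenance 6%/yr and insurance 1%/yr
    of Lang-factored capital, Lang factor 3, 12-year straight-line
    depreciation.
    """

    hours_per_day: float = 22.0
    maintenance_hours_per_day: float = 2.0
    days_per_year: float = 250.0
    operators_per_shift: float = 2.0
    labor_rate: float = 45.0           # $/h
    water_rate: float = 0.71           # $/m3
    steam_rate: float = 12.0           # $/ton
    electricity_rate: float = 0.10     # $/kWh
    maintenance_frac: float = 0.06     # of capital, per year
    insurance_frac: float = 0.01       # of capital, per year
    lang_factor: float = 3.0
    depreciation_years: float = 12.0
    wpi_price: float = 10.70           # $/kg, reported separately, never rolled up

    def __post_init__(self) -> None:
        for name in ("hours_per_day", "maintenance_hours_per_day",
                     "days_per_year", "operators_per_shift", "labor_rate",
                     "water_rate", "steam_rate", "electricity_rate",
                     "maintenance_frac", "insurance_frac", "wpi_price"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.lang_factor < 1:
            raise ValidationError("lang_factor must be >= 1")
        if self.depreciation_years <= 0:
            raise ValidationError("depreciation_years must be positive")


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention of the reported tables)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)
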