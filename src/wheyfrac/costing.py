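"""Lang-factor capital roll-up and annualized production-cost model.

Capital = (sum of delivered equipment costs) x Lang factor (3 here: the
installed-plant multiplier covering piping, electrical, instrumentation,
buildings, engineering and start-up).  Annual operating cost is the sum of

* facility: capital annualized over straight-line depreciation plus
  maintenance and insurance fractions of capital,
* labor: operators x rate x staffed hours (production + maintenance) x days,
* utilities: a per-scenario input (the model supplies utility *rates* but no
  per-unit consumptions, so utilities cannot be built bottom-up).

Production cost is reported per kg of WPI powder treated, excluding the WPI
raw-material price, which is carried separately.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import ValidationError
from .types import EconomicModel, EquipmentCatalog, EquipmentUnit


@dataclass(frozen=True)
class CostReport:
    """Capital and annual operating costs of one scenario."""

    equipment_total: float       # K$
    capital: float               # K$, Lang-factored
    facility_annual: float       # K$/yr
    labor_annual: float          # K$/yr
    utilities_annual: float      # K$/yr
    throughput_annual: float     # kg WPI/yr
    cost_per_kg: float           # $/kg WPI treated (excl. WPI price)
    section_split: dict[str, float]   # K$/yr of annual operating cost
    wpi_material_annual: float   # K$/yr, reported separately

    @property
    def operating_annual(self) -> float:
        return self.facility_annual + self.labor_annual + self.utilities_annual


def total_equipment_cost(catalog: EquipmentCatalog) -> float:
    """Sum of unit costs plus the unlisted-equipment lump, K$."""
    if not catalog.units and catalog.unlisted_kusd == 0:
        return 0.0
    return catalog.total_kusd


def total_plant_cost(equipment_total: float, lang_factor: float) -> float:
    """Installed plant capital from delivered equipment cost, K$."""
    if lang_factor < 1:
        raise ValidationError("lang_factor must be >= 1")
    return equipment_total * lang_factor


def annual_facility_cost(capital: float, econ: EconomicModel) -> float:
    """Depreciation + maintenance + insurance, K$/yr, on Lang-factored capital."""
    return capital * (1.0 / econ.depreciation_years
                      + econ.maintenance_frac + econ.insurance_frac)


def annual_labor_cost(econ: EconomicModel) -> float:
    """Operator cost over staffed hours (production + maintenance), K$/yr."""
    staffed = econ.hours_per_day + econ.maintenance_hours_per_day
    return (econ.operators_per_shift * econ.labor_rate
            * staffed * econ.days_per_year) / 1000.0


def annual_throughput(feed_wpi_rate: float, econ: EconomicModel) -> float:
    """WPI powder treated per year (kg/yr) from the production schedule."""
    if feed_wpi_rate < 0:
        raise ValidationError("feed_wpi_rate must be >= 0")
    return feed_wpi_rate * econ.hours_per_day * econ.days_per_year


def production_cost_per_kg(facility: float, labor: float, utilities: float,
                           throughput: float) -> float:
    """$/kg of WPI treated from annual cost components (K$/yr) and kg/yr."""
    if throughput <= 0:
        raise ValidationError("throughput must be positive")
    return 1000.0 * (facility + labor + utilities) / throughput


def _section_shares(catalog: EquipmentCatalog) -> dict[str, float]:
    """Capital share per section with the unlisted lump spread pro-rata."""
    listed = {s: catalog.section_kusd(s) for s in ("reaction", "separation")}
    total_listed = sum(listed.values())
    if total_listed == 0:
        return {s: 0.5 for s in listed}
    return {s: v / total_listed for s, v in listed.items()}


def cost_report(
    feed_wpi_rate: float,
    catalog: EquipmentCatalog,
    utilities_annual: float,
    econ: EconomicModel = EconomicModel(),
) -> CostReport:
    """Full cost roll-up for one scenario.

    ``feed_wpi_rate`` is the WPI powder flow in kg/h; ``utilities_annual``
    the scenario's utilities bill in K$/yr.  The reaction/separation split
    allocates annual operating cost pro-rata on section capital shares.
    """
    if catalog is None:
        raise ValidationError("an equipment catalog is required")
    equipment = total_equipment_cost(catalog)
    capital = total_plant_cost(equipment, econ.lang_factor)
    facility = annual_facility_cost(capital, econ)
    labor = annual_labor_cost(econ)
    throughput = annual_throughput(feed_wpi_rate, econ)
    per_kg = production_cost_per_kg(facility, labor, utilities_annual, throughput)
    operating = facility + labor + utilities_annual
    shares = _section_shares(catalog)
    split = {s: operating * w for s, w in shares.items()}
    return CostReport(
        equipment_total=equipment,
        capital=capital,
        facility_annual=facility,
        labor_annual=labor,
        utilities_annual=utilities_annual,
        throughput_annual=throughput,
        cost_per_kg=per_kg,
        section_split=split,
        wpi_material_annual=econ.wpi_price * throughput / 1000.0,
    )


# ---------------------------------------------------------------------------
# Catalog variants for parametric comparisons.  The reference catalog is for
# low-pressure (5.5 MPa), 10 wt% operation; scaling other operating points
# uses the reported relative equipment-cost deltas, not predictions.

def _scale_unit(unit: EquipmentUnit, factor: float) -> EquipmentUnit:
    return replace(unit, cost_kusd=unit.cost_kusd * factor)


def _apply_factors(catalog: EquipmentCatalog,
                   factors: dict[str, float]) -> EquipmentCatalog:
    units = tuple(_scale_unit(u, factors.get(u.tag, 1.0)) for u in catalog.units)
    return EquipmentCatalog(units=units, unlisted_kusd=catalog.unlisted_kusd)


def high_pressure_variant(catalog: EquipmentCatalog,
                          reactor_increase: float = 2.8) -> EquipmentCatalog:
    """Catalog for 31 MPa operation: reactor cost up by up to 280%.

    Utilities rise separately (electricity up to +18%, glycol +36% for the
    compressor); see :func:`utilities_variant`.
    """
    if reactor_increase < 0:
        raise ValidationError("reactor_increase must be >= 0")
    return _apply_factors(catalog, {"V-103": 1.0 + reactor_increase})


def dilute_feed_variant(catalog: EquipmentCatalog) -> EquipmentCatalog:
    """Catalog for 5 wt% feed (doubled solution flow at constant WPI rate).

    Two reactors in parallel (cost x2), larger centrifuge (+52%), spray
    dryer (+59%) and blending tank (+10%).
    """
    return _apply_factors(catalog, {
        "V-103": 2.0, "CFUGE": 1.52, "SDR-107": 1.59, "V-105": 1.10,
    })


def higher_temperature_variant(catalog: EquipmentCatalog,
                               drum_dryer_increase: float = 0.40) -> EquipmentCatalog:
    """Catalog for hotter operation (more precipitate): drum dryer up ~40%."""
    return _apply_factors(catalog, {"DDR-108": 1.0 + drum_dryer_increase})


def utilities_variant(utilities_annual: float,
                      high_pressure: bool = False,
                      dilute_feed: bool = False) -> float:
    """Scenario utilities bill from the reference one, K$/yr.

    High pressure raises the compressor's electricity draw by up to 18%
    (glycol by more); dilute feed roughly doubles all consumptions.  These
    are documented scenario multipliers, not bottom-up predictions.
    """
    u = utilities_annual
    if high_pressure:
        u *= 1.18
    if dilute_feed:
        u *= 2.0
    return u
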