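"""Capital roll-up, annualization and production-cost arithmetic."""
import dataclasses

import pytest
from hypothesis import given
from hypothesis import strategies as st

from wheyfrac import (EconomicModel, EquipmentCatalog, ValidationError,
                      annual_facility_cost, annual_labor_cost,
                      annual_throughput, cost_report, dilute_feed_variant,
                      generate_equipment_catalog, high_pressure_variant,
                      higher_temperature_variant, production_cost_per_kg,
                      total_equipment_cost, total_plant_cost,
                      utilities_variant)


class TestEquipmentAndCapital:
    def test_catalog_total(self, catalog):
        # Independent column sum: 28+9+1+1094+1+450+897+370+400+169+603.
        assert total_equipment_cost(catalog) == 4022

    def test_total_without_drum_dryer(self, catalog):
        trimmed = EquipmentCatalog(
            units=tuple(u for u in catalog.units if u.tag != "DDR-108"),
            unlisted_kusd=catalog.unlisted_kusd)
        assert total_equipment_cost(trimmed) == 3652

    def test_empty_catalog(self):
        assert total_equipment_cost(EquipmentCatalog(units=())) == 0

    def test_lang_factor(self):
        assert total_plant_cost(4022, 3) == 12066
        assert total_plant_cost(123.0, 1) == 123.0
        assert total_plant_cost(0, 3) == 0


class TestAnnualization:
    def test_facility_reference(self, econ):
        # 12066 * (1/12 + 0.06 + 0.01) = 1850.1 K$/yr
        assert annual_facility_cost(12066, econ) == pytest.approx(1850.1, abs=0.1)

    def test_facility_ten_year_alternative(self, econ):
        e = dataclasses.replace(econ, depreciation_years=10)
        assert annual_facility_cost(12066, e) == pytest.approx(2051.2, abs=0.1)

    def test_facility_vanishes_without_charges(self):
        e = EconomicModel(maintenance_frac=0, insurance_frac=0,
                          depreciation_years=1e12)
        assert annual_facility_cost(12066, e) == pytest.approx(0.0, abs=1e-6)

    def test_labor_staffed_hours(self, econ):
        # 2 x $45 x (22+2) h x 250 d = 540 K$/yr exactly.
        assert annual_labor_cost(econ) == pytest.approx(540.0, abs=1e-12)

    def test_labor_production_hours_only_does_not_match(self, econ):
        e = dataclasses.replace(econ, maintenance_hours_per_day=0)
        assert annual_labor_cost(e) == pytest.approx(495.0)

    def test_zero_operators(self, econ):
        e = dataclasses.replace(econ, operators_per_shift=0)
        assert annual_labor_cost(e) == 0.0

    def test_throughput(self, econ):
        assert annual_throughput(90.7, econ) == pytest.approx(498_850)
        assert annual_throughput(45.35, econ) == pytest.approx(249_425)
        assert annual_throughput(0, econ) == 0.0


class TestProductionCost:
    def test_reference_components(self):
        assert production_cost_per_kg(1850, 540, 314, 498_850) \
            == pytest.approx(5.42, abs=0.01)

    def test_without_utilities(self):
        assert production_cost_per_kg(1850, 540, 0, 498_850) \
            == pytest.approx(4.79, abs=0.01)

    def test_linear_in_components(self):
        base = production_cost_per_kg(1850, 540, 314, 498_850)
        assert production_cost_per_kg(3700, 1080, 628, 498_850) \
            == pytest.approx(2 * base, rel=1e-12)

    def test_zero_throughput(self):
        with pytest.raises(ValidationError):
            production_cost_per_kg(1, 1, 1, 0)


class TestCostReport:
    def test_reference_scenario(self, catalog, econ):
        rep = cost_report(90.7, catalog, 314.0, econ)
        assert rep.cost_per_kg == pytest.approx(5.42, abs=0.01)
        assert rep.capital == pytest.approx(12066)
        # closure: section split sums to total annual operating cost
        assert sum(rep.section_split.values()) == pytest.approx(
            rep.operating_annual, abs=1e-9)
        # cost_per_kg consistency invariant
        assert rep.cost_per_kg == pytest.approx(
            1000 * rep.operating_annual / rep.throughput_annual, abs=1e-9)
        # WPI raw material reported separately, never rolled up
        assert rep.wpi_material_annual == pytest.approx(10.70 * 498_850 / 1000)

    def test_doubled_catalog_doubles_facility_only(self, catalog, econ):
        doubled = EquipmentCatalog(
            units=tuple(dataclasses.replace(u, cost_kusd=2 * u.cost_kusd)
                        for u in catalog.units),
            unlisted_kusd=2 * catalog.unlisted_kusd)
        a = cost_report(90.7, catalog, 314.0, econ)
        b = cost_report(90.7, doubled, 314.0, econ)
        assert b.facility_annual == pytest.approx(2 * a.facility_annual)
        assert b.labor_annual == a.labor_annual
        assert b.utilities_annual == a.utilities_annual

    def test_cost_decreasing_in_throughput(self, catalog, econ):
        lo = cost_report(45.35, catalog, 314.0, econ)
        hi = cost_report(90.7, catalog, 314.0, econ)
        assert hi.cost_per_kg < lo.cost_per_kg


class TestParametricOrdering:
    """Relative cost orderings across operating points hold for any catalog
    built with the documented equipment-delta multipliers."""

    @given(seed=st.integers(0, 2**31 - 1))
    def test_high_pressure_costs_more(self, seed, econ):
        base = generate_equipment_catalog(seed, perturbation=0.3)
        lo = cost_report(90.7, base, 314.0, econ)
        hi = cost_report(90.7, high_pressure_variant(base),
                         utilities_variant(314.0, high_pressure=True), econ)
        assert hi.cost_per_kg > lo.cost_per_kg

    @given(seed=st.integers(0, 2**31 - 1))
    def test_dilute_feed_costs_more(self, seed, econ):
        base = generate_equipment_catalog(seed, perturbation=0.3)
        conc = cost_report(90.7, base, 314.0, econ)
        dil = cost_report(90.7, dilute_feed_variant(base),
                          utilities_variant(314.0, dilute_feed=True), econ)
        assert dil.cost_per_kg > conc.cost_per_kg

    def test_higher_temperature_raises_cost_slightly(self, catalog, econ):
        base = cost_report(90.7, catalog, 314.0, econ)
        hot = cost_report(90.7, higher_temperature_variant(catalog), 314.0, econ)
        assert base.cost_per_kg < hot.cost_per_kg < base.cost_per_kg + 0.2
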