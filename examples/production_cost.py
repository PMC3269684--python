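"""Roll up capital and annual operating cost for the reference case.

Case 6 (62 degC, 10 wt%, 5.5 MPa) is the cheapest operating point: its
equipment catalog and utilities bill are packaged, so the full cost report
is computable.
"""
from wheyfrac import (dilute_feed_variant, high_pressure_variant,
                      load_equipment_catalog, run_case, utilities_variant,
                      cost_report, EconomicModel)

report = run_case(6)
cost = report.cost
print(f"equipment total:     {cost.equipment_total:8.0f} K$")
print(f"capital (Lang x3):   {cost.capital:8.0f} K$")
print(f"facility annual:     {cost.facility_annual:8.1f} K$/yr")
print(f"labor annual:        {cost.labor_annual:8.1f} K$/yr")
print(f"utilities annual:    {cost.utilities_annual:8.1f} K$/yr")
print(f"throughput:          {cost.throughput_annual:8.0f} kg WPI/yr")
print(f"production cost:     {cost.cost_per_kg:8.2f} $/kg WPI treated")
# Facility = depreciation (12 y) + maintenance (6%) + insurance (1%) on the
# Lang-factored capital; the $/kg figure excludes the WPI raw material
# (reported separately as wpi_material_annual).

catalog = load_equipment_catalog()
econ = EconomicModel()
hp = cost_report(90.7, high_pressure_variant(catalog),
                 utilities_variant(314, high_pressure=True), econ)
dil = cost_report(90.7, dilute_feed_variant(catalog),
                  utilities_variant(314, dilute_feed=True), econ)
print(f"\nwith a 31 MPa reactor:   {hp.cost_per_kg:6.2f} $/kg")
print(f"with a 5 wt% (2x) feed:  {dil.cost_per_kg:6.2f} $/kg")
# Catalog variants apply the documented equipment-cost deltas (reactor up to
# +280% at high pressure; dual reactors and larger separation train at 5%);
# both directions raise the production cost, as observed.
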