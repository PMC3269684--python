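"""Flow-sheet assembly, centrifuge split and species conservation."""
import pytest

from wheyfrac import (REFERENCE_CO2_CHARGE, ClosureError, CO2SolubilityTable,
                      FractionationOutcome, GeneratorSpec, ProcessConditions,
                      SolubilityRangeError, Stream, StreamTable,
                      build_flowsheet, check_conservation, co2_equilibrium,
                      feed_stream, generate_experiment_table, lookup_outcome,
                      recoveries_from_streams, split_centrifuge)
from wheyfrac.types import PROTEINS, SPECIES


@pytest.fixture()
def reference_scenario():
    return ProcessConditions(T=60, P=31.0, C_wpi=5, feed_rate=907)


@pytest.fixture()
def reference_table(table, reference_scenario):
    outcome = lookup_outcome(60, 5, 31.0, table)
    return build_flowsheet(reference_scenario, outcome,
                           initial_co2_charge=REFERENCE_CO2_CHARGE)


class TestFeedStream:
    def test_species_flows_match_reference(self):
        s = feed_stream(907, 5)
        assert s.get("alpha_la") == pytest.approx(8.16, abs=0.01)
        assert s.get("beta_lg") == pytest.approx(22.45, abs=0.01)
        assert s.get("gmp") == pytest.approx(7.35, abs=0.01)
        assert s.get("minor") == pytest.approx(2.86, abs=0.01)
        assert s.get("minerals") == pytest.approx(0.91, abs=0.01)
        assert s.get("lactose") == pytest.approx(0.45, abs=0.01)
        assert s.get("water") == pytest.approx(864.82, abs=0.01)
        assert s.total == pytest.approx(907.0, abs=1e-9)

    def test_null_feed(self):
        s = feed_stream(0, 5)
        assert s.total == 0.0


class TestCO2Equilibrium:
    def test_anchor_points(self):
        feed = feed_stream(907, 5)
        assert co2_equilibrium(feed, 31.0) == pytest.approx(103.26, abs=1e-9)
        assert co2_equilibrium(feed, 8.3) == pytest.approx(47.0, abs=1e-9)

    def test_linear_in_feed_mass(self):
        half = feed_stream(453.5, 5)
        assert co2_equilibrium(half, 31.0) == pytest.approx(51.63, abs=1e-9)

    def test_outside_span_is_an_error(self):
        feed = feed_stream(907, 5)
        with pytest.raises(SolubilityRangeError):
            co2_equilibrium(feed, 5.5)


class TestReferenceStreamTable:
    def test_reactor_effluent_total(self, reference_table):
        assert reference_table[4].total == pytest.approx(1010.26, abs=0.01)

    def test_centrifuge_partition(self, reference_table):
        assert reference_table[7].get("alpha_la") == pytest.approx(7.13, abs=0.01)
        assert reference_table[8].get("beta_lg") == pytest.approx(18.79, abs=0.01)
        assert reference_table[8].get("gmp") == pytest.approx(7.10, abs=0.01)

    def test_transient_charge_reported(self, reference_table):
        assert reference_table[2].get("co2") == pytest.approx(197.52)
        assert reference_table[3].get("co2") == pytest.approx(197.52 + 103.26)

    def test_recycle_closes(self, reference_table):
        assert reference_table[5].get("co2") == pytest.approx(103.26, abs=1e-9)
        report = check_conservation(reference_table)
        assert report.ok
        assert max(report.residuals.values()) < 1e-6

    def test_no_co2_in_products(self, reference_table):
        assert reference_table[7].get("co2") == 0.0
        assert reference_table[8].get("co2") == 0.0

    def test_dry_solids_equal_yield_closure(self, reference_table, table):
        o = lookup_outcome(60, 5, 31.0, table)
        dry7 = sum(reference_table[7].get(k)
                   for k in PROTEINS + ("minerals", "lactose"))
        assert dry7 == pytest.approx(o.solid_yield * 45.35, abs=1e-6)


class TestCentrifugeSplit:
    def test_no_precipitation_passes_everything_through(self):
        s6 = Stream(6, dict(feed_stream(907, 5).flows) | {"co2": 0.0})
        outcome = FractionationOutcome(
            T=60, C_wpi=5, P=8.3, solid_yield=0.0,
            recovery_solid={"alpha_la": 0.0, "beta_lg": 0.0, "gmp": 0.0},
        )
        s7, s8 = split_centrifuge(s6, outcome)
        assert s7.total == pytest.approx(0.0, abs=1e-9)
        for sp in SPECIES:
            assert s8.get(sp) == pytest.approx(s6.get(sp), abs=1e-9)

    def test_impossible_yield_closure_raises(self):
        s6 = Stream(6, dict(feed_stream(907, 5).flows) | {"co2": 0.0})
        outcome = FractionationOutcome(
            T=60, C_wpi=5, P=8.3, solid_yield=0.9,
            recovery_solid={"alpha_la": 0.1, "beta_lg": 0.1, "gmp": 0.1},
        )
        with pytest.raises(ClosureError, match="minor"):
            split_centrifuge(s6, outcome)

    def test_minor_modes_differ_for_measured_rows(self, table):
        s6 = Stream(6, dict(feed_stream(907, 5).flows) | {"co2": 0.0})
        o = lookup_outcome(60, 5, 31.0, table)
        s7_closure, _ = split_centrifuge(s6, o, minor_mode="closure")
        s7_comp, _ = split_centrifuge(s6, o, minor_mode="composition")
        assert s7_closure.get("minor") != pytest.approx(
            s7_comp.get("minor"), abs=1e-6)


def test_corrupted_stream_names_failing_species(reference_table):
    bad7 = dict(reference_table[7].flows)
    bad7["beta_lg"] += 0.5
    streams = dict(reference_table.streams)
    streams[7] = Stream(7, bad7)
    report = check_conservation(StreamTable(streams=streams))
    assert not report.ok
    assert report.failing_species() == ["beta_lg"]


def test_recovery_round_trip_on_synthetic_outcomes():
    """Recoveries recomputed from streams 6/7 equal the generator's observed
    recoveries to 1e-9 for every synthetic node in the solubility span."""
    outcomes = generate_experiment_table(GeneratorSpec(seed=3))
    for o in outcomes:
        if not (8.3 <= o.P <= 31.0):
            continue
        scenario = ProcessConditions(T=o.T, P=o.P, C_wpi=o.C_wpi,
                                     feed_rate=907)
        ft = build_flowsheet(scenario, o)
        rec = recoveries_from_streams(ft)
        for k in PROTEINS:
            assert rec[k] == pytest.approx(o.recovery_solid[k], abs=1e-9)
        assert ft.closure.ok
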