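"""End-to-end scenario orchestration: conditions -> pH -> outcome ->
flow-sheet -> sizing -> cost report.

The seven reference cases span the experimentally covered operating window
(T = 60-65 degC, C = 5-10 wt%, P = 5.5-31 MPa) at a fixed 90.7 kg/h WPI
feed.  Quantities whose inputs were never published (equipment catalogs for
all but the reference low-pressure case; CO2 solubility below 8.3 MPa) are
reported as unavailable with a reason, never guessed.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

from . import datasets
from .costing import CostReport, cost_report
from .errors import SolubilityRangeError, WheyfracError
from .flowsheet import (ClosureReport, Stream, StreamTable, build_flowsheet,
                        check_conservation, feed_stream, split_centrifuge)
from .fractionation import (PurityReport, interpolate_outcome, lookup_outcome,
                            purity_report)
from .sizing import TankSpec, tank_spec
from .types import (SPECIES, EconomicModel, FractionationOutcome,
                    ProcessConditions, WPIComposition, WPI_ASSAY,
                    WPI_FLOWSHEET)

logger = logging.getLogger(__name__)

#: Reference cases: id -> (C_wpi wt%, T degC, P MPa).
CASES: dict[int, tuple[float, float, float]] = {
    1: (5, 60, 8.3),
    2: (5, 60, 31.0),
    3: (5, 65, 8.3),
    4: (10, 60, 8.3),
    5: (10, 60, 31.0),
    6: (10, 62, 5.5),
    7: (10, 65, 5.5),
}

#: The only case whose equipment catalog is published (the packaged one).
REFERENCE_CASE = 6

#: Reference WPI powder feed rate, kg/h (200 lb/h).
DEFAULT_WPI_RATE = 90.7


@dataclass(frozen=True)
class RunReport:
    """Bundle of everything derivable for one scenario."""

    case_id: int | None
    scenario: ProcessConditions
    outcome: FractionationOutcome
    purity: PurityReport
    alpha_fraction_yield: float
    beta_fraction_yield: float
    tank: TankSpec
    stream_table: StreamTable | None
    stream_table_reason: str | None
    cost: CostReport | None
    cost_reason: str | None
    provenance: dict[str, str]

    def to_dict(self) -> dict:
        d = {
            "case_id": self.case_id,
            "scenario": asdict(self.scenario),
            "purity": asdict(self.purity),
            "alpha_fraction_yield": self.alpha_fraction_yield,
            "beta_fraction_yield": self.beta_fraction_yield,
            "tank": asdict(self.tank),
            "provenance": self.provenance,
            "stream_table_reason": self.stream_table_reason,
            "cost_reason": self.cost_reason,
        }
        if self.stream_table is not None:
            d["streams_kg_h"] = {
                str(sid): {sp: s.get(sp) for sp in SPECIES}
                for sid, s in sorted(self.stream_table.streams.items())
            }
        if self.cost is not None:
            d["cost"] = asdict(self.cost)
        return d

    def to_json(self) -> str:
        """Byte-identical for identical inputs: keys sorted, fixed format."""
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def _liquid_side_table(scenario: ProcessConditions,
                       outcome: FractionationOutcome,
                       comp: WPIComposition) -> StreamTable:
    """Streams 1, 6, 7, 8 when the CO2 loop cannot be quantified."""
    s1 = feed_stream(scenario.feed_rate, scenario.C_wpi, comp)
    s6 = Stream(6, dict(s1.flows) | {"co2": 0.0})
    s7, s8 = split_centrifuge(s6, outcome, comp)
    residuals = {sp: abs(s6.get(sp) - s7.get(sp) - s8.get(sp))
                 for sp in SPECIES}
    return StreamTable(
        streams={1: s1, 6: s6, 7: s7, 8: s8},
        scenario=scenario,
        closure=ClosureReport(residuals=residuals),
        notes=("co2 loop omitted: solubility uncharacterized at this pressure",),
    )


def run_scenario(
    scenario: ProcessConditions,
    outcome: FractionationOutcome,
    case_id: int | None = None,
    catalog=None,
    utilities_annual: float | None = None,
    econ: EconomicModel = EconomicModel(),
    comp: WPIComposition = WPI_FLOWSHEET,
) -> RunReport:
    """Assemble the full report for one scenario and outcome."""
    purity = purity_report(outcome)
    provenance = {"outcome": "interpolated" if outcome.interpolated else "measured"}
    for f in outcome.derived_fields:
        provenance[f] = "derived"
    logger.info("stage=purity case=%s ratio=%.3f", case_id, purity.purity_ratio)

    reason = None
    try:
        table = build_flowsheet(scenario, outcome, comp)
    except SolubilityRangeError as exc:
        table = _liquid_side_table(scenario, outcome, comp)
        reason = f"CO2-loop streams unavailable: {exc}"
    logger.info("stage=flowsheet case=%s streams=%d", case_id, len(table.streams))

    tank = tank_spec(scenario.feed_rate, scenario.P)

    cost = None
    cost_reason = None
    if catalog is not None and utilities_annual is not None:
        cost = cost_report(scenario.wpi_rate, catalog, utilities_annual, econ)
        logger.info("stage=cost case=%s per_kg=%.2f", case_id, cost.cost_per_kg)
    else:
        cost_reason = ("no equipment catalog / utilities published for this "
                       "operating point; cost not computed")
    assert purity.solid_yield is not None
    return RunReport(
        case_id=case_id,
        scenario=scenario,
        outcome=outcome,
        purity=purity,
        alpha_fraction_yield=purity.solid_yield,
        beta_fraction_yield=1.0 - purity.solid_yield,
        tank=tank,
        stream_table=table,
        stream_table_reason=reason,
        cost=cost,
        cost_reason=cost_reason,
        provenance=provenance,
    )


def run_case(
    case_id: int,
    table: list[FractionationOutcome] | None = None,
    wpi_rate: float = DEFAULT_WPI_RATE,
    econ: EconomicModel = EconomicModel(),
) -> RunReport:
    """Run one reference case end to end.

    Cost is computed only for the reference case (its catalog and utilities
    bill are packaged); other cases report it unavailable with a reason.
    """
    if case_id not in CASES:
        raise WheyfracError(
            f"unknown case {case_id}; valid ids: {sorted(CASES)}"
        )
    C, T, P = CASES[case_id]
    if table is None:
        table = datasets.load_experiment_table()
    outcome = lookup_outcome(T, C, P, table)
    scenario = ProcessConditions(T=T, P=P, C_wpi=C,
                                 feed_rate=wpi_rate / (C / 100.0))
    catalog = utilities = None
    if case_id == REFERENCE_CASE:
        catalog = datasets.load_equipment_catalog()
        utilities = datasets.REFERENCE_UTILITIES_KUSD
    return run_scenario(scenario, outcome, case_id=case_id, catalog=catalog,
                        utilities_annual=utilities, econ=econ)


def sweep(
    points: list[tuple[float, float, float]],
    table: list[FractionationOutcome] | None = None,
    comp: WPIComposition = WPI_ASSAY,
) -> list[dict]:
    """Purity trade-off table over a (T, C_wpi, P) grid.

    Grid nodes reproduce the measured rows; off-node points are interpolated
    within the experimental hull.  Hull violations yield row-level error
    entries rather than aborting the sweep.  Row order follows input order.
    """
    if table is None:
        table = datasets.load_experiment_table()
    rows = []
    for T, C, P in points:
        row: dict = {"T": T, "C_wpi": C, "P": P, "error": None}
        try:
            try:
                outcome = lookup_outcome(T, C, P, table, comp)
            except WheyfracError:
                outcome = interpolate_outcome(T, C, P, table, comp)
            rep = purity_report(outcome, comp)
            row.update({
                "alpha_purity": rep.alpha_purity,
                "alpha_recovery": rep.alpha_recovery,
                "beta_recovery_liquid": rep.beta_recovery_liquid,
                "gmp_recovery_liquid": rep.gmp_recovery_liquid,
                "purity_ratio": rep.purity_ratio,
                "solid_yield": rep.solid_yield,
                "interpolated": outcome.interpolated,
            })
        except WheyfracError as exc:
            row["error"] = str(exc)
        rows.append(row)
    return rows
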