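"""Eight-stream steady-state mass balance of the semi-continuous process.

Stream map (species flows in kg/h):

  1  WPI + water feed solution
  2  initial CO2 charge of the reactor (transient only; excluded from the
     steady-state closure)
  3  CO2 headspace + dissolved CO2 (= stream 2 + stream 5 at steady state)
  4  pressurized reactor effluent = feed + dissolved CO2
  5  CO2 recycle recovered in the de-foaming tank (= dissolved CO2)
  6  degassed liquid entering the centrifuge (= stream 1 species-wise)
  7  wet precipitate (alpha-LA-enriched solid)
  8  supernatant (beta-LG/GMP-enriched solution)

Ideal CO2 recycling is assumed: all dissolved CO2 vaporises in the de-foaming
tank and is returned; no CO2 reaches products 7 or 8.  The residual dissolved
CO2 that in reality drifts the product pH from ~6.0 to ~6.8 is neglected.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ClosureError, ValidationError
from .types import (PROTEINS, SPECIES, SOLUTES, CO2SolubilityTable,
                    FractionationOutcome, ProcessConditions, WPIComposition,
                    WPI_FLOWSHEET)

#: Water mass fraction of the wet precipitate (stream 7), calibrated to the
#: reference stream table (29.40 / 42.17).  The model never states it
#: directly, so it is an explicit parameter everywhere.
DEFAULT_WET_MOISTURE = 0.697

STREAM_IDS = (1, 2, 3, 4, 5, 6, 7, 8)


@dataclass(frozen=True)
class Stream:
    """One material stream: species -> mass flow (kg/h)."""

    id: int
    flows: dict[str, float]

    def __post_init__(self) -> None:
        unknown = set(self.flows) - set(SPECIES)
        if unknown:
            raise ValidationError(f"unknown species {sorted(unknown)}")
        for k, v in self.flows.items():
            if v < -1e-9:
                raise ValidationError(f"stream {self.id}: negative {k} flow {v}")

    def get(self, species: str) -> float:
        return self.flows.get(species, 0.0)

    @property
    def total(self) -> float:
        return sum(self.flows.values())

    def __sub__(self, other: "Stream") -> dict[str, float]:
        return {k: self.get(k) - other.get(k)
                for k in set(self.flows) | set(other.flows)}


@dataclass(frozen=True)
class ClosureReport:
    """Species conservation residuals at every junction of the flow-sheet."""

    residuals: dict[str, float]   # species -> max |in - out| over junctions, kg/h
    tolerance: float = 1e-6

    @property
    def ok(self) -> bool:
        return all(abs(r) < self.tolerance for r in self.residuals.values())

    def failing_species(self) -> list[str]:
        return sorted(k for k, r in self.residuals.items()
                      if abs(r) >= self.tolerance)


@dataclass(frozen=True)
class StreamTable:
    streams: dict[int, Stream]
    scenario: ProcessConditions | None = None
    closure: ClosureReport | None = None
    notes: tuple[str, ...] = ()

    def __getitem__(self, sid: int) -> Stream:
        return self.streams[sid]

    def to_frame(self) -> pd.DataFrame:
        """Species rows x stream columns, kg/h, with a Total row."""
        data = {sid: [self.streams[sid].get(sp) for sp in SPECIES]
                for sid in sorted(self.streams)}
        df = pd.DataFrame(data, index=list(SPECIES))
        df.loc["total"] = df.sum(axis=0)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().round(2).to_csv(path, index_label="species")


def feed_stream(feed_rate: float, C_wpi: float,
                comp: WPIComposition = WPI_FLOWSHEET) -> Stream:
    """Stream 1: WPI powder dissolved in water at ``C_wpi`` wt%.

    The water row is added dilution water plus the powder's own moisture.
    """
    if feed_rate < 0:
        raise ValidationError("feed_rate must be >= 0")
    if feed_rate == 0:
        return Stream(1, {sp: 0.0 for sp in SPECIES if sp != "co2"})
    wpi = feed_rate * C_wpi / 100.0
    flows = {k: wpi * comp.species_fraction(k) for k in PROTEINS}
    flows["minerals"] = wpi * comp.minerals_fraction
    flows["lactose"] = wpi * comp.lactose_fraction
    flows["water"] = feed_rate - wpi * (1.0 - comp.moisture_fraction)
    return Stream(1, flows)


def co2_equilibrium(feed: Stream, P: float,
                    solubility: CO2SolubilityTable | None = None) -> float:
    """Dissolved CO2 mass flow (kg/h) in the feed at pressure ``P`` MPa."""
    if solubility is None:
        solubility = CO2SolubilityTable()
    return solubility.dissolved_ratio(P) * feed.total


def split_centrifuge(
    stream6: Stream,
    outcome: FractionationOutcome,
    comp: WPIComposition = WPI_FLOWSHEET,
    wet_moisture: float = DEFAULT_WET_MOISTURE,
    minor_mode: str = "auto",
) -> tuple[Stream, Stream]:
    """Partition the degassed liquor into wet solid (7) and supernatant (8).

    Each measured protein goes to the solid at its experimental recovery.
    Water follows from the wet-precipitate moisture; dissolved minerals and
    lactose partition in proportion to water.  The minor proteins, whose
    recovery is never measured directly, default to yield closure: total dry
    solids in stream 7 must equal Y times the WPI powder flow.

    ``minor_mode``: ``auto`` honours a measured/synthetic minor recovery and
    falls back to closure otherwise; ``closure`` forces closure;
    ``composition`` uses the outcome's minor recovery (including one derived
    from the solid composition) directly.
    """
    if minor_mode not in ("auto", "closure", "composition"):
        raise ValidationError(f"unknown minor_mode {minor_mode!r}")
    if not (0.0 <= wet_moisture < 1.0):
        raise ValidationError("wet_moisture must be in [0, 1)")
    protein_feed = {k: stream6.get(k) for k in PROTEINS}
    total_protein = sum(protein_feed.values())
    if total_protein == 0:
        s7 = Stream(7, {sp: 0.0 for sp in SPECIES if sp != "co2"})
        return s7, Stream(8, dict(stream6.flows) | {"co2": 0.0})
    rec = dict(outcome.recovery_solid)
    missing = [k for k in ("alpha_la", "beta_lg", "gmp") if k not in rec]
    if missing:
        raise ValidationError(f"outcome lacks recoveries for {missing}")
    if outcome.solid_yield is None:
        raise ValidationError("outcome lacks a solid yield")

    wpi_mass = total_protein / comp.protein_fraction
    s7 = {k: protein_feed[k] * rec[k] for k in ("alpha_la", "beta_lg", "gmp")}

    minor_is_derived = "recovery_solid.minor" in outcome.derived_fields
    if minor_mode == "composition":
        use_explicit = "minor" in rec
        if not use_explicit:
            raise ValidationError("composition mode needs a minor recovery")
    elif minor_mode == "closure":
        use_explicit = False
    else:
        use_explicit = "minor" in rec and not minor_is_derived
    if use_explicit:
        # Explicit recovery (e.g. synthetic outcomes): water scales with the
        # dry solid via the moisture ratio; solutes follow water.
        s7["minor"] = protein_feed["minor"] * rec["minor"]
        protein7 = sum(s7.values())
        a = wet_moisture / (1.0 - wet_moisture)
        solute_per_water = ((stream6.get("minerals") + stream6.get("lactose"))
                            / stream6.get("water"))
        water7 = a * protein7 / (1.0 - a * solute_per_water)
        w_frac = water7 / stream6.get("water")
        s7["minerals"] = stream6.get("minerals") * w_frac
        s7["lactose"] = stream6.get("lactose") * w_frac
    else:
        # Yield closure: dry solids in stream 7 = Y * WPI powder flow.
        dry7 = outcome.solid_yield * wpi_mass
        water7 = dry7 * wet_moisture / (1.0 - wet_moisture)
        w_frac = water7 / stream6.get("water")
        s7["minerals"] = stream6.get("minerals") * w_frac
        s7["lactose"] = stream6.get("lactose") * w_frac
        minor7 = dry7 - sum(s7.values())
        rec_minor = minor7 / protein_feed["minor"]
        if not (-1e-9 <= rec_minor <= 1.0 + 1e-9):
            raise ClosureError(
                f"closure-derived minor-protein recovery {rec_minor:.3f} "
                f"outside [0, 1]: yield Y={outcome.solid_yield} is "
                "inconsistent with the measured recoveries"
            )
        s7["minor"] = minor7
    s7["water"] = water7
    stream7 = Stream(7, s7)
    diff = stream6 - stream7
    diff.pop("co2", None)
    if any(v < -1e-9 for v in diff.values()):
        bad = {k: v for k, v in diff.items() if v < -1e-9}
        raise ClosureError(f"stream 7 exceeds stream 6 for {bad}")
    stream8 = Stream(8, {k: max(v, 0.0) for k, v in diff.items()})
    return stream7, stream8


def build_flowsheet(
    scenario: ProcessConditions,
    outcome: FractionationOutcome,
    comp: WPIComposition = WPI_FLOWSHEET,
    solubility: CO2SolubilityTable | None = None,
    wet_moisture: float = DEFAULT_WET_MOISTURE,
    initial_co2_charge: float = 0.0,
) -> StreamTable:
    """Assemble streams 1-8 at steady state and verify species conservation.

    ``initial_co2_charge`` is the transient reactor headspace charge shown in
    stream 2; it is reported for completeness but excluded from closure.
    """
    s1 = feed_stream(scenario.feed_rate, scenario.C_wpi, comp)
    if scenario.feed_rate == 0:
        dissolved = 0.0
    else:
        dissolved = co2_equilibrium(s1, scenario.P, solubility)
    s2 = Stream(2, {"co2": initial_co2_charge})
    s3 = Stream(3, {"co2": initial_co2_charge + dissolved})
    s4 = Stream(4, dict(s1.flows) | {"co2": dissolved})
    s5 = Stream(5, {"co2": dissolved})
    s6 = Stream(6, dict(s1.flows) | {"co2": 0.0})
    if s1.total > 0:
        s7, s8 = split_centrifuge(s6, outcome, comp, wet_moisture)
    else:
        s7 = Stream(7, {sp: 0.0 for sp in SPECIES if sp != "co2"})
        s8 = Stream(8, {sp: 0.0 for sp in SPECIES if sp != "co2"})
    table = StreamTable(
        streams={1: s1, 2: s2, 3: s3, 4: s4, 5: s5, 6: s6, 7: s7, 8: s8},
        scenario=scenario,
    )
    report = check_conservation(table)
    if not report.ok:
        raise ClosureError(
            f"species conservation violated for {report.failing_species()}"
        )
    return StreamTable(streams=table.streams, scenario=scenario, closure=report)


def check_conservation(table: StreamTable) -> ClosureReport:
    """Per-species |inflow - outflow| residuals at each steady-state junction.

    Junctions: reactor (1 + 5 = 4), de-foamer (4 = 5 + 6), centrifuge
    (6 = 7 + 8).  Stream 2 is transient and excluded.
    """
    s = table.streams
    residuals: dict[str, float] = {}
    junctions = (
        ({1, 5}, {4}),
        ({4}, {5, 6}),
        ({6}, {7, 8}),
    )
    for sp in SPECIES:
        worst = 0.0
        for ins, outs in junctions:
            r = (sum(s[i].get(sp) for i in ins)
                 - sum(s[o].get(sp) for o in outs))
            worst = max(worst, abs(r))
        residuals[sp] = worst
    return ClosureReport(residuals=residuals)


def recoveries_from_streams(table: StreamTable) -> dict[str, float]:
    """Recompute per-protein solid recoveries from streams 6 and 7."""
    s6, s7 = table[6], table[7]
    return {k: s7.get(k) / s6.get(k) for k in PROTEINS if s6.get(k) > 0}
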