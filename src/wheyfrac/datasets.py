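"""Packaged fixtures and tabular I/O for experiment grids and equipment catalogs.

The experiment grid is the pilot-scale fractionation table: one row per
(T, C_wpi, P) condition with solid yield, dry-solid composition, per-protein
recoveries and replicate standard deviations.  Percentages are stored as
fractions in [0, 1]; blank cells mean "not measured", never zero.
"""
from __future__ import annotations

import io
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import SchemaError, ValidationError
from .types import (EquipmentCatalog, EquipmentUnit, FractionationOutcome,
                    WPIComposition, WPI_ASSAY)

#: Initial reactor CO2 charge of the reference stream table, kg/h (transient
#: stream only; excluded from steady-state closure).
REFERENCE_CO2_CHARGE = 197.52

#: Annual utilities bill of the reference costing scenario, K$/yr.
REFERENCE_UTILITIES_KUSD = 314.0

_GRID_COLUMNS = [
    "row", "T_C", "C_wpi_pct", "P_MPa", "pH",
    "solid_yield", "solid_yield_sd",
    "x_alpha_solid", "x_alpha_solid_sd", "x_beta_solid", "x_gmp_solid",
    "x_minor_solid",
    "rec_alpha_solid", "rec_alpha_solid_sd", "purity_ratio",
    "x_beta_liquid", "rec_beta_liquid", "rec_beta_liquid_sd",
    "x_gmp_liquid", "rec_gmp_liquid",
]


def _fixture_path(name: str):
    return resources.files("wheyfrac.data") / name


def load_experiment_table(source=None) -> list[FractionationOutcome]:
    """Load a fractionation experiment table.

    Parameters
    ----------
    source : path-like, file object or None
        CSV file in the packaged schema.  ``None`` loads the packaged
        pilot-scale fixture (11 conditions).

    Returns
    -------
    list of FractionationOutcome
        One outcome per row.  Recoveries are on the solid-fraction basis:
        beta-LG and GMP recoveries are stored in the file on the liquid side
        (as reported) and converted to ``1 - liquid`` here.
    """
    if source is None:
        source = io.StringIO(_fixture_path("experiment_grid.csv").read_text())
    df = pd.read_csv(source, float_precision="round_trip")
    if df.empty:
        raise SchemaError("experiment table is empty")
    missing = [c for c in _GRID_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"experiment table missing column {missing[0]!r}", column=missing[0]
        )
    outcomes = []
    for _, r in df.iterrows():
        comp = {
            "alpha_la": r["x_alpha_solid"],
            "beta_lg": r["x_beta_solid"],
            "gmp": r["x_gmp_solid"],
            "minor": r["x_minor_solid"],
        }
        comp = {k: float(v) for k, v in comp.items() if pd.notna(v)}
        rec = {}
        if pd.notna(r["rec_alpha_solid"]):
            rec["alpha_la"] = float(r["rec_alpha_solid"])
        if pd.notna(r["rec_beta_liquid"]):
            rec["beta_lg"] = 1.0 - float(r["rec_beta_liquid"])
        if pd.notna(r["rec_gmp_liquid"]):
            rec["gmp"] = 1.0 - float(r["rec_gmp_liquid"])
        sd = {
            "solid_yield": r["solid_yield_sd"],
            "x_alpha_solid": r["x_alpha_solid_sd"],
            "rec_alpha_solid": r["rec_alpha_solid_sd"],
            "rec_beta_liquid": r["rec_beta_liquid_sd"],
        }
        sd = {k: float(v) for k, v in sd.items() if pd.notna(v)}
        outcomes.append(FractionationOutcome(
            T=float(r["T_C"]),
            C_wpi=float(r["C_wpi_pct"]),
            P=float(r["P_MPa"]),
            ph=float(r["pH"]) if pd.notna(r["pH"]) else None,
            solid_yield=float(r["solid_yield"]) if pd.notna(r["solid_yield"]) else None,
            solid_composition=comp,
            recovery_solid=rec,
            replicate_sd=sd,
        ))
    return outcomes


def save_experiment_table(outcomes: list[FractionationOutcome], path) -> None:
    """Write outcomes back to the CSV schema of :func:`load_experiment_table`."""
    rows = []
    for i, o in enumerate(outcomes, start=1):
        rows.append({
            "row": i,
            "T_C": float(o.T), "C_wpi_pct": float(o.C_wpi),
            "P_MPa": float(o.P), "pH": o.ph,
            "solid_yield": o.solid_yield,
            "solid_yield_sd": o.replicate_sd.get("solid_yield"),
            "x_alpha_solid": o.solid_composition.get("alpha_la"),
            "x_alpha_solid_sd": o.replicate_sd.get("x_alpha_solid"),
            "x_beta_solid": o.solid_composition.get("beta_lg"),
            "x_gmp_solid": o.solid_composition.get("gmp"),
            "x_minor_solid": o.solid_composition.get("minor"),
            "rec_alpha_solid": o.recovery_solid.get("alpha_la"),
            "rec_alpha_solid_sd": o.replicate_sd.get("rec_alpha_solid"),
            "purity_ratio": None,
            "x_beta_liquid": None,
            "rec_beta_liquid": (1.0 - o.recovery_solid["beta_lg"]
                                if "beta_lg" in o.recovery_solid else None),
            "rec_beta_liquid_sd": o.replicate_sd.get("rec_beta_liquid"),
            "x_gmp_liquid": None,
            "rec_gmp_liquid": (1.0 - o.recovery_solid["gmp"]
                               if "gmp" in o.recovery_solid else None),
        })
    pd.DataFrame(rows, columns=_GRID_COLUMNS).to_csv(path, index=False)


def check_recovery_consistency(
    outcome: FractionationOutcome,
    comp: WPIComposition = WPI_ASSAY,
    tol: float = 0.015,
) -> dict[str, float]:
    """Residuals of the recovery identity rec_k = x_k,agg * Y / x_k,wpi.

    Returns per-species |measured - composition-derived| for species where
    the measured recovery, solid composition and yield are all present;
    raises :class:`ValidationError` if any residual exceeds ``tol``.
    """
    residuals: dict[str, float] = {}
    if outcome.solid_yield is None:
        return residuals
    for k, measured in outcome.recovery_solid.items():
        if k not in outcome.solid_composition:
            continue
        x_wpi = comp.species_fraction(k)
        derived = outcome.solid_composition[k] * outcome.solid_yield / x_wpi
        residuals[k] = abs(measured - derived)
        if residuals[k] > tol:
            raise ValidationError(
                f"recovery of {k} at (T={outcome.T}, C={outcome.C_wpi}, "
                f"P={outcome.P}) inconsistent with composition: "
                f"measured {measured:.3f} vs derived {derived:.3f}"
            )
    return residuals


def load_equipment_catalog(source=None) -> EquipmentCatalog:
    """Load an equipment catalog CSV (tag, description, spec, cost K$, section).

    Rows with section ``shared`` are folded into the catalog's unlisted
    equipment lump.  ``None`` loads the packaged reference catalog.
    """
    if source is None:
        source = io.StringIO(_fixture_path("equipment_catalog.csv").read_text())
    df = pd.read_csv(source)
    required = ["tag", "description", "specification", "cost_kusd", "section"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"equipment catalog missing column {missing[0]!r}", column=missing[0]
        )
    units = []
    unlisted = 0.0
    for _, r in df.iterrows():
        if float(r["cost_kusd"]) < 0:
            raise ValidationError(f"{r['tag']}: negative cost")
        if r["section"] == "shared":
            unlisted += float(r["cost_kusd"])
            continue
        units.append(EquipmentUnit(
            tag=str(r["tag"]),
            description=str(r["description"]),
            specification="" if pd.isna(r["specification"]) else str(r["specification"]),
            cost_kusd=float(r["cost_kusd"]),
            section=str(r["section"]),
        ))
    return EquipmentCatalog(units=tuple(units), unlisted_kusd=unlisted)


def save_equipment_catalog(catalog: EquipmentCatalog, path) -> None:
    rows = [{
        "tag": u.tag, "description": u.description,
        "specification": u.specification, "cost_kusd": u.cost_kusd,
        "section": u.section,
    } for u in catalog.units]
    if catalog.unlisted_kusd:
        rows.append({"tag": "UNLISTED", "description": "Unlisted Equipment",
                     "specification": "", "cost_kusd": catalog.unlisted_kusd,
                     "section": "shared"})
    pd.DataFrame(rows).to_csv(path, index=False)
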