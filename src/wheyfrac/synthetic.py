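"""Synthetic fractionation tables and equipment catalogs for testing.

The generator emulates the *structure* of the pilot experiment table: per
(T, C, P) node it draws "true" per-protein solid recoveries from smooth
monotone trend surfaces (logistic in T and in ln P — a qualitative shape
matching the observed directions: both alpha-LA and beta-LG precipitation
increase with T and P, with beta-LG accelerating faster so the purity ratio
falls with P and with T above ~62 degC), adds replicate Gaussian noise, and
back-computes yields and solid compositions so the recovery identity
rec = x_agg * Y / x_wpi holds exactly.  It is synthetic test scaffolding,
not a model of the precipitation chemistry.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import ph as ph_model
from .errors import ValidationError
from .types import PROTEINS, FractionationOutcome, WPIComposition, WPI_ASSAY

#: The experimental (T, C_wpi, P) grid of the pilot study.
DEFAULT_GRID: tuple[tuple[float, float, float], ...] = (
    (60, 10, 5.5), (60, 10, 8.3), (60, 10, 31.0),
    (60, 5, 8.3), (60, 5, 31.0),
    (62, 10, 5.5),
    (65, 10, 5.5), (65, 10, 8.3), (65, 10, 31.0),
    (65, 5, 8.3), (65, 5, 31.0),
)

#: Logistic trend coefficients (b0, bT, bP): logit(rec) = b0 + bT*(T - 62.5)
#: + bP*(ln P - ln 9), chosen to land in the observed recovery bands.
DEFAULT_TRENDS: dict[str, tuple[float, float, float]] = {
    "alpha_la": (1.2, 0.30, 0.45),
    "beta_lg": (-1.3, 0.25, 0.35),
    "gmp": (-2.8, 0.15, 0.15),
    "minor": (0.3, 0.20, 0.25),
}

_T0 = 62.5
_LNP0 = math.log(9.0)


def _logistic(z: float) -> float:
    return 1.0 / (1.0 + math.exp(-z))


@dataclass(frozen=True)
class GeneratorSpec:
    """Specification of a synthetic experiment table.

    ``node_truth`` (optional) pins exact true recoveries per node, overriding
    the trend surfaces — used for noiseless regeneration of a reference
    table.  ``noise_sd`` is the replicate standard deviation per species,
    at the scale of the pilot table's error columns.  ``seed`` is mandatory;
    all randomness flows from it.
    """

    seed: int
    grid: tuple[tuple[float, float, float], ...] = DEFAULT_GRID
    trends: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TRENDS))
    node_truth: dict[tuple[float, float, float], dict[str, float]] | None = None
    replicate_count: int = 3
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {k: 0.04 for k in PROTEINS})

    def __post_init__(self) -> None:
        if self.replicate_count < 1:
            raise ValidationError("replicate_count must be >= 1")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValidationError("noise sd must be >= 0")

    def true_recovery(self, species: str, T: float, P: float,
                      C_wpi: float) -> float:
        """Pre-clip true recovery of ``species`` at a node."""
        if self.node_truth is not None:
            return self.node_truth[(T, C_wpi, P)][species]
        b0, bT, bP = self.trends[species]
        return _logistic(b0 + bT * (T - _T0) + bP * (math.log(P) - _LNP0))


def generate_experiment_table(
    spec: GeneratorSpec,
    comp: WPIComposition = WPI_ASSAY,
) -> list[FractionationOutcome]:
    """Draw one synthetic experiment table.

    Observed recoveries are replicate means of Gaussian draws around the
    node truths, clipped to [0, 1]; yield and solid compositions are
    back-computed from the observed recoveries so the table is exactly
    self-consistent.  Raises if more than 10% of the pre-clip node truths
    fall outside [0, 1] (a mis-specified trend or truth table).
    """
    rng = np.random.default_rng(spec.seed)
    truths: dict[tuple, dict[str, float]] = {}
    n_out = 0
    for node in spec.grid:
        T, C, P = node
        t = {k: spec.true_recovery(k, T, P, C) for k in PROTEINS}
        n_out += sum(1 for v in t.values() if not (0.0 <= v <= 1.0))
        truths[node] = {k: min(max(v, 0.0), 1.0) for k, v in t.items()}
    if n_out > 0.1 * len(spec.grid) * len(PROTEINS):
        raise ValidationError(
            f"{n_out} pre-clip true recoveries outside [0, 1]: trend or "
            "truth table is mis-specified"
        )
    outcomes = []
    for node in spec.grid:
        T, C, P = node
        rec_obs: dict[str, float] = {}
        sd_obs: dict[str, float] = {}
        for k in PROTEINS:
            sd = spec.noise_sd.get(k, 0.0)
            draws = truths[node][k] + sd * rng.standard_normal(spec.replicate_count)
            rec_obs[k] = float(np.clip(np.mean(draws), 0.0, 1.0))
            sd_obs[k] = sd / math.sqrt(spec.replicate_count)
        x_wpi = {k: comp.species_fraction(k) for k in PROTEINS}
        Y = sum(rec_obs[k] * x_wpi[k] for k in PROTEINS)
        x_agg = {k: rec_obs[k] * x_wpi[k] / Y for k in PROTEINS}
        outcomes.append(FractionationOutcome(
            T=T, C_wpi=C, P=P,
            ph=ph_model.ph_at(P, C),
            solid_yield=Y,
            solid_composition=x_agg,
            recovery_solid=rec_obs,
            replicate_sd={f"rec_{k}": v for k, v in sd_obs.items()},
        ))
    return outcomes


def true_recovery_table(spec: GeneratorSpec) -> dict[tuple, dict[str, float]]:
    """Clipped true recoveries per node — the generator's ground truth."""
    return {
        node: {k: min(max(spec.true_recovery(k, node[0], node[2], node[1]),
                          0.0), 1.0)
               for k in PROTEINS}
        for node in spec.grid
    }


def generate_equipment_catalog(seed: int, scale_factor: float = 1.0,
                               perturbation: float = 0.0):
    """Reference-shaped equipment catalog with seeded cost perturbations.

    Each unit cost is the reference cost times (1 + perturbation * u) with
    u ~ Uniform(-1, 1), then scaled by ``scale_factor`` (so the total is
    exactly linear in it).
    """
    from dataclasses import replace

    from .datasets import load_equipment_catalog

    if scale_factor <= 0:
        raise ValidationError("scale_factor must be positive")
    if not (0.0 <= perturbation < 1.0):
        raise ValidationError("perturbation must be in [0, 1)")
    base = load_equipment_catalog()
    rng = np.random.default_rng(seed)
    units = tuple(
        replace(u, cost_kusd=u.cost_kusd * scale_factor
                * (1.0 + perturbation * rng.uniform(-1.0, 1.0)))
        for u in base.units
    )
    unlisted = base.unlisted_kusd * scale_factor \
        * (1.0 + perturbation * rng.uniform(-1.0, 1.0))
    return replace(base, units=units, unlisted_kusd=unlisted)
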