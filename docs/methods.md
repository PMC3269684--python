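# Methods

This note documents the models implemented in `wheyfrac`, the choices made
where the published record is ambiguous, and what the tests do and do not
demonstrate.

## pH model

pH of a CO₂-saturated WPI solution is an empirical fit,
`pH = −0.25·ln(P_psi) + f(C_WPI)`, with a cubic `f` in concentration
(wt%). The fit was calibrated at 60 °C between 0.5 and 13.8 MPa; its use
at 31 MPa is an extrapolation inherited from the source study, not
re-validated here. Temperature is accepted by `ph_at` for interface
symmetry but has no effect (a log notice is emitted when T ≠ 60 °C). The
MPa→psi conversion (145.038 psi/MPa) is internal — callers always pass
MPa. Reported-table comparisons round to 1 decimal with ties away from
zero. The inversion `pressure_for_ph` is closed-form; at the 34 MPa
boundary a relative 10⁻¹² slack absorbs exp/log round-off so round-trips
are exact.

## Feed composition: two profiles, deliberately unreconciled

The WPI powder assay (90.1% protein, 2.9% ash, 3.6% moisture) and the
composition implied by the reference stream table (90.0% protein, 2.0%
minerals, 1.0% lactose, 7.0% moisture) disagree; the record offers no
reconciliation, so both are shipped. `WPI_ASSAY` is the default basis for
recovery arithmetic (feed α-LA content 0.901×0.20 = 18.0% of powder);
`WPI_FLOWSHEET` is the default for stream tables, which it closes to the
printed 2-decimal flows. The protein split (55/20/18/7 for
β-LG/α-LA/GMP/minor) is common to both. Species fractions are exposed on
both powder and protein bases; powder is the default.

## Fractionation grid

The 11-condition experiment grid stores percentages as fractions; blank
cells are absent values, never zeros. β-LG and GMP recoveries are recorded
liquid-side (as measured) and converted to solid-side complements on load,
so `rec_solid + rec_liquid = 1` holds by construction. Missing solid
recoveries are back-filled from the recovery identity and flagged
`derived`. The identity check holds within 0.015 on every α-LA and β-LG
cell; one GMP cell (65 °C/10%/31 MPa) sits at 0.0158, consistent with
1-significant-figure rounding of its 3.5% composition entry — the test
asserts this exception explicitly rather than widening the tolerance.

Interpolation is per-field and multilinear: linear (barycentric) within
each concentration plane over (T, ln P), then linear across the two planes
in C. It is exact at nodes, bounded by bracketing node values, and
refuses any query outside the measured hull — the grid is too sparse to
justify extrapolation, and no kinetic model of the precipitation exists to
replace it. Residence time is 2 h for every grid row; scenarios requesting
other hold times are rejected rather than rescaled.

## Flow-sheet

Steady-state only. Stream 2 (the initial CO₂ charge) is transient and
excluded from closure; it defaults to 0 and the reference value
(197.52 kg/h) is available as a constant. Dissolved CO₂ comes from a
two-point solubility table (47 kg/h per 907 kg/h feed at 8.3 MPa;
103.26 at 31 MPa), linearly interpolated and never extrapolated — at
5.5 MPa the CO₂ loop is reported unavailable-with-reason while the liquid
side is still computed. CO₂ recycling is ideal: products carry no CO₂, and
the residual dissolved CO₂ that slowly raises product pH from ~6.0 to ~6.8
is neglected.

Centrifuge split: each measured protein partitions at its experimental
recovery; water goes to the wet solid at a moisture fraction of 0.697
(calibrated to the reference stream table, 29.40/42.17, and exposed as a
parameter); dissolved minerals and lactose follow water. The
minor-protein recovery is never measured, so by default it comes from
yield closure (dry solids in the wet precipitate = Y × WPI powder flow);
a composition-derived alternative (`minor_mode="composition"`) and a
forced-closure mode are available. The two modes give 1.75 vs 1.79 kg/h
of minors in the reference solid against a printed 1.69 — within the
rounding noise of the inputs but not exact; no headline quantity depends
on it. Synthetic outcomes carry an explicit minor recovery and bypass
closure, which is what makes the flow-sheet recovery round-trip exact to
10⁻⁹. Conservation is checked species-wise at the reactor, de-foamer and
centrifuge junctions to 10⁻⁶ kg/h and violations raise.

## Sizing

The de-foaming tank volume is foam volumetric inflow over drainage rate,
`V = (W_liq/60)/(d_foam·r_drainage)`, giving 377.9 L at the 907 kg/h
reference (the "minimum" volume: no safety factor is applied here; plant
costing uses its own 30-min residence sizing). The residence-time relation
as originally typeset, (1/r)·(d_foam/d_liq), evaluates to 0.25 min —
dimensionally inconsistent with its own reported 25 min; the implemented
form is the volume-over-flow identity t_s = d_liq/(r·d_foam), which
reproduces both the 377 L and the 25 min. The literal form is kept behind
`literal=True` for comparison only. Foam constants default to the measured
0.1 kg/L and 0.4 /min (approximately constant over 3–14 MPa); above 14 MPa
foam self-collapses, but a tank is still included in every plant design.
Liquid density defaults to 1.0 kg/L (dilute aqueous solution).

## Economics

Capital = delivered equipment total × Lang factor 3. Facility annual cost
is capital × (1/n + maintenance 6% + insurance 1%). The depreciation
period n is nowhere stated; n = 12 y is the unique round value for which
3×4022 K$ of capital annualizes to the quoted 1850 K$/yr (12066/12 +
0.07×12066 = 1850.1), and it is an exposed parameter. The 6%/1% fractions
are taken on Lang-factored capital; an equipment-basis reading admits no
such calibration. Labor uses staffed hours = 22 production + 2 maintenance
h/day — the unique reading that gives exactly 540 K$/yr at 2 operators ×
$45/h × 250 d/yr. Throughput is WPI rate × 22 h × 250 d. Utilities are a
per-scenario input (314 K$/yr for the reference case): utility *rates* are
known but per-unit consumptions are not, so bottom-up utility modelling is
out of scope. The WPI raw-material cost ($10.70/kg) is excluded from the
$/kg production cost and reported separately.

Only the reference case's equipment catalog is published. Other operating
points are reachable through documented catalog transformers — reactor
+280% at 31 MPa; dual reactors, centrifuge +52%, spray dryer +59%,
blending tank +10% at 5 wt% feed; drum dryer +40% at higher temperature —
plus utilities multipliers (×1.18 high pressure, ×2 dilute feed). These
encode reported *relative* deltas for trend analysis; they do not predict
absolute costs of the uncatalogued cases, and `run_case` marks those costs
unavailable rather than guessing. The reaction/separation split of annual
operating cost is allocated pro-rata on section capital shares (unlisted
equipment spread proportionally); the resulting ~45% reaction share for
the reference case is reported, not asserted, since the published
per-section basis is unknown.

## Synthetic data

The generator emulates the experiment table's structure, not its
chemistry: true recoveries per node come from logistic surfaces in T and
ln P whose directions match observation (both main proteins precipitate
faster with T and P; selectivity falls with P and with T above ~62 °C),
with coefficients chosen once to land in the observed recovery bands.
Observed values are replicate means (default 3 replicates, matching the
2–4 experimental repeats) of Gaussian draws at sd 0.04 — the scale of the
experiment table's replicate-error columns — clipped to [0,1]; yields and
compositions are then back-computed so the recovery identity is exact.
Passing tests on synthetic tables therefore demonstrates bookkeeping
correctness (partitioning, closure, round-trips), not that the trend
surfaces describe real precipitation kinetics. A `node_truth` table can
pin exact recoveries per node, which with zero noise regenerates any
measured grid.

## Numerical conventions

Tolerances: species conservation 10⁻⁶ kg/h; recovery round-trips 10⁻⁹;
recovery-identity validation 0.015; composition sums 1 ± 0.02; recoveries
marginally above 1 (≤ 0.02, from rounded inputs) clip with a warning,
larger excesses raise. Table comparisons use 1-decimal
round-half-away-from-zero. Lookup tolerances are ±0.5 °C, ±0.5 wt%,
±0.2 MPa. All randomness flows from a single integer seed per generator
call; reports serialize with sorted keys so identical inputs give
byte-identical JSON.

## Known limitations

No transient/charging simulation; no aggregation-kinetics model (the grid
is the model); no foam-drainage dynamics beyond the lumped constants; no
equipment-cost correlations or NPV analysis; CO₂ solubility known at only
two pressures; concentrations above 10 wt% unsupported for centrifuge
selection (no compaction plateau observed). The 15 wt% operating branch
and the secondary β-LG/GMP fractionation at 75–80 °C are out of scope.
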