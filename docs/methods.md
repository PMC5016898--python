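# Methods

`odepsim` is a desk-scale digital twin of an optically-induced-
dielectrophoresis (ODEP) microfluidic cell sorter used to purify
circulating tumour cells (CTCs) after negative-selection enrichment.
Five coupled models make up the twin: junction hydrodynamics, ODEP
force physics, synthetic cell samples, the sorting protocol, and the
expression-dilution analysis.  This note records the models, their
assumptions, the tunable parameters, and the known limits of what the
simulations show.

## T-junction flow

The chip is a T-shaped channel: a 25 mm x 1000 um x 100 um main channel
for sample transport and a 15 mm x 400 um x 100 um dead-end side
channel for collection, meeting at a 1000 x 1000 um isolation zone.
Only a window around the junction is meshed (default +/-1.5 mm along
the main channel, 1.5 mm into the side arm); recirculation in a slot of
width w decays on a length scale of roughly w/4.2 (~95 um for the
400 um arm), so the window boundaries are far beyond any feature of
interest and doubling the window changes the readouts by well under 1%.

At the operating conditions the Reynolds number is 0.02-0.8, so the
solver drops the inertial terms and solves steady incompressible Stokes
flow on a marker-and-cell staggered grid with a direct sparse
factorisation.  Boundary conditions: no-slip walls, plane-Poiseuille
inlet and outlet profiles carrying the imposed 2-D flux, and a closed
side-channel end (an `open` mode with a prescribed flow split exists
for sensitivity studies).  The depth direction is depth-averaged by
convention, 2-D flux = Q / H; an optional Brinkman term `-12 mu u / H^2`
emulates the shallow-channel ceiling/floor drag and is off by default
(plain two-dimensional treatment).  Because the discretisation enforces
continuity cell by cell, the discrete divergence vanishes to machine
precision, and the whole field is exactly linear in the flow rate.

Two things were validated against independent theory: a straight-channel
solve reproduces the analytic Poiseuille parabola to discretisation
precision, and the deep side-arm decay of a shear-driven slot matches
the Papkovich-Fadle eigenvalue (decay length w/4.21) and the Moffatt
eddy spacing (pi w / 2.25) to within a few percent.

### Penetration distance

"How deep does the main-channel flow stir the side arm?" is read from
the speed profile along the side-channel centreline versus distance
from the junction mouth.  The criterion "the flow velocity nearly
reaches zero" needs a threshold.  A *relative* threshold would make the
readout flow-rate independent (linearity), so the convention is: a
threshold *fraction* is calibrated once on the 1.0 ul/min condition
against its 40.2 um anchor, converted to an absolute speed using that
condition's mean inlet speed (166.7 um/s), and then held fixed across
flow rates and side widths.  The calibrated fraction lands at ~0.12 of
the mean inlet speed.  The crossing is the first distance at which the
speed falls below the threshold and stays below it, linearly
interpolated between grid nodes.  The readout changes by <3% when the
grid is refined from 10 um to 5 um spacing.

### Cell travel distance

Cells carried past the open mouth are observed to end up tens to
hundreds of micrometres deep in the side arm.  A passive tracer cannot
do this: in a steady 2-D field no streamline crosses into the closed
recirculation, so pure advection predicts essentially zero excursion
for any entry offset (and a flow-rate-independent one at that).  The
twin therefore uses an entrainment model: a cell whose centre passes
the mouth within half a side-channel width of the wall is handed into
the mouth recirculation, rides its downstream flank at its entry
stand-off from the wall, and advances until the local speed falls below
the same frozen "nearly zero" threshold (surface friction holds a cell
that weakly-moving fluid cannot drag).  Cells passing further out -
e.g. on the main-channel centreline - simply transit, excursion 0.  The
entry stand-off is the single calibrated parameter (1.0 ul/min
condition, 37.1 um anchor, bisection; if the anchor lies outside the
model's range the best-fitting offset is used and the residual
reported - at the production grid the residual is +0.5 um).  Trajectory
integration is adaptive RK45 on the bilinearly interpolated field.

### What the flow model does not reproduce

With the frozen threshold the twin predicts penetration depths of
~84 um at 2.5 ul/min and ~106 um at 5.0 ul/min, and a travel distance
of ~104 um at 5.0 ul/min - the correct ordering and roughly the right
scale, but short of the reported characterisation values (125.6 and
170.9 um penetration; 153.0 +/- 13.7 um travel).  The discrepancy is
structural, not numerical: those values imply a near-mouth decay length
of ~93 um, whereas a converged linear-regime solution of this geometry
decays at ~35-60 um over the first half-width (validated against the
slot eigenvalue benchmark above).  Two candidate explanations were
tested and excluded: steady Navier-Stokes with the full convective term
(Picard iteration) changes the crossings by <0.1 um at Re <= 0.83, and
deliberately coarse grids emulating a ~45 um element size change them
by <6%.  Whatever produced the reported spacing - transient effects,
three-dimensionality, cell-cell collisions near the mouth, or
read-off conventions - is outside a steady 2-D single-phase model, and
the twin reports its own converged values rather than tuning toward
numbers it cannot mechanistically reach.

## ODEP force physics

Single-shell dielectrics: each cell is a conductive cytoplasm sphere
wrapped in a thin membrane treated as a surface admittance
(capacitance C_m, conductance G_m).  The effective particle
permittivity is `eps_p* = r c* eps_i* / (r c* + eps_i*)` with
`c* = C_m - j G_m / omega`, and the Clausius-Mossotti factor
`K = (eps_p* - eps_m*) / (eps_p* + 2 eps_m*)` is bounded in
[-0.5, 1] for physical parameters (property-tested).  Defaults (all
configurable):

| parameter | live | dead | unit |
|---|---|---|---|
| membrane capacitance | 1e-2 | 1e-2 | F/m^2 |
| membrane conductance | 1e2 | 1e5 | S/m^2 |
| cytoplasm conductivity | 0.3 | 3.4e-4 | S/m |
| cytoplasm rel. permittivity | 60 | 50 | - |

The dead-cell values encode membrane permeabilisation and equilibration
of the cytoplasm with the 250 mM sucrose medium (3.4 uS/cm, eps_r 78).
At the 100 kHz / 8 V operating point this gives Re[K] ~ +0.96..+0.98
for live cells and ~-0.076 for dead ones: live cells are pulled toward
an illuminated edge, dead cells pushed ahead of it.  Constructors
enforce this sign structure.  Cell radii: cancer cells 11.5 um
(diameter 23 +/- 2.1 um), leukocytes 5 um (a conventional 10 um
diameter; force estimates scale with r, so the radius is recorded in
every calibration report).

The projected light edge is modelled parametrically:
`|grad E^2|(d) = A(w) V^2 exp(-d / lambda(w))`, peaked at the edge.
V^2 scaling is exact by construction (Laplace linearity); a full field
solve of the electrode sandwich is out of scope.  The per-bandwidth
amplitudes follow a fixed attenuation ladder encoding the observed
orderings - bars: 150 > 200 > 250 um; hollow circles: 40 > 60 > 20 um,
with the 20 um annulus (comparable to the cell diameter) flagged as an
unstable trap - and the absolute scale comes from inverting the DEP
formula at the live-cancer anchor (A ~ 1.5e11 V^-0 m^-3 per V^2,
i.e. |grad E^2| ~ 1e13 V^2/m^3 at 8 V).

Calibration matches the four measured 8-V maximum manipulation
velocities (250.49 / 115.57 um/s for live/dead leukocytes under the
150 um bar; 290.01 / 82.84 um/s for live/dead cancer cells under the
40 um circle) exactly, through one effective-polarisability scale per
(cell type, viability) class.  The model is therefore a *net* force
model - surface friction is folded into the anchors, which is also how
the measurements themselves were taken (maximum speed of a moving light
image, converted by Stokes drag `F = 6 pi r eta v`).  Escape thresholds
in the protocol use the class-level calibrated maxima (evaluated at the
class reference radius); an `use_cell_radius` switch enables per-cell
r^2 scaling for sensitivity runs.

## Synthetic samples

The generator emulates the validation mixture: 500 cancer cells
(emulating spiking into 8 ml of blood, 62.5 cells/ml) over a 1e4
leukocyte background, default 90% viable in both classes.  Radii are
truncated normals (cancer 11.5 +/- 1.05 um, leukocyte 5.0 +/- 0.75 um,
floor 2.5 um).  Marker intensities are log-normal: EpCAM positive on
cancer cells, CD45 positive on leukocytes, Hoechst positive on every
nucleated cell, with a 100:1 positive-to-background median separation
and sigma_log 0.25.  At these defaults the single-channel Bayes error
is ~1e-19, so perfect three-channel gating is expected - the simulated
100% purity is a statement about the protocol logic and force
thresholds, *not* about imaging performance on real cells.  A single
`overlap` parameter inflates the spread to stress the gating
(purity degrades monotonically with it, property-tested).  Generation
is bit-reproducible from (seed, parameters).

Batches of 30 cells (configurable) are staged uniformly in the
1000 x 1000 um isolation zone with non-overlap (centre gap of one cell
radius beyond contact), with a packing guard and bounded retries.

## Sorting protocol

A discrete-event loop: stage a batch; detect (any gated cancer cell
triggers stop-flow; otherwise the batch passes to waste); gate
(cancer = EpCAM+ CD45- Hoechst+; leukocyte = CD45+ EpCAM- Hoechst+;
everything else unclassified and conservatively swept); enclose each
gated cancer cell with a hollow circle; sweep the rest with the bar at
100 um/s; carry the circles to the side channel at 50 um/s; relay
within the side channel at 100 um/s.  The escape rule is sharp: a cell
follows a pattern iff the pattern speed does not exceed its calibrated
maximum velocity (no hysteresis, no stochastic escape by default).
Manipulation happens under suspended flow, so the carrier field plays
no role in the stop-flow phases.

A cell is *collected* once delivered past the junction mouth; relay
lag (the dead-cancer maximum of 82.84 um/s is below the 100 um/s relay
bar) is logged but does not revoke collection - harvesting suctions
the whole side channel.  Optional per-step Bernoulli losses
(`collection_loss_probability`, `detection_miss_probability`) emulate
bench attrition; at defaults they are off, which is why in-silico
recovery is 100% while bench recovery (~40%) reflects staining and
transfer losses that have no mechanistic model here.  Purity =
collected true-cancer / collected total; recovery = collected
true-cancer / spiked cancer; both reported as percentages, purity
flagged undefined on an empty collection.

## Expression dilution

A harvested pool with cancer fraction p measures, for gene g,
`R(p) = [p E_c G_c + (1-p) E_l G_l] / [p G_c + (1-p) G_l]` relative to
GAPDH.  Defaults: leukocytes express no MRP4/MRP5 (configurable) and
per-cell GAPDH is equal across types (configurable ratio).  Under
those defaults R(p) = p x pure value, the purified/unpurified fold is
1/p, and `implied_purity_from_fold` inverts the general Moebius form in
closed form (round-trip exact to 1e-12).  Applied to the measured
folds: 9.69-fold (MRP4) implies 10.3% purity of the
negative-selection-only arm - inside the 10-16% range cited for that
class of methods - while 3.44-fold (MRP5) implies 29.1%; the
disagreement is surfaced per gene as a diagnostic, never averaged.
Amplification-efficiency and Ct-noise modelling (ddCt machinery) is
deliberately out of scope: the model works at the level of relative
abundances.

## Numerical and reproducibility choices

- Lengths in um, speeds in um/s, forces in N, voltages in V; SI
  internally in the dielectric formulas.  Grids are 0-based with
  cell-centred sampling.
- Direct sparse solve (SuperLU) of the Stokes saddle system; one
  pinned pressure cell; residual guard at 1e-8 of the driving scale.
  The production grid is 5 um (~4.3e5 unknowns, ~30 s on one core);
  unit tests run at 20 um, which resolves every tested invariant.
- Threshold crossings and calibrations: linear interpolation between
  nodes; bisection for the entry offset with a best-fit fallback.
- One global seed fans out to per-stage child seeds via
  `numpy.random.SeedSequence.spawn`; identical configs give
  byte-identical metrics files.
- Degenerate inputs fail loudly: zero/negative dimensions, too-coarse
  grids, fractions outside [0, 1], overcrowded staging zones, missing
  marker channels, folds inconsistent with zero leukocyte expression.

## Known limitations

- The flow model is steady, 2-D, single-phase and linear; see "What
  the flow model does not reproduce" above for the consequences.
- The travel-distance entrainment hand-off is phenomenological; it
  exists to give cells a physically plausible route into the closed
  recirculation, not to model the (likely 3-D, collision-mediated)
  transfer mechanism.
- The light-edge field model is parametric; absolute grad E^2 values
  inherit the anchor measurements' uncertainty and the leukocyte
  reference radius assumption.
- Aggregation above 8 V is flagged, not simulated; multi-cell
  enclosure, cell-cell hydrodynamics and image segmentation are out of
  scope.
- Simulated 100% purity shows the protocol logic is sound under
  separable markers and calibrated thresholds; it does not certify
  imaging or wet-lab performance on patient samples.
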