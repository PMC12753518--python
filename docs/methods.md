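# Methods

`cochsim` simulates the excitation of human auditory nerve fibers (ANFs) by
cochlear-implant electrode arrays with the standard two-step approach of
computational CI studies: (1) a volume-conductor solve for the extracellular
potential Ve of a monopolar contact injecting 1 μA, and (2) a multi-compartment
cable model of a type-I spiral ganglion cell driven by that potential, with a
bisection search for the threshold current of a 50 μs monophasic pulse.

This note documents the model, its parameters, the synthetic geometry that
stands in for a μCT-traced cochlea, the numerical choices, and the known
limitations — in particular which behaviors of the full-scale problem the
synthetic stand-in does and does not reproduce.

## Synthetic cochlear geometry

No real segmentation is used. The cochlea is a parametric solid of revolution:

* **Spiral.** Insertion angle α runs 0°–690° (≈1.9 turns, α=0 at the basal
  entry). The duct-center radius decays log-linearly from 3195 μm to 1226 μm
  and the height rises linearly by 2800 μm. These values were chosen once so
  that fitted electrode arrays come out 23–27 mm long.
* **Ducts.** At every α three circular cross-sections are stacked: scala
  tympani (ST, radius 380→220 μm), scala media (SM, 200→150 μm) and scala
  vestibuli (SV, 360→200 μm), separated by 20 μm septa. A conical modiolus
  (which, as in five-domain cochlear models, includes the osseous spiral
  lamina) hugs the medial duct walls at 50 μm clearance; a 150 μm bone shell
  surrounds everything, and the exterior continues at bone conductivity out to
  the grounded boundary.
* **Fibers.** 25 ANF trajectories at the angles named in the result tables
  (23°, 77°, 195°, 256°, 416°, 467°, 494°, 680°) plus evenly spaced fillers.
  Each fiber starts at a terminal 30 μm above the ST roof (basilar-membrane
  level, inside the SM pocket), curls up into the inter-scalar band, runs
  medially along the lamina, descends along the medial ST wall to the soma in
  Rosenthal's canal, and continues as a 5.6 mm central axon toward the
  cochlear axis. Dendritic lengths follow a fixed monotone (basal-longest)
  profile, piecewise linear through the order statistics 1320 / 1732 /
  2312 μm, so the default 25-fiber set reproduces those exactly. The geometry
  is fully deterministic; a seed only matters if angular jitter is requested.

### Voxelization

Domains are rasterized on a regular grid (default 60 μm; most analyses and
all tests run at 300 μm) by voxel-center membership, with exterior padding of
one cochlear diameter on every side standing in for the distant grounded
return. Two discretization choices matter at coarse spacing:

* the thin inter-scalar lamina septa are rasterized **conservatively**
  (dilated by half a voxel into the adjacent scalae, except across the open SM
  pocket) so that the ST/SV separation never disappears — thin insulating
  structures otherwise vanish entirely at 300 μm;
* contact cylinders are dilated by half a voxel so an electrode always
  occupies at least one voxel.

Both dilations shrink linearly with spacing, so labeled domain volumes
converge to the analytic tube volumes of the parametric ducts (tested for the
ST: <10 % change per spacing halving). The SM, being the smallest structure,
converges more slowly.

## Electrode arrays

Four arrays are built: peri-modiolar (pm) and lateral-wall (lw) styles in ST
and SV. The centerline fit is an iterative constrained procedure: control
points every 15° hold a radial and vertical offset inside the canal
cross-section; each iteration moves them (damped, Gaussian-weighted over ±30°)
toward the 255 μm iso-distance surface of the nearest fiber, re-splines
(cubic), clamps into the canal, and stops when the update falls below 1 μm
(maximum 200 iterations, error with per-fiber residuals otherwise). The fiber
set therefore dictates the vertical profile while the style only sets the
initial lateral bias (lw: outer wall; pm: toward the axis). The fit is stable:
re-running from a perturbed initialization moves the converged centerline by
<20 μm. Lateral coupling of an ST/SV pair freezes the shared radial
coordinate, dictated by the narrower canal, and re-converges the vertical
profile only.

The carrier tapers linearly from 600 μm diameter at the base to 300 μm at the
apex. Contacts are cylinders (radius 150 μm, height 50 μm — not fixed by any
measured morphometry, hence configurable) centered on the carrier surface,
facing the fibers by default (up in ST, down in SV) or the cochlear axis in
the alternative orientation.

The resulting contact-to-fiber minimum distances are 120–260 μm for lw
arrays and pmST, with lw arrays closest at the dendritic tip and pmST
approaching its basal fibers mid-dendrite. **pmSV is special:** the 255 μm
constraint forces its centerline to hover directly above the spiral lamina,
so its fiber-facing contacts come within 5–110 μm of their target fibers —
much closer than anything in a real implantation. Two basal pmSV pairs
actually intersect the contact metal; `arrays.contact_clearance` identifies
such degenerate pairings and pair-level excitation claims exclude them.

## Volume conductor

Conductivities (S/m): perilymph (ST, SV) 1.43, endolymph (SM) 1.67, modiolus
0.0334, bone and exterior 0.016, contact 1000. The silicone carrier is a
near-perfect insulator; it is assigned 10⁻⁶ S/m so the discrete operator
stays non-singular. Ossification is modeled as reduced ST conductivity:
1.0 / 0.65 / 0.3 / 0.03 S/m for developing / moderate / severe / complete.

The Poisson problem ∇·(σ∇V) = −s is discretized with a 7-point finite-volume
scheme (harmonic-mean face conductivities); 1 μA is injected uniformly over
the active contact's voxels and the padded box boundary is grounded
(homogeneous Dirichlet). The symmetric positive-definite system is solved
with Jacobi-preconditioned conjugate gradients to a relative residual of
10⁻⁸. Fields are computed once per contact at 1 μA and rescaled during the
threshold search. Verified properties: agreement with the analytic point
source I/(4πσr) to <5 % (max, ~1 % typical) in the 5-voxel-to-quarter-box
shell when the analytic values are prescribed on the boundary (the grounded
box itself depresses absolute potentials — its image term is a property of
the desk-scale domain, not of the discretization, which is why the oracle
uses manufactured boundary data); discrete current conservation to 10⁻⁶;
exact source/probe reciprocity.

## Fiber cable model

Compartments along the fiber arc (curvature enters through arc-length
placement): 10 μm unmyelinated terminal → peripheral internodes alternating
with 2.5 μm nodes of Ranvier → 100 μm pre-somatic segment → 20 μm spherical
soma → 5 μm post-somatic segment → ten central internodes (500 μm) with
nodes. Diameters: dendrite 1.3 μm (0.5 μm when severely degenerated), axon
2.6 μm, soma 20 μm. The peripheral internode count n minimizes
|(span − 2.5(n−1))/n − 250| over n ∈ [4, 10], where span is the dendritic
length minus terminal and pre-somatic segments; the default fiber set yields
5–9 internodes of 233–274 μm. The soma center sits 12.5 μm from the
post-somatic center.

Membranes: internodes are passive sheets (1 μF/cm² and 0.1 mS/cm² per sheet,
divided by 40 sheets on the dendrite and 80 on the axon). Active compartments
carry classic squid-type Hodgkin–Huxley kinetics in the reduced-voltage
convention (rest = 0 mV; E_Na = 115 mV, E_K = −12 mV; the leak reversal is
computed so V = 0 is the exact equilibrium), with a tenfold conductance boost
at the terminal, nodes and pre/post-somatic segments reflecting high channel
density. The soma is active with membrane capacitance and conductances
divided by its three surrounding layers. Intracellular resistivity is
0.1 kΩ·cm; axial coupling uses half-compartment resistances 2ρL/(πd²).

Two electrical subdivisions matter and are defaults:

* the 100 μm pre-somatic segment is split into 10 sub-compartments — a single
  lumped segment sees the soma as one large load and blocks propagation;
* each internode is split into 2 sub-compartments — thresholds move by up to
  7 % from 1→2 segments but <1 % from 2→4, so 2 is the converged default.

All HH rate constants are multiplied by a temperature factor k. The default
is k = 9, calibrated so that (a) action potentials last well under a
millisecond, as appropriate for the human cochlea, and (b) severely
degenerated (0.5 μm) dendrites still carry spikes across the soma at
elevated threshold (≈1.4–2× healthy), reproducing the qualitative
degeneration pattern. At k = 12 the briefer APs always block at the soma for
thin dendrites, which would make the degeneration experiments vacuous.

Integration is semi-implicit first order (implicit axial coupling and
linearized membrane with gating updated implicitly from the previous
voltage), dt = 1 μs, unconditionally stable; the extracellular drive enters
through axial differences of Ve scaled by the signed pulse amplitude during
the 50 μs window (onset 0.1 ms). The window (1.6 ms) extends automatically
while an AP is still in flight. A numba-compiled kernel is used when
available, with an equivalent pure-NumPy fallback.

A spike is a crossing of +60 mV (reduced) at either of the two most central
nodes; the initiation site (SIS) is the compartment with the earliest voltage
peak among those exceeding the criterion, ties broken toward the terminal.
Both thresholds are configurable.

## Threshold search

Brackets expand geometrically from 10 μA (×2 up to a 20 mA cap, ÷2 down to a
0.1 μA floor), then bisect to a 1 % relative width; the threshold is the
bracket midpoint, and SIS/latency are read at 1.01× threshold to avoid
borderline non-spikes. Pairs silent at the cap are masked. Bisection agrees
with an independent 0.5 %-step amplitude sweep to within 1 % on randomized
fiber/electrode pairs, and thresholds are stable to <2 % under dt halving and
internode re-subdivision. Because Ve is linear in the injected current,
doubling the unit field halves the threshold exactly.

## Population analyses

Specificity normalizes the fiber×contact threshold matrix per contact
(percentage increase over the column minimum; exactly one 0 % entry per
contact), selectivity per fiber; summary medians exclude the 0 % argmin
entries by default (configurable), since including them shifts medians
downward and the convention used for the printed summaries is not stated.
Conductivity sweeps re-solve the fields per modified map (cached per map
signature and contact) and compare per-fiber target-contact thresholds with
the default condition, reporting per-fiber and median percentage changes and
an ordinary-least-squares regression of new-vs-default thresholds.

The degeneration experiments compare healthy, thin-dendrite (all peripheral
diameters 0.5 μm, terminal included) and dendrite-free chains on the same
fields. The robustness variants rerun healthy thresholds with (a) the
peripheral internode target halved to 125 μm and (b) the soma re-anchored at
1.7 mm arc length along the unchanged path (the natural way to fix the
dendritic length of a traced fiber without moving its terminal or its
electrode distances). Their summary statistic is the change of the *mean*
threshold: individual fibers may move substantially in both directions while
the level stays put, and that is the claim worth testing.

## Problem sizes

The default test-scale conditions, chosen once: 300 μm voxels; three
representative fibers at one-third, middle and two-thirds of the fiber set
for volume-conductor sweeps (spiral-end fibers are excluded because the
synthetic duct terminations distort their local fields); five mid-set fibers
for cable-side orderings; dt = 1 μs. A single field solve at 300 μm takes a
few seconds; the full acceptance battery solves ≈70 fields.

## What the synthetic geometry does and does not reproduce

Reproduced (and asserted in the test suite):

* 255 μm median centerline-to-fiber distances for all four arrays, with
  per-fiber spread <3 %; array lengths 23–27 mm;
* lw arrays closest to the dendritic tip, pmST mid-dendrite for basal fibers;
  axis-facing (alternative) contacts farther from every lw target fiber;
* terminal spike initiation with somatic delay for near-terminal cathodic
  stimulation; SIS progression terminal → peripheral → somatic/central with
  degeneration; thin-dendrite thresholds above healthy for every
  non-degenerate pairing; strictly increasing threshold with electrode
  distance;
* tenfold modiolus conductivity raises median thresholds strongly (the
  fibers live inside the modiolus/lamina domain, which a more conductive
  modiolus drains), and doubled bone conductivity does much less;
* progressive ST ossification monotonically lowers ST-array median
  thresholds (access-resistance amplification around an in-ST contact) with
  positive new-vs-default regression slopes that flatten as ossification
  progresses;
* the carrier-potential profile peaks at the active contact and, with a
  conductive modiolus, shows a second rise one turn (+360°) above it;
* fixing all dendritic lengths at 1.7 mm changes the mean threshold by <5 %.

Not reproduced at this scale (documented limitations, left failing in the
acceptance battery rather than weakened):

* **SV-array insensitivity to ST ossification.** In the compact synthetic
  cochlea a large fraction of an SV contact's return current drains through
  the scala-media window into the ST; blocking the ST elevates the
  distal-fiber potential relative to the soma and lowers SV thresholds by
  16–38 % already at moderate/severe stages (bound: <15 %). In the full-scale
  anatomy — with a 100 mm grounded far field and fibers sealed inside the
  lamina — that drain fraction is negligible. Finer grids recover part of the
  separation but cost ~2 min per solve at 150 μm. Many variants (bone-shell
  thickness, window size, closed partitions, fiber routing) were explored;
  none preserved the SV stability without destroying the ST-side response.
* **Half-internode robustness.** Halving the peripheral internode length
  moves the mean threshold by −12 % (bound: <5 %), dominated by the pmSV
  array whose near-touching contacts are hypersensitive to node positions;
  at realistic (≥233 μm) contact distances this sensitivity vanishes.
* The cross-turn anodic initiation mode (central-node SIS in far fibers) and
  the additivity of simultaneous modiolus+bone changes appear only partially.

Passing tests therefore validate the machinery (solvers, cable model, search,
analyses) and the direction/ordering structure of the findings on a synthetic
stand-in; they do not certify quantitative agreement with any real cochlea.
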