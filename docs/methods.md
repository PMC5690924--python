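# Methods

## Scope and model

`sbrtqa` evaluates stereotactic body radiotherapy (SBRT) plans for
peripheral lung targets against the RTOG 0915 dosimetric compliance
criteria.  The package does not compute dose — it takes a 3D absorbed-dose
grid (from a treatment planning system, a DICOM-RT export, or the built-in
phantom generator) plus a structure set, and derives:

1. a voxel-exact cumulative DVH per structure;
2. the spillage metrics R100% (conformity index), R50%, D2cm and normal
   lung V20/V5;
3. OAR point/volume doses (cord D0.35cc, lung D1000cc, esophagus D5cc,
   heart D15cc, rib Dmax/D1cc/D5cc/D10cc, 3D isocenter-to-rib distance);
4. per-metric compliance categories and a plan-level verdict;
5. cohort aggregates: AVG/STDEV rows, deviation counts, the rank
   correlation between rib proximity and rib Dmax, and linear-quadratic
   BED with α/β = 3 Gy for ribs.

## Conventions and numerical choices

**Geometry.** All metrics are dose-grid quantities.  Voxel index (0,0,0)
has its *center* at the grid origin; coordinates are physical millimetres;
spacing may be anisotropic.  Structures read from DICOM-RT are rasterized
onto the dose grid by a voxel-center-inside test with the even-odd polygon
rule; partial voxels are not fractionally weighted.  This matches common
TPS DVH behaviour and is a documented limitation: volumes of small convex
structures carry a discretization error of a few percent at 2 mm spacing.

**DVH.** The curve is the descending-sorted list of voxel doses — no
binning.  `V(d)` uses an inclusive threshold (dose *d or more*).  `D(v)`
is the largest dose whose covered volume is at least `v`, linearly
interpolated between adjacent sorted voxel doses; it tends to the maximum
voxel dose as `v → 0⁺`.  "Dose to < X cc" metrics are evaluated as
`D(X cc)`, the minimum dose received by the hottest X cc.

**Normalization.** Plans are evaluated after DVH normalization: every
voxel dose is scaled by one factor so that 95% of the PTV receives the
prescription (D95% = Rx).  The factor is recorded in plan metadata.

**Distances.** Margin expansion uses the Euclidean distance transform with
per-axis sampling; the boundary is inclusive (a voxel center exactly at
the margin belongs to the expansion).  The D2cm exclusion region is the
complement of the 20 mm expansion of the PTV, unbounded outward and not
restricted to the body contour (air included).  Point-to-structure
distance is the minimum center-to-center distance; sub-voxel surface
precision is not attempted, since the 2 mm grid dominates the error budget
and one convention is used everywhere.  Point "maximum doses" are voxel
maxima.

**Compliance bands.** A band `(lower, upper)` is classified as:
per-protocol iff `value ≤ lower`; minor iff `lower < value ≤ upper`;
major iff `value > upper`.  This boundary rule is the one that reproduces
every deviation footnote in the reference cohort (e.g. an R50 of 4.2 in
band 4.2–5.2 passes, a D2cm of 61.9 at upper bound 61.9 is minor).  R100%
(1.2–1.5) and V20 (10–15%) bands are volume-independent; R50% and D2cm
bands are linear interpolations, in PTV volume, of bound functions through
the 20 published (volume, band) pairs, clamped outside the anchor range.
Duplicate anchor volumes (two 20.1 cc patients with D2cm lower bounds 53.0
vs 53.1) are merged by averaging; the 0.05% difference is far inside the
table's printing precision.  Whether the source protocol interpolated
linearly or used nearest-row lookup is not documented; linear interpolation
through the published pairs is this package's choice, and the criteria
file is user-replaceable JSON.  OAR limits are single thresholds; an
exceedance is reported as a deviation without a minor/major split.

**BED.** `BED = n·d·(1 + d/(α/β))` with `d = D/n`, applied to the dose
metric itself with each patient's own fraction count (3 fx for the
54 Gy patients, 5 fx for the 50 Gy patients).  This convention is
validated by the cohort tests: it reproduces the reference mean BED3 of
249 Gy (rib Dmax) and 173 Gy (rib D1cc) exactly after integer rounding.
The protocol reference values 165/112 Gy are stored as displayed
constants: recomputing BED3 of the stated 4-fraction rib limits (40 Gy
max, 32 Gy to <1 cc) yields 173.3/117.3 Gy, so the published derivation is
not reproducible and is deliberately not reverse-engineered.

**Statistics.** Cohort SD is the sample (n−1) standard deviation; both
conventions round to the published digits, so the choice is by convention.
The distance–dose association uses Spearman rank correlation plus binned
means over the qualitative proximity bands <2 cm, 2–5 cm, >5 cm.

## The embedded reference cohort

A packaged, checksummed CSV holds the 20-patient peripheral lung SBRT
evaluation tables: PTV volume (11.1–163.0 cc), prescription (54 Gy/3 fx
for patients 1–5, 50 Gy/5 fx for 6–20), the four spillage metrics with
their per-patient R50/D2cm bands, OAR doses, and rib doses with the 3D
isocenter-to-rib distance.  These per-patient values are *inputs*: they
cannot be recomputed without the clinical dose grids.  What the package
recomputes from them is everything downstream — classification flags,
deviation counts, summary rows, BED means, and the distance–dose trend.

## The synthetic phantom

The generator emulates the geometry of a peripheral lung SBRT plan, not
its physics.  Dose is `Rx · f(r_eff)` where `r_eff` is the
ellipsoid-equivalent radius of the PTV (isodose surfaces are scaled copies
of the PTV) and `f` is 1 on a plateau of radius `r100 = r100_scale·r_geo`
followed by exponential falloff with half-value distance `g50`:
`f(r) = 2^(−(r−r100)/g50)`.  Because volumes of `r_eff`-shells are
`4/3·π·r³`, the spillage metrics are available in closed form
(R100 = r100_scale³, R50 = ((r100+g50)/r_geo)³, D2cm from `f` evaluated
2 cm past the longest semi-axis), and `solve_profile_for_targets` inverts
them.  Structures: ellipsoidal PTV, ITV = PTV eroded by the 5 mm setup
margin, a large spherical lung region, a rib shell at a configurable
isocenter distance, and a cord cylinder near the grid edge.  Defaults
follow the modelled study conditions: 2 mm isotropic grid, PTV volumes
sampled log-uniformly over 11.1–163 cc, prescriptions 54 Gy/3 fx (25% of
plans) or 50 Gy/5 fx, conformity targets spanning the clinically observed
range (R100 1.05–1.45, R50 3.2–5.5).  Optional seeded multiplicative
Gaussian noise (off by default) emulates Monte Carlo statistical noise
for robustness tests.

The isocenter is placed at an asymmetric sub-voxel offset from the voxel
lattice: centering an analytic sphere exactly on a lattice point produces
volume artifacts of several percent in voxel-center counts, while the
offset keeps rasterized volumes within about 1% of analytic across the
radius range.

What passing phantom tests show: the DVH, geometry, metric and compliance
code is correct for radially monotone dose distributions on clean masks.
What they do not show: behaviour on real multi-beam dose topologies
(non-convex isodoses, hot spots in ribs), contouring noise, or TPS
interpolation conventions — those require clinical data.

## Problem sizes

Test phantoms use 2 mm grids of roughly 60–130 voxels per axis (one 1 mm
oracle at 105³); the recovery suite runs a 20-plan cohort at 2 mm.  The
full test suite completes in well under a minute on one CPU; the
cohort-table reproductions alone run in milliseconds.

## Known limitations

* Voxel-max stands in for point max dose; no finer interpolated grid.
* No fractional-volume (partial voxel) DVH weighting.
* D2cm is not restricted to the body contour (none exists on phantoms).
* The DICOM-RT reader is read-only, assumes axis-aligned orientation
  (1,0,0,0,1,0) and uniform slice spacing, and takes the PTV centroid as
  isocenter when none is supplied.
* BED assumes uniform dose per fraction of the queried metric.
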