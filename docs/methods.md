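# Methods

This note documents the models, numerical choices and limitations behind
`tabfx`.  It is written for a reader who wants to judge what the package's
results do and do not demonstrate.

## The question and the experimental design

CT-based attenuation correction (CTAC) in SPECT always includes the patient
table in the attenuation map, because the table is in the beam for part of
the orbit.  CT-less attenuation correction cannot model the table.  The
package measures the table's contribution by a paired design: one set of
projection data is simulated from an object *resting in a table* (the
physical reality), then reconstructed twice — arm A with the attenuation
map from the full CT, arm B with the attenuation map from the
table-stripped CT.  Everything else (projections, scatter correction,
reconstruction parameters) is shared, so any difference is attributable to
the table's attenuation alone.

## Synthetic data

**Coordinate convention.** World axes: `x` = patient left, `y` = patient
posterior (the table side is `+y`), `z` = axial.  Voxel centers at
`origin + index * spacing`, 0-based.

**Patient table.** An arc-shell cradle (circular-arc annulus cross-section,
uniform along `z`): chord 450 mm, sagitta 60 mm, thickness 12 mm, uniform
−620 HU, with a 10 mm air gap between the cradle's deepest inner point and
the object's lowest point.  Real vendor pallets are carbon-fiber sandwiches
whose geometry and density are not published, so the defaults were
*calibrated once* against the three published constraints available for
clinical tables: (i) the mean per-angle photopeak count loss over a 360°
orbit must lie in the reported 2–12 % band (the defaults give 3.3 %, with a
per-angle maximum of 8.1 %), and (ii) the phantom reconstruction difference
must not exceed the reported 17.5 % maximum (the defaults give 16.0 % / 16.8 %
for the QC / MPI protocols).  A thicker or denser shell (e.g. 15 mm at
−400 HU) overshoots constraint (ii) at oblique posterior views, where rays
graze the curved wings near-tangentially with path lengths of 100+ mm —
a geometric effect a flat-slab intuition misses.

**Jaszczak-type phantom.** Flangeless-model dimensions: 216 mm interior
diameter, 186 mm interior height, 9.5 mm acrylic shell (120 HU), water fill
(0 HU) carrying uniform activity 1.0 per voxel.  Sphere and rod inserts are
omitted: the question is attenuation, not resolution.  The phantom model
and fill are declared defaults, not inferred from any scanner's inventory.

**Cardiac studies.** Torso = elliptic soft-tissue cylinder (0 HU); left
ventricle = half-ellipsoid shell (outer semi-axes 32/32/45 mm, wall
~12 mm) in the anterior half of the torso, long axis tilted
apex-anterior-left-inferior.  Myocardial activity 100, background 10
(fraction 0.1).  A perfusion defect is an angular sector of the wall
(default 90° span, 85 % of the long axis from the base) scaled to a
residual-uptake fraction.  Lungs are omitted: the table effect acts through
the posterior path length, which lung tissue anterior of the heart does not
change qualitatively.  Habitus variation maps a BMI draw (truncated normal,
mean 29.7, SD 6.0, range 17.3–40.8, matching the published cohort) linearly
onto torso semi-axis bounds of 140–195 × 95–140 mm; the stress:rest mix is
13:6 and one study in three carries a defect.  All generation is
deterministic given the spec; the cohort sampler is deterministic given its
seed.

## Attenuation maps

Bilinear HU→μ at 140 keV: `μ = μ_w (1 + HU/1000)` for HU ≤ 0 (clamped at
0), `μ = μ_w (1 + 0.5·HU/1000)` above, with `μ_w = 0.154 cm⁻¹`.  Vendor
conversion curves are proprietary; this is the standard two-segment model
with both constants exposed in `MuCalibration`.  CT (1–2 mm in-plane,
5 mm slices) is resampled onto the reconstruction grid by trilinear
interpolation in world coordinates, filling −1000 HU (air) outside the CT
extent.

One deliberate departure from the clinical grid description: a 128×128
matrix of 1 mm pixels cannot contain a 450 mm-wide table, so the CT grid
keeps the 1 mm pixel option but widens the matrix to cover a fixed 512 mm
field of view (512/d pixels at d mm for downsample factor d).

## Projection and reconstruction

**Geometry.** Ideal parallel beam, rays confined to transaxial planes.
The detector at angle θ (from anterior, rotating toward patient-left)
receives rays along `(sin θ, −cos θ)`.  The MPI protocol's converging
collimator is approximated as parallel ("nearly parallel at the edges"),
and its cardiocentric orbit as circular: for a parallel geometry with a
full-width detector the orbit center and radius do not enter the model.
Two detector heads are an acquisition-time detail with no effect on
simulated projections.  Distance-dependent resolution, septal penetration
and dead time are not modeled.

**Operator.** Per view the volume is rotated in-plane by a sparse bilinear
matrix so rays align with a grid axis.  Two rotation forms are used:
activity is rotated with the mass-conserving *splat* (transpose of the
inverse-angle interpolation matrix) so each emission voxel contributes its
full content at every view — a point source at any in-grid position
projects identical totals at all angles to machine precision; the μ-map is
rotated with the value-exact *gather*, appropriate for sampling a path
integral.  Along the ray the rotated volume is supersampled 2× by linear
interleaving (step = half the in-plane spacing) and attenuated by
`exp(−Δt Σ_{t'≥t} μ)`, the cumulative integral from the emission sample to
the detector.  Projection values are per unit voxel path length, so with
μ ≡ 0 the per-view total equals the total activity and OSEM preserves
counts.  Because the rotations are explicit sparse matrices, the
backprojector is the *exact* adjoint of the forward projector; the pair is
verified against an exhaustive per-voxel line-integral oracle and by an
inner-product adjointness identity in the test suite.

**Scatter.** The optional noise model scales the noiseless primary to a
target total count, builds the lower-window estimate as a transaxial
Gaussian blur (40 mm) of the primary with lower-window/primary total
ratio = `scatter_fraction` (0.3), adds a configurable fraction of that
shape into the photopeak, and Poisson-samples both windows with a seeded
generator.  Correction uses the energy-window estimate
`S = (C_low/21 keV)·(21 keV)/2` subtracted and clamped at zero — with only
a lower window the upper-window term of the triple-energy-window method is
zero.  The headline phantom results are noiseless; scatter correction is
then an identity, which is intended: the comparison isolates attenuation.

**OSEM.** Multiplicative EM update per subset with the attenuated system
matrix; 10 iterations × 3 subsets by default.  Views are assigned to
subsets by bit-reversal interleaving (balanced angular coverage); the
remainder views join the last subset, and views within a subset are kept in
natural order so a single subset reduces exactly to MLEM.  Forward
projections in the denominator are floored at 1e-12; voxels with zero
subset sensitivity are set to zero; all voxels are floored at 1e-12 to
keep the multiplicative update alive.  Scattered counts are subtracted
before reconstruction (not added inside the EM denominator); an additive
mode would be a straightforward extension.  No post-filter is applied.

## Polar maps and scores

The reconstructed volume is resampled so the LV long axis lies along `+z`
(apex low).  The rotation is built from the LV frame (projected anterior →
`−y`) rather than a minimal-rotation formula, so the polar angular
convention (0° anterior, increasing toward the lateral wall, viewed from
apex) is preserved without azimuthal twist.  The ground-truth axis from the
generator is used instead of automatic axis finding — axis estimation is a
failure mode orthogonal to the question being asked.  Twenty short-axis
slices spanning 5–92 % of the apex→base length (margins avoid pure
partial-volume samples at the tip and base edge) are sampled at 60 angles
by the maximum value along each radial ray (standard in MPI
quantification; mean-count sampling is a config switch away).  Samples are
normalized to the polar-map maximum; the 17 AHA segments (6 basal, 6 mid,
4 apical over fixed 60°/90° sectors, 1 apex cap for the first quarter of
slices) average the normalized samples.  Scores 0–4 come from fixed
descending uptake thresholds (70/50/30/10 %).  Absolute scores are
package-defined — no normal-database z-scoring — but both AC arms share
the rule, so *paired* score differences remain meaningful.

## Comparison statistics

Percentage difference `100·(A−B)/A` with A = with-table-AC arm, masked at
`A > 0.05·max(A)` (formula and mask fraction are config-exposed; the
maximum *absolute* value is reported).  Cohort scores are compared as
paired observations: one pooled paired t-test over all study–segment
pairs, Shapiro–Wilk per arm (reported even though integer scores are
grossly non-normal — the p≈0 outcome is itself informative), Pearson
correlation of the pooled pairs, and 17 per-segment paired t-tests with no
multiple-testing correction (raw per-segment significance is what the
clinical comparison reports).  Degenerate cases (zero-variance
differences) report p = 1.0 with a flag, and the self-correlation of
identical arms is defined as exactly 1.

## Problem sizes and determinism

The package's reference experiments run at a desk scale chosen as the
coarsest grid that preserves the full 614 mm field of view and resolves the
phantom wall: SPECT 64³ at 9.6 mm (half the clinical 128³/4.8 mm
resolution), CT 256²×48 at 2×2×5 mm; the cohort uses 64×64×32 with MPI's
34 views.  All headline runs are noiseless and bit-reproducible; the only
randomness (cohort sampling, optional Poisson noise) is driven by explicit
seeds.  The full clinical grids are available by constructing the default
grids with `downsample=1`; the physics does not change, only discretization.

## Limitations

* Everything is synthetic: no CT beam physics (kVp, kernels, artifacts),
  no anthropomorphic anatomy, no motion, no misregistration between SPECT
  and CT.  Passing tests demonstrate internal consistency of the measured
  table effect, not agreement with any particular scanner.
* The table is a single uniform material; real pallets are layered
  sandwiches, and cross-sections that vary along `z` (head holders,
  rails) are out of scope.
* Parallel-beam optics understate the converging collimator's center
  magnification; the MPI-protocol results should be read as a geometry
  (which views cross the table), not a sensitivity model.
* Integer scores from a synthetic normalization are not clinical scores;
  only between-arm differences are interpretable.
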