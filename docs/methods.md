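# Methods

## Scope and model

`protonarc` answers one geometric question: what is the smallest maximum
beam energy that lets a coplanar proton gantry reach the distal edge of
every cranial target from the angles an arc of length ϕ must use?  It is a
range calculation, not a dose calculation: multiple Coulomb scattering,
nuclear interactions, energy straggling and dose deposition are all out of
scope, as are non-coplanar (vertex) fields and critical-structure
avoidance — removing angles for avoidance reasons can only lower a maximum,
so the reported values are upper bounds on the energy a delivery system
needs.

The per-patient statistic is

    En(phi) = max_i  min_k  max_{j in window k} E_max[i, j]

with targets *i*, gantry angles *j* (J = 51 equally spaced over 360°), and
windows *k* of m = floor(phi / (360/J)) + 1 consecutive angles (clamped to
J), one starting at each grid angle, wrapping modulo 360°.  ϕ = 1°
therefore means a single direction (m = 1) and ϕ = 360° uses every angle.
The floor-plus-one rule matches a window "spanning 0°–90°" holding the grid
angles up to 84.7° (13 of them at J = 51); rounding up instead would change
En(90°) by at most one window member.  Ties among winning windows go to the
smallest start index.

## Pipeline stages and the parameters that matter

**Tissue model.**  Density cutoffs 0.005 / 1.100 / 1.500 g/cm³ partition
voxels into air, adipose, muscle, bone (boundary convention: air is
[0, 0.005), the adipose band is closed on both ends, bone is strictly
> 1.500).  Stopping-power ratios to water — 1.029, 0.884, 0.930, 0.989 —
are energy-averaged constants over 50–250 MeV; their residual energy
dependence is below 0.5% and is not modelled.  Both sets are overridable
via config; a `WATER` classification (all ratios 1) exists for phantoms
whose geometry must be checked against closed-form chord lengths.

**Beams.**  Default source model is a parallel beam (SAD = ∞); finite SAD
is supported but for cranial geometry the divergence correction to path
length is second order, and parallel beams make the analytic oracles exact.
Gantry 0° places the source on the +y side of the isocenter, angles
increasing toward +x; the isocenter defaults to the centroid of the
patient's target masks.  Spot lattice: one volume-axis-aligned 3-D grid at
0.235 cm spacing per target (0.235 = 0.4 × FWHM of a σ = 0.25 cm Gaussian
beamlet).  A beam's-eye-view-aligned lattice would shift individual spots
by at most one spacing and is not used.

**Distal-spot selection.**  The target mask is sampled along each spot's
ray at quarter-voxel steps; the last in-target sample marks the distal
boundary.  Per lateral ray column (columns quantized at the spot spacing)
the spot *nearest* the boundary survives — from either side, so the depth
error is centred with half-spacing scale rather than a systematic
full-spacing undershoot.  The cap is half a spacing; if lattice/voxel
quantization at a particular angle leaves no spot that close (a resonance
that does occur at coarse voxel sizes), the cap relaxes to the nearest
available gap, never beyond one full spacing.  Rays grazing the target
contribute no spot.

**Ray tracing.**  WEPL is the exact Siddon-style sum of per-voxel
intersection length × effective density between the grid entry point and
the spot.  Sub-segments are attributed to the voxel containing their
midpoint, which yields a half-open face convention per axis and makes the
additivity invariant (splitting a ray at any interior point changes nothing
beyond 1e−9 relative) hold.  Accumulation starts at the grid boundary:
exterior air at 0.0012 g/cm³ × 1.029 contributes < 0.1%, so no patient
surface detection is needed.  The distal margin (default 0, typical
clinical choice up to 1 cm) is added to d_max in water-equivalent cm before
the energy lookup; in near-unit-density brain, geometric and
water-equivalent margins coincide to a few percent.

**Range–energy model.**  The Bragg peak depth is approximated by the CSDA
range in water — the difference is sub-millimetre at these energies, far
below the ~2% energy uncertainty already implied by stopping-power
conversion.  R = α·E^p is fitted by least squares on log R vs log E to the
embedded 12-point NIST PSTAR CSDA table (50–250 MeV); the fit reproduces
every fixture point within 2% (enforced at construction; measured max
deviation 1.5%, p ≈ 1.763, α ≈ 0.00228 cm·MeV⁻ᵖ) and is tabulated at every
1 MeV.  Lookup returns the grid energy with the nearest range; ties go to
the lower energy; depths outside the covered interval clamp to 50 or
250 MeV with a machine-readable flag that propagates into the reports
rather than aborting a cohort run.

**Cohort statistics.**  Histograms use left-closed 5 MeV bins anchored at
50 MeV.  The coverage statistic rounds the required patient count to the
nearest whole patient (half up, minimum one), so "67% of three patients"
means two.  Medians of even cohorts are midpoint averages.  The linear
regressions of max/median vs ϕ are descriptive characterizations of the
trend only; no inference statistics are attached.

## Synthetic phantoms

The head phantom is an ellipsoidal skull: exterior air (0.0012 g/cm³, not
exactly zero so the air classification branch is exercised), a bone shell
(default 0.6 cm, 1.61 g/cm³), a brain interior (1.04 g/cm³), an optional
scalp-fat layer, and ellipsoidal targets that must lie fully inside the
brain.  Layer surfaces are the head ellipsoid with semi-axes shrunk by the
layer thicknesses — an offset-surface approximation adequate for thin
shells.  Optional Gaussian density noise (seeded, clipped at zero, default
off) applies inside the head only.  The cohort generator jitters head size
a few percent, places 1–2 targets of 0.7–1.4 cm semi-axes within 55% of
the brain radius, and draws disease labels from a typical SRS case mix so
grouped summaries have content.

What the phantoms do *not* emulate: real CT calibration and noise texture,
air cavities and sinuses, anatomical asymmetry, and the clinical
distribution of target depths.  Passing tests therefore demonstrate that
the geometry/range machinery is correct and self-consistent, not that any
specific clinical cohort's energy values are reproduced; synthetic-cohort
summaries are qualitatively comparable (requirements rise roughly linearly
with arc length) but numerically specific to the phantom population.

Default grids: the clinical-export voxel size 0.0703 × 0.0703 × 0.125 cm
is the `PhantomSpec` default; the cohort generator and the test suite use
coarser grids (128×128×64 at 0.15/0.15/0.25 cm, and smaller still for unit
tests) to keep runs to seconds per patient.  The geometry-oracle checks run
at the clinical voxel size, where the sphere phantom reproduces the 9 cm
analytic chord to ~1 mm.

## Numerical and design choices

- Coordinates: right-handed axes in cm, origin at the volume corner, voxel
  centres at (index + 0.5) × voxel size; NIfTI (mm, centre-based affine) is
  converted on I/O.  Densities are stored as float64, masks as uint8, so
  round-trips are exact.
- The minimax is evaluated via stacked circular shifts (vectorized window
  maxima, O(J·m) work at J = 51 — negligible); an independent brute-force
  double loop lives in the test suite as the oracle.
- Degenerate inputs: empty targets, empty spot sets, negative or
  non-finite densities, non-monotone range fixtures and out-of-range arc
  lengths all raise with messages naming the offending object (target
  label, (i, j) pair, voxel index).
- Determinism: every stochastic step (phantom noise, cohort sampling) takes
  an explicit integer seed; identical seeds give bit-identical volumes and
  byte-identical curve CSVs.

## Known limitations

- The distal-spot depth carries ± half-spot-spacing scatter by
  construction; at voxel sizes ≳ 0.25 cm the lattice/surface quantization
  can make d_max angle-dependent by several millimetres on perfectly
  symmetric phantoms.  Fine grids (≤ 0.125 cm) reduce this to ~1 mm.
- The Bragg–Kleeman power law is a two-parameter summary of the range
  table; its ≤ 1.5% fixture error is inherited by every energy estimate,
  consistent with the ~2% accuracy the tissue model already limits the
  pipeline to.
- Finite-SAD mode shares all code paths with parallel mode but its
  divergence effect on path length is not separately validated against an
  analytic oracle.
- `EnergyMatrix` requires all entries within the 50–250 MeV grid; targets
  shallower than the 50 MeV range (≈ 2.2 cm water) appear as clamped
  entries, flagged but indistinguishable from exactly-50 MeV requirements
  in the statistics.
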