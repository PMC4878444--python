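# protonarc

Estimates the **maximum proton kinetic energy** an accelerator must deliver
to treat cranial stereotactic radiosurgery (SRS) targets with **coplanar
arc-based proton therapy**, as a function of the gantry arc length used.
The accelerator's maximum energy dominates the size and cost of a proton
system, and cranial targets are shallow, so a machine dedicated to brain SRS
can plausibly get away with far less than the conventional 230–250 MeV —
*if* the treatment arcs are chosen well.  This package quantifies that
trade-off on voxelized density volumes.

It is aimed at medical-physics researchers studying accelerator requirements
and treatment-geometry trade-offs; it computes range geometry only — no dose.

## Method

For a patient with target ROIs indexed by *i* and *J* = 51 coplanar gantry
angles equally spaced over 360° indexed by *j*:

1. **Effective density.** Each voxel of the mass-density volume is classified
   by density into air (< 0.005), adipose (0.005–1.100), muscle
   (1.100–1.500) or bone (> 1.500 g/cm³) and multiplied by that tissue's
   mass-stopping-power ratio to water (1.029, 0.884, 0.930, 0.989), giving a
   water-equivalent density grid.
2. **Distal spots.** A 3-D lattice of beam spots at 0.235 cm spacing (40% of
   the FWHM of a σ = 0.25 cm Gaussian beamlet) covers each target; for every
   gantry angle, the spots closest to the last target→non-target transition
   along their ray are kept — the distal edge of the target.
3. **Radiological depth.** The water-equivalent path length (WEPL) from the
   beam origin to each distal spot is the Siddon-style exact sum of
   per-voxel intersection length × effective density; the per-angle maximum
   is *d*<sub>max,*i*,*j*</sub> (an optional distal margin, in
   water-equivalent cm, is added here).
4. **Energy.** *d*<sub>max,*i*,*j*</sub> maps to *E*<sub>max,*i*,*j*</sub>,
   the 1 MeV-grid energy (50–250 MeV) whose Bragg-peak depth in water is
   closest, using a Bragg–Kleeman model *R* = α·*E*<sup>*p*</sup> fitted to
   an embedded NIST PSTAR CSDA water-range table (fit error < 2%).
5. **Arc minimax.** For an arc of ϕ degrees the per-patient requirement is

   *En*(ϕ) = max<sub>*i*</sub> [ min<sub>*k*</sub> ( max<sub>*j* ∈ window *k*</sub> *E*<sub>max,*i*,*j*</sub> ) ]

   over the *J* circular windows of consecutive angles spanning ϕ
   (ϕ = 1° means a single direction).  *En* is nondecreasing in ϕ.
6. **Cohort summaries.** Per-disease maxima, 5 MeV histograms,
   max/median/mean vs ϕ with descriptive linear regressions, and coverage
   ("smallest energy treating a given fraction of patients").

Clinical CT cohorts are not distributed with the package; a seeded synthetic
head-phantom generator (elliptical bone shell, brain-density interior,
ellipsoidal targets, NIfTI I/O) stands in for them, and uniform-sphere
phantoms provide closed-form oracles.

## Worked example

`examples/03_arc_requirement.py` builds one synthetic head with an
off-centre 1.2 cm lesion and runs the full 51-angle pipeline:

```
E_max over angles: min 86 MeV, max 119 MeV
En(    1 deg) =    86 MeV   (best arc starts at angle index 10)
En(   90 deg) =    92 MeV   (best arc starts at angle index 4)
En(  180 deg) =   106 MeV   (best arc starts at angle index 48)
En(  270 deg) =   113 MeV   (best arc starts at angle index 38)
En(  360 deg) =   119 MeV   (best arc starts at angle index 0)
```

Reading: from the best single direction this lesion needs only 86 MeV
(the shallowest approach); requiring a full 360° rotation forces the beam
through the far side of the head and raises the requirement to 119 MeV.
The other examples cover the sphere WEPL oracle, the range–energy lookup,
and the cohort pipeline; the CLI mirrors the latter:

```bash
protonarc phantoms --n 10 --seed 42 --out scratch/cohort
protonarc run --manifest scratch/cohort/manifest.yaml --out scratch/reports
protonarc report --curves scratch/reports/curves.csv --out scratch/tables
```

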