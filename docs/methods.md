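# Methods

## The dose model

The package converts a segmented micrograph into an areal dose under a
**sphere/monolayer model**.  Particles are solid spheres of primary
diameter *d* (nm) and bulk density *ρ* (g/cm³); the projected area of one
particle is the equatorial disk π d²/4 and its mass ρ π d³/6.  A field with
particle-occupied area *A* out of total area *F* therefore carries

    N = A / (π d²/4)          particles,
    m = N ρ π d³/6            mass,
    dose = m / F = (A/F) × (2/3) ρ d.

Assumptions, stated explicitly:

* **Monolayer.** Every segmented pixel is one particle-layer thick.
  Vertically stacked aggregates add mass without projected area, so the
  model under-reports them by construction.  The simulator's stacking mode
  turns this from a caveat into a measured curve: at stacking probability
  0 / 0.3 / 0.6 the measured-over-true dose ratio falls roughly as
  1 / 0.7 / 0.4 (each stacked particle hides its full mass).
* **Primary size enters as diameter.**  The sphere model has no other
  defensible reading of a "primary particle size" given only a size and a
  density.
* **The imaged field is representative of the insert.**  Dose per field is
  reported as insert-level dose; several fields per condition are averaged
  (mean ± sd) by the pipeline.
* **No particle identity.**  Any pixel above threshold counts; debris and
  substrate texture are the user's responsibility to exclude via the
  threshold.

Nominal dose is concentration (µg/mL) × volume (µL) × 10⁻³ / insert area
(cm²); defaults are 30 µL on a 1.1 cm² hanging insert.  Deposition
efficiency is 100 × measured/nominal.

### Units and rounding

Lengths are carried in nm, image areas in nm²/µm², doses in µg/cm²; every
conversion factor lives in `nebudose.units`.  All computation runs at full
precision.  Printed-style rounding (2 significant figures for doses,
integer percent for efficiencies) is applied only in the report layer —
deliberately, because integer efficiencies are generally *not* recoverable
from 2 s.f. dose columns of the same table (0.02/0.027 rounds to 74% while
the full-precision pair behind such a row may round to 92%).  Reported
reference efficiencies are therefore anchored on internally consistent dose
pairs only (0.24/0.27 → 89%, 0.58/0.68 → 85%, 0.18/0.68 → 26%).

## Segmentation

A pixel is particle iff its intensity is **strictly greater** than the
threshold.  The default threshold policy is between-class-variance (Otsu)
maximization on the intensity histogram, because deposition micrographs are
near-bimodal (substrate vs particle) and no universal fixed threshold
exists across instruments; the threshold actually used is always recorded
in the result and the logs, and a fixed value can be passed instead.  A
constant image cannot be auto-thresholded and raises.

Aggregation is summarized by connected components with **8-connectivity**
(diagonal-touching pixels merge — conservative for aggregate detection;
lateral resolution of touching particles is explicitly out of scope).  The
single-particle cutoff for calling a component an aggregate is twice the
projected area of one primary particle.

## The simulator

`simulate_deposition` emulates a secondary-electron micrograph of disk-like
deposits on a flat substrate, with ground truth exact by construction
(mass = particle count × sphere mass; dose = mass / field area; every
invariant is an equality, not an approximation).

* **Homogeneous mode** places centers by a uniform spatial point process —
  the pattern a stable, well-dispersed suspension leaves.  Given a target
  dose the count is Poisson around the matching intensity; an exact count
  can be requested instead.
* **Clustered mode** uses a Thomas process (Poisson parents, isotropic
  Gaussian offspring of scale `cluster_radius_nm`, default 200 nm, mean
  cluster size default 10) — emulating the small and large aggregates an
  unstable suspension deposits.  When an exact total count is requested,
  particles are assigned to uniformly chosen parents (a Thomas process
  conditioned on its total), and offspring are wrapped torus-fashion onto
  the field so mass conservation stays exact.
* **Stacking**: with probability `stacking_prob` a particle lands atop an
  existing center (multiplicity + 1, no new projected area).
* **Rendering**: a pixel is particle if its center lies inside a disk of
  diameter *d*; overlapping disks merge, as touching particles do in a real
  image.  Disks are clipped at field edges while ground truth counts whole
  particles (negligible bias for *d* ≪ field).  Intensities default to
  8-bit, background 40, particle 200 — arbitrary but fixed for reproducible
  fixtures — with additive Gaussian noise of sd 5.1 (2% of the 8-bit
  dynamic range), then clipping and quantization.  Particles smaller than
  one pixel cannot be rendered and raise with advice to refine the
  calibration (relevant for 6.5 nm particles on a ~10 nm pitch).
* **Determinism**: one `numpy` generator seeded per field; identical
  parameters and seed give bit-identical images and ground truth.

The default field is 10 µm × 10 µm at 1024² px (~9.8 nm pitch, so a 100 nm
particle spans ~10 px).  Tests and the acceptance script use 5 µm × 5 µm at
512² px — the same pitch at a quarter of the rendering cost; coverage-based
summaries are pitch-, not field-size-, dependent.

What the simulator does **not** model — and what passing tests therefore do
not show about real data: secondary-electron image formation (edge
brightening, charging), detector point-spread, drying rings and other
droplet artifacts, substrate texture (insert pores!), polydisperse primary
sizes, and non-disk particle shapes.  Recovery within 10% on simulated
fields validates the *computational chain*, not the microscope.

Endpoint readouts are simulated through a linear plate-reader model
(signal = blank + gain × effect + Gaussian noise, defaults blank 50, gain
1000) with basolateral tracer concentrations clipped to the mass-balance
ceiling C_Bl ≤ C0·V_Ap/V_Bl, so generated fixtures can never show > 100%
passage.

## Endpoint formulas

Tracer passage: 100 × (C_Bl × V_Bl)/(C0 × V_Ap); dimensionless in
concentration and volume ratios, so any shared units work.  Values above
100% are returned as computed but flagged as mass-balance violations.
Defaults: 0.5 mL apical, 1.5 mL basolateral.  At full equilibration of a
0.4 mg/mL donor across those volumes, C_Bl = 0.1 mg/mL and passage is
exactly 75% — the closed-form oracle used in tests.

Viability: 100 × (sample − blank)/(control − blank).  Blank subtraction is
made explicit with default 0, so the bare sample/control ratio is the
blank = 0 special case.  Negative values clamp to 0 with a warning;
control ≤ blank is rejected.

## Numerical and design choices

* Poisson counts and all noise come from `numpy.random.default_rng(seed)`;
  pipeline runs derive per-image seeds from the run seed and condition/image
  indices via `SeedSequence`, so runs are reproducible while images stay
  independent.
* Thresholding ties: the strict `>` comparison means a threshold equal to
  the maximum intensity yields an empty mask.
* `aggregate_area_fraction` is defined as 0 for an empty mask.
* Test and acceptance problem sizes (512² fields, 50 seeds for recovery, 25
  per stacking level) were chosen so the whole suite runs in seconds while
  medians are stable to well under the asserted tolerances.

## Known limitations

* The monolayer model's under-reporting under stacking is quantified but
  not corrected; correcting it needs depth information the method lacks.
* Lateral aggregation (merged disks) does not bias the dose — projected
  area is conserved under union minus overlap, and overlap is second-order
  at low coverage — but it does bias any per-particle counting, which is
  why the package reports component statistics rather than particle counts.
* Otsu thresholding assumes a bimodal histogram; very low coverage (< ~0.1%)
  makes the particle mode vanish and an explicit threshold is then the
  better choice.
* Field-to-insert extrapolation assumes spatially uniform deposition across
  the insert; radial nebulizer deposition gradients would require stratified
  imaging.
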