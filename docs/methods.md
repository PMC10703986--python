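# Methods

This note documents the models behind `sctsa`, the defaults and why they were
chosen, and what the synthetic experiments can and cannot say about real
patient data.

## The dose functional

The quantity under study is the dose at the treatment isocentre — the centre
of the prostate — as a function of the CT image. The engine is a
primary-fluence model, not a clinical dose calculation:

* **Beams.** Seven coplanar 6 MV beams at gantry angles `i·360/7°`
  (`i = 0…6`), source-axis distance (SAD) 1000 mm, equal weights. Gantry 0°
  places the source anterior to the patient; axes lie in the transverse plane
  through the isocentre. Clinical IMRT plans do not publish canonical angles
  or weights, so these are configuration with documented defaults
  (`BeamPlan`).
* **Attenuation.** Each beam contributes
  `w_b · exp(−μ_w · WEPL(source_b, v)) · (SAD/|source_b − v|)²` at point `v`,
  where WEPL is the water-equivalent path length: the line integral of
  relative electron density along the ray, sampled uniformly with a step no
  larger than half the smallest voxel dimension (halving the step changes the
  isocentre dose by < 0.1%, tested). `μ_w = 0.0049 mm⁻¹` approximates the
  broad-beam linear attenuation of water at 6 MV.
* **Field aperture.** Contributions are restricted to a cylinder of radius
  40 mm around each beam axis — large enough to enclose the prostate, small
  enough that the "field" resembles a conformal beam. Scatter, build-up and
  in-field divergence are ignored. This is the central simplification: the
  sensitivity analysis only needs a dose functional that responds physically
  — monotonically, through radiological depth — to HU perturbations.
  Absolute gray values away from the normalisation point are therefore not
  clinically meaningful and are never claimed; only signs, rankings and
  relative responses are interpreted.
* **HU → density.** Piecewise-linear calibration with control points
  (−1000, 0.0), (0, 1.0), (1000, 1.6), (3000, 2.1) — a generic bilinear-style
  CT calibration anchored at air and water — clamped at its endpoints, and
  configurable because every scanner has its own curve.
* **Normalisation.** A single global factor is fixed on the *unperturbed*
  volume so that the isocentre receives the full prescription
  (39 fractions × 2 Gy = 78 Gy), then reused unchanged for every perturbed
  image of that patient. This mirrors clinical practice, where reference-plan
  beam parameters are copied onto modified images, and makes the baseline an
  exact fixed point: a null perturbation reproduces 78 Gy identically.

Two evaluation routes exist and are cross-checked in the tests: a full dose
grid (3 mm isotropic, trilinear interpolation at the isocentre; used for
exports) and a direct point evaluation at the isocentre
(`IsocentreDoseModel`; used by the screening loops, hundreds of evaluations
per patient at ~10 ms each). Each route carries its own normalisation so both
deliver exactly 78 Gy at baseline.

## Error models

* **Artefact** (`ArtefactSpec`): every voxel centre within `diameter/2` of
  the sphere centre gets `delta_hu` *added*, then clamped at −1000 HU below.
  Addition (rather than replacement) makes `delta_hu = 0` a true identity and
  keeps the factor a pure intensity offset. Membership is a deterministic
  voxel-centre-in-sphere test; partial-volume weighting was rejected for
  testability. The sphere centre is `isocentre + distance · û`, with `û` the
  source-to-isocentre unit vector of the chosen beam. Spheres smaller than
  the voxel grid may contain no voxel centre; they are treated as
  sub-resolution no-ops when inside the body, while an artefact entirely
  outside the body is rejected as misuse.
* **Displacement axis.** The analysis default displaces the artefact along
  beam 2 (gantry ≈ 102.9°, lateral-oblique). The pelvis is wider than it is
  deep: along the anterior beam the 0–100 mm displacement range would leave
  the body (AP semi-axis ≈ 90 mm), whereas the lateral axis accommodates it
  fully. Any beam index can be configured.
* **Organ shifts** (`OrganShiftSpec`): additive offsets per structure, the
  soft-tissue offset applying to body minus the four delineated organs, with
  the same −1000 HU clamp (a −1000 HU rectal shift legitimately turns the
  rectum into gas). Masks are disjoint by construction, so shift order is
  irrelevant.

## Morris screening

* Trajectories use the standard `p = 4` levels with `Δ = p/(2(p−1)) = 2/3` in
  normalised [0, 1] space; design coordinates are built in integer level
  arithmetic so they sit exactly on the grid. Each trajectory starts at a
  random grid point and moves every factor exactly once by ±Δ (the sign that
  stays inside the cube).
* Elementary effects divide by the *signed* Δ, so forward and backward moves
  of a linear model give identical effects, and are computed in normalised
  space so factors with different units (HU, mm) share one μ\*–σ plane;
  physical-space designs are available via `denormalise`.
* σ is the sample (n−1) standard deviation; `D = √(μ*² + σ²)` ranks factors.
  Classification: *negligible* when both μ\* and σ fall below 5% of the
  largest D (configurable), *nonlinear-or-interacting* when σ > μ\*,
  *linear/additive* otherwise.
* Seeding: each patient's design derives from `(seed, patient_index)`, so
  patients are screened on independent designs and the whole pipeline is
  bit-reproducible from one integer.

## Synthetic cohort

The phantom is parametric: an elliptic soft-tissue body cylinder
(semi-axes 115 × 90 mm) containing two femoral-head spheres and two iliac
rods (bone, 600 ± 150 HU), a bladder ellipsoid anterior-superior
(10 ± 8 HU), a prostate spheroid at the body centre (40 ± 8 HU), and a
rectum cylinder posterior (−20 ± 15 HU) with an optional −1000 HU gas
pocket (probability 0.3). Soft tissue is 40 ± 10 HU; outside the body is
−1000 HU air. Voxel noise is Gaussian truncated at 3.5 sd, so each tissue
class stays inside its nominal mean ± 4 sd band. Tissue values follow
standard CT literature ranges. Per-patient variability multiplies organ radii
by ±10% (body ±5%) and shifts tissue means by ±10 HU (bone ±100 HU),
emulating population variability in size and density. The default grid is
128 × 128 × 64 at 2 × 2 × 2.5 mm — a desk-scale stand-in for a
256 × 256 × 128 planning CT; full resolution is a `PhantomSpec` parameter.

What the phantom reproduces: relative organ topology (bladder anterior,
rectum posterior of the target, bone lateral), HU contrast between tissue
classes, rectal-gas uncertainty, cohort-level geometric/intensity spread.
What it does not: realistic texture and noise correlation, anatomical shape
detail, organ motion, metal or beam-hardening artefacts, scanner-specific
calibration. Passing tests therefore demonstrate that the *methodology*
(injection → dose → screening) behaves correctly and reproduces the expected
qualitative structure — monotone SCC signs, bladder non-dominance, soft
tissue dominance — not that the numerical μ\*/σ values transfer to any
clinical cohort. Deriving clinical HU-acceptability thresholds requires
re-running the pipeline on centre-specific data and a clinical dose engine.

## Numerical choices and degenerate inputs

* Ray sampling: midpoint rule on the segment clipped to the voxel-centre
  hull; material outside the hull counts as air.
* Dose grid: 3 mm isotropic covering the CT extent; trilinear interpolation
  for point queries; the baseline normalisation makes the unperturbed
  isocentre dose equal the prescription to machine precision by construction.
* Degenerate factor ranges (`lower == upper`) are allowed; they denormalise
  to a constant and produce zero elementary effects (useful for ablations).
* Constant sweeps have no defined rank correlation; the SCC is reported as
  NaN, never coerced to 0.
* Dose evaluations inside an experiment are memoised on the perturbation
  parameters, so repeated design points cost one evaluation.

## Problem sizes

Unit tests run on 64 × 64 × 32 phantoms (4 × 4 × 5 mm) with R ∈ [2, 6];
end-to-end experiment checks and `scripts/acceptance.py` use 5 full-resolution
phantoms with R = 10 — enough repetitions for stable signs and rankings on
the synthetic cohort, where the full study scale (39 patients, R = 50/40)
adds sampling precision but no new structure. The full scale remains a
one-line configuration change (`cohort(n_patients=39)`,
`run_experiment1(repetitions=50)`).

## Known limitations

* No fluence optimisation, MLC/VMAT modelling, scatter kernels, DVH or gamma
  analysis; the dose model is a screening instrument, not a treatment
  planning system.
* Only the isocentre dose is analysed; organ-at-risk dose sensitivity would
  need a different output functional.
* Geometric (registration) errors and organ motion are out of scope; all
  perturbations are pure intensity changes.
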