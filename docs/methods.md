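# Methods

## Scope and model overview

`ctffr` implements an image-to-FFR chain for a single straight vessel
with one stenosis, at desk scale: every stage is validated against
analytic ground truth or an independent oracle rather than against
clinical data.  The chain is

phantom CT → clustering-threshold segmentation → largest-component
cleanup → marching-cubes surface → equivalent-radius lumen profile →
reduced-order steady flow → FFR,

plus a parallel cohort layer (synthetic SYNTAX-stratified patients and
the statistics toolbox).

## Synthetic phantoms

The imaging phantom is a bright tube in a dark background.  The lumen
radius along the centerline arclength `s` (mm) is

    r(s) = R0 (1 − d g(s)),    g(s) = exp(−(s − s0)² / (2 w²)),

with `R0` the baseline radius, `d ∈ [0, 1)` the fractional diameter
reduction at the throat, `s0` the lesion center and `w` the Gaussian
width.  A Gaussian bump was chosen because it is smooth, two-parameter
and the standard idealization of a focal stenosis.  Defaults: `R0` =
1.5 mm (a 3 mm vessel, comfortably above the 1.5 mm diameter floor
used for lesion inclusion), `L` = 30 mm, `w` = 4 mm, `d` = 0.5,
mid-vessel lesion.

Rasterization marks each voxel by its center (hard in/out by default,
so the analytic cylinder-volume oracle is exact up to the O(h)
boundary bias); `supersample = k` averages `k³` sub-voxel occupancy
samples for partial-volume softening.  Intensities are HU-like: lumen
350, soft tissue 50, additive Gaussian noise with default σ = 10
(contrast-to-noise 30; the acceptance segmentation runs use σ = 30,
CNR 10).  One `numpy.random.default_rng(seed)` stream per artifact
makes identical specs bit-identical.

Not emulated: CT physics (beam hardening, gating artifacts, partial
k-space effects), curved centerlines, branching trees, calcified
plaque. Passing tests therefore demonstrate correctness of the
algorithms under ideal tube geometry, not robustness to clinical CT
artifacts.

## Synthetic cohorts

Patients carry an integer SYNTAX score, four lipid measures, binary
covariates, a MACCE flag and follow-up time.  The score marginal is a
rounded gamma (shape 7.5, scale 3.6, capped at 50): non-negative,
right-skewed, and splitting a cohort into low/medium/high groups in
roughly the 31/37/32% proportions typical of PCI populations.  Lipids
use matched-moment lognormal marginals (total cholesterol 4.8 ± 1.0,
triglyceride 1.7 ± 0.9, LDL-C 3.0 ± 0.9 mmol/L; ApoB/ApoA1
0.85 ± 0.25) so values stay positive.

Score–lipid dependence comes from a one-factor Gaussian copula:
`corr(score, lipid_j) = r_j` on the latent scale, `corr(lipid_j,
lipid_k) = r_j r_k`, positive semidefinite for any `|r_j| < 1`.  The
default target is r = 0.3, the magnitude of the reported score–lipid
correlations this layer is meant to emulate.  The marginal transforms
(gamma rounding, lognormal warping) attenuate the observable Pearson
correlation by well under 0.02 at these settings, which is far inside
Monte-Carlo error at the cohort sizes used; the recovery and coverage
tests measure this directly.  MACCE events are Bernoulli draws at
group-specific probabilities, default (0.10, 0.10, 0.40) for
(low, medium, high) — a deliberately strong high-group excess so that
a 3000-patient cohort detects it at α = 0.05 with power ≈ 1.

## Segmentation

The threshold selector partitions voxels at a test threshold `t` into
foreground `B1` (intensity ≥ t) and background `B2`, computes the
class means `ā1, ā2` and counts `M1, M2`, and minimizes the total
within-class sum of squared deviations

    G(t) = Σ_{p∈B1} (p − ā1)² + Σ_{p∈B2} (p − ā2)².

This is the two-class clustering (Otsu / 2-means) criterion.  Fixed
conventions: foreground is the *bright* class (`≥ t`, contrast-filled
lumen); the scan grid defaults to every integer intensity in range;
ties in `G` break toward the smallest `t`; an empty class contributes
zero scatter.  The production scan uses sorted cumulative sums
(O(N log N + T)); the test suite checks it against a literal two-pass
evaluation of `G` at every scanned `t`, and both agree exactly on all
fixtures because identical partitions produce identical floating-point
reductions within each method.

Cleanup keeps the largest 26-connected component (6/18/26
configurable), with size ties broken toward the component containing
the lowest linear index.  The live-wire extractor is a classic
minimum-cost-path boundary tracer: stepping onto pixel `q` costs
`[w_g (1 − |∇I|/max|∇I|) + w_z (1 − zc)] × (√2 for diagonals)`, with
`zc` a Laplacian zero-crossing indicator and default weights
`w_g = 0.8, w_z = 0.2` from the live-wire literature.  It is exposed
as a programmatic operation, independent of the threshold selector.

## Surface reconstruction

Marching cubes is implemented from scratch via face contouring: for
each mixed cell, marching-squares segments are computed on the six
faces (oriented so the ≥-isolevel region lies left when viewed from
outside the cell), ambiguous faces are resolved by the **asymptotic
decider** — the bilinear saddle value `(f00 f11 − f10 f01)/(f00 + f11
− f10 − f01)` compared with the isolevel decides whether the diagonal
high corners connect (ties and degenerate denominators default to
"separated", applied identically by both adjacent cells) — and the
directed segments are stitched into closed loops and fan-triangulated
about their centroid.  Because face contours depend only on shared
face data, neighbouring cells always agree on patch boundaries: the
mesh is watertight with consistent outward winding whenever the
surface does not touch the volume boundary.  Vertices are linearly
interpolated along cell edges and mapped to physical millimetres
(`vertex = origin + index · spacing`), so areas/volumes are metric.

Binary masks are surfaced at isolevel 0.5 on the 0/1 field (binary
marching-cubes semantics).  Vessel ends that reach the volume boundary
produce open tubes; `mesh_report` distinguishes strict watertightness
from "watertight up to boundary rings" and reports V/E/F, the Euler
characteristic χ = V − E + F, summed triangle area and the signed
tetrahedron-sum volume.  Laplacian smoothing (`v ← v + λ(mean(N(v)) −
v)`) preserves connectivity exactly and mildly shrinks closed
surfaces.

The lumen profile is the equivalent radius `r(s) = √(A(s)/π)` with
`A(s)` the cross-sectional area per axial slice — voxel count × pixel
area for masks, section-polygon area for meshes (the two estimators
agree to discretization tolerance on phantoms).

## Reduced-order hemodynamics

The full transient 3-D problem is replaced by a steady axisymmetric
reduced-order model, on the grounds that (i) FFR is defined at a
steady maximal-hyperemia operating point where `dv/dt` averages out,
and (ii) the reduced model is validated against the closed forms any
correct 3-D solver must also satisfy in the tube limit.  Mass
conservation is exact by construction (one unknown `Q`;
`v(s) = Q/A(s)`).  The pressure field integrates segmentwise
Poiseuille gradients (local mean radius per segment) plus one lumped
Young–Tsai stenosis loss applied across the throat segment:

    Δp_s = Kv μ Q / D₀³ + Kt (ρ / 2A₀²) (A₀/A_s − 1)² Q²,
    Kv = 32 (0.83 La + 1.64 D_s) (A₀/A_s)² / D₀,   Kt = 1.52,

with `A₀/D₀` the reference (widest) area/diameter, `A_s/D_s` the
throat values and `La` the extent of >5% constriction.  The empirical
`Kv`/`Kt` are the classic Young–Tsai values used throughout
reduced-order FFR practice; the quadratic term carries the convective
(expansion) loss the 1-D viscous model misses.

Boundary conditions: prescribed flow, or prescribed pressures (flow
recovered by bisection on the monotone `Q ↦ Δp` map, bracketed by the
zero-loss Poiseuille bound through the widest radius), or inlet
pressure with a lumped distal resistance.  Maximal hyperemia defaults
to a prescribed flow of 3× a 0.5 mL/s resting flow — 1.5 mL/s, a
physiologic hyperemic value for a mid-size epicardial vessel that also
keeps the whole severity sweep `d ∈ {0…0.7}` inside the passive-vessel
regime `0 < FFR ≤ 1`; the alternative reduced-resistance hyperemia is
available through `FlowBC`.  Fluid defaults: ρ = 1060 kg/m³,
μ = 0.0035 Pa·s (blood).  SI internally; mmHg at the interface
(1 mmHg = 133.322 Pa).

`Pr` and `Ps` default to the inlet and outlet of the modeled segment
(both stations configurable).  Waveform averaging uses trapezoidal
integration over whole cardiac cycles; the generator subtracts the
discrete mean of the pulsatile component so "time average = mean"
holds exactly on the sampled grid, not just in the continuum limit.

## Cohort statistics

Grouping: low 0–22, medium 23–32, high ≥ 33 (the only reading that
partitions the score line); fractional scores round half-up.  Vessel
inclusion is strict on both criteria (> 1.5 mm and > 50%).  Pearson r
carries a Fisher-z CI (`se = 1/√(n−3)`) and a t-test p on n−2 df;
ANOVA and chi-square are the classical sum-of-squares and
expected-count forms; ROC/AUC uses the trapezoidal rule over unique
thresholds and equals Mann–Whitney concordance with ties counted half.
The diagnostic cutoff defaults to FFR ≤ 0.80 (universal clinical
convention).  Pairwise group comparisons are reported uncorrected,
with the comparison count included so a Bonferroni adjustment can be
applied; follow-up is summarized as crude incidence (no time-to-event
modeling).

## Numerical choices and problem sizes

- Threshold scan: integer grid by default; first-minimum argmin gives
  the smallest-t tie-break deterministically.
- Bisection: 200 iterations max, relative bracket tolerance 1e−12;
  a failure raises `ConvergenceError` with diagnostics.
- Marching cubes: cells preselected vectorially; only mixed cells are
  polygonized in Python. Degenerate loops cannot arise because every
  edge crossing joins exactly two face segments.
- Default problem sizes keep everything interactive: phantoms are
  ~20–60k voxels, severity sweeps use 201 stations, cohort recovery
  uses 200 replicates of 250 patients, and the simulated diagnostic
  study uses 200 lesions.

## Known limitations

- Single straight vessel, one stenosis; no branches, curvature or
  multi-outlet trees.
- Rigid walls; no fluid–structure interaction, vessel elasticity or
  gravity.
- The severity a voxel grid can represent is resolution-limited: the
  throat diameter should span ≳ 2.5 voxels, otherwise the equivalent
  radius quantizes low and the stenosis loss is overestimated (e.g. a
  d = 0.7 lesion of a 1.5 mm-radius vessel needs ≲ 0.35 mm voxels).
- The profile-based solver sees only `r(s)`; eccentric or non-circular
  lumina are folded into the equivalent radius.
- Synthetic cohorts reproduce correlation and event-rate *structure*,
  not the joint distribution of any real population.
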