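# Methods

This note records the model implemented by `svftrace`, the numerical choices
made where the construction was genuinely open, and what the synthetic
phantoms do and do not establish about behaviour on real microscopy data.

## Coordinate and intensity conventions

Voxel centers sit at integer, 0-based `(x, y, z)`; `x` varies fastest within
a slice and `z` is the slice index (`Volume.data[x, y, z]`).  Intensities
are floats in `[0, 255]`; 16-bit stacks are rescaled linearly on load.
Physical spacing is carried through to SWC export but **all filter and
snake parameters are in voxel units**, matching how such parameters are
quoted in practice.  Off-grid values are read with trilinear interpolation;
samples outside the voxel-center hull contribute a zero gradient (hence a
zero convergence index).  Gradients with magnitude below `EPS_GRAD = 0.5`
intensity units/voxel — half an 8-bit quantisation step — are treated as
orientation-free everywhere: their VCI is 0 and they carry no band evidence.

## Sliding volume filter

For a center `O` and direction `u`, band samples sit at integer radial
offsets `ρ ∈ {r − d/2, …, r + d/2}` (`d` even, so `d + 1` integer samples);
the VCI of each sample is the cosine between the local gradient and the
direction back toward `O`.  The response at `O` maximises the band average
over integer band centers `r` strictly inside `(R_min, R_max)` and averages
over a polar direction grid with `a = 2πi/2L`, `b = πj/L` (`M = 2L²`
directions).

Two choices depart from the most literal reading of the construction, both
forced by making the standard threshold `T = 0.7` operative on tubes:

* **Solid-angle weighting.**  The `(a, b)` grid is heavily oversampled near
  the poles.  With uniform weights, the polar (axial) directions — which on
  a tube carry no convergence information — cap the centerline response of
  an *ideal* tube at `2/π ≈ 0.64`, below any usable threshold.  Directions
  are therefore weighted by `sin b`, the solid angle they represent; the
  ideal-tube centerline response becomes `π/4 ≈ 0.785`, and on the
  reference helix the measured profile is 0.80 on the axis, 0.74 at one
  voxel off, 0.65 at two, 0.40 at the wall: the threshold 0.7 selects the
  centerline core.
* **Band normalisation (seeding).**  Neurites are routinely thinner than
  the band (width 9 voxels at the standard `d = 8`, against radii 2–6), so
  a fixed `1/(d+1)` denominator lets flat background mask the wall signal
  (response ≤ ~0.45 on a radius-4 tube).  For seeding, the band average
  runs over the gradient-bearing samples only, with the denominator floored
  at `⌈(d+1)/2⌉` so bands with token support cannot score full marks
  (`band_norm="adaptive"`).  Radius estimation (below) keeps the fixed
  denominator — there the dilution of part-empty bands *is* the edge
  localisation.

`svf_volume` evaluates responses only at voxels above a mask floor; the
floor is a speed device, not a model element — any voxel above it gets
exactly the unmasked value.  The pipeline resolves the floor with Otsu's
threshold on a lightly smoothed copy so that noisy background is skipped
too; masked voxels are reported as −1 and can never seed.

Volume enhancement is `I_SVF = 15·√(min(I·(1 + SVF), 255))`, clamped at 0
before the root; its range is `[0, 15√255 ≈ 239.5]`.

## Noise-adaptive gradient scale

Gradients are Gaussian-smoothed central differences.  The base scale is
`σ_g = 1` voxel.  Because the filter uses gradient *orientations* only, the
relevant failure mode under noise is directional decorrelation: once the
propagated per-component gradient noise approaches the signal gradients,
band averages collapse toward zero (measured on the reference helix with
variance-0.04 noise: on-axis response 0.50 at `σ_g = 1`, versus 0.78 when
adequately smoothed).  The pipeline therefore estimates the noise standard
deviation (wavelet-MAD) and picks the smallest `σ_g ≥ 1` at which the noise
passed through the discrete smoothed-derivative kernel stays below
`EPS_GRAD` — the same level the filter already deems orientation-free.
Clean volumes keep `σ_g = 1` exactly; variances 0.01/0.02/0.04 on the unit
scale resolve to 1.5/1.75/2.0.  One rule, no per-dataset switches.

## Seeding

Raw seeds are voxels with response `> T`.  The ridge criterion then demands
the gradient be orthogonal to the two cross-sectional Hessian eigenvectors
(`σ_h = 1.5` voxel Gaussian Hessian; eigenvalues ordered by magnitude,
`ev₁` axial).  At integer voxels the printed tolerance (0.001, intensity
units) is unsatisfiable — any voxel a fraction off-axis has cross-plane
gradients of tens of units — so, following the ridge-traversal literature,
the test is applied at the *Newton-refined in-plane ridge point*: starting
from the seed, Newton steps within the `(ev₂, ev₃)` plane on the trilinear
gradient field converge to the exact in-plane zero, where the 0.001
residual is meaningful.  A seed is kept if its cross-plane curvatures are
negative (a bright ridge), the iteration converges, and the ridge point
lies within 1.5 voxels.  Seed positions stay on the voxel grid.  Measured
on the reference helix, refinement tightens the mean centerline deviation
from 1.16 to 0.98 voxels and never loosens it.

Final seeds are sorted by descending response (ties broken by lexicographic
position, which makes the list order independent of input permutation) with
greedy suppression of any seed within 2 voxels of a stronger one.

## Open-curve snake

The internal operator discretises `α(−c_ss) + β c_ssss` per coordinate:
second-difference rows at interior nodes, **zero rows at the two end
nodes** (free ends — the ends are driven only by the image and stretching
forces), and stiffness assembled as `D₂ᵀ·β·D₂`, which vanishes at the ends
by construction.  Straight evenly spaced curves are exact null vectors and
the spectrum is real and non-negative, though the α-part is not symmetric;
`γI + A` is always solvable.  Node spacing is resampled to 1.5 voxels after
each deformation.

The external force is the unit-normalised GVF of the enhanced volume
(diffusion `μ = 0.1`, 50 iterations, `Δt = min(1, 1/6μ)`, initialised at
`∇f`) plus, at growing ends only, a stretching force along the outward
tangent.  Its magnitude is the Hessian tube-likeness
`|√|λ₂λ₃|/(|λ₁|+0.01) − 1|`, which is huge mid-tube (the formula's
denominator is nearly zero there); the applied force is capped at 1 so it
stays commensurate with the unit flow field, while the raw magnitude drives
convergence (an end is converged after it stays below 0.2 for three
consecutive extensions).  Two qualifications proved necessary:

* the stretch applies only on a **bright ridge** (`λ₂, λ₃ < 0`), and a
  strong cross-plane *saddle* (positive curvature exceeding a quarter of
  the negative one) stops the end outright.  Without this a snake entering
  a Y-junction climbs the bright wedge *between* the branches — on a
  symmetric phantom the on-axis path is an unstable equilibrium the
  dynamics never leave — and corrupts both seed ownership and the branch
  point.  The saddle margin is large compared with Hessian noise at the
  tested noise levels, so mid-tube ends are unaffected;
* ends also stop on sustained background intensity (below 1.0 twice) or
  when they fail to advance half an extension step three times (pinned
  against a bright cap or the volume border).

Curves grow one node (1.5 voxels) per round at each growing end, deform for
up to 10 semi-implicit steps, then claim all unclaimed seeds within the
claim radius (`max(2, radius estimate)`; the estimate starts at `R_min`).
A growing end within the claim radius of a *foreign-claimed* seed collides:
the junction is registered as the node of the other curve nearest the hit
seed (the seed itself may sit several voxels up a branch), and the end is
cut back so it ends `D = 2 ×` the radius estimate away from that junction —
only the missing length is trimmed, since the collision trigger already
stops short.  Tracing pops the strongest unclaimed seed until none remain;
curves with fewer than three nodes are discarded.  The whole procedure is
deterministic.

## Radius estimation

At each node the local frame takes `v₁` from the central-difference tangent
and `v₂` as the projection of the global axis least aligned with it;
`v₃ = v₁ × v₂`.  Along each of `n = 16` in-plane rays the band (full
`1/(d+1)` normalisation; band width reduced to `min(d, 2·R_min)` so the
innermost band stays off the center) slides over integer radii and the
boundary point is placed at the winning band center.  Because the
convergence index ignores gradient magnitude, on clean data every band
wholly inside the gradient-bearing shell ties at the maximum; the winner is
taken at the **midpoint of the near-maximal plateau** (responses within
0.01 of the best), i.e. the band centered on the wall.  First-max selection
would bias radii low by roughly half the plateau (measured: 3.75 for a
radius-5 tube, versus 4.75 with the plateau rule).  A flat volume, where
all responses are zero, therefore degenerates to the middle of the sliding
range.  Nodes within the backoff distance of a branch point are skipped
(the cross-section is ambiguous there) and inherit the nearest estimate;
the per-curve mean radius feeds back into the SWC export.

With the standard seeding range (`R_min = 5`) the smallest measurable
radius is 6; radius-recovery experiments use `R_min = 2, R_max = 12`, under
which hard-profile tubes of radius 3/5/8 measure 3.0/4.75/8.0 and a 4×8
elliptical cross-section yields a 2:1 radius ratio.

## Phantoms

Tubes are rasterised at 3× supersampling per axis then box-averaged, with a
`cosine` profile (`I = peak·cos²(πρ/2r)`, the bright-centerline convex
region the SVF targets) or a `hard` binary profile (all gradient at the
wall, used for edge-localisation experiments — a cosine profile has no
edge-concentrated gradient for the band to lock onto, and its smoothing
tail biases the estimate high).  The reference helix (64³ volume, helix
radius 18, pitch 20, two turns, tube radius 4, peak 200, cosine, noiseless)
is the repository's fixed reference condition.  Degradations follow the
standard robustness protocol: multiplicative signal attenuation (10–40 %)
and additive Gaussian noise with variance 0.01–0.04 *on the unit intensity
scale* (std `√v·255` on the 8-bit scale), clamped to `[0, 255]`,
deterministic under a fixed seed.

What the phantoms do not emulate: a microscope point-spread function and
its axial anisotropy, autofluorescence background and uneven illumination,
touching or crossing neurites from *different* cells, somata, and varying
voxel anisotropy.  Passing the phantom suite demonstrates the geometric
correctness and noise behaviour of the machinery, not performance parity on
any particular real dataset.

## Default parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `rad` | 20 | voxels | support-region radius of the sliding filter |
| `d` | 8 | voxels | band thickness (even; `d+1` samples) |
| `L` | 20 | — | angular resolution (`M = 2L²` directions) |
| `R_min, R_max` | 5, 16 | voxels | band-center sliding range (open interval); `R_max = rad − d/2` |
| `T` | 0.7 | — | seed-response threshold |
| `σ_g` | auto (≥1) | voxels | gradient scale, noise-adaptive (see above) |
| `σ_h` | 1.5 | voxels | Hessian scale (ridge test, stretch force, snake init) |
| `ridge_tol` | 0.001 | intensity/voxel | cross-plane gradient residual at the ridge point |
| `α, β, γ` | 0.8, 0.2, 2 | — | snake elasticity, stiffness (0 at ends), step control |
| `t_max` | 10 | — | deformation steps per extension round |
| `extend_step`, `node_spacing` | 1.5, 1.5 | voxels | end growth per round; resampling interval |
| `stretch_eps` | 0.2 | — | tube-likeness below which an end converges |
| `backoff_factor` | 2 | — | collision cut-back, × mean radius |
| `n` | 16 | — | boundary rays per cross-section |
| `mask_floor` | auto | intensity | SVF evaluation floor (Otsu on smoothed copy) |

## Problem sizes

All experiments run on 64³ (reference helix, Y-branch) or ≤ 48³ (straight
and elliptical tubes) volumes: large enough for the standard support radius
(20) and two full helix turns, small enough that the complete suite,
including the noisy and attenuated pipelines, runs in minutes on one core.

## Known limitations

* The SVF with the standard range cannot report radii below `R_min + 1`,
  and the cosine-profile radius estimate is biased high by the smoothing
  tail (the helix, true radius 4, measures ~6): radius accuracy claims hold
  for edge-type (hard) profiles.
* Branch points are estimated from seed ownership, so their accuracy is
  bounded by the claim radius and seed density near the junction (measured
  ~2.6 voxels on the 60° Y-branch).
* Junction surfaces are left open in the lofted mesh (contours are skipped
  within the backoff distance); the mesh is watertight per curve, not per
  tree.
* One curve is traced at a time; densely interleaved structures from
  different cells would be claimed greedily by whichever seed fires first.
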