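# Methods

This note records the models, conventions and numerical choices behind
`ptosiskit`, and what the synthetic test substrate does and does not show.

## Coordinate and angle conventions

All coordinates are 0-based image pixels, x rightward, y downward, subpixel
floats throughout. Lid contours are open polylines from the medial to the
lateral canthus, strictly monotone in x, so each lid is a function of the
image column and is evaluated by linear interpolation; nearest-pixel rounding
would break the solver's exactness guarantees.

Radial measurements use an eye-local frame: 0° toward the lateral canthus,
90° toward the upper lid, counterclockwise in a y-up sense. This convention
is a design choice (not imposed by the measurement's definition): it makes
left and right eyes directly comparable, so mirror-symmetry ratios can be
formed per angle without explicitly flipping either profile. The angle grid
"0° to 360° in 15° steps" is sampled half-open (24 angles); a 360° sample
would duplicate 0° and double-weight that direction in profile means.

## Measurements

`MRR = r0 / r1` with `r1` defined as the iris radius. The iris *top point*
of the circular iris model is `(cx, cy − r)`, so the two definitions agree
when the iris is fully visible, but the radius stays well-defined when a
drooping lid occludes the physical iris top — exactly the severe cases where
measurement matters. `r0` is signed (positive above the iris center):
`MRR <= 0` encodes lids at or below the pupil center instead of failing, and
raises a `closed_eye` flag. MPLPD(θ) is the distance from the iris center to
the full closed eye outline (not the upper lid alone), so all 24 angles are
defined whenever the center is interior; if the center falls outside the
outline the angle is reported missing with a `center_outside_contour` flag.
Ray–outline intersection is exact segment intersection via the polygon
exterior, taking the smallest positive hit; vertex hits count once.

## Target-lid solver

Let b(x) be the canthal baseline (the line through the two canthi), h(x) the
lid's height above it, and c the iris column. The solved lid is

    h'(x) = s · h(x),   s = h'_c / h_c,   h'_c = b(c) − (cy − MRR_target · r1).

Because b is linear and the lid is piecewise linear, scaling commutes with
interpolation, so the re-measured MRR of the solved contour equals the
request to machine precision, with both canthi pinned. When `h_c <= 1 px`
(near-closed eye) the multiplicative factor is ill-conditioned, so the
solver switches to an additive vertical lift, full at the iris column and
cosine-decayed to zero at each canthus. Targets that would push the upper
lid below the lower lid are rejected ("target collapses palpebral fissure").
The multiplicative model was chosen over free-form deformation because it
preserves the lid's shape character, is anchored at anatomically fixed
points, and is solvable in closed form; how a conditioning edge map should
"reflect" a target MRR is otherwise an open design question.

## Conditioning artifacts

Edges: Canny on the grayscale image (skimage implementation, sigma 1),
thresholds on the 8-bit scale with the conventional 1:3 ratio (50, 150) by
default; edge pixels inside the editing mask are erased and replaced by the
rasterized target contour — a 1-px anti-aliased stroke thresholded at 0.5.
An optional supratarsal-crease stroke `crease_offset` px above the lid is
off by default (0): whether a crease line should be drawn explicitly or left
to the generative engine is exposed rather than decided.

Mask: the band between the original and target lid curves (column-wise
fill), united with both lid strokes, dilated by `mask_margin` (default 5 px
at a 256-px eye-crop scale, to be scaled proportionally for larger crops),
minus iris pixels below the lower envelope of the two lid curves (the
visible pupil must not be repainted). Thin strokes are 8-connected, so
single-component enforcement uses 8-connectivity and keeps the largest
component if the iris exclusion ever splits the region. Two ablation
switches reproduce degraded workflows: `edges_off` emits an empty
conditioning image (no structural guidance), `mask_off` replaces the mask
with the whole-eye bounding box plus margin (editing no longer confined to
the lid region). Bundle invariant, asserted per run: every lit pixel of the
target stroke lies inside the mask.

## Diffusion sampler and guidance

The sampler implements the standard discrete-time formulation: forward
marginal `x_t = sqrt(ᾱ_t) x_0 + sqrt(1−ᾱ_t) ε` and reverse step
`x_{t−1} = (x_t − (1−α_t)/sqrt(1−ᾱ_t) ε̂)/sqrt(α_t) + σ_t z`, with z forced
to 0 at t = 1. Defaults are the configuration the field's references assume
— T = 1000, β linear from 1e−4 to 0.02, σ_t² = β_t — all configurable. No
network is trained; the workflow is training-free, and where a noise
estimate is needed for testing, the exact posterior-mean estimate for
Gaussian data

    ε*(x_t, t) = sqrt(1−ᾱ_t) (x_t − sqrt(ᾱ_t) µ) / (ᾱ_t σ0² + 1 − ᾱ_t)

serves as the analytic oracle. Measurement guidance shifts the reverse-step
output by `w · ∇_x[−(y(x) − y0)²]` evaluated at x_t, with y0 the target MRR.
The gradient of a pixel-space MRR measurement is not differentiable in
general, so the measurement is a pluggable function: analytic gradients when
supplied, otherwise central finite differences with step 1e−3 (intended for
low-dimensional toys, where the guidance mathematics is actually verified).
Weight 0 reproduces the unguided step bit-exactly.

## Backends

All backends honour one contract: pixels outside the mask are returned
bit-identical to the input. `geometric_warp` resamples each masked column
vertically with a piecewise-linear map sending the original lid row to the
target row, displacement decaying to zero at the mask's top and bottom; it
is deterministic, ignores the seed, and is this repository's reference
generator — it is *not* a diffusion model, and produces geometry, not
texture. `ddpm_toy` noises the warp output inside the mask to
`t* = strength·T` and denoises with the analytic Gaussian estimate (σ0 =
0.02 in [0,1] intensity units) under a seeded generator; it demonstrates the
sampler on real rasters, nothing more. `controlnet` is an adapter slot
delegating image, edge image, mask, seed and strength to an external
edge-conditioned inpainting engine with pretrained weights; without an
engine it raises a typed "backend not installed" error (mapped to the
configuration exit code, distinct from runtime I/O failures). The
inpainting strength/denoise fraction such engines use is exposed as
`strength` with no claimed canonical default.

## Symmetry evaluation

Alignment is translation-only: both outlines move their iris centers to the
origin and the treated outline's x is negated. No rotation or scale
normalisation — scaling would mask exactly the size asymmetry the statistics
are meant to capture, and the iris center is the natural anchor because
MPLPD is iris-centered by definition. The overlap ratio is computed by
supersampled rasterization (4 samples per pixel per axis by default; agrees
with exact polygon clipping to well under 0.01 on eye-sized outlines). MPLPD
ratios are averaged over present angles with the count recorded; a pair
where every angle is missing raises an evaluation error naming the
closed-eye cause. Cohort summaries report mean ± SD (n−1 denominator) per
condition; the cohort MPLPD ratio is the mean of per-case means (each case
first averaged over its angle grid), not a pool over all angle×case pairs —
the two differ under missing angles, and the per-case-first form weights
every case equally.

Predicted-eye contours come from re-running the annotation pipeline on the
predicted image when a landmark provider for photographs is available;
otherwise (as in this repository's self-contained runs) the solved target
contour is used by construction, and the report records the source. With
construction-based contours a prediction targeting the fellow eye's MRR is a
perfect mirror on schematic scenes, so predicted overlap and MPLPD ratios
reach 1.0 exactly; re-detected contours on real photographs would not.

## Synthetic scenes

The generator renders two-eye face crops (default 384×192, eyes of 88-px
palpebral width, 18-px iris) with flat shading: skin 180, sclera 235, iris
60 on the 8-bit scale (pairwise separation ≥ 30 guarantees detectable
edges), parabolic lid arcs, optional crease line, additive Gaussian noise
(σ = 3 by default) under a per-scene seed. The upper-lid apex height is set
analytically from the intrinsic MRR, so measuring the stored 17-point-per-lid
annotation reproduces the parameter exactly; the annotation *is* the ground
truth. The 468-point face-mesh landmark interface is honoured by placing the
periocular points on the true contours and the remainder on a fixed
canonical grid — no operation consumes the non-periocular points, they exist
for interface fidelity. Unilateral cohorts draw the fellow eye's MRR from a
healthy band [0.75, 0.95] and the ptotic eye's from a configurable severity
range (default [0.05, 0.55], spanning mild to severe), alternating the
affected side draw by draw.

What passing tests show — and don't. The scenes have exact annotations,
frontal pose, flat illumination and no skin texture, eyelashes, brows or
specular highlights. They validate the geometry, the conditioning artifacts,
the sampler mathematics and the evaluation statistics end to end; they say
nothing about landmark-detection accuracy on photographs, about a pretrained
inpainting engine's output quality, or about clinical measurement noise.
Problem sizes used by the default test run and the acceptance script — 26
cohort cases, 50–100 random fixtures per oracle suite, 10⁴ draws/chains for
the sampler diagnostics — were chosen as the smallest sizes at which the
statistical checks are stable. Intensity-based lid re-detection (a test-only
column-transition detector) is quantized to ±0.5 px by the renderer's binary
rasterization, so recovery-from-pixels checks use scenes with a 40-px iris,
where half a pixel stays within the 0.02 MRR tolerance; ground-truth
annotation checks are scale-free and run at the default geometry.

## Known limitations

- The lid deformation is vertical-only; it cannot model canthal
  repositioning or horizontal lid laxity.
- MPLPD against the full outline means lower-lid asymmetry influences the
  ratio profile even when only the upper lid was treated — intended for the
  symmetry statistics, but worth remembering when reading single angles.
- Bilateral cases have no fellow-eye reference: target MRR must be given
  explicitly per eye and bilateral records are skipped by the cohort
  evaluator.
- The finite-difference guidance path scales linearly with sample dimension
  and is unsuitable for pixel-space guidance; supply an analytic or learned
  gradient for anything beyond toys.
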