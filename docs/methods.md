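# Methods

This note documents the models, conventions and numerical choices behind
`dynajoint`, and what the synthetic experiments do and do not demonstrate.

## Coordinate and transform conventions

All positions are world millimetres in a right-handed (x, y, z) frame; a
voxel's world position is its centre, indices are 0-based, and the world
position of index **n** is `origin + direction @ (spacing * n)`.

A registration result maps **fixed-space points into moving space** — the
resampling convention, under which propagating the moving image's labels
onto the fixed grid needs no inverse. Propagating *points* that live in
the moving image (atlas landmarks) into fixed space uses the inverse:
exact for rigid/affine, and a per-point fixed-point iteration for
B-splines (tolerance 1e-3 mm, cap 100 iterations; the B-spline
displacement is small and smooth, so the iteration contracts). Composite
transforms invert stage by stage in reverse order.

## Registration

The pairwise scheme is the classic three-stage recipe: rigid, then affine
initialized from the rigid result, then a cubic B-spline free-form
deformation on top of the affine (moving-initial-transform composition).
Similarity is MSD, NCC or MI (32-bin joint histogram), evaluated on
randomly sampled points, multi-resolution with a shrink pyramid of
2^(L−1) … 1 and matched Gaussian smoothing. Library defaults follow
common clinical practice: 4 levels, 2000 samples per iteration, iteration
caps 2000/1000/1000 for the three stages.

The optimizer is SimpleITK's regular-step gradient descent with parameter
scales estimated from physical shift: a maximum step (default 2 mm)
halved-ish (relaxation 0.6) on every gradient direction change until the
step falls below `min_step`. With fresh random samples every iteration
this is a stochastic gradient descent; all registrations force a single
thread so a given seed reproduces the parameter trajectory bit for bit.

Deformable-stage smoothness is controlled through the control-point
spacing (default 16 mm final grid) and the multi-resolution schedule
rather than an explicit bending-energy penalty, which the optimizer
backend does not expose; on the smooth synthetic deformations used here
the coarse grid alone keeps displacement fields well-behaved (population
generation additionally rejects fields with non-positive Jacobian).

Two conditioning details matter in practice and are worth stating:

* **Rotation centre.** Rigid stages re-parameterize the incoming transform
  about the mask centroid (or image centre). Optimizing a rotation about a
  distant origin couples rotation and translation and stalls the
  step-halving schedule; re-centring fixed a systematic ~3° tracking lag.
* **Dense sampling for tracking.** The masked rigid registration used for
  bone tracking defaults to *dense* in-mask sampling (every mask voxel):
  the mask is small (~10⁴ voxels), and removing sampling noise lets the
  optimizer anneal to a sub-0.1° optimum instead of stalling on gradient
  noise. The atlas registrations keep random sampling — their domains are
  the whole volume and candidate fusion absorbs residual jitter.

`compute_similarity` is an independent numpy implementation (trilinear
interpolation, Pearson NCC, hard-binned joint-histogram MI in nats) used
for atlas ranking, overlap pre-checks and metric sanity tests; it shares
no code with the optimizer path. MI uses hard bin assignment so that
MI(f, f) equals the Shannon entropy of the marginal histogram exactly.
Fewer than 50 % of requested samples landing inside the moving domain
raises a degenerate-overlap error; the same probe runs before every
registration stage because the optimizer otherwise stalls silently at
zero overlap.

## Multi-atlas segmentation and fusion

Candidates are built by registering every atlas to the target (the target
itself is excluded by id — cross-validation discipline), resampling atlas
intensities linearly and labels nearest-neighbour. Fusion is a per-voxel
vote over the full label alphabet including background, which guarantees a
partition; ties go to the smallest label value (deterministic and
order-free). GNCC restricts the vote to the `r` atlases with the best
global NCC against the target over its foreground bounding box (air
threshold default 150, avoiding empty-background inflation); LNCC
restricts it per voxel to the `r` atlases with the highest local NCC.

Local NCC statistics come from normalized convolution (Gaussian of
σ = `k` voxels by default, boxcar of edge 2k+1 as an option): smoothing
with a constant-padded kernel divided by the smoothed indicator. This
keeps local means unbiased at the image border and makes the large-kernel
limit converge to the global statistics, so LNCC → GNCC-style behaviour as
`k` outgrows the image — a property the tests pin down. Voxels with
vanishing local variance get weight 0.

Landmark transfer reuses the per-atlas transforms: each atlas proposes its
landmark's preimage in target space, and the candidate whose atlas has the
highest LNCC weight at that voxel wins. Atlases whose candidate falls
outside the target domain abstain; a landmark with no remaining candidates
is reported missing rather than invented.

## Motion tracking and kinematics

Each bone's binary mask is dilated by a Euclidean ball of 3 voxels
(radius in voxels, not mm) so the registration sees the bone *and* its
immediate vicinity. Tracking registers the reference frame (fixed) to
every other frame (moving), walking outward from the reference index in
both temporal directions with the neighbouring frame's transform as the
initializer — sequential initialization is what keeps large inter-frame
motion inside the optimizer's capture range. A failed frame keeps its
neighbour's transform and is flagged; downstream kinematics mark flagged
frames invalid instead of aborting.

Bone-embedded frames follow the direction-cosine convention: rows of `R`
are the unit vectors **i**, **j**, **k** of the anatomical axes expressed
in scanner coordinates (so `R` maps global to bone-local coordinates).
The frame is built from a primary axis (two landmarks), a plane landmark
closing the primary plane, and cross products; right-handedness is
enforced by construction and collinear landmarks are a hard error. Frame
definitions are *data* (YAML), not code: the exact landmark-to-axis
mapping for a joint is an editable modelling choice, and per-definition
sign masks handle left/right mirror conventions. The shipped knee and
thumb definitions name plausible anatomical landmarks and document their
assumptions; only the phantom definitions are validated against ground
truth.

The relative rotation between segments is
`R_rel = R_distal · R_proximalᵀ`. Joint motion at frame *t* is expressed
relative to the reference posture as `M_t = R_rel,ref · R_rel,tᵀ`, which
is the rotation of the distal segment in its own anatomical axes: the
reference frame is exactly (0, 0, 0), a physical +θ rotation of the distal
bone about one of its axes reads out as +θ on that axis, and a rigid
motion applied to *both* segments cancels identically. Cardan angles are
the intrinsic (mobile-axes) factorization, ZXY or ZYX, with the middle
angle in [−90°, 90°]; |sin| within 1e-9 of 1 flags gimbal lock, sets the
third angle to 0 and warns. One notational remark: the direction-cosine
matrix is written here with rows (i, j, k) each spelled out to their x, y
and z components — the z component of **k** included.

## Evaluation metrics

Overlap: Dice `2|A∩B|/(|A|+|B|)`, false-positive fraction `|B∖A|/|B|`,
false-negative fraction `|A∖B|/|A|` (truth A, test B; a label absent from
the test scores 0/0/1). Surfaces are boundary voxels (mask minus its
6-connected erosion); directed distances come from an exact Euclidean
distance transform honouring anisotropic spacing, measured between voxel
centres. Mean/max/SD are taken over the pooled symmetric set of both
directed distance sets; the Hausdorff distance is the maximum of the two
directed maxima (numerically the pooled maximum — both are reported
because summary tables often list them separately).

Bland–Altman: bias = mean(a−b), limits = bias ± 1.96·SD with the sample
(n−1) SD. ICC(2,k) is the average-measures absolute-agreement coefficient
from the two-way ANOVA decomposition,
`(MSR − MSE) / (MSR + (MSC − MSE)/n)`; the single-measures variant is
exposed but not the default. Zero total variance yields NaN with no
pretence of a defined coefficient.

## Synthetic phantoms

The generator emulates what the estimation pipeline actually relies on in
musculoskeletal CT, not CT physics. Bones are ellipsoids or capsules with
a bright cortical shell (default 1200) around a trabecular core (300) on
soft tissue (50), Gaussian noise SD 20 — arbitrary but fixed CT-like
values. Epiphyses carry off-axis ellipsoidal lobes: a smooth symmetric
ellipsoid is a pathological case for intensity-based rotation estimation,
and real bone ends are lobed (condyles), so the default two-bone joint is
deliberately asymmetric. The joint gap is kept wider than the tracking
mask dilation so a bone's mask does not capture its neighbour's cortical
shell — on phantoms that contamination produced a measurable systematic
under-rotation, and in real joints with sub-3-voxel cartilage gaps the
same bias should be expected. Landmarks are exact support points of the
bone surface (extremal along a direction), computed analytically.

Atlas populations warp one base anatomy with random B-spline displacement
fields (coefficient SD = `deformation_sd`, default 3 mm, control spacing
16 mm, redrawn while any Jacobian determinant ≤ 0.05); images, labels and
landmarks are warped consistently, with fresh noise per atlas. Dynamic
sequences move each bone rigidly (axis-angle ramps about the bone centre
by default, frame 0 = identity), rendering from the *noise-free* anatomy
with cubic interpolation and adding one noise realization per frame —
rendering from the noisy image would double-count acquisition noise, and
linear rendering measurably biases the registration optimum. Ground-truth
transforms and per-frame landmarks are returned exactly.

What passing these tests shows: the estimation machinery recovers known
piecewise-rigid motion and known label geometry through the full pipeline
under CT-like contrast and noise. What it does not show: robustness to
beam hardening, metal or cropping artifacts, cartilage-scale joint gaps,
pathological morphology outside the atlas population's deformation model,
or through-plane motion blur — none of which the generator emulates.

## Problem sizes and runtime choices

The validation experiments run on 64³ volumes at 1 mm with 15-frame
sequences and 6-atlas populations — large enough that multi-resolution,
masking and sequential initialization all matter, small enough for a
laptop-class single-CPU run. At this scale the full clinical iteration
caps only add runtime, so the experiment configurations use a reduced
stage list (`desk_stages`: 150/100/80 iterations, B-spline on a 2-level
pyramid); both presets are plain configuration objects. Tolerances used
in the tests (e.g. cardan round trip 1e-9, fusion oracle exact equality,
tracked angle RMS 0.3°, held-out Dice 0.90) are stated in the test suite
itself and in `scripts/acceptance.py`, which recomputes every quantity
from freshly generated phantoms.

## Known limitations

* The deformable stage has no explicit bending-energy term (smoothness by
  grid spacing only); very large `deformation_sd` values can exceed what
  the default control grid recovers.
* The B-spline inverse is pointwise-numeric; inverting it across a whole
  volume is slow by design — label propagation is arranged so it never
  needs a dense inverse.
* ICC assumes a complete subjects × raters matrix; missing cells are
  rejected, not imputed.
* The shipped knee/thumb frame definitions encode plausible but unverified
  landmark-to-axis mappings; treat them as templates to edit against your
  own atlas annotations.
* Tracking accuracy degrades when a bone's dilated mask overlaps a
  neighbouring bone (narrow joint gaps) or when a bone is nearly
  rotationally symmetric about the motion axis.
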