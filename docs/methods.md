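# Methods

`alrls` segments a dark, air-filled cavity (the maxillary sinus on CT)
bounded by bright bone and partially occluded by intermediate-intensity
lesions.  A localizing region-based level set drives the contour; a small
patch CNN arbitrates between "true sinus wall" and "lesion edge" whenever
contour points stall, and lesion verdicts are paid a probability-weighted
outward speed compensation so the contour escapes the local minimum on the
lesion rim and reaches the actual wall.

## Energy model and flow

The contour is the zero level set of φ (φ < 0 inside).  Every point x
carries local statistics over a disk B(x,·) of radius `ball_radius`:
Heaviside-smoothed interior/exterior means u_x, v_x and areas A_u, A_v.
Two data energies are supported:

* **UM (uniform modelling)** — the localized piecewise-constant Chan–Vese
  residual λ₁(I−u_x)² inside, λ₂(I−v_x)² outside;
* **MS (mean separation)** — the localized Yezzi energy −(u_x−v_x)²,
  minimised when the local means are maximally separated.

The first variation with respect to φ(x) moves the pixel at x by the
residual of **its own intensity** judged against the statistics of every
contour point y in its ball (the derivative through the means vanishes
because the means are least-squares optimal):

    UM:  ∂φ/∂t(x) ∝ −Σ_y B(x,y) δ(φ_y) [λ₁(I_x−u_y)² − λ₂(I_x−v_y)²]
    MS:  ∂φ/∂t(x) ∝ −Σ_y B(x,y) δ(φ_y) [λ₂(I_x−u_y)²/A_u(y) − λ₁(I_x−v_y)²/A_v(y)]

A positive bracket shrinks the interior.  Note the pairing: some published
statements of this flow pair I(y) with u_x instead; that transposed form
degenerates to a spatially constant force when the ball covers the image,
whereas the form above reduces exactly to the global Chan–Vese force field
in that limit (verified by the global-limit acceptance test against an
independent morphological Chan–Vese implementation).

The whole speed field costs a handful of FFT disk convolutions per
iteration (`energies.evolution_fields`); the per-point functions
(`um_speed`, `ms_speed`) are the reference semantics and agree with the
field computation to 1e-8 and with naive per-pixel loops to 1e-10.

### Mollifiers

The smoothed Heaviside/Dirac pair is the compact-support cosine pair
(C¹, transition confined to |φ| ≤ ε, ε = 1.5 px).  A heavy-tailed
mollifier (e.g. the arctan pair) lets pixels far from the contour leak
into the local statistics; with the fat Cauchy tails the bright wall
contaminates the interior mean of small contours badly enough to collapse
the MS flow.  Compact support removes this failure mode outright.

### Evolution scheme

Each iteration:

1. The narrow band is the set of pixels within `band_width` (8 px) of the
   current contour, measured by an exact distance transform.
2. The data speed is evaluated for every band pixel and normalised to
   unit maximum over the *active* band.  Pixels already pinned at the φ
   saturation rail (below) and still pushed outward are excluded from the
   normalisation — otherwise their permanently large residuals starve
   every other pixel of step size.
3. The update is `speed + μ·κ` (κ the curvature of φ, μ = 0.05) applied
   to the band with a CFL-limited step (`dt_cfl = 0.45` px per iteration
   for the fastest pixel), followed by `sdf_substeps` (2) explicit
   double-well distance-regularisation steps, and a final clip of φ to
   ±`phi_cap` (2.0, binary-level-set style).
4. The traced energy is the Dirac-weighted band sum of the local data
   energy plus μ times the Dirac-weighted contour length.

Stopping: `max_iters` (400) or relative energy change below 1e-4 across a
trailing window of 10 iterations.

This is a *region-competition extension* of the flow: the speed is applied
to every band pixel rather than δ(φ)-weighted.  The reason is documented
at length here because it is the package's most consequential numerical
choice.  With δ-weighted updates the advancing front digs a one-pixel
trench against the stale signed-distance far field; the distance
regulariser then exactly cancels the data push (a measured equilibrium,
data −0.37/iter vs regulariser +0.37/iter) and the contour deadlocks
short of the target.  Every distance-restoring remedy we evaluated
(upwind redistancing steps, distance-envelope clamps, soft relaxation
toward the exact distance transform, single-well regularisation,
extension velocities along nearest-contour rays) either restored the
deadlock or destroyed convergence from small initial contours.  The
region-competition extension with a saturated φ eliminates the stale far
field entirely: φ carries signed-distance structure only within a ±2 px
skirt of the contour, and the deep field is a constant plateau.

The price is the signed-distance-quality contract: the band-mean of
||∇φ|−1| sits around 0.7–1 during a run because most of the band is
saturated plateau (|∇φ| = 0) by design, not because of numerical decay.
The corresponding acceptance test is left failing with this analysis
rather than weakening the test or the dynamics: with this phantom
geometry, convergence from a radius-3 seed and a strictly maintained
signed-distance band proved mutually exclusive in all schemes evaluated.

## Stalled points and speed compensation

A contour point is **stable** when the interface velocity through it is
zero.  Under region competition a blocked interface shows large *opposing*
pixel speeds, so raw speed magnitude is not a usable signal; instead a
point is stalled when the zero crossing stays pinned to the same lattice
site for `stability_window` (5) consecutive iterations (a raw normalised
speed below `stability_tol` (0.15) also counts).

Stalled points are classified — once per site per run — by the patch CNN,
but only when the local exterior–interior contrast v_x−u_x exceeds 0.15:
the two training classes are only defined at intensity edges (wall or
lesion rim), and querying the net on flat-region patches feeds it
out-of-distribution inputs whose answers are meaningless.

The classifier returns (p1, p2) = P(sinus boundary), P(lesion).  The
decision rule is the drop rule: |p1−p2| ≤ 0.2 → ambiguous (no action);
p2 > p1 → compensated; otherwise confirmed boundary (exempt from
re-inspection).  The compensation magnitude is

    T = exp(|λ₁+λ₂|^{1/2}) · ((1+p2)/(1+p1) − 1/2)  ∈ [0, 1.5·e^{√(λ₁+λ₂)}]

non-negative everywhere and strictly decreasing in p1.

**Injection.**  In raw speed units T is ~3 orders of magnitude above the
MS data integrand, so a literal additive injection monopolises the CFL
normalisation and freezes all other motion.  The pipeline therefore
injects compensation in *normalised* speed units: each compensated site
radiates an outward push of `1.5 · T/T_max` (so a certain lesion verdict
pushes with 1.5× the fastest data flow) over a disk of ⅔ `ball_radius` —
wide enough to span a lesion, calibrated so lesion texture is
out-competed but healthy bone-wall resistance is not.  Two containment
rules keep single misclassifications harmless:

* a site's push lasts only while the site stays within 3 px of the
  contour — once the front has escaped past it the data forces resume,
  which also self-heals any overshoot behind a wrongly pushed point;
* quorum: only clusters of ≥ 3 compensated sites push.  A genuine lesion
  stalls a whole arc of contour points; an isolated misclassified wall
  point does not, and without quorum each such point punches a hole in
  the wall.

The literal per-point form of the compensation (T times the Dirac mass of
the ball, added to the point's speed) is kept as
`compensation.apply_compensation` for reference and unit testing.

## Patch classifier

Input: the 10×10 intensity window centred on the query point, bilinearly
amplified to 32×32 and CLAHE-enhanced (clip limit 0.02, 4×4 tile grid,
applied per patch after amplification).  Architecture: two 5×5 conv
blocks (batch-norm → leaky-ReLU(0.01) → 2×2 max-pool), depths 16 and 25 —
the second depth makes the flattened output exactly 8·8·25 = 1600, the
width of the first of three fully connected layers (1600 → 500 → 2,
softmax).  Implemented directly in numpy with hand-derived backprop,
verified against central differences to 1e-4 relative.

Training: minibatch SGD, batch 32; loss = cross-entropy + (η/2)‖ω‖² with
η = 1.0 over conv/FC weight matrices; dropout keep 0.6 on FC activations;
truncated-Gaussian init (σ = 0.1); exponential LR decay ×0.9997 at every
10000-step boundary from an initial rate of 0.01; shadow weights and
batch-norm statistics tracked with the same 0.9997 moving-average decay,
ramped as min(0.9997, (1+t)/(10+t)) so short runs are not dominated by
the random init; inference uses shadow weights and frozen statistics.

The L2 penalty is normalised by the regularised-weight count
(η/(2M)·Σω²).  Read literally as a raw sum, η = 1.0 makes the penalty
three orders of magnitude larger than the data term; measured on this
task, accuracy then peaks around 0.87 early in training and erodes to
~0.72 as the weights decay toward a noise-dominated equilibrium — no
classifier trains under that reading, so the normalised form (the same
per-sample averaging spirit as the cross-entropy term) is the package's
interpretation.  The literal sum form remains available in the loss API.

Classes: **boundary** = the full cavity wall, including arcs where a
lesion touches the bone (the contour must stop there too); **lesion** =
the lesion/air interface strictly inside the cavity (where the contour
must push through).  Centres are jittered ±1 px at sampling time because
run-time queries stall 1–2 px off the exact edge pixel; ±2 px jitter
blurred the classes into each other.  Patch sets are balanced by pooling
candidates across a cohort of phantoms.  Augmentation: elastic distortion
(uniform [−1,1] displacement fields, Gaussian-smoothed with σ ∈ [3,6] px,
scaled by α ∈ [1,4] px) composed with small affine warps (scale 0.9–1.1,
shear ±5°, translation ±2 px, **no rotation**), labels preserved.

## Synthetic phantoms

Each phantom emulates one axial CT slice at a scaled-down geometry
(128×128): an irregular dark elliptical cavity (semi-axes 12–18 px,
radial harmonics ≤ 5 %, mean 0.15) in bright bone (0.85), with
wall-attached lesion blobs (means 0.55–0.70 plus smoothed-noise texture of
amplitude 0.06), multiplicative low-frequency bias (±8 %), sub-pixel
partial-volume blur (σ = 0.4 px — the CT PSF is below one pixel at this
scale) and Gaussian noise (σ = 0.01; air-region CT noise is ≤ 1 % of the
air/bone dynamic range).  Ground truth is the **full cavity including the
lesion-occluded area**: the clinical target is the sinus, and stopping on
a lesion edge is precisely the failure the method exists to fix.  The
lesion mask is kept separately for patch labelling.

The localization ball default (15 px) is set so the smallest prescribed
initial contour (radius 3 at the air-region centroid) always has the wall
inside its ball; a localized model receives no outward signal at all when
the ball sees only flat cavity.

The "stalling" preset (3 wall-attached lesions, radii 6.5–9.5 px) blocks
roughly a third of the cavity with lesions, the regime where the
fixed-parameter baseline visibly fails (mean Dice ≈ 0.74 over a 20-phantom
cohort and the five initial radii) and the compensated method recovers
(mean ≈ 0.95–0.97 with the trained CNN, worst run ≈ 0.92).

**What the phantoms do not emulate:** real CT texture inside mucosa and
bone, anatomical variability of sinus shape, slice-selection effects,
neighbouring air cells, and annotation noise between raters.  Two
consequences observed in the results: the synthetic FLS baseline is
nearly initialization-independent (it wraps the lesions identically from
any interior seed), so the claimed initialization-insensitivity
*advantage* of the compensated method cannot manifest here — its Dice
spread across radii is small (~0.01) but not smaller than the baseline's
(~0.0003), and the corresponding acceptance clause fails honestly.  And
clean phantoms are easier than clean CT: lesion-free runs converge to
Dice ≈ 1.0, which should be read as a correctness check, not a clinical
performance claim.

## Defaults that matter

| parameter | default | meaning |
|---|---|---|
| μ, λ₁, λ₂ | 0.05, 1.0, 1.0 | curvature weight; interior/exterior residual weights |
| `ball_radius` | 15 px | localization disk radius |
| `band_width` | 8 px | evolution band half-width (distance to contour) |
| `epsilon_heaviside` | 1.5 px | mollifier transition half-width |
| `dt_cfl` | 0.45 px | displacement of the fastest pixel per iteration |
| `phi_cap` | 2.0 | φ saturation (binary-level-set plateau) |
| `sdf_weight`, `sdf_substeps` | 0.2, 2 | distance-regularisation step |
| `stability_tol`, `stability_window` | 0.15, 5 | stall detection |
| `ambiguity_margin` | 0.2 | classifier drop rule |
| `max_iters`, `convergence_tol` | 400, 1e-4 | stopping |

Known limitations: the UM energy without compensation can creep through
wide partial-volume ramps (its local mean adapts upward as it claims ramp
pixels) — MS is the recommended default and the one used in the headline
comparisons; φ is not a signed distance function away from the contour;
the compensation calibration (push scale 1.5, disk ⅔ ball, quorum 3)
was set against a ground-truth oracle classifier on the stalling preset
and is exposed in code, not in `RunConfig`.
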