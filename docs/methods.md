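# Methods

`broncholoc` localizes a bronchoscope camera inside a 3-D bronchial-tree
model from monocular video alone, in two phases: a fast inter-frame
**tracking** phase that proposes a pose increment, and a **verification**
phase that renders the virtual airway at the proposed pose, compares the
render against the real frame, and corrects the pose when the match is
poor. A discrete HMM plans fork-coded routes through the airway's junction
graph. This note records the model, the parameters that matter, the
numerical choices, and what the synthetic study fixtures do and do not
show.

## Phase 1 — inter-frame tracking

Two displacement estimators run on every consecutive frame pair:

* **Sparse feature matching.** SIFT keypoints (scikit-image) with
  mutual-nearest-neighbour matching and a 0.8 Lowe ratio filter. The DoG
  threshold is lowered to 0.002 because endoscopic frames are
  low-contrast: most of the image is a dimly lit lumen. ORB and
  CENSURE+BRIEF are selectable for the detector-comparison harness
  (`feature_report`).
* **Block-matching optical flow.** For each 16 px block of the earlier
  frame, the displacement within a ±12 px search window maximizing the
  normalized cross-correlation

      CC(G, H) = Σ (g − ḡ)(h − h̄) / (M·N·σ_G·σ_H)

  with block means and population SDs. The MN normalization puts CC in
  [−1, 1] with CC(G, G) = 1; the argmax over displacements is unchanged by
  it. Blocks whose intensity SD is below 1e−9 (constant up to float
  accumulation) are flagged invalid.

**Lifting 2-D motion to a 3-D increment.** A RANSAC-estimated 2-D
similarity transform (2-point minimal samples, 2 px inlier threshold, 500
iterations, fixed seed) summarizes the correspondences. The transform's
displacement of the principal point gives the lateral translation
(mm = px · depth/focal); its rotation angle gives roll about the view
axis; its scale s gives the axial advance dz = z_eff (1 − 1/s).
Monocular scale is resolved with depth from the *virtual* model at the
current pose: one ray is cast per matched feature, and because the
least-squares scale weights each feature by its squared radius about the
center, z_eff is the radius²-weighted harmonic mean of the inlier feature
depths (the unweighted median overestimates dz by ~12% in a tube, since
peripheral features are nearer than the median ray). Confidence is the
RANSAC inlier fraction.

**Arbitration.** A two-input fuzzy system decides, per frame, whether to
trust the feature estimate or wait for the flow result. Its inputs are
(a) *suddenness* — the larger of the two candidates' deviation from the
mean of the last 5 increments, in units of the mean historic step length
(clipped at 10; with no history the motion cannot be judged sudden) — and
(b) the feature estimate's RANSAC confidence. Sudden motion blurs the
frame it lands on; a blurred feature match can return a deceptively small
vector, which is why suddenness considers both candidates. The chosen
increment is integrated as a body-frame right-multiplication
(T ← T·ΔT), with the rotation kept normalized.

## Phase 2 — render-and-verify

The airway is a union of capsules (straight tube segments with spherical
ends, radii decaying geometrically per generation). The renderer casts one
ray per pixel and intersects it *analytically* with the capsule union
(each capsule is convex, so its ray intersection is one interval; the exit
point of the union interval containing t = 0 is the wall hit). Shading is
a camera headlight: Lambert term × inverse-square falloff (12 mm scale) ×
a deterministic sinusoidal 3-D mucosa texture (1.6 mm scale, ±22%
amplitude), tinted pink (albedo 0.86/0.55/0.50). The result has the
canonical endoscopic appearance — dark distal tunnel, bright textured near
walls — and is exactly reproducible. Default frames are 128×128 with
focal 0.6·width; the study fixtures use 200×200 (400×400 for the glare
fixture) as a deliberate desk-scale choice.

The verification pipeline for a real/virtual frame pair:

1. **Subblock statistics** (40 px tiles at the 400–512 px scale, 12 px on
   200 px frames; edge tiles average their own pixels): per-block mean HSV
   saturation S and value V.
2. **Glare masking** (real frame only — the renderer emits no specular
   saturation): a two-input fuzzy system on (S, V). Specular glare
   saturates the sensor (V→1, S→0) while tissue keeps its color ratio
   under any shading, so low S is the primary signature, with V gating
   out dark regions. The crossover sits where about half of a block's
   pixels are saturated. A plain V-threshold detector is kept as the
   comparison baseline.
3. **Saliency selection**: per block, the square-root-free non-uniformity
   statistic I = Σ(x² − 2xu + u²) = N·SD² over luma intensities in [0,1].
   A single-input fuzzy system maps I to importance (crossover at
   SD ≈ 1% of full scale, i.e. I = N·10⁻⁴); selected blocks must score
   ≥ 0.5, not be glare, and have no 8-neighbour whose thresholded decision
   differs (boundary blocks are unreliable).
4. **Polar shape context**: selected block centers are binned into 16
   polar regions (8 angular × 2 radial, theta clockwise from +x with
   image y down, radial rings uniform to the image half-diagonal) around
   the image center, and two layouts compared with
   C = ½ Σ (h_i − h_j)²/(h_i + h_j) (empty bins contribute 0). The
   normalized similarity is s = 1 − C/(n_i + n_j) ∈ [0, 1], higher is
   better. C and s are averaged over the nominal center plus four
   half-block offsets: the histogram is a count of quantized block
   centers, and this de-aliases the quantization without breaking the
   exact s = 1 self-match.
5. **Acceptance and line search**: a single-input fuzzy system thresholds
   s; its crossover sits near 0.985 because count histograms over
   ~100–200 blocks score a correct registration above 0.99 and a pose a
   couple of millimetres off at 0.94–0.98 — the discriminating band is
   narrow and high. On rejection, the increment is re-applied from the
   pre-increment pose scaled by {±0.25, ±0.5, ±0.75, 1.25, 1.5}
   (rotation scaled on the geodesic), each candidate re-rendered and
   scored; the argmax-s candidate wins, flagged best-effort if its
   decision still fails. Candidates falling outside the lumen are skipped.

## The fuzzy engine

All four decision points share one engine: triangular membership
functions, AND = min, implication = clipping, aggregation = max, and
center-of-gravity defuzzification on a fixed 1001-point discretization of
the output domain. If no rule fires, the output-domain midpoint is
returned with a warning rather than crashing mid-sequence. The shipped
default models are hand-constructed rule bases (documented above); any can
be replaced by a JSON model or tuned with the trainer — minibatch gradient
descent with central finite differences on the MF vertices, seeded
shuffling, an l ≤ p ≤ r projection, and a coverage projection that keeps
each input partition spanning the observed data range (finite-difference
gradients plateau once a foot crosses past the data, which otherwise opens
dead zones). The best-RMSE snapshot over the run is returned, so training
never ends worse than it started.

## HMM path planner

Routes are coded as fork sequences: every traversed node contributes the
index of the chosen branch among its children ordered by label, so a
straight run down first branches in a 3-generation tree reads 0-0-0. The
discrete HMM (default 3 hidden states over 3 fork symbols) uses a
log-space forward recursion, Viterbi with ties broken toward the lower
state index, and scaled-forward/backward Baum-Welch stopping when the mean
per-sequence log-likelihood changes by less than 0.01 (log-likelihood is
the only numerically meaningful reading of "average likelihood change";
raw products underflow). EM only finds local optima — on planted-model
recovery roughly half of random initializations merge two symbols — so
training runs 5 seeded Dirichlet(1) restarts and keeps the best training
log-likelihood. In a tree the source→target path is unique and the planner
degenerates to traversal plus likelihood annotation; with cycles it
enumerates simple paths and returns the coding with maximal forward
likelihood.

## Synthetic study fixtures

Clinical video and patient CT cannot be redistributed, so every input is
generated with ground truth: procedural binary trees (root 30 mm × 5 mm
radius, length decay 0.75, radius decay 0.78, branching angles
N(35°, 5°), self-intersection rejected), smooth in-lumen trajectories
(0.25 mm steps, sinusoidal lateral sway), saturated circular glare blobs
with a narrow 12%-of-radius feather placed collision-free off-center,
optional single-coefficient fisheye warp r′ = r(1 + k r²), Gaussian sensor
noise (σ = 0.005), and an optional camera-response mismatch (gamma 0.8,
per-channel gain) between "real" frames and the virtual renders. The
named fixtures: `slow_stable` (50 smooth steps), `sudden_jump` (5 mm
axial jump at step 25, with a σ = 5 px Gaussian blur on the jump frame —
the motion-smear that actually defeats feature matching), `glare_heavy`
(3 frames, 8 blobs each, 400², camera-response mismatch), `straight_tube`
and `tree_g3`. All are bit-reproducible from their seeds.

**What the fixtures do not show.** The renders share one appearance model
between "real" and virtual frames, so there is no true domain gap
(tissue texture, BRDF, deformation); the plain-MSE registration baseline
is therefore *not* disadvantaged here the way it is on clinical data, and
the comparison harness reports both methods' errors without asserting a
ranking. Glare is circular and sharply feathered, saliva bubbles and
breathing deformation are absent, and frames are rendered undistorted
(fisheye exists only as an optional degradation). Passing tests show
parameter recovery under these conditions, not clinical performance.

## Evaluation conventions

Block-level glare ground truth calls a block glare when ≥ 50% of its
pixels are in the saturated mask; blocks within 5 percentage points of
that boundary are excluded from recall/preservation scoring as
label-ambiguous. Tracking quality is the final-position error as a
fraction of path length on `slow_stable`, and the arbitrated-vs-
features-only final error on `sudden_jump`. Verification quality is the
self-match property (accept with s = 1 in one pass) and the fraction of
2 mm / 5° perturbed poses whose error shrinks after verification in the
straight tube. Problem sizes throughout (200² frames, 50-step sequences,
50 recovery trials, 1000-block identity checks) are the package's chosen
desk scale.

## Known limitations

* The monocular depth scale leans on the virtual model; a wrong model
  (or a pose far off the centerline) degrades the lift from pixels to mm.
* The 16-region count histogram saturates: beyond a few millimetres of
  pose error, s no longer decreases monotonically, so verification
  corrects locally but cannot re-localize globally.
* The line search only rescales the last increment's direction; errors
  orthogonal to it survive until later steps.
* The fuzzy defaults encode this synthetic world's statistics (e.g.
  tissue saturation ≈ 0.42); clinical deployment would retrain them.
* Fork symbols are capped by the binary trees at 2 in practice (the HMM
  default allows 3); states carry no anatomical semantics.
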