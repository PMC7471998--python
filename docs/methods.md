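# Methods

This note documents the models and procedures implemented in `melcbp`, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not establish.

## Problem setting

Micro-expressions are involuntary facial movements lasting roughly 1/25 to
1/3 of a second with very low intensity. Recognizing them from video is a
three-stage problem: normalize heterogeneous clips, build a spatiotemporal
representation sensitive to subtle local changes, and classify under a
protocol that measures generalization to unseen people. `melcbp`
implements a complete chain of that form: cube-based binary descriptors,
multi-region sparse feature selection, and a multi-kernel SVM under
leave-one-subject-out (LOSO) evaluation.

## Preprocessing

Clips arrive as ordered image frames and are converted to gray with ITU-R
BT.601 luma weights (0.299, 0.587, 0.114) — a fixed convention so that
color and gray inputs are interchangeable. Spatial resizing is bilinear
(`skimage.transform.resize`, center-aligned convention). Temporal length
is normalized to a fixed count (default 20 frames) by per-pixel linear
interpolation over normalized time [0, 1]. Published work in this area
typically uses a graph-embedding temporal interpolation model for this
step; the linear scheme here is a deliberate, documented stand-in — it is
deterministic, preserves the first and last frames exactly, maps constant
clips to constant clips, keeps monotone pixel trajectories monotone, and
is idempotent, all of which are tested. Resizing is applied before
temporal interpolation (the reverse order would interpolate between
differently-sized frames); the order is a convention, not a necessity.
Intensities are held as float64 throughout so the signed arithmetic below
(differences, mask responses up to 8·255) is exact.

## Enhanced LCBP descriptors

The encoding unit is the 3×3×3 cube: the 3×3 spatial neighborhood of a
pixel at frames t−Δt, t, t+Δt. Δt defaults to 1 and is exposed as a
parameter. Only complete cubes are coded (1-pixel spatial margin, Δt-frame
temporal margin). Three complementary code streams are computed per cube:

**Spatial Difference codes** (3 per cube, 8 bits each). For each temporal
center c_i ∈ {c_{t−Δt}, c_t, c_{t+Δt}},

    code(c_i) = Σ_{n=1..8} s(x_n − c_i) 2^{n−1},   s(x) = 1 iff x ≥ 0,

where x_n are the eight neighbors of the *last* frame in the cube.
Neighbor order is top-left, then clockwise; any fixed order is valid for
histogramming, this one is fixed for reproducibility. The c_{t+Δt} stream
is plain LBP of frame t+Δt; the other two additionally encode how the
center has drifted across frames.

**Temporal Direction codes** (4 per cube, values 0..63). Four temporal
planes are cut through the cube center: the horizontal, vertical,
main-diagonal and anti-diagonal spatial lines, each tracked across the
three frames (rows = time ascending, columns = line position in raster
order). Together the planes cover all 27 cube cells. Eight zero-sum 3×3
compass masks a_1..a_8 (N, NE, …, NW; +1 on a three-cell boundary arc,
−3 at the center) are correlated with each plane, and the code is

    code(P_j) = 8·argmax_i D_i(P_j) + argmin_i D_i(P_j),

ties going to the lowest index (so a constant plane codes as 0). The mask
and plane geometry is a reconstruction from stated constraints — zero
response to uniform patches, eight directions, full cube coverage — since
only a pictorial definition exists; the compass-rotation symmetry of the
masks is tested.

**Temporal Gradient codes** (1 per cube, 2 bits). A center-surround
response S_i = (8·center − Σ neighbors) per frame, then
g1 = (S_t − S_{t−Δt})/Δt, g2 = (S_{t+Δt} − S_t)/Δt, and the code is the
sign pattern (g1 ≥ 0, g2 ≥ 0): 11 steadily brightening, 00 steadily
darkening, 10 up-then-down, 01 down-then-up. The published case table
lists 11 twice; the fourth case is encoded as 01, keeping the scheme
bijective.

All three streams are built from differences or zero-sum mask responses,
so a uniform gray shift leaves every code unchanged — a property tested
directly and important because facial data differ in global brightness.

**Grid histograms.** Codes are binned per spatial grid cell (cell width
⌊W/cols⌋, last row/column absorbs the remainder) to retain location
information: per cell, three 256-bin spatial histograms (768 values) and
four 64-bin direction histograms plus one 4-bin gradient histogram (260
values). Histograms are L1-normalized per sub-histogram by default so
cells are comparable across clip lengths; unnormalized mass equals the
number of valid cube centers, which is the conservation law the tests
check. The evaluation default is a 4×4 grid (appropriate for 64×64
synthetic frames); 8×8 is typical for 128×128 face crops.

## Multi-region joint sparse learning

Grid cell i contributes a design matrix X_i (s×d) and a coefficient block
W_i (d×c) against shared one-hot labels Y (s×c); W = [W_1 … W_β] is d×βc.
The fit minimizes

    Σ_i ‖X_i W_i − Y‖_F² + θ1‖W‖_F² + δ Σ_{u<v} (‖m_u − m_v‖² + ε)^{-1}
        + θ2‖W‖_{2,1}

with m_u the class-u mean of the weighted features (per-sample
concatenation of X_i W_i rows) and ‖W‖_{2,1} the sum of row norms. Rows of
W index per-cell feature dimensions, so the ℓ2,1 penalty discards the same
feature across all grids (a shared sparsity pattern); the interclass term
pushes class centers apart. Reading notes: the interclass sum is over
unordered pairs u < v (u = v would be infinite) with the inverse *squared
Euclidean* distance, guarded by ε = 1e−8; Y is one-hot so the multi-class
case is well defined. Defaults θ1 = θ2 = δ = 0.1 (reported as an
insensitive region in this family of models), max_iter = 200, tol = 1e−5,
selection threshold τ = 1e−6.

**Solver.** Accelerated proximal gradient: gradient of the smooth part at
the momentum search point, row-wise shrinkage
row ← row·max(0, 1 − λ/(2‖row‖)) with λ = θ2/ρ, momentum factor
φ_k = 2/(k+2). The step 1/ρ starts from the spectral curvature of the
least-squares + ridge part (largest per-grid singular value) and is halved
by backtracking until the quadratic majorization of the smooth part holds
— necessary because the interclass term's curvature is unbounded near
coincident means. A monotone safeguard keeps the previous iterate when a
candidate raises the objective (momentum still continues from the
candidate), so the objective trace is non-increasing by construction.
Initialization is the per-grid ridge solution: the all-zero point has
coincident class means, where the interclass penalty is maximal and its
gradient vanishing-ill-conditioned. Convergence is declared on accepted
steps only, when the relative objective change falls below `tol`.

**Selection.** Row importance is the ℓ2 norm of the corresponding row of
W; rows with norm > τ are kept, and kept features are scaled by their row
norm. Grid importance is ‖W_i‖_F. A subtlety worth recording: grid norms
rank *informative* grids highest only in the low-signal regime. When
class separation is far above the noise floor, a near-perfect fit needs
only small coefficients and noise grids can carry larger norms; with
separation below the noise floor (the micro-expression regime, and the
regime of the recovery benchmark, prototype scale 0.25 vs noise σ 0.5)
the informative grids attract the weight mass.

## Classification and evaluation

Per descriptor domain (spatial, temporal), the selected weighted features
are unit-L2-normalized and mapped through a linear kernel; the SVM runs
on the convex combination K = c1·K_spatial + c2·K_temporal. Normalizing
per type before the kernel makes c_z comparable — without it the two
domains have incommensurate scales. The weights are chosen from
c1 ∈ {0, 0.25, 0.5, 0.75, 1} by stratified 5-fold inner CV on the
training subjects of each LOSO fold (leak-free, and re-tuned per fold);
ties go to the smallest c1. The SVM is scikit-learn's SVC with a
precomputed kernel (libsvm one-vs-one decomposition), C = 1 by default.

LOSO evaluation: one fold per subject, all of that subject's clips held
out. Overall accuracy is 100·ΣT_i/ΣS_i over subjects; macro-F1 averages
per-class F1 with classes at p + r = 0 contributing zero. The sparse
models, kernel weights and SVM are all fit inside each training fold only.

## Synthetic data

Each clip is: a subject-specific smooth background (Gaussian-filtered
white noise, σ = 8 px, contrast std 4 gray levels, plus a per-subject
offset in ±10), one class-specific event, and i.i.d. pixel noise
(σ = 2), clipped to [0, 255]. Events are soft-edged ~14 px boxes
(Gaussian edge σ = 1.5 — sharp enough that the moving boundary generates
the local spatial gradients the descriptors respond to), amplitude 12
gray levels, drifting 6 px over the clip. The three classes differ in
event type (monotone brightening ramp / monotone darkening ramp /
onset–apex–offset pulse), location (distinct quadrants) and drift
direction — mapping onto the distinct sensitivities of the three code
streams. The background field is reused across a subject's clips, so
LOSO on this data genuinely measures transfer across appearance. The
background contrast is deliberately modest relative to the event: it is
calibrated so that class identity, not subject identity, dominates raw
feature distances (between-class L1 distance exceeds within-class on the
defaults), which is the regime the whole method assumes.

Amplitude 0 is allowed as a degenerate case (static clips, useful for
identity tests); negative amplitude and amplitude at or below the noise
level are rejected.

What passing on this data shows: the descriptors detect localized
low-amplitude spatiotemporal events against per-subject nuisance
variation, the sparse model concentrates weight on event-bearing regions,
and the pipeline is leak-free under LOSO. What it does not show:
performance on real faces — no facial geometry, landmark motion,
head pose, compression artifacts or illumination drift are modeled, and
real class boundaries are far subtler than event-location cues.

## Problem sizes and numerical conventions

The evaluation defaults (60 clips of 20×64×64, 4×4 grid, 10 LOSO folds)
are desk-scale choices: one full LOSO run takes on the order of a minute,
which keeps the whole evaluation — including the permuted-label control —
cheap to rerun. Tie-breaks: argmax/argmin over mask responses take the
first index; SVM prediction ties resolve by libsvm's one-vs-one voting
order (lowest class first). Degenerate inputs: all-zero histogram cells
stay zero under normalization; a model whose every row falls below τ
raises (the advice being to lower θ2); a single-subject dataset cannot be
LOSO-evaluated and raises.

## Known limitations

* The mask/plane geometry is a faithful reconstruction of a pictorially
  defined scheme; a different +1/−3 arrangement satisfying the same
  constraints would permute histogram bins (harmless for learning but not
  bit-identical).
* The linear temporal interpolation stand-in ignores the manifold
  structure a graph-embedding interpolation would capture; clips with
  strongly non-uniform motion sampling are distorted.
* The interclass penalty is non-convex; the solver guarantees monotone
  descent, not a global optimum. Ridge initialization makes the reached
  stationary point reproducible.
* Kernel weights are tuned per fold on a coarse grid; no continuous
  multiple-kernel-learning optimization is attempted.
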