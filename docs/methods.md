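# Methods

`cortexcad` implements a cortical region-based computer-aided diagnosis of
mild cognitive impairment (MCI) from structural T1 MRI. Inputs are assumed
skull-stripped and registered to MNI space with an accompanying brain mask
and an AAL-style integer atlas; all registration and segmentation is out of
scope. The pipeline is: surface reconstruction → per-vertex curvature
descriptors → per-region aggregation → CCA fusion → two-layer diagnosis.
This note documents the model, its numerical choices, and what the synthetic
test data do and do not show.

## Surface reconstruction

The masked scan is thresholded at an automatically selected isovalue α and
triangulated by marching cubes (scikit-image backend, standard case table;
saddle-cube ambiguities are resolved by the case table and not re-decided).
Vertices are mapped to world millimetres through the NIfTI affine; faces are
wound so normals point outward (away from the ≥ α side), verified per closed
mesh by a positive divergence-theorem volume. Zero-area faces from
lattice-coincident crossings are dropped before curvature analysis.

**Isovalue heuristic.** An `n_bins` (default 64) histogram of all voxels is
taken; the background peak — the modal bin plus the contiguous run of bins
holding ≥ 1% of all voxels around it — is removed whole, bins holding < 1%
of the remaining voxels are discarded, and α is the midpoint between the
background mode and the count-median surviving bin. Removing the peak as a
contiguous run rather than a single bin makes the rule robust to background
noise that spreads the zero mode over several bins; for noise-free binary
and bimodal volumes the rule reduces to the midpoint between the two modes.

**Volumes.** Enclosed volume is the divergence-theorem sum |Σ det(v0,v1,v2)|/6
over faces — exact for polyhedra, no re-voxelization error. Region volumes
mask the scan to one atlas region, re-run marching cubes, and sum the closed
components. Mesh-enclosed volume is the default "volume" feature (voxel
counting is available as an independent check in tests only).

## Curvature descriptors

At each vertex, all vertices within `rings` edge hops (default 2, escalated
to 4 on rank deficiency) are rotated into the vertex's normal frame and a
least-squares quadric f(x,y) = ax² + by² + cxy + dx + ey + f is fitted to
the neighborhood heights. Heights are measured toward the inside of the
tissue, so with outward normals a convex surface has positive curvature and
a ball of radius R has mean curvature +1/R. Principal curvatures λ1 ≥ λ2
are the eigenvalues of the Hessian [[2a, c], [c, 2b]]; when the fitted
tangent plane is appreciably tilted (√(d²+e²) > 0.05 — a rotation-invariant
criterion) the full Weingarten map I⁻¹·II of the graph is used instead,
which keeps the sphere oracle tight on coarse meshes. Vertex normals are
area-weighted averages of incident face normals. At umbilics (λ1 = λ2) the
principal directions are an arbitrary orthonormal tangent pair; nothing
downstream depends on them.

The four descriptors per vertex are gaussian = λ1λ2 (1/mm²),
mean = (λ1+λ2)/2 (1/mm), sharpness = (λ1−λ2)² (1/mm²) and
curvedness = √((λ1²+λ2²)/2) (1/mm).

## Region features and normalization

Vertices take the label of the atlas voxel containing their world
coordinate. Because isosurface vertices sit between tissue and background
voxels, lookup uses the atlas after a 1-voxel nearest-nonzero dilation
(radius √3 voxels, so diagonal neighbors count); a raw lookup would label
roughly half the surface background. Per region the vertex descriptors are
averaged (median available) and the region volume appended, giving the
5-vector (gaussian, mean, sharpness, curvedness, volume). Regions with
fewer than 10 labeled vertices, or without a reconstructable surface, are
flagged missing — never silently zero.

Each (region, feature) column is min–max scaled to [0,1] with statistics
computed on training subjects only, frozen, and replayed with clipping on
test subjects; a constant column is set to 0.5 with a warning. Missing
cells are imputed with training column means before scaling; regions
missing in more than half of the training subjects are dropped.

The packaged atlas dictionary contains 76 cortical regions: the 90 cerebrum
parcels of the standard AAL scheme minus the 12 subcortical nuclei
(hippocampus, amygdala, caudate, putamen, pallidum, thalamus, both sides)
and olfactory cortex, with the standard AAL label ids.

## CCA fusion

For matched feature sets X ∈ R^{p×n}, Y ∈ R^{q×n}, transforms Wx, Wy
maximize corr(WxᵀX, WyᵀY) subject to var = 1, solved by SVD of the whitened
cross-covariance Sxx^{-1/2} Sxy Syy^{-1/2}; d = rank(Sxy) is the count of
singular values above 1e-10 of the largest, correlations δ1 ≥ … ≥ δd, and
the fused output is Z = [WxᵀX; WyᵀY] ∈ R^{2d×n}, whose training covariance
has identity diagonal blocks and diag(δ) off-diagonals. Covariances use the
1/n convention (exactly invariant under sample duplication); a within-set
covariance with condition number above 1e10 receives ridge 1e-8·trace/p
with a warning; transform signs are fixed deterministically (largest-|·|
entry of each Wx column positive).

The five scalar region features are fused sequentially in the fixed order
(gaussian, mean, sharpness, curvedness, volume), two at a time:
Z1 = fuse(f1, f2), Zk = fuse(Zk−1, fk+1). Every pairwise step has d = 1, so
the final fused vector per region is 2-dimensional. A step whose
cross-covariance has rank 0 (constant feature) is skipped with a warning.
Chains are fitted on training folds only and replayed on test folds.

## Diagnosis

Layer 1: per region, an SVM (linear by default; polynomial degree 3 and RBF
with the 1/(d·var) bandwidth heuristic available; C = 1) with Platt sigmoid
calibration fitted by inner stratified 3-fold CV on the training portion,
yielding a regional MCI probability — the personalized severity map.
Layer 2: a standard SVM of the same kernel on the vector of regional
probabilities; the global call is MCI when the oriented decision value is
≥ 0, resolving the tie toward MCI (favoring sensitivity). The global layer
is trained on the calibrated probabilities of the training subjects
themselves (no additional nesting); the inner calibration CV already
tempers the optimism of these inputs.

Evaluation uses stratified k-fold CV (k = 4 and 10 in the harness) with a
fixed, logged seed. Per fold, imputation means, normalization statistics,
CCA chains and both classifier layers are fitted on the training portion
only — an invariant enforced by a refit-fingerprint audit (deleting a
test-fold subject must leave the fold's fit bit-identical). Confusion
counts are pooled over folds (per-fold rates also reported) with MCI
positive: accuracy (TP+TN)/n, sensitivity TP/(TP+FN), specificity
TN/(TN+FP), as percentages; zero denominators yield NaN, not 0. The
comparison harness runs the three SVM kernels (both layers) plus decision
tree, random forest and k-NN replacing the global layer, all on identical
folds verified by fold hash. Behavioral correlations are plain Pearson r
with two-sided t-based p-values, pairwise deletion, and
Benjamini–Hochberg q-values emitted alongside the raw p.

## Synthetic data

Phantoms voxelize ball / ellipsoid / cube / slab / two-blob shapes with
partial-volume antialiasing (boundary intensity ramps linearly with the
signed distance over one voxel, so the half-tissue level set sits on the
true surface; hard binarization available) and Gaussian intensity noise,
default sd 2% of tissue intensity. Every phantom carries its closed-form
volume and curvature, so geometry tests never compare the pipeline against
itself. Curvature tolerances (±15% on mean curvature of the R = 10 mm ball
at 1 mm spacing) reflect marching-cubes discretization under this default
noise.

Cohorts draw, per subject × region, a latent factor u ~ N(0,1) entering the
five features with loading 0.6 plus independent noise sd 0.8 (unit total
variance), scaled to loosely realistic per-feature units (e.g. mean
curvature 0.10 ± 0.02 /mm, volume 8000 ± 1200 mm³). Group sizes default to
60 NC / 86 MCI, matching the two-group study design; affected regions
(default: the first 5 of 76) shift every feature of MCI subjects by
`effect_size` (default 3) pooled SDs. Generation is bit-reproducible from
the seed.

**What the synthetic cohort does not show.** It plants a strong, aligned
mean shift with Gaussian, region-independent noise; real cortical features
have spatially correlated, heteroscedastic, demographically confounded
variation and far subtler effect sizes. Passing the end-to-end recovery
checks demonstrates that the pipeline is correct and leak-free, not that
real NC/MCI discrimination reaches any particular accuracy. With the 60/86
imbalance, a signal-free (label-permuted) run drifts toward the majority
rate (≈59%), which still lies inside the binomial 99% band around chance
used by the null check.

## Problem sizes and known limitations

The test suite and the acceptance script use a 64³ ball phantom
(~1,900 vertices), the 146-subject × 76-region cohort for the 10-fold
evaluations, and 20 repeats of a 33-subject × 12-region cohort for the
effect-localization check; the full suite runs in about a minute on one
core. Limitations: no mesh smoothing or topology correction (meshes may
have handles at the voxel scale); curvature estimates degrade below ~8
voxels of feature radius; the sequential fusion discards information
whenever the true joint structure needs d > 1; calibration quality is poor
for regions with near-constant fused features; hemisphere assignment is
delegated entirely to the atlas labels.
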