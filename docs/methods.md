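# Methods

This note documents the models, algorithms and numerical choices behind
`sonocomplete`, in the order the pipeline runs.

## Geometry and units

All coordinates are world millimeters. NIfTI label volumes are converted to
world space through their affine at load time, so metric thresholds (the
5 mm facet tolerance, the 0.5 mm centerline densification step) apply
directly. Per-vertebra meshes are extracted from a label's binary mask by
marching cubes at iso-level 0.5, unsmoothed by default so the ground truth
stays auditable; one optional Laplacian pass is available. Point clouds are
normalized per vertebra by centroid-centering and max-norm unit-sphere
scaling; the ×10⁴ Chamfer reporting scale refers to these normalized
coordinates, which makes values comparable across vertebra sizes.

Because the installed mesh library's spatial-index features (ray queries,
point–surface distance, containment) require an unavailable extra, the
package carries its own vectorized geometric kernels: Möller–Trumbore
ray–triangle intersection with an axis-aligned-bounding-box prefilter and
chunking, Eberly-style point–triangle distance, and even-odd containment.
The test suite checks the ray caster against a separate, deliberately
slower per-ray/per-face plane-intersection oracle.

## Synthetic vertebrae and spines

The fixture generator exists so the whole pipeline is testable without any
external CT dataset. A vertebra is the implicit union (pointwise minimum)
of analytic signed-distance primitives — an ellipsoidal body (default
semi-axes 17 × 13 × 11 mm), a torus arch around an 8 mm spinal canal, a
caudally angled tapered spinous process (28 mm, 30°), two lateral
transverse processes (22 mm) and four articular prominences rooted on the
arch — sampled on a grid (default 2 mm) that is mirror-symmetric about the
sagittal plane, then iso-surfaced at zero. This guarantees a single
connected watertight component, bit-exact determinism under a fixed seed,
and sagittal symmetry up to the float32 resolution of the iso-surfacer
(≈3 µm at this scale). Optional low-frequency jitter (a sum of four seeded
sinusoidal displacement fields, amplitude in mm) breaks the symmetry the
way real anatomy does. The vertebrae are stylized: what matters for this
pipeline is the topological layout ultrasound exploits — an occludable
anterior body beneath a posterior arch — not anatomical accuracy.

Spines stack five levels (4 mm gaps) along a circular sagittal arc (default
total 15°). Landmark ground truth — the spinous-process dorsal crest
polyline and the four articular-prominence centers per level — is emitted
at construction time rather than re-detected, removing annotation ambiguity
from evaluation. An adjacent-pair containment check rejects placements with
interpenetrating vertebrae.

## Curvature reposing

Patient posture changes lumbar curvature (sitting flexes and opens the
interlaminar space; prone mildly extends). Each curvature sample draws one
sagittal rotation per intervertebral joint from a truncated normal inside a
physiological limit (default ±10°; sitting biased to +limit/3, prone to
−limit/6). Every vertebra then receives a single rigid transform: the
composition of the rotations of the joints cranial to it, each about the
left-right axis through its joint pivot (midpoint of the adjacent body
centroids). Rigidity is exact by construction. The deformed spine carries
its moved pivots as provenance; reusing them makes deformation by a sample
followed by its negation an exact inverse (for sagittal-only rotations,
which share an axis direction — the opt-in axial/coronal jitter does not
have that property). Interpenetration after reposing raises an error and
the caller resamples.

## Ultrasound-consistent occlusion

Virtual probes are posed 60 mm posterior to each spinous-process apex (the
most posterior vertex of the level), looking anteriorly; a transverse sweep
can interpolate additional poses at a fixed step. Each pose casts a
rectangular angular fan (default 64 × 64 rays over 60°, approximating a
curvilinear footprint). Three physical effects are modeled:

* **Acoustic shadowing** — only the first intersection along each ray
  across the whole scene survives.
* **Grazing incidence** — a hit is kept only if the angle between the ray
  and the inward surface normal is below a threshold, default 90° (the
  grazing cut); tightening the threshold monotonically shrinks the kept
  set.
* **Scattering** — the scene is duplicated and translated by ±2 mm (both
  copies in one pass) perpendicular to the view direction in the transverse
  direction; an original-surface hit survives only when no shifted copy
  intersects the ray closer to the probe. With zero shift this reduces
  exactly to plain ray casting, and its output is always a subset of it.

Hits are masked per source vertebra; neighboring-cloud fusion then donates
`round(fraction × |neighbor|)` points (default fraction 0.15) from each
directly adjacent view, preferentially from the 25 % of the neighbor's
cranio-caudal extent nearest the shared boundary. Donated points keep their
true level labels so ground-truth pairing stays clean. Each surviving view
is paired with a ground-truth cloud uniformly area-sampled from the
complete vertebra surface; both clouds share the ground truth's
normalization, the partial is clipped to the unit sphere + 10 % (dropping
fused points that fall outside, counted in the manifest) and resampled to a
fixed cardinality (farthest-point subsample when too many points,
seeded duplicate-padding when too few; defaults 2048/2048). A JSON-lines
manifest records every parameter and derived seed; replaying it reproduces
byte-identical pairs.

## Completion network

The model is a dual-path variational architecture realized at configurable
width (the exact reference block structure is not reproduced layer for
layer):

* **Encoders.** A shared per-point MLP (3→64→128→`feature_dim`) followed by
  max-pooling gives a permutation-invariant global feature. Linear heads
  map it to the mean and log-variance (clamped to [−10, 10]) of a diagonal
  Gaussian: the *prior* from the partial cloud, the *posterior* from the
  complete cloud (a separate encoder, used only in training).
* **Coarse decoder.** `[latent ‖ global feature]` → MLP → `n_coarse` × 3,
  with a scaled tanh keeping outputs inside the normalized ball.
* **Refinement.** The partial and coarse clouds are concatenated; a fixed
  strided subset of `n_out` points is carried forward. Per-point features
  feed dot-product self-attention restricted to k-nearest neighborhoods at
  several scales (defaults 8 and 16), concatenated with the point, its
  feature and a tiled global feature, and an MLP predicts a residual offset
  (bounded by tanh·0.5). The residual form is what preserves observed
  input detail.
* **Loss.** `kl_weight · KL(posterior‖prior) + CD(coarse, gt) + CD(fine, gt)`
  with squared-distance Chamfer terms (no ×10⁴ scale inside the loss).
  `kl_weight` defaults to 0.5 with a linear warm-up over the first 10 % of
  epochs to avoid posterior collapse. The latent is sampled from the
  posterior by reparameterization during training; **inference decodes the
  prior mean** — a MAP point estimate, so completion is deterministic.

Training uses Adam (paper-scale default learning rate 10⁻⁴, batch 8,
100 epochs) with a subject-level 60/20/20 split: all pairs from one source
spine land in a single split, and every split keeps at least one subject.
The best-validation parameters are checkpointed. Everything is seeded; two
runs with the same seed produce identical loss histories.

The network runs on a small reverse-mode autodiff engine written on numpy
(`_autodiff.py`) — broadcasted arithmetic, matmul, standard
nonlinearities, axis reductions, gathers, softmax, and a Chamfer node whose
nearest-neighbor correspondence is held fixed in the backward pass (the
argmin is piecewise constant in the points). Its gradients are verified
against finite differences in the test suite. Two presets exist: `paper`
(2048-point clouds, feature 1024, latent 64) and `smoke` (256 points,
feature 64, latent 16, 30 epochs) for desk-scale work; the pipeline syncs
cloud cardinalities to the generated data.

## Metrics

* **Chamfer distance**: mean of squared Euclidean nearest-neighbor
  distances in each direction, summed over the two directions, ×10⁴ on
  normalized clouds (the completion-benchmark convention). Squared vs
  unsquared and the reporting scale are configurable.
* **EMD**: mean transport cost of the exact optimal one-to-one assignment
  (Hungarian solve), exact up to 4096 points; larger clouds are
  farthest-point subsampled with the approximation flagged by a warning.
* **F1**: precision/recall at a distance threshold, default 1 % of the
  ground-truth bounding-box diagonal. At desk-scale cloud densities
  (≈128–256 points per vertebra) that default sits below the mean sampling
  spacing and even a perfect completion scores near zero, so the
  scaled-down pipeline configurations use an absolute threshold of 0.1 in
  normalized units (≈10 % of the vertebra radius) instead.
* **SP-CD**: the Chamfer convention applied to spinous-process centerline
  polylines densified to ≤0.5 mm spacing. On fixture data the centerlines
  are annotated automatically: each ground-truth crest vertex is replaced
  by the centroid of cloud points within an adaptive radius (three median
  nearest-neighbor spacings, floor 4 mm); vertices without support are
  dropped, and the metric is reported only when both the input and the
  completion yield at least two distinct annotation points. Anatomy
  metrics are computed only for neutral-posture pairs, since the landmark
  table describes the undeformed spine.
* **Facet distance**: Euclidean error of a facet-joint center in mm; a
  level's pair is "acceptable" when the mean of its left and right errors
  is within 5 mm, the cited tolerance for a successful anesthetic effect.
  On fixtures the predicted center is the centroid of completion points
  within 6 mm of the ground-truth center (≥5 points required).

Aggregation (`summarize`) emits per-item rows plus mean/median rows over
non-missing entries. One convention inherited from the published per-level
table: the overall facet mean is printed truncated (not rounded) to two
decimals.

## Pipeline and post-processing

`run_pipeline` chains fixtures → gen-data → train → complete → evaluate →
reconstruct into a run directory holding the serialized configuration, a
library-version stamp, the data manifest, checkpoints, clouds, the metric
CSV and logs. Identical configuration and seed reproduce byte-identical
manifests and CSVs. A failing stage halts the run with the stage named and
keeps partial outputs.

Normals for meshing are estimated from k-NN PCA plane fits (k = 16), made
globally consistent by flipping along a breadth-first traversal of the k-NN
graph and orienting each component toward a reference point — the
acquisition camera when provenance exists, else the cloud centroid pushed
posteriorly. Poisson reconstruction splats the inward normal field onto a
regular grid of side `2^depth` (default 7; 5–6 for desk-scale clouds),
smooths it (Gaussian, 1.5 voxels), solves ∇²χ = ∇·V spectrally with DCT
(Neumann boundaries), extracts the iso-surface at the mean indicator value
over the input samples, trims to the input bounding box inflated 10 % and
keeps the largest connected component. On 5000 oriented sphere samples the
median radial error is ≈0.2 %.

## Desk-scale problem sizes

The shipped test suite and acceptance script run everything at reduced
sizes chosen as this package's own desk-verification conditions: fixture
grids of 2.5–3 mm, 24–32² ray fans, 128–256-point clouds, the smoke model
preset, and 3–5 synthetic spines with 2–3 curvature samples. The smoke
learning benchmark — 200 sphere-with-cap-removed pairs, 30 epochs — checks
that the variational machinery learns at all (held-out completion-vs-
identity Chamfer ratio ≈0.2) rather than that it reaches clinical quality.

## What the synthetic data does and does not show

The generator reproduces the *geometry* of ultrasound visibility
(posterior-only coverage — under half of the vertebra surface by
construction — shadowing, grazing loss, scatter occlusion, level
bleed-through) but not image-level physics: no speckle, no soft-tissue
echoes, no beamforming artifacts, no segmentation noise beyond the fusion
augmentation. Fixture vertebrae are stylized and share one parametric
family, so desk-scale results demonstrate pipeline correctness and
learnability, not generalization across real anatomical variation; that
requires training on CT-derived meshes (e.g. a public vertebra
segmentation corpus) at the paper-scale preset.

## Known limitations

* The refinement stage's strided subset selection ties `n_out` to the
  concatenated cloud size rather than learning which points to keep.
* EMD above 4096 points is subsampled, not solved with an ε-solver.
* The scatter model uses a single fixed lateral shift magnitude; real
  scattering is frequency- and depth-dependent.
* Automatic centerline/facet annotation on sparse clouds can fail to find
  support; the metrics are then reported as missing rather than guessed.
* The interpenetration check probes a vertex subsample (300 per mesh), so
  very thin overlaps can escape it.
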