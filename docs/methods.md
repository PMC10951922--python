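# Methods

## Model and procedure

`fibermap` treats a reference population of 2D parametric maps as
realizations of a zero-mean, stationary, isotropic Gaussian random
field (GRF). The model is deliberately minimal — three numbers:

* **σ** — the field's standard deviation (map units),
* **|Λ|** — the determinant of the 2×2 covariance matrix of the
  per-pixel gradient (map units² / pixel²; a roughness measure),
* **S** — the image area in pixels.

Learning averages per-map estimates of σ, |Λ| and S arithmetically over
the training maps. A single training map is allowed; both built-in
synthetic experiments learn from one reference realization, and with k
identical maps the model equals the single-map estimate.

Testing thresholds a (gaussianized) map at each configured level t,
extracts 8-connected components — including single-pixel ones — and
assigns each component two null probabilities: the expected-cluster-count
ratio for its intensity peak and the exponential extent law for its
pixel count. Both laws derive from the expected Euler characteristic of
the excursion set and are asymptotic in t; the detection layer therefore
refuses thresholds below σ (with a warning) and the recommended working
range is t ≥ 2σ.

### Assumptions

* Stationarity and isotropy of the reference field. Maps with strong
  global gradients (uneven illumination, vignetting) violate this and
  should be flattened upstream.
* Only the first-order marginal is gaussianized. The transform fixes
  the intensity histogram but not the spatial dependence structure;
  smooth maps (built here with ≥5 px smoothing kernels) are close
  enough to Gaussian in their joint structure for the cluster laws to
  calibrate well (verified by Monte Carlo, below).
* Per-cluster inference at a fixed p-value. No family-wise correction
  across thresholds or images is applied; counts of significant
  clusters are descriptive statistics to be compared between groups.

## Gaussianization

The 1-D optimal transport map between an empirical histogram and a
Gaussian is the monotone quantile map: the pixel of rank i (stable
sort; ties keep array order) is sent to Φ⁻¹((i−0.5)/N), rescaled to
zero mean and **exactly** the input's sample variance. Rescaling to the
empirical variance of the input rather than to the ideal grid variance
makes the transform exactly idempotent (a second application reproduces
the same values bit-for-bit up to floating point) while staying within
1% of the ideal normal quantiles at any realistic image size. Constant
maps have no transport map and are rejected.

## Gradient estimator

σ is the sample standard deviation over all pixels; the gradient
covariance is estimated from **one-pixel forward increments** on
interior pixels (the one-pixel border is excluded). The increment
stencil matters: cluster counts of the *sampled* field respond to the
roughness at the lattice scale, and a central-difference stencil
(2-pixel spacing) low-passes the field enough to under-predict the
empirical cluster count by ~3–4% on the reference conditions — a
systematic error several Monte-Carlo standard errors wide. With
unit-lattice increments, over 100 unit-variance realizations
(512×512, 3-px kernel, t = 2.5σ) the empirical mean cluster count and
mean cluster extent agree with the closed forms within 3 standard
errors, and the extent distribution is within Kolmogorov–Smirnov
distance 0.06 of the exponential law.

Degenerate fields (constant, pure ramps) have singular gradient
covariance and raise `FlatFieldError`.

## Whether to gaussianize a test image

Two protocols are exposed:

* **Parametric maps** (fiber length, pore directionality): each test
  map is gaussianized to its own empirical variance and tested against
  the averaged training σ. This is the default for real maps, whose
  native histograms are far from Gaussian. Note the consequence: a map
  containing anomalies has an inflated empirical variance, which
  *raises* its gaussianized values relative to the learned σ — anomaly
  contrast survives the transform through the variance, not through
  the (rank-capped) quantiles.
* **Fields that are already Gaussian plus additive anomalies** (the
  GRF + ellipse experiment): the scene is analyzed directly. The clean
  field is a fixed point of gaussianization, and rank-transforming the
  anomalous copy would cap every anomaly peak at the image's extreme
  quantile — with six objects present, the sixth-strongest peak can
  never rank much above ~3σ regardless of its true intensity, putting
  a hard floor under its peak probability. The
  `gaussianize_test` switch selects between the protocols.

## Detection parameters

| parameter | default | rationale |
|---|---|---|
| p-value | 0.05 | conventional per-cluster significance level |
| thresholds (GRF scene) | (2, 3, 4)σ | spans the asymptotic regime up to near the field maximum |
| thresholds (fiber maps) | (2.0, 2.75, 3.5)σ | same span; the joint pair keeps the 4:7 low/high ratio |
| joint rule (GRF scene) | surface @ 2σ ∩ intensity @ 4σ | foreign objects are extended at low t *and* sharply peaked at high t; background clusters rarely both |
| joint rule (fiber maps) | surface @ 2.0σ ∩ intensity @ 3.5σ | as above; thresholds are expressed in learned-σ units so the rule transfers across map scales |
| "non-null intersection" | ≥ 1 shared pixel | literal reading; higher-threshold clusters nest inside lower-threshold ones |

Selected regions for scoring are the union of qualifying clusters,
re-labeled as connected components; per-threshold cluster tables are
also retained.

## Fiber graphs and parametric maps

* **Gabor bank**: 8 orientations × wavelengths (4, 8, 16) px, kernel
  bandwidth 1 octave, per-pixel maximum response magnitude. The bank
  parameters are implementation defaults (fully configurable), not
  values inherited from any particular instrument.
* **Binarization**: Otsu by default; absolute override available.
* **Skeleton**: morphological thinning followed by removal of residual
  2×2 blocks via simple-point deletion, guaranteeing a strictly
  1-px-wide skeleton. Nodes are skeleton pixels with ≠2 neighbors
  (1 → endpoint, ≥3 → crosslink); adjacent junction pixels merge into
  one node at their centroid; crosslinks joined by paths shorter than
  3 px are contracted (rasterized junctions often split). Geodesic edge
  length counts axial steps as 1 and diagonal steps as √2, plus the
  centroid-to-path-end offsets, and is clamped from below by the chord
  so the metric inequality (chord ≤ geodesic) always holds. Spurs
  shorter than 5 px are pruned once — enough to remove thinning
  artifacts without deleting short genuine fibers at ~0.27 µm/px.
* **Fiber length map**: chords of the simplified graph are rasterized
  with integer line drawing; overlapping chords keep the **maximum**
  length (longer fibers are the anomaly direction of interest, so their
  signal must not be overwritten); unassigned pixels take the value of
  the nearest assigned pixel (Euclidean distance transform); Gaussian
  smoothing with σ = 5 px.
* **Pore directionality map**: pores are 4-connected background
  components not touching the border; orientation θ ∈ [0°, 180°) from
  second-order central moments (angles measured counterclockwise from
  the +x/column axis with y up); the circular median orientation
  (minimizing summed folded deviations, ties → lower angle) is
  subtracted to remove global rotation; differences are folded into
  [0°, 90°]; the score is 1/(ε + Δ) with **ε = 1°**, since the
  unregularized inverse diverges at Δ = 0 — the score is therefore
  capped at 1. Near-circular pores (axis ratio < 1.05) keep their
  fitted angle but are flagged orientation-unreliable. Smoothing σ =
  5 px.

## Synthetic data

The generators define the study conditions; their defaults are fixed
and the tests run against them.

* **GRF**: white noise smoothed with an isotropic Gaussian kernel
  (width 3 px), periodic boundaries (exactly stationary), sample mean
  removed and sample SD set exactly to the target. 512×512 frames.
* **Ellipse anomalies**: six mutually disjoint ellipses (3-px
  separation), semi-axes a ∈ [8, 18], b ∈ [5, 10] px (areas ≈ 126–565
  px), random orientations, added intensities evenly spaced over
  (4.0–8.0)σ with the largest area paired to the lowest intensity — so
  detectability is spread between the extent criterion (large, faint)
  and the peak criterion (small, bright), and every object is
  individually significant under both criteria of the joint rule.
* **Fiber networks**: offset lattice (rows d·√3/2 apart, odd rows
  shifted d/2), uniform jitter of amplitude d/4 per coordinate,
  Delaunay triangulation, edges rendered as 1-px lines; a margin of two
  lattice spacings beyond the frame prevents artificial long border
  edges (edges with an endpoint in the margin are dropped). Defaults:
  1024×1024, d_normal = 16 px, d_defect = 28 px inside three disjoint
  elliptical defect regions (fixed canonical layout, scaled to the
  frame). The generating graph is retained as ground truth;
  re-extraction from the rendered image reproduces its node and edge
  counts within 10%.

What the generators do **not** emulate: fiber width and intensity
variation, imaging noise and point-spread blur, fiber curvature and
waviness, and the density/anisotropy correlations of real matrices.
Passing tests demonstrate the statistical machinery and the geometric
pipeline, not biological realism; on real confocal data the Gabor
enhancement and binarization steps carry the burden the simulators
skip.

## Problem sizes

The built-in experiments use 512×512 GRF scenes (20 replicates),
1024×1024 fiber scenes (20 replicates), and 100 realizations for the
Monte-Carlo calibration — sizes at which the sampling error of every
reported statistic is comfortably below the effect sizes being checked.

## Known limitations

* 2D only; no 3D random-field theory.
* The exponential extent law and the EC cluster-count formula are
  asymptotic in t; below ~2σ both drift from the empirical behavior.
* Crosslinks from genuine junctions and from 2D projection of crossing
  fibers are indistinguishable.
* Heavier fiber post-processing (reconnection across gaps, curvature-
  aware pruning) is out of scope; only minimal spur pruning is applied.
* The per-cluster p-value is not corrected for multiplicity across
  thresholds or images.
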