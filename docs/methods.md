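# Methods

This note records the model behind each stage, the defaults that
matter, the numerical conventions, and what the synthetic experiment
does and does not establish.

## Synthetic plate model

The simulator generates the statistical structure the analysis relies
on; it is not a photorealistic optics model.

**Cell states.** Each cell has a phase (G1, early S, S/G2/M, double
negative, or apoptotic) and a DNA content in N-genome equivalents:
exactly 2 in G1, uniform on [2, 2.5] in early S, uniform on [2.5, 4] in
S/G2/M. Double-negative nuclei (Fucci-dark, around late M/early G1)
are drawn uniform on [2, 4] — their content distribution is not
characterized experimentally, and leaving it broad makes the DN class
deliberately hard. A condition preset holds the (G1, earlyS, SG2M, DN)
mix among viable cells and an apoptotic fraction; the built-in presets
are qualitative translations of the expected pharmacology (S/G2/M
accumulation under 5-FU/SN-38 in HeLa, G1 arrest under ZSTK474 in MCF7,
heavy apoptosis under staurosporine), with the exact fractions free
config parameters.

**Rendering.** Fields default to 512 × 512 px, 16-bit, 0.66 µm/px,
~100 nuclei placed by dart throwing without overlap — nucleus
equivalent diameters then fall in the 15–25 px range expected of a 10×
high-content acquisition. A viable nucleus is an ellipse (axis ratio
≤ 1.35) whose truth-mask area is `230 px² · (content/2)^(2/3)` — volume
proportional to DNA content, projected area to volume^(2/3) — and whose
integrated DNA intensity is `340 000 counts · content/2`, each times a
log-normal nuisance factor (σ = 0.08 area, σ = 0.10 staining).
Chromatin texture is unit-variance band-passed Gaussian noise
multiplied onto a flat-top radial profile, with grain that coarsens
with DNA content (σ = content/2 px, i.e. 1 px at 2N to 2 px at 4N,
emulating progressive chromatin condensation), so texture features
carry cycle signal through the same latent variable as intensity and
area — S/G2/M nuclei have coarser grain than G1 as a consequence, not
by construction from the class label. Fucci
channels are filled flat over the footprint with a per-nucleus target
mean drawn log-uniform in a band at least 30% away from the gating
threshold on the correct side, then multiplied by log-normal reporter
noise (σ = 0.15), which yields roughly 2% of nuclei crossing a
threshold — a controllable label-noise floor. Apoptotic nuclei are 3–6
bright Gaussian fragments inside one footprint with hard dark gaps, so
the footprint CV exceeds the 70% exclusion cutoff; both Fucci channels
are dark. Per channel, the renderer adds a smooth parabolic
illumination background (DNA: base 40 + amplitude 80 counts; Fucci:
4 + 8 — the Fucci channels must stay near-dark because the MCF7 gate
sits at 150/300 counts), Poisson shot noise, and Gaussian read noise
(σ = 3). All randomness flows from one `numpy` generator, so output is
byte-identical per seed.

**What the simulator omits:** PSF convolution beyond implicit pixel
averaging, cytoplasm and bright-field signal, spectral crosstalk
between channels, cell clumping and overlap, focus drift, real
chromatin substructure (nucleoli, condensation patterns), and
time-lapse dynamics. Consequently the classifiers' accuracies here are
*optimistic*: passing tests shows the pipeline is correct and the
method sound under its own assumptions, not that these accuracies
transfer to real images.

## Background correction and segmentation

The sliding-parabola filter estimates background as the grey-scale
opening with the paraboloid `b(u,v) = -c(u²+v²)` and subtracts it.
Parabolic structuring functions are separable, so each erosion/dilation
is an exact 1-D quadratic lower-envelope transform per row then column
(O(n) per line, effectively unbounded support; a numba kernel with a
pure-Python fallback). Default curvature c = 0.005 counts/px²: it must
exceed the illumination background's curvature (~0.002 for an 80-count
bow across 512 px) while staying small enough that a 20-px nucleus is
not absorbed (the estimate under a nucleus rises by at most
c·r² ≈ 0.7 counts). The operator is idempotent to < 1 count on
noise-free fields; under shot noise a second pass removes a few more
counts of residual noise floor — unavoidable for any morphological
background estimator.

Nucleus finding: Gaussian smoothing (σ = 2 px) → global Otsu →
hole filling → distance-transform watershed seeded at distance peaks
(min separation 7 px) → discard objects under 50 px and objects
touching the field border (partial nuclei would distort area and
intensity features). Fucci channel means are measured on the *raw*
channels; only the DNA channel is background-corrected (configurable —
whether the original instrument measured Fucci on filtered images is
unknown).

## The 240-feature catalog

All features are computed from the background-corrected DNA channel
over the ROI mask. The catalog (order, names, families) is frozen:
9 intensity + 4 morphology + 16 SER + 4 Haralick + 23 × 9 STAR = 240.

* **Intensity (9):** mean, population SD, median, max, min, sum,
  CV = 100·SD/mean (%), quantile-50% (= median, kept as its own catalog
  slot), Michelson contrast (max−min)/(max+min). Conventions: CV = 0
  when the mean is 0; contrast = 0 when max+min = 0.
* **Morphology (4):** area (px count × pixel size²), roundness
  4π·area/perimeter² clipped to [0, 1] with the 4-direction Crofton
  perimeter (the naive boundary-step perimeter overestimates digital
  circles enough to push a disc's roundness below 0.92), and
  width/length as minor/major axis lengths of the mask's second-moment
  ellipse. Single-pixel masks: width = length = pixel size,
  roundness 1.
* **SER (8 filters × 2 scales):** from the scale-normalized Hessian
  eigenvalues λ₁ ≤ λ₂ of the Gaussian-smoothed image (σ = 1, 2 px),
  the scale-normalized gradient magnitude, and a 4σ coarse background:
  spot √(λ₁⁻λ₂⁻), hole √(λ₁⁺λ₂⁺), ridge λ₁⁻−λ₂⁻, valley λ₂⁺−λ₁⁺,
  saddle √(λ₁⁻λ₂⁺), edge = |∇|, bright/dark = positive/negative part of
  smooth − coarse (x⁻ = max(0,−x), x⁺ = max(0,x)). Per ROI the feature
  is mean(response²)/mean(intensity)², making texture energy invariant
  to staining brightness. The image is offset by its minimum before
  differentiation: this cancels the small DC bias of the discrete
  derivative kernels (a constant image yields exactly zero) and, unlike
  a mean offset, is invariant to pixel permutation, preserving exact
  translation equivariance.
* **Haralick (4):** ROI pixels quantized to 32 levels between ROI min
  and max; symmetric co-occurrence matrix at distance 1 over the four
  directed axial neighbours, restricted to pixel pairs both inside the
  ROI, normalized to sum 1; contrast, correlation, homogeneity (inverse
  difference moment), and sum variance (variance of i+j about the sum
  average). Constant ROI → (0, 0, 1, 0).
* **STAR (23 per variant × 9 variants):** intensity-weighted shape
  descriptors about the intensity-weighted centroid — symmetry
  harmonics k = 1..8, threshold compactness at 30–70% of max (set area
  ÷ convex-hull pixel area, computed with Qhull plus Pick's theorem and
  capped at 1), axial √λmin/√λmax/anisotropy/ratio of the weighted
  second-moment matrix, radial mean / relative deviation / mean
  normalized by equivalent radius / inner-intensity fraction, and two
  profile features (correlation of intensity with border distance;
  outer-band to interior mean-intensity ratio, band = lowest 25% of the
  border-distance range). Variants: the raw DNA channel and each σ = 1
  SER response ("Nucleus Radial Mean SER-Edge" etc.). A pixel at
  numerically zero radius has no defined direction and is excluded from
  the harmonic numerators (kept in the normalizing total); this is what
  keeps the symmetry features exactly invariant under rigid motions.
  Degenerate conventions (≤ 2-pixel threshold sets → compactness 1,
  zero-total-intensity ROIs → zeros, constant profiles → correlation 0)
  guarantee a finite 240-vector for every mask of ≥ 1 pixel.

## Gating and dataset construction

Thresholds on the Fucci channel means (inclusive on ≥): HeLa red 700 /
green 2500; MCF7 red 150 / green 300 (camera counts). Red-only → G1,
both → early S, green-only → S/G2/M, neither → DN; the plane is
partitioned exhaustively. Apoptotic exclusion drops nuclei with DNA
CV strictly above 70%, before sampling; it is enabled by default only
for MCF7 (whose cultures carry heavy dead-cell contamination), matching
the original protocol. Training (7500) and validation (2500) rows are
a uniform disjoint random sample, not stratified. Min–max bounds are
fitted on the training rows only and applied to validation with
clipping to [0, 1] (fitting on all rows is available by config but
leaks validation information); constant features map to 0.

## Models

Five families per one-vs-rest task, conventional defaults, all
configurable: plain logistic regression (unpenalized, lbfgs); backward
stepwise logistic regression; RBF SVM (C = 1, kernel width 1/(p·var));
random forest (500 trees by default, 100 at pipeline desk scale,
√p features per split); feed-forward network with exactly three hidden
layers (128/64/32, ReLU, early stopping on a 10% internal holdout —
automatically disabled below 1000 samples, where a 10% holdout is
noise). Backward stepwise uses the classic Wald-ordered scheme: drop
the smallest-|z| coefficient, refit, keep the drop only while AIC
improves. An exhaustive best-single-drop search would need O(p²) ≈ 29k
logistic fits at p = 240; the Wald ordering needs one fit per step and
recovers planted signal sets reliably.

Cross-validation: 10 folds, shuffled once per seed, non-stratified,
accuracy at probability cutoff 0.5; selection by mean CV accuracy, ties
broken by higher minimum fold accuracy then fixed family order.
In the default pipeline the SVM, stepwise and neural-net families are
cross-validated on a seeded 2500-row subsample (config `cv_subsample`)
to keep the end-to-end run at desk scale; the selected model's final
fit always uses all 7500 rows. Validation metrics: confusion counts at
cutoff 0.5, sensitivity/specificity with the 0/0 → 0 convention, AUC as
the probability a random positive outscores a random negative (ties ½).
Importance: random-forest mean decrease in impurity, normalized to
sum 1, top 10 reported. The early-S task is trained and reported but
not used downstream — its prevalence (~7%) makes the positive class
hard to detect, and the per-condition reports rely on the G1 and S/G2/M
models only.

## Reporting statistics

The Wilcoxon rank-sum test uses midranks for ties; with ≤ 12 pooled
observations and no ties the two-sided p is exact (enumeration of all
rank assignments), otherwise a normal approximation with tie and
continuity corrections (it matches the asymptotic two-sided
Mann–Whitney p to machine precision). Two-sided p-values throughout.
Per-condition summaries report Fucci class fractions and
predicted-positive fractions for the G1 and S/G2/M models; the original
pie-chart presentation is replaced by a table plus stacked bars — the
information, not the figure style, is the target.

## Reproducibility and problem sizes

One master seed fans out to per-stage seeds via `SeedSequence`, so
stages are independently re-runnable yet jointly reproducible; the run
manifest records config, version, per-stage wall clock and SHA-256 of
every artifact. Default experiment: 6 HeLa presets × 20 fields × ~100
nuclei ≈ 12 000 segmented nuclei, of which 7500/2500 are sampled. The
test suite builds this plate once (a few minutes) and shares it across
tests; statistical properties that would need many full plate builds
(e.g. family-ranking stability across seeds) are checked on subsampled
versions, and the chi-square/goodness-of-fit and recall/precision
checks run at n = 1000–10 000 where the stated tolerances (3 binomial
SDs, α = 0.01) have the intended power.

## Known limitations

* **Residual apoptotic contamination.** The CV > 70% filter removes
  intact fragmented nuclei, but when the watershed splits a fragment
  cluster into compact pieces those pass the filter and gate as DN.
  At the ~30% apoptotic fraction of the staurosporine preset this
  inflates the DN class by several points; at ≤ 10% contamination the
  gated fractions recover the generating distribution within 3 binomial
  SDs. The same failure mode exists in the real assay.
* **Label noise floor.** Reporter noise crosses the gating thresholds
  for ~2% of nuclei by design, so "ground truth" labels are themselves
  noisy — as Fucci gating is in reality. Noise-free renders gate with
  100% agreement.
* **Optimistic accuracy.** DNA content is the simulator's only latent
  phase variable, so intensity-sum separates S/G2/M almost perfectly;
  real chromatin images carry biological variance the simulator does
  not model. Headline accuracies on synthetic data bound what the
  pipeline can do, not what real data would give.
* **Model ranking is generator-dependent.** On real imaging data the
  random forest won the cross-validated comparison; on this simulation
  the RBF SVM edges the forest by a few tenths of a point on the G1
  task at every scale tested, because the synthetic phase signal is a
  smooth function of a single latent variable (DNA content) — ideal
  terrain for a kernel method. The forest remains within a point of
  the best family and clearly above the linear baseline; the selection
  machinery, not the winner's identity, is what the synthetic
  experiment can validate.
* **Importance dilution among content proxies.** Mean-decrease-in-
  impurity importance splits mass across correlated features. Because
  every strong feature in this simulation proxies the single latent
  DNA-content variable (integrated intensity, area, width, the radial
  SER family), their individual ranks are photo-finishes decided by
  their relative noise levels; the *family* of content proxies reliably
  occupies the top of the ranking, individual members trade places.
* **Feature values are re-specifications, not vendor replicas.** The
  SER/STAR formulas implement the feature-family names with standard
  scale-normalized differential geometry; commercial high-content
  analysis suites compute proprietary variants, so absolute feature
  values are not comparable to vendor output — only the pipeline's
  behavior is.
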