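# Methods

This note records the models, conventions and design choices behind
`radfuse`, in the order data flows through the pipeline.

## Synthetic cohort generator

The generator stands in for a clinical mpMRI cohort and defines the
conditions under which every stochastic property of the package is tested.

**Class structure.** Default cohort: 466 lesions — HR+ 336, HEBC 76, TNBC
54 — with a held-out test cohort of 129 (stratified largest-remainder
allocation, giving exactly 337/129). Lesion diameters are lognormal with
class medians 21 / 27 / 26 mm (HR+/HEBC/TNBC) and log-scale sigmas
0.466 / 0.631 / 0.509 derived from the corresponding interquartile ranges.
Margin irregularity (a 0–1 parameter) is normal around 0.45 / 0.33 / 0.30
(sd 0.15): HR+ lesions are the most irregular, matching the
irregular/spiculated margins of slowly growing luminal tumors versus the
rounder, smoother TN/HER-2 lesions.

**Feature mode.** Each (lesion, channel) draws three latent factors —
*level* (overall intensity), *spread* (dispersion), *smoothness* (texture
correlation) — as `class effect + N(0,1)`. A fixed loading matrix maps the
latents to the 94 intensity/texture features by name (e.g. all `*Entropy`
features load −0.8 on smoothness, dispersion features +0.8 on spread), plus
idiosyncratic noise (sd 0.6) and a deterministic per-feature loading jitter
so no two columns coincide. Morphology features are synthesized from
diameter and irregularity with the package's own identities intact
(Sphericity × SphericalDisproportion = 1, Compactness2 = Sphericity³) and
are identical across channels, as they are after co-registration.

**Effect layout.** The class/channel effect table is the scientific core of
the generator: ADC carries the strongest TNBC signal (level −0.6, spread
−0.7, smoothness +0.8, i.e. darker, narrower, smoother — hence lower
intensity entropy and lower mean absolute deviation than non-TNBC), T2WI
and DWI600 carry complementary, independently noised TNBC signal, DWI600 /
DWI800 / DCE5 separate HR− from HR+, and DCE2 adds TNBC-vs-HEBC contrast.
Because each channel's latent noise is independent, fusing channels averages
noise and must outperform any single channel — the generator is built so
that multi-sequence fusion has a real target, with enough noise that the
advantage is statistical, not trivial.

**Image mode.** Masks are superellipsoids (exponent 2.5, axis ratios
1 : 0.8 : 0.65) with a radial Gaussian-random-field boundary perturbation
whose amplitude scales with irregularity; measured maximum 3D diameters are
unbiased for the drawn diameter to ~3 %. Channel volumes are Gaussian
random fields whose correlation length, amplitude and in-mask contrast
follow the same three latents; smoothness additionally stretches the field's
tails (power transform of exponent `1 + 0.8·smoothness`) so that the
fixed-bin-count discretized histogram becomes more peaked — this is what
carries the entropy direction through the actual extraction path, since
fixed-bin-count discretization over the in-mask range is scale-invariant.
Not modeled: DICOM metadata, registration error, coil inhomogeneity,
non-mass enhancement, or any real anatomy. Passing tests therefore show the
*pipeline* behaves as specified under a controlled signal layout; they say
nothing about classification performance on real patients.

**Rater pairs.** A second-rater mask is derived by adding a unit-variance
smooth field, scaled by the perturbation in mm, to the signed Euclidean
distance of the boundary. Zero perturbation returns the identical mask; a
perturbation of at least twice the lesion inradius is rejected as no longer
a plausible delineation.

All randomness flows from one integer seed through `numpy.SeedSequence`
sub-streams keyed per lesion, channel and stage, so per-class outputs are
reproducible independently of the rest of the cohort.

## Preprocessing and feature extraction

Volumes are resampled to 1.096 × 1.096 × 1.2 mm (trilinear; nearest for
masks; output shape `ceil(extent/spacing)` with half-voxel-center
alignment), then min–max normalized to 0–255 over the whole volume
(constant volumes map to 127.5). Texture features discretize in-mask
intensities to 32 gray levels by fixed bin count; upper-edge values go to
the last bin, constant regions to bin 1.

The default registry has 109 features: 19 first-order, 15 morphology, 75
texture (24 direction-averaged GLCM + 14 GLCM direction-variance variants +
16 GLRLM + 16 GLSZM + 5 NGTDM). The direction-variance variants quantify
texture anisotropy and complete the texture family at the documented count;
membership is configurable. Conventions that change numbers and are
therefore fixed and tested:

* GLCM/GLRLM statistics aggregate over the 13 unique 3D directions at
  distance 1 (GLCM symmetrically); gray-level zones use 26-connectivity.
* Surface area uses the voxel-face convention, so a cube's sphericity is
  `(36π)^{1/3}/6 ≈ 0.806` exactly.
* Axis lengths are `4·sqrt(eigenvalue)` of the voxel-coordinate covariance;
  percentiles interpolate linearly; kurtosis is not excess-corrected;
  skewness/kurtosis of a constant region are 0.
* Morphology is computed once per lesion from the mask and repeated per
  channel.

Degenerate inputs (mask under 2 voxels, mask lost in resampling, non-finite
features) raise errors naming the lesion rather than propagating NaN.

## Reliability filter

ICC from the two-way ANOVA mean-squares decomposition; the default form is
ICC(2,1) (two-way random effects, absolute agreement, single rater) so a
systematic delineation bias between raters lowers agreement; ICC(3,1) is
available. Features are retained when ICC > 0.75 (strict), with the single
exception that an ICC of exactly 1 (bit-identical columns) always passes,
which keeps a threshold of exactly 1.0 meaningful. Zero-variance features
have undefined ICC and are dropped. ICC is computed per sequence by
default; pooling across sequences is a caller decision.

## Selector bank

Fifteen selectors behind one deterministic interface (`run_selector`), all
scoring features and returning the top-k with ties broken toward the lower
index. Scale-sensitive members standardize internally. The three fully
specified methods:

* **trace_ratio** — maximizes `Σa_j / Σb_j` over k-subsets (a/b = between-/
  within-class scatter diagonals) by the lambda iteration
  (`score_j = a_j − λ b_j`, `λ ← Σa/Σb`, tolerance 1e-8, ≤100 iterations).
  The λ sequence is monotone non-decreasing and the fixed point is the
  global subset optimum, verified against exhaustive search in tests.
* **MCFS** — heat-kernel 5-NN graph (bandwidth = median pairwise distance),
  bottom non-trivial eigenvectors of the normalized Laplacian as a spectral
  embedding, least-angle (L1) regression of each eigenvector on the
  features stopping at k active, score = max |coefficient|. A disconnected
  graph falls back to centered component indicators plus component-wise
  eigenvectors (with a warning) — the indicators *are* the cluster
  structure a disconnected graph encodes. Note the standard L1 caveat:
  strongly redundant informative features may not all enter the path.
* **UDFS** — minimizes `tr(WᵀMW) + γ‖W‖₂,₁` over orthonormal W, with M the
  local total-scatter matrix accumulated over 5-NN neighborhoods, solved by
  iteratively reweighted eigendecomposition (2 components, tolerance 1e-6,
  ≤200 iterations, monotone surrogate objective); features scored by row
  norms of W. Because W stays orthonormal, an extreme γ equalizes rather
  than annihilates row norms; selection then degenerates to index order
  through the tie-break.

The remaining twelve are standard filter/embedded/wrapper members
(variance, Fisher score, t-score, Gini stump gain, ReliefF, mRMR
(F-relevance − mean |correlation| redundancy), Laplacian score, SPEC,
chi-square on min–max scaled features, CFS-style merit search, L1-logistic
coefficients, RFE on logistic regression); the bank is configuration-driven
and replaceable.

## Fusion

Two strategies, both fitted exclusively on training rows with per-view
standardization statistics stored in the transform:

* **featurewise** (default): per feature, whiten the S×S between-class
  scatter of the cross-view value vector and keep the top c−1 eigen
  directions (eigenvalues below 1e-10 of the maximum truncated; eigenvector
  signs fixed by largest-magnitude component). Binary tasks map S values →
  1 fused value per feature, so the fused matrix keeps the registry width.
  The fused training between-class scatter is the identity by construction.
* **viewlevel**: per-view between-class whitening to ≤ c−1 dimensions, then
  SVD alignment of cross-view covariance per view pair, folded in
  sequentially in the caller's order (descending single-view AUC rank;
  pairwise fusion is order-dependent) with sum or concatenation.

Identical classes raise a named error (zero between-class scatter).
Transforms serialize to JSON.

## Model bank, cross-validation and comparison

Ten classifiers (logistic regression — the mandatory member — LDA, 5-NN,
Gaussian naive Bayes, decision tree, random forest of 60 trees, linear and
RBF SVM, 50 gradient-boosted stumps, ridge), all with fixed defaults and
seeded where stochastic; 15 × 10 = 150 base models. Classifiers without
`predict_proba` contribute a logistic squashing of their decision function;
AUC is rank-based and unaffected, and the 0.5 threshold coincides with the
0 decision boundary.

Stratified ten-fold CV is the default; standardization, feature selection
and fusion are all fit inside each training fold. AUC uses the Mann-Whitney
rank statistic with midrank ties (identical to the all-pairs statistic);
ACC/SEN/SPE threshold at 0.5 against the stated positive class (HR− for
HR+ vs HR−, TNBC otherwise). Per-fold means are the primary aggregate; the
pooled-prediction AUC is also reported. Every argmax breaks ties by AUC,
then ACC, then identifier, so reruns are bit-stable.

The paired Wilcoxon signed-rank test drops zero differences, uses midranks,
computes the exact two-sided null for n ≤ 25 by convolution over doubled
rank sums (identical to enumerating all 2ⁿ sign assignments) and a
tie-corrected normal approximation above; all-zero differences give p = 1.
Model comparisons pair per-fold AUCs over matched folds; the end-to-end
Rss-vs-R_FF comparison uses 3 × 10 repeated stratified folds, since 10
pairs alone bound the attainable two-sided p at 1/512.

## Problem sizes and tolerances

Texture oracles run on random 8×8×8 volumes (1e-10 relative agreement);
fusion whitening is checked to 1e-6; the fusion-benefit property is
measured on 20 independent full-size (466-lesion, 4-channel) cohorts with a
reduced bank (Fisher score + logistic regression, 5-fold CV), the
end-to-end comparison on one full-size cohort with ten-fold repeated CV.
ICC recovery uses n = 500 pairs (±0.05), the permutation AUC baseline 20
label shuffles (0.5 ± 0.1). These sizes were chosen so the whole suite and
the acceptance script each run in well under a minute on a laptop core
while keeping every stochastic margin wide.

## Known limitations

* The generator's latent-factor feature model produces near-Gaussian
  marginals; real radiomics features are often heavy-tailed and the
  ICC-filter and selector behavior on such data is not exercised.
* The texture-family composition beyond the standard four matrices (the 14
  direction-variance variants) is a documented package choice, as is the
  exact membership of the selector and classifier banks.
* `Maximum2DDiameter*` features use a per-slice definition; other toolkits
  measure in-plane distances on the full surface mesh.
* The viewlevel fusion strategy is implemented and property-tested but the
  pipeline default is featurewise; only the default is exercised end to
  end.
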