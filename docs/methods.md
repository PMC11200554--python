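# Methods

## Model

The encoder/decoder are fully connected networks over flattened 64×64×3
crops in [0,1]: encoder 12288 → 256 → 128 (ReLU) with linear heads for the
posterior mean and log-variance (stddev = exp(½·logvar), guaranteeing
positivity); decoder mirrors it with a sigmoid output. An MLP at this scale
trains in minutes on one CPU while still recovering the image factors the
synthetic cells vary (nucleus size/shape/darkness, hue, brightness); a
convolutional backbone would be the natural upgrade for real micrographs.
Both run on a small internal reverse-mode autodiff engine
(`cytovae.autodiff`) whose gradients are tested against central finite
differences for every composite expression the losses use.

The reconstruction term is a unit-variance Gaussian likelihood on pixels
(squared error plus the Gaussian constant), summed over pixels and averaged
over the batch. A Bernoulli likelihood would also be defensible for [0,1]
intensities; the Gaussian choice keeps the loss interpretable in nats and
matches the continuous-valued synthetic images.

## Objectives

* VAE / β-VAE: closed-form diagonal KL, KL(q‖N(0,I)) =
  Σ_j ½(μ_j² + σ_j² − 1 − log σ_j²), weighted by β (β = 1 recovers the VAE).
* β-TCVAE: the KL decomposes into index-code mutual information, total
  correlation, and dimension-wise KL. The aggregate posterior q(z) and its
  marginals are intractable, so log q(z_i) is estimated from the minibatch
  with stratified importance weights: the sample's own posterior carries
  weight 1/N (N = dataset size, passed explicitly) and each of the other
  B−1 posteriors carries (N−1)/(N(B−1)). These weights sum to one, which
  makes the estimator exact under posterior collapse (all three terms vanish
  when every q(z|x) equals the prior) — a property the plain log(NB)
  normalizer lacks (it yields MI = log N there). Whatever the weighting, the
  three terms telescope to the single-sample estimate of the mean KL, so
  α = β = γ = 1 reproduces the VAE objective in expectation; the tests check
  this against the closed form within 5% by averaging over eps draws at
  batch 256. Batch size 1 leaves the estimator undefined and raises.

Training uses Adam (lr 1e-3, β₁ 0.9, β₂ 0.999), batch 64, 20 epochs by
default, with all randomness (init, shuffling, eps, augmentation) drawn from
a single seeded generator; runs are bit-reproducible under fixed BLAS
threading. Only NILM-labelled crops are accepted — passing any other label
raises, enforcing the one-class contract.

## Augmentation

Three modes: `none`; `fa` = random horizontal/vertical flips (p = 0.5 each),
rotation uniform over the full circle and translation up to ±10% of the
side; `fab` = `fa` plus a multiplicative brightness factor in [0.8, 1.2].
Magnitudes are declared defaults (configurable), chosen as plausible
microscope-acquisition variation. Flip, rotation and translation are
composed into a single bilinear resample with reflection padding, applied to
the larger source window *before* the final 64 px center crop so no
out-of-frame background enters the model input. `fa` never changes pixel
intensities, only geometry.

## Scoring

The normal-class density is a full multivariate normal over latent means of
normal crops held out from training (the trained aggregate posterior drifts
from the standard-normal prior — the fitted density, not the prior, is what
makes the score work; a test verifies the fitted Gaussian beats the prior on
held-out normal latents). Estimation uses the sample mean and unbiased
(n−1) covariance plus a ridge (default 1e-6·trace/d) for small folds; with
fewer than d+1 samples the covariance falls back to its diagonal. The score
is evaluated at the posterior mean μ(x) for determinism (sampling z instead
is a one-line change). AUROC treats abnormal as positive with midrank tie
handling. Thresholded metrics (accuracy, F1, sensitivity, specificity) use
a configurable rule: Youden's J maximized on a validation split (default),
a quantile of normal-class scores (needs no abnormal data), or a fixed
value. k-fold evaluation splits normals so the Gaussian is always fitted on
folds not being scored, splits abnormals into k folds, and reserves half of
each evaluation fold for threshold selection.

## CRSD and clustering

Gaussian cross-entropy is implemented as CE(r, q) = −E_r[log q] (the paper
convention for cross-entropy; the distance uses absolute differences, so the
sign convention does not affect any of its properties) with a vectorized
diagonal path and a full-covariance path sharing one interface. The pairwise
matrix over n posteriors and |R| references costs O(|R|·n) cross-entropy
evaluations plus O(|R|·n²) subtractions; the reference set defaults to the
posteriors of the evaluated fold, with seeded subsampling for large n.
Agglomerative clustering runs on the precomputed matrix with average
linkage — centroid-type linkages (Ward) need coordinates, which a
pseudometric does not provide; ties break by scipy's deterministic condensed
ordering. Baselines (Euclidean agglomerative, K-means, spectral, DBSCAN)
run on posterior means with library defaults (DBSCAN eps 0.5,
min_samples 5), overridable per call. h/c/V come from scikit-learn and are
cross-checked in the tests against a direct evaluation of the entropy
formulas.

## Interpretation

Traversals decode 10 evenly spaced points from −4 to +4 standard deviations
(inclusive endpoints) about the latent center of non-augmented normal data,
one dimension at a time, using the decoder mean (no sampling), so grids are
exactly reproducible from their arguments. Pairwise latent densities use a
2-D Gaussian KDE per dimension pair and display group (Scott's bandwidth,
100×100 grid over mean ± 4 sd, renormalized to integrate to one on the
grid); label merge maps pool clinically adjacent categories. Cluster
queries return co-cluster members sorted by dissimilarity to the query,
plus a per-cluster class-composition table ranked by purity.

## Synthetic data

Each crop is one cell: an anti-aliased elliptical nucleus (area πr²
regardless of eccentricity, via semi-axes r/(1−e²)^¼ and r(1−e²)^¼) on a
cytoplasm disc over a white background, with controllable nucleus radius,
eccentricity and darkness, cytoplasm hue, global brightness, and additive
Gaussian noise. The abnormal class defaults to a 1.5× nucleus radius, 0.2
lower nucleus value and higher eccentricity — the hyperchromatic
enlarged-nucleus signature of high-grade squamous lesions. Defaults:
normal radius U(13,19) px, eccentricity U(0,0.35), nucleus value
U(0.40,0.55), hue U(25°,45°), brightness U(0.9,1.1), noise sd
U(0.02,0.03); cell centers jitter ±6 px around the crop center and are
recorded in the CRIC-style annotation CSV (image_id, center_x, center_y,
class; 0-based, x = column).

What the generator does **not** emulate: staining variability and texture,
overlapping cells and clumps, debris, out-of-focus blur, multi-cell scenes,
and the graded Bethesda spectrum (it has one abnormal class). Passing
tests therefore demonstrate that the pipeline recovers a known, strong
morphological contrast under controlled conditions — not clinical-grade
performance on real smears.

## Problem sizes and numerical choices

The shipped experiments are desk-scale by design: smoke training uses
80–200 crops for 6–20 epochs; the end-to-end validation trains on 200
normal crops (20 epochs, FAB augmentation) and evaluates on 100 normal +
100 abnormal held-out cells; clustering fixtures use 40–60 posteriors in
d = 8 over 10 seeds. Monte-Carlo oracles use 10⁵–10⁶ draws with 3-standard-
error tolerances. Degenerate inputs are handled explicitly: empty datasets,
single-sample covariance fits, singular covariances without ridge,
n_clusters > n, empty reference sets and singleton TCVAE batches all raise
with messages naming the offending argument.

## Known limitations

* The MLP backbone caps reconstruction fidelity; traversal strips are
  correspondingly soft compared to what a convolutional decoder produces.
* The abnormality score is a ranking signal, not a calibrated probability;
  thresholds must be chosen per deployment.
* CRSD is a pseudometric: distinct posteriors equidistant in cross-entropy
  from every reference are indistinguishable. Larger, well-spread reference
  sets shrink this equivalence class but cost O(|R|·n²).
* On strongly separated populations AUROC saturates, so comparisons between
  configurations near AUROC = 1 are uninformative; the clustering fixtures
  are the sharper instrument there.
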