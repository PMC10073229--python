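# Methods

This note records the models, defaults and design choices behind
`symbiolipo`, in the order data flow through the package.

## Imaging model and segmentation

A `ConfocalStack` holds named `(z, y, x)` channels — `oxidised` (ex/em
488/510), `reduced` (ex/em 561/590), optional `chlorophyll` — with physical
voxel sizes. The default synthetic geometry is 512 × 512 px over
135 × 135 µm (pixel edge 135/512 ≈ 0.2637 µm) and ~1.0 µm z-slices,
matching the acquisition setup this pipeline targets; recovery experiments
in the tests use a 0.5 µm z-step so a ~2 µm body spans enough slices for
its volume to be well sampled.

**Detection.** The detection signal is the *sum* of the two lipid channels,
Gaussian-smoothed in-plane (σ = 1 px; z is not smoothed because slice
spacing is ~4× the pixel edge). The threshold is Otsu computed within the
cell mask, overridable by a fixed value. Above-threshold voxels inside the
mask are labelled with 26-connectivity so a body spanning slices is one
ROI; components below 4 voxels are rejected as noise. These defaults are
this package's own, parameter-free replacements for an interactive macro
workflow; every one of them is configurable.

**Measurement.** Per-channel ROI means are arithmetic means of the *raw*
(unsmoothed) intensities, so the oxidised/reduced ratio is unbiased by the
detection pipeline; scaling both channels by any positive constant leaves
every ratio unchanged (the ratiometric guarantee, tested to 1e-9). ROI
area is the voxel count times the in-plane pixel area — i.e. in-plane areas
summed across slices — and an ROI whose reduced mean is zero has no
defined ratio and is dropped with a warning.

## Per-cell metrics

* **Inclusion-body exclusion.** Inclusion bodies (large, round, very bright
  structures that are not lipid stores) are removed by explicit cut-offs:
  keep area ∈ [0.2, 20] µm² and ratio ≤ 5 by default. The cut-offs stand in
  for a manual curation step, are mandatory in the config, and are recorded
  in output provenance; the summed-area cut-offs scale with the z-step and
  should be adapted to the acquisition. Both partitions are returned so
  exclusions stay auditable, and the filter is idempotent.
* **LPO ratio** = unweighted mean of the kept lipid-body ratios (each body
  counts once regardless of size). An area-weighted variant exists but is
  off by default — with per-body ratios constant within a body, weighting
  is a modelling choice, and equal weighting treats each organelle as one
  observation. Cells with no kept body are flagged `no_lipid`, counted in
  the log, and omitted from ratio analyses.
* **Lipid volume** = (Σ kept ROI areas) × slice thickness (default 1.0 µm,
  configurable).
* **Co-hosted pairs.** Host cells imaged with two endosymbionts are
  collapsed to one measurement by averaging ratio and volume; groups larger
  than two violate the two-symbionts-per-host study design and raise.

## Synthetic data

**Images.** Bodies are isotropic Gaussian blobs, σ = radius/2, truncated at
3σ — smooth, PSF-like, and analytically invertible: the set of voxels a
detector thresholding at T should find is the sphere of radius
σ√(2 ln(peak/T)) (capped at 3σ). The generator exposes this
(`expected_volume_um3`, `body_footprint_voxels`), which is the recovery
oracle used throughout the tests: measured volumes are compared with the
analytic expectation *at the threshold the detector actually used*. The
oxidised channel is exactly `true_ratio` times the reduced channel before
noise, so recovered ratios have an exact target. Noise, when enabled, is
Poisson shot noise on the expected counts followed by additive Gaussian
read noise, independent per channel — the standard confocal approximation.
Inclusion bodies are planted with radius and brightness outside the
lipid-body cut-offs so the exclusion filter has true positives to catch.
Not modelled (out of scope): optical PSFs, spectral bleed-through,
photobleaching; passing recovery tests therefore shows correctness of the
measurement pipeline, not robustness to those instrument effects.

**Tables.** Cells are drawn from a three-component bivariate Gaussian
mixture in (lipid volume, LPO ratio), on the scale "multiples of the
endosymbiotic component mean", then multiplied by per-species baselines.
Defaults: component means (1.0, 1.0), (3.0, 0.52), (6.0, 0.40); weights
0.40/0.25/0.35; endosymbiont mix probabilities 0.90/0.34/0.00 (the
three-profile structure the pipeline is built to recover: an
endosymbiont-dominated profile, a mixed transition profile, a purely
ex-symbiotic profile); three species at realistic dinoflagellate scales
(endosymbiont lipid volume 18–25 µm³, LPO ratio 1.2–1.7); 150 cells and 4
colonies per species (within the 3–5 colony range typical of such designs).
Colony effects are additive on log volume (volumes are positive and
right-skewed, so colony variation is naturally multiplicative; sd 0.05)
and on the raw ratio (sd 0.03). Component separations are chosen so the
profiles are visually distinct clusters — the regime the clustering stage
assumes; the lipid-body size/count distributions per cell have no published
reference and are free parameters. Non-positive draws are floored at a
small positive value and flagged `truncated`.

## Normalisation and statistics

* **Normalisation.** Each variable is divided by the mean over the species'
  endosymbiotic cells, so within each species the endosymbiont mean of
  every relative variable is exactly 1 and species become comparable.
* **Assumptions.** Shapiro–Wilk on the (transformed) values; Levene with
  median centring (Brown–Forsythe), the default of R's `car::leveneTest`
  that this workflow mirrors. The `auto` transform policy tries
  none → log → √ and keeps the first under which both tests pass at 0.05.
* **Mixed model.** y = Xβ + u_colony + ε, u ~ N(0, σ²_c), ε ~ N(0, σ²_e),
  REML. The criterion is profiled over λ = σ²_c/σ²_e (closed-form GLS for
  every λ) and optimised by bounded scalar search after a coarse log-grid —
  deterministic and exact for the single-random-intercept case. Two
  readings of "mixed models on colony means with colony as a random
  factor" are supported and reported: per-cell responses with a colony
  intercept (default) and colony-mean responses with a colony intercept
  (`mode="colony_mean"`, the low-denominator-df reading that yields t(2)–
  t(4) with 3–5 colonies).
* **Satterthwaite df** per coefficient: df = 2f²/(gᵀAg) with f the
  coefficient's sampling variance, g its gradient in (σ²_c, σ²_e) (central
  differences, relative step 1e-4) and A the inverse observed information
  of the REML log-likelihood (numerical Hessian). This reproduces R's
  `lmerTest` to ~6 significant digits on shared fits (cross-checked in the
  test suite). When σ̂²_c hits the zero boundary the fit is flagged and
  t/p reduce exactly to OLS with n − p df (the Satterthwaite machinery is
  undefined at the boundary). Simulated type-I error of the cell-type test
  under colony heterogeneity is ~4–5% at the nominal 5%.
* **BIC comparison.** Candidates are OLS/ML fits on identical
  complete-case rows; BIC = −2ℓ + k ln n with k counting mean parameters
  plus the error variance (matching R's `BIC()` on `lm`/`gls` objects).
  Errors are i.i.d.; per-group variance weights are out of scope here
  because no reference correlation structure is available.

## Clustering

* K-means (Euclidean, Lloyd) via scikit-learn, best of n_init = 50
  k-means++ restarts, tolerance 1e-6 — effectively deterministic under a
  fixed seed; verified against exhaustive partition enumeration for n ≤ 8.
  Features are clustered on the relative scale without z-scoring (both
  axes are dimensionless ratios near 1); a z-scoring option exists.
* Clusters are renumbered by descending centroid LPO ratio, so cluster 1
  is always the endosymbiotic-like profile and the last cluster the
  ex-symbiotic-like one regardless of initialisation.
* **Gap statistic**: gap(k) = mean_b log WSS*_b(k) − log WSS(k) over B = 100
  uniform draws from the data's bounding box (the simplest reference
  scheme), se with the √(1+1/B) inflation, recommendation by the one-SE
  rule (smallest k with gap(k) ≥ gap(k+1) − se(k+1)). On elongated,
  unequal-spread clusters this reference is known to keep gap rising with
  k; the report therefore presents all three diagnostics (WSS elbow,
  silhouette maximum, gap) side by side without forcing agreement, and on
  the default study silhouette cleanly identifies k = 3.
* Condition shifts (e.g. heat stress) default to *assigning* treated cells
  to the control-fitted centroids (nearest centroid, ties to the lowest
  index) rather than refitting, so the profiles keep one meaning across
  conditions; refitting remains available.

## Pipeline, sizes and limitations

Each stage writes a CSV plus a provenance JSON (config snapshot, software
version, input checksums, seeds, timestamp) and is skipped on rerun when
its output exists, so runs resume from completed stages.

Problem sizes in the shipped tests and acceptance script — 128² × 16
recovery stacks, 450-cell studies, 500–1000 calibration replicates, 25–50
k-selection datasets — were chosen as the smallest sizes at which the
Monte-Carlo tolerances used (binomial 95% intervals, ±2% on error rates)
are meaningful.

Known limitations: cell masks are supplied, not computed (whole-cell
segmentation of host tissue is a different problem); the mixed model
supports a single random intercept only; GLS with correlated errors is not
implemented; the published per-cell dataset this pipeline mirrors is not
redistributable, so the direct reproduction checks run only when a user
supplies it (see README).
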