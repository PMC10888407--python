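# Methods

## Model

A bright-field two-stain image is modelled in relative optical density
(OD). With `I` the 3×N RGB intensity matrix and `I₀` the white level
(255 for 8-bit), `X = −ln(clip(I, 1, I₀)/I₀)` ≥ 0. Beer–Lambert makes OD
approximately linear in chromogen concentration, so

```
X ≈ W H,   W ∈ R^{3×2} ≥ 0 (columns: hematoxylin, DAB),   H ∈ R^{2×N} ≥ 0.
```

The intensity clip floor of one grey level bounds OD by `ln 255 ≈ 5.54`
per channel and keeps fully black pixels finite; the natural logarithm is
used throughout (any fixed base rescales all OD vectors uniformly and
cancels in every angle, ratio and normalized feature).

Key assumptions, and what breaks when they fail:

* **Rank-2 structure** — pixels lie in the cone spanned by the two stain
  vectors. Dispersion, glare and out-of-gamut pigments add out-of-plane
  energy; the third eigenvalue of `X Xᵀ/N` measures it.
* **Stain-dominant darkness** — the highest-norm pixels concentrate near
  the pure-stain directions (dense nuclei; dense extranuclear DAB). The
  angular peak estimator reads the stain directions off exactly this
  structure; an image violating it (e.g. every dark pixel an equal
  mixture) cannot be separated by any per-image method of this family.
* **Two stains present** — a single-stain image has a rank-1 OD cloud.
  Such images are detected (`L₂/L₁ ≤ 1e−4`), skipped during per-image
  estimation, and deconvolved with the cohort-average basis instead.

## Separation stage

Uncentered PCA (no mean subtraction — centering would destroy the cone
geometry) gives eigenpairs `(q_i, L_i)` of `X Xᵀ/N`, eigenvalues
descending, each eigenvector sign-flipped so its entry sum is ≥ 0 (the
decomposition is sign-ambiguous; the convention pins a reproducible
angular frame). Projections use unit-power scaling, `z_i = q_iᵀX/√L_i`,
so each planar component has mean square 1; this widens the angular gap
between the stain directions, which sit close together inside the first
octant.

The angular profile takes `θ(n) = atan2(z₂, z₁)` and `r(n) = ‖z(:,n)‖`
over foreground pixels (background = OD 1-norm below `tau_bg = 0.05`;
the mask only affects the profile, not PCA or deconvolution, and can be
switched off). The occupied range `[min θ, max θ]` is split into 1000
equal bins holding the mean `r` of their members (empty bins hold 0 —
interpolation was rejected as the peaks live in dense regions). The
profile is smoothed by an 8th-order Butterworth low-pass at digital
cutoff 0.035, applied forward–backward (`sosfiltfilt`) so it is
zero-phase and peak positions do not shift; second-order sections keep
the design numerically stable at this low cutoff.

Peak selection: the global maximum of the smoothed profile gives one
stain angle; the second is the **largest local maximum** in the half of
the occupied range not containing the first. Restricting to local maxima
matters: the monotone tail of a dominant peak, sliced off at the range
midpoint, would otherwise win the opposite half whenever the second
stain is much weaker. If the opposite half holds no local maximum the
plain half-maximum is used; if it holds no mass at all the image is
declared single-stain.

The planar basis `B̂ = [(cos φ, sin φ)₁, (cos φ, sin φ)₂]` is lifted by
`Ŵ = [q₁√L₁, q₂√L₂]·B̂` — the exact inverse of the projection on the
plane. Column identity (which column is hematoxylin) is assigned by
maximal cosine similarity to the classical reference OD directions
(0.650, 0.704, 0.286) and (0.269, 0.568, 0.778); ties break toward the
larger blue-channel OD being DAB. Entries pushed slightly negative by
noise are clipped at 0; a column with an entry below −5% of its norm
marks the basis as suspect and excludes the image from cohort averaging.

Deconvolution solves the overdetermined per-pixel system by the left
pseudoinverse, `Ĥ = (ŴᵀŴ)⁻¹Ŵᵀ X`, clips negatives to 0, and refits
every column left with exactly one positive entry against that single
stain vector (`h = max(0, wᵀx/‖w‖²)`) — a pixel attributed to one stain
gets that stain's best fit rather than a residue of the clipped joint
fit. One refinement pass then re-estimates each planar direction as the
normalized mean of the unit-power projections of pixels whose
concentration dominates the other stain at least 10-fold, and
re-deconvolves. Refinement is deliberately a single pass. Measured on
synthetic data: it is decisive where the profile peak is unreliable
(weak-DAB images at 5% OD noise: median error 33°→21°, improved in 20/20
seeds) and adds a small bias (~0.1–0.2° at the default 2% noise) where
the peak is already sub-degree accurate — a trade the pipeline accepts
by keeping it always on.

The cohort-average basis `W̄` (entry-wise mean of the non-degenerate,
non-suspect per-image estimates) re-deconvolves every image. This is
what makes near-negative-control images usable: their own DAB direction
is barely estimable, but their concentrations under `W̄` are accurate.

## Features

With `w̄₂ = W̄:,₂` (DAB column) and `h̄₂ = H̄_{2,:}`:

* `M1(m) = ‖w̄₂‖₁‖h̄₂‖₁/(3N_m)`, `f1 = M1/max_m M1` — mean DAB intensity,
  cohort-normalized to [0, 1] with the maximum attained.
* `R_s(m)` = 99th percentile (linear interpolation) of the 3N entries of
  the rank-one intensity matrix `w̄_s h̄_s`; with `m* = argmax R₂`:
  `f2 = (R₂/R₂(m*)) / (R₁/R₁(m*))` — a robust-maximum DAB/hematoxylin
  ratio that cancels section thickness and exposure. `R₁` is floored at
  1e−9 against hematoxylin-free synthetic edge cases.
* `M3(m) = ‖w̄₂‖₂‖h̄₂‖₂/(3N_m)`, `f3 = M3/max_m M3` — root-power analogue
  of f1 (the Frobenius norm of a rank-one matrix is the product of the
  factor 2-norms).
* `f4(m) = ‖ŵ₂‖₂‖ĥ₂‖₂/√(3N_m)` from the image's **own** basis — the only
  feature carrying absolute intensity, with the √ prefactor forced by its
  reading as the root of the average power. Degenerate images fall back
  to the cohort-average surrogate, flagged in the log.

Every feature normalizes by its own image's N, so mixed ×20/×40 cohorts
are handled. f1–f3 are invariant to the arbitrary scale split between
`W̄` and `H̄`; all four are pixel-permutation invariant.

## Scoring

For the feature-count T the defaults are (p, q, iterations) =
(1.5, 1/1.8, 1) for T=2 (f1, f2), (1.9, 1/1.75, 2) for T=3 (+f3), and
(2.5, auto, 3) for T=4 (+f4). The p-norm of each feature vector orders
images by expression; sorted, the norms follow a power-like curve. The
automatic q fits `y = a·mᵇ` to each half of the sorted curve (m = global
ascending rank) and sets `q = 2/(b₁+b₂)`. The fit is nonlinear least
squares in linear space, seeded by the log–log slope: in log coordinates
a plateau of near-zero norms (a cohort with many unstained images) would
dominate the exponent; fitting in linear space weights the informative
upper range, and on the default cohort lands at q ≈ 0.48–0.51, i.e. the
square root. A half with fewer than three positive points falls back to
q = 1/2.

The reshaped values `v = ‖f‖_p^q` are split into five equal-length
intervals over `[min v, max v]` (half-open, top interval closed);
interval members seed the clusters and member means seed the centroids.
An empty interval receives the uniform vector whose p-norm raised to q
equals the interval midpoint. Exactly three assignment+update k-means
iterations follow under the p-norm distance, with member-mean centroid
updates (the update uses the mean even though the mean is not the exact
p-norm minimizer for p ≠ 2; it preserves the fixed-point property and
the centroid-norm ordering); a cluster that empties keeps its centroid
frozen. Final clusters are ranked by ascending centroid p-norm and
labelled 1 ("1+") to 5 ("5+"). The scorer contains no random state.

## Synthetic cohorts

The generator emulates the statistical structure the method assumes, not
tissue appearance:

* **Hematoxylin**: 120 Gaussian nuclear blobs per 128×128 field
  (uniform centers, radii U(1.5, 2.5) px, peak amplitudes lognormal
  around 1.0 OD) — a desk-scale stand-in for megapixel microscope
  fields; smaller fields leave the weak-stain angular profile
  quantization-limited.
* **DAB**: a smooth Gaussian random field (σ = 3 px) through a
  thresholded normal CDF — exactly zero on ~25% of the tissue
  (antigen-free regions), bounded above (chromogen density saturates, so
  the darkest DAB stays inside the camera's dynamic range), mean equal
  to the tier scale — then steeply suppressed inside nuclei
  (`·exp(−8·hema)`: chromatin displaces the chromogen, leaving a thin
  partial-volume shell at nucleus rims). Without nuclear exclusion the
  darkest pixels would be H+DAB superpositions and the angular peaks
  would be biased by tens of degrees; with a hard cutoff instead of the
  steep rolloff, full-strength rim mixtures dominate the profile
  mid-range. The rolloff is the realistic middle.
* **Tiers**: mean DAB OD per tier (0.05, 0.3, 0.8, 1.5, 2.5), assigned
  round-robin; tier 1 is a near-negative control. Per-image field
  randomness gives ~5% natural amplitude variability within a tier, so
  recovery is not trivially 100% by construction.
* **Nuisances**: 25% near-white background (concentrations ×0.02 on a
  smooth region), additive Gaussian OD noise (sd 0.02), 8-bit rounding.
  Everything derives from one `default_rng(seed)` stream.

What the generator does **not** emulate: tissue texture and nuclear
morphology, chromatic aberration and uneven illumination, stain
co-localization beyond partial volume, scanner color profiles. Passing
tests therefore demonstrate correctness of the algorithmic chain under
the model's own assumptions, not clinical performance on real slides.

## Numerical choices and degenerate inputs

* Eigen-decomposition via `eigh` on the 3×3 second-moment matrix;
  verified against an SVD oracle to 1e−10 relative.
* Rank threshold `L₂/L₁ ≤ 1e−4` flags single-stain images; blank images
  (all-zero OD) raise immediately.
* The smoothing filter requires the profile to exceed its padding length
  (27 bins); the bin count is a parameter but 1000 is the tested value.
* Boundary rule for interval membership is half-open with a closed top;
  `v` exactly on an inner edge goes to the upper interval.
* All-identical cohorts (zero norm range) and all-DAB-free cohorts are
  rejected with specific errors rather than scored.
* Problem sizes used by the test-suite and acceptance runs: 128×128
  images, cohorts of 20 (separation checks) and 50 (end-to-end), 100
  random matrices for the spectral oracle.

## Known limitations

* Exactly two stains; no fluorescence, no >2-chromogen panels, no
  whole-slide formats. Single-chromogen images are out of scope (f2
  requires hematoxylin).
* `I₀` is a fixed scalar; no per-image white-balance estimation.
* The five-level scale is the tested configuration; `n_clusters` is a
  parameter but other values are structurally supported only.
* Scores are relative to the cohort: the normalizations of f1–f3 make
  them cohort-calibrated, so scoring one image in isolation is
  meaningless and adding images can change other images' scores.
* Per-image stain vectors of a nearly absent stain are unreliable by
  nature (tier-1 images: 2–3° even noiseless, tens of degrees under
  noise); the cohort-average basis is the supported read-out there.
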