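# Methods

This note documents the models, conventions, numerical choices, and known
limitations behind `lusaug`. It is the package's own account of its design;
empirical statements below are limited to what the test suite and
`scripts/acceptance.py` compute.

## Coordinates, pixel pipeline, and the FOV model

Images use 0-based `(row, col)` coordinates, origin top-left, depth
increasing with row. Pixels are 8-bit `[0, 255]` on disk and `float64`
`[0, 1]` in memory; every transform operates in `[0, 1]` with clipping, and
quantization (round-half-up) happens only on save. This avoids cumulative
quantization across chained transforms.

The field of view (FOV) is parameterised by probe kind:

- **linear** — the rectangle rows `[r_min, r_max]`, lateral extent `width`
  centred on `apex_col`; `theta0 = 0` by definition.
- **curvilinear / phased** — the annular sector of radii `[r_min, r_max]`
  about the apex (possibly above the frame) and beam angles
  `[-theta0, +theta0]`, with θ measured from the vertical centreline,
  positive rightward. A fan is classified *phased* when
  `r_min / r_max ≤ 0.05` (the apex effectively touches the top of the
  image).

Invariant maintained throughout: every pixel outside the FOV mask is exactly
zero after any operation (the semantics of preprocessed ultrasound).

### Mask estimation

Real ultrasound frames carry vendor overlays; the preprocessing contract
assumes the FOV mask comes from dedicated cleaning software or manual
annotation. The built-in estimator is a stand-in for clean or synthetic
frames only: threshold at 2/255, morphological closing with a 5×5 element,
largest connected component, hole filling. Phantoms have exact-zero
background, so any small threshold works; the threshold and element size are
configurable.

### Geometry fitting

Fit of a fan mask proceeds by: per-row extreme columns; rows above the
widest row lie on the straight lateral edges (below it they lie on the outer
arc), so those rows are fit with total-least-squares lines (TLS via SVD —
robust to pixelation, mean perpendicular residual tolerated up to 1.5 px);
the apex is the line intersection; `theta0` is the mean unsigned angle of
the two edges from vertical; radii come from mask-pixel distances to the
apex with a half-pixel correction for raster under-coverage. Masks whose
row-widths are constant within 2 px are classified linear. Anything fitting
neither model raises a fit error.

### Scan conversion

`scan_convert` bilinearly interpolates beam-space content (rows = depth,
columns = beam angle) at the `(r, θ)` of each in-mask Cartesian pixel;
`inverse_scan_convert` samples the Cartesian frame on a regular `(r, θ)`
lattice with `round(r_max − r_min)` depth rows and, by default, outer-arc
arc-length angular resolution. Bilinear interpolation with constant-0 fill
is used everywhere; it is the conventional scan-conversion choice and keeps
round trips interpolation-limited. The convexity-change operator oversamples
its intermediate beam lattice 2× so its Cartesian→beam→Cartesian chain loses
as little as possible; round-trip fidelity (MAE < 0.02) is guaranteed only
for band-limited content — pixel-scale speckle cannot survive two bilinear
resamplings, which is inherent to resampling, not a defect.

## Transform parameterisation

Published sources for this family of pipelines print application
probabilities but not every operator's parameter ranges; the defaults below
are the package's choices, follow the SimCLR/BYOL family's published
settings where those exist, and are all configurable per transform in
pipeline configs.

| Operator | Default parameters |
|---|---|
| A00 crop-and-resize | area fraction U[0.08, 1.0], aspect log-U[3/4, 4/3], output 128×128, ≤10 rejection attempts then centred √c_min fallback |
| A02 colour jitter | strengths (0.8, 0.8, 0.8, 0.2); brightness/contrast factors U[1−s, 1+s]; saturation/hue drawn but identity on single-channel input |
| A04 Gaussian blur | σ ~ U[0.1, 2.0], kernel radius ceil(3σ), reflective boundary |
| A05 solarize | threshold 0.5 |
| B00 probe-type change | linear→fan: θ0 ~ U[0.3, 0.7] rad, inner ratio r_min/r_max = 0.3, fan scaled to the frame; fan→linear: inverse scan conversion resized to the frame |
| B01 convexity change | multiplier U[0.7, 1.3]; θ0′ clamped to [0.1, 1.2] rad |
| B02 wavelet denoise | `db2` (4-tap Daubechies), 3 levels, per-band retention n_j = M/(j+1)^α with α = 3, M = coarsest approximation size, j = 1 the coarsest detail level |
| B03 CLAHE | clip limit U[1.0, 4.0] × uniform bin height, 8×8 tiles, 256 bins |
| B04 gamma | γ log-U[0.7, 1.5] |
| B05 brightness/contrast | a ~ U[0.8, 1.2], b ~ U[−0.12, 0.12] |
| B06 depth change | zoom U[0.85, 1.25], radial about the apex (fan) or vertical about the FOV top (linear); mask and geometry exactly preserved |
| B07 speckle | multiplicative zero-mean Gaussian field, σ = 0.25, smoothed by a σ=1 px Gaussian for spatial correlation |
| B08 Gaussian noise | i.i.d. multiplicative, σ = 0.1 |
| B09 salt & pepper | per-pixel replacement rate 0.01 (≤ 0.1), 0 or 1 equiprobable |
| B11 rotate/shift | angle U[−15°, 15°], per-axis shift U[−10%, +10%] of the dimension |

Notes on individual operators:

- **CLAHE** is implemented directly (per-tile clipped histograms over
  *in-FOV* pixels only, excess redistributed evenly, bilinear interpolation
  of tile mappings) because library variants neither restrict histograms to
  a mask nor expose the clip limit relative to uniform bin height. Tiles
  containing no FOV pixels inherit the global in-FOV histogram, which makes
  a constant FOV map to a constant and keeps interpolation well-defined at
  the FOV boundary.
- **Speckle** is a smoothed multiplicative Gaussian field — spatially
  correlated "synthetic speckle", not a physical Rayleigh/K-distribution RF
  simulation. The smoothing attenuates the field's standard deviation by a
  factor computable from the kernel (`SpeckleNoise.expected_field_std`),
  which the calibration tests use.
- **B11 fill regions** are re-masked: the transformed mask is re-binarized
  at 0.5 and content re-zeroed outside it, so rotation does not introduce
  spurious non-zero background.
- **Crop discretisation** uses ceil for window dimensions, so every realised
  window area is at or above the sampled target — the 8% lower bound holds
  exactly after integer rounding.

## Pipelines, seeding, and provenance

A pipeline is an ordered list of `(id, probability, params)` entries plus a
final bilinear resize to 128×128 (masks re-binarized). The three builtins
ship as packaged YAML configs. We resize *after* augmentation (the
alternative — resizing before — is configurable via `out_size` and input
sizing).

Randomness contract: one master seed; each transform's Bernoulli gate and
parameter draws come from separate sub-streams seeded by
`(seed, image_index, view_index, transform_id, role)` via
`numpy.random.SeedSequence`. Consequences: skipped transforms consume no
randomness, and removing one transform from a pipeline leaves every other
transform's draws unchanged — leave-one-out conditions are maximally paired,
which reduces the variance of ablation comparisons. Noise transforms log a
31-bit sub-seed rather than the noise field, so provenance stays small and
`replay` reproduces any view bit-exactly.

## Phantoms

Phantoms are schematic, not physically simulated: their purpose is to place
canonical lung-ultrasound structures at known locations so augmentation
invariants and the ablation harness have ground truth. Rendering happens in
beam space and is scan-converted under the frame's geometry: a tissue
background with mild depth attenuation; multiplicative speckle
(`1 + σ·N(0,1)`, σ defaulting to U[0.25, 0.4] per video); log compression
`log(1 + 20x)/log(21)` to mimic B-mode dynamic range; a bright pleural band
at a configurable fraction of `r_max`; A-line replicas at integer multiples
of the probe–pleura distance with amplitude decay 0.35^k; B-line rays as
bright fixed-angle columns from the pleura to maximum depth; and an optional
anechoic effusion wedge. Labels: `A` (A-lines only), `B` (≥1 B-line),
`effusion`, `normal`; labels attach at the video level and apply to every
frame.

What phantoms do *not* emulate: realistic speckle statistics, attenuation/
time-gain compensation, probe-specific artifacts, vendor overlays, motion,
or multi-finding pathology. Passing tests therefore demonstrate the
*mechanics* of the pipelines and the decision procedure — not clinical
performance on real ultrasound.

## Ablation statistics

`grouped_kfold` shuffles patients under the seed and deals them round-robin
(fold patient-counts differ by ≤1, folds patient-disjoint). AUROC is the
rank-statistic probability that a random positive outranks a random
negative (ties half), delegated to scikit-learn. The Friedman statistic uses
within-block average ranks and the standard tie correction
(χ²/(1 − ΣT/(nk(k²−1)))); an all-tied matrix returns (0, 1). Wilcoxon
signed-rank drops zero differences, ranks |d| with average ties, and reports
W = min(W+, W−) with an exact two-sided p — the probability under random
signs that min(W+, W−) is at most the observed value — enumerated
exhaustively for up to 12 nonzero differences, and a tie-corrected normal
approximation with continuity correction beyond. Holm–Bonferroni is the
standard step-down procedure. The Wilcoxon tests are two-sided; direction
("lower"/"higher" than baseline) is classified by median difference, and
the Holm family is the set of ablated conditions within one task.

`run_leave_one_out` realises the condition dependence of full-scale SSL
pretraining at desk scale: each image is augmented once per condition (paired
sub-seeded draws), embedded by a pluggable `embed_fn` (default: 31
handcrafted features — row/column band means, an in-FOV intensity
histogram, bright-pixel fractions, strongest-column responses), and scored
by patient-grouped-fold AUCs of a standardised logistic regression.
`embed_fn` may accept `(image, condition)` so tests can model encoders
whose quality depends on the pretraining condition (the "synthetically
degraded ablation" probe). Folds that lack a class in train or test are
skipped with a warning, reducing k identically across conditions. The
distilled pipeline contains exactly the contributory transforms, ordered by
a fixed convention — ultrasound intensity operators, standard
intensity/jitter operators, geometric operators, crop-and-resize last —
which reproduces the published distilled sequence `[B03, A02, B11, A00]`
for the contributory set {A00, A02, B03, B11}; each transform keeps its
source pipeline's probability.

## Problem sizes used by the test suite

Chosen as the package's own test design: randomized operator invariants run
200 cases per operator on 48×48 mixed-geometry phantoms; application
frequencies use 10,000 pipeline invocations on one 128×128 phantom; crop
statistics use 10,000 draws on a 256×256 frame; geometry round trips use
100 random fan geometries; Type-I calibration uses 1,000 replicates of
10-fold × 5-condition null score matrices; planted-effect recovery uses 200
replicates of 50-patient datasets (2 videos × 2 frames, 48×48, k = 10).

## Known limitations

- The mask estimator is not a substitute for vendor-overlay removal on real
  machines; supply external masks for real data.
- Fit-based geometry recovery assumes a single, roughly upright FOV; tilted
  or composite FOVs raise fit errors.
- B01 can clip a widened fan at the frame edges; the stored geometry remains
  the intended parametric fan.
- Wavelet retention with α = 3 is aggressive by design (denoising/
  compression regime); it visibly smooths fine texture.
- The harness's handcrafted features stand in for a pretrained encoder; with
  condition-blind features an omission can only reduce single-view
  distortion, so genuine "contributory" findings require condition-aware
  embeddings (as in SSL pretraining, or the planted-effect probe).
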