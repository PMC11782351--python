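# Methods

This note documents the models, conventions and numerical choices behind
`vstain`. The package implements a label-free "virtual staining" workflow for
plant-cell microscopy — bright-field to synthetic-fluorescence image
translation with a residual-channel-attention UNet — together with the
quantitative analyses used to validate such stains, and a synthetic scene
generator that supplies ground truth for all of them.

## Synthetic scene generator (`vstain.imgen`)

The generator is the package's stand-in for raw microscopy. It renders a
transmittance map (background ~1.0, cell interiors 0.85, nuclei darker,
chloroplasts darkest), adds a signed difference-of-Gaussians halo
(`G(σ) − G(2σ)`, gain 1.5, σ = `defocus_sigma_px`) to emulate the
edge shadows of slightly defocused transmitted-light imaging, adds Gaussian
read noise, and clips to [0, 1]. Fluorescence channels are rendered from the
same geometry: a membrane channel as a Gaussian band (σ = 1 px) along label
boundaries, nucleus/vacuole/chloroplast channels as filled interiors.

Geometry per shape model:

* **pavement** — Voronoi tessellation of Poisson-disk seeds, regularized by
  two Lloyd iterations, with boundaries displaced by sinusoidal domain
  warping of amplitude `lobe_amplitude` (0 gives convex, straight-walled
  cells; larger values give the interdigitated puzzle shapes of leaf
  epidermis). The tessellation is confluent: every pixel belongs to a cell.
* **by2_file** — elongated ellipses (default major/minor ratio 2.5) in
  near-horizontal files, each with a nucleus blob and a vacuole (eroded
  interior minus nucleus).
* **chloroplast_field** — non-overlapping disks of radius 4–7 px on a
  cytoplasm background, at the 0.28 µm/px calibration typical of such
  recordings (other scenes default to 0.56 µm/px).
* **viability_crop** — one cell per 64×64 crop. Living cells: smooth
  interior, one dark nucleus, 3–13 small organelle granules, crisp boundary.
  Dead cells: shrunken, wavy contour and a coarse "crumple" pattern
  (thresholded smoothed noise, blobs 2–3 px) standing for collapsed internal
  membranes. A per-crop *severity* in [0, 1] scales how visible the death
  phenotype is in bright-field (shrinkage, sharp speckle); the crumple's
  smooth, low-amplitude bright-field shadow and its strong imprint on the
  membrane channel are always present. Per-crop nuisances — background
  level, illumination tilt, defocus σ ∈ [1.0, 2.5] px, noise
  σ ∈ [0.015, 0.05] — affect bright-field only. These choices emulate
  plate-imager data in which transmitted light under-determines viability
  while a membrane stain does not.

Time lapses move chloroplasts by a seeded correlated random walk: per frame,
speed ~ N(mean, sd) truncated at 0, heading persistence in [0, 1], steps
converted by `dt / pixel_size`. Steps that would leave the canvas have the
offending component negated (a bounce), and steps that would bring two
objects within contact distance are rotated to a free heading of the same
length (organelles are solid bodies); both rules preserve step length, so
truth speeds — recomputed from positions as |Δx|·pixel_size/dt — equal the
drawn speeds exactly. A fully boxed-in object stays put for that frame.

All randomness flows from a single `numpy` generator seeded per call:
identical specs regenerate bit-identical scenes. Object placement is
rejection sampling with 200 retries; overflow raises a placement error rather
than silently truncating.

What the generator does **not** emulate: optical point-spread physics, phase
contrast, 3-D structure, uneven focus within a field, debris and
out-of-focus neighbors, camera fixed-pattern noise, or chromatic registration
error. Passing tests therefore show that the pipeline's algorithms are
correct and well-calibrated on images with these idealizations — not that a
model trained here transfers to a real microscope.

## Virtual staining (`vstain.staining`, `vstain.nn`)

The regressor is a UNet whose convolution blocks are residual
channel-attention (RCA) blocks: two 3×3 convolutions with ReLU, then a
channel-attention gate — global average pool per channel, a bottleneck dense
layer of width `channels/r` (ReLU), a dense layer back to `channels`,
sigmoid — that rescales each channel, then a residual addition of the block
input (through a 1×1 projection when the channel count changes). The encoder
has `depth` levels (2× max-pool between levels, channels doubling from
`base_channels`); the decoder mirrors it with nearest-neighbor upsampling and
skip concatenation; a 1×1 linear head emits one channel.

The network and its training loop are implemented directly on `numpy`
(im2col convolutions, a minimal taped reverse-mode autodiff, Adam with the
standard bias correction) in float32. Backpropagation is verified against
central finite differences in float64 in the test suite. Weight
initialization is He-style, seeded; training is deterministic given the seed
and a fixed BLAS threading policy (the only residual nondeterminism we know
of is BLAS reduction order, which has been bit-stable in practice on one
thread).

Training samples one random `patch_size` window per image pair per epoch,
optionally applies one of the 8 dihedral transforms, and sweeps shuffled
minibatches under MSE (MAE selectable) with Adam at 1e-3 (defaults; the
desk-scale tasks in this repository use 2e-3). Inputs and targets are
percentile-normalized: the [P1, P99] range maps to [0, 1] per image, recorded
in the model. Predictions are in these normalized units; that is immaterial
downstream because both the overlap score and Otsu segmentation are
intensity-rank based.

Prediction pads to a multiple of `2^depth` and runs whole images up to
256 px; larger images are tiled. Tiled prediction is two-pass: the
channel-attention gates are captured from one pass over the whole image
(2×-downsampled beyond 512 px) and injected into every tile, making tiles
agree with the whole-image computation away from their borders; each tile's
outer `overlap/2` margin is discarded and the rest blended with a raised-
cosine feather. With the default tile 128 / overlap 64, the margin exceeds
the network's receptive-field half-width at depth 2, so tiled and whole-image
predictions agree to float precision.

Checkpoints are a `weights.npz` plus a JSON sidecar (config, normalization,
channel name); the sidecar is the documented interface. Reloading reproduces
predictions bit-identically.

Desk-scale model configuration used throughout the tests: depth 2, base
8 channels, attention reduction 4, patch 64, batch 8, learning rate 2e-3,
10 epochs (16 for the viability stainer), trained on 150–300 generated
64×64 pairs. At the top-1-percentile overlap score, this model reaches the
practical ceiling on the membrane task: even lightly blurred ground truth
scores only ≈ 0.58 against itself at that selection size.

## Colocalization: threshold overlap score (`vstain.coloc`)

For two images of N pixels, select the top `t` percent of each by rank —
exactly `n1 = ceil(t/100 · N)` pixels, ties broken by intensity descending
then row-major index, so the count is exact and the selection invariant under
monotone intensity transforms. With observed co-selection `n12`, expectation
`E = n1·n2/N`, maximum `M = min(n1, n2)` and minimum `m = max(0, n1+n2−N)`,
the log-rescaled score is

    tos_log = ln(n12/E) / ln(M/E)                     if n12 ≥ E
    tos_log = ln(max(n12, ½)/E) / ln(E/max(m, ½))     if n12 < E

clipped to [−1, 1]: −1 at minimum possible overlap (complete
anticolocalization), 0 at the independence expectation, +1 at maximum overlap
(complete colocalization). The half-pixel floor keeps the score finite when
`n12 = 0` or `m = 0`; results where the floor engaged, or where `E ≤ ½`
(tiny images), are flagged. A linear rescaling with the same endpoints is
also reported.

A property worth knowing: the score is exactly 0 *at* `n12 = E`, but its
*mean under independent noise* is slightly negative when E is small, because
the two branches normalize by different logs (at 200×200 px and t = 1,
E = 4 and the mean is ≈ −0.09; by 512×512, E = 26 and it is within 0.02 of
zero). The acceptance script reports this quantity as measured.

## Segmentation and morphometrics (`vstain.morph`)

* **Otsu threshold** — 256-bin histogram between the image extrema;
  exhaustive maximization of between-class variance; ties take the lowest
  cut; foreground is `image > threshold`.
* **Particle extraction** — 8-connected components, minimum area 50 px,
  border-touching components excluded by default (a flag includes them;
  whether the original particle analyses excluded them is not documented, so
  the safer exclusion is the default).
* **Marker-controlled watershed** — optional Gaussian presmooth; optional
  morphological gradient (disk radius `gradient_radius_px`) for
  filled-object inputs; membrane-style images are already ridge reliefs and
  are flooded directly, so the watershed line lands on the membrane crest.
  Minima shallower than `tolerance` are suppressed by grayscale
  reconstruction (h-minima) before flooding from the surviving regional
  minima (4-connected). The output partitions the image; there is no
  watershed-line label. `tolerance` is in the intensity units of the input:
  on [0, 1] images useful values are ~0.02–0.5; divide 16-bit-scale numbers
  by 65535. In the pipeline, virtual stains are segmented at 2× zoom
  (bilinear), which places watershed lines with sub-pixel precision; labels
  are then measured with `pixel_size / 2`.
* **Per-cell metrics** — the outer boundary is one marching-squares contour
  at level 0.5, smoothed by a 3-point circular moving average (removes the
  half-pixel staircase, which otherwise inflates smooth perimeters by ~6%;
  smoothing a convex curve keeps it convex). Circularity `4πS/L²` and
  solidity `S / hull area` use the polygon area, polygon perimeter, and the
  convex hull of the same contour, so convex rasters measure solidity 1
  exactly and circularity stays ≤ ~1. `area_um2` is the pixel-count area
  (what particle analyzers report). Aspect ratio is the fitted-ellipse
  (second-central-moment) major/minor ratio; bounding-box ratios are not
  used. Coordinates: pixel centers at integers, origin top-left, x = column,
  outputs in µm. Verified endpoints: disk r = 100 circularity 0.979, square
  circularity 0.813 vs π/4 ≈ 0.785, rectangle solidity 1.0.
* **Agreement** — ordinary least squares of source B on A; R² is the squared
  correlation; zero variance in either source is an error.

## Tracking (`vstain.motion`)

Per frame: Otsu binarization, 8-connected components ≥ 9 px,
intensity-weighted centroids. Linking between consecutive frames is greedy
mutual-nearest-neighbor: candidate pairs in ascending distance order, each
detection used once, pairs beyond `max_disp_px` (default 15, ≳ 2× the
fastest simulated per-frame displacement) rejected; unmatched detections
start tracks, unmatched ends terminate. Speeds are Euclidean displacement ×
pixel_size / dt; single-point stubs are kept but excluded from speed
statistics. With object spacing > 2× the per-frame displacement the greedy
assignment equals ground truth, so nothing fancier (e.g. Hungarian
assignment) is needed for sparse organelles.

Noise propagation sets what speed agreement is achievable: i.i.d. centroid
jitter of σ px adds speed error of σ√2 · pixel_size/dt, so R² ≈
var(speeds)/(var(speeds) + 2(σ·px/dt)²). Otsu centroids on generated frames
have σ ≈ 0.2 px, which supports R² > 0.95 at the default speed spread.

## Viability classification (`vstain.viability`)

Crops are quantized to 64 gray levels (min–max by default; a 1–99-percentile
"robust" mode is provided and used for network outputs, whose rare out-of-
range excursions would otherwise compress the histogram), co-occurrence
matrices computed at distance 1 and angles 0/45/90/135° (symmetric,
normalized), and summarized by the 13 classical Haralick statistics averaged
over angles (one block per distance). Sum variance is centered on the sum
average (not sum entropy, an ambiguity in the original definitions);
correlation is defined as 0 when either marginal is degenerate. The exact
feature list of the plugin used in the original workflow is not published;
the canonical 13 statistics are the documented substitute.

The classifier is a random forest with the customary defaults: 500 trees,
√p candidate features per split, unlimited depth, bootstrap sampling,
majority vote. Evaluation keeps the train/test split fixed and retrains
under each seed (the reading of "ten classifiers with different random
seeds"), reporting per-seed accuracies, mean ± SD, and the first seed's
confusion matrix (rows true, columns predicted, living before dead).

In the comparison experiment, classification from virtually stained crops
beats bright-field because the stain (i) converts the smooth crumple shadow —
nearly invisible to distance-1 co-occurrence statistics — into sharp,
GLCM-strong texture, and (ii) is free of the illumination/defocus/noise
nuisances that corrupt bright-field features. Both effects are properties of
the feature extractor, not extra information: the network is a deterministic
function of the bright-field image, as in any virtual-staining workflow.

## Experiment problem sizes

The figure-analog experiments run at sizes chosen to exercise the full
pipeline on one CPU core in minutes:

* staining specificity: 200 membrane / 150 nucleus training pairs of
  64×64 px, 10 epochs, 10–20 held-out scenes;
* morphometric agreement: 20 pavement scenes of 224×224 px, 12 cells each
  (cell diameter ≈ 60 px), lobe amplitude swept 0–8 across scenes so the
  population spans convex to strongly lobed cells; watershed tolerance 0.4,
  presmooth σ 1, 2× zoom. Measured R²: area 0.997, circularity 0.968,
  solidity 0.985 (n = 49 matched cells);
* speed recovery: 30 objects, 10 frames at 0.5 s and 0.28 µm/px, speeds
  1.5 ± 0.5 µm/s; R² ≈ 0.99;
* viability: stainer trained on 300 crops; classifier on 900 train / 300
  test crops per class, 10 forest seeds. Typical accuracies ≈ 0.79
  (bright-field) vs ≈ 0.88 (virtual stain).

## Known limitations

* 2-D only; no 3-D reconstruction, consistent with the underlying method.
* The numpy network is CPU-scale: suitable for the 64–384 px synthetic tasks
  here, not for training on full-resolution microscope frames.
* The log-rescaled overlap score's small-E null bias (above) means scores
  near 0 on very small images/selections should be read with that offset in
  mind.
* Morphometrics assume a single outer contour per label; cells with interior
  holes would need the hole area subtracted, which is not implemented.
* The generator's living/dead textures are a two-population caricature with
  a severity continuum; real death phenotypes are more heterogeneous still.
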