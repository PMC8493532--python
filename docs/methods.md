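# Methods

## Heart phantoms

Each phantom is an assembly of closed analytic compartments in millimetre
coordinates: the LV blood pool is a truncated half-ellipsoid capped by a
flat disk at the mitral plane, the myocardium the region between it and a
concentric epicardial half-ellipsoid, the atria upper half-ellipsoids, the
RV a laterally offset half-ellipsoid whose cavity reaches mid-septum, the
aorta a tilted capped tube, and the mitral valve a thin disk (heart models
of this kind represent the valve as a flat disk, and the pipeline keeps
that convention). Twelve shape parameters (long-axis length 70–100 mm, wall
thickness 6–14 mm, chamber radii, etc.) control the geometry; a cohort
jitters them uniformly within ±8% of the defaults, plus a small rigid pose
jitter (±3°, ±2 mm) per phantom. All phantoms are built on one fixed
template triangulation, so vertex-wise correspondence across a cohort holds
by construction — the property the shape model needs. Landmarks are template
vertices (apex = endocardial pole, mitral center = cap center, aortic valve
center = tube base center), so they survive any resampling of vertex
coordinates.

What the phantoms do *not* emulate: trabeculation, papillary muscles,
pulmonary vessels and venae cavae, pathology-specific remodeling, and
temporal deformation. Downstream stages consume only labeled geometry plus
landmarks, so passing tests demonstrates the pipeline's mechanics, not
anatomical realism of any individual structure.

## Shape model

Alignment is generalized Procrustes restricted to rotation + translation;
scale is deliberately retained because overall heart size is a genuine
anatomical mode. The iteration runs to a fixed point (mean shape RMS change
< 1e-12 mm), which makes alignment idempotent. PCA uses the thin SVD of the
(n × 3V) centered data matrix — the exact dual of the 3V × 3V covariance
eigenproblem for n ≪ 3V — with machine-noise modes (σ < 1e-10·σ₁) dropped.
The retained mode count k is the smallest reaching the variance target
(default 0.90), not a hard-coded number: on real CT-derived cohorts that
threshold lands near 9 modes, on the phantom cohort near 5, because the
phantoms have fewer independent degrees of freedom.

Sampling draws per-mode coefficients i.i.d. uniform on [−2, 2] SD units.
Uniform is the least-assuming reading of "within two standard deviations"
and guarantees the bound by construction; a truncated standard normal is
available (`distribution="truncnorm"`). All k coefficients are sampled
jointly per model; single-mode sweeps (the usual mode-variation
visualization) are a separate utility (`mode_sweep`).

## View planes and rasterization

The A4C plane is fixed by the three landmarks exactly (residuals at machine
precision); its in-plane frame puts the apex at the top of the image and
the mitral valve below it. The A2C plane rotates the A4C frame 70° about
the LV long axis — positive angles are counter-clockwise viewed from the
apex toward the base (right-handed about the apex→base direction).
Foreshortening draws one rotation within ±10° about the long axis and one
within ±5° about each of the two orthogonal short axes, all through the LV
blood-pool centroid; ranges are configurable and the drawn angles are kept
in the plane's provenance. No published parametrization exists for these
ranges; the defaults produce visible but non-pathological foreshortening.

Rasterization labels each pixel center by the compartment containing the
corresponding 3D point. Because the query points all lie in the cut plane
and compartments are watertight, the containment test is evaluated exactly
on the plane: mesh–plane intersection segments are chained into closed
cross-section polygons and pixel centers are classified by the even-odd
rule. A brute-force ray-casting point-in-mesh oracle verifies bitwise
agreement in the tests. Painting order is blood pools > myocardium > valve
disk, so nested compartments resolve deterministically (no pixel inside the
cavity is ever myocardium). Default raster: 256×256 at 0.6 mm/px (the tests
and acceptance runs use 128×128 at 1.2 mm/px, the same field of view at
half resolution, to keep CPU time in minutes).

## Pseudo rendering

Tissue codes map to fixed gray levels (pools ≈ 0.10–0.14, myocardium 0.70,
valve 0.55, intra-cone background 0.30): the values are package choices
producing ultrasound-like contrast, exposed in `GRAY_LEVELS`. The scan cone
(apex top-center, 75° opening, radius 0.92·H) hard-masks both image and
label; every emitted pair satisfies image·(1−cone) ≡ 0 and label·(1−cone)
≡ 0. Cropping targets either the whole heart or the LV (≈70% of cone
depth), followed by rotation (±10°), anisotropic squeeze (0.9–1.1) and
small translation jitter; the identical affine chain is applied to the
intensity image (bilinear) and the label raster (nearest-neighbor, because
codes are categorical). A draw whose task labels would leave the cone is
rejected and redrawn, with a 5% per-attempt shrink so a fit always exists
within the 20-attempt budget. Noise is uniform U(−a, a) inside the cone
(default a = 0.08), shadows are 1–3 angular sectors of width 5–20° and
attenuation 0.3–0.7 fanning from the cone apex, and the final blur is
Gaussian with σ = 2 px — roughly the minimum removing staircase edges at
256². Named profiles (`camus`, `echonet`, `site_a`) vary the crop mix and
depth to mimic per-dataset extraction settings.

## Translation and segmentation networks

Both networks are U-Nets built from stride-2 convolution encoders and
nearest-upsampling decoders with skip connections, instance normalization
(skipped where the feature map is ≤ 2 px) and leaky-ReLU activations. The
CycleGAN uses the canonical recipe: least-squares adversarial losses on
patch discriminators, cycle-consistency L1 with λ = 10, identity L1 with
0.5λ, Adam at lr 2e-4 (β = 0.5/0.999) with linear decay over the second
half of 200 epochs, checkpoints every 5 epochs, 8 generator down-sampling
levels at 256² (the image size must divide by 2^levels; smaller experiments
reduce the level count). No image-replay buffer is used; at the batch sizes
involved its stabilizing effect is minor. The discriminator sees the full
unmasked frame, matching standard practice. By default the last checkpoint
is used; emitting one sample per checkpoint for manual review remains
possible since every checkpoint holds the full four-network state, and
warm-starting a new run from a trained transform (`init_from`) covers the
fine-tuning use case.

The segmenter trains with pixelwise cross-entropy (Adam, lr 1e-3, batch 1,
30 epochs, one checkpoint per epoch) on [0, 1] images with no further
preprocessing. Checkpoint selection computes, per checkpoint, the median
simplicity of the predicted mask of a chosen structure (default the LV
blood pool) over an unlabeled selection set; empty predictions score 0, and
exact ties resolve to the later epoch. The selection function receives
images only, so reference labels cannot influence the choice.

All training runs on the package's own numpy autograd; gradients are
verified against finite differences in the test suite. Reduced-scale
experiments used by the tests: a 10-pair, 30-epoch overfit at 128² (4
levels, 8 base channels) reaching median LV Dice > 95, and a two-domain toy
problem (same ellipses at gray 0.25 vs 0.75 + noise, 64², 3 levels, 100
epochs, lr 1e-3) where the trained generator closes most of the interior
intensity gap. The untrained baseline for that comparison averages the gap
over five independent initializations, because a single random generator
occasionally lands near the target intensity by chance. These sizes were
chosen so each experiment completes in minutes on one core; they exercise
the full training mechanics, not full-scale image quality.

## Metrics

Areas are pixel counts. Contours are sub-pixel marching-squares boundaries;
their polylines get two passes of 3-point averaging before arc-length
measurement, since the raw marching-squares perimeter of a rasterized disk
is biased ≈5% high (chamfered staircase), which would bias simplicity low;
after smoothing a radius-50 disk scores S_p = 0.995. Simplicity of a
multi-component mask uses total area over total perimeter; the empty mask
scores 0. Dice of two empty masks returns 0 with a warning (a conservative
convention). Bias of two empty masks is undefined and raises. Mean contour
distance averages point-to-segment distances from each contour's vertices
to the other contour and is symmetrized by default (a one-directional flag
exists). The Wilcoxon signed-rank test drops zero differences (Pratt
variant by flag) and uses the exact null for n ≤ 25 without ties, the
tie-corrected normal approximation otherwise; an all-tied sample raises
rather than returning a meaningless p.

## Known limitations

Pseudo-image realism is structural, not physical: no speckle physics,
scan-line geometry or depth-dependent resolution. The CycleGAN and
segmenter are CPU-scale; full-resolution 200-epoch training is expressible
but slow, and no claim is made about segmentation accuracy on real clinical
images — validating that requires real datasets outside this package's
scope. Phantom anatomical variability is parametric and modest, so shape
models fitted to phantoms have fewer, cleaner modes than models fitted to
real anatomies.
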