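# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `paintdense`. It is the reference for what the package
computes; every number quoted here is produced by the test suite or by
`scripts/acceptance.py`, not asserted from elsewhere.

## Coordinate and grid conventions

All coordinates are 0-based and sub-pixel, with integer coordinate *i* at the
centre of pixel *i*. Conversion to any 0.5-offset dialect happens only at I/O
boundaries, so no half-pixel shift can accumulate across the summing →
training → extraction chain. The upsampled prediction grid relates to the
camera grid by `X = u·x + (u−1)/2`; pixel edges of the two grids coincide,
and the inverse is applied once, at localization extraction.

## DNA-PAINT binding model

Each docking site is an independent stationary two-state process: exponential
unbound waits with association rate `r = c·k_on` and exponential bright
dwells of mean `τ_b`. The stationary occupancy is

    p = r·τ_b / (1 + r·τ_b),

so the expected number of simultaneously bright emitters per frame is
`N_sites · p` and the emitter density is `N_sites · p / area`. The initial
state of every site is drawn from the stationary distribution, so the density
has no transient — the simulated movies are stationary from frame 0 to
arbitrary length, reflecting the absence of photobleaching in DNA-PAINT.
Concentration is the experimental knob: at low occupancy density is linear in
concentration, which is the assumption behind emulating a c₂ acquisition by
summing groups of `round(c₂/c₁)` frames of a c₁ acquisition.

Defaults: `k_on = 10⁶ M⁻¹s⁻¹`, `τ_b = 0.5 s`, 2,000 detected photons per
full-frame binding, PSF σ = 110 nm, 10 background photons/pixel/frame. These
are typical literature values for Cy3B-labelled 9-nt imagers, chosen once so
that pM-range settings land in the sparse regime (~0.03 emitters/µm²) and
nM-range settings in the dense regime (1–6 emitters/µm²). The constants are
deliberately *not* treated as validated observables — only the resulting
density is, which is why `concentration_for_density` inverts the occupancy
formula for a given field and `measured_density` estimates density from a
ground-truth table. Counting table rows per frame would overstate the
instantaneous density by `(τ_b + t_int)/τ_b` (events crossing a frame
boundary appear in two frames); `measured_density` therefore weights each
instance by its frame-overlap fraction, which is unbiased.

Events contribute photons to each frame pro-rata to their temporal overlap;
emitters are immobile within an event and have no sub-event blinking
structure — one binding is one PSF. Image formation: pixel-integrated
Gaussian (difference of error functions) per active emitter, Poisson shot
noise on photons + background, multiplication by camera gain, additive
Gaussian read noise, constant offset, rounding and clipping to the 16-bit
range. The EMCCD excess-noise factor is not modelled (gain is a plain
multiplier); for the densities and photon budgets simulated here it would
only rescale the effective SNR.

Structures: filaments are points sampled uniformly along random polylines
(microtubule-like), patches are uniformly filled disks (dense 2D clusters),
outlines are ellipse perimeters (mitochondria-like). The spec's per-structure
site densities default to values that produce strong local clustering —
deliberately harsher than a uniform field, since real tissue shows epitope
hotspots.

## Training-patch synthesis (image summing)

From a sparse movie plus its localization table, one P×P patch is cropped per
localization, centred on the integer pixel containing it (column `floor(x)`,
row `floor(y)`; crops that would leave the image are discarded and counted).
The patch's coordinate list contains *all* localizations of that frame inside
the crop, at full sub-pixel precision. High-density patches are then formed
by summing k patches drawn uniformly **without replacement within one output
and with replacement across outputs** — the same PSF can never appear twice
in one output (which would double its intensity unphysically), while tens of
thousands of outputs can still be generated from a few thousand sparse
patches. Each output is reduced by `(k−1)·offset` and clipped at zero
(clipped pixels are logged); its emitter count is conserved exactly.

k is either given or derived from a target density:
`k = max(1, round(target · (P·pixel_size/1000)² / mean_emitters_per_patch))`.
On simulated sparse input the achieved mean density lands within a few
percent of the target (the acceptance run reports the exact figure).

Both patch sizes in common use, 16 and 17 px, are supported; 16 is the
default because the three-level network halves the grid twice and therefore
needs P divisible by 4. The offset is estimated as the mean pixel value of a
closed-shutter (dark) movie.

## Network, targets, loss

The network is a compact three-level encoder–decoder written directly in
NumPy (im2col 3×3 convolutions backed by BLAS, hand-derived backpropagation,
Adam): channels (c, 2c, 4c) with c = 16 by default, 2×2 max-pooling, nearest
upsampling, skip concatenations, and a final convolution to u² channels that
a pixel-shuffle rearranges into a single map on the u-times finer grid. All
convolutions run at camera resolution, which is what makes CPU training
practical; the sub-pixel information reaches the fine grid through the
pixel-shuffle head. The output activation is linear; predictions are clipped
to ≥ 0 at inference (map values are intensities). Prediction is fully
convolutional: any H×W is reflect-padded to a multiple of 4 and the output
map cropped back, so patch-trained models predict whole frames seam-free.

Targets place, for each emitter, an impulse of mass 100 at its nearest
upsampled pixel, convolved with a Gaussian of σ = 1 upsampled pixel (kernel
mass normalized to 1, so the map sums to 100 × emitter count). The mass of
100 per emitter is the conventional scale for dense-emitter heatmap
regression; with unit-mass targets the MSE gradients are small enough that
the optimizer settles into the all-zero prediction. The loss is

    L = mean[(G_σ * ŷ − y)²] + λ·mean|ŷ|,   λ = 10⁻²,

i.e. MSE between the Gaussian-smoothed prediction and the (already smoothed)
target plus an L1 sparsity term that drives the prediction toward sharp,
near-impulse maps.

Two training configurations are distinguished deliberately. The default
`TrainConfig` mirrors the full-scale recipe (100 epochs, batch 256, learning
rate 10⁻⁵, 15 % validation) for users reproducing a full-scale run. The
desk-scale configuration used throughout the tests and the acceptance script
(`REDUCED_TRAIN_CONFIG`: 10 epochs, batch 8, Adam at 1.5·10⁻³, 24 base
filters, 10 % validation) is tuned to this reduced NumPy network by a small
seed-replicated study — a learning rate of 10⁻⁵ belongs to a much larger
model trained ~60× longer and does not move this network off its
initialization in 10 epochs, while small batches and the wider first level
measurably improve recovery of dim partial-frame emitters within the
10-epoch budget. The upsampling factor defaults
to 8; the desk-scale runs use u = 4, which keeps per-frame maps small while
its quantization limit (≈ 0.07 px per axis) is far below the benchmark's
0.5 px RMSE gate. Training is deterministic per seed (pure NumPy, one
generator for init, split and batch order).

## Localization extraction

Per frame: local maxima (a point whose value is maximal in its
`neighborhood_size` window) are collected, then greedily suppressed in order
of decreasing intensity (ties toward smaller row, then column) so no two
accepted peaks lie within the same window. With local averaging on, each
peak is refined to the intensity-weighted centroid of its window. Map
coordinates are converted back to camera pixels by the inverse grid mapping.
The numeric threshold keeps peaks strictly above it; the "auto" mode requires
an explicit target count and selects the threshold whose total localization
count across frames best matches it — the ground-truth-matching rule made
explicit and visible rather than silently coupled to a GT table. Greedy
suppression by a brighter peak never depends on the threshold, so
auto-thresholding is a pure filter on the candidate list.

## Assessment

* **Rendering**: 2D histogram on an oversampled grid; one-pixel blur is a
  Gaussian of σ = 1 rendered pixel. Total intensity equals the localization
  count up to blur truncation at the border.
* **Linking**: greedy nearest-first chaining across consecutive frames within
  `max_distance`, tolerating up to `max_dark_frames` gaps; chains merge to
  the photon-weighted mean position with summed photons.
* **Acquisition time**: computed with exact decimal (Fraction) arithmetic so
  10,000 × 0.15 s is exactly 1,500 s = 25 min, with no binary-float residue.
* **NeNA precision**: nearest-neighbour distances from each localization in
  frame t to frame t+1 are fitted by maximum likelihood with the first-order
  model `p(d) = (1−w)·d/(2σ²)·exp(−d²/4σ²) + w·2d/d_max²` for d below a
  100 nm cutoff (truncation-corrected Rayleigh plus uniform-in-area
  background). Higher-order correction terms of the full published model are
  omitted: for simulation-validated use the first-order form recovers 2, 5
  and 10 nm jitter within 10 % at ≥ 1,000 pairs, which the acceptance run
  verifies. Fewer than 100 distance samples is an error (unstable fit).
* **Cluster areas**: both images are binarized with Otsu's 256-bin threshold,
  8-connected components below `min_area_px` (default 4 rendered pixels) are
  dropped, clusters are paired by nearest centroid within 250 nm (default —
  below typical inter-synapse spacing, above registration error), and paired
  areas are fitted by least squares through the origin; Pearson r is reported
  alongside.
* **Image similarity**: a plain Pearson correlation of intensity-normalized
  images. This is an internal stand-in for the published structural
  comparison tools, which are outside this package's scope.

## The reduced-scale recovery benchmark

The acceptance benchmark trains on 5,000 summed 16×16 patches (derived from a
simulated 128×128 px sparse acquisition at 0.028 emitters/µm², summed to a
1.9 emitters/µm² target) for 10 epochs and evaluates on held-out movies of a
*uniform* 64×64 px field at 1.0 and 8.0 emitters/µm². Matching is greedy
nearest-first within 1 camera pixel. Gates: recall ≥ 0.8, precision ≥ 0.8,
RMSE ≤ 0.5 px at 1.0 /µm², and strictly lower recall at 8 /µm² (the
performance-window degradation). The uniform evaluation field is the
standard protocol for dense-emitter recovery benchmarks: it makes the mean
density the binding constraint, whereas the clustered training-style
structures contain hotspots whose local density exceeds any network's
operating window and would test the geometry, not the method. The ground
truth includes partial-frame binding instances down to arbitrarily small
photon yields; the dimmest of these (< ~5 % frame overlap) are physically
undetectable and bound recall away from 1 by a few percent.

Problem sizes throughout the tests (patch counts, frame counts, field sizes,
10 epochs, u = 4) are chosen so the whole suite and the acceptance script
each run in minutes on a single CPU; they are reduced-scale versions of the
same procedures, not different procedures.

## What the simulator does and does not capture

Captured: stationary binding statistics and their concentration scaling,
clustered target geometries, pixel-integrated PSFs, shot noise, camera
offset/gain/read noise, partial-frame events, density hotspots.

Not captured: drift (inputs are assumed drift-corrected upstream), EMCCD
excess noise and clock-induced charge, PSF aberrations and depth dependence,
imager depletion or docking-strand damage, diffusing-imager background
structure (background is uniform Poisson), localization error in the training
coordinates (the simulator provides true positions, whereas experimentally
derived training labels carry the fitting precision — on real data that error
adds in quadrature to the network's own). Passing the recovery benchmark
therefore demonstrates the correctness of the pipeline's arithmetic and the
trainability of the network on faithful synthetic data; it does not certify
performance on any particular microscope's data.

## Known limitations

* The NumPy network is CPU-bound; full-scale training (30,000 patches ×
  100 epochs) is configuration-supported but slow compared to a GPU
  framework.
* `sum_frame_groups` assumes the input movie is drift-corrected; no
  correction is applied or checked.
* The NeNA fit uses the first-order displacement model; strongly clustered
  localizations at sub-10 nm spacing would bias σ upward via the background
  term.
* Linking is greedy and nearest-first; pathological crossings of two close
  trajectories can swap chains.
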