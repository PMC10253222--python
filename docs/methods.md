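# Methods

## Coordinate and unit conventions

All coordinates, including z, are kept in pixel units: 512 px correspond
to 500 mm in-plane (1 px = 0.9765625 mm), and axial slices taken at 5 mm
intervals therefore sit at multiples of 5 / (500/512) = 5.12 px.  Using a
common unit for all three axes makes per-axis errors commensurate and
the 3D Euclidean distance meaningful.  Slice stacks are indexed
`[y, x, z]` with z = 0 the most caudal slice; landmark tables store
`(x, y, z)`.

CT stored values are used raw — no rescale slope/intercept is applied —
because the bone segmentation thresholds the stored integers directly
(≥ 1100 → bone).  The comparison is inclusive so the threshold value
itself counts as bone.  A calibration cross (rows and column 255 set to
4000) can be burnt into the most caudal slice as a fiducial; it is
retained in the network inputs by default and can be disabled in the
pipeline configuration.

In-plane compression (512 → 96 for the coarse phase) uses exact
area-weighted box resampling, implemented as a separable overlap-matrix
product.  This preserves constants exactly, is the identity when sizes
match, and is applied to raw intensities *before* thresholding, so thin
bright structures contribute their area-weighted intensity to the
downsampled cell rather than being dropped.

## The three phases

* **Phase 1**: compressed whole-volume binary stack (96 × 96 × 81 at full
  scale) → 48 outputs, the global coordinates of all 16 landmarks.
* **Phase 2**: per landmark, a 100-px full-resolution window centered on
  the phase-1 (x, y), full z extent, zero-padded outside the frame →
  3 outputs `(x_local, y_local, z_global)`.
* **Phase 3**: as phase 2 with a 50-px window centered on the phase-2
  estimate.

Crop centers are rounded to integers before the origin is computed
(`origin = round(center) − width/2`), which keeps window placement and
the remapping `global = origin + local` exact.  Windows may straddle or
leave the image border; out-of-frame voxels are zero.  The remapping
round trip is exactly lossless for coordinates on any fixed-point lattice
(the tests use 1/1024 px); for arbitrary doubles it is exact to one ulp,
since adding and subtracting the integer origin may round once.

Refinement windows are placed using only the prior (x, y); the predicted
z propagates to the output but never moves the window, because crops
always span the full z extent.

### Shift-grid augmentation

Training crops are taken at every offset of the half-open Cartesian
lattice `[-s, +s) × [-s, +s)` stepped by `d` — phase 2: s = 30, d = 10;
phase 3: s = 15, d = 5 — giving (2s/d)² = 36 offsets per case and
90 × 36 = 3240 examples per landmark at the full-scale training size.
The half-open convention is deliberate: a closed lattice would give 49
offsets (4410 examples), which contradicts the augmented-set size the
protocol is defined around, and the unshifted offset (0, 0) is always a
member.  The target moves opposite to the shift: a crop centered at
`(x + dx, y + dy)` has target `(w/2 − dx, w/2 − dy, z)` for integer
landmark coordinates.  Augmentation is in-plane only; no z shifts or
rotations are used.

## Networks and optimisation

Each regressor is a 3D residual convolutional network with a linear
(unbounded) output head: a stride-2 stem convolution, stages of residual
blocks with stride-2 downsampling at each stage entry after the first,
then either global average pooling or a flattened feature map into the
final dense layer.  The default configuration — bottleneck blocks in a
(3, 4, 6, 3) layout with 64 base channels — is the classic 50-layer
residual network (1 stem + 48 block convolutions + 1 dense).
`width_scale` multiplies every channel count so the same topology spans
full scale and desk scale.

The networks are implemented directly in NumPy with hand-written
backward passes (windowed tensor contractions for the convolutions);
analytic gradients are verified against central finite differences in
the test suite.  Design choices where the protocol is open:

* **Loss**: mean squared error on the coordinate vector — the canonical
  choice for a linear-head regressor.
* **Optimizer**: Adam at a fixed learning rate (default 10⁻³ full scale,
  8 × 10⁻³ desk scale), no schedule, no early stopping, and no
  train/validation split within the training cases.
* **Target standardization**: targets are standardized per output
  dimension before optimisation and the constants are stored with the
  weights and inverted at prediction time.  With a randomly initialised
  linear head and a few hundred optimizer steps, unstandardized targets
  of magnitude ~10²–10³ px would spend the whole budget moving the output
  bias; standardization makes the optimisation scale-free.
* **Phase-1 targets are in the global pixel frame** even though the
  input stack is compressed; this avoids an undocumented rescale at
  inference time.
* **Batch sizes/epochs** default to 8/150 (phase 1) and 16/100, 16/150
  (phases 2, 3) at full scale; the desk preset uses 15/12/12 epochs.

Weight files are single `.w` containers (NumPy archive) holding the
parameter arrays, the architecture description and the target scaler;
loading validates shapes and reproduces predictions bit-for-bit.  A full
run persists `phase1.w`, `phase2_L01.w` … `phase3_L16.w` — 33 files.

## The phantom generator

The phantom emulates the properties of the head-and-neck CT cohort that
the method's data contract depends on, not anatomy:

* binarizable bone-like structures: an ellipsoidal vault shell (slab-
  integrated voxelization so the coarse slice spacing leaves the shell
  26-connected), a mandibular arch with rami joining the skull base, and
  a small bone blob at each landmark so every landmark has a local shape
  cue and provably lies within 1.5 px of bone;
* disjoint stored-value bands: soft tissue 200–800, bone 1500–2500
  (threshold 1100 between them), optional Gaussian noise off by default;
* head centers scattered more along y than x (σ_y = 3 σ_x, truncated at
  2.5 σ), emulating patients centered left-right but positioned variably
  front-to-back — this is what makes the coarse phase genuinely harder
  along y;
* bilateral landmark pairs mirrored about the midsagittal plane, with
  per-landmark jitter; landmark z values snapped near slice planes (the
  slice is chosen from the unjittered geometry so mirror pairs share a
  slice);
* at most the configured number of slices per case; cases are
  bit-reproducible from `(seed, case_index)` and order-independent.

Geometry draws are made in normalized unit space and mapped through the
pixel-valued parameters, so scaling a spec scales every ground-truth
coordinate exactly (`PhantomSpec.scaled`).  Two presets ship: full
scale (512 × 512 × 81) and desk scale (96 × 96 × 24, all lengths scaled
by 96/512, z step unchanged at 5.12 px).

What the phantom does **not** model: realistic skull anatomy, CT physics
(beam hardening, noise spectra, partial-volume effects), pathology,
missing teeth, or inter-observer annotation ambiguity.  Passing the
desk-scale benchmark therefore demonstrates that the pipeline's
machinery — preprocessing, augmentation, training, window placement,
remapping, evaluation — is correct and that coarse-to-fine refinement
works when the signal is present; it says nothing about error magnitudes
on clinical data.

## The desk-scale benchmark

`pipeline.run_benchmark` generates a fixed-seed desk cohort (default 20
training / 10 test cases), trains all 33 networks (shallow basic-block
variant, width_scale 0.25, flattened readout — average pooling discards
too much spatial information for tiny networks to recover position), and
evaluates three-phase inference on the held-out cases.  The headline
property is monotone refinement: mean d₃ strictly decreases
phase 1 → 2 → 3, with the phase-1 vs phase-3 difference significant in
the Conover–Iman test.  Desk shift grids are ±6 step 3 and ±2 step 1 (16
offsets each), scaled from the full-scale geometry; the whole benchmark
runs in about five minutes on one CPU core.

## Statistics

`pipeline.compare_groups` implements the Conover–Iman post-hoc test:
observations are pooled and ranked (mid-ranks for ties); for groups i, j

    t = (R̄ᵢ − R̄ⱼ) / √(S² · (N − 1 − H)/(N − k) · (1/nᵢ + 1/nⱼ))

with S² the tie-corrected rank variance and H the Kruskal–Wallis
statistic; two-sided p-values come from the t distribution with N − k
degrees of freedom and are Holm-adjusted (the adjustment is not named by
the protocol; Holm is conservative and order-free).  Degenerate input
(all observations tied) yields a warning and a matrix of ones rather
than a failure.  Summary statistics pool all case × landmark
observations per phase; the standard deviation is the sample (n − 1)
form.

## Known limitations

* The desk benchmark's absolute errors reflect phantom difficulty, not
  clinical performance; full-scale training on real annotated CT is out
  of scope here.
* Thin-slice (< 5 mm) resampling, Hounsfield calibration and mesh
  reconstruction are not implemented.
* Training the full-scale 50-layer configuration in NumPy is possible
  but slow; the implementation targets correctness and desk-scale
  experimentation, not GPU-class throughput.
* The DICOM reader assumes one consistent series per directory sorted by
  slice position (ties broken by instance number) with uniform pixel
  spacing.
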