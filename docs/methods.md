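# Methods

## The problem

Through-plane phase-contrast (PC) CMR of the aortic valve acquires paired
magnitude and phase images over 20–30 cardiac frames.  The magnitude channel
shows anatomy; the phase channel encodes signed through-plane velocity up to
the VENC limit.  Quantifying net forward flow requires a per-frame valve
mask, conventionally drawn by hand.  `aortaflow` automates the mask with a
residual U-net applied to the magnitude images and integrates the masked
velocities into a cycle net flow.

## Velocity decoding

Two conversion conventions ("dialects") are implemented, selected per call
and recorded in the output:

- **phase-linear** (default): `v = P · VENC / P_max` with `P_max = 4096`,
  the conventional linear mapping of the signed phase pixel to cm/s.
- **magnitude-scaled**: `v = P · M · ASF` with `ASF = 10 π R / VENC`, where `M`
  is the raw magnitude pixel and `R` the reconstruction scale from the
  header.  Taken literally this makes velocity proportional to the magnitude
  value, so it yields calibrated cm/s only when `M · ASF` is itself
  calibrated; it likely describes a magnitude-masked phase reconstruction.
  Both dialects are shipped and round-trip exactly against the phantom's
  matching encoder; neither is asserted to be the other's "true intent".
  Note the conditioning issue: with integer phase storage the velocity
  quantization step under this dialect is `M · ASF` per phase LSB, so
  synthetic exams encoded this way use a small reconstruction scale
  (`R = 10⁻³` in the tests) to keep the step sub-cm/s.

No phase-unwrapping (anti-aliasing) or background-phase (eddy-current)
correction is applied; velocities beyond VENC pass through with a warning.

## Flow integral

`NetFlow = Σₙ Σᵢ S[n,i] · V[n,i] · a · Δt` in mL, with `S` the binary mask,
`V` the velocity map in cm/s, `a` the pixel area in cm² (header spacing in
mm², converted once by the factor 0.01) and `Δt` the frame interval in s.
Signed velocities are retained, so regurgitant flow subtracts.  `Δt` is a
single scalar; when DICOM trigger times are unevenly spaced the mean gap is
used and a warning logged, since the integral assumes uniform sampling.

## Segmentation network

A 2D encoder–decoder with skip connections between the contracting and
expanding paths.  Each resolution level is a residual block (two 3×3
convolutions with an identity shortcut, 1×1-projected when channels change);
downsampling is 2×2 max-pooling, upsampling nearest-neighbor followed by a
3×3 convolution, and the head a 1×1 convolution to two per-pixel class
logits.  Channel counts double per level.  Two profiles:

| profile | depth | base filters | input | use |
|---|---|---|---|---|
| default | 5 | 32 | 256×256 | clinical-scale images |
| reduced | 3 | 8 | 64×64 | desk-scale experiments and tests |

The exact layer dimensions of the original clinical model are not public;
depth and width are therefore configuration, with the defaults above.
Only the magnitude image is input; the phase channel is never fed to the
network.  Segmentation is per-frame (no temporal context), per-pixel argmax
over the two logits with exact ties resolved to non-valve, and inference is
deterministic (no stochastic layers).

The engine is a self-contained NumPy implementation with hand-derived
backward passes (im2col convolutions reduced to BLAS matmuls), float32
parameters and activations.  At this model scale it trains in minutes on
one CPU and is bit-reproducible for a fixed seed.  Max-pool gradients route
to the first maximum on exact ties — a valid subgradient; finite-difference
checks therefore avoid tied inputs.

## Preprocessing

Frames larger than the working resolution are bilinearly resampled to fit,
then zero-padded symmetrically to the square working size (256×256 default;
odd gaps put the extra pixel on the bottom/right).  Magnitude intensity is
min-max rescaled to [0,1] **per exam** (not per frame), computed on native
content before padding so a constant stack degenerates to zeros rather than
ones.  A geometry record makes the mapping exactly invertible for masks
(nearest-neighbor back-resampling).

## Loss and optimization

Per-pixel class-weighted softmax cross-entropy,
`loss(x, i) = −w[i] · ln(e^{x[i]} / Σⱼ e^{x[j]})`, computed via a stabilized
log-sum-exp, averaged over pixels and frames (mean reduction keeps the loss
scale-invariant in image size).  Default weights `w = (0.2, 0.8)` for
(non-valve, valve), countering class imbalance: the valve occupies a few
percent of pixels.  Weights are applied per pixel as the formula states,
not re-balanced per batch.  Optimization is RMSProp (ρ = 0.9, ε = 1e-8);
unstated hyperparameters default to learning rate 1e-3, batch size 8.

Training stops on a training-set Dice plateau: Dice is computed each epoch
on the non-augmented training images with the inference argmax rule, and
training halts once it has failed to improve by `plateau_delta` (0.002) for
`plateau_patience` (10; 2 in the desk-scale benchmark) consecutive epochs,
or at `max_epochs`.  The returned model carries the best-Dice epoch's
parameters.

## Augmentation

At batch time each (image, mask) pair receives one shared geometric
transform — random zoom (0.9–1.1), rotation (±15°), random crop to the
training size (224×224 under the default profile; 56×56 under the reduced
profile), horizontal/vertical flips (p = 0.5 each) — with the mask resampled
nearest-neighbor and re-binarized, plus Gaussian noise (σ = 0.02 of the
intensity range) on the image only.  The crop is a training-time
augmentation; inference always runs on the full working grid.  Ranges are
configuration since the original values are unpublished.

## Agreement metrics

Dice `2|A∩B|/(|A|+|B|)` and Jaccard `|A∩B|/|A∪B|` are pooled over all
frames of a case.  Surface distances operate on surface plots obtained by
zeroing valve pixels with no neighboring non-valve pixel, using
4-connectivity with the frame border counting as non-valve (the strictest
boundary rule; documented so results are reproducible).  Hausdorff distance
is the per-frame symmetric maximum of nearest-neighbor surface distances,
summarized per case as the maximum over frames; ASSD is the per-frame mean
of all distances in both directions, summarized as the mean over frames.
Both aggregations are arguments, since pooled-3D variants exist.
Conventions: both masks empty → overlap 1.0; exactly one empty → overlap
0.0 and distances NaN with a warning.  Cohort summaries report the mean
with a nonparametric percentile bootstrap CI (2000 resamples, seeded).

## Phantom generator

Each synthetic exam is a disc ("valve") on a dim background, drifting
sinusoidally by a few pixels and modulating its radius ±10% with the
velocity waveform to emulate valve motion and deformation.  Through-plane
velocity inside the disc is parabolic, `v(r) = Vmax(t)(1 − r²/R_v²)`,
driven by a half-sine systolic lobe (40% of the cycle) with an optional
negative diastolic lobe emulating regurgitation.  Defaults emulate a
clinical acquisition: 20 frames over 0.8 s, VENC 150 cm/s, 1.5 mm pixels,
peak velocity ~100 cm/s; cohort generation randomizes radius (6–11 px),
peak velocity (60–130 cm/s), noise (σ = 1–4% of full scale on both
channels), drift, and gives 20% of exams a regurgitant lobe.  Phase pixels
are produced by inverting the selected decoding dialect, stored unrounded
(so zero-noise decode is exact); integer quantization enters only on DICOM
export.  Optional artifact modes add a peri-valvular signal-void patch and
frame-misregistration jitter.  The analytic net flow
`Σₙ Vmax[n] · π (r[n]·s)²/2 · Δt` (the exact disc integral of the parabolic
profile) is the generator's ground truth.

What the phantom does **not** emulate: realistic anatomy and texture,
partial-volume effects, phase aliasing and wrap, eddy-current background
phase, k-space acquisition physics.  Passing tests therefore demonstrate
correctness of the pipeline's arithmetic, training machinery and
bookkeeping — not clinical-grade segmentation difficulty: the bright-disc
task is far easier than clinical valve delineation, and held-out Dice near
1.0 on phantoms says nothing about Dice on patients.

A numerical note: rasterization error of the discrete flow against the
closed form decays like O(1/r²) in the disc radius in pixels for generic
sub-pixel disc centers; a disc centered exactly on the pixel grid enjoys
accidental error cancellation that masks this decay, so convergence
experiments use offset, drifting centers.

## Desk-scale benchmark

`aortaflow.benchmark.heldout_phantom_experiment` trains the reduced profile
on 60 phantom exams of 6 frames each and evaluates 20 held-out exams
(disjoint seeding), measuring Dice/Jaccard/HD/ASSD and net-flow agreement.
Flow agreement compares the integral under the predicted mask against the
same integral under the truth mask on identical decoded velocities,
isolating segmentation error the way a manual-vs-automated comparison
does.  Six frames per exam and 12 epochs with patience 2 keep a full cycle
to roughly two minutes on one CPU; these problem sizes are the package's
desk-scale study conditions, stated here so results are interpreted at the
right scale.

## DICOM dialects

Public DICOM tags cover geometry (PixelSpacing) and timing (TriggerTime);
classic 2D PC exports have no public tag for VENC or the reconstruction
scale, and each vendor uses a different private block.  The reader resolves
these through a configurable dialect mapping (field → pydicom keyword or
`(group, element)` tag); the package's own writer stores them in a private
creator block ("AORTAFLOW", group 0x0011).  Frames are ordered by trigger
time, never by filename.

## Known limitations

- Single 2D through-plane series per exam; no 4D flow, no multi-slice.
- No aliasing correction, background-phase correction, or test-time
  augmentation/ensembling.
- The NumPy engine is CPU-only and single-batch; it is sized for this
  model family, not for general deep learning.
- Cohort statistics of the clinical validation type (Bland–Altman against
  manual readers, ICC, regression) are out of scope; the evaluation
  harness stops at per-case agreement metrics and their bootstrap CIs.
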