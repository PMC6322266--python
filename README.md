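# aortaflow

Fully automated aortic flow quantification for phase-contrast (PC) cardiac
MRI: a residual U-net segments the aortic valve on magnitude images, phase
pixels are decoded to through-plane velocities, and the masked velocities
are integrated into cycle net flow — plus a synthetic phantom generator
with analytic ground truth so the whole pipeline can be trained and
verified on one CPU with no clinical data.

Intended users: CMR researchers automating PC flow analysis, and developers
who need a transparent, dependency-light reference implementation of the
segmentation-to-flow pipeline with oracle-tested numerics.

## Method

A through-plane PC acquisition yields paired magnitude/phase stacks over
the cardiac cycle.  The pipeline is:

1. **Segmentation.** Magnitude frames are resampled/zero-padded to a square
   working grid (256×256 by default) and min-max rescaled per exam; a 2D
   residual U-net (encoder–decoder with skip connections, residual blocks
   per level) emits per-pixel logits for valve/non-valve; masks are the
   per-pixel argmax, mapped back to native geometry.  Training minimizes a
   class-weighted softmax cross-entropy,
   `loss(x, i) = −w[i] · ln(e^{x[i]}/Σⱼ e^{x[j]})` with `w = (0.2, 0.8)`,
   under RMSProp, with zoom/rotation/crop/flip/noise augmentation and
   stopping on a training-set Dice plateau.
2. **Velocity decoding.** `v = P · VENC / P_max` (phase-linear, default) or
   `v = P · M · ASF` with `ASF = 10πR/VENC` (magnitude-scaled dialect).
3. **Flow integration.**
   `NetFlow = Σₙ Σᵢ S[n,i] · V[n,i] · a · Δt` (mL), with `S` the binary
   mask, `a` the pixel area in cm², `Δt` the frame interval in s; signed
   velocities make regurgitant flow subtract.
4. **Evaluation.** Dice, Jaccard, Hausdorff and average symmetric surface
   distance between mask stacks (surfaces = valve pixels with a non-valve
   4-neighbor), per-case reports with bootstrap CIs, and a k-fold
   cross-validation harness.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```sh
# simulate a cohort of 10 synthetic exams with ground truth
aortaflow simulate --out-dir cohort --n 10 --seed 1

# train the reduced desk-scale profile on it
cat > reduced.yaml <<EOF
model: {depth: 3, base_filters: 8, input_size: 64}
train: {crop_size: 56, max_epochs: 10, plateau_patience: 2}
EOF
aortaflow train --data-dir cohort --out-dir run --seed 1 --config reduced.yaml

# quantify flow on one exam with the trained checkpoint
aortaflow flow --exam cohort/phantom000.npz --checkpoint run/checkpoint.npz --out-dir flow_out
```

The train step prints, for example:

```
trained 10 epochs; final train Dice 0.9999
```

and the flow step:

```
net 76.90 mL (forward 76.99, backward -0.09)
```

meaning a cycle-integrated net forward volume of ~76.9 mL through the
valve plane with a negligible regurgitant (negative) component —
consistent with this phantom's forward-only waveform (the small backward
term is decoded pixel noise).  `cohort/manifest.csv` lists each exam's
analytic ground-truth flow for comparison (76.81 mL here, i.e. the
automated measurement is within 0.2%).  Identical seeds reproduce
identical outputs bit for bit.

The same pipeline is available as a library (`aortaflow.phantom`,
`aortaflow.training`, `aortaflow.model`, `aortaflow.velocimetry`,
`aortaflow.metrics`), including six-fold cross-validation via
`aortaflow.training.cross_validate`.

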