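# Methods

## Problem and model

The semicircular canals are segmented from CT volumes as a binary
voxel-labelling problem with extreme class imbalance (target prevalence
well under 1%). The model is a 3D U-Net encoder–decoder whose skip
connections are replaced by attention modules:

* **Spatial squeeze-and-excitation (sSE).** For an encoder feature map
  `U0 ∈ R^{C×D×H×W}`, a 3×3×3 convolution with one output channel produces
  a projection `U1 ∈ R^{1×D×H×W}`; the gated output is
  `U2 = σ(U1) · U0`. Since `σ(U1) ∈ (0,1)`, sSE can only attenuate
  activations, never amplify them.
* **Global attention upsample (GAU).** Given a low-level map `F1`
  (C_L channels) and the next-deeper map `F2` (C_H channels at half
  resolution), global average pooling of `F2` followed by a 1×1×1
  convolution + batch norm + ReLU produces a channel gate `W1 ∈ R^{C_L}`;
  `F1` is transformed by a 1×1×1 convolution + BN + ReLU to `F3`;
  `F2` is upsampled by a transposed convolution + BN to `F4`; the stage
  output is `F5 = W1 ⊙ F3 + F4`.

The decoder cascades one GAU per resolution level starting at the
bottleneck, and a 1×1×1 convolution maps the full-resolution features to
one logit channel. Six variants are wired for ablation: a plain 3D U-Net
(transposed-conv upsampling + concatenation skips + double-conv blocks),
GAU-only, sSE-only (sSE on every encoder level, baseline decoder), the two
sequential attention orders, and the parallel elementwise sum
`sSE(F1) + GAU(F1, F2)`. The spatial-first sequential order is the
default. In sSE-containing attention variants, sSE is also applied to the
bottleneck feature map before the first GAU (flag `sse_on_bottleneck`).
The three combined arrangements share identical parameter counts (same
submodules, different wiring); this is asserted in the tests.

### Design choices where the architecture description is open

* **Bottleneck width.** Encoder widths are stated as 32/64/128 for the
  first three levels; the fourth continues the doubling pattern to 256
  (configurable).
* **GAU gate path.** How the pooled C_H-vector is matched to C_L channels
  is not fully specified; we use a 1×1×1 convolution + BN + ReLU, the
  Pyramid-Attention-Network-style choice.
* **GAU upsampling anisotropy.** A transposed convolution with kernel
  [1,4,4] and stride [1,2,2] cannot restore a depth axis halved by 2×2×2
  pooling. The default `gau_upsample_mode='isotropic'` uses kernel
  [4,4,4]/stride [2,2,2]; `'paper_literal'` keeps the anisotropic
  upsample and pairs it with [1,2,2] pooling so shapes remain consistent
  (the depth axis is then never downsampled).
* **Parallel-arrangement projection.** The sSE output already carries C_L
  channels (it gates the same tensor the GAU consumes), so the parallel
  sum needs no extra projection convolution.
* **Initialisation.** Kaiming fan-in normal for convolutions, BN scale 1 /
  shift 0, all driven by the config seed, so builds are bit-reproducible.

## Training

Patches are cropped so that **every** training patch contains at least one
foreground voxel: the set of valid crop origins (windows with non-zero
label sum, computed exactly with a 3D summed-area table) is sampled
uniformly. Patches are sampled fresh each step; no epoch structure or
data augmentation is imposed.

The loss is the soft Dice loss with smoothing constant `s = 1e-5`
(guarding the 0/0 case on all-background patches; at binary predictions
and `s→0` the loss equals `1 − DSC`). The optimizer is Adam with
β₁ = 0.97 (the "momentum" knob; Adam has no separate momentum term),
β₂ = 0.999, classic L2 weight decay 5×10⁻⁴ added to the gradient; an
SGD+momentum switch is provided. Intensities are z-score normalised per
volume before the network.

Two named profiles fix the remaining scales:

| profile | channels | patch (D,H,W) | batch | lr | purpose |
|---|---|---|---|---|---|
| `paper_profile` | 32/64/128/256 | (32, 64, 64) | 8 | 1e-4 | full-scale protocol |
| `tiny_profile` | 8/16/32/64 | (16, 32, 32) | 2 | 3e-2 | desk-scale CPU runs |

The desk-scale learning rate 3e-2 is chosen so that a few hundred Adam
steps suffice for convergence on phantom data; the full-scale profile
keeps the protocol value 1e-4, which assumes GPU-scale step counts.

**Validation and checkpointing.** At a configurable interval the model is
evaluated by full sliding-window inference on the validation volumes; the
checkpoint with the best mean validation DSC is retained. The total step
count is fully configurable (no canonical value exists).

**Batch-norm recalibration.** On short CPU runs the exponential running
statistics of batch norm lag behind rapidly-moving weights, and the GAU
gate normalises a C×1×1×1 vector whose within-batch variance is degenerate
at small batch sizes. Before validation and before the final checkpoint
is captured, the running statistics are therefore recomputed as exact
cumulative averages over `bn_refresh_batches` (default 10) freshly sampled
training batches. Evaluation mode keeps the standard contract (stored
statistics); training mode uses batch statistics.

**Divergence.** A non-finite loss aborts with `TrainingDiverged`.

## Inference

Whole volumes are swept with overlapping patches (defaults: 64×64×32
patches, steps 28/28/8 in X/Y/Z; internally depth-first). Window start
positions are `0, step, 2·step, …` plus one final start clamped to
`extent − patch` when the grid does not align, so coverage is complete
(the full-size 512×512×64 case aligns exactly: 17×17×5 = 1445 windows).
Raw logits are accumulated into a sum grid, a count matrix records
per-voxel coverage, and the averaged logits pass through sigmoid and a
0.5 threshold (configurable). A flag averages post-sigmoid probabilities
instead; for any spatially constant model the two coincide.

## Metrics

* `DSC = 2|P∩G| / (|P|+|G|)`.
* `AVD = max(d(P,G), d(G,P))` with `d(A,B)` the mean over `a∈A` of the
  nearest-neighbour Euclidean distance to `B`, in physical mm (voxel
  offsets × spacing).
* `ASD` pools nearest-surface distances symmetrically over both masks'
  surface voxels, where a surface voxel has at least one face-adjacent
  (6-connectivity) background or out-of-grid neighbour. 6-connectivity
  with the grid boundary treated as background is the most common
  convention; it is pinned by brute-force oracle tests.

Nearest-neighbour queries use a KD-tree, which is exact; the tests verify
agreement with all-pairs brute force to 1e-9. Empty masks (or empty
surfaces) raise a hard error rather than returning a sentinel, since a
silent 0 or ∞ would corrupt per-case averages; the per-case report
surfaces such cases as NaN rows with a note.

## Synthetic phantoms

Each phantom places `n_canals` (default 3) circular arcs per side (both
sides by default) inside the volume: each arc spans `arc_fraction`
(default 2/3) of a circle of `canal_diameter_mm` (default 6.5 mm), lies in
one of three mutually orthogonal canonical planes jittered by a small
random rotation (±12°), and is rasterised as a tube of `tube_radius_mm`
(default 0.75 mm, a realistic lumen radius) around the densely sampled
polyline — a voxel is foreground iff its centre lies within the tube
radius of the polyline (exact point-to-segment distances). Intensities
are a soft-tissue-like background (50), a brighter bone-like shell
(700, 1 mm thick) around each tube, a darker fluid-like lumen (−100),
plus additive Gaussian noise (σ = 25, giving a lumen/background contrast
of 6σ). Voxel centres sit at `(index + 0.5) · spacing`.

The default geometry matches the documented study conditions — 512×512×64
voxels at 1 mm isotropic spacing, label prevalence far below 1% — and the
default dataset split is 26/7/6 volumes with per-volume seeds derived
deterministically from one master seed.

What the phantoms do **not** model: temporal-bone anatomy beyond the
canal tubes, real CT reconstruction physics (beam hardening, streaks,
partial-volume mixtures), anatomical variability of canal shape, or
clinical HU statistics (none are published for this dataset; the
intensity levels are free parameters, not claims about clinical data).
Passing tests therefore demonstrate that the architecture, loss, sampler,
inference and metrics are implemented correctly and that the network can
learn tubular low-prevalence targets — not clinical-grade accuracy.

## Problem sizes used in tests and the acceptance script

Correctness tests run on reduced grids (8³ metric masks, 24–48-voxel
phantom volumes, 4–8-channel networks); the learning checks use the
desk-scale profile — a 200-step single-patch overfit and a 500-step run
on eight 32×64×64 phantoms with two held-out volumes. The sliding-window
coverage contract is checked on the full 512×512×64 geometry with a
constant-logit stub model. These sizes are the package's own desk-scale
choices; the full-scale profile is provided for GPU-class reproduction.

## Known limitations

* CPU-only numpy backend: full-scale (32/64/128/256-channel) training is
  impractical here; the full profile exists for completeness and for
  porting the configuration to a GPU framework.
* Batch-norm behaviour at batch size 1 with the GAU gate is intrinsically
  degenerate (zero within-batch variance); the recalibration step
  mitigates but does not remove this — prefer batch sizes ≥ 2.
* Desk-scale training exhibits seed-to-seed variance in held-out DSC;
  the trained-beats-untrained margin is large in all observed seeds, but
  absolute DSC values on phantoms are not comparable to clinical results.
* No test-time augmentation, Gaussian window blending, or
  connected-component post-processing (deliberately out of scope).
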