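# canalseg

Automatic segmentation of the **semicircular canals** — the three
membranous tubes of the inner-ear vestibular system, each spanning roughly
two-thirds of a circle of ~6.5 mm diameter — in volumetric CT, for
researchers and engineers working on computer-aided otology. The target
occupies well under 1% of a 512×512×64 CT volume, an extreme class
imbalance that defeats plain thresholding and region growing.

The package implements an **attention-augmented 3D U-Net**:

* **Encoder** — double 3×3×3 conv + BN + ReLU blocks at widths
  32/64/128/256 separated by 2×2×2 max pooling (8× downsampling at the
  bottleneck).
* **3D spatial squeeze-and-excitation (sSE)** on each encoder level: a
  3×3×3 convolution squeezes channels to a one-channel projection `U1`,
  and `U2 = σ(U1) · U0` re-weights every spatial position.
* **3D global attention upsample (GAU)** decoder stages replacing skip
  connections: globally average-pooled high-level features are projected
  to a channel gate `W1`; the low-level map is transformed by a 1×1×1
  conv + BN + ReLU into `F3` and gated channel-wise; the high-level map is
  upsampled by transposed convolution into `F4`; the stage emits
  `F5 = W1 · F3 + F4`.
* Six wiring variants for ablation: `baseline_3dunet`, `gau_only`,
  `sse_only`, `sequential_spatial_first` (default), 
  `sequential_channel_first`, `parallel`.

Training minimises the soft Dice loss
`L = 1 − (2 Σ pᵢgᵢ + s) / (Σ pᵢ + Σ gᵢ + s)` over patches sampled so that
every crop contains part of a canal; whole volumes are segmented by
overlap-averaged sliding-window inference (64×64×32 patches, steps 28/28/8
in X/Y/Z), and predictions are scored with DSC, average Hausdorff distance
(AVD, mm) and average symmetric surface distance (ASD, mm).

Because clinical canal CT datasets are generally not redistributable, the
package ships a **synthetic canal-phantom generator** reproducing the
documented data statistics (volume geometry, tubular 2/3-circle targets,
<1% foreground), so the entire pipeline is buildable and testable without
patient data. The neural-network layer beneath the model is a
self-contained numpy autograd core (3D conv/transposed-conv/pooling/batch
norm with reverse-mode differentiation), so the package has no
deep-learning-framework dependency and runs on any CPU.

## Worked example

```python
from canalseg import CanalSegmenter, PhantomSpec, generate_dataset

spec = PhantomSpec(volume_shape=(32, 64, 64), bilateral=False)
train_vols, _, test_vols = generate_dataset(spec, 8, 0, 2, seed=11)

est = CanalSegmenter(encoder_channels=(8, 16, 32, 64),
                     patch_size=(16, 32, 32), batch_size=2,
                     learning_rate=3e-2, max_steps=500,
                     validation_interval=0,
                     sliding_steps=(8, 16, 16), seed=0)
est.fit(train_vols)
print(est.evaluate(test_vols).to_string(index=False))
```

```
    case      dsc   avd_mm   asd_mm note
Sample 1 0.900585 0.283830 0.160212
Sample 2 0.937853 0.167738 0.093783
    Mean 0.919219 0.225784 0.126998
```

Each row scores one held-out phantom: `dsc` is voxel overlap (1.0 =
perfect), `avd_mm`/`asd_mm` are mean voxel- and surface-distance errors in
millimetres (0 = perfect). This 500-step desk-scale run (≈100 s on one
CPU) reaches DSC ≈ 0.92 on held-out phantoms; an untrained network scores
≈ 0.001.

The same pipeline is available from the shell:

```bash
canalseg generate --out data --n-train 8 --n-val 2 --n-test 2 --seed 11
canalseg train   --config cfg.yaml --data data --out model --seed 0
canalseg predict --checkpoint model/checkpoint.npz --in data/test/test_000_img.nii.gz --out pred.nii.gz
canalseg evaluate --pred pred.nii.gz --truth data/test/test_000_lbl.nii.gz --out report
canalseg ablate  --variants baseline_3dunet,sequential_spatial_first --data data --out ablation
```

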