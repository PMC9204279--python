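# msfa-seg

Automatic thyroid-gland segmentation on radiotherapy-localization CT with
**MSFA-U-Net** — a U-Net whose encoder is rebuilt around HRNet-style parallel
multi-resolution branches with repeated multi-scale feature fusion, and whose
convolution blocks carry channel squeeze-and-excitation (cSE) attention with
residual shortcuts.

The thyroid is an organ at risk in head-and-neck and breast radiotherapy:
exceeding ~26–30 Gy mean dose raises the risk of hypothyroidism, so the gland
must be delineated on every planning CT. It is small, bilobed, and surrounded
by vessels and soft tissues of nearly identical attenuation, which makes
manual contouring slow and plain encoder–decoder networks prone to over- and
under-segmentation at the edges.

Because clinical planning CTs cannot be redistributed, the package ships a
deterministic **phantom generator** that emulates the setting — HU-valued
slices with a bilobed gland (60–100 HU) on neck soft tissue (40 HU),
surrounded by vessel-like confounders drawn from the *same* HU range, plus
Gaussian noise — so the entire pipeline (DICOM/PNG I/O, preprocessing,
training, evaluation) runs end to end with no external data.

## Model

* Encoder stage *k* holds branches 0..*k* at resolutions `full / 2^i` with
  `base_channels · 2^i` channels. Each branch runs an **attention residual
  block**; branches then exchange information via multi-scale fusion
  (elementwise sum of identity / 3×3 stride-2 conv / 3×3 transposed-conv
  transitions). Downsampling is by stride convolution, not max pooling.
* Attention residual block:
  `cSE(ReLU(BN(conv3×3(ReLU(BN(conv3×3(x))))))) + BN(conv1×1(x))`, where the
  cSE gate is `σ(W₂ ReLU(W₁ GAP(x)))` with `W₁` halving the channel count.
* Decoder: U-Net merge-up (transposed conv → skip concatenation → dropout
  0.2 → attention residual block), final 1×1 conv + sigmoid.
* Training: soft Dice loss `DL = 1 − (2|X∩Y| + ε)/(|X| + |Y| + ε)` (robust to
  the extreme foreground/background imbalance of a small gland), Adam,
  batch 2, initial learning rate 2·10⁻⁴ with staircase exponential decay
  (×0.96 every 300 steps).
* Evaluation: DSC, JSC, PPV, SE and the exact symmetric Hausdorff distance,
  reported per case and as mean ± std with box-plot summaries.

The network, backpropagation and optimizer are implemented in pure
numpy (`msfaseg.nn`, a compact reverse-mode autodiff engine); gradients are
verified against finite differences and convolutions against
`scipy.signal` in the test suite.

## Worked example

```bash
msfa-seg phantoms --n 80 --out data/ --seed 1 --image-size 64
msfa-seg train --config examples/train_small.yaml --data data/ --out run/
msfa-seg predict --ckpt run/best.npz --data data/ --out preds/
msfa-seg eval --pred preds/ --gt data/ --out report.csv
```

The same experiment through the library (≈2 minutes on a laptop CPU):

```python
from msfaseg.experiments import phantom_study
study = phantom_study(seed=1)   # 80 phantoms, 60/10/10 split, 25 epochs
print(study["report"].summary_table())
```

```
metric  mean ± std
DSC   0.92 ± 0.02
JSC   0.86 ± 0.03
PPV   0.91 ± 0.01
SE    0.94 ± 0.04
HD    1.85 ± 0.62
```

DSC/JSC/PPV/SE are overlap ratios in [0, 1] (1 = perfect agreement with the
reference masks on the 10 held-out test phantoms); HD is the worst
boundary-to-boundary disagreement in pixels — here under 2 px on 64×64
slices. These numbers characterize the phantom benchmark, not clinical CT.

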