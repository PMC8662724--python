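# maffresunet

Automatic segmentation of gliomas in multimodal brain MRI with
**MAFF-ResUNet** — a residual U-Net whose decoder feature maps are fused by
a multi-scale attention feature fusion (MAFF) head.

Gliomas are evaluated in three *nested* subregions derived from the BraTS
label convention (0 background, 1 necrosis/non-enhancing tumor, 2 edema,
4 enhancing tumor):

* **WT** — whole tumor, labels {1, 2, 4},
* **TC** — tumor core, labels {1, 4},
* **ET** — enhancing tumor, label {4},

with ET ⊆ TC ⊆ WT. Each case provides four co-registered, skull-stripped
3D volumes (T1, T1ce, T2, Flair) that are z-scored, sliced axially,
filtered to tumor-containing planes, center-cropped, and stacked as a
4-channel 2D input. The network predicts three independent sigmoid
probability maps, one per subregion.

The package targets researchers who want a fully inspectable, CPU-scale
reference implementation of this architecture: every stage — phantom data
generation, preprocessing, the network, the composite loss, the optimizer
schedule, and the evaluation metrics — is plain numpy, tested against
independent oracles, and bit-reproducible for a fixed seed. A bundled
synthetic phantom generator emulates the BraTS layout (nested ellipsoidal
tumors, per-modality tissue contrasts), so the whole pipeline runs without
downloading any external dataset.

## Model

The down path has four residual encoder blocks (two 3×3 conv + BN + ReLU
with an additive shortcut, then 2×2 max-pooling) and a residual
intermediate layer — five residual blocks in total. The up path mirrors it
with bilinear up-sampling and skip connections. The four decoder outputs
are projected to C channels, resampled to input resolution (pyramid levels
F₁..F₄) and concatenated into the hybrid map F_m ∈ R^{4C×H×W}. Per level,
an attention feature block computes

    A_i = softmax( up×4( g( concat(F_i, conv1×1(F_m)) ) ) ),
    g(x) = conv1×1( pool( conv3×3( pool( conv3×3(x) ) ) ) )

with BN + PReLU after each convolution in g. A_i re-weights F_m, the
attended map is concatenated with F_i and refined back to C channels; the
four refined maps are mapped to class logits, averaged and passed through
a sigmoid.

Training minimizes the composite objective

    Loss = α·BCE + β·(1 − (2|p∩g| + ε)/(|p| + |g| + ε)),
    α = 0.5, β = 1, ε = 1e-5,

per subregion channel (averaged), with Adam (β₁ = 0.90, weight decay 1e-4)
and the poly schedule lr = lr_init·(1 − iter/max_iter)^0.9, lr_init = 3e-4.
Evaluation reports IoU, sensitivity, PPV, Dice (DSC) and the exact
symmetric Hausdorff distance between mask boundaries, aggregated as
slice-level mean ± SD.

## Worked example

```python
from maffresunet import (PhantomSpec, generate_case, preprocess_case,
                         slice_and_filter, make_split)
from maffresunet.model import MAFFResUNet, ModelConfig
from maffresunet.train_eval import TrainConfig, train, evaluate

case = preprocess_case(generate_case(PhantomSpec(seed=0), 0))
pairs = slice_and_filter(case, crop_size=64)
split = make_split(pairs, (0.8, 0.1, 0.1), seed=42)

model = MAFFResUNet(ModelConfig(base_filters=2, fusion_channels=4, seed=0))
cfg = TrainConfig(lr_init=5e-3, batch_size=4, max_iter=30, seed=0,
                  checkpoint_every=1000)
state = train(model, pairs, None, cfg)
report = evaluate(model, pairs, cfg)
```

This prints (via the obvious format calls):

```
10 tumor-containing slices from case phantom_0000_000
split sizes: 8/1/1
loss: 1.2761 -> 0.9613
WT: DSC 0.912 +/- 0.029, HD 2.32 mm
TC: DSC 0.444 +/- 0.325, HD 7.08 mm
ET: DSC 0.080 +/- 0.144, HD 11.68 mm
```

After only 30 steps the narrow demonstration model already segments the
whole tumor well (DSC 0.91) while the smaller nested subregions still lag
— the expected ordering, since TC and ET occupy far fewer pixels. The
200-step experiment below drives all three to DSC ≈ 1 on its training
slices. `state.history` holds the per-step learning rate and loss;
`report` serializes to CSV/JSON.

The same workflow is available from the shell:

```bash
maffresunet phantom --out raw/ --n-cases 4 --seed 0
maffresunet preprocess --data raw/ --out slices/ --config config.yaml
maffresunet train --data slices/ --out run/ --config config.yaml
maffresunet evaluate --checkpoint run/best.npz --data slices/ --out report.csv
```

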