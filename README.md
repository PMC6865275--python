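# gridattn

Attention-based classification of high-resolution esophageal
histopathology tissue images from **tissue-level labels only** — no
lesion bounding boxes — together with the sliding-window baseline it is
compared against, a statistical evaluation toolkit, and a synthetic
tissue generator that makes the whole pipeline runnable on a laptop.

## Who this is for

Researchers in computational pathology who want a compact, fully
inspectable reference implementation of grid-based soft attention for
whole-tissue classification: every stage — preprocessing, feature
extraction, attention, training, visualization, statistics — is plain
NumPy/SciPy code with tests, not a framework wrapper.

## The model

A tissue image is tiled into an r × c grid of 492-px cells (resized to
224 px, standardized by training-set channel statistics). A shared CNN
backbone maps each cell to a k-vector, forming the grid feature map
**U** ∈ R^{r×c×k}. F learnable 3-D convolutional filters of size
k × d × d (d = 3; zero padding 0 in depth, 1 in height/width) score the
grid; each filter's map is softmax-normalized over the r·c positions
into an attention map **α**_f ≥ 0, Σ α_f = 1, which weights an affine
combination of cell features:

```
z_f = Σ_ij α_f[i,j] · U[i,j,·],   z = concat(z_1 … z_F)
```

Dropout (p = 0.5) and one fully connected layer map z to the four class
logits (normal, BE-no-dysplasia, BE-with-dysplasia, adenocarcinoma;
BE = Barrett esophagus). Training uses cross-entropy against the
tissue label alone; because the attention module is convolutional, the
same model handles any grid shape. The baseline sliding-window method
— a 224-px crop classifier trained on annotated lesion boxes plus a
tuned vote-counting heuristic — is included for paired comparison and
fails loudly without annotations, which the attention model never needs.

## Worked example

```python
import numpy as np
from gridattn.attention import AttentionConfig, AttentionModel
from gridattn.backbone import make_backbone
from gridattn.inference import predict
from gridattn.preprocessing import compute_normalization_stats
from gridattn.synthetic import generate_tissue_image, sample_dataset_specs
from gridattn.training import TrainConfig, initialize_weights, train

samples = [(generate_tissue_image(s).pixels, s.label)
           for s in sample_dataset_specs(100, seed=1)]
stats = compute_normalization_stats(img for img, _ in samples)
model = initialize_weights(
    AttentionModel(backbone=make_backbone("tiny", feature_dim=16, seed=0),
                   config=AttentionConfig(n_filters=8), seed=0), seed=0)
model, log = train(samples, model,
                   TrainConfig(total_epochs=20, cycle_length=20,
                               augment=False, seed=0), stats=stats)

tests = [generate_tissue_image(s) for s in sample_dataset_specs(20, seed=99)]
preds = [predict(t.pixels, model, stats) for t in tests]
acc = np.mean([p[0] == t.label for p, t in zip(preds, tests)])
print(f"held-out accuracy on 20 tissues: {acc:.2f}")
cls, probs, amap = preds[0]
print(f"first tissue: true={tests[0].label} predicted={cls} probs={np.round(probs, 3)}")
```

prints, for this seed (about two minutes on one CPU):

```
held-out accuracy on 20 tissues: 1.00
first tissue: true=be_no_dysplasia predicted=be_no_dysplasia probs=[0.001 0.719 0.174 0.107]
```

The first held-out tissue, a Barrett esophagus without dysplasia, is
classified correctly with probability 0.719, and all 20 held-out
tissues are classified correctly; `amap.alpha` holds the 8 attention
maps over the 3 × 4 grid, each summing to 1. The scripts in
`examples/` extend this to attention-map
overlays, the sliding-window baseline, and full metric reports
(one-vs-rest accuracy/recall/precision/specificity/F1 with bootstrap
95% CIs, McNemar–Bowker comparisons, ROC/AUC). `docs/methods.md`
documents the model, the training recipe, and what the synthetic data
does and does not demonstrate.

## Command line

```bash
gridattn synth --n 100 --out data/ --seed 0          # synthetic dataset
gridattn train --manifest data/manifest.csv --out runs/attn
gridattn predict --model runs/attn/model.npz --stats runs/attn/channel_stats.json \
                 --manifest data/manifest.csv --out preds.csv --save-attention maps/
gridattn evaluate --pred preds.csv --truth data/manifest.csv --out metrics.json
gridattn baseline --manifest train.csv --boxes data/boxes.csv \
                  --val-manifest val.csv --test-manifest test.csv --out base.csv
```

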