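# ingseg

Weakly-supervised ingredient segmentation from the feature maps of a
gated-CNN single-ingredient classifier.

The classifier ("AttNet") is a stack of eight gated blocks
(conv → batch-norm → sigmoid score → element-wise product) trained with
image-level labels only, either on leaf labels (SLM) or on all four levels
of an ingredient taxonomy with a descending weighted loss (MLM). Because
classification logits are the global average pool of a grid with one
channel per class, the last stage's activations act as per-class spatial
evidence. Two procedures turn that grid into segmentation masks:

* **Method 1** — keep channels whose sigmoid-normalized global mean exceeds
  0.5, merge transitively all positively-correlated channels, binarize each
  merged map.
* **Method 2** — k-means the per-pixel feature vectors into K clusters
  (K + 1 when a uniform blue background is present; the cluster overlapping
  the blue region most is dropped).

Masks are upscaled (nearest-neighbour) to image resolution and multiplied
into the image to cut out segments, then scored with five
recognition-oriented metrics: IoU, Dice, Purity, Entirety and LoGTs
(fraction of ground-truth foreground missed entirely).

The whole stack is numpy-based (no GPU framework needed): convolution,
batch-norm and the gated activation ship with hand-written backward passes
and an Adam optimizer, validated by numerical gradient checks.

A seeded synthetic generator (`ingseg.synthetic`) renders single-"ingredient"
texture images organised by class/variant, plus multi-ingredient composites
with exact label maps and the blue-background evaluation convention, so the
full pipeline is testable offline.

## CLI

```bash
# synthetic dataset (+ composites with ground truth)
ingseg synth --classes 8 --variants 2 --images-per-variant 6 --size 64 \
             --scenes 4 --seed 0 --out data/

# train a single-level (slm) or multi-level (mlm) model
ingseg train slm --data data/ --epochs 30 --out model/

# segment one image
ingseg segment --model model/model.npz --image data/scenes/scene_000.png \
               --method 2 --k 2 --background-blue --out preds/scene_000

# score predictions against label maps
ingseg evaluate --pred-dir preds/ --gt-dir gts/ --out report.csv

# or the whole pipeline from a YAML config
ingseg run --config run.yaml
```

`run.yaml` needs at least `taxonomy_path` and `out_dir`; see
`ingseg.io.RunConfig` for every knob. Each run writes its config hash and
seed into all artifacts so it can be reproduced exactly.

## Layout

| path | contents |
|---|---|
| `src/ingseg/taxonomy.py` | four-level taxonomy model, validation, label lifting |
| `src/ingseg/nn/` | numpy conv-net primitives with backprop + Adam |
| `src/ingseg/attnet.py` | AttNet variants, multi-level model, feature maps, checkpoints |
| `src/ingseg/training.py` | SLM/MLM training, weighted multi-level loss, metrics, 80/20 split |
| `src/ingseg/segmentation.py` | Methods 1 & 2, mask upscaling, segment extraction |
| `src/ingseg/seg_metrics.py` | IoU / Dice / Purity / Entirety / LoGTs + aggregation |
| `src/ingseg/synthetic.py` | seeded texture images, composite scenes, label maps |
| `src/ingseg/io.py`, `cli.py` | formats, run config, pipeline, `ingseg` CLI |
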