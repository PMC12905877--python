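# plumcma

Tooling for plum surface-defect detection built around five defect classes
(diseased, insect-damaged, bird-pecked, cracked, normal):

- **`plumcma.synthetic`** — deterministic generator of stylized orchard images
  with YOLO-format ground truth, standing in for field-collected data.
- **`plumcma.data`** — YOLO label IO, manifests, class statistics, and the
  stratified 7:2:1 train/val/test split.
- **`plumcma.augment`** — four-weather photometric simulation (sunny / rainy /
  foggy / night) and the class-balancing planner that tops every class up to a
  target count (default 2,000/class).
- **`plumcma.nn`** — a numpy-based implementation of the YOLO-CMA detector:
  the nano-scale attention-CSP baseline, the CIB/C2fCIB fusion blocks, the
  gated-CNN C3k2_Mambaout block, parameter/FLOP accounting, anchor
  re-clustering, and a smoke-training loop with a simplified detection loss.
- **`plumcma.metrics`** — greedy detection matching and the evaluation
  protocol: P, R, F1, AP (all-point PR envelope), mAP50 and mAP50–95.

The network stack runs on a small reverse-mode autodiff engine over numpy
(`plumcma.nn.core`), so no deep-learning framework is required. Model
variants are selected by two independent flags (`use_c2fcib`,
`use_c3k2_mambaout`), giving the four ablation configurations; with both
flags off the unmodified baseline is reproduced (2,520,639 parameters), with
both on the full model (2,425,693 parameters, 5.9 GFLOPs under the
detector-summary counting convention).

## CLI

```sh
plumcma synth --counts 1767,788,709,1524,1127 --seed 7 --out DIR
plumcma augment --weather foggy --seed 3 IN.png OUT.png
plumcma balance --target 2000 --seed 3 DIR       # DIR from `synth`
plumcma split --ratios 0.7,0.2,0.1 --seed 3 DIR
plumcma model-info --variant cma --imgsz 416
plumcma train-smoke --variant cma --steps 50
plumcma evaluate --gt LABELS_DIR --dets dets.json
plumcma run --seed 5 --out runs/demo             # full pipeline, toy scale
```

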