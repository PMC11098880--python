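# orssg — semantic scene graphs for operating-room activity

A toolkit for holistic modeling of operating-room scenes as semantic scene
graphs (SSGs): typed entity nodes (staff, patient, equipment, a virtual
`instrument` node) connected by directed semantic relations such as
`(head surgeon, Sawing, patient)`.  It covers the full pipeline:

- **`orssg.core`** — graph/sequence types, a 14+1-relation and configurable
  entity vocabulary, validation, triplet queries, JSON (de)serialization.
- **`orssg.synthetic`** — a procedural simulator of knee-surgery takes at
  1 Hz: colored point clouds with ground-truth instance labels, orthographic
  multi-view images, 14-joint skeletons, 3D boxes, ground-truth graphs,
  clinical roles and the eight workflow phases.  Every other module is
  testable end-to-end without any external dataset.
- **`orssg.instances`** — per-point instance labeling from detected poses and
  boxes (boxes > skeleton bones > wrist spheres / virtual instrument), plus
  fixed-size entity and pair point sampling.
- **`orssg.augment`** — training augmentations: cloud-level
  scale/translate/rotate/brightness/hue, per-object jitter for relation pair
  clouds, and crop-to-hand.
- **`orssg.sgg`** — the multimodal scene-graph generation network:
  permutation-invariant point encoders for entities and ordered pairs, an
  optional global image feature fused by concatenation, a graph-convolution
  stage and class-balanced cross-entropy heads.  Built on a small numpy
  autodiff engine (`orssg.nn`) — no deep-learning framework required.
- **`orssg.tracking`** — Hungarian person tracking, heuristic and learned
  (target-marked graph encoder) role likelihoods, and greedy bijective
  role assignment.
- **`orssg.phases`** — transparent rule-based surgical-phase recognition over
  role-augmented graph sequences (8 phases, latched started/finished state,
  optional majority smoothing).
- **`orssg.metrics`** — the evaluation protocol: per-class and macro P/R/F1
  over ordered ground-truth entity pairs (15 relation classes including the
  background class), reused for roles and phases.

## CLI

```bash
orssg simulate --seed 0 --out data/ --takes 1 --length 120   # write a take
orssg validate data/take_0/gt_graphs.json                    # check invariants
orssg roles  --graphs data/take_0/gt_graphs.json             # assign roles
orssg phases --graphs data/take_0/gt_graphs.json --smooth 5  # recognize phases
orssg eval --pred pred.json --gt gt.json --report report.json
orssg train-sgg --config train.yaml --out model.npz
```

## Python pipeline

```python
from orssg import synthetic, sgg, tracking, phases, metrics

bundles = synthetic.simulate_timeline(synthetic.SimConfig(seed=0, take_length_s=120))
frames = [sgg.frame_from_bundle(b) for b in bundles]
model, losses = sgg.train_sgg(frames, sgg.SGGConfig(epochs=10, n_obj_points=96,
                                                    n_rel_points=192, learning_rate=1e-3))
predicted = [sgg.predict_graph(f, model) for f in frames]
scores = metrics.relation_prf(predicted, [b.gt_graph for b in bundles])
```

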