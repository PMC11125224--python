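# stagcn

Ordinal expert–novice skill classification from skeleton motion with a
confidence-aware spatiotemporal attention graph convolutional network.

## The problem

Coaches and sports scientists want to grade how skilled a movement is —
not just "expert vs. novice" but an *ordered* scale of levels — from
motion-capture joint trajectories, and to see *which joints* drove the
grade. This package implements such a classifier for skeleton sequences
(`F` frames × `N` joints × 3 coordinates) with ordinal levels
`1..M`, and exports per-joint, per-frame attention maps as the
explanation.

## The model

The network is a spatiotemporal attention GCN (STA-GCN) with two
additions aimed at the weaknesses of plain attention:

1. **Confidence-aware node-level attention.** The attention branch
   produces attention nodes `V ∈ (0,1)^{F×N}` and a class posterior
   `p_att`. For every attention node `(n, f)` the branch is re-run with
   that node masked to zero; the confidence of the node is
   `c̄_{n,f} = 1 − c_{n,f}`, where `c_{n,f}` is the masked probability of
   the reference class. Nodes whose masking collapses the classification
   get high weight; nodes the classifier never relied on are damped. The
   perception branch then classifies from `C ∘ V ∘ Y^FE` together with
   nonnegative attention-edge matrices via a fused graph convolution.

2. **Ordinality-weighted loss.** Each branch minimizes

   `L = −log p(label) − Σ_{m≠label} |label−m|² log(1−p(m))`,

   so probability mass placed on classes far from the true level is
   charged with squared label distance; `L_total = L_att + L_per`.

The backbone is the standard skeleton-GCN machinery: spatial graph
convolution over a partitioned, symmetrically normalized skeleton
adjacency (`uni` / `distance` / `spatial` strategies), depthwise
temporal convolution (kernel 9), STGC blocks (S-GC → BN → ReLU → T-GC →
Dropout + skip), trained with plain SGD (lr 0.01, batch 64). Everything
runs on a small built-in reverse-mode autodiff over NumPy — no deep
learning framework required. See `docs/methods.md` for the full model
description and design choices.

A synthetic-data module generates stick-figure gait datasets with a
controllable ordinal skill signal on designated "salient" joints, so
training, ablation and attention-localization checks run end to end
without any external dataset.

## Worked example

```python
import numpy as np
from stagcn import ModelConfig, RunConfig, SynthConfig, generate_dataset, make_topology, train
from stagcn.pipeline import stack_batch

topo = make_topology(8)                      # stick figure: pelvis, spine, arms, legs
cfg = SynthConfig(samples_per_class=40, effect_size=1.0, noise_sd=0.1, seed=0)
samples = generate_dataset(cfg)              # 160 labelled trials, 80/20 split

res = train(samples, topo, ModelConfig(variant="pm", seed=0),
            RunConfig(epochs=100, eval_every=10, seed=0))
print(f"train acc {res.final_train.accuracy:.3f}  "
      f"test acc {res.final_test.accuracy:.3f}  test MAE {res.final_test.mae:.3f}")

x, _ = stack_batch(samples)
v = np.concatenate([res.model.eval().forward(x[i:i+64]).v.data
                    for i in range(0, len(x), 64)])
sal = [j - 1 for j in cfg.salient_joints]    # the arm joints carry the skill signal
non = [j for j in range(8) if j not in sal]
print(f"attention: salient {v[:, :, sal].mean():.3f}  other {v[:, :, non].mean():.3f}")
```

prints (about four minutes on one CPU):

```
train acc 1.000  test acc 1.000  test MAE 0.000
attention: salient 0.633  other 0.524
```

The classifier masters the separable synthetic benchmark (zero
label-distance error on held-out trials), and the learned attention is
visibly higher on the joints that actually carry the skill signal —
the desk-scale analogue of attention maps highlighting the upper body
for skilled athletes. `stagcn visualize` renders these maps as skeleton
overlays; `stagcn ablate` reproduces the comparative grid (plain
ST-GCN / attention / sample-level confidence / node-level confidence,
each with and without the ordinal loss term).

A CLI wraps the library: `stagcn generate | train | evaluate | ablate |
visualize` (see `--help` on each verb; YAML config with flag overrides).

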