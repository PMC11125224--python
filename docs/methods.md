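# Methods

This package implements an ordinal skill-level classifier for skeleton
motion sequences: a spatiotemporal attention graph convolutional network
(STA-GCN) extended with a *confidence-aware node-level attention
mechanism* and an *ordinality-weighted loss*. This note records the
model, its assumptions, the numerical choices, what the synthetic
benchmark does and does not show, and known limitations.

## Model

**Input.** A trial is an `F x N x C` array: `F` frames, `N` body joints,
`C` coordinate channels (default 3, raw x/y/z positions; optional root
centering). Internally arrays are channel-first `(C, F, N)` and batches
are `(B, C, F, N)`. All sequences in a dataset must share `F`; longer
trials are downsampled by regular-interval index selection (endpoints
kept, no interpolation).

**Spatial graph convolution (S-GC).** Per frame,

    Y_space = sum_h ( W_h^Edge o Lam_h^{-1/2} (A_h + I) Lam_h^{-1/2} ) X W_h^Node,

where `A_h` are the partition matrices of the skeleton adjacency,
`Lam_nn = sum_i (A_ni + I_ni)`, `W_h^Edge` is a learnable multiplicative
mask on the normalized adjacency (initialized to ones, so the layer
starts as a standard graph convolution) and `W_h^Node` mixes channels.
Three partition strategies are supported — `uni` (one matrix, all
neighbours), `distance` (self vs. neighbours) and `spatial` (self,
centripetal, centrifugal w.r.t. hop distance to a root joint; equal-hop
neighbours join the self class). `spatial` (H = 3) is the default, the
standard choice in this model family. Nodes unreachable from the root
fall back to the neighbour class with a warning.

**Temporal graph convolution (T-GC).** A depthwise (channel-wise)
convolution along frames, `y(v_f) = sum_tau alpha_tau o x(v_{f-tau})`,
odd kernel `kappa` (default 9), zero padding, stride 1, so the frame
count is preserved. A channel-mixing "full" temporal convolution is the
convention in some related architectures; here the kernel is Hadamard
per channel, which is what the layer's defining equation states.

**STGC block.** `S-GC -> BatchNorm -> ReLU -> T-GC -> Dropout` plus a
skip connection (identity when shapes match, else a learned 1x1
projection). A single BatchNorm per block; no second normalization after
the temporal convolution. The feature extractor stacks three blocks.

**Attention branch.** From the extracted map `Y^FE`:

* *attention nodes* `V in (0,1)^{F x N}`: 1x1 convolutions
  (C -> hidden -> 1) with BatchNorm, linear interpolation along time
  back to `F` frames if the extractor strides, then a sigmoid;
* *attention edges* `E`: global average pooling over time, a 1x1
  convolution to `phi` head embeddings, a bilinear similarity per head,
  BatchNorm, tanh, ReLU — nonnegative with exact zeros for suppressed
  joint pairs. `phi` defaults to 3, mirroring the spatial partition
  count;
* the attended map `Y^AN = V o Y^FE` and the auxiliary posterior
  `p_att` (1x1 convolution to M channels, GAP over the frame-joint
  grid, softmax).

**Confidence-aware node-level reweighting.** The confidence of
attention node `(n, f)` is `1 - c_{n,f}`, where `c_{n,f}` is the
probability the attention head assigns to the *reference class* after
that single attention value is masked to zero. Masking a node that the
classifier depends on collapses the reference probability, giving that
node high confidence weight; masking an irrelevant node changes nothing
and its weight settles near `1 - p_ref`. The adjusted map is
`Y^CAN = C o Y^AN`.

Implementation note: everything downstream of `V` inside the branch
(gating, one 1x1 convolution, global average pooling) is linear before
the softmax, so masking entry `(f, n)` subtracts exactly that entry's
pooled contribution from the logits. The probe therefore computes all
`F x N` masked posteriors in a single batched pass via this exact logit
update — algebraically identical to literally re-running the branch per
mask, and verified in the tests against a literal full recompute at
1e-10 and against the per-entry loop bitwise. The probe is a
measurement: the confidence matrix re-enters the graph as a constant and
contributes no gradient path (second-order paths through `F x N` probes
would be costly, and nothing in the mechanism's definition trains
through it). The reference class is the ground-truth label during
training and the unmasked attention-branch argmax at inference, when no
label is available.

Three confidence granularities exist: `node_frame` (the full mechanism,
default), `node` (one probe per joint, masking all its frames), and
`sample` (the predecessor sample-level scheme: the unmasked
reference-class probability itself, one scalar per sample).

**Perception branch.** Its input is `Y^CAN` (a config switch restores
the literal alternative of convolving the raw input, which disconnects
the confidence mechanism and exists only for comparison). The opening
layer fuses a fixed-topology S-GC term with a graph convolution over the
attention edges,

    Y_out = Y_space + sum_phi Lam_phi^{-1/2}(A_phi + I)Lam_phi^{-1/2} X W_phi,

renormalizing the (input-dependent) attention edges per sample with the
same degree rule. Two further STGC blocks, GAP, a fully connected layer
and a softmax yield the final posterior `p_per`.

**Loss.** For each branch posterior `p` and label `l in {1..M}`:

    L = -log p(l) - sum_{m != l} |l - m|^2 log(1 - p(m)),

cross-entropy plus an ordinal penalty charging probability mass on
classes far from the truth, with squared label distance (no
normalization by `(M-1)^2`). `L_total = L_att + L_per`; batch reduction
is the mean. The one-hot target in the first term is the only reading
under which it is standard cross-entropy. Probabilities are clamped to
`[1e-7, 1 - 1e-7]` before logarithms.

**Optimization.** Plain SGD, learning rate 0.01, batch size 64, no
momentum or weight decay (both exposed, default 0). Epoch count is
config-driven. The confidence matrix is recomputed on every forward
pass, training and evaluation alike.

One numerical guard accompanies the optimizer: the ordinal term's
clamped `log(1 - p)` has gradient `|l-m|^2 / (1 - p)`, which blows up
(to ~1e8 near the clamp) if a class saturates mid-training; without a
guard this intermittently destroys a converged model (loss spiking by
an order of magnitude, accuracy collapsing to chance before slowly
recovering). Gradients are therefore clipped to a global L2 norm of 50
per step — roughly ten times the healthy-regime norm, so ordinary steps
are untouched. The clip applies identically to every variant and can be
disabled (`grad_clip_norm=None`).

Because the learning rate is constant (no schedule is part of the study
conditions), the optimizer keeps bouncing around the optimum after
convergence instead of settling. The pipeline therefore snapshots
parameters at every evaluation point and returns the checkpoint with
the best *training* accuracy (ties broken by lower training loss); no
held-out information enters the selection. Final-epoch reporting is
available with `keep_best=False`.

## Ablation variants

`stgcn` bypasses attention entirely (V = 1, C = 1, E = 0; the
attention-edge term then reduces to `sum_phi X W_phi` because zero edges
normalize to the identity) — tests verify it equals an independently
wired plain GCN sharing the same weights. `stagcn` keeps attention but
no confidence; `confsta` uses sample-level confidence; `pm` is the full
node-level mechanism. Each combines with or without the ordinal loss
term, reproducing an eight-cell comparison grid on synthetic data.

## Numerical and engineering choices

* The network runs on a small reverse-mode autodiff engine over float64
  NumPy arrays (`stagcn.autodiff`); the model is small enough that a
  deep-learning framework is unnecessary. Gradients of every primitive
  are tested against central finite differences.
* T-GC is computed as one einsum over strided sliding windows; its
  backward pass is the transposed convolution (taps flipped), hand
  written and finite-difference checked.
* BatchNorm: per-channel over (batch, frame, joint); eps 1e-5, running
  statistics with momentum 0.1 (eval mode uses running estimates).
* Initialization: He-uniform for node/tap/1x1 weights, edge masks at 1,
  BN gamma = 1, beta = 0; fully determined by the model seed.
* Ties: argmax prediction and max-std frame selection take the lowest
  index; quantile binning sends boundary ties to the lower class.
* Downsampling uses rounded even spacing including both endpoints;
  consecutive index gaps differ by at most one.
* Degenerate inputs are errors, not silent: non-finite motion data,
  even temporal kernels, negative attention edges, all-identical scores
  in quantile binning, empty metric inputs, non-finite training loss.

## Synthetic benchmark

The generator emulates the empirical signature this model family is
used to detect: higher skill levels recruit additional (upper-body)
joints. A stick-figure skeleton (default 8 joints; pelvis root, spine,
arms, legs) follows a sinusoidal gait-like trajectory with a random
per-sample phase; ordinal level `l` adds motion amplitude
`l x effect_size` on the arm joints only, plus isotropic Gaussian noise.
Class information therefore lives exclusively in the salient joints'
amplitudes — giving a ground-truth importance map for attention checks —
and class centroids in amplitude space are collinear and ordered, the
structure the ordinal loss exploits. An 80/20 stratified split is drawn
with a seed independent of the data seed.

Two study conditions are used throughout the tests, sized for a
single-CPU desk run:

* **separable**: 4 levels x 40 samples, 32 frames, effect 1.0, noise
  0.1 — the full model reaches train accuracy 1.0 (typically by epoch
  ~40 of a fixed 100-epoch run) and perfect or near-perfect held-out
  accuracy. Attention localization on the salient joints keeps
  strengthening after accuracy saturates, which is why training runs a
  fixed length rather than stopping at first perfect accuracy.
* **overlapping**: 4 levels x 16 samples, 24 frames, effect 0.4, noise
  0.3 — adjacent classes overlap; used for the paired five-seed
  comparison of the full model with and without the ordinal term
  (a directional claim on median test MAE only).

What passing these tests does *not* show: the generator has no
biomechanics (no bone-length constraints, no inverse kinematics, no
inter-subject variability), its class signal is a single amplitude
statistic, and the desk-scale network (16/32/64 extractor channels,
32-channel perception stack) is far smaller than what real motion
datasets need. Results on real expert-novice data depend on dataset
scale, split protocol and pose quality, none of which the synthetic
benchmark exercises.

## Known limitations

* All trials must share a frame count; downsampling can discard
  decisive frames.
* The attention-edge construction (bilinear similarity of pooled node
  embeddings) is one concrete reading of "1x1 convolutions + GAP"; it is
  config-isolated so an alternative wiring can be substituted.
* Per-frame visualization averages raw attention nodes `V`; averaging
  the confidence-adjusted product instead is available behind a flag.
* Single-person graphs only; no temporal dilation; no learned adjacency
  beyond the edge masks; no score regression (continuous scores are
  quantile-binned).
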