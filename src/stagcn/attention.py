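"""Attention branch: attention nodes/edges, auxiliary posterior and the
confidence-aware node-level reweighting.

The branch reads the extracted feature map ``Y^FE`` and produces

* attention nodes ``V`` in (0,1), one importance scalar per joint per
  frame (1x1 convs -> BN -> linear time interpolation -> sigmoid);
* attention edges ``E``, a stack of nonnegative N x N joint-pair
  importance matrices (time-pooled embeddings -> bilinear similarity ->
  BN -> tanh -> ReLU, so suppressed pairs are exactly zero);
* the attended map ``Y^AN = V o Y^FE`` and the auxiliary class posterior
  ``p_att`` (1x1 conv to M channels -> GAP -> softmax).

The confidence measure of attention node (n, f) is ``1 - c_{n,f}`` where
``c_{n,f}`` is the probability the branch assigns to the reference class
after that single attention value is masked to zero. Everything
downstream of ``V`` inside the branch (multiplicative gating, a 1x1
convolution and global average pooling) is linear in ``Y^AN``, so masking
one entry shifts the logits by exactly that entry's pooled contribution;
the probe computes all F*N masked posteriors in one batched pass through
this exact logit update. The probe is a measurement: no gradients flow
through the confidence matrix.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, einsum, relu, sigmoid, softmax, tanh
from .nn import BatchNorm, Conv1x1, Module

__all__ = [
    "AttentionBranch",
    "apply_attention",
    "apply_confidence",
    "interpolation_matrix",
    "attention_posterior",
    "masked_posteriors",
    "confidence_for_node",
    "confidence_matrix",
    "export_attention_h5",
    "export_attention_csv",
]


def interpolation_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Linear-interpolation matrix P (n_out x n_in): out = P @ in.

    Endpoints map to endpoints; with n_out == n_in this is the identity.
    """
    if n_in < 1 or n_out < 1:
        raise ValueError("frame counts must be positive")
    p = np.zeros((n_out, n_in))
    if n_in == 1:
        p[:, 0] = 1.0
        return p
    pos = np.linspace(0.0, n_in - 1.0, n_out)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    w = pos - lo
    for i in range(n_out):
        p[i, lo[i]] += 1.0 - w[i]
        p[i, hi[i]] += w[i]
    return p


def apply_attention(yfe: Tensor, v: Tensor) -> Tensor:
    """Y^AN[c,f,n] = V[f,n] * Y^FE[c,f,n] (broadcast over channels)."""
    b, _, f, n = yfe.shape
    if v.shape != (b, f, n):
        raise ValueError("attention nodes must be (B, F, N) matching the feature map")
    return yfe * v.reshape(b, 1, f, n)


def apply_confidence(yan: Tensor, c: Tensor) -> Tensor:
    """Y^CAN[c,f,n] = C[f,n] * Y^AN[c,f,n] (broadcast Hadamard)."""
    return apply_attention(yan, c)


class AttentionBranch(Module):
    def __init__(self, in_channels: int, n_classes: int, rng: np.random.Generator,
                 hidden: int = 16, edge_heads: int = 3, edge_dim: int = 8):
        super().__init__()
        self.n_classes = n_classes
        self.edge_heads = edge_heads
        self.edge_dim = edge_dim
        # attention-node head
        self.node_conv1 = Conv1x1(in_channels, hidden, rng)
        self.node_bn1 = BatchNorm(hidden)
        self.node_conv2 = Conv1x1(hidden, 1, rng)
        self.node_bn2 = BatchNorm(1)
        # attention-edge head
        self.edge_conv = Conv1x1(in_channels, edge_heads * edge_dim, rng)
        self.edge_bn = BatchNorm(edge_heads)
        # classifier head (shared by p_att and the confidence probe)
        self.head = Conv1x1(in_channels, n_classes, rng)

    # ----------------------------------------------------------- components
    def attention_nodes(self, yfe: Tensor, target_frames: int) -> Tensor:
        """(B, F, N) attention values in (0, 1)."""
        pre = self.node_bn2(self.node_conv2(relu(self.node_bn1(self.node_conv1(yfe)))))
        f_in = pre.shape[2]
        if f_in != target_frames:
            p = Tensor(interpolation_matrix(target_frames, f_in))
            pre = einsum("fg,bcgn->bcfn", p, pre)
        b, _, f, n = pre.shape
        return sigmoid(pre.reshape(b, f, n))

    def attention_edges(self, yfe: Tensor) -> Tensor:
        """(B, phi, N, N) nonnegative joint-pair importances."""
        z = yfe.mean(axis=2, keepdims=True)  # GAP over time -> (B, C, 1, N)
        emb = self.edge_conv(z)  # (B, phi*d, 1, N)
        b, _, _, n = emb.shape
        emb = emb.reshape(b, self.edge_heads, self.edge_dim, n)
        sim = einsum("bpdn,bpdm->bpnm", emb, emb)
        return relu(tanh(self.edge_bn(sim)))

    def posterior(self, yan: Tensor) -> Tensor:
        """p_att: 1x1 conv to M channels -> GAP over (F, N) -> softmax."""
        logits = self.head(yan).mean(axis=(2, 3))
        return softmax(logits, axis=1)

    # ----------------------------------------------------------- confidence
    def head_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return self.head.weight.data, self.head.bias.data


def export_attention_h5(path, sample_ids, nodes, edges, confidence=None) -> None:
    """Write per-sample attention artifacts to an HDF5 container:
    ``<sample>/attention/nodes`` (F x N), ``.../edges`` (phi x N x N) and,
    when available, ``.../confidence`` (F x N)."""
    import h5py

    with h5py.File(path, "w") as fh:
        for i, sid in enumerate(sample_ids):
            grp = fh.create_group(f"{sid}/attention")
            grp.create_dataset("nodes", data=np.asarray(nodes[i]))
            grp.create_dataset("edges", data=np.asarray(edges[i]))
            if confidence is not None:
                grp.create_dataset("confidence", data=np.asarray(confidence[i]))


def export_attention_csv(path, sample_ids, nodes) -> None:
    """Long-format CSV of per-frame attention-node values
    (sample_id, frame, joint, value; 1-based frame/joint) for plotting."""
    import pandas as pd

    rows = []
    for sid, v in zip(sample_ids, nodes):
        v = np.asarray(v)
        for f in range(v.shape[0]):
            for n in range(v.shape[1]):
                rows.append((sid, f + 1, n + 1, v[f, n]))
    pd.DataFrame(rows, columns=["sample_id", "frame", "joint", "value"]).to_csv(
        path, index=False
    )


def _promote(v: np.ndarray, yfe: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    v = np.asarray(v, dtype=np.float64)
    yfe = np.asarray(yfe, dtype=np.float64)
    if v.ndim == 2:  # single sample (F, N) / (C, F, N)
        return v[None], yfe[None], True
    return v, yfe, False


def _pooled_contributions(v, yfe, weight, bias):
    """Per-entry pooled logit contributions and the unmasked logits.

    contrib[b, m, f, n] is what attention node (f, n) adds to logit m after
    gating, 1x1 convolution and global average pooling; the unmasked logits
    are the sum over (f, n) plus the bias.
    """
    fr, n = v.shape[1], v.shape[2]
    gated = yfe * v[:, None, :, :]  # Y^AN
    contrib = np.einsum("cm,bcfn->bmfn", weight, gated, optimize=True) / (fr * n)
    base = contrib.sum(axis=(2, 3)) + bias[None, :]
    return contrib, base


def _softmax_np(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def attention_posterior(v, yfe, weight, bias) -> np.ndarray:
    """Unmasked branch posterior computed with the probe's kernel
    (identical operation order, so probe no-ops match it bitwise)."""
    v, yfe, single = _promote(v, yfe)
    _, base = _pooled_contributions(v, yfe, weight, bias)
    probs = _softmax_np(base, axis=1)
    return probs[0] if single else probs


def masked_posteriors(v, yfe, weight, bias) -> np.ndarray:
    """(B, F, N, M) branch posteriors with attention node (f, n) masked.

    Masking entry (f, n) removes exactly its pooled contribution from the
    logits (the head is linear up to the softmax), so all F*N masked
    passes are computed in one batch.
    """
    v, yfe, single = _promote(v, yfe)
    contrib, base = _pooled_contributions(v, yfe, weight, bias)
    masked = base[:, :, None, None] - contrib  # (B, M, F, N)
    probs = _softmax_np(masked, axis=1).transpose(0, 2, 3, 1)
    return probs[0] if single else probs


def confidence_for_node(v, yfe, weight, bias, n: int, f: int, ref_class: int) -> float:
    """c_{n,f}: reference-class probability with attention node (n, f) masked.

    ``n``/``f`` are 0-based indices; ``ref_class`` is a 1-based label.
    """
    v_arr = np.asarray(v, dtype=np.float64)
    fr, nn = (v_arr.shape if v_arr.ndim == 2 else v_arr.shape[1:])
    if not (0 <= f < fr and 0 <= n < nn):
        raise IndexError("node/frame index out of range")
    probs = masked_posteriors(v, yfe, weight, bias)
    if probs.ndim == 4:
        raise ValueError("confidence_for_node expects a single sample")
    m = weight.shape[1]
    if not 1 <= ref_class <= m:
        raise ValueError("ref_class out of range")
    return float(probs[f, n, ref_class - 1])


def confidence_matrix(v, yfe, weight, bias, ref_classes, mode: str = "node_frame") -> np.ndarray:
    """(B, F, N) confidence weights C.

    ``node_frame``: C[f, n] = 1 - c_{n,f} (per-node-per-frame masking).
    ``node``: masks a joint across all frames (one probe per joint).
    ``sample``: one scalar per sample - the unmasked reference-class
    probability itself, replicated over the grid (the predecessor
    sample-level confidence).
    """
    v, yfe, single = _promote(v, yfe)
    b, fr, n = v.shape
    ref = np.atleast_1d(np.asarray(ref_classes, dtype=int))
    if ref.size == 1 and b > 1:
        ref = np.full(b, ref[0])
    if ref.shape != (b,):
        raise ValueError("need one reference class per sample")
    m = weight.shape[1]
    if np.any((ref < 1) | (ref > m)):
        raise ValueError("reference class out of range")
    bi = np.arange(b)

    contrib, base = _pooled_contributions(v, yfe, weight, bias)
    if mode == "node_frame":
        masked = base[:, :, None, None] - contrib
        probs = _softmax_np(masked, axis=1)
        c = probs[bi, ref - 1]  # (B, F, N)
        out = 1.0 - c
    elif mode == "node":
        masked = base[:, :, None] - contrib.sum(axis=2)  # (B, M, N)
        probs = _softmax_np(masked, axis=1)
        out = np.broadcast_to((1.0 - probs[bi, ref - 1])[:, None, :], (b, fr, n)).copy()
    elif mode == "sample":
        probs = _softmax_np(base, axis=1)
        out = np.broadcast_to(probs[bi, ref - 1][:, None, None], (b, fr, n)).copy()
    else:
        raise ValueError(f"unknown confidence mode {mode!r}")
    return out[0] if single else out
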