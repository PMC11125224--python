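"""Independent reference implementations used as test oracles.

Everything here is deliberately written as plain scalar loops (or the
most naive vectorized form) with no code shared with the package, so
that agreement is evidence of correctness rather than tautology.
"""

from __future__ import annotations

import numpy as np


def normalize_adjacency_loops(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    lam = np.zeros(n)
    for i in range(n):
        for j in range(n):
            lam[i] += a[i, j] + (1.0 if i == j else 0.0)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = (a[i, j] + (1.0 if i == j else 0.0)) / np.sqrt(lam[i] * lam[j])
    return out


def s_gc_loops(x: np.ndarray, a_parts: np.ndarray, w_edge: np.ndarray,
               w_node: np.ndarray) -> np.ndarray:
    """x: (C_in, F, N); a_parts: (H, N, N) raw partitions; returns (C_out, F, N)."""
    h_count, n, _ = a_parts.shape
    c_in, f_count, _ = x.shape
    c_out = w_node.shape[2]
    out = np.zeros((c_out, f_count, n))
    for h in range(h_count):
        a_hat = normalize_adjacency_loops(a_parts[h])
        for f in range(f_count):
            for i in range(n):
                for o in range(c_out):
                    acc = 0.0
                    for j in range(n):
                        for c in range(c_in):
                            acc += (w_edge[h, i, j] * a_hat[i, j]
                                    * x[c, f, j] * w_node[h, c, o])
                    out[o, f, i] += acc
    return out


def t_gc_loops(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """x: (C, F, N); taps: (kappa, C), tap i has offset tau = i - kappa//2."""
    c_count, f_count, n = x.shape
    kappa = taps.shape[0]
    half = kappa // 2
    out = np.zeros_like(x)
    for c in range(c_count):
        for f in range(f_count):
            for j in range(n):
                for i in range(kappa):
                    tau = i - half
                    src = f - tau
                    if 0 <= src < f_count:
                        out[c, f, j] += taps[i, c] * x[c, src, j]
    return out


def per_edge_conv_loops(x: np.ndarray, e: np.ndarray, w: np.ndarray) -> np.ndarray:
    """x: (C_in, F, N); e: (phi, N, N); w: (phi, C_in, C_out)."""
    phi, n, _ = e.shape
    c_in, f_count, _ = x.shape
    c_out = w.shape[2]
    out = np.zeros((c_out, f_count, n))
    for p in range(phi):
        a_hat = normalize_adjacency_loops(e[p])
        for f in range(f_count):
            for i in range(n):
                for o in range(c_out):
                    for j in range(n):
                        for c in range(c_in):
                            out[o, f, i] += a_hat[i, j] * x[c, f, j] * w[p, c, o]
    return out


def masked_attention_posterior_naive(v: np.ndarray, yfe: np.ndarray,
                                     weight: np.ndarray, bias: np.ndarray,
                                     f: int, n: int) -> np.ndarray:
    """Full literal recompute: zero attention entry (f, n), re-gate, re-pool.

    v: (F, N); yfe: (C, F, N); weight: (C, M); bias: (M,).
    """
    vm = v.copy()
    vm[f, n] = 0.0
    yan = yfe * vm[None, :, :]
    logits = np.tensordot(weight.T, yan, axes=1).mean(axis=(1, 2)) + bias
    z = logits - logits.max()
    e = np.exp(z)
    return e / e.sum()


def plain_stgcn_posterior(model, x: np.ndarray) -> np.ndarray:
    """Independently wired plain spatiotemporal GCN forward (eval mode),
    reusing the model's weights but none of its forward code.

    Mirrors the attention-bypassed wiring: extractor blocks, a fused
    spatial layer whose attention-edge term reduces to sum_phi X W_phi
    (zero attention edges normalize to the identity), the head blocks,
    GAP and the softmax classifier.
    """

    def bn_eval(h, bn):
        gamma = bn.gamma.data.reshape(1, -1, 1, 1)
        beta = bn.beta.data.reshape(1, -1, 1, 1)
        mu = bn.running_mean.reshape(1, -1, 1, 1)
        var = bn.running_var.reshape(1, -1, 1, 1)
        return gamma * (h - mu) / np.sqrt(var + bn.eps) + beta

    def sgc_np(h, sgc):
        parts = sgc.partition.matrices
        out = 0.0
        for k in range(parts.shape[0]):
            a_hat = normalize_adjacency_loops(parts[k])
            mat = sgc.edge_weights.data[k] * a_hat
            spread = np.einsum("nm,bcfm->bcfn", mat, h)
            out = out + np.einsum("bcfn,co->bofn", spread, sgc.node_weights.data[k])
        return out

    def tgc_np(h, taps):
        kappa = taps.shape[0]
        half = kappa // 2
        out = np.zeros_like(h)
        for i in range(kappa):
            tau = i - half
            lo_dst, hi_dst = max(0, tau), h.shape[2] + min(0, tau)
            lo_src, hi_src = max(0, -tau), h.shape[2] - max(0, tau)
            out[:, :, lo_dst:hi_dst, :] += (
                taps[i][None, :, None, None] * h[:, :, lo_src:hi_src, :]
            )
        return out

    def block_np(h, blk):
        y = tgc_np(np.maximum(bn_eval(sgc_np(h, blk.sgc), blk.bn), 0.0), blk.tgc.taps.data)
        skip = h
        if blk.projection is not None:
            skip = np.einsum("bcfn,co->bofn", skip, blk.projection.weight.data)
        return y + skip

    h = np.asarray(x, dtype=np.float64)
    for blk in model.extractor.blocks:
        h = block_np(h, blk)
    per = model.perception
    fused = sgc_np(h, per.fuse_sgc) + np.einsum(
        "bcfn,co->bofn", h, per.per_edge_weights.data.sum(axis=0)
    )
    for blk in per.blocks:
        fused = block_np(fused, blk)
    pooled = fused.mean(axis=(2, 3))
    logits = pooled @ per.fc.weight.data + per.fc.bias.data
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)
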