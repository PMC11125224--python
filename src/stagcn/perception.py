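"""Perception branch: final classification from confidence-adjusted
features and attention edges.

The branch opens with a fused spatial layer: a fixed-topology S-GC term
plus a graph convolution over the (input-dependent) attention-edge
matrices,

    Y_out = Y^space + Y^per,
    Y^per = sum_phi  Lam_phi^{-1/2}(A_phi + I)Lam_phi^{-1/2}  X  W_phi,

where ``A_phi`` is attention-edge head phi, renormalized per sample with
the same degree rule as the skeleton adjacency. A short STGC stack, GAP
over the frame x joint grid, a fully connected layer and a softmax
produce the final posterior ``p_per``.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, einsum, softmax
from .graph_conv import STGCBlock
from .nn import Linear, Module, he_uniform
from .skeleton import SpatialPartition
from .graph_conv import SGC

__all__ = ["per_edge_conv", "fuse", "PerceptionBranch"]


def per_edge_conv(x: Tensor, e: Tensor, weights: Tensor) -> Tensor:
    """Graph convolution over attention edges, (B, C, F, N) -> (B, C_out, F, N).

    ``e``: (B, phi, N, N) nonnegative; ``weights``: (phi, C_in, C_out).
    Normalization is recomputed per sample from the attention edges.
    """
    if np.any(e.data < 0):
        raise ValueError("attention edges must be nonnegative")
    b, phi, n, _ = e.shape
    if weights.shape[0] != phi:
        raise ValueError("head count mismatch between edges and weights")
    eye = Tensor(np.eye(n))
    ai = e + eye.reshape(1, 1, n, n)
    deg = ai.sum(axis=3)  # row sums, >= 1 by the self-loop
    dinv = deg**-0.5
    anorm = dinv.reshape(b, phi, n, 1) * ai * dinv.reshape(b, phi, 1, n)
    spread = einsum("bpnm,bcfm->bpcfn", anorm, x)
    return einsum("bpcfn,pco->bofn", spread, weights)


def fuse(space: Tensor, per: Tensor) -> Tensor:
    """Elementwise sum of the fixed-topology and attention-edge terms."""
    if space.shape != per.shape:
        raise ValueError("fused feature maps must have identical shapes")
    return space + per


class PerceptionBranch(Module):
    def __init__(self, partition: SpatialPartition, in_channels: int, mid_channels: int,
                 n_classes: int, edge_heads: int, kernel_size: int,
                 rng: np.random.Generator, n_head_blocks: int = 2, dropout: float = 0.0):
        super().__init__()
        self.fuse_sgc = SGC(partition, in_channels, mid_channels, rng)
        self.per_edge_weights = Tensor(
            he_uniform(rng, (edge_heads, in_channels, mid_channels),
                       in_channels * edge_heads),
            requires_grad=True,
        )
        self.blocks = [
            STGCBlock(partition, mid_channels, mid_channels, kernel_size, rng,
                      dropout=dropout)
            for _ in range(n_head_blocks)
        ]
        self.fc = Linear(mid_channels, n_classes, rng)

    def __call__(self, x: Tensor, e: Tensor) -> Tensor:
        y = fuse(self.fuse_sgc(x), per_edge_conv(x, e, self.per_edge_weights))
        for block in self.blocks:
            y = block(y)
        logits = self.fc(y.mean(axis=(2, 3)))
        return softmax(logits, axis=1)
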