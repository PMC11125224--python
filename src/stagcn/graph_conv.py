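"""Spatial and temporal graph convolution and the STGC block.

Spatial graph convolution (S-GC) acts per frame on the skeleton graph:

    Y_out = sum_h  (W_h^Edge o  Lam_h^{-1/2}(A_h + I)Lam_h^{-1/2})  Y_in  W_h^Node

with one term per adjacency partition h. ``W_h^Edge`` is a learnable
multiplicative mask on the normalized adjacency (initialized to ones) and
``W_h^Node`` mixes channels.

Temporal graph convolution (T-GC) is a depthwise convolution along the
frame axis: y(v_f) = sum_tau alpha_tau o x(v_{f-tau}) with an odd kernel
size kappa, zero padding and stride 1, so each channel has its own
kappa-tap filter and the frame count is preserved.

An STGC block chains S-GC -> BatchNorm -> ReLU -> T-GC -> Dropout and
adds a skip connection (identity when shapes match, otherwise a learned
1x1 projection).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, einsum, relu
from .nn import BatchNorm, Conv1x1, Dropout, Module, he_uniform
from .skeleton import SpatialPartition

__all__ = ["s_gc", "t_gc", "SGC", "TGC", "STGCBlock", "FeatureExtractor"]


def s_gc(x: Tensor, partition: SpatialPartition, edge_weights: Tensor,
         node_weights: Tensor) -> Tensor:
    """Functional S-GC on a (B, C_in, F, N) tensor.

    ``edge_weights``: (H, N, N); ``node_weights``: (H, C_in, C_out).
    """
    if x.shape[3] != partition.n_joints:
        raise ValueError("node count of input does not match partition")
    if edge_weights.shape[0] != partition.n_partitions:
        raise ValueError("H mismatch between partition and edge weights")
    masked = edge_weights * Tensor(partition.normalized)  # Hadamard per partition
    spread = einsum("hnm,bcfm->hbcfn", masked, x)
    return einsum("hbcfn,hco->bofn", spread, node_weights)


def _windows(arr: np.ndarray, kappa: int) -> np.ndarray:
    """Sliding frame windows of a zero-padded (B, C, F, N) array:
    returns a strided view (B, C, F, kappa, N) with w[..., f, k, :] = ap[..., f+k, :]."""
    pad = kappa // 2
    ap = np.pad(arr, ((0, 0), (0, 0), (pad, pad), (0, 0)))
    b, c, fp, n = ap.shape
    f = fp - 2 * pad
    sb, sc, sf, sn = ap.strides
    return np.lib.stride_tricks.as_strided(
        ap, shape=(b, c, f, kappa, n), strides=(sb, sc, sf, sf, sn), writeable=False
    )


def t_gc(x: Tensor, taps: Tensor) -> Tensor:
    """Functional depthwise T-GC on a (B, C, F, N) tensor.

    ``taps``: (kappa, C); tap index i multiplies the feature at frame
    f - tau with tau = i - kappa//2 (zero padding, stride 1).

    Implemented as one einsum over sliding frame windows; window position
    k corresponds to tap index kappa-1-k, so the tap array enters flipped.
    The backward pass for the input is the same correlation with the taps
    flipped back (transposed convolution), also via windows.
    """
    kappa, c = taps.shape
    if kappa % 2 == 0:
        raise ValueError("temporal kernel size must be odd")
    if x.shape[1] != c:
        raise ValueError("tap length must equal channel count")
    w = _windows(x.data, kappa)
    flipped = taps.data[::-1]
    out = np.einsum("bcfkn,kc->bcfn", w, flipped, optimize=True)

    def back(g: np.ndarray):
        g_taps = None
        if taps.requires_grad:
            g_taps = np.einsum("bcfn,bcfkn->kc", g, w, optimize=True)[::-1].copy()
        g_x = None
        if x.requires_grad:
            gw = _windows(g, kappa)
            g_x = np.einsum("bcfkn,kc->bcfn", gw, taps.data, optimize=True)
        return (g_x, g_taps)

    return Tensor(out, parents=(x, taps), backward_fn=back)


class SGC(Module):
    def __init__(self, partition: SpatialPartition, in_channels: int, out_channels: int,
                 rng: np.random.Generator):
        super().__init__()
        h, n = partition.n_partitions, partition.n_joints
        self.partition = partition
        # multiplicative mask on the normalized adjacency: start as a no-op
        self.edge_weights = Tensor(np.ones((h, n, n)), requires_grad=True)
        self.node_weights = Tensor(
            he_uniform(rng, (h, in_channels, out_channels), in_channels * h),
            requires_grad=True,
        )

    def __call__(self, x: Tensor) -> Tensor:
        return s_gc(x, self.partition, self.edge_weights, self.node_weights)


class TGC(Module):
    def __init__(self, channels: int, kernel_size: int, rng: np.random.Generator):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError("temporal kernel size must be odd")
        self.taps = Tensor(
            he_uniform(rng, (kernel_size, channels), kernel_size), requires_grad=True
        )

    def __call__(self, x: Tensor) -> Tensor:
        return t_gc(x, self.taps)


class STGCBlock(Module):
    """S-GC -> BN -> ReLU -> T-GC -> Dropout, with a skip connection."""

    def __init__(self, partition: SpatialPartition, in_channels: int, out_channels: int,
                 kernel_size: int, rng: np.random.Generator, dropout: float = 0.0,
                 temporal_stride: int = 1, residual: bool = True):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.stride = temporal_stride
        self.residual = residual
        self.sgc = SGC(partition, in_channels, out_channels, rng)
        self.bn = BatchNorm(out_channels)
        self.tgc = TGC(out_channels, kernel_size, rng)
        self.dropout = Dropout(dropout, rng)
        self.projection = None
        if residual and (in_channels != out_channels):
            self.projection = Conv1x1(in_channels, out_channels, rng, bias=False)

    def __call__(self, x: Tensor) -> Tensor:
        y = self.dropout(t_gc(relu(self.bn(self.sgc(x))), self.tgc.taps))
        if self.stride > 1:
            y = y[:, :, ::self.stride, :]
        if not self.residual:
            return y
        skip = x
        if self.projection is not None:
            skip = self.projection(skip)
        if self.stride > 1:
            skip = skip[:, :, ::self.stride, :]
        return y + skip


class FeatureExtractor(Module):
    """A stack of STGC blocks mapping the raw (B, C, F, N) input to Y^FE."""

    def __init__(self, partition: SpatialPartition, channels: list[int],
                 in_channels: int, kernel_size: int, rng: np.random.Generator,
                 dropout: float = 0.0):
        super().__init__()
        if not channels:
            raise ValueError("need at least one STGC block")
        self.blocks = []
        prev = in_channels
        for width in channels:
            self.blocks.append(
                STGCBlock(partition, prev, width, kernel_size, rng, dropout=dropout)
            )
            prev = width
        self.out_channels = prev

    def __call__(self, x: Tensor) -> Tensor:
        for block in self.blocks:
            x = block(x)
        return x
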