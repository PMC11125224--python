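"""Attention nodes/edges ranges, the auxiliary posterior, and the
confidence probe (masking semantics, batch/loop agreement, gradient
isolation)."""

import numpy as np
import pytest

from oracles import masked_attention_posterior_naive
from stagcn.attention import (
    AttentionBranch,
    apply_attention,
    apply_confidence,
    confidence_for_node,
    confidence_matrix,
    interpolation_matrix,
    masked_posteriors,
)
from stagcn.autodiff import Tensor


@pytest.fixture()
def branch():
    return AttentionBranch(in_channels=6, n_classes=4,
                           rng=np.random.default_rng(0), hidden=4,
                           edge_heads=2, edge_dim=3).eval()


def random_yfe(rng, b=2, c=6, f=8, n=5):
    return Tensor(rng.normal(size=(b, c, f, n)))


class TestAttentionNodes:
    def test_values_strictly_inside_unit_interval(self, branch):
        v = branch.attention_nodes(random_yfe(np.random.default_rng(1)), 8)
        assert v.shape == (2, 8, 5)
        assert np.all(v.data > 0.0) and np.all(v.data < 1.0)

    def test_zero_head_gives_one_half_everywhere(self, branch):
        branch.node_conv2.weight.data[:] = 0.0
        branch.node_conv2.bias.data[:] = 0.0
        v = branch.attention_nodes(random_yfe(np.random.default_rng(2)), 8)
        np.testing.assert_allclose(v.data, 0.5)

    def test_interpolation_matches_endpoint_blend(self):
        """Upsampling 2 -> 4 frames blends the endpoints with weights
        (1, 2/3, 1/3, 0) before the sigmoid."""
        p = interpolation_matrix(4, 2)
        np.testing.assert_allclose(
            p, [[1, 0], [2 / 3, 1 / 3], [1 / 3, 2 / 3], [0, 1]]
        )
        assert np.allclose(interpolation_matrix(6, 6), np.eye(6))


class TestAttentionEdges:
    def test_nonnegative_with_exact_zeros(self, branch):
        e = branch.attention_edges(random_yfe(np.random.default_rng(3)))
        assert e.shape == (2, 2, 5, 5)
        assert np.all(e.data >= 0.0)
        assert np.any(e.data == 0.0)  # ReLU(tanh(.)) kills nonpositive entries

    def test_equal_node_embeddings_give_equal_offdiagonals(self, branch):
        x = np.ones((1, 6, 8, 5))
        e = branch.attention_edges(Tensor(x)).data[0]
        for head in e:
            off = off_diagonal(head)
            assert np.allclose(off, off[0])


def off_diagonal(a):
    return a[~np.eye(a.shape[0], dtype=bool)]


class TestApplyAttentionAndConfidence:
    def test_identity_and_annihilation_gates(self):
        rng = np.random.default_rng(4)
        yfe = random_yfe(rng, b=1)
        ones = Tensor(np.ones((1, 8, 5)))
        np.testing.assert_array_equal(apply_attention(yfe, ones).data, yfe.data)
        v = np.ones((1, 8, 5))
        v[0, 3, 2] = 0.0
        gated = apply_attention(yfe, Tensor(v))
        assert np.all(gated.data[0, :, 3, 2] == 0.0)

    def test_matches_elementwise_loop(self):
        rng = np.random.default_rng(5)
        yfe = rng.normal(size=(1, 3, 4, 2))
        v = rng.uniform(size=(1, 4, 2))
        out = apply_attention(Tensor(yfe), Tensor(v)).data
        for c in range(3):
            for f in range(4):
                for n in range(2):
                    assert out[0, c, f, n] == pytest.approx(
                        v[0, f, n] * yfe[0, c, f, n]
                    )

    def test_apply_confidence_extremes(self):
        rng = np.random.default_rng(6)
        yan = random_yfe(rng, b=1)
        np.testing.assert_array_equal(
            apply_confidence(yan, Tensor(np.ones((1, 8, 5)))).data, yan.data
        )
        np.testing.assert_array_equal(
            apply_confidence(yan, Tensor(np.zeros((1, 8, 5)))).data, 0.0 * yan.data
        )


class TestPosterior:
    def test_zero_head_gives_uniform(self, branch):
        branch.head.weight.data[:] = 0.0
        branch.head.bias.data[:] = 0.0
        p = branch.posterior(random_yfe(np.random.default_rng(7)))
        np.testing.assert_allclose(p.data, 0.25)

    def test_sums_to_one_and_grid_permutation_invariant(self, branch):
        rng = np.random.default_rng(8)
        yan = rng.normal(size=(1, 6, 8, 5))
        p = branch.posterior(Tensor(yan)).data
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
        perm_f = rng.permutation(8)
        perm_n = rng.permutation(5)
        p2 = branch.posterior(Tensor(yan[:, :, perm_f][:, :, :, perm_n])).data
        np.testing.assert_allclose(p2, p, atol=1e-12)


class TestConfidence:
    def setup_method(self):
        rng = np.random.default_rng(9)
        self.yfe = rng.normal(size=(3, 6, 2))  # (C, F, N)
        self.v = rng.uniform(0.1, 0.9, size=(6, 2))
        self.w = rng.normal(size=(3, 4))
        self.b = rng.normal(size=4)

    def test_entries_within_unit_interval(self):
        c = confidence_matrix(self.v, self.yfe, self.w, self.b, 2)
        assert c.shape == (6, 2)
        assert np.all((c >= 0.0) & (c <= 1.0))

    def test_masking_zero_attention_entry_is_noop(self):
        v = self.v.copy()
        v[4, 1] = 0.0
        unmasked = masked_attention_posterior_naive(v, self.yfe, self.w, self.b, 4, 1)
        # entry already zero: posterior with it masked equals the unmasked one
        yan = self.yfe * v[None]
        logits = np.tensordot(self.w.T, yan, axes=1).mean(axis=(1, 2)) + self.b
        base = np.exp(logits - logits.max())
        base /= base.sum()
        np.testing.assert_array_equal(unmasked, base)
        c = confidence_for_node(v, self.yfe, self.w, self.b, n=1, f=4, ref_class=3)
        assert c == pytest.approx(base[2], abs=1e-12)

    def test_batched_equals_per_entry_loop(self):
        batch = confidence_matrix(self.v, self.yfe, self.w, self.b, 1)
        loop = np.array([
            [1.0 - confidence_for_node(self.v, self.yfe, self.w, self.b, n, f, 1)
             for n in range(2)]
            for f in range(6)
        ])
        np.testing.assert_array_equal(batch, loop)

    def test_matches_naive_full_recompute(self):
        probs = masked_posteriors(self.v, self.yfe, self.w, self.b)
        for f in range(6):
            for n in range(2):
                ref = masked_attention_posterior_naive(
                    self.v, self.yfe, self.w, self.b, f, n
                )
                np.testing.assert_allclose(probs[f, n], ref, atol=1e-10)

    def test_zero_head_gives_uniform_complement(self):
        c = confidence_matrix(self.v, self.yfe, np.zeros_like(self.w),
                              np.zeros_like(self.b), 2)
        np.testing.assert_allclose(c, 1.0 - 0.25)

    def test_sole_informative_entry_attains_max_confidence(self):
        """When one node-frame carries all the class evidence, masking it
        hurts the reference class most, so it tops the confidence map."""
        yfe = np.zeros((2, 4, 3))
        yfe[0, 2, 1] = 5.0  # the only signal, routed to class 1 by w
        v = np.full((4, 3), 0.9)
        w = np.array([[3.0, -1.0, -1.0, -1.0], [0.0, 0.0, 0.0, 0.0]])
        c = confidence_matrix(v, yfe, w, np.zeros(4), ref_classes=1)
        assert np.unravel_index(np.argmax(c), c.shape) == (2, 1)

    def test_node_mode_constant_over_frames(self):
        c = confidence_matrix(self.v, self.yfe, self.w, self.b, 2, mode="node")
        assert np.allclose(c, c[:1, :])

    def test_sample_mode_is_unmasked_reference_probability(self):
        c = confidence_matrix(self.v, self.yfe, self.w, self.b, 3, mode="sample")
        yan = self.yfe * self.v[None]
        logits = np.tensordot(self.w.T, yan, axes=1).mean(axis=(1, 2)) + self.b
        p = np.exp(logits - logits.max())
        p /= p.sum()
        np.testing.assert_allclose(c, p[2], atol=1e-12)

    def test_invalid_indices_and_class_error(self):
        with pytest.raises(IndexError):
            confidence_for_node(self.v, self.yfe, self.w, self.b, n=5, f=0, ref_class=1)
        with pytest.raises(ValueError):
            confidence_matrix(self.v, self.yfe, self.w, self.b, 9)
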