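"""GNN encoder: community convolution, message passing, pooling, embedding."""

import numpy as np
import pytest

from graphomix import autodiff as ad
from graphomix.autodiff import Tensor, grad
from graphomix.encoder import (CommunityEncoding, ConvBlock, EncoderConfig,
                               GNNEncoder, MemoryPool, TopKGate,
                               community_transform, encode, message_pass)
from graphomix.priors import ModalityGraphSpec
from graphomix.synthetic import generate_prior_graph


def random_spec(n, p, seed):
    rng = np.random.default_rng(seed)
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)
             if rng.random() < p]
    return ModalityGraphSpec("g", [f"G{i}" for i in range(n)], edges)


class TestCommunityTransform:
    def test_single_community_is_plain_linear_map(self, rng):
        enc = CommunityEncoding(5, 1, 3, 2, rng)
        h = Tensor(rng.normal(size=(5, 3)))
        out = community_transform(h, enc)
        assert np.allclose(out.data, h.data @ enc.weight.data)

    def test_one_hot_rows_select_community_blocks(self, rng):
        c, cin, cout, n = 3, 2, 2, 4
        enc = CommunityEncoding(n, c, cin, cout, rng)
        members = np.array([0, 2, 1, 2])
        p = Tensor(np.eye(c)[members])
        h = rng.normal(size=(n, cin))
        out = community_transform(Tensor(h), enc, p=p)
        W = enc.weight.data.reshape(cin, c, cout)
        expected = np.stack([h[j] @ W[:, members[j], :] for j in range(n)])
        assert np.allclose(out.data, expected)

    def test_hand_computed_mixture(self, rng):
        # 2 nodes, c=2, scalar channels, blocks w=(2,4), h=(1,1)^T
        enc = CommunityEncoding(2, 2, 1, 1, rng)
        enc.weight.data = np.array([[2.0, 4.0]])
        p = Tensor(np.array([[0.5, 0.5], [1.0, 0.0]]))
        out = community_transform(Tensor(np.array([[1.0], [1.0]])), enc, p=p)
        assert np.allclose(out.data, [[3.0], [2.0]])

    def test_membership_rows_stochastic(self, rng):
        enc = CommunityEncoding(7, 4, 1, 1, rng)
        p = enc.membership().data
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6) and (p >= 0).all()

    def test_shape_mismatch_rejected(self, rng):
        enc = CommunityEncoding(5, 2, 3, 2, rng)
        with pytest.raises(ValueError):
            community_transform(Tensor(np.zeros((5, 4))), enc)


def dense_gcn(spec, h, W=None, b=0.0):
    A = spec.adjacency() + np.eye(spec.n_nodes)
    d = A.sum(1)
    N = A / np.sqrt(np.outer(d, d))
    out = N @ (h if W is None else h @ W)
    return out + b


class TestMessagePass:
    def test_isolated_node_passes_through(self):
        spec = ModalityGraphSpec("g", ["A"], [])
        h = Tensor(np.array([[3.0]]))
        assert np.allclose(message_pass(h, spec).data, [[3.0]])

    def test_two_node_hand_example(self):
        spec = ModalityGraphSpec("g", ["A", "B"], [(0, 1)])
        h = Tensor(np.array([[2.0], [0.0]]))
        assert np.allclose(message_pass(h, spec).data, [[1.0], [1.0]])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_oracle(self, seed):
        spec = random_spec(int(np.random.default_rng(seed).integers(5, 30)),
                           0.2, seed)
        rng = np.random.default_rng(seed + 100)
        h = rng.normal(size=(spec.n_nodes, 3))
        out = message_pass(Tensor(h), spec)
        assert np.allclose(out.data, dense_gcn(spec, h), atol=1e-6)

    def test_node_relabeling_equivariance(self, rng):
        spec = random_spec(12, 0.3, 5)
        perm = rng.permutation(12)
        edges_p = [(int(np.argsort(perm)[u]), int(np.argsort(perm)[v]))
                   for u, v in spec.edges]
        spec_p = ModalityGraphSpec("gp", [spec.feature_ids[i] for i in perm],
                                   edges_p)
        h = rng.normal(size=(12, 2))
        out = message_pass(Tensor(h), spec).data
        out_p = message_pass(Tensor(h[perm]), spec_p).data
        assert np.allclose(out[perm], out_p, atol=1e-6)


class TestTopK:
    def test_keeps_argmax_k_of_scores(self, rng):
        gate = TopKGate(3, rng)
        h = Tensor(rng.normal(size=(2, 10, 3)))
        active = np.ones((2, 10), dtype=bool)
        out, new_active = gate(h, active, keep=5)
        s = gate.scores(h).data[..., 0]
        for b in range(2):
            assert new_active[b].sum() == 5
            assert set(np.flatnonzero(new_active[b])) == \
                set(np.argsort(-s[b])[:5])
            assert np.allclose(out.data[b][~new_active[b]], 0.0)

    def test_keep_all_ratio_one(self, rng):
        blk = ConvBlock(6, 2, 1, rng, use_batchnorm=False)
        h = Tensor(rng.normal(size=(1, 6, 2)))
        spec = random_spec(6, 0.4, 0)
        _, active = blk(h, spec, np.ones((1, 6), dtype=bool), keep=6)
        assert active.all()

    def test_no_topk_keeps_node_set(self, rng):
        blk = ConvBlock(6, 2, 1, rng, use_batchnorm=False)
        h = Tensor(rng.normal(size=(1, 6, 2)))
        spec = random_spec(6, 0.4, 0)
        _, active = blk(h, spec, np.ones((1, 6), dtype=bool), keep=None)
        assert active.all()


class TestMemoryPool:
    def test_rows_stochastic(self, rng):
        pool = MemoryPool(3, 4, 2, rng)
        S = pool.assignments(Tensor(rng.normal(size=(2, 9, 3)))).data
        assert np.allclose(S.sum(axis=-1), 1.0, atol=1e-6) and (S >= 0).all()

    def test_identical_nodes_identical_assignments(self, rng):
        pool = MemoryPool(3, 4, 2, rng)
        h = rng.normal(size=(1, 5, 3))
        h[0, 2] = h[0, 4]
        S = pool.assignments(Tensor(h)).data
        assert np.allclose(S[0, 2], S[0, 4])

    def test_single_cluster_is_linear_map_of_sum(self, rng):
        pool = MemoryPool(3, 1, 2, rng)
        h = rng.normal(size=(1, 6, 3))
        out = pool(Tensor(h), np.ones((1, 6), dtype=bool)).data
        expected = h.sum(axis=1, keepdims=True) @ pool.proj.weight.data \
            + pool.proj.bias.data
        assert np.allclose(out, expected, atol=1e-8)

    def test_fixed_output_shape_regardless_of_active_count(self, rng):
        pool = MemoryPool(3, 4, 2, rng)
        h = Tensor(rng.normal(size=(1, 10, 3)))
        full = pool(h, np.ones((1, 10), dtype=bool))
        part = pool(h, np.arange(10)[None, :] < 4)
        assert full.shape == part.shape == (1, 4, 2)

    def test_zero_active_nodes_rejected(self, rng):
        pool = MemoryPool(3, 2, 2, rng)
        with pytest.raises(ValueError, match="active"):
            pool(Tensor(rng.normal(size=(1, 5, 3))),
                 np.zeros((1, 5), dtype=bool))


class TestEncoder:
    def test_deterministic_and_correct_dimension(self, rng):
        spec = random_spec(20, 0.2, 1)
        cfg = EncoderConfig(embedding_dim=16)
        x = rng.normal(size=(20,))
        z1 = encode(x, spec, cfg, seed=3)
        z2 = encode(x, spec, cfg, seed=3)
        assert z1.shape == (16,) and np.array_equal(z1, z2)

    def test_node_cap_enforced_before_pooling(self, rng):
        spec = generate_prior_graph(1000, "scale_free", seed=0)
        cfg = EncoderConfig(n_conv_blocks=2, channels=2, node_cap=300,
                            n_communities=2, embedding_dim=8)
        enc = GNNEncoder(spec, cfg, rng)
        enc.eval()
        with ad.no_grad():
            enc(Tensor(rng.normal(size=(2, 1000))))
        assert enc.last_active_count is not None
        assert enc.last_active_count <= 300

    def test_dimension_mismatch_rejected(self, rng):
        spec = random_spec(10, 0.3, 2)
        enc = GNNEncoder(spec, EncoderConfig(channels=2, embedding_dim=4), rng)
        with pytest.raises(ValueError):
            enc(Tensor(rng.normal(size=(1, 9))))

    def test_full_conv_layer_reduces_to_standard_gcn(self, rng):
        """c=1, no pooling/batchnorm: layer equals the dense-matrix oracle."""
        for seed in range(20):
            g = np.random.default_rng(seed)
            spec = random_spec(int(g.integers(5, 30)), 0.25, seed + 17)
            enc = CommunityEncoding(spec.n_nodes, 1, 2, 2,
                                    np.random.default_rng(seed))
            h = g.normal(size=(spec.n_nodes, 2))
            out = message_pass(community_transform(Tensor(h), enc), spec,
                               enc.bias)
            oracle = dense_gcn(spec, h, enc.weight.data, enc.bias.data)
            assert np.abs(out.data - oracle).max() <= 1e-5

    def test_every_parameter_receives_gradient(self, rng):
        spec = generate_prior_graph(40, "scale_free", seed=1)
        cfg = EncoderConfig(n_communities=2, n_conv_blocks=2, channels=3,
                            n_clusters=2, features_per_cluster=2,
                            embedding_dim=8, node_cap=20)
        enc = GNNEncoder(spec, cfg, rng)
        z = enc(Tensor(rng.normal(size=(8, 40))))
        loss = (z * z).sum()
        loss.backward()
        for name, p in enc.named_parameters():
            assert p.grad is not None and np.abs(p.grad).max() > 0, name
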