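"""Per-modality GNN feature extractor.

Pipeline: community positional encoding -> community-weighted graph
convolution blocks with residual connections, batch normalization and
optional top-k node masking -> memory pooling to a fixed-size coarse
representation -> residual projection of the raw input -> m-dimensional
embedding.

The graph convolution extends the standard symmetric-normalized layer
(D̂^{-1/2} (A+I) D̂^{-1/2} · h · W + b, degrees counting the unit self-loop):
nodes are softly assigned to c learnable communities and each community has
its own weight block, so the effective per-node weight matrix is the
community-probability-weighted mixture of blocks.  With c = 1 the layer
reduces exactly to the standard convolution.

Top-k masking keeps the highest-scoring nodes under a learnable scoring
vector and gates the kept features by a sigmoid of their scores; the mask is
carried forward so that at most ``node_cap`` active nodes enter memory
pooling regardless of input graph size.  Masked topology is represented as
a per-sample boolean mask over the fixed graph rather than a rebuilt
subgraph; masked node features are zeroed, so they send nothing downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Parameter, Tensor
from .nn import BatchNorm, Linear, Module
from .priors import ModalityGraphSpec

__all__ = ["EncoderConfig", "CommunityEncoding", "community_transform",
           "message_pass", "ConvBlock", "MemoryPool", "GNNEncoder", "encode"]


@dataclass(frozen=True)
class EncoderConfig:
    n_communities: int = 4          # c
    n_conv_blocks: int = 2          # N
    channels: int = 8               # C_in = C_out inside blocks (residual add)
    n_clusters: int = 4             # d_c
    features_per_cluster: int = 4   # d_i' (width of the post-pool linear map)
    embedding_dim: int = 16         # m
    node_cap: int = 300
    use_batchnorm: bool = True

    def __post_init__(self):
        if min(self.n_communities, self.n_conv_blocks, self.embedding_dim,
               self.node_cap, self.channels, self.n_clusters,
               self.features_per_cluster) < 1:
            raise ValueError("all encoder sizes must be >= 1")


class CommunityEncoding(Module):
    """Soft node-community membership plus per-community linear weights.

    ``logits`` is a lookup-table embedding of nodes into communities,
    softmax-normalized to the row-stochastic membership matrix ``p``;
    ``weight`` packs the c per-community C_in x C_out blocks.
    """

    def __init__(self, n_nodes: int, n_communities: int, c_in: int, c_out: int,
                 rng: np.random.Generator):
        super().__init__()
        self.n_communities = n_communities
        self.c_in, self.c_out = c_in, c_out
        self.logits = Parameter(rng.normal(0, 0.1, size=(n_nodes, n_communities)))
        scale = np.sqrt(2.0 / (c_in + c_out))
        self.weight = Parameter(rng.normal(0, scale,
                                           size=(c_in, n_communities * c_out)))
        self.bias = Parameter(np.zeros(c_out))

    def membership(self) -> Tensor:
        return ad.softmax(self.logits, axis=-1)


def community_transform(h: Tensor, enc: CommunityEncoding,
                        p: Tensor | None = None) -> Tensor:
    """Community-weighted linear map: ĥ_j = Σ_k p[j,k] · (h_j W_k).

    ``h``: (..., nodes, C_in) -> (..., nodes, C_out).
    """
    if h.shape[-1] != enc.c_in:
        raise ValueError(f"expected {enc.c_in} input channels, got {h.shape[-1]}")
    if p is None:
        p = enc.membership()
    n = h.shape[-2]
    if p.shape[0] != n:
        raise ValueError("membership rows must match node count")
    t = h @ enc.weight  # (..., n, c*C_out)
    t = t.reshape(t.shape[:-1] + (enc.n_communities, enc.c_out))
    return (t * p.reshape((n, enc.n_communities, 1))).sum(axis=-2)


def message_pass(h_hat: Tensor, graph: ModalityGraphSpec | np.ndarray,
                 bias: Tensor | np.ndarray | None = None) -> Tensor:
    """Symmetric-normalized message passing with unit self-loops.

    h_out[j] = b + Σ_{r in {j} ∪ A_j} e_rj · ĥ_r / sqrt(d̂_r d̂_j), with d̂
    counting the self-loop.  Equivalent to the dense product
    D̂^{-1/2}(A+I)D̂^{-1/2} ĥ + b.
    """
    A = graph.normalized_adjacency() if isinstance(graph, ModalityGraphSpec) \
        else np.asarray(graph)
    out = Tensor(A) @ h_hat
    if bias is not None:
        out = out + bias
    return out


class TopKGate(Module):
    """Learnable node scoring; keeps the top nodes and sigmoid-gates them."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.score_vec = Parameter(rng.normal(0, 1.0, size=(channels, 1)))

    def scores(self, h: Tensor) -> Tensor:
        norm = float(np.linalg.norm(self.score_vec.data)) or 1.0
        return (h @ self.score_vec) * (1.0 / norm)  # (..., n, 1)

    def forward(self, h: Tensor, active: np.ndarray, keep: int):
        """``active``: (..., n) boolean mask; keeps ``keep`` active nodes."""
        s = self.scores(h)
        sdata = s.data[..., 0].copy()
        sdata[~active] = -np.inf
        k = min(keep, int(active.sum(axis=-1).min()))
        order = np.argsort(-sdata, axis=-1, kind="stable")
        new_active = np.zeros_like(active)
        np.put_along_axis(new_active, order[..., :k], True, axis=-1)
        new_active &= active
        gate = ad.sigmoid(s) * new_active[..., None].astype(float)
        return h * gate, new_active


class ConvBlock(Module):
    """relu(message-pass(community-transform)) + residual -> batchnorm -> top-k."""

    def __init__(self, n_nodes: int, channels: int, n_communities: int,
                 rng: np.random.Generator, use_batchnorm: bool = True):
        super().__init__()
        self.enc = CommunityEncoding(n_nodes, n_communities, channels, channels, rng)
        self.bn = BatchNorm(channels) if use_batchnorm else None
        self.topk = TopKGate(channels, rng)

    def forward(self, h: Tensor, graph, active: np.ndarray,
                keep: int | None = None):
        msg = message_pass(community_transform(h, self.enc), graph, self.enc.bias)
        out = h + ad.relu(msg)
        if self.bn is not None:
            out = self.bn(out)
        if keep is not None and keep < int(active.sum(axis=-1).max()):
            out, active = self.topk(out, active, keep)
        else:
            out = out * active[..., None].astype(float)
        return out, active


class MemoryPool(Module):
    """Soft assignment of active nodes to learnable centroids.

    S = softmax over clusters of the negative squared Euclidean distance to
    the centroids (rows nonnegative, summing to 1); the pooled cluster
    features S^T x̃ are linearly mapped to ``features_per_cluster`` channels,
    a fixed-size output regardless of the active-node count.
    """

    def __init__(self, channels: int, n_clusters: int, features_per_cluster: int,
                 rng: np.random.Generator):
        super().__init__()
        self.centroids = Parameter(rng.normal(0, 1.0, size=(n_clusters, channels)))
        self.proj = Linear(channels, features_per_cluster, rng)

    def assignments(self, h: Tensor) -> Tensor:
        # squared distance: ||h||^2 - 2 h mu^T + ||mu||^2  -> (..., n, d_c)
        sq_h = (h * h).sum(axis=-1, keepdims=True)
        cross = h @ self.centroids.T
        sq_mu = (self.centroids * self.centroids).sum(axis=-1)
        d2 = sq_h - 2.0 * cross + sq_mu
        return ad.softmax(-d2, axis=-1)

    def forward(self, h: Tensor, active: np.ndarray) -> Tensor:
        if int(np.asarray(active).sum(axis=-1).min()) == 0:
            raise ValueError("memory pooling requires at least one active node")
        S = self.assignments(h) * active[..., None].astype(float)
        axes = tuple(range(S.ndim - 2)) + (S.ndim - 1, S.ndim - 2)
        pooled = S.transpose(axes) @ h  # (..., d_c, C)
        return self.proj(pooled)        # (..., d_c, d_i')


class GNNEncoder(Module):
    """Full feature extractor g(x, graph) -> z in R^m for one modality."""

    def __init__(self, graph: ModalityGraphSpec, cfg: EncoderConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.graph = graph
        self.cfg = cfg
        d = graph.n_nodes
        c, C = cfg.n_communities, cfg.channels
        self.lift = CommunityEncoding(d, c, 1, C, rng)
        self.blocks = [ConvBlock(d, C, c, rng, cfg.use_batchnorm)
                       for _ in range(cfg.n_conv_blocks)]
        self.pool = MemoryPool(C, cfg.n_clusters, cfg.features_per_cluster, rng)
        flat = cfg.n_clusters * cfg.features_per_cluster
        self.input_residual = Linear(d, flat, rng)
        self.out = Linear(flat, cfg.embedding_dim, rng)
        self.keep_schedule = self._schedule(d)
        self.last_active_count: int | None = None

    def _schedule(self, d: int) -> list[int | None]:
        """Per-block active-node targets so <= node_cap nodes reach pooling."""
        cap, N = self.cfg.node_cap, self.cfg.n_conv_blocks
        if d <= cap:
            return [None] * N
        ratio = (cap / d) ** (1.0 / N)
        targets = []
        prev = d
        for k in range(N):
            n_k = max(1, int(np.floor(d * ratio ** (k + 1))))
            n_k = min(n_k, prev)
            targets.append(n_k)
            prev = n_k
        targets[-1] = min(targets[-1], cap)
        return targets

    def forward(self, x: Tensor) -> Tensor:
        """``x``: (..., d) node features (one scalar per node) -> (..., m)."""
        if x.shape[-1] != self.graph.n_nodes:
            raise ValueError(
                f"expected {self.graph.n_nodes} features, got {x.shape[-1]}")
        h = x.reshape(x.shape + (1,))
        h = community_transform(h, self.lift) + self.lift.bias
        active = np.ones(x.shape, dtype=bool)
        for block, keep in zip(self.blocks, self.keep_schedule):
            h, active = block(h, self.graph, active, keep)
        self.last_active_count = int(active.sum(axis=-1).max())
        z_prime = self.pool(h, active)  # (..., d_c, d_i')
        flat = z_prime.reshape(z_prime.shape[:-2]
                               + (z_prime.shape[-1] * z_prime.shape[-2],))
        return self.out(flat + self.input_residual(x))


def encode(x, graph: ModalityGraphSpec, cfg: EncoderConfig,
           encoder: GNNEncoder | None = None, seed: int = 0) -> np.ndarray:
    """Convenience wrapper: embed ``x`` (d,) or (n, d) with a (new) encoder."""
    if encoder is None:
        encoder = GNNEncoder(graph, cfg, np.random.default_rng(seed))
    encoder.eval()
    x = np.asarray(x, dtype=np.float64)
    squeeze = x.ndim == 1
    with ad.no_grad():
        z = encoder(Tensor(x[None] if squeeze else x)).data
    return z[0] if squeeze else z
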