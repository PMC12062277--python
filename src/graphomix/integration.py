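"""Multimodal integration with a class-token set transformer.

Per-modality embeddings are collected into a token set Z = (z_0, z_1, ...,
z_K) with a learnable class token z_0, passed through a stack of standard
transformer encoder blocks (multi-head self-attention + tokenwise
feed-forward, residual connections and layer normalization, no positional
encodings), and the transformed class token is mapped to class scores by an
MLP head.  Because there are no positional encodings, the class-token
readout is invariant to the order of the modality tokens.

Samples missing a modality bypass the transformer: each modality also has
its own MLP classifier head over its embedding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Parameter, Tensor
from .encoder import EncoderConfig, GNNEncoder
from .nn import MLP, LayerNorm, Linear, Module, MultiheadSelfAttention
from .priors import ModalityGraphSpec

__all__ = ["IntegratorConfig", "TransformerEncoderBlock", "SetTransformer",
           "UnimodalHead", "MultiOmicsModel", "full_model_forward"]


@dataclass(frozen=True)
class IntegratorConfig:
    n_blocks: int = 2
    n_heads: int = 4
    ffn_hidden: int | None = None       # default 2m
    mlp_head_hidden: int | None = None  # default 2m
    n_classes: int = 2

    def __post_init__(self):
        if self.n_blocks < 1 or self.n_heads < 1 or self.n_classes < 2:
            raise ValueError("invalid integrator configuration")


class TransformerEncoderBlock(Module):
    """Z' = LN(Z + MSA(Z)); Z_out = LN(Z' + FFN(Z')), FFN tokenwise, shared."""

    def __init__(self, dim: int, n_heads: int, ffn_hidden: int,
                 rng: np.random.Generator):
        super().__init__()
        self.msa = MultiheadSelfAttention(dim, n_heads, rng)
        self.ln1 = LayerNorm(dim)
        self.ln2 = LayerNorm(dim)
        self.ffn1 = Linear(dim, ffn_hidden, rng)
        self.ffn2 = Linear(ffn_hidden, dim, rng)

    def forward(self, Z: Tensor) -> Tensor:
        Z = self.ln1(Z + self.msa(Z))
        ffn = self.ffn2(ad.relu(self.ffn1(Z)))
        return self.ln2(Z + ffn)


class SetTransformer(Module):
    """Class-token set transformer producing class scores from token sets."""

    def __init__(self, dim: int, cfg: IntegratorConfig, rng: np.random.Generator):
        super().__init__()
        if dim % cfg.n_heads != 0:
            raise ValueError(f"embedding dim {dim} not divisible by "
                             f"{cfg.n_heads} heads")
        ffn_hidden = cfg.ffn_hidden or 2 * dim
        head_hidden = cfg.mlp_head_hidden or 2 * dim
        self.dim = dim
        self.class_token = Parameter(rng.normal(0, 0.1, size=(dim,)))
        self.blocks = [TransformerEncoderBlock(dim, cfg.n_heads, ffn_hidden, rng)
                       for _ in range(cfg.n_blocks)]
        self.head = MLP([dim, head_hidden, cfg.n_classes], rng)

    def encode_tokens(self, tokens: Tensor) -> Tensor:
        """``tokens``: (..., K, m) modality embeddings -> (..., K+1, m)."""
        lead = tokens.shape[:-2]
        ct = ad.broadcast_to(self.class_token.reshape((1,) * len(lead) + (1, self.dim)),
                             lead + (1, self.dim))
        Z = ad.concatenate([ct, tokens], axis=-2)
        for block in self.blocks:
            Z = block(Z)
        return Z

    def class_token_representation(self, tokens: Tensor) -> Tensor:
        Z = self.encode_tokens(tokens)
        sl = (slice(None),) * (Z.ndim - 2) + (0,)
        return Z[sl]

    def forward(self, tokens: Tensor) -> Tensor:
        if tokens.shape[-2] < 1:
            raise ValueError("at least one modality token is required")
        return self.head(self.class_token_representation(tokens))


class UnimodalHead(Module):
    """Per-modality MLP classifier over the modality embedding."""

    def __init__(self, dim: int, hidden: int, n_classes: int,
                 rng: np.random.Generator):
        super().__init__()
        self.net = MLP([dim, hidden, n_classes], rng)

    def forward(self, z: Tensor) -> Tensor:
        return self.net(z)


class MultiOmicsModel(Module):
    """End-to-end model: per-modality GNN encoders, unimodal MLP heads, and a
    class-token set transformer integrating the embeddings of complete
    samples."""

    def __init__(self, graphs: dict[str, ModalityGraphSpec],
                 encoder_cfg: EncoderConfig, integrator_cfg: IntegratorConfig,
                 rng: np.random.Generator):
        super().__init__()
        m = encoder_cfg.embedding_dim
        head_hidden = integrator_cfg.mlp_head_hidden or 2 * m
        self.modalities = list(graphs)
        self.encoders = {name: GNNEncoder(g, encoder_cfg, rng)
                         for name, g in graphs.items()}
        self.heads = {name: UnimodalHead(m, head_hidden,
                                         integrator_cfg.n_classes, rng)
                      for name in graphs}
        self.integrator = SetTransformer(m, integrator_cfg, rng)

    def embed(self, features: dict[str, Tensor]) -> dict[str, Tensor]:
        return {name: self.encoders[name](x) for name, x in features.items()}

    def forward(self, features: dict[str, Tensor],
                masks: dict[str, np.ndarray] | None = None) -> dict:
        """Batched forward over a (possibly incomplete) sample batch.

        ``features[name]``: (n, d_name) with arbitrary values in absent rows;
        ``masks[name]``: (n,) availability.  Returns per-modality unimodal
        logits (present rows only, with their row indices) and integrated
        logits for complete rows.
        """
        names = [n for n in self.modalities if n in features]
        if not names:
            raise ValueError("sample batch has no modalities")
        for name in names:
            if self.encoders.get(name) is None:
                raise ValueError(f"modality {name!r} has no matching graph/encoder")
        n = features[names[0]].shape[0]
        if masks is None:
            masks = {name: np.ones(n, dtype=bool) for name in names}

        out = {"unimodal": {}, "integrated": None, "embeddings": {}}
        embeddings = {}
        for name in names:
            present = np.flatnonzero(masks[name])
            if present.size == 0:
                continue
            z = self.encoders[name](features[name][present])
            embeddings[name] = (z, present)
            out["unimodal"][name] = (self.heads[name](z), present)
        out["embeddings"] = embeddings

        complete = np.ones(n, dtype=bool)
        for name in names:
            complete &= masks[name]
        complete_idx = np.flatnonzero(complete)
        if complete_idx.size and len(names) == len(self.modalities) > 1:
            tokens = []
            for name in self.modalities:
                z, present = embeddings[name]
                pos = np.searchsorted(present, complete_idx)
                tokens.append(z[pos].reshape((complete_idx.size, 1, -1)))
            Z = ad.concatenate(tokens, axis=1)
            out["integrated"] = (self.integrator(Z), complete_idx)
        return out

    def predict(self, dataset, prefer_integrated: bool = True) -> dict:
        """Per-sample predicted labels: integrated for complete samples,
        unimodal for single-modality samples.  Returns arrays keyed by
        source plus a combined per-sample vector (-1 where absent)."""
        feats = {m: Tensor(np.nan_to_num(dataset.modality_features[m]))
                 for m in self.modalities}
        masks = {m: dataset.modality_masks[m] for m in self.modalities}
        self.eval()
        with ad.no_grad():
            out = self.forward(feats, masks)
        n = dataset.n_samples
        combined = np.full(n, -1, dtype=int)
        sources = np.full(n, "absent", dtype=object)
        for name, (logits, idx) in out["unimodal"].items():
            pred = logits.data.argmax(axis=1)
            fill = combined[idx] == -1
            combined[idx[fill]] = pred[fill]
            sources[idx[fill]] = name
        if prefer_integrated and out["integrated"] is not None:
            logits, idx = out["integrated"]
            combined[idx] = logits.data.argmax(axis=1)
            sources[idx] = "integrated"
        return {"label": combined, "source": sources, "outputs": out}


def full_model_forward(model: MultiOmicsModel, sample: dict[str, np.ndarray],
                       ) -> dict[str, np.ndarray]:
    """Score one sample: integrated + per-modality scores when complete,
    the single available modality's scores otherwise."""
    present = [name for name, x in sample.items() if x is not None]
    if not present:
        raise ValueError("sample has no modalities")
    feats = {name: Tensor(np.asarray(sample[name])[None]) for name in present}
    with ad.no_grad():
        out = model.forward(feats, {name: np.ones(1, dtype=bool)
                                    for name in present})
    scores = {name: logits.data[0]
              for name, (logits, _) in out["unimodal"].items()}
    if out["integrated"] is not None:
        scores["integrated"] = out["integrated"][0].data[0]
    return scores
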