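"""Neural-network building blocks (modules, layers, optimizer, losses).

Thin module system over :mod:`graphomix.autodiff`: a :class:`Module` owns
:class:`~graphomix.autodiff.Parameter` leaves and submodules, and exposes
``parameters()`` / ``train()`` / ``eval()`` in the conventional way.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Parameter, Tensor

__all__ = [
    "Module", "Linear", "MLP", "LayerNorm", "BatchNorm", "MultiheadSelfAttention",
    "Adam", "weighted_cross_entropy", "init_rng",
]


def init_rng(seed: int | None) -> np.random.Generator:
    return np.random.default_rng(seed)


class Module:
    def __init__(self):
        self.training = True

    def parameters(self):
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        out.append(item)
            elif isinstance(v, dict):
                for item in v.values():
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        out.append(item)
        return out

    def named_parameters(self, prefix: str = ""):
        out = []
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Parameter):
                out.append((name, v))
            elif isinstance(v, Module):
                out.extend(v.named_parameters(prefix=name + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{name}.{i}."))
                    elif isinstance(item, Parameter):
                        out.append((f"{name}.{i}", item))
            elif isinstance(v, dict):
                for kk, item in v.items():
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{name}.{kk}."))
                    elif isinstance(item, Parameter):
                        out.append((f"{name}.{kk}", item))
        return out

    def modules(self):
        out = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                out.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                out.extend(m for item in v if isinstance(item, Module)
                           for m in item.modules())
            elif isinstance(v, dict):
                out.extend(m for item in v.values() if isinstance(item, Module)
                           for m in item.modules())
        return out

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # checkpointing -----------------------------------------------------
    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, arr in state.items():
            if own[name].data.shape != np.asarray(arr).shape:
                raise ValueError(f"shape mismatch for {name}")
            own[name].data = np.asarray(arr, dtype=np.float64).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        scale = np.sqrt(2.0 / (in_features + out_features))
        self.weight = Parameter(rng.normal(0.0, scale, size=(in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class MLP(Module):
    """Fully connected net; hidden activation "relu" (default) or "tanh"
    (smooth, useful when path-integral attributions need fast quadrature
    convergence)."""

    def __init__(self, sizes: list[int], rng: np.random.Generator,
                 activation: str = "relu"):
        super().__init__()
        self.layers = [Linear(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])]
        if activation not in ("relu", "tanh"):
            raise ValueError(f"unknown activation {activation!r}")
        self.activation = activation

    def forward(self, x: Tensor) -> Tensor:
        act = ad.relu if self.activation == "relu" else ad.tanh
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = act(x)
        return x


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xn = xc * ad.power(var + self.eps, -0.5)
        return xn * self.gamma + self.beta


class BatchNorm(Module):
    """Normalizes the trailing channel axis over all leading axes.

    Evaluation (and attribution) uses frozen running statistics so that
    per-sample explanations are deterministic.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        axes = tuple(range(x.ndim - 1))
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=axes, keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.reshape(-1))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.reshape(-1))
            xn = xc * ad.power(var + self.eps, -0.5)
        else:
            xn = (x - self.running_mean) * (self.running_var + self.eps) ** -0.5
        return xn * self.gamma + self.beta


class MultiheadSelfAttention(Module):
    """Standard scaled dot-product multi-head self-attention over a token set.

    No positional encodings: the layer is permutation-equivariant in its
    tokens, which is what makes the class-token readout order-invariant.
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads != 0:
            raise ValueError(f"embedding dim {dim} not divisible by n_heads {n_heads}")
        self.dim = dim
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)
        self.last_attention: np.ndarray | None = None

    def forward(self, x: Tensor) -> Tensor:
        # x: (..., T, dim)
        lead = x.shape[:-2]
        T = x.shape[-2]
        H, D = self.n_heads, self.head_dim

        def split(t):
            t = t.reshape(lead + (T, H, D))
            axes = tuple(range(len(lead))) + (len(lead) + 1, len(lead), len(lead) + 2)
            return t.transpose(axes)  # (..., H, T, D)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ _swap(k)) * (1.0 / np.sqrt(D))  # (..., H, T, T)
        attn = ad.softmax(scores, axis=-1)
        self.last_attention = attn.data
        out = attn @ v  # (..., H, T, D)
        axes = tuple(range(len(lead))) + (len(lead) + 1, len(lead), len(lead) + 2)
        out = out.transpose(axes).reshape(lead + (T, H * D))
        return self.wo(out)


def _swap(t: Tensor) -> Tensor:
    axes = list(range(t.ndim))
    axes[-1], axes[-2] = axes[-2], axes[-1]
    return t.transpose(tuple(axes))


def weighted_cross_entropy(logits: Tensor, labels: np.ndarray,
                           class_weights: np.ndarray | None = None) -> Tensor:
    """Class-weighted softmax cross entropy, mean over the batch.

    ``logits``: (n, C); ``labels``: (n,) integer classes.
    """
    labels = np.asarray(labels, dtype=int)
    n = logits.shape[0]
    logp = ad.log_softmax(logits, axis=-1)
    picked = logp[(np.arange(n), labels)]
    if class_weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(class_weights, dtype=np.float64)[labels]
    return -(picked * w).sum() * (1.0 / max(w.sum(), 1e-12))


class Adam:
    """Adam optimizer over a parameter list (diagonal moment estimates)."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
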