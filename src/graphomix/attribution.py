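"""Integrated gradients and integrated Hessians attribution.

Integrated gradients attribute a class score f_c to input features along the
straight path from a baseline x' to the input x:

    phi_i = (x_i - x'_i) * int_0^1 df_c(x' + a (x - x')) / dx_i da,

approximated with a midpoint Riemann sum; the completeness identity
sum_i phi_i = f_c(x) - f_c(x') holds in the quadrature limit.

Integrated Hessians extend this to pairwise interactions.  Off-diagonal:

    Gamma_ij = (x_i - x'_i)(x_j - x'_j)
               * int int a b  d2 f_c(x' + a b (x - x')) / dx_i dx_j  da db,

via a nested midpoint rule; the self-interaction absorbs the remainder,
Gamma_ii = phi_i - sum_{j != i} Gamma_ij, so every row of Gamma sums to phi.

Model functions are callables mapping a batch Tensor (P, d) of inputs to a
(P,) Tensor of class scores; second derivatives come from differentiating
the gradient graph again (the autodiff engine supports double backward).
The default baseline is the per-feature mean over training *control*
samples, matching the convention for case/control omics attribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "AttributionResult", "InteractionMatrix", "control_mean_baseline",
    "integrated_gradients", "integrated_gradients_batch", "integrated_hessians",
    "token_interactions", "model_class_score",
]


@dataclass
class AttributionResult:
    phi: np.ndarray
    baseline: np.ndarray
    class_index: int
    n_steps: int
    method: str = "ig"
    sample_id: str | None = None

    def __post_init__(self):
        if not np.isfinite(self.phi).all():
            raise ValueError("non-finite attribution scores")


@dataclass
class InteractionMatrix:
    gamma: np.ndarray  # (d, d); rows sum to phi
    phi: np.ndarray
    baseline: np.ndarray
    n_steps: int

    def __post_init__(self):
        if not np.isfinite(self.gamma).all():
            raise ValueError("non-finite interaction scores")


def control_mean_baseline(training_data: np.ndarray, labels: np.ndarray,
                          control_label: int = 0) -> np.ndarray:
    """Per-feature mean over training control samples only."""
    training_data = np.asarray(training_data, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    controls = training_data[labels == control_label]
    if controls.shape[0] == 0:
        raise ValueError("no control samples to build a baseline from")
    return controls.mean(axis=0)


def _check_finite(values: np.ndarray, what: str):
    if not np.isfinite(values).all():
        bad = int(np.flatnonzero(~np.isfinite(values).reshape(
            values.shape[0], -1).all(axis=1))[0])
        raise FloatingPointError(
            f"non-finite {what} at interpolation index {bad}")


def integrated_gradients_batch(model_fn, X: np.ndarray, baseline: np.ndarray,
                               n_steps: int = 50) -> np.ndarray:
    """Midpoint-rule integrated gradients for a batch of inputs.

    ``model_fn``: Tensor (P, d) -> Tensor (P,).  Returns phi of shape X.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    baseline = np.asarray(baseline, dtype=np.float64).reshape(1, -1)
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    S, d = X.shape
    alphas = (np.arange(n_steps) + 0.5) / n_steps
    diff = X - baseline                                   # (S, d)
    pts = baseline[None] + alphas[:, None, None] * diff   # (K, S, d)
    t = Tensor(pts.reshape(n_steps * S, d), requires_grad=True)
    out = model_fn(t)
    _check_finite(out.data, "model output")
    (g,) = ad.grad(out.sum(), [t])
    grads = g.data.reshape(n_steps, S, d)
    return diff * grads.mean(axis=0)


def integrated_gradients(model_fn, x: np.ndarray, baseline: np.ndarray,
                         class_index: int = 1, n_steps: int = 50,
                         sample_id: str | None = None) -> AttributionResult:
    phi = integrated_gradients_batch(model_fn, np.asarray(x)[None],
                                     baseline, n_steps)[0]
    return AttributionResult(phi=phi, baseline=np.asarray(baseline, float),
                             class_index=class_index, n_steps=n_steps,
                             method="ig", sample_id=sample_id)


def integrated_hessians(model_fn, x: np.ndarray, baseline: np.ndarray,
                        n_steps: int = 50, ig_steps: int | None = None,
                        ) -> InteractionMatrix:
    """Pairwise interaction scores via nested midpoint quadrature.

    ``n_steps`` is per axis (n_steps^2 path points); ``ig_steps`` controls
    the integrated-gradients quadrature for the diagonal (default 200).
    """
    x = np.asarray(x, dtype=np.float64).reshape(-1)
    baseline = np.asarray(baseline, dtype=np.float64).reshape(-1)
    d = x.size
    diff = x - baseline
    mid = (np.arange(n_steps) + 0.5) / n_steps
    scale = np.multiply.outer(mid, mid).reshape(-1)       # a*b per point
    pts = baseline[None] + scale[:, None] * diff[None]    # (K^2, d)
    t = Tensor(pts, requires_grad=True)
    out = model_fn(t)
    _check_finite(out.data, "model output")
    (g,) = ad.grad(out.sum(), [t], create_graph=True)     # (K^2, d)
    H_weighted = np.empty((d, d))
    w = scale / scale.size
    for j in range(d):
        (hj,) = ad.grad((g[:, j] * Tensor(w)).sum(), [t])
        H_weighted[j] = hj.data.sum(axis=0)               # int int a b H[j,:]
    gamma = diff[:, None] * diff[None, :] * H_weighted
    phi = integrated_gradients_batch(model_fn, x[None], baseline,
                                     ig_steps or 200)[0]
    np.fill_diagonal(gamma, 0.0)
    np.fill_diagonal(gamma, phi - gamma.sum(axis=1))
    return InteractionMatrix(gamma=gamma, phi=phi, baseline=baseline,
                             n_steps=n_steps)


def integrated_hessians_batch(model_fn, X: np.ndarray, baseline: np.ndarray,
                              n_steps: int = 20, ig_steps: int | None = None,
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Interaction matrices for a batch of inputs sharing one baseline.

    All samples' quadrature points are stacked, so the d backward passes of
    the Hessian computation are shared across the batch.  Returns
    ``(gamma (S, d, d), phi (S, d))``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    baseline = np.asarray(baseline, dtype=np.float64).reshape(-1)
    S, d = X.shape
    diff = X - baseline                                   # (S, d)
    mid = (np.arange(n_steps) + 0.5) / n_steps
    scale = np.multiply.outer(mid, mid).reshape(-1)       # (K^2,)
    P = scale.size
    pts = baseline[None, None] + scale[None, :, None] * diff[:, None, :]
    t = Tensor(pts.reshape(S * P, d), requires_grad=True)
    out = model_fn(t)
    _check_finite(out.data, "model output")
    (g,) = ad.grad(out.sum(), [t], create_graph=True)
    w = np.tile(scale / P, S)                             # (S*P,)
    H_weighted = np.empty((S, d, d))
    for j in range(d):
        (hj,) = ad.grad((g[:, j] * Tensor(w)).sum(), [t])
        H_weighted[:, j, :] = hj.data.reshape(S, P, d).sum(axis=1)
    gamma = diff[:, :, None] * diff[:, None, :] * H_weighted
    phi = integrated_gradients_batch(model_fn, X, baseline, ig_steps or 200)
    for s in range(S):
        np.fill_diagonal(gamma[s], 0.0)
        np.fill_diagonal(gamma[s], phi[s] - gamma[s].sum(axis=1))
    return gamma, phi


def token_interactions(model_over_tokens, token_inputs: np.ndarray,
                       baseline_tokens: np.ndarray, n_steps: int = 20,
                       ig_steps: int | None = None) -> InteractionMatrix:
    """Token-level interactions: dimension-level Gamma aggregated by summing
    each token-block, which preserves the row-sum identity at token level.

    ``model_over_tokens``: Tensor (P, K, m) -> Tensor (P,);
    ``token_inputs`` / ``baseline_tokens``: (K, m).
    """
    token_inputs = np.asarray(token_inputs, dtype=np.float64)
    K, m = token_inputs.shape

    def flat_fn(t: Tensor) -> Tensor:
        return model_over_tokens(t.reshape((t.shape[0], K, m)))

    res = integrated_hessians(flat_fn, token_inputs.reshape(-1),
                              np.asarray(baseline_tokens).reshape(-1),
                              n_steps=n_steps, ig_steps=ig_steps)
    gamma_tok = res.gamma.reshape(K, m, K, m).sum(axis=(1, 3))
    phi_tok = res.phi.reshape(K, m).sum(axis=1)
    return InteractionMatrix(gamma=gamma_tok, phi=phi_tok,
                             baseline=np.asarray(baseline_tokens, float),
                             n_steps=n_steps)


def model_class_score(model, modality: str | None = None,
                      fixed: dict[str, np.ndarray] | None = None,
                      class_index: int = 1):
    """Build a batch score function f_c over one modality's node features.

    For a multimodal model, the other modalities' inputs are held fixed at
    ``fixed[name]`` (e.g. the sample's own values) and broadcast across the
    evaluation batch; the integrated head's score for ``class_index`` is
    returned when the model is multimodal and all modalities are present,
    otherwise the unimodal head's score.
    """
    fixed = fixed or {}

    def fn(t: Tensor) -> Tensor:
        P = t.shape[0]
        feats = {modality: t}
        for name, vals in fixed.items():
            if name == modality:
                continue
            arr = np.broadcast_to(np.asarray(vals, float).reshape(1, -1),
                                  (P, np.asarray(vals).size))
            feats[name] = Tensor(arr)
        masks = {name: np.ones(P, dtype=bool) for name in feats}
        out = model.forward(feats, masks)
        if out["integrated"] is not None:
            logits, _ = out["integrated"]
        else:
            logits, _ = out["unimodal"][modality]
        return logits[:, class_index]

    return fn
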