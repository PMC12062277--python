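"""Reusable end-to-end analysis routines.

These wire the library layers together the way an analysis would: train the
multimodal model on a cohort, attribute node importances on validation
samples, threshold them against permutation nulls, and rank markers; plus
the auxiliary set transformer used for biodomain-interaction analysis.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .attribution import control_mean_baseline, integrated_gradients_batch
from .autodiff import Tensor
from .cohort import CohortDataset
from .discovery import call_informative, select_threshold, train_null_models
from .encoder import EncoderConfig
from .integration import IntegratorConfig, SetTransformer
from .nn import Adam, init_rng, weighted_cross_entropy
from .training import (LossConfig, TrainConfig, build_model, evaluate_accuracy,
                       fit, make_class_weights)

__all__ = [
    "attribute_cohort", "attribute_modality", "marker_discovery",
    "aux_token_train_fn", "aux_token_interaction_fn",
    "train_aux_set_transformer",
]


def _class_score(logits, class_index: int, score: str):
    if score == "logit":
        return logits[:, class_index]
    # "margin": log-odds toward class_index; for a two-class head this is
    # f_c - f_other.  The common-mode of a softmax head is unconstrained by
    # training, so attributing the raw logit mixes in pure noise; the
    # margin is the quantity the loss actually shapes.
    other = 1 - class_index if logits.shape[-1] == 2 else 0
    return logits[:, class_index] - logits[:, other]


def attribute_cohort(model, dataset: CohortDataset,
                     baselines: dict[str, np.ndarray], n_steps: int = 32,
                     class_index: int = 1, chunk: int = 16,
                     score: str = "margin") -> dict[str, np.ndarray]:
    """Integrated-gradient node attributions for every sample in a cohort.

    Complete samples attribute the integrated (set-transformer) class score
    over the concatenation of all modality inputs in one pass, so each
    modality's slice of phi is obtained jointly; single-modality samples
    attribute their unimodal head's score.  Samples are chunked and the
    interpolation path batched, so the cost is a few large forward/backward
    passes rather than one per sample.

    Returns ``{modality: (n_present, d_modality)}``, rows ordered by the
    sample order of ``dataset`` restricted to where the modality is present.
    """
    model.eval()
    names = model.modalities
    masks = dataset.modality_masks
    dims = {m: len(dataset.feature_ids[m]) for m in names}
    X = {m: np.nan_to_num(dataset.modality_features[m]) for m in names}
    phi = {m: np.zeros((int(masks[m].sum()), dims[m])) for m in names}
    pos = {m: {i: k for k, i in enumerate(np.flatnonzero(masks[m]))}
           for m in names}

    complete = np.ones(dataset.n_samples, dtype=bool)
    for m in names:
        complete &= masks[m]
    offsets = np.cumsum([0] + [dims[m] for m in names])

    def joint_fn(t: Tensor) -> Tensor:
        P = t.shape[0]
        feats = {m: t[:, offsets[k]:offsets[k + 1]]
                 for k, m in enumerate(names)}
        out = model.forward(feats, {m: np.ones(P, bool) for m in names})
        logits, _ = out["integrated"]
        return _class_score(logits, class_index, score)

    if len(names) > 1 and complete.any():
        joint_baseline = np.concatenate([baselines[m] for m in names])
        idx = np.flatnonzero(complete)
        for start in range(0, idx.size, chunk):
            sel = idx[start:start + chunk]
            joint_x = np.concatenate([X[m][sel] for m in names], axis=1)
            joint_phi = integrated_gradients_batch(joint_fn, joint_x,
                                                   joint_baseline, n_steps)
            for k, m in enumerate(names):
                rows = [pos[m][i] for i in sel]
                phi[m][rows] = joint_phi[:, offsets[k]:offsets[k + 1]]

    for m in names:
        only = masks[m] & ~complete if len(names) > 1 else masks[m]
        idx = np.flatnonzero(only)

        def uni_fn(t: Tensor, m=m) -> Tensor:
            out = model.forward({m: t}, {m: np.ones(t.shape[0], bool)})
            logits, _ = out["unimodal"][m]
            return _class_score(logits, class_index, score)

        for start in range(0, idx.size, chunk):
            sel = idx[start:start + chunk]
            ph = integrated_gradients_batch(uni_fn, X[m][sel],
                                            baselines[m], n_steps)
            rows = [pos[m][i] for i in sel]
            phi[m][rows] = ph
    return phi


def attribute_modality(model, dataset: CohortDataset, modality: str,
                       baseline: np.ndarray, n_steps: int = 32,
                       class_index: int = 1) -> np.ndarray:
    """One modality's rows of :func:`attribute_cohort` (other modalities'
    baselines default to their control-free feature means)."""
    baselines = {modality: np.asarray(baseline, float)}
    for m in model.modalities:
        if m != modality:
            present = dataset.modality_masks[m]
            baselines[m] = np.nan_to_num(
                dataset.modality_features[m][present]).mean(axis=0)
    return attribute_cohort(model, dataset, baselines, n_steps=n_steps,
                            class_index=class_index)[modality]


def marker_discovery(dataset: CohortDataset, graphs, encoder_cfg: EncoderConfig,
                     integrator_cfg: IntegratorConfig, loss_cfg: LossConfig,
                     train_cfg: TrainConfig, train_idx, val_idx,
                     n_null: int = 10, pi0: float = 0.97,
                     fdr_target: float = 0.05, ig_steps: int = 32,
                     null_pools: dict[str, np.ndarray] | None = None,
                     seed: int = 0) -> dict:
    """Full marker-discovery pass on one train/validation split.

    Trains the multimodal model, attributes validation samples, thresholds
    |phi| against a permutation null pool (reused across calls when given),
    and returns per-modality informative sets plus accuracies.
    """
    train_ds, val_ds = dataset.subset(train_idx), dataset.subset(val_idx)

    def fit_fn(ds, s):
        model = build_model(ds, graphs, encoder_cfg, integrator_cfg, seed=s)
        fit(model, ds, loss_cfg,
            TrainConfig(lr=train_cfg.lr, batch_size=train_cfg.batch_size,
                        n_epochs=train_cfg.n_epochs, seed=s))
        return model

    model = fit_fn(train_ds, seed)
    acc = evaluate_accuracy(model, val_ds)

    baselines = {
        name: control_mean_baseline(
            np.nan_to_num(train_ds.modality_features[name]
                          [train_ds.modality_masks[name]]),
            train_ds.labels[train_ds.modality_masks[name]])
        for name in model.modalities}

    if null_pools is None:
        modality_names = list(model.modalities)
        raw_pools = {name: [] for name in modality_names}

        # the null statistic must match the observed one: attribute the
        # same validation samples, only the training labels were permuted
        def null_score_fn(m, _permuted_train):
            out = attribute_cohort(m, val_ds, baselines, n_steps=ig_steps)
            return np.concatenate(
                [np.abs(out[name]).ravel() for name in modality_names])

        # one permutation-trained model yields null scores for all modalities
        per_model = train_null_models(train_ds, fit_fn, null_score_fn,
                                      B=n_null, seed=seed + 7919)
        # recover per-modality segments from the concatenated layout
        for flat in per_model:
            start = 0
            for name in modality_names:
                size = int(val_ds.modality_masks[name].sum()) \
                    * len(val_ds.feature_ids[name])
                raw_pools[name].append(flat[start:start + size])
                start += size
        null_pools = {name: np.concatenate(raw_pools[name])
                      for name in modality_names}

    phis = attribute_cohort(model, val_ds, baselines, n_steps=ig_steps)
    calls, decisions = {}, {}
    for name in model.modalities:
        phi = phis[name]
        decision = select_threshold(np.abs(phi).ravel(), null_pools[name],
                                    B=n_null, pi0=pi0, target=fdr_target)
        decisions[name] = decision
        present = np.flatnonzero(val_ds.modality_masks[name])
        sample_ids = [val_ds.sample_ids[i] for i in present]
        correct = acc["correct_mask"][present]
        calls[name] = call_informative(phi, decision.threshold, correct,
                                       sample_ids=sample_ids,
                                       feature_ids=val_ds.feature_ids[name])

    per_gene: dict[str, set] = {}
    for name in calls:
        for sid, feats in calls[name].items():
            for f in feats:
                per_gene.setdefault(f, set()).add(sid)
    return {"model": model, "accuracy": acc, "decisions": decisions,
            "informative": calls, "per_gene": per_gene, "phi": phis,
            "null_pools": null_pools,
            "n_correct": int(acc["correct_mask"].sum())}


# ---------------------------------------------------------------------------
# auxiliary set transformer over biodomain class tokens
# ---------------------------------------------------------------------------

def train_aux_set_transformer(token_stack: np.ndarray, labels: np.ndarray,
                              seed: int = 0, n_epochs: int = 80,
                              lr: float = 3e-3, batch_size: int = 32,
                              cfg: IntegratorConfig | None = None,
                              weight_decay: float = 1e-2,
                              ) -> SetTransformer:
    """Train a class-token set transformer on per-biodomain token sets.

    ``token_stack``: (S, K, m) class-token representations, one token per
    biodomain, for S complete samples.  The L2 weight penalty matters here:
    it limits how sharply a label-permuted (null) retraining can bend its
    decision surface, keeping null interaction curvature comparable to the
    observed model's.
    """
    from .training import l2_weight_penalty

    S, K, m = token_stack.shape
    rng = init_rng(seed)
    model = SetTransformer(m, cfg or IntegratorConfig(), rng)
    opt = Adam(model.parameters(), lr=lr)
    weights = make_class_weights(labels)
    for _ in range(n_epochs):
        order = rng.permutation(S)
        for start in range(0, S, batch_size):
            idx = order[start:start + batch_size]
            logits = model(Tensor(token_stack[idx]))
            loss = weighted_cross_entropy(logits, labels[idx], weights)
            if weight_decay > 0:
                loss = loss + weight_decay * l2_weight_penalty(model)
            opt.zero_grad()
            loss.backward()
            opt.step()
    model.eval()
    return model


def aux_token_train_fn(token_stack, labels, seed):
    return train_aux_set_transformer(token_stack, labels, seed=seed)


def aux_token_interaction_fn(model: SetTransformer, token_stack: np.ndarray,
                             n_steps: int = 8, class_index: int = 1,
                             ) -> np.ndarray:
    """Per-sample token-level interaction matrices (S, K, K) of the class-1
    score against the token-mean baseline.  Dimension-level interactions
    are aggregated by summing token blocks, preserving the row-sum
    identity; all samples share the batched Hessian passes."""
    S, K, m = token_stack.shape
    d = K * m
    X = token_stack.reshape(S, d)
    baseline = token_stack.mean(axis=0).reshape(-1)
    model.eval()

    def flat_fn(t):  # (P, K*m) -> (P,)
        return _class_score(model(t.reshape((t.shape[0], K, m))),
                            class_index, "margin")

    # token-level nested-midpoint quadrature: one double-backward pass per
    # *token* rather than per dimension, folding the per-sample path offset
    # diff_j and the quadrature weight into the scalar being differentiated
    diff = X - baseline
    mid = (np.arange(n_steps) + 0.5) / n_steps
    scale = np.multiply.outer(mid, mid).reshape(-1)
    P = scale.size
    pts = baseline[None, None] + scale[None, :, None] * diff[:, None, :]
    t = Tensor(pts.reshape(S * P, d), requires_grad=True)
    g, = ad.grad(flat_fn(t).sum(), [t], create_graph=True)
    w_rows = np.repeat(scale[None, :], S, axis=0).reshape(S * P) / P

    gamma = np.zeros((S, K, K))
    block = lambda b: slice(b * m, (b + 1) * m)
    for b in range(K):
        W = np.zeros((S * P, d))
        W[:, block(b)] = (w_rows[:, None]
                          * np.repeat(diff[:, block(b)], P, axis=0))
        (hb,) = ad.grad((g * Tensor(W)).sum(), [t])
        M = hb.data.reshape(S, P, d).sum(axis=1)  # sum_j∈b w diff_j H[j, :]
        for a in range(K):
            if a != b:
                gamma[:, b, a] = (M[:, block(a)] * diff[:, block(a)]).sum(axis=1)

    from .attribution import integrated_gradients_batch
    phi = integrated_gradients_batch(flat_fn, X, baseline, n_steps=64)
    phi_tok = phi.reshape(S, K, m).sum(axis=2)
    for a in range(K):
        gamma[:, a, a] = phi_tok[:, a] - (gamma[:, a, :].sum(axis=1)
                                          - gamma[:, a, a])
    return gamma
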