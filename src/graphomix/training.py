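"""Training: composite loss, embedding alignment, incomplete-sample epochs,
stratified cross-validation, and grid search.

The composite objective is

    L = sum_i L_i + lambda1 * L_int + lambda2 * sum_{i>j} L_align(i,j)
        + lambda3 * L_reg,

with class-weighted cross-entropy prediction losses L_i (unimodal heads) and
L_int (set transformer), a correlation-based alignment loss between modality
embeddings, and an L2 penalty over weight matrices (not biases).  For
batches holding a single modality, L_int and L_align are exactly zero (the
integrator never enters the computation graph).

Alignment, complete samples: for each embedding dimension j, the Pearson
correlation r_j of z1[:, j] with z2[:, j] across the batch; the loss is
-mean_j |r_j| in [-1, 0], with zero-variance dimensions contributing 0.
Alignment, cross-pair mode: for every cross-modality pair of samples with
equal labels, the Pearson correlation across the m dimensions; the loss is
-mean |r| over pairs.

An epoch over an incomplete cohort is one pass over each availability
subset (complete / modality-1-only / modality-2-only), the subset order
redrawn from the seeded generator each epoch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import autodiff as ad
from .autodiff import Tensor
from .cohort import CohortDataset
from .encoder import EncoderConfig
from .integration import IntegratorConfig, MultiOmicsModel
from .nn import Adam, init_rng, weighted_cross_entropy

__all__ = [
    "LossConfig", "CvPlan", "TrainConfig", "make_class_weights",
    "alignment_loss_complete", "alignment_loss_crosspair", "total_loss",
    "train_epoch_incomplete", "fit", "evaluate_accuracy", "stratified_kfold",
    "grid_search", "build_model", "train_model",
]


@dataclass(frozen=True)
class LossConfig:
    lambda1: float = 1.0
    lambda2: float = 0.1
    lambda3: float = 1e-4
    class_weights: tuple[float, ...] | None = None  # None: inverse frequency
    alignment_mode: str = "complete_only"  # or "complete_plus_crosspair"

    def __post_init__(self):
        if min(self.lambda1, self.lambda2, self.lambda3) < 0:
            raise ValueError("lambda weights must be nonnegative")
        if self.class_weights is not None and min(self.class_weights) <= 0:
            raise ValueError("class weights must be positive")
        if self.alignment_mode not in ("complete_only", "complete_plus_crosspair"):
            raise ValueError(f"unknown alignment_mode {self.alignment_mode!r}")


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    batch_size: int = 16
    n_epochs: int = 200
    seed: int = 0


@dataclass
class CvPlan:
    n_folds: int
    fold_assignment: np.ndarray  # fold index per sample
    n_seeds_per_split: int = 3

    def split(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        val = np.flatnonzero(self.fold_assignment == fold)
        train = np.flatnonzero(self.fold_assignment != fold)
        return train, val


def make_class_weights(labels: np.ndarray, n_classes: int = 2) -> np.ndarray:
    """Inverse class frequency, normalized to mean 1."""
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels, minlength=n_classes).astype(float)
    counts[counts == 0] = 1.0
    w = 1.0 / counts
    return w / w.mean()


def alignment_loss_complete(z1: Tensor, z2: Tensor) -> Tensor:
    """-mean_j |Pearson r of z1[:, j] vs z2[:, j]| across the batch."""
    if z1.shape != z2.shape:
        raise ValueError("embedding batches must have identical shapes")
    n, m = z1.shape
    if n < 3:
        warnings.warn("alignment loss needs >= 3 complete samples; returning 0")
        return Tensor(0.0)
    c1 = z1 - z1.mean(axis=0, keepdims=True)
    c2 = z2 - z2.mean(axis=0, keepdims=True)
    v1 = (c1 * c1).mean(axis=0)
    v2 = (c2 * c2).mean(axis=0)
    cov = (c1 * c2).mean(axis=0)
    ok = ((v1.data > 0) & (v2.data > 0)).astype(float)
    denom = ad.sqrt(v1 * v2 + (1.0 - ok))  # inert where a variance is zero
    r = cov * ad.power(denom, -1.0) * ok
    return -ad.abs_(r).sum() * (1.0 / m)


def alignment_loss_crosspair(z1: Tensor, z2: Tensor,
                             labels1: np.ndarray, labels2: np.ndarray) -> Tensor:
    """-mean |Pearson r across dimensions| over same-label cross-modality pairs."""
    labels1 = np.asarray(labels1, dtype=int)
    labels2 = np.asarray(labels2, dtype=int)
    pair_mask = (labels1[:, None] == labels2[None, :]).astype(float)
    n_pairs = pair_mask.sum()
    if n_pairs == 0:
        warnings.warn("no same-label cross-modality pairs; alignment loss 0")
        return Tensor(0.0)
    m = z1.shape[1]

    def row_normalize(z):
        c = z - z.mean(axis=1, keepdims=True)
        v = (c * c).mean(axis=1, keepdims=True)
        ok = (v.data > 0).astype(float)
        return c * ad.power(ad.sqrt(v + (1.0 - ok)), -1.0) * ok

    r = (row_normalize(z1) @ row_normalize(z2).T) * (1.0 / m)
    return -(ad.abs_(r) * pair_mask).sum() * (1.0 / n_pairs)


def l2_weight_penalty(model) -> Tensor:
    """Squared L2 norm over weight matrices/tables; biases excluded."""
    total = Tensor(0.0)
    for name, p in model.named_parameters():
        leaf = name.rsplit(".", 1)[-1]
        if leaf in ("bias", "beta"):
            continue
        total = total + (p * p).sum()
    return total


def total_loss(outputs: dict, labels: np.ndarray, cfg: LossConfig,
               model=None, class_weights: np.ndarray | None = None,
               ) -> tuple[Tensor, dict]:
    """Assemble the composite loss from a model forward pass.

    ``outputs`` is the dict returned by :meth:`MultiOmicsModel.forward`;
    ``labels`` indexes the same batch the forward saw.
    """
    labels = np.asarray(labels, dtype=int)
    if class_weights is None:
        class_weights = np.asarray(cfg.class_weights) \
            if cfg.class_weights is not None else make_class_weights(labels)
    components: dict[str, float] = {}
    loss = Tensor(0.0)
    for name, (logits, idx) in outputs["unimodal"].items():
        li = weighted_cross_entropy(logits, labels[idx], class_weights)
        components[f"pred_{name}"] = li.item()
        loss = loss + li

    multimodal = outputs.get("integrated") is not None
    if multimodal:
        logits, idx = outputs["integrated"]
        lint = weighted_cross_entropy(logits, labels[idx], class_weights)
        components["pred_integrated"] = lint.item()
        loss = loss + cfg.lambda1 * lint

        emb = outputs["embeddings"]
        names = list(emb)
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                za, ia = emb[names[a]]
                zb, ib = emb[names[b]]
                common = np.intersect1d(ia, ib)
                align = Tensor(0.0)
                if common.size >= 3:
                    pa = np.searchsorted(ia, common)
                    pb = np.searchsorted(ib, common)
                    align = alignment_loss_complete(za[pa], zb[pb])
                if cfg.alignment_mode == "complete_plus_crosspair":
                    align = align + alignment_loss_crosspair(
                        za, zb, labels[ia], labels[ib])
                components[f"align_{names[a]}_{names[b]}"] = align.item() \
                    if isinstance(align, Tensor) else float(align)
                loss = loss + cfg.lambda2 * align

    if cfg.lambda3 > 0 and model is not None:
        reg = l2_weight_penalty(model)
        components["reg"] = reg.item()
        loss = loss + cfg.lambda3 * reg
    components["total"] = loss.item()
    return loss, components


def _batches(idx: np.ndarray, batch_size: int, rng: np.random.Generator):
    idx = rng.permutation(idx)
    for start in range(0, len(idx), batch_size):
        yield idx[start:start + batch_size]


def train_epoch_incomplete(dataset: CohortDataset, model: MultiOmicsModel,
                           optimizer: Adam, loss_cfg: LossConfig,
                           rng: np.random.Generator, batch_size: int = 16,
                           class_weights: np.ndarray | None = None) -> list[dict]:
    """One epoch = one full pass over each availability subset, in an order
    redrawn from ``rng``; returns one log record per optimizer step."""
    groups = dataset.availability_group()
    subset_names = [g for g in dict.fromkeys(groups) if g != "absent"]
    subsets = {g: np.flatnonzero(groups == g) for g in subset_names}
    subsets = {g: v for g, v in subsets.items() if v.size}
    if not subsets:
        raise ValueError("all availability subsets are empty")
    if class_weights is None:
        class_weights = make_class_weights(dataset.labels)

    order = rng.permutation(list(subsets))
    feats_all = {m: np.nan_to_num(dataset.modality_features[m])
                 for m in model.modalities}
    log = []
    model.train()
    for gname in order:
        sub = subsets[gname]
        present = [m for m in model.modalities
                   if dataset.modality_masks[m][sub].all()]
        for batch in _batches(sub, batch_size, rng):
            feats = {m: Tensor(feats_all[m][batch]) for m in present}
            out = model.forward(feats, {m: np.ones(len(batch), dtype=bool)
                                        for m in present})
            loss, comps = total_loss(out, dataset.labels[batch], loss_cfg,
                                     model=model, class_weights=class_weights)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            log.append({"subset": gname, "n": len(batch), **comps})
    return log


def fit(model: MultiOmicsModel, dataset: CohortDataset,
        loss_cfg: LossConfig | None = None, train_cfg: TrainConfig | None = None,
        log_path=None) -> list[dict]:
    """Train ``model`` on ``dataset``; returns per-epoch mean-loss records."""
    loss_cfg = loss_cfg or LossConfig()
    train_cfg = train_cfg or TrainConfig()
    rng = init_rng(train_cfg.seed)
    optimizer = Adam(model.parameters(), lr=train_cfg.lr)
    class_weights = np.asarray(loss_cfg.class_weights) \
        if loss_cfg.class_weights is not None \
        else make_class_weights(dataset.labels)
    history = []
    for epoch in range(train_cfg.n_epochs):
        steps = train_epoch_incomplete(dataset, model, optimizer, loss_cfg,
                                       rng, train_cfg.batch_size, class_weights)
        rec = {"epoch": epoch,
               "loss": float(np.mean([s["total"] for s in steps])),
               "n_steps": len(steps)}
        history.append(rec)
        if log_path is not None:
            mode = "w" if epoch == 0 else "a"
            with open(log_path, mode) as fh:
                if epoch == 0:
                    fh.write("epoch\tloss\tn_steps\n")
                fh.write(f"{rec['epoch']}\t{rec['loss']:.6f}\t{rec['n_steps']}\n")
    return history


def evaluate_accuracy(model: MultiOmicsModel, dataset: CohortDataset,
                      prefer_integrated: bool = True) -> dict:
    """Fraction of correct argmax predictions; integrated predictions for
    complete samples, unimodal for single-modality samples."""
    pred = model.predict(dataset, prefer_integrated=prefer_integrated)
    scored = pred["label"] >= 0
    correct = pred["label"][scored] == dataset.labels[scored]
    per_source = {}
    for src in np.unique(pred["source"][scored]):
        sel = pred["source"][scored] == src
        per_source[str(src)] = float(correct[sel].mean())
    return {"accuracy": float(correct.mean()), "n": int(scored.sum()),
            "correct_mask": pred["label"] == dataset.labels,
            "per_source": per_source, "predictions": pred}


def stratified_kfold(labels: np.ndarray, k: int = 3, seed: int = 0) -> CvPlan:
    """Label-stratified folds (per-fold class counts within 1 of n_class/k)."""
    labels = np.asarray(labels, dtype=int)
    if k == 1:
        return CvPlan(n_folds=1, fold_assignment=np.zeros(len(labels), dtype=int))
    counts = np.bincount(labels)
    if counts[counts > 0].min() < k:
        raise ValueError(f"every class needs >= {k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_, val) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignment[val] = fold
    return CvPlan(n_folds=k, fold_assignment=assignment)


def build_model(dataset: CohortDataset, graphs, encoder_cfg=None,
                integrator_cfg=None, seed: int = 0) -> MultiOmicsModel:
    encoder_cfg = encoder_cfg or EncoderConfig()
    integrator_cfg = integrator_cfg or IntegratorConfig()
    return MultiOmicsModel(graphs, encoder_cfg, integrator_cfg, init_rng(seed))


def train_model(dataset: CohortDataset, graphs, encoder_cfg=None,
                integrator_cfg=None, loss_cfg=None, train_cfg=None,
                ) -> tuple[MultiOmicsModel, list[dict]]:
    train_cfg = train_cfg or TrainConfig()
    model = build_model(dataset, graphs, encoder_cfg, integrator_cfg,
                        seed=train_cfg.seed)
    history = fit(model, dataset, loss_cfg, train_cfg)
    return model, history


def grid_search(grid: list[dict], dataset: CohortDataset, plan: CvPlan,
                evaluator, base_seed: int = 0) -> tuple[dict, list[dict]]:
    """3 splits x ``plan.n_seeds_per_split`` seeds per config; the score is
    the mean validation accuracy; ties broken by lexicographic config order.

    ``evaluator(config, dataset, train_idx, val_idx, seed) -> float``.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    table = []
    scores = []
    for cfg_id, config in enumerate(grid):
        accs = []
        for fold in range(plan.n_folds):
            train_idx, val_idx = plan.split(fold)
            for s in range(plan.n_seeds_per_split):
                seed = base_seed + 1000 * fold + s
                acc = float(evaluator(config, dataset, train_idx, val_idx, seed))
                table.append({"config_id": cfg_id, "fold": fold, "seed": seed,
                              "accuracy": acc, **{f"cfg_{k}": v
                                                  for k, v in config.items()}})
                accs.append(acc)
        scores.append(float(np.mean(accs)))
    order = sorted(range(len(grid)),
                   key=lambda i: (-scores[i], sorted(grid[i].items()).__repr__()))
    best = grid[order[0]]
    return best, table
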