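"""Permutation-based empirical FDR, informative-marker calling and ranking,
and biodomain-interaction analysis.

Null attribution scores come from models re-trained on label-permuted data.
For a score threshold d the empirical false discovery rate is

    FDR(d) = pi0 * ( sum_b |{i : phi_i^(b) > d}| / B ) / |{i : phi_i > d}|,

with pi0 the prior probability that a marker is uninformative (default
0.97).  Candidate thresholds are taken just below each unique observed
score (so the score itself is discoverable under the strict inequality);
the selected threshold d* is the smallest candidate whose FDR is at or
under the target.  If no candidate reaches the target, no threshold is
returned and the minimum attainable FDR is reported; nothing is then called
informative.

Markers are called only in correctly predicted validation samples; the
cross-study ranking counts, per gene and study, the unique sample
identifiers for which the gene was informative across modalities and
analyses, divides by the study's number of correctly predicted validation
samples, and ranks genes by the mean fraction across studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FdrDecision", "InteractionRanking", "train_null_models", "empirical_fdr",
    "select_threshold", "call_informative", "rank_markers",
    "biodomain_interaction_analysis",
]


@dataclass
class FdrDecision:
    observed: np.ndarray
    null_pool: np.ndarray
    n_null_models: int
    pi0: float
    threshold: float | None
    fdr_at_threshold: float | None
    min_attainable_fdr: float
    informative: np.ndarray  # boolean over observed scores

    def __post_init__(self):
        if self.n_null_models < 1:
            raise ValueError("B must be >= 1")
        if not (0 < self.pi0 <= 1):
            raise ValueError("pi0 must lie in (0, 1]")


@dataclass
class InteractionRanking:
    per_repeat_top: list[list[tuple]]          # top-10% pairs per repeat
    appearance_counts: dict[tuple, int]
    sample_counts: dict[tuple, int]            # total informative samples
    ranked: list[tuple]                        # final retained, ranked
    n_repeats: int


def train_null_models(dataset, fit_fn, score_fn, B: int, seed: int = 0,
                      ) -> list[np.ndarray]:
    """Train B models on label-permuted copies of ``dataset``.

    ``fit_fn(dataset, seed) -> model``; ``score_fn(model, dataset) ->
    ndarray`` of attribution scores (any shape).  Returns one flat score
    array per null model; the pool is reusable across analyses of the same
    dataset (different folds / initializations).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    pools = []
    for b in range(B):
        perm = rng.permutation(dataset.n_samples)
        permuted = _with_labels(dataset, dataset.labels[perm])
        model = fit_fn(permuted, int(rng.integers(2 ** 31 - 1)))
        pools.append(np.asarray(score_fn(model, permuted), float).ravel())
    return pools


def _with_labels(dataset, labels):
    import copy
    ds = copy.copy(dataset)
    ds.labels = np.asarray(labels, dtype=int)
    return ds


def empirical_fdr(observed, null_pool, B: int, pi0: float = 0.97,
                  d: float = 0.0) -> float:
    """FDR(d) per the permutation formula; errors if nothing exceeds d."""
    observed = np.asarray(observed, float).ravel()
    null_flat = _flatten_pool(null_pool)
    n_disc = int((observed > d).sum())
    if n_disc == 0:
        raise ValueError(f"no observed scores exceed threshold d={d}")
    n_null = int((null_flat > d).sum())
    return pi0 * (n_null / B) / n_disc


def _flatten_pool(null_pool) -> np.ndarray:
    if isinstance(null_pool, np.ndarray):
        return null_pool.ravel()
    return np.concatenate([np.asarray(p, float).ravel() for p in null_pool])


def select_threshold(observed, null_pool, B: int, pi0: float = 0.97,
                     target: float = 0.05) -> FdrDecision:
    """Smallest threshold on the observed-score grid with FDR <= target.

    Candidates sit just below each unique observed score, evaluated in
    increasing order; FDR only changes at observed values.
    """
    observed = np.asarray(observed, float).ravel()
    null_flat = _flatten_pool(null_pool)
    candidates = np.unique(observed)
    best_d = None
    best_fdr = None
    min_fdr = np.inf
    for t in candidates:
        d = np.nextafter(t, -np.inf)
        fdr = empirical_fdr(observed, null_flat, B, pi0, d)
        min_fdr = min(min_fdr, fdr)
        if fdr <= target:
            best_d, best_fdr = d, fdr
            break
    informative = observed > best_d if best_d is not None \
        else np.zeros(observed.size, dtype=bool)
    return FdrDecision(observed=observed, null_pool=null_flat,
                       n_null_models=B, pi0=pi0, threshold=best_d,
                       fdr_at_threshold=best_fdr,
                       min_attainable_fdr=float(min_fdr),
                       informative=informative)


def call_informative(attributions: np.ndarray, threshold: float | None,
                     correct_mask: np.ndarray,
                     sample_ids=None, feature_ids=None,
                     use_magnitude: bool = True) -> dict:
    """Feature f is informative for sample s iff s is a correctly predicted
    validation sample and score_{s,f} > threshold.

    ``use_magnitude`` scores |phi| (biomarkers are features with large
    magnitude attribution toward the disease class)."""
    attributions = np.atleast_2d(np.asarray(attributions, float))
    S, d = attributions.shape
    correct_mask = np.asarray(correct_mask, bool)
    sample_ids = list(sample_ids) if sample_ids is not None \
        else [f"s{i}" for i in range(S)]
    feature_ids = list(feature_ids) if feature_ids is not None \
        else [f"f{j}" for j in range(d)]
    scores = np.abs(attributions) if use_magnitude else attributions
    out = {}
    for i in range(S):
        if threshold is None or not correct_mask[i]:
            out[sample_ids[i]] = set()
        else:
            out[sample_ids[i]] = {feature_ids[j]
                                  for j in np.flatnonzero(scores[i] > threshold)}
    return out


def rank_markers(per_study_informative: dict[str, dict[str, set]],
                 per_study_correct_counts: dict[str, int]) -> pd.DataFrame:
    """Cross-study marker ranking.

    ``per_study_informative[study][gene]`` is the set of unique sample ids
    for which the gene was informative (already unioned across modalities
    and analyses).  Rank by mean fraction of correctly predicted validation
    samples across studies, ties by total sample count then symbol.
    """
    studies = []
    for study, counts in per_study_correct_counts.items():
        if counts == 0:
            warnings.warn(f"study {study!r} has no correctly predicted "
                          "validation samples; excluded")
            continue
        studies.append(study)
    if not studies:
        raise ValueError("no study with correctly predicted samples")
    genes = sorted({g for s in studies
                    for g in per_study_informative.get(s, {})})
    rows = []
    for gene in genes:
        fracs, counts = {}, {}
        for study in studies:
            samples = per_study_informative.get(study, {}).get(gene, set())
            counts[study] = len(samples)
            fracs[study] = len(samples) / per_study_correct_counts[study]
        rows.append({
            "symbol": gene,
            "mean_fraction": float(np.mean([fracs[s] for s in studies])),
            "total_samples": int(sum(counts.values())),
            **{f"n_samples_{s}": counts[s] for s in studies},
        })
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df = df.sort_values(["mean_fraction", "total_samples", "symbol"],
                        ascending=[False, False, True],
                        kind="stable").reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


def _pair_scores(gamma: np.ndarray, use_magnitude: bool = True) -> dict[tuple, float]:
    """Unordered-pair interaction scores from a token Gamma matrix
    (symmetrized sum, magnitude by default)."""
    K = gamma.shape[0]
    out = {}
    for i in range(K):
        for j in range(i + 1, K):
            v = gamma[i, j] + gamma[j, i]
            out[(i, j)] = abs(v) if use_magnitude else v
    return out


def biodomain_interaction_analysis(tokens: dict[str, np.ndarray],
                                   labels: np.ndarray,
                                   train_fn, interaction_fn,
                                   n_repeats: int = 10,
                                   n_null: int = 5,
                                   fdr_target: float = 0.05,
                                   pi0: float = 0.97,
                                   top_fraction: float = 0.10,
                                   min_appearances: int = 3,
                                   seed: int = 0) -> InteractionRanking:
    """Rank biodomain-pair interactions over repeated auxiliary trainings.

    ``tokens[name]``: (S, m) class-token representations of the complete
    samples for one biodomain; all biodomains must cover the same samples.
    ``train_fn(token_array (S,K,m), labels, seed) -> model``;
    ``interaction_fn(model, token_array) -> (S, K, K)`` per-sample token
    interaction matrices.

    Per repeat: train the auxiliary set transformer, score per-sample pair
    interactions, threshold them by permutation FDR (``n_null`` permuted
    retrainings), count informative samples per pair, and note the top
    ``top_fraction`` of pairs.  Pairs noted in >= ``min_appearances``
    repeats are kept, ranked by appearance count then total informative
    samples.
    """
    names = list(tokens)
    sizes = {tokens[n].shape[0] for n in names}
    if len(sizes) != 1:
        raise ValueError("all biodomains must provide tokens for the same samples")
    if any(tokens[n] is None for n in names):
        raise ValueError("missing biodomain token")
    S = sizes.pop()
    K = len(names)
    stack = np.stack([np.asarray(tokens[n], float) for n in names], axis=1)
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    pair_keys = [(i, j) for i in range(K) for j in range(i + 1, K)]
    n_top = max(1, int(np.ceil(top_fraction * len(pair_keys))))

    # held-out scoring split: interactions (observed and null alike) are
    # scored on samples the auxiliary model did not train on, matching the
    # marker procedure; otherwise memorization inflates the null pool
    from sklearn.model_selection import StratifiedKFold
    skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
    tr_idx, va_idx = next(skf.split(np.zeros(S), labels))
    n_val = va_idx.size

    per_repeat_top: list[list[tuple]] = []
    appearance: dict[tuple, int] = {}
    total_samples: dict[tuple, int] = {}
    for rep in range(n_repeats):
        model = train_fn(stack[tr_idx], labels[tr_idx],
                         int(rng.integers(2 ** 31 - 1)))
        obs = interaction_fn(model, stack[va_idx])  # (n_val, K, K)
        obs_pairs = np.array([[_pair_scores(obs[s])[k] for k in pair_keys]
                              for s in range(n_val)])
        null_scores = []
        for _ in range(n_null):
            perm = rng.permutation(tr_idx.size)
            nm = train_fn(stack[tr_idx], labels[tr_idx][perm],
                          int(rng.integers(2 ** 31 - 1)))
            ng = interaction_fn(nm, stack[va_idx])
            null_scores.append(np.array(
                [[_pair_scores(ng[s])[k] for k in pair_keys]
                 for s in range(n_val)]).ravel())
        decision = select_threshold(obs_pairs.ravel(), null_scores,
                                    B=n_null, pi0=pi0, target=fdr_target)
        informative = obs_pairs > decision.threshold \
            if decision.threshold is not None \
            else np.zeros_like(obs_pairs, dtype=bool)
        counts = informative.sum(axis=0)  # per pair
        top_idx = np.argsort(-counts, kind="stable")[:n_top]
        top_pairs = [pair_keys[i] for i in top_idx if counts[i] > 0]
        per_repeat_top.append([(names[i], names[j]) for i, j in top_pairs])
        for i, j in top_pairs:
            key = (names[i], names[j])
            appearance[key] = appearance.get(key, 0) + 1
        for idx, (i, j) in enumerate(pair_keys):
            key = (names[i], names[j])
            total_samples[key] = total_samples.get(key, 0) + int(counts[idx])

    kept = [k for k, c in appearance.items() if c >= min_appearances]
    ranked = sorted(kept, key=lambda k: (-appearance[k],
                                         -total_samples.get(k, 0), k))
    return InteractionRanking(per_repeat_top=per_repeat_top,
                              appearance_counts=appearance,
                              sample_counts=total_samples,
                              ranked=ranked, n_repeats=n_repeats)
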