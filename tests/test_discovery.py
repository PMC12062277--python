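"""Permutation FDR arithmetic, marker calling/ranking, interaction ranking."""

import numpy as np
import pandas as pd
import pytest

from graphomix.discovery import (FdrDecision, biodomain_interaction_analysis,
                                 call_informative, empirical_fdr,
                                 rank_markers, select_threshold,
                                 train_null_models)

OBSERVED = np.array([5.0, 4.0, 1.0])
NULLS = [np.array([2.0, 0.0, 0.0]), np.array([4.0, 0.0, 0.0])]


def brute_force_fdr(observed, null_pools, B, pi0, d):
    n_null = sum(int((p > d).sum()) for p in null_pools)
    n_obs = int((np.asarray(observed) > d).sum())
    return pi0 * (n_null / B) / n_obs


class TestEmpiricalFdr:
    def test_worked_example(self):
        assert empirical_fdr(OBSERVED, NULLS, B=2, pi0=0.97, d=3) == \
            pytest.approx(0.2425)

    def test_matches_brute_force_on_random_pools(self, rng):
        for _ in range(20):
            obs = rng.normal(size=30)
            pools = [rng.normal(size=50) for _ in range(4)]
            d = float(rng.choice(obs))  # strict >, so discoveries exist
            d -= 1e-9
            assert empirical_fdr(obs, pools, B=4, pi0=0.9, d=d) == \
                pytest.approx(brute_force_fdr(obs, pools, 4, 0.9, d))

    def test_null_below_observed_gives_zero(self):
        assert empirical_fdr(OBSERVED, [np.zeros(3)], B=1, d=0.5) == 0.0

    def test_no_discoveries_is_an_error(self):
        with pytest.raises(ValueError):
            empirical_fdr(OBSERVED, NULLS, B=2, d=10.0)

    def test_observed_equal_to_null_gives_fdr_near_one(self, rng):
        scores = rng.normal(size=500)
        med = np.median(scores) - 1e-9
        fdr = empirical_fdr(scores, [scores.copy()], B=1, pi0=1.0, d=med)
        assert fdr == pytest.approx(1.0, abs=0.02)


class TestSelectThreshold:
    def test_all_null_below_gives_zero_fdr(self):
        decision = select_threshold(OBSERVED, [np.zeros(3), np.zeros(3)],
                                    B=2, target=0.05)
        assert decision.fdr_at_threshold == 0.0
        assert decision.informative.all()

    def test_worked_example_at_target_quarter(self):
        decision = select_threshold(OBSERVED, NULLS, B=2, pi0=0.97,
                                    target=0.25)
        assert decision.fdr_at_threshold == pytest.approx(0.2425)
        # scores 4 and 5 are called informative at this threshold
        assert set(OBSERVED[decision.informative]) == {4.0, 5.0}

    def test_unreachable_target_reports_min_fdr(self):
        decision = select_threshold(np.array([1.0, 1.5]),
                                    [np.array([2.0, 2.5])] * 3, B=3,
                                    pi0=0.97, target=0.01)
        assert decision.threshold is None
        assert decision.min_attainable_fdr > 0.01
        assert not decision.informative.any()

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            FdrDecision(OBSERVED, np.zeros(3), 0, 0.97, None, None, 1.0,
                        np.zeros(3, bool))
        with pytest.raises(ValueError):
            FdrDecision(OBSERVED, np.zeros(3), 2, 1.5, None, None, 1.0,
                        np.zeros(3, bool))


class _ToyDataset:
    def __init__(self, labels):
        self.labels = np.asarray(labels)
        self.n_samples = len(labels)


class TestTrainNullModels:
    def test_pool_counting_and_label_multiset(self):
        ds = _ToyDataset([0, 1] * 5)
        seen = {}

        def fit_fn(d, seed):
            seen["labels"] = d.labels.copy()
            return "model"

        def score_fn(model, d):
            return np.ones((10, 7))

        pools = train_null_models(ds, fit_fn, score_fn, B=1, seed=0)
        assert len(pools) == 1 and pools[0].size == 70
        assert sorted(seen["labels"]) == sorted(ds.labels)

    def test_fixed_seed_reproduces_permutations(self):
        ds = _ToyDataset([0, 1, 1, 0, 1])
        perms = [[], []]
        for trial in range(2):
            train_null_models(
                ds, lambda d, s: perms[trial].append(tuple(d.labels)),
                lambda m, d: np.zeros(1), B=3, seed=42)
        assert perms[0] == perms[1]


class TestCallInformative:
    def test_misclassified_sample_gets_empty_set(self):
        attr = np.array([[10.0, 0.0], [10.0, 10.0]])
        calls = call_informative(attr, threshold=1.0,
                                 correct_mask=[False, True],
                                 sample_ids=["a", "b"],
                                 feature_ids=["g1", "g2"])
        assert calls["a"] == set() and calls["b"] == {"g1", "g2"}

    def test_scores_below_threshold_empty(self):
        calls = call_informative(np.ones((2, 3)), threshold=5.0,
                                 correct_mask=[True, True])
        assert all(v == set() for v in calls.values())

    def test_hand_enumeration(self):
        attr = np.array([[2.0, -3.0, 0.5], [0.1, 4.0, -0.2]])
        calls = call_informative(attr, threshold=1.0,
                                 correct_mask=[True, True],
                                 sample_ids=["s1", "s2"],
                                 feature_ids=["a", "b", "c"])
        assert calls == {"s1": {"a", "b"}, "s2": {"b"}}  # |phi| scoring

    def test_signed_mode(self):
        attr = np.array([[2.0, -3.0]])
        calls = call_informative(attr, 1.0, [True], feature_ids=["a", "b"],
                                 use_magnitude=False)
        assert calls["s0"] == {"a"}


class TestRankMarkers:
    def test_mean_fraction_arithmetic(self):
        table = rank_markers(
            {"A": {"geneX": {f"a{i}" for i in range(8)}},
             "B": {"geneX": {f"b{i}" for i in range(6)}}},
            {"A": 10, "B": 10})
        assert table.loc[0, "mean_fraction"] == pytest.approx(0.7)

    def test_unique_sample_ids_counted_once(self):
        # the same sample flags the gene in both modalities upstream: the
        # per-study set already unions, so the count stays 1
        table = rank_markers({"A": {"g": {"s1"}}}, {"A": 2})
        assert table.loc[0, "n_samples_A"] == 1

    def test_never_informative_gene_ranked_last(self):
        table = rank_markers(
            {"A": {"good": {"s1", "s2"}, "dud": set()}}, {"A": 4})
        assert list(table["symbol"]) == ["good", "dud"]
        assert table.loc[1, "mean_fraction"] == 0.0

    def test_zero_correct_study_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            table = rank_markers({"A": {"g": {"s"}}, "B": {"g": {"t"}}},
                                 {"A": 5, "B": 0})
        assert "n_samples_B" not in table.columns

    def test_tie_break_by_total_samples_then_symbol(self):
        table = rank_markers(
            {"A": {"g2": {"s1"}, "g1": {"s1"}, "g3": {"s1", "s2"}}},
            {"A": 4})
        # g3 has more samples; g1/g2 tie broken alphabetically
        assert list(table["symbol"]) == ["g3", "g1", "g2"]


class TestInteractionRanking:
    """Bookkeeping of the repeat/top-10% protocol with stub models."""

    def run(self, scores_per_repeat, n_repeats, K=5, n_top_override=None):
        names = [f"bd{k}" for k in range(K)]
        tokens = {n: np.zeros((6, 2)) for n in names}
        labels = np.array([0, 1, 0, 1, 0, 1])
        n_null = 1
        state = {"call": -1}

        def train_fn(stack, labels, seed):
            # per repeat: one observed model, then n_null null models
            state["call"] += 1
            return state["call"]

        def interaction_fn(model, stack):
            gam = np.zeros((6, K, K))
            if model % (1 + n_null) == 0:  # observed model of this repeat
                rep = model // (1 + n_null)
                for (i, j), v in scores_per_repeat[rep].items():
                    gam[:, i, j] = v
            return gam

        return biodomain_interaction_analysis(
            tokens, labels, train_fn, interaction_fn, n_repeats=n_repeats,
            n_null=n_null, fdr_target=0.5, pi0=0.97,
            top_fraction=0.10 if n_top_override is None else n_top_override,
            seed=0)

    def test_three_of_ten_retained_two_dropped(self):
        # pair (0,1) strong in 3 repeats, pair (2,3) in only 2
        reps = []
        for r in range(10):
            table = {}
            if r < 3:
                table[(0, 1)] = 5.0
            if r in (4, 5):
                table[(2, 3)] = 5.0
            reps.append(table)
        ranking = self.run(reps, n_repeats=10)
        kept = set(ranking.ranked)
        assert ("bd0", "bd1") in kept
        assert ("bd2", "bd3") not in kept

    def test_tie_broken_by_total_informative_samples(self):
        reps = []
        for r in range(10):
            table = {}
            if r < 5:
                table[(0, 1)] = 5.0
                table[(0, 2)] = 5.0
            reps.append(table)
        ranking = self.run(reps, n_repeats=10, n_top_override=0.5)
        assert set(ranking.ranked) >= {("bd0", "bd1"), ("bd0", "bd2")}

    def test_mismatched_token_samples_rejected(self):
        tokens = {"a": np.zeros((6, 2)), "b": np.zeros((5, 2))}
        with pytest.raises(ValueError, match="same samples"):
            biodomain_interaction_analysis(tokens, np.zeros(6, int),
                                           None, None)
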