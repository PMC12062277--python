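"""Composite loss, alignment, incomplete-epoch scheduling, CV, grid search."""

import numpy as np
import pytest

from graphomix.autodiff import Tensor, grad
from graphomix.nn import Adam, init_rng
from graphomix.synthetic import SimulationConfig, generate_cohort
from graphomix.training import (LossConfig, TrainConfig,
                                alignment_loss_complete,
                                alignment_loss_crosspair, build_model,
                                evaluate_accuracy, fit, grid_search,
                                make_class_weights, stratified_kfold,
                                total_loss, train_epoch_incomplete)


class TestAlignmentComplete:
    def test_identical_embeddings_give_minus_one(self, rng):
        z = Tensor(rng.normal(size=(20, 8)))
        assert alignment_loss_complete(z, z).item() == pytest.approx(-1.0, abs=1e-9)

    def test_affine_map_still_minus_one(self, rng):
        z = Tensor(rng.normal(size=(20, 8)))
        z2 = Tensor(-3.0 * z.data + 7.0)
        assert alignment_loss_complete(z, z2).item() == pytest.approx(-1.0, abs=1e-9)

    def test_independent_batches_near_zero(self, rng):
        z1 = Tensor(rng.normal(size=(200, 16)))
        z2 = Tensor(rng.normal(size=(200, 16)))
        assert abs(alignment_loss_complete(z1, z2).item()) < 0.15

    def test_bounded_in_minus_one_zero(self, rng):
        for _ in range(10):
            z1 = Tensor(rng.normal(size=(15, 6)))
            z2 = Tensor(rng.normal(size=(15, 6)))
            val = alignment_loss_complete(z1, z2).item()
            assert -1.0 - 1e-12 <= val <= 0.0

    def test_zero_variance_dimension_contributes_zero(self, rng):
        z1 = rng.normal(size=(10, 4))
        z1[:, 2] = 5.0
        loss = alignment_loss_complete(Tensor(z1), Tensor(z1)).item()
        assert loss == pytest.approx(-3.0 / 4.0, abs=1e-9)

    def test_too_few_samples_warns_and_returns_zero(self, rng):
        with pytest.warns(UserWarning):
            val = alignment_loss_complete(Tensor(rng.normal(size=(2, 4))),
                                          Tensor(rng.normal(size=(2, 4))))
        assert val.item() == 0.0


class TestAlignmentCrosspair:
    def test_identical_pair_gives_minus_one(self, rng):
        z = rng.normal(size=(1, 6))
        val = alignment_loss_crosspair(Tensor(z), Tensor(z), [1], [1]).item()
        assert val == pytest.approx(-1.0, abs=1e-9)

    def test_mixed_label_pairs_excluded(self, rng):
        z1, z2 = rng.normal(size=(2, 5)), rng.normal(size=(2, 5))
        full = alignment_loss_crosspair(Tensor(z1), Tensor(z2),
                                        [1, 0], [1, 0]).item()
        # only (0,0) and (1,1) pairs enter; verify against a direct oracle
        r00 = np.corrcoef(z1[0], z2[0])[0, 1]
        r11 = np.corrcoef(z1[1], z2[1])[0, 1]
        assert full == pytest.approx(-(abs(r00) + abs(r11)) / 2, abs=1e-10)

    def test_two_by_two_pairing_matches_correlation_oracle(self, rng):
        z1, z2 = rng.normal(size=(2, 3)), rng.normal(size=(2, 3))
        val = alignment_loss_crosspair(Tensor(z1), Tensor(z2),
                                       [1, 1], [1, 1]).item()
        rs = [abs(np.corrcoef(z1[i], z2[j])[0, 1])
              for i in range(2) for j in range(2)]
        assert val == pytest.approx(-np.mean(rs), abs=1e-10)

    def test_no_valid_pair_warns_zero(self, rng):
        with pytest.warns(UserWarning):
            val = alignment_loss_crosspair(Tensor(rng.normal(size=(1, 4))),
                                           Tensor(rng.normal(size=(1, 4))),
                                           [0], [1])
        assert val.item() == 0.0


@pytest.fixture(scope="module")
def model_and_batch(tiny_cohort, small_encoder_cfg, small_integrator_cfg):
    model = build_model(tiny_cohort, tiny_cohort.graphs, small_encoder_cfg,
                        small_integrator_cfg, seed=0)
    feats = {m: Tensor(np.nan_to_num(tiny_cohort.modality_features[m][:16]))
             for m in model.modalities}
    masks = {m: tiny_cohort.modality_masks[m][:16] for m in model.modalities}
    return model, feats, masks, tiny_cohort.labels[:16]


class TestTotalLoss:
    def test_lambdas_zero_leaves_prediction_losses(self, model_and_batch):
        model, feats, masks, labels = model_and_batch
        out = model.forward(feats, masks)
        cfg = LossConfig(lambda1=0, lambda2=0, lambda3=0)
        loss, comps = total_loss(out, labels, cfg, model=model)
        expected = sum(v for k, v in comps.items() if k.startswith("pred_")
                       and k != "pred_integrated")
        assert loss.item() == pytest.approx(expected, rel=1e-10)

    def test_perfect_logits_drive_loss_to_zero(self):
        logits = Tensor(np.array([[10.0, -10.0], [-10.0, 10.0]]))
        out = {"unimodal": {"m": (logits, np.array([0, 1]))},
               "integrated": None, "embeddings": {}}
        loss, _ = total_loss(out, np.array([0, 1]),
                             LossConfig(lambda1=0, lambda2=0, lambda3=0))
        assert loss.item() <= 1e-3

    def test_single_modality_batch_gives_exactly_zero_integrator_grad(
            self, model_and_batch, tiny_cohort):
        model, _, _, _ = model_and_batch
        feats = {"rna": Tensor(np.nan_to_num(
            tiny_cohort.modality_features["rna"][:8]))}
        out = model.forward(feats, {"rna": np.ones(8, bool)})
        loss, _ = total_loss(out, tiny_cohort.labels[:8],
                             LossConfig(lambda3=0.0), model=model)
        model.zero_grad()
        loss.backward()
        for _, p in model.integrator.named_parameters():
            assert p.grad is None or np.all(p.grad == 0.0)

    def test_class_weights_inverse_frequency_mean_one(self):
        w = make_class_weights(np.array([1, 1, 1, 0]))
        assert w.mean() == pytest.approx(1.0)
        assert w[0] / w[1] == pytest.approx(3.0)


class TestIncompleteEpoch:
    def make(self, seed=0):
        cfg = SimulationConfig(n_samples_complete=8, n_samples_mod1_only=4,
                               n_samples_mod2_only=4,
                               n_nodes_per_modality=(10, 10), n_informative=2,
                               seed=seed)
        return generate_cohort(cfg)

    def test_step_count_over_disjoint_subsets(self, small_encoder_cfg,
                                              small_integrator_cfg):
        ds = self.make()
        model = build_model(ds, ds.graphs, small_encoder_cfg,
                            small_integrator_cfg, seed=0)
        opt = Adam(model.parameters())
        log = train_epoch_incomplete(ds, model, opt, LossConfig(),
                                     init_rng(0), batch_size=4)
        assert len(log) == 4  # subsets of 8, 4, 4 at batch 4

    def test_subset_order_reproducible(self, small_encoder_cfg,
                                       small_integrator_cfg):
        orders = []
        for _ in range(2):
            ds = self.make()
            model = build_model(ds, ds.graphs, small_encoder_cfg,
                                small_integrator_cfg, seed=0)
            log = train_epoch_incomplete(ds, model, Adam(model.parameters()),
                                         LossConfig(), init_rng(5), batch_size=4)
            orders.append([rec["subset"] for rec in log])
        assert orders[0] == orders[1]

    def test_complete_only_reduces_to_standard_epoch(self, small_encoder_cfg,
                                                     small_integrator_cfg):
        cfg = SimulationConfig(n_samples_complete=12, n_samples_mod1_only=0,
                               n_samples_mod2_only=0,
                               n_nodes_per_modality=(10, 10), n_informative=2,
                               seed=1)
        ds = generate_cohort(cfg)
        model = build_model(ds, ds.graphs, small_encoder_cfg,
                            small_integrator_cfg, seed=0)
        log = train_epoch_incomplete(ds, model, Adam(model.parameters()),
                                     LossConfig(), init_rng(0), batch_size=6)
        assert {rec["subset"] for rec in log} == {"complete"}
        assert all("pred_integrated" in rec for rec in log)

    def test_loss_decreases_over_twenty_epochs(self):
        """Median final-epoch loss below first-epoch loss on planted signal."""
        firsts, lasts = [], []
        for seed in range(3):
            cfg = SimulationConfig(n_samples_complete=40,
                                   n_samples_mod1_only=10,
                                   n_samples_mod2_only=10,
                                   n_nodes_per_modality=(20, 20),
                                   n_informative=4, effect_size=2.0, seed=seed)
            ds = generate_cohort(cfg)
            from graphomix.encoder import EncoderConfig
            from graphomix.integration import IntegratorConfig
            model = build_model(ds, ds.graphs,
                                EncoderConfig(n_communities=2, n_conv_blocks=1,
                                              channels=3, n_clusters=2,
                                              features_per_cluster=2,
                                              embedding_dim=8),
                                IntegratorConfig(n_blocks=1, n_heads=2),
                                seed=seed)
            hist = fit(model, ds, LossConfig(),
                       TrainConfig(n_epochs=20, batch_size=16, seed=seed))
            firsts.append(hist[0]["loss"])
            lasts.append(hist[-1]["loss"])
        assert np.median(lasts) < np.median(firsts)


class TestStratifiedKFold:
    def test_nine_samples_six_three(self):
        plan = stratified_kfold(np.array([1] * 6 + [0] * 3), k=3, seed=0)
        for fold in range(3):
            _, val = plan.split(fold)
            labels = np.array([1] * 6 + [0] * 3)[val]
            assert (labels == 1).sum() == 2 and (labels == 0).sum() == 1

    def test_single_fold_is_everything(self):
        plan = stratified_kfold(np.array([0, 1, 0, 1]), k=1)
        assert np.array_equal(plan.fold_assignment, np.zeros(4, dtype=int))

    def test_reproducible(self):
        labels = np.array([0, 1] * 10)
        a = stratified_kfold(labels, 3, seed=9).fold_assignment
        b = stratified_kfold(labels, 3, seed=9).fold_assignment
        assert np.array_equal(a, b)

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_kfold(np.array([0, 0, 0, 1, 1]), k=3)


class TestGridSearch:
    def evaluator(self, config, dataset, train_idx, val_idx, seed):
        # score tracks the config's "quality" plus seeded noise
        rng = np.random.default_rng(seed)
        return config["quality"] + 0.01 * rng.random()

    def test_singleton_grid(self):
        labels = np.array([0, 1] * 6)
        ds = type("D", (), {"labels": labels})()
        plan = stratified_kfold(labels, 3, seed=0)
        best, table = grid_search([{"quality": 0.5}], ds, plan, self.evaluator)
        assert best == {"quality": 0.5} and len(table) == 9

    def test_sabotaged_config_loses(self):
        labels = np.array([0, 1] * 6)
        ds = type("D", (), {"labels": labels})()
        plan = stratified_kfold(labels, 3, seed=0)
        best, table = grid_search([{"quality": 0.0}, {"quality": 0.9}],
                                  ds, plan, self.evaluator)
        assert best == {"quality": 0.9} and len(table) == 18

    def test_real_training_grid_zero_lr_loses(self, tiny_cohort,
                                              small_encoder_cfg,
                                              small_integrator_cfg):
        plan = stratified_kfold(tiny_cohort.labels, k=3, seed=0)
        plan.n_seeds_per_split = 1

        def evaluator(config, dataset, train_idx, val_idx, seed):
            model = build_model(dataset, dataset.graphs, small_encoder_cfg,
                                small_integrator_cfg, seed=seed)
            fit(model, dataset.subset(train_idx), LossConfig(),
                TrainConfig(lr=config["lr"], n_epochs=4, batch_size=16,
                            seed=seed))
            return evaluate_accuracy(model, dataset.subset(val_idx))["accuracy"]

        best, table = grid_search([{"lr": 0.0}, {"lr": 5e-3}],
                                  tiny_cohort, plan, evaluator)
        assert best == {"lr": 5e-3} and len(table) == 6
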