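"""Splits, schedule, augmentation, metrics, and the training loop."""

import numpy as np
import pytest
from sklearn import metrics as skm

from vitfusion.model import ModelConfig, MultiModalViT
from vitfusion.nn import cross_entropy
from vitfusion.synthetic import CohortConfig, generate_cohort
from vitfusion.training import (AugmentConfig, TrainConfig, augment_volume,
                                binary_metrics, evaluate, split, train,
                                warmup_step_lr)


class TestSplit:
    def test_100_subjects_split_80_10_10(self):
        labels = ["patient"] * 50 + ["control"] * 50
        folds = split(labels, TrainConfig(seed=1))
        assert len(folds) == 10
        for fold in folds:
            assert (len(fold["train"]), len(fold["val"]), len(fold["test"])) \
                == (80, 10, 10)

    def test_sets_disjoint_and_cover_cohort(self):
        labels = ["patient"] * 23 + ["control"] * 31
        folds = split(labels, TrainConfig(seed=2))
        for fold in folds:
            all_idx = np.concatenate([fold["train"], fold["val"], fold["test"]])
            assert len(all_idx) == len(set(all_idx)) == 54

    def test_stratification_within_one_subject(self):
        labels = np.array(["patient"] * 40 + ["control"] * 60)
        global_frac = 0.4
        for fold in split(labels, TrainConfig(seed=3)):
            for part in ("train", "val", "test"):
                sub = labels[fold[part]]
                expected = global_frac * len(sub)
                assert abs((sub == "patient").sum() - expected) <= 1

    def test_deterministic_given_seed(self):
        labels = ["patient"] * 15 + ["control"] * 15
        a = split(labels, TrainConfig(seed=7))
        b = split(labels, TrainConfig(seed=7))
        for fa, fb in zip(a, b):
            for part in fa:
                np.testing.assert_array_equal(fa[part], fb[part])

    def test_class_smaller_than_fold_count_rejected(self):
        with pytest.raises(ValueError, match="fewer"):
            split(["patient"] * 5 + ["control"] * 20, TrainConfig())


class TestSchedule:
    def test_ramp_and_decay_closed_form(self):
        cfg = TrainConfig(total_epochs=200, warmup_epochs=30, lr_step=50,
                          lr_gamma=0.5)
        assert warmup_step_lr(0, cfg) == pytest.approx(1 / 30)
        assert warmup_step_lr(29, cfg) == pytest.approx(1.0)
        assert warmup_step_lr(30, cfg) == 1.0
        assert warmup_step_lr(30 + 100, cfg) == pytest.approx(0.25)
        assert warmup_step_lr(30 + 149, cfg) == pytest.approx(0.25)

    def test_epoch_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            warmup_step_lr(200, TrainConfig())

    def test_warmup_must_precede_total(self):
        with pytest.raises(ValueError, match="warmup"):
            TrainConfig(total_epochs=10, warmup_epochs=10)


class TestAugmentation:
    def test_shape_preserved_and_volume_changed(self, rng):
        vol = rng.standard_normal((16, 16, 16))
        aug = AugmentConfig()
        out = augment_volume(vol, aug, np.random.default_rng(0))
        assert out.shape == vol.shape
        assert not np.array_equal(out, vol)

    def test_disabled_augmentation_is_identity(self, rng):
        vol = rng.standard_normal((8, 8, 8))
        out = augment_volume(vol, AugmentConfig(enabled=False),
                             np.random.default_rng(0))
        np.testing.assert_array_equal(out, vol)

    def test_fnc_and_labels_untouched_during_training(self, tiny_cohort,
                                                      fast_train_config,
                                                      tiny_model_config):
        _, records, _ = tiny_cohort
        fncs_before = [r.fnc.copy() for r in records]
        labels_before = [r.label for r in records]
        cfg = fast_train_config
        cfg.augmentation = AugmentConfig(crop_shift=1, affine_degrees=2,
                                         noise_sd=0.01)
        model = MultiModalViT(tiny_model_config, rng=0)
        train(model, records, cfg, np.arange(8))
        for rec, fnc, label in zip(records, fncs_before, labels_before):
            np.testing.assert_array_equal(rec.fnc, fnc)
            assert rec.label == label


class TestMetrics:
    def test_hand_computed_confusion_matrix(self):
        # TP=3, FP=1, FN=2, TN=4
        y = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        s = np.array([.9, .8, .7, .2, .1, .6, .3, .2, .1, .05])
        rep = binary_metrics(y, s)
        assert rep.precision == pytest.approx(0.75)
        assert rep.f1 == pytest.approx(2 / 3)
        assert rep.balanced_accuracy == pytest.approx(0.7)

    def test_perfect_separation(self):
        rep = binary_metrics(np.array([0, 0, 1, 1]),
                             np.array([0.1, 0.2, 0.8, 0.9]))
        assert rep.auc == 1.0 and rep.balanced_accuracy == 1.0

    def test_constant_predictor_balanced_accuracy_half(self):
        rep = binary_metrics(np.array([0, 1, 0, 1]), np.ones(4))
        assert rep.balanced_accuracy == pytest.approx(0.5)

    def test_single_class_auc_missing_with_warning(self):
        with pytest.warns(RuntimeWarning, match="AUC"):
            rep = binary_metrics(np.ones(4, dtype=int), np.linspace(0, 1, 4))
        assert rep.auc is None

    def test_agrees_with_reference_implementation_on_100_cases(self):
        """All five metrics match scikit-learn to 1e-10 on random vectors."""
        gen = np.random.default_rng(123)
        for _ in range(100):
            n = int(gen.integers(10, 40))
            y = gen.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                y[0], y[1] = 0, 1
            s = np.round(gen.random(n), 2)  # ties included
            rep = binary_metrics(y, s)
            pred = (s >= 0.5).astype(int)
            assert rep.auc == pytest.approx(skm.roc_auc_score(y, s), abs=1e-10)
            assert rep.accuracy == pytest.approx(
                skm.accuracy_score(y, pred), abs=1e-10)
            assert rep.balanced_accuracy == pytest.approx(
                skm.balanced_accuracy_score(y, pred), abs=1e-10)
            assert rep.f1 == pytest.approx(
                skm.f1_score(y, pred, zero_division=0), abs=1e-10)
            assert rep.precision == pytest.approx(
                skm.precision_score(y, pred, zero_division=0), abs=1e-10)


class TestTrainLoop:
    def test_zero_epochs_leave_model_unchanged(self, tiny_cohort,
                                               tiny_model_config):
        _, records, _ = tiny_cohort
        model = MultiModalViT(tiny_model_config, rng=1)
        before = {k: v.copy() for k, v in model.state_dict().items()}
        cfg = TrainConfig(total_epochs=0, warmup_epochs=0, seed=0)
        train(model, records, cfg, np.arange(8))
        for k, v in model.state_dict().items():
            np.testing.assert_array_equal(v, before[k])

    def test_loss_decreases_on_separable_toy_cohort(self):
        """Large effect, no noise: early loss curve decreases in >= 9/10 seeds."""
        cohort_cfg = CohortConfig(n_subjects_per_group=6,
                                  volume_shape=(16, 16, 16), n_timepoints=100,
                                  effect_size_structural=0.8,
                                  effect_size_fnc=0.45, noise_sd=0.0, seed=77)
        records, _ = generate_cohort(cohort_cfg)
        model_cfg = ModelConfig(volume_shape=(16, 16, 16), patch3d=(8, 8, 8),
                                d_model=16, depth_3d=1, depth_2d=1, heads=2,
                                ca_heads=2, head_hidden=8)
        wins = 0
        for seed in range(10):
            model = MultiModalViT(model_cfg, rng=seed)
            cfg = TrainConfig(total_epochs=10, warmup_epochs=2, batch_size=12,
                              seed=seed,
                              augmentation=AugmentConfig(enabled=False))
            _, log = train(model, records, cfg, np.arange(12))
            losses = [e["loss"] for e in log]
            wins += losses[-1] < losses[0]
        assert wins >= 9

    def test_gradient_matches_finite_difference_on_sampled_weight(self,
                                                                  tiny_cohort):
        _, records, _ = tiny_cohort
        cfg = ModelConfig(volume_shape=(32, 32, 32), patch3d=(16, 16, 16),
                          d_model=8, depth_3d=1, depth_2d=1, heads=2,
                          ca_heads=2, head_hidden=4)
        model = MultiModalViT(cfg, rng=2)
        vols = np.stack([r.volume for r in records[:4]])
        fncs = np.stack([r.fnc for r in records[:4]])
        y = np.array([0, 0, 1, 1])

        def loss():
            return cross_entropy(model(vols, fncs).logits, y)

        loss().backward()
        w = model.blocks3d[0].attn.w_q.weight
        ana = w.grad.flat[3]
        eps = 1e-5
        orig = w.data.flat[3]
        w.data.flat[3] = orig + eps
        up = loss().data.item()
        w.data.flat[3] = orig - eps
        dn = loss().data.item()
        w.data.flat[3] = orig
        num = (up - dn) / (2 * eps)
        assert ana == pytest.approx(num, rel=1e-4)

    def test_best_validation_checkpoint_restored(self, tiny_cohort,
                                                 tiny_model_config,
                                                 fast_train_config):
        _, records, _ = tiny_cohort
        model = MultiModalViT(tiny_model_config, rng=3)
        model, log = train(model, records, fast_train_config, np.arange(12),
                           np.arange(12, 16))
        assert any("val_balanced_accuracy" in e for e in log)
        rep = evaluate(model, records, np.arange(16, 20))
        assert 0.0 <= rep.balanced_accuracy <= 1.0
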