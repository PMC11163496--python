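"""Training protocol: splits, augmentation, early stopping, ensembles."""

import numpy as np
import pandas as pd
import pytest

from qaerr.network import HybridNet, NetConfig
from qaerr.training import (
    AugmentConfig,
    TrainConfig,
    augment_channels,
    ensemble_predict,
    kfold_by_plan,
    split_plan_level,
    train_fold,
)
from qaerr.nn.optim import AdamW, CosineAnnealingLR


def _manifest(n_plans: int, rows_per_plan: int = 9) -> pd.DataFrame:
    rows = []
    for p in range(n_plans):
        for r in range(rows_per_plan):
            rows.append({"plan_id": f"p{p:02d}", "beam_id": "b0",
                         "family": ["error_free", "shift", "shift", "opening",
                                    "opening", "closing", "closing", "random",
                                    "random"][r % 9]})
    return pd.DataFrame(rows)


TINY_NET = NetConfig(
    input_size=16, in_channels=1, stem_channels=4, stem_kernel=3,
    stem_stride=2, rca_stages=((4, 1, 2),), bottleneck_ratio=1.0,
    attention_stages=((8, 2, 2, 2),), mlp_ratio=1.0, dropout=0.0,
    droppath=0.0, seed=0)


def _toy_data(n_per_class: int = 10, seed: int = 0):
    """Linearly separable two-class images: constant +0.5 vs -0.5."""
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for cls, level in ((0, 0.5), (1, -0.5)):
        x = level + rng.normal(0, 0.05, (n_per_class, 1, 16, 16))
        xs.append(x)
        ys.append(np.full(n_per_class, cls))
    return (np.concatenate(xs).astype(np.float32),
            np.concatenate(ys).astype(np.int64))


class TestSplit:
    def test_ratio_and_disjointness(self):
        train, test = split_plan_level(_manifest(10), 0.2, seed=1)
        assert train["plan_id"].nunique() == 8
        assert test["plan_id"].nunique() == 2
        assert not set(train["plan_id"]) & set(test["plan_id"])

    def test_seed_determinism(self):
        m = _manifest(10)
        t1 = split_plan_level(m, 0.2, seed=5)[1]
        t2 = split_plan_level(m, 0.2, seed=5)[1]
        assert list(t1["plan_id"]) == list(t2["plan_id"])

    def test_every_plan_tests_at_expected_rate(self):
        m = _manifest(10)
        hits = {f"p{p:02d}": 0 for p in range(10)}
        n_seeds = 400
        for seed in range(n_seeds):
            _, test = split_plan_level(m, 0.2, seed=seed)
            for p in set(test["plan_id"]):
                hits[p] += 1
        freqs = np.array(list(hits.values())) / n_seeds
        assert np.all(np.abs(freqs - 0.2) < 0.1)

    def test_single_plan_rejected(self):
        with pytest.raises(ValueError):
            split_plan_level(_manifest(1), 0.2, seed=0)


class TestKFold:
    def test_exact_partition(self):
        m = _manifest(10)
        folds = kfold_by_plan(m, 5, seed=2)
        assert len(folds) == 5
        val_ids = [set(v["plan_id"]) for _, v in folds]
        assert all(len(v) == 2 for v in val_ids)
        union = set().union(*val_ids)
        assert union == set(m["plan_id"])
        for i in range(5):
            for j in range(i + 1, 5):
                assert not val_ids[i] & val_ids[j]
            tr, va = folds[i]
            assert len(tr) + len(va) == len(m)
            assert not set(tr["plan_id"]) & set(va["plan_id"])

    def test_class_balance_within_one(self):
        m = _manifest(10)
        folds = kfold_by_plan(m, 5, seed=3)
        overall = m["family"].value_counts()
        n_plans = m["plan_id"].nunique()
        for _, val in folds:
            frac = val["plan_id"].nunique() / n_plans
            counts = val["family"].value_counts()
            for fam, total in overall.items():
                assert abs(counts.get(fam, 0) - total * frac) <= 1 + 1e-9

    def test_too_few_plans_rejected(self):
        with pytest.raises(ValueError):
            kfold_by_plan(_manifest(3), 5, seed=0)


class TestAugment:
    def test_all_switches_off_is_identity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 0.3, (32, 32, 3)).astype(np.float32)
        out = augment_channels(x, AugmentConfig.none(), rng)
        np.testing.assert_array_equal(out, np.clip(x, -1, 1))

    def test_horizontal_flip_is_involution(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 0.3, (16, 16, 3)).astype(np.float32)
        np.testing.assert_array_equal(x[:, ::-1][:, ::-1], x)

    def test_channels_transformed_identically(self):
        rng = np.random.default_rng(2)
        base = rng.normal(0, 0.3, (32, 32)).astype(np.float32)
        x = np.stack([base] * 3, axis=-1)
        cfg = AugmentConfig(jitter=False)  # jitter is per-sample, still global
        out = augment_channels(x, cfg, np.random.default_rng(3))
        np.testing.assert_array_equal(out[:, :, 0], out[:, :, 1])
        np.testing.assert_array_equal(out[:, :, 0], out[:, :, 2])

    def test_jitter_preserves_pixel_rank_order(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(-0.5, 0.5, (24, 24, 3)).astype(np.float32)
        cfg = AugmentConfig(erasure=False, affine=False, rotation=False,
                            flip=False, jitter=True)
        out = augment_channels(x, cfg, np.random.default_rng(5))
        for c in range(3):
            np.testing.assert_array_equal(
                np.argsort(out[:, :, c].ravel(), kind="stable"),
                np.argsort(x[:, :, c].ravel(), kind="stable"))

    def test_erasure_zeroes_a_rectangle_in_all_channels(self):
        x = np.full((32, 32, 3), 0.5, np.float32)
        cfg = AugmentConfig(erasure=True, affine=False, rotation=False,
                            flip=False, jitter=False)
        out = augment_channels(x, cfg, np.random.default_rng(6))
        zero_mask = np.all(out == 0.0, axis=2)
        assert zero_mask.any()
        rows = np.where(zero_mask.any(axis=1))[0]
        cols = np.where(zero_mask.any(axis=0))[0]
        assert zero_mask[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1].all()

    def test_output_clipped(self):
        x = np.full((16, 16, 3), 0.99, np.float32)
        cfg = AugmentConfig(erasure=False, affine=False, rotation=False,
                            flip=False, jitter=True,
                            contrast_range=(1.5, 1.5),
                            brightness_range=(0.2, 0.2))
        out = augment_channels(x, cfg, np.random.default_rng(7))
        assert out.max() <= 1.0


class TestTrainFold:
    def test_lr_starts_at_config_and_follows_cosine(self):
        x, y = _toy_data(6)
        tc = TrainConfig(lr=1e-3, batch_size=8, max_epochs=4, patience=4,
                         augment=AugmentConfig.none(), seed=0)
        _, hist = train_fold(x, y, x, y, TINY_NET, tc)
        assert hist.lr[0] == pytest.approx(1e-3)
        expected = [1e-3 * 0.5 * (1 + np.cos(np.pi * e / 4)) for e in range(4)]
        np.testing.assert_allclose(hist.lr, expected, rtol=1e-12)

    def test_toy_problem_reaches_perfect_training_accuracy(self):
        x, y = _toy_data(10)
        tc = TrainConfig(lr=3e-3, batch_size=8, max_epochs=20, patience=20,
                         augment=AugmentConfig.none(), seed=1)
        model, _ = train_fold(x, y, x, y, TINY_NET, tc)
        acc = (model.predict_proba(x).argmax(1) == y).mean()
        assert acc == 1.0

    def test_patience_zero_stops_at_first_non_improvement(self):
        x, y = _toy_data(6)
        tc = TrainConfig(lr=0.5, batch_size=8, max_epochs=30, patience=0,
                         augment=AugmentConfig.none(), seed=2)
        _, hist = train_fold(x, y, x, y, TINY_NET, tc)
        if hist.stopped_epoch >= 0:  # early stop triggered
            assert hist.stopped_epoch == hist.best_epoch + 1

    def test_best_checkpoint_has_minimum_val_loss(self):
        x, y = _toy_data(8)
        tc = TrainConfig(lr=3e-3, batch_size=8, max_epochs=10, patience=10,
                         augment=AugmentConfig.none(), seed=3)
        model, hist = train_fold(x, y, x, y, TINY_NET, tc)
        assert hist.best_epoch == int(np.argmin(hist.val_loss))

    def test_bit_reproducible_under_fixed_seed(self):
        x, y = _toy_data(6)
        tc = TrainConfig(lr=1e-3, batch_size=8, max_epochs=3, patience=3,
                         seed=4)  # augmentation ON: its draws must be seeded
        m1, h1 = train_fold(x, y, x, y, TINY_NET, tc)
        m2, h2 = train_fold(x, y, x, y, TINY_NET, tc)
        assert h1.train_loss == h2.train_loss
        for (n1, p1), (n2, p2) in zip(m1.named_parameters(),
                                      m2.named_parameters()):
            np.testing.assert_array_equal(p1.data, p2.data), n1


class TestEnsemble:
    def test_identical_models_equal_single(self):
        x, _ = _toy_data(4)
        model = HybridNet(TINY_NET)
        single = model.predict_proba(x)
        ens = ensemble_predict([model] * 5, x)
        np.testing.assert_allclose(ens, single, atol=1e-7)

    def test_rows_remain_normalized(self):
        x, _ = _toy_data(4)
        models = [HybridNet(TINY_NET), HybridNet(
            NetConfig(**{**TINY_NET.__dict__, "seed": 9}))]
        ens = ensemble_predict(models, x)
        np.testing.assert_allclose(ens.sum(1), 1.0, atol=1e-6)

    def test_ensemble_logloss_bounded_by_worst_member(self):
        x, y = _toy_data(8, seed=5)
        models = [HybridNet(NetConfig(**{**TINY_NET.__dict__, "seed": s}))
                  for s in range(4)]

        def logloss(p):
            return -np.mean(np.log(p[np.arange(len(y)), y] + 1e-12))

        member_losses = [logloss(m.predict_proba(x)) for m in models]
        assert logloss(ensemble_predict(models, x)) <= max(member_losses) + 1e-9

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            ensemble_predict([], np.zeros((1, 1, 16, 16), np.float32))


def test_cosine_schedule_endpoints():
    class P:  # minimal parameter stub
        data = np.zeros(1)
        grad = None

    opt = AdamW([], lr=1e-3)
    sched = CosineAnnealingLR(opt, t_max=10)
    assert sched.lr_at(0) == pytest.approx(1e-3)
    assert sched.lr_at(5) == pytest.approx(5e-4)
    assert sched.lr_at(10) == pytest.approx(0.0)
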