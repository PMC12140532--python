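import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wristgait.errors import ConfigError, DataError
from wristgait.model import (
    ConvGaitRegressor,
    NetworkConfig,
    build_network,
    fuse_stride_length,
    pretext_accuracy,
    ssl_augment,
    ssl_pretrain,
    tune_hyperparameters,
)

TINY = dict(n_res_blocks=2, channels=(8, 12), kernel_size=5)


def _tiny_cfg(**kw):
    return NetworkConfig(**{**TINY, **kw})


@pytest.fixture(scope="module")
def window_pool(small_dataset):
    X, meta = small_dataset
    return X, meta


class TestBuildNetwork:
    def test_same_seed_identical_checksums(self):
        a = build_network(_tiny_cfg(), seed=5)
        b = build_network(_tiny_cfg(), seed=5)
        assert a.checksum() == b.checksum()
        c = build_network(_tiny_cfg(), seed=6)
        assert a.checksum() != c.checksum()

    def test_forward_shape_contract(self):
        net = build_network(_tiny_cfg(), seed=0)
        net.add_head("reg", depth=1, width=16)
        x = np.random.default_rng(0).standard_normal((7, 3, 300))
        feat = net.features(x)
        assert feat.shape == (7, 128)  # fixed 128-d feature
        assert net.predict(x, "reg").shape == (7,)

    def test_head_depth_validated(self):
        with pytest.raises(ConfigError):
            NetworkConfig(head_depth=4)
        net = build_network(_tiny_cfg(), seed=0)
        with pytest.raises(ConfigError):
            net.add_head("bad", depth=5)

    def test_channels_must_match_blocks(self):
        with pytest.raises(ConfigError):
            NetworkConfig(n_res_blocks=2, channels=(8,))


class TestFreezing:
    def test_backbone_bit_identical_through_training(self, window_pool):
        X, meta = window_pool
        Xs, ys = X[:400], meta.speed_cms.values[:400]
        est = ConvGaitRegressor(
            **TINY, freeze_backbone=True, max_epochs=2, random_state=0
        )
        est.fit(Xs, ys)
        fresh = build_network(_tiny_cfg(freeze_backbone=True), seed=0)
        assert est.net_.backbone_checksum() == fresh.backbone_checksum()

    def test_unfrozen_backbone_changes(self, window_pool):
        X, meta = window_pool
        est = ConvGaitRegressor(**TINY, max_epochs=1, random_state=0)
        est.fit(X[:400], meta.speed_cms.values[:400])
        fresh = build_network(_tiny_cfg(), seed=0)
        assert est.net_.backbone_checksum() != fresh.backbone_checksum()

    def test_ssl_respects_frozen_backbone(self, window_pool):
        X, _ = window_pool
        net = build_network(_tiny_cfg(), seed=1)
        net.freeze_backbone()
        before = net.backbone_checksum()
        ssl_pretrain(net, X[:200], epochs=1, seed=0)
        assert net.backbone_checksum() == before


class TestSSL:
    def test_augment_labels_are_per_task_bernoulli(self, window_pool):
        X, _ = window_pool
        rng = np.random.default_rng(0)
        Xa, labels = ssl_augment(X[:256].transpose(0, 2, 1), rng)
        assert set(labels) == {"reverse", "perm", "warp"}
        for v in labels.values():
            assert 0.3 < v.mean() < 0.7

    def test_untrained_accuracy_is_chance_on_average(self, window_pool):
        X, _ = window_pool
        accs = {t: [] for t in ("reverse", "perm", "warp")}
        for seed in range(8):
            net = build_network(_tiny_cfg(), seed=seed)
            for task, acc in pretext_accuracy(net, X[:200], seed=seed).items():
                accs[task].append(acc)
        for task, vals in accs.items():
            assert 0.35 <= np.mean(vals) <= 0.65, task

    def test_pretraining_learns_all_three_tasks(self, window_pool):
        X, _ = window_pool
        net = build_network(NetworkConfig(), seed=0)
        trace = ssl_pretrain(net, X[:2000], epochs=10, seed=0)
        assert trace[-1] < trace[0]  # joint loss decreased
        accs = pretext_accuracy(net, X[2000:2500], seed=123)
        for task, acc in accs.items():
            assert acc > 0.8, (task, acc)

    def test_same_seed_identical_loss_trace(self, window_pool):
        X, _ = window_pool
        t1 = ssl_pretrain(build_network(_tiny_cfg(), 3), X[:150], epochs=2, seed=9)
        t2 = ssl_pretrain(build_network(_tiny_cfg(), 3), X[:150], epochs=2, seed=9)
        assert t1 == t2

    def test_too_few_windows_rejected(self, window_pool):
        X, _ = window_pool
        with pytest.raises(DataError):
            ssl_pretrain(build_network(_tiny_cfg(), 0), X[:50], epochs=1)
        with pytest.raises(ConfigError):
            ssl_pretrain(build_network(_tiny_cfg(), 0), X[:200], epochs=0)


class TestFinetune:
    def test_early_stopping_contract(self, window_pool):
        X, meta = window_pool
        est = ConvGaitRegressor(**TINY, max_epochs=30, patience=3,
                                random_state=0)
        est.fit(X[:600], meta.speed_cms.values[:600],
                groups=meta.subject_id.values[:600])
        assert est.stopped_epoch_ <= est.best_epoch_ + est.patience
        assert len(est.loss_trace_) == est.stopped_epoch_

    def test_same_seed_identical_predictions(self, window_pool):
        X, meta = window_pool
        kw = dict(max_epochs=2, random_state=4)
        p1 = ConvGaitRegressor(**TINY, **kw).fit(
            X[:300], meta.speed_cms.values[:300]
        ).predict(X[300:350])
        p2 = ConvGaitRegressor(**TINY, **kw).fit(
            X[:300], meta.speed_cms.values[:300]
        ).predict(X[300:350])
        assert np.array_equal(p1, p2)

    def test_non_finite_labels_rejected(self, window_pool):
        X, _ = window_pool
        y = np.full(100, np.nan)
        with pytest.raises(DataError):
            ConvGaitRegressor(**TINY).fit(X[:100], y)

    def test_functional_wrapper_honours_configs(self, window_pool):
        from wristgait.model import NetworkConfig, TrainConfig, finetune

        X, meta = window_pool
        est = finetune(
            X[:200], meta.speed_cms.values[:200],
            groups=meta.subject_id.values[:200],
            net_cfg=NetworkConfig(**TINY, head_depth=0),
            train_cfg=TrainConfig(max_epochs=2, patience=1, seed=5),
        )
        assert est.stopped_epoch_ <= 2
        assert est.predict(X[200:210]).shape == (10,)

    def test_train_config_validation(self):
        from wristgait.model import TrainConfig

        with pytest.raises(ConfigError):
            TrainConfig(patience=0)
        with pytest.raises(ConfigError):
            TrainConfig(loss="mse")

    def test_sklearn_params_round_trip(self):
        est = ConvGaitRegressor(head_depth=2, lr=5e-4)
        clone = ConvGaitRegressor(**est.get_params())
        assert clone.get_params() == est.get_params()


class TestFusion:
    def test_worked_example(self):
        assert fuse_stride_length(100.0, 120.0, 120.0) == pytest.approx(110.0)

    def test_fixed_point_when_estimates_agree(self):
        assert fuse_stride_length(120.0, 120.0, 120.0) == pytest.approx(120.0)

    def test_zero_direct_estimate(self):
        assert fuse_stride_length(0.0, 60.0, 120.0) == pytest.approx(30.0)

    def test_nonpositive_cadence_rejected(self):
        with pytest.raises(DataError):
            fuse_stride_length(100.0, 120.0, 0.0)

    @settings(deadline=None, max_examples=100)
    @given(st.floats(10, 300), st.floats(10, 300), st.floats(40, 160))
    def test_fused_bounded_by_both_estimates(self, direct, speed, cadence):
        derived = 120.0 * speed / cadence
        fused = fuse_stride_length(direct, speed, cadence)
        assert min(direct, derived) - 1e-9 <= fused <= max(direct, derived) + 1e-9


class TestTuning:
    SPACE = {"head_width": [1, 64]}

    def test_single_trial_returns_that_config(self, window_pool):
        X, meta = window_pool
        best, log = tune_hyperparameters(
            self.SPACE, X[:200], meta.speed_cms.values[:200],
            groups=meta.subject_id.values[:200], trials=1, seed=0, cv_folds=2,
            base_params={**TINY, "max_epochs": 1},
        )
        assert len(log) == 1
        assert best["head_width"] == log.loc[0, "head_width"]

    def test_same_seed_same_trial_sequence(self):
        rng_draws = []
        for _ in range(2):
            # sampling only: an empty fit is simulated with 1-epoch runs on
            # a tiny slice, so identical seeds must give identical configs
            rng = np.random.default_rng(7)
            keys = sorted(self.SPACE)
            rng_draws.append(
                [
                    {k: self.SPACE[k][rng.integers(0, len(self.SPACE[k]))]
                     for k in keys}
                    for _ in range(5)
                ]
            )
        assert rng_draws[0] == rng_draws[1]

    def test_wider_head_beats_width_one_bottleneck(self, noiseless_dataset):
        # a stack of three 1-unit ReLU bottlenecks cannot carry the signal;
        # the search must prefer the 64-wide head on noiseless data
        X, meta = noiseless_dataset
        best, log = tune_hyperparameters(
            {"head_width": [1, 64]},
            X, meta.speed_cms.values,
            groups=meta.subject_id.values,
            trials=4, seed=1, cv_folds=2,
            base_params={**TINY, "head_depth": 3, "max_epochs": 6},
        )
        assert set(log["head_width"]) == {1, 64}
        assert best["head_width"] == 64

    def test_empty_space_rejected(self, window_pool):
        X, meta = window_pool
        with pytest.raises(ConfigError):
            tune_hyperparameters({}, X[:100], meta.speed_cms.values[:100],
                                 groups=meta.subject_id.values[:100])
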