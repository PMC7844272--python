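import numpy as np
import pytest

from _oracles import oracle_total_loss
from plateseg.model import tiny_model_config, tiny_train_config
from plateseg.model_zoo import NetworkParams, build_network, partition_params
from plateseg.nn import Adam, Parameter
from plateseg.training import (
    LossParams,
    TrainConfig,
    cross_entropy_map,
    loss_tensor,
    lr_schedule,
    one_hot,
    run_experiment,
    total_loss,
    train_instance,
)
from plateseg.volume_io import ImageVolume, LabelVolume, normalize_zscore
from plateseg.weight_maps import WeightVolume
from plateseg.windowing import WindowSpec

EMPTY_PARTS = NetworkParams()


class TestCrossEntropyMap:
    def test_reference_values(self, rng):
        lab = rng.integers(0, 7, size=(2, 3, 3))
        x = one_hot(lab)
        assert np.allclose(cross_entropy_map(x, x), 0.0, atol=1e-9)
        uniform = np.full((7, 2, 3, 3), 1.0 / 7)
        np.testing.assert_allclose(cross_entropy_map(x, uniform), np.log(7))
        half = np.full((7, 2, 3, 3), 0.5 / 6)
        np.put_along_axis(half, lab[None], 0.5, axis=0)
        np.testing.assert_allclose(cross_entropy_map(x, half), np.log(2))


class TestTotalLoss:
    def test_perfect_prediction_zero_loss(self, rng):
        lab = rng.integers(0, 7, size=(2, 4, 4))
        x = one_hot(lab)
        w = np.ones((2, 4, 4))
        assert total_loss(x, x, x, w, LossParams(), EMPTY_PARTS) == pytest.approx(0.0)

    def test_uniform_heads_give_scaled_log7(self, rng):
        lab = rng.integers(0, 7, size=(2, 4, 4))
        x = one_hot(lab)
        uniform = np.full((7, 2, 4, 4), 1.0 / 7)
        w = np.ones((2, 4, 4))
        val = total_loss(x, uniform, uniform, w, LossParams(), EMPTY_PARTS)
        assert val == pytest.approx(1.33 * np.log(7), rel=1e-9)

    def test_regularization_only(self, rng):
        lab = rng.integers(0, 7, size=(2, 4, 4))
        x = one_hot(lab)
        parts = NetworkParams(
            theta_3d=[Parameter(np.array([2.0], np.float32), "p", "theta_3d")]
        )
        val = total_loss(x, x, x, np.ones((2, 4, 4)), LossParams(), parts)
        assert val == pytest.approx(4e-5, rel=1e-6)

    def test_multi_loss_off_equals_dropping_2d_term(self, rng):
        lab = rng.integers(0, 7, size=(2, 4, 4))
        x = one_hot(lab)
        p3 = np.random.default_rng(0).dirichlet(np.ones(7), (2, 4, 4)).transpose(3, 0, 1, 2)
        p2 = np.random.default_rng(1).dirichlet(np.ones(7), (2, 4, 4)).transpose(3, 0, 1, 2)
        w = np.ones((2, 4, 4))
        no_ml = total_loss(x, p3, p2, w, LossParams(), EMPTY_PARTS, use_multi_loss=False)
        zero_c = total_loss(x, p3, p2, w, LossParams(c_2d=0.0), EMPTY_PARTS)
        assert no_ml == pytest.approx(zero_c, rel=1e-12)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_naive_loop_oracle(self, trial):
        rng = np.random.default_rng(trial)
        lab = rng.integers(0, 7, size=(3, 8, 8))
        x = one_hot(lab)
        p3 = rng.dirichlet(np.ones(7), (3, 8, 8)).transpose(3, 0, 1, 2)
        p2 = rng.dirichlet(np.ones(7), (3, 8, 8)).transpose(3, 0, 1, 2)
        w = rng.uniform(0.01, 3.0, size=(3, 8, 8))
        parts = NetworkParams(
            theta_2d=[Parameter(rng.normal(size=(4, 3)).astype(np.float32), "a", "theta_2d")],
            theta_3d=[Parameter(rng.normal(size=(2,)).astype(np.float32), "b", "theta_3d")],
            theta_2dp=[Parameter(rng.normal(size=(3,)).astype(np.float32), "c", "theta_2dp")],
            theta_3dp=[Parameter(rng.normal(size=(3,)).astype(np.float32), "d", "theta_3dp")],
        )
        lp = LossParams()
        mine = total_loss(x, p3, p2, w, lp, parts)
        oracle = oracle_total_loss(
            x, p3, p2, w, lp.c_2d, lp.lambda_2d, lp.lambda_3d, lp.lambda_p,
            [parts.theta_2d[0].data], [parts.theta_3d[0].data],
            [parts.theta_2dp[0].data], [parts.theta_3dp[0].data],
        )
        assert mine == pytest.approx(oracle, rel=1e-6)

    def test_loss_nonnegative(self, rng):
        lab = rng.integers(0, 7, size=(2, 4, 4))
        x = one_hot(lab)
        p = rng.dirichlet(np.ones(7), (2, 4, 4)).transpose(3, 0, 1, 2)
        w = rng.uniform(0, 2, size=(2, 4, 4))
        assert total_loss(x, p, p, w, LossParams(), EMPTY_PARTS) >= 0

    def test_missing_required_head_rejected(self, rng):
        lab = rng.integers(0, 7, size=(2, 4, 4))
        x = one_hot(lab)
        with pytest.raises(ValueError):
            total_loss(x, None, None, np.ones((2, 4, 4)), LossParams(), EMPTY_PARTS)


class TestLrSchedule:
    def test_reference_decay_points(self):
        cfg = TrainConfig()
        assert lr_schedule(0, cfg) == pytest.approx(1e-3)
        interval = int(round(10 ** 3.4))
        assert lr_schedule(interval, cfg) == pytest.approx(7.5e-4, rel=1e-3)
        assert lr_schedule(2 * interval, cfg) == pytest.approx(5.625e-4, rel=1e-3)

    def test_staircase_holds_between_intervals(self):
        cfg = TrainConfig(staircase_decay=True)
        assert lr_schedule(100, cfg) == cfg.lr0


class TestGradientSanity:
    def test_single_adam_step_reduces_data_term(self, rng):
        net = build_network(tiny_model_config(init_seed=1))
        parts = partition_params(net)
        x = rng.normal(size=(1, 3, 32, 32)).astype(np.float32)
        lab = rng.integers(0, 7, size=(3, 28, 28))
        w = np.ones((3, 28, 28))
        lp = LossParams(lambda_2d=0, lambda_3d=0, lambda_p=0)
        opt = Adam(net.parameters())
        before = None
        for _ in range(3):
            opt.zero_grad()
            x2d, x3d = net.forward_tensors(x)
            loss = loss_tensor(x2d, x3d, lab, w, lp, parts)
            if before is None:
                before = float(loss.data)
            loss.backward()
            opt.step(1e-3)
        x2d, x3d = net.forward_tensors(x)
        after = float(loss_tensor(x2d, x3d, lab, w, lp, parts).data)
        assert after < before


def _tiny_setup(rng):
    from plateseg.synthetic import PhantomConfig, generate_phantom
    from plateseg.weight_maps import build_weight_volume

    img, lab = generate_phantom(PhantomConfig(shape=(10, 32, 32), n_cells=1, seed=21))
    img = normalize_zscore(img)
    w = build_weight_volume(lab)
    spec = WindowSpec((3, 32, 32), (3, 28, 28), (4, 32, 32))
    return img, lab, w, spec


class TestTrainInstance:
    def test_zero_epochs_returns_initialized_network(self, rng):
        img, lab, w, spec = _tiny_setup(rng)
        cfg = tiny_train_config(epochs=0, window_spec=spec)
        rec = train_instance(img, lab, w, (img, lab), tiny_model_config(), cfg)
        assert rec.trace == [] and rec.steps_taken == 0
        net = rec.load_best_network()
        ref = build_network(tiny_model_config(init_seed=cfg.seed))
        for a, b in zip(net.parameters(), ref.parameters()):
            np.testing.assert_array_equal(a.data, b.data)

    def test_early_stop_flags_weak_instance(self, rng):
        img, lab, w, spec = _tiny_setup(rng)
        cfg = tiny_train_config(
            epochs=3, window_spec=spec, early_stop_miou=0.99, early_stop_epoch=1
        )
        rec = train_instance(img, lab, w, (img, lab), tiny_model_config(), cfg)
        assert rec.halted_early
        assert len(rec.trace) == 1

    def test_short_training_reduces_loss(self, rng):
        img, lab, w, spec = _tiny_setup(rng)
        cfg = tiny_train_config(epochs=8, window_spec=spec, max_steps=60, seed=4)
        rec = train_instance(img, lab, w, (img, lab), tiny_model_config(), cfg)
        assert rec.trace[-1]["loss"] < rec.trace[0]["loss"]
        assert rec.best_miou >= rec.trace[-1]["eval_miou_all"] - 1e-12


class TestRunExperiment:
    def test_duplicate_seeds_rejected(self, rng):
        img, lab, w, spec = _tiny_setup(rng)
        with pytest.raises(ValueError):
            run_experiment(
                [1, 1], img, lab, w, (img, lab),
                tiny_model_config(), tiny_train_config(window_spec=spec),
            )

    def test_ranking_sorted_by_best_miou(self, rng):
        img, lab, w, spec = _tiny_setup(rng)
        cfg = tiny_train_config(epochs=1, window_spec=spec, max_steps=4)
        result = run_experiment(
            [0, 1, 2], img, lab, w, (img, lab), tiny_model_config(), cfg
        )
        ranked = result.ranked_instances()
        assert len(ranked) == 3
        mious = [r.best_miou for r in ranked]
        assert mious == sorted(mious, reverse=True)
        assert sorted(r.seed for r in ranked) == [0, 1, 2]
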