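import numpy as np
import pytest

from bnmic.dynamics import ar_system, propagator, spiral_system
from bnmic.ic_estimator import (
    EstimatorConfig,
    estimate_ic,
    inference_rollout,
    load_estimator,
    predict_horizon,
    save_estimator,
    train,
)
from bnmic.synthetic import SpiralSpec, make_spiral_dataset

TINY = EstimatorConfig(hidden_size=32, n_epochs=400, warmup=3, seed=0,
                       learning_rate=1e-2, patience=60)


@pytest.fixture(scope="module")
def random_walk_segments():
    """Random-walk windows: the best one-step forecast is the current value."""
    rng = np.random.default_rng(10)
    return [np.cumsum(rng.standard_normal((3, 30)), axis=1) * 0.3
            for _ in range(24)]


@pytest.fixture(scope="module")
def ar_estimator(random_walk_segments):
    return train(random_walk_segments, ar_system(3), TINY)


@pytest.fixture(scope="module")
def spiral_data():
    return make_spiral_dataset(SpiralSpec(n_sequences=80, n_points=60, seed=4))


@pytest.fixture(scope="module")
def spiral_estimator(spiral_data):
    system = spiral_system(spiral_data.spec.A_true)
    config = EstimatorConfig(hidden_size=32, n_epochs=150, warmup=3, seed=1)
    return train(spiral_data.observations[:60], system, config,
                 sampling_interval=spiral_data.spec.dt)


class TestTrain:
    def test_loss_decreases(self, ar_estimator):
        curve = ar_estimator.training_loss_curve
        assert curve[-1] < curve[0]

    def test_ar_optimum_is_persistence(self, ar_estimator, random_walk_segments):
        # with zero drift the forecast is the current state, so the trained
        # loss approaches the mean squared increment of the random walk
        X = np.stack([s.T for s in random_walk_segments])
        w = ar_estimator.warmup
        increments = float(np.mean((X[:, w + 1:, :] - X[:, w:-1, :]) ** 2))
        assert ar_estimator.training_loss_curve[-1] < 1.5 * increments

    def test_deterministic_given_seed(self, random_walk_segments):
        cfg = EstimatorConfig(hidden_size=8, n_epochs=5, warmup=3, seed=9)
        a = train(random_walk_segments, ar_system(3), cfg)
        b = train(random_walk_segments, ar_system(3), cfg)
        assert a.training_loss_curve == b.training_loss_curve
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_dimension_mismatch_rejected(self, random_walk_segments):
        with pytest.raises(ValueError, match="state_dim"):
            train(random_walk_segments, ar_system(5), TINY)

    def test_spiral_beats_noise_floor(self, spiral_data, spiral_estimator):
        # on noiseless spiral data the one-step loss of the trained estimator
        # drops below the observation-noise floor of the noisy control
        noise_floor = spiral_data.spec.noise_std**2
        assert spiral_estimator.training_loss_curve[-1] < 2.0 * noise_floor


class TestEstimateIC:
    def test_ar_outputs_last_observation(self, ar_estimator, random_walk_segments):
        seg = random_walk_segments[-1]
        out = estimate_ic(ar_estimator, seg[:, :20])
        rmse = np.sqrt(np.mean((out - seg[:, 19]) ** 2))
        scale = np.std(seg)
        assert rmse < 0.35 * scale

    def test_deterministic(self, ar_estimator, random_walk_segments):
        seg = random_walk_segments[0][:, :10]
        np.testing.assert_array_equal(
            estimate_ic(ar_estimator, seg), estimate_ic(ar_estimator, seg)
        )

    def test_empty_prefix_rejected(self, ar_estimator):
        with pytest.raises(ValueError):
            estimate_ic(ar_estimator, np.empty((3, 0)))

    def test_longer_prefix_more_accurate(self, spiral_data, spiral_estimator):
        """Estimates sharpen as the network observes more of each sequence."""
        short_d, long_d = [], []
        t_long = 20
        for i in range(60, len(spiral_data.observations)):
            obs = spiral_data.observations[i]
            est_long = estimate_ic(spiral_estimator, obs[:, :t_long + 1])
            long_d.append(np.linalg.norm(
                est_long - spiral_data.latent[i][:, t_long]))
            est_short = estimate_ic(spiral_estimator, obs[:, :1])
            short_d.append(np.linalg.norm(
                est_short - spiral_data.latent[i][:, 0]))
        assert np.mean(long_d) < np.mean(short_d)


class TestPredictHorizon:
    def test_horizon_one_matches_training_propagation(
        self, ar_estimator, random_walk_segments
    ):
        seg = random_walk_segments[2]
        P = propagator(ar_estimator.system)
        x0 = estimate_ic(ar_estimator, seg[:, :11])
        pred = predict_horizon(ar_estimator, ar_estimator.system, seg, 10, 1)
        np.testing.assert_allclose(pred[0], P @ x0)

    def test_ar_constant_continuation(self, ar_estimator, random_walk_segments):
        seg = random_walk_segments[3]
        x0 = estimate_ic(ar_estimator, seg[:, :11])
        pred = predict_horizon(ar_estimator, ar_estimator.system, seg, 10, 5)
        np.testing.assert_allclose(pred, np.tile(x0, (5, 1)))

    def test_noise_deterministic_given_seed(self, ar_estimator, random_walk_segments):
        seg = random_walk_segments[4]
        a = predict_horizon(ar_estimator, ar_estimator.system, seg, 10, 5,
                            sigma=0.2, seed=11)
        b = predict_horizon(ar_estimator, ar_estimator.system, seg, 10, 5,
                            sigma=0.2, seed=11)
        np.testing.assert_array_equal(a, b)

    def test_warmup_and_bounds_enforced(self, ar_estimator, random_walk_segments):
        seg = random_walk_segments[5]
        with pytest.raises(ValueError, match="warmup"):
            predict_horizon(ar_estimator, ar_estimator.system, seg, 1, 2)
        with pytest.raises(ValueError, match="past the end"):
            predict_horizon(ar_estimator, ar_estimator.system, seg, 10, 100)


@pytest.fixture(scope="module")
def inference_estimator(random_walk_segments):
    cfg = EstimatorConfig(hidden_size=16, n_epochs=60, warmup=3, seed=2,
                          distributional=True)
    return train(random_walk_segments, ar_system(3), cfg)


class TestInferenceRollout:
    def test_seeds_differ(self, inference_estimator, random_walk_segments):
        prefix = random_walk_segments[0][:, :10]
        a = inference_rollout(inference_estimator, prefix, 5, seed=0)
        b = inference_rollout(inference_estimator, prefix, 5, seed=1)
        assert not np.allclose(a, b)

    def test_zero_horizon_empty(self, inference_estimator, random_walk_segments):
        out = inference_rollout(inference_estimator,
                                random_walk_segments[0][:, :10], 0)
        assert out.shape == (0, 3)

    def test_stepwise_variance_positive(self, inference_estimator,
                                        random_walk_segments):
        prefix = random_walk_segments[0][:, :10]
        rollouts = np.stack([
            inference_rollout(inference_estimator, prefix, 4, seed=s)
            for s in range(100)
        ])
        assert np.all(rollouts.var(axis=0) > 0.0)

    def test_point_estimator_rejected(self, ar_estimator, random_walk_segments):
        with pytest.raises(ValueError, match="distributional"):
            inference_rollout(ar_estimator, random_walk_segments[0][:, :10], 3)

    def test_distributional_head_requires_ar(self, random_walk_segments):
        from bnmic.dynamics import exp_decay_system

        cfg = EstimatorConfig(hidden_size=8, n_epochs=2, distributional=True)
        with pytest.raises(ValueError, match="inference null"):
            train(random_walk_segments, exp_decay_system(3), cfg)


class TestCheckpointing:
    def test_round_trip(self, tmp_path, ar_estimator, random_walk_segments):
        path = tmp_path / "est.npz"
        save_estimator(ar_estimator, path)
        back = load_estimator(path, ar_estimator.system)
        seg = random_walk_segments[0][:, :12]
        np.testing.assert_array_equal(
            estimate_ic(back, seg), estimate_ic(ar_estimator, seg)
        )

    def test_mismatched_system_refused(self, tmp_path, ar_estimator):
        path = tmp_path / "est.npz"
        save_estimator(ar_estimator, path)
        from bnmic.dynamics import exp_decay_system

        with pytest.raises(ValueError, match="different system"):
            load_estimator(path, exp_decay_system(3))
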