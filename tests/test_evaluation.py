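import numpy as np
import pytest

from bnmic.dynamics import ar_system, frm_system, simulate
from bnmic.evaluation import (
    HorizonScores,
    fc_matrix,
    fc_similarity,
    horizon_scores,
    long_term_parameterization,
    null_ic_horizon_scores,
    r_squared,
    region_of_predictability,
    sensitivity_slope,
)
from bnmic.ic_estimator import EstimatorConfig, train
from bnmic.preprocess import TimeseriesDataset


class TestRSquared:
    def test_perfect_prediction(self, rng):
        obs = rng.standard_normal(66)
        assert r_squared(obs, obs) == 1.0

    def test_mean_prediction_scores_zero(self, rng):
        obs = rng.standard_normal(66)
        assert r_squared(np.full(66, obs.mean()), obs) == pytest.approx(0.0)

    def test_hand_computed(self):
        assert r_squared([1.0, 2.0, 4.0], [1.0, 2.0, 3.0]) == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            r_squared([1.0, 2.0], [3.0, 3.0])


class TestSensitivitySlope:
    def test_flat_scores(self):
        assert sensitivity_slope(
            [(0.0, 0.5), (0.5, 0.5), (1.0, 0.5)]
        ) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form(self):
        slope = sensitivity_slope([(0.0, 0.6), (0.5, 0.4), (1.0, 0.2)])
        assert slope == pytest.approx(-0.4)

    def test_order_invariant(self):
        pts = [(1.0, 0.2), (0.0, 0.6), (0.5, 0.4)]
        assert sensitivity_slope(pts) == pytest.approx(-0.4)

    def test_requires_fraction_zero(self):
        with pytest.raises(ValueError, match="fraction 0"):
            sensitivity_slope([(0.1, 0.5), (0.5, 0.4)])

    def test_requires_two_points(self):
        with pytest.raises(ValueError):
            sensitivity_slope([(0.0, 0.5)])


class TestFunctionalConnectivity:
    def test_fc_matrix_properties(self, rng):
        states = rng.standard_normal((100, 5))
        fc = fc_matrix(states)
        np.testing.assert_allclose(np.diag(fc), 1.0)
        np.testing.assert_allclose(fc, fc.T)

    def test_duplicate_region_fully_correlated(self, rng):
        a = rng.standard_normal(50)
        states = np.column_stack([a, a, rng.standard_normal(50)])
        fc = fc_matrix(states)
        assert fc[0, 1] == pytest.approx(1.0)

    def test_self_similarity_is_one(self, rng):
        fc = fc_matrix(rng.standard_normal((60, 4)))
        assert fc_similarity(fc, fc) == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        states = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="zero-variance"):
            fc_matrix(states)

    def test_uncoupled_noise_fc_near_identity(self, small_conn):
        # with k = 0 the regions are independent noise-driven decays, so the
        # off-diagonal FC vanishes as duration grows
        from bnmic.dynamics import exp_decay_system

        sys_ = exp_decay_system(10, sigma=0.3)
        traj = simulate(sys_, np.zeros(10), 3000, seed=0)
        fc = fc_matrix(traj.states[100:])
        off = fc[~np.eye(10, dtype=bool)]
        assert np.abs(off).mean() < 0.05


@pytest.fixture(scope="module")
def tiny_setup(rng=None):
    """A quickly trained AR estimator on a small random-walk dataset."""
    gen = np.random.default_rng(5)
    subjects = [np.cumsum(gen.standard_normal((4, 100)), axis=1) * 0.3
                for _ in range(2)]
    ds = TimeseriesDataset(subjects=subjects, segment_length=50)
    est = train(ds.segments(), ar_system(4),
                EstimatorConfig(hidden_size=16, n_epochs=40, warmup=5, seed=0))
    return ds, est


class TestHorizonScores:
    def test_deterministic(self, tiny_setup):
        ds, est = tiny_setup
        a = horizon_scores(est, est.system, ds, horizons=(1, 2), sigma=0.1,
                           n_realizations=3, seed=4)
        b = horizon_scores(est, est.system, ds, horizons=(1, 2), sigma=0.1,
                           n_realizations=3, seed=4)
        np.testing.assert_array_equal(a.r2, b.r2)
        np.testing.assert_array_equal(a.mse, b.mse)

    def test_group_scores_less_dispersed_than_individual(self, tiny_setup):
        ds, est = tiny_setup
        kw = dict(horizons=(1, 2, 3), sigma=0.2, n_realizations=2, seed=0)
        group = horizon_scores(est, est.system, ds, group_batch=True, **kw)
        indiv = horizon_scores(est, est.system, ds, group_batch=False, **kw)
        assert group.r2.std(axis=1).mean() < indiv.r2.std(axis=1).mean()

    def test_trial_counts(self, tiny_setup):
        ds, est = tiny_setup
        group = horizon_scores(est, est.system, ds, horizons=(1,))
        indiv = horizon_scores(est, est.system, ds, horizons=(1,),
                               group_batch=False)
        n_windows = len(ds.segments())
        assert indiv.n_trials == group.n_trials * n_windows


class TestRegionOfPredictability:
    def _scores(self, values):
        arr = np.asarray(values, dtype=float)
        return HorizonScores(horizons=tuple(range(1, arr.shape[0] + 1)),
                             r2=arr, mse=np.zeros_like(arr))

    def test_identical_scores_not_significant(self, rng):
        base = rng.standard_normal((5, 40))
        rp = region_of_predictability(self._scores(base), self._scores(base))
        assert rp.significant == ()

    def test_uniform_improvement_all_significant(self, rng):
        null = 0.3 + 0.01 * rng.standard_normal((5, 100))
        node = null + 0.2
        rp = region_of_predictability(self._scores(node), self._scores(null))
        assert rp.significant == (1, 2, 3, 4, 5)
        assert rp.mean_node_r2 > rp.mean_null_r2

    def test_single_horizon_window(self, rng):
        null = rng.standard_normal((5, 30))
        node = null + 1.0
        rp = region_of_predictability(self._scores(node), self._scores(null),
                                      window_seconds=0.72)
        assert rp.horizons == (1,)

    def test_mismatched_trials_rejected(self, rng):
        a = self._scores(rng.standard_normal((5, 30)))
        b = self._scores(rng.standard_normal((5, 31)))
        with pytest.raises(ValueError, match="mismatched"):
            region_of_predictability(a, b)


class TestLongTermParameterization:
    def test_recovers_coupling_on_own_reference(self, small_conn):
        sys_true = frm_system(small_conn, k=0.9, sigma=0.3)
        traj = simulate(sys_true, np.zeros(small_conn.n_regions), 700, seed=2)
        reference_fc = fc_matrix(traj.states[100:])
        result = long_term_parameterization(
            small_conn, ks=(0.0, 0.9), sigmas=(0.3,), reference_fc=reference_fc,
            duration_steps=600, seed=0, apply_preprocessing=False,
        )
        assert result.argmax[0] == 0.9
        k0 = result.scores[result.ks.index(0.0), 0, 0]
        k9 = result.scores[result.ks.index(0.9), 0, 0]
        assert k9 > k0

    def test_duration_floor(self, small_conn):
        with pytest.raises(ValueError, match="duration"):
            long_term_parameterization(small_conn, (0.9,), (0.3,),
                                       np.eye(20), duration_steps=50)


def test_null_ic_scores_use_last_observation(tiny_setup):
    # for the AR null the previous-timepoint initial condition predicts a
    # constant continuation, so horizon-1 r2 equals the persistence score
    ds, est = tiny_setup
    null = null_ic_horizon_scores(est.system, ds, horizons=(1,), warmup=5)
    X = np.stack([s.T for s in ds.segments()])
    t_indices = range(5, X.shape[1] - 1)
    manual = []
    for t in t_indices:
        pred = X[:, t, :]
        obs = X[:, t + 1, :]
        sse = np.sum((pred - obs) ** 2)
        sst = np.sum((obs - obs.mean(axis=1, keepdims=True)) ** 2)
        manual.append(1.0 - sse / sst)
    np.testing.assert_allclose(null.r2[0], manual, atol=1e-12)
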