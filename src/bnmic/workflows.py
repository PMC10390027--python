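"""End-to-end study pipelines built from the library primitives.

These are the two canonical experiments: system identification on the 2-D
spiral benchmark (ground truth known exactly), and parameter recovery on
surrogate BOLD generated by a known firing rate model.  The command-line
interface and the acceptance checks both call these functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectome import normalize_spectral, synth_connectome
from .dynamics import ar_system, exp_decay_system, frm_system, propagator
from .evaluation import (
    HorizonScores,
    SweepResult,
    fc_matrix,
    horizon_scores,
    long_term_parameterization,
    null_ic_horizon_scores,
    parameter_sweep,
)
from .ic_estimator import EstimatorConfig, TrainedEstimator, estimate_ic_batch, train
from .preprocess import TimeseriesDataset
from .synthetic import (
    SpiralSpec,
    SurrogateSpec,
    make_spiral_dataset,
    make_surrogate_bold,
    perturbation_ladder,
)


def spiral_validation(
    n_sequences: int = 100,
    n_test: int = 60,
    noise_std: float = 0.1,
    hidden_size: int = 32,
    epochs: int = 120,
    t_index: int = 30,
    max_horizon: int = 15,
    seed: int = 0,
    perturb_scales: tuple[float, ...] = (0.25, 0.5),
    crossover_horizon: int = 5,
) -> dict:
    """Fit candidate spiral systems W1 (true), W2, W3 (perturbed) to spiral data.

    One estimator is trained per candidate matrix on the same noisy training
    sequences; on held-out sequences, each candidate's trajectory from its
    estimated state is compared with the observations.  The verdict records
    whether the true matrix is closest at every horizon from
    ``crossover_horizon`` to ``max_horizon`` (short horizons are expected to
    be indistinguishable: every candidate is fit tangentially).
    """
    spec = SpiralSpec(
        n_sequences=n_sequences + n_test, noise_std=noise_std,
        perturb_scales=perturb_scales, seed=seed,
    )
    data = make_spiral_dataset(spec)
    train_obs = data.observations[:n_sequences]
    test_obs = data.observations[n_sequences:]
    config = EstimatorConfig(
        hidden_size=hidden_size, n_epochs=epochs, warmup=5, seed=seed,
    )
    curves = []
    for A in data.candidate_matrices:
        from .dynamics import spiral_system

        system = spiral_system(A)
        est = train(train_obs, system, config, sampling_interval=spec.dt)
        P = propagator(system, spec.dt)
        prefixes = np.stack([o.T[:t_index + 1] for o in test_obs])
        x = estimate_ic_batch(est, prefixes)
        dists = []
        for h in range(1, max_horizon + 1):
            x = x @ P.T
            obs_h = np.stack([o[:, t_index + h] for o in test_obs])
            dists.append(float(np.mean(np.linalg.norm(x - obs_h, axis=1))))
        curves.append(dists)
    curves_arr = np.array(curves)  # (n_candidates, max_horizon)
    hs = slice(crossover_horizon - 1, max_horizon)
    ordered = bool(
        np.all(curves_arr[0, hs] < curves_arr[1, hs])
        and np.all(curves_arr[1, hs] < curves_arr[2, hs])
    ) if curves_arr.shape[0] >= 3 else None
    return {
        "horizons": list(range(1, max_horizon + 1)),
        "mean_distance": {f"W{i + 1}": c for i, c in enumerate(curves_arr.tolist())},
        "candidate_matrices": [A.tolist() for A in data.candidate_matrices],
        "true_matrix_closest_beyond_crossover": ordered,
        "crossover_horizon": crossover_horizon,
        "n_test": n_test,
        "seed": seed,
    }


@dataclass
class SurrogateStudy:
    """Everything the surrogate parameter-recovery experiment produces."""

    dataset: TimeseriesDataset
    connectome: object
    ladder: list
    estimators: dict[tuple[float, float], TrainedEstimator]
    ar_estimator: TrainedEstimator
    sweep: SweepResult
    noiseless_scores: dict[str, HorizonScores]
    node_scores: HorizonScores
    null_scores: HorizonScores
    fc_fit: SweepResult


def surrogate_study(
    n_regions: int = 20,
    density: float = 0.3,
    k_true: float = 0.9,
    sigma_true: float = 0.3,
    n_subjects: int = 4,
    timepoints: int = 500,
    ks: tuple[float, ...] = (0.0, 0.45, 0.9),
    sigmas: tuple[float, ...] = (0.0001, 0.3),
    fractions: tuple[float, ...] = (0.0, 0.25, 0.5),
    horizon: int = 4,
    hidden_size: int = 64,
    epochs: int = 80,
    n_realizations: int = 10,
    fc_duration_steps: int = 1667,
    seed: int = 0,
    stride: int = 1,
) -> SurrogateStudy:
    """Full parameter-recovery experiment on surrogate BOLD.

    Generates a normalized synthetic connectome and surrogate data from
    FRM(k_true, sigma_true), trains one estimator per (k, perturbation)
    grid cell plus the AR null, then runs the sensitivity sweep, the
    noiseless model comparison, the estimator-vs-null initial-condition
    comparison, and the long-term FC criterion.
    """
    rng = np.random.default_rng(seed)
    conn = normalize_spectral(
        synth_connectome(n_regions, density=density, seed=int(rng.integers(2**31)),
                         bilateral=n_regions % 2 == 0)
    )
    ds = make_surrogate_bold(SurrogateSpec(
        connectome=conn, k_true=k_true, sigma_true=sigma_true,
        n_subjects=n_subjects, timepoints=timepoints,
        seed=int(rng.integers(2**31)),
    ))
    ladder = perturbation_ladder(conn, list(fractions), seed=int(rng.integers(2**31)))
    segments = ds.segments()
    estimators: dict[tuple[float, float], TrainedEstimator] = {}
    for k in ks:
        for f, w in zip(fractions, ladder):
            if k == 0.0 and (0.0, fractions[0]) in estimators:
                estimators[(k, f)] = estimators[(0.0, fractions[0])]
                continue
            system = (exp_decay_system(conn.n_regions) if k == 0.0
                      else frm_system(w, k=k))
            config = EstimatorConfig(hidden_size=hidden_size, n_epochs=epochs,
                                     seed=int(rng.integers(2**31)))
            estimators[(k, f)] = train(segments, system, config,
                                       sampling_interval=ds.sampling_interval)
    ar_est = train(
        segments, ar_system(conn.n_regions),
        EstimatorConfig(hidden_size=hidden_size, n_epochs=epochs,
                        seed=int(rng.integers(2**31))),
        sampling_interval=ds.sampling_interval,
    )
    sweep = parameter_sweep(
        estimators, ds, ks, sigmas, fractions, horizon=horizon,
        n_realizations=n_realizations, seed=int(rng.integers(2**31)),
        stride=stride,
    )
    horizons = tuple(range(1, max(horizon, 5) + 1))
    noiseless = {}
    best_k = max(k for k in ks)
    for name, est in {
        "frm_high_k": estimators[(best_k, 0.0)],
        "exp_decay": estimators[(0.0, 0.0)],
        "ar": ar_est,
    }.items():
        noiseless[name] = horizon_scores(
            est, est.system, ds, horizons=horizons, sigma=0.0,
            seed=int(rng.integers(2**31)), stride=stride,
        )
    node_est = estimators[(best_k, 0.0)]
    rp_seed = int(rng.integers(2**31))
    node_scores = horizon_scores(
        node_est, node_est.system, ds, horizons=horizons, sigma=0.0,
        group_batch=False, seed=rp_seed, stride=stride,
    )
    null_scores = null_ic_horizon_scores(
        node_est.system, ds, horizons=horizons, sigma=0.0,
        group_batch=False, warmup=node_est.warmup, seed=rp_seed, stride=stride,
    )
    reference_fc = np.mean([fc_matrix(s.T) for s in ds.subjects], axis=0)
    fc_fit = long_term_parameterization(
        conn, ks, sigmas, reference_fc, duration_steps=fc_duration_steps,
        seed=int(rng.integers(2**31)), sampling_interval=ds.sampling_interval,
    )
    return SurrogateStudy(
        dataset=ds, connectome=conn, ladder=ladder, estimators=estimators,
        ar_estimator=ar_est, sweep=sweep, noiseless_scores=noiseless,
        node_scores=node_scores, null_scores=null_scores, fc_fit=fc_fit,
    )
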