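"""Scoring and model selection for short-horizon trajectory prediction.

Candidate systems are compared by how well trajectories integrated from
estimated initial conditions track held-out observations: coefficient of
determination (r²) and MSE per prediction horizon, aggregated either per
trial or across a group batch (pooling errors over windows before forming
r², which has markedly lower variance).  Model selection uses (a) the
sensitivity slope — the change of horizon-4 r² per unit of structural
perturbation, whose maximizer over (k, sigma) picks the parameterization
most dependent on the true connectome — and (b) the classical long-term
criterion, correlation between simulated and reference functional
connectivity.  The Region of Predictability is the initial window (3.6 s,
five sampled steps) over which estimator-derived initial conditions
significantly beat previous-timepoint null conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dynamics import (
    DEFAULT_TR,
    DivergenceError,
    DynamicalSystem,
    Trajectory,
    frm_system,
    propagator,
    simulate,
    simulate_batch,
)
from .ic_estimator import TrainedEstimator, estimate_ic_batch
from .preprocess import TimeseriesDataset, preprocess_chain

DEFAULT_EVAL_HORIZON = 4
DEFAULT_N_REALIZATIONS = 10
RP_WINDOW_SECONDS = 3.6


def r_squared(pred: np.ndarray, obs: np.ndarray) -> float:
    """Coefficient of determination across regions, 1 - SSE/SST.

    Can be negative for predictions worse than the observation mean; this is
    deliberate so that poor candidate systems rank below the trivial mean
    predictor.
    """
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    if pred.shape != obs.shape or obs.size < 2:
        raise ValueError("pred and obs must have equal length >= 2")
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("observation vector has zero variance")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / sst


def mse(pred: np.ndarray, obs: np.ndarray) -> float:
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    return float(np.mean((obs - pred) ** 2))


@dataclass
class HorizonScores:
    """r² and MSE per (horizon, trial).

    With group aggregation a trial is one evaluation timepoint (errors pooled
    across all windows of the batch before forming r²); individually a trial
    is one (window, timepoint) pair.
    """

    horizons: tuple[int, ...]
    r2: np.ndarray  # (n_horizons, n_trials)
    mse: np.ndarray
    aggregation: str = "group"

    @property
    def n_trials(self) -> int:
        return self.r2.shape[1]

    def mean_r2(self, horizon: int) -> float:
        return float(self.r2[self.horizons.index(horizon)].mean())


def _iter_eval_points(
    dataset: TimeseriesDataset, warmup: int, max_horizon: int, stride: int
) -> tuple[np.ndarray, list[int]]:
    """Stack all windows (B, L, n) and list scored timepoint indices."""
    segs = dataset.segments()
    if not segs:
        raise ValueError("dataset has no segments")
    X = np.stack([s.T for s in segs])  # (B, L, n)
    L = X.shape[1]
    t_indices = list(range(warmup, L - max_horizon, stride))
    if not t_indices:
        raise ValueError(
            f"no evaluation timepoints: length {L}, warmup {warmup}, "
            f"max horizon {max_horizon}"
        )
    return X, t_indices


def _score_provider(
    x0_provider: Callable[[np.ndarray], np.ndarray],
    system: DynamicalSystem,
    dataset: TimeseriesDataset,
    horizons: Sequence[int],
    sigma: float,
    n_realizations: int,
    seed: int | None,
    group_batch: bool,
    warmup: int,
    stride: int,
) -> HorizonScores:
    horizons = tuple(int(h) for h in horizons)
    if min(horizons) < 1:
        raise ValueError("horizons must be >= 1")
    max_h = max(horizons)
    X, t_indices = _iter_eval_points(dataset, warmup, max_h, stride)
    B, L, n = X.shape
    P = propagator(system, dataset.sampling_interval)
    rng = np.random.default_rng(seed)
    n_real = n_realizations if sigma > 0.0 else 1
    r2_cells: list[list[float]] = [[] for _ in horizons]
    mse_cells: list[list[float]] = [[] for _ in horizons]
    for t in t_indices:
        x0 = x0_provider(X[:, :t + 1, :])  # (B, n)
        obs = X[:, t + 1:t + max_h + 1, :]  # (B, max_h, n)
        preds = np.empty((n_real, B, max_h, n))
        if sigma == 0.0:
            x = x0
            traj = np.empty((B, max_h, n))
            for h in range(max_h):
                x = x @ P.T
                traj[:, h, :] = x
            preds[0] = traj
        else:
            noisy = system.with_sigma(sigma)
            for r in range(n_real):
                preds[r] = simulate_batch(
                    noisy, x0, max_h, seed=int(rng.integers(2**31)),
                    sampling_interval=dataset.sampling_interval,
                )
        for hi, h in enumerate(horizons):
            p_h = preds[:, :, h - 1, :]  # (n_real, B, n)
            o_h = obs[:, h - 1, :]  # (B, n)
            if group_batch:
                # pool errors over the batch, then form one r² per realization
                sse = np.sum((p_h - o_h) ** 2, axis=(1, 2))  # (n_real,)
                sst = np.sum((o_h - o_h.mean(axis=1, keepdims=True)) ** 2)
                r2_cells[hi].append(float(np.mean(1.0 - sse / sst)))
                mse_cells[hi].append(float(np.mean((p_h - o_h) ** 2)))
            else:
                sse = np.sum((p_h - o_h) ** 2, axis=2)  # (n_real, B)
                sst = np.sum((o_h - o_h.mean(axis=1, keepdims=True)) ** 2, axis=1)
                r2_cells[hi].extend(np.mean(1.0 - sse / sst, axis=0).tolist())
                mse_cells[hi].extend(np.mean((p_h - o_h) ** 2, axis=(0, 2)).tolist())
    agg = "group" if group_batch else "individual"
    return HorizonScores(
        horizons=horizons,
        r2=np.array(r2_cells),
        mse=np.array(mse_cells),
        aggregation=agg,
    )


def horizon_scores(
    est: TrainedEstimator,
    system: DynamicalSystem,
    dataset: TimeseriesDataset,
    horizons: Sequence[int] = (1, 2, 3, 4, 5),
    sigma: float = 0.0,
    n_realizations: int = DEFAULT_N_REALIZATIONS,
    seed: int | None = 0,
    group_batch: bool = True,
    stride: int = 1,
) -> HorizonScores:
    """Score a trained estimator + system on every evaluation timepoint.

    At each timepoint past the warmup the estimator infers the state from
    the observed prefix, the system is integrated forward (with evaluation
    noise ``sigma``, averaging r² over ``n_realizations`` realizations), and
    r²/MSE are recorded per horizon.
    """
    provider = lambda prefixes: estimate_ic_batch(est, prefixes)
    return _score_provider(
        provider, system, dataset, horizons, sigma, n_realizations, seed,
        group_batch, est.warmup, stride,
    )


def null_ic_horizon_scores(
    system: DynamicalSystem,
    dataset: TimeseriesDataset,
    horizons: Sequence[int] = (1, 2, 3, 4, 5),
    sigma: float = 0.0,
    n_realizations: int = DEFAULT_N_REALIZATIONS,
    seed: int | None = 0,
    group_batch: bool = True,
    warmup: int = 10,
    stride: int = 1,
) -> HorizonScores:
    """Scores when the previous observation itself is used as the state.

    The null initial condition at timepoint t is the measurement at t; the
    system is integrated from it exactly as for estimator-derived states.
    """
    provider = lambda prefixes: prefixes[:, -1, :]
    return _score_provider(
        provider, system, dataset, horizons, sigma, n_realizations, seed,
        group_batch, warmup, stride,
    )


def sensitivity_slope(scores_by_fraction: Sequence[tuple[float, float]]) -> float:
    """Least-squares slope of mean r² against perturbation fraction.

    More negative means more sensitive to the structural connectome; callers
    rank by magnitude and report the sign.
    """
    pts = sorted(scores_by_fraction)
    if len(pts) < 2:
        raise ValueError("need at least two (fraction, score) points")
    fr = np.array([p[0] for p in pts])
    sc = np.array([p[1] for p in pts])
    if np.unique(fr).size < 2:
        raise ValueError("need at least two distinct fractions")
    if fr.min() != 0.0:
        raise ValueError("the unperturbed fraction 0 must be present")
    slope, _ = np.polyfit(fr, sc, 1)
    return float(slope)


@dataclass
class SweepResult:
    """Mean r² on a (coupling × noise × perturbation) grid plus slopes."""

    ks: tuple[float, ...]
    sigmas: tuple[float, ...]
    fractions: tuple[float, ...]
    horizon: int
    scores: np.ndarray  # (n_k, n_sigma, n_fraction) mean r²
    slopes: np.ndarray | None = None  # (n_k, n_sigma), signed
    argmax: tuple[float, float] | None = None  # (k, sigma) maximizing |slope|
    flagged: list[tuple[float, float]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, k in enumerate(self.ks):
            for j, s in enumerate(self.sigmas):
                for m, f in enumerate(self.fractions):
                    rows.append({
                        "k": k, "sigma": s, "fraction": f,
                        "horizon": self.horizon,
                        "mean_r2": self.scores[i, j, m],
                        "slope": (self.slopes[i, j]
                                  if self.slopes is not None else np.nan),
                    })
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        out = {
            "horizon": self.horizon,
            "ks": list(self.ks),
            "sigmas": list(self.sigmas),
            "fractions": list(self.fractions),
        }
        if self.argmax is not None:
            out["argmax_k"], out["argmax_sigma"] = self.argmax
        if self.flagged:
            out["flagged_cells"] = [list(c) for c in self.flagged]
        return out


def parameter_sweep(
    estimators: Mapping[tuple[float, float], TrainedEstimator],
    dataset: TimeseriesDataset,
    ks: Sequence[float],
    sigmas: Sequence[float],
    fractions: Sequence[float],
    horizon: int = DEFAULT_EVAL_HORIZON,
    n_realizations: int = DEFAULT_N_REALIZATIONS,
    seed: int | None = 0,
    stride: int = 1,
) -> SweepResult:
    """Fill the (k, sigma, fraction) score grid and rank by |sensitivity slope|.

    ``estimators`` maps (k, fraction) to the estimator trained for that cell
    (the evaluation-noise axis reuses them, since noise is never used in
    training).  The grid must include fraction 0.
    """
    ks = tuple(float(k) for k in ks)
    sigmas = tuple(float(s) for s in sigmas)
    fractions = tuple(float(f) for f in fractions)
    if 0.0 not in fractions:
        raise ValueError("the fraction grid must include 0 (the original connectome)")
    missing = [
        (k, f) for k in ks for f in fractions if (k, f) not in estimators
    ]
    if missing:
        raise ValueError(f"missing estimators for cells: {missing}")
    scores = np.empty((len(ks), len(sigmas), len(fractions)))
    rng = np.random.default_rng(seed)
    for i, k in enumerate(ks):
        for m, f in enumerate(fractions):
            est = estimators[(k, f)]
            for j, s in enumerate(sigmas):
                hs = horizon_scores(
                    est, est.system, dataset, horizons=(horizon,), sigma=s,
                    n_realizations=n_realizations,
                    seed=int(rng.integers(2**31)), stride=stride,
                )
                scores[i, j, m] = hs.mean_r2(horizon)
    slopes = np.empty((len(ks), len(sigmas)))
    for i in range(len(ks)):
        for j in range(len(sigmas)):
            slopes[i, j] = sensitivity_slope(
                list(zip(fractions, scores[i, j, :]))
            )
    flat = np.argmax(np.abs(slopes))
    i, j = np.unravel_index(flat, slopes.shape)
    return SweepResult(
        ks=ks, sigmas=sigmas, fractions=fractions, horizon=horizon,
        scores=scores, slopes=slopes, argmax=(ks[i], sigmas[j]),
    )


def fc_matrix(traj: Trajectory | np.ndarray) -> np.ndarray:
    """Pearson correlation of every region pair over time (n×n, unit diagonal)."""
    states = traj.states if isinstance(traj, Trajectory) else np.asarray(traj, float)
    if states.shape[0] < 3:
        raise ValueError("need at least 3 timepoints for a correlation matrix")
    sd = states.std(axis=0)
    dead = np.flatnonzero(sd == 0.0)
    if dead.size:
        raise ValueError(f"zero-variance region(s): {dead.tolist()}")
    return np.corrcoef(states.T)


def fc_similarity(fc_a: np.ndarray, fc_b: np.ndarray) -> float:
    """Pearson correlation of the two upper triangles (diagonal excluded)."""
    fc_a = np.asarray(fc_a, float)
    fc_b = np.asarray(fc_b, float)
    if fc_a.shape != fc_b.shape:
        raise ValueError("FC matrices must share shape")
    iu = np.triu_indices(fc_a.shape[0], k=1)
    r, _ = stats.pearsonr(fc_a[iu], fc_b[iu])
    return float(r)


def long_term_parameterization(
    connectome,
    ks: Sequence[float],
    sigmas: Sequence[float],
    reference_fc: np.ndarray,
    duration_steps: int = 1667,
    burn_in: int = 100,
    seed: int | None = 0,
    sampling_interval: float = DEFAULT_TR,
    apply_preprocessing: bool = True,
) -> SweepResult:
    """Classical long-horizon criterion: FC similarity over a (k, sigma) grid.

    Each cell simulates the firing rate model for ``duration_steps`` sampled
    steps (~20 min at the default TR for the default 1667), conditions the
    series like the data, and correlates its FC with ``reference_fc``.
    Unstable or degenerate cells are flagged rather than fatal.
    """
    if duration_steps < 100:
        raise ValueError("duration_steps must be >= 100")
    ks = tuple(float(k) for k in ks)
    sigmas = tuple(float(s) for s in sigmas)
    scores = np.full((len(ks), len(sigmas), 1), np.nan)
    flagged: list[tuple[float, float]] = []
    rng = np.random.default_rng(seed)
    for i, k in enumerate(ks):
        for j, s in enumerate(sigmas):
            sys_ks = frm_system(connectome, k=k, sigma=s)
            x0 = rng.standard_normal(connectome.n_regions) * max(s, 1e-4)
            try:
                traj = simulate(
                    sys_ks, x0, burn_in + duration_steps,
                    seed=int(rng.integers(2**31)),
                    sampling_interval=sampling_interval, include_initial=False,
                )
                series = traj.states[burn_in:].T  # region×time
                if apply_preprocessing:
                    series = preprocess_chain(series, fs=1.0 / sampling_interval)
                scores[i, j, 0] = fc_similarity(fc_matrix(series.T), reference_fc)
            except (DivergenceError, ValueError):
                flagged.append((k, s))
    if np.all(np.isnan(scores)):
        raise RuntimeError("every (k, sigma) cell was unstable or degenerate")
    flat = np.nanargmax(scores[:, :, 0])
    i, j = np.unravel_index(flat, scores[:, :, 0].shape)
    return SweepResult(
        ks=ks, sigmas=sigmas, fractions=(0.0,), horizon=0,
        scores=scores, slopes=None, argmax=(ks[i], sigmas[j]), flagged=flagged,
    )


@dataclass
class RPSummary:
    """Per-horizon comparison of estimator vs null initial conditions."""

    horizons: tuple[int, ...]
    p_values: np.ndarray
    significant: tuple[int, ...]
    mean_node_r2: float
    mean_null_r2: float
    window_seconds: float
    alpha: float


def region_of_predictability(
    node_scores: HorizonScores,
    null_scores: HorizonScores,
    window_seconds: float = RP_WINDOW_SECONDS,
    alpha: float = 0.05,
    sampling_interval: float = DEFAULT_TR,
) -> RPSummary:
    """Horizons (within the initial window) where estimated ICs beat null ICs.

    Paired two-sided Wilcoxon signed-rank per horizon on matched trials; a
    horizon is significant when p < alpha AND the estimator's mean r² is the
    larger one.
    """
    n_h = int(round(window_seconds / sampling_interval))
    horizons = tuple(range(1, n_h + 1))
    for h in horizons:
        if h not in node_scores.horizons or h not in null_scores.horizons:
            raise ValueError(f"both score sets must cover horizon {h}")
    if node_scores.n_trials != null_scores.n_trials:
        raise ValueError(
            f"mismatched trial counts: {node_scores.n_trials} vs "
            f"{null_scores.n_trials}"
        )
    p_values = np.empty(n_h)
    significant = []
    for idx, h in enumerate(horizons):
        a = node_scores.r2[node_scores.horizons.index(h)]
        b = null_scores.r2[null_scores.horizons.index(h)]
        diff = a - b
        if np.allclose(diff, 0.0):
            p_values[idx] = 1.0
        else:
            p_values[idx] = float(stats.wilcoxon(a, b).pvalue)
        if p_values[idx] < alpha and a.mean() > b.mean():
            significant.append(h)
    in_window = [node_scores.horizons.index(h) for h in horizons]
    null_idx = [null_scores.horizons.index(h) for h in horizons]
    return RPSummary(
        horizons=horizons,
        p_values=p_values,
        significant=tuple(significant),
        mean_node_r2=float(node_scores.r2[in_window].mean()),
        mean_null_r2=float(null_scores.r2[null_idx].mean()),
        window_seconds=window_seconds,
        alpha=alpha,
    )
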