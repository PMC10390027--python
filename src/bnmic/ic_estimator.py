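"""Forward-time recurrent initial-condition estimator.

A single-layer LSTM consumes an observed window one timepoint at a time, in
forward time, and at every timepoint emits a candidate state of a prescribed
dynamical system ("the initial condition at that timepoint").  Training never
sees the true state: the loss is the mean squared error between the next
observation and the one-sampling-interval noiseless integration of the
system from the emitted state, so gradients flow through the system's exact
linear propagator ``expm((kW - I) * dt)``.  One estimator is trained per
(coupling, connectome) pair; noise is never used during training.

The inference null variant carries a diagonal-Gaussian head (mean +
log-variance) over the next observation and is rolled out autoregressively
by feeding sampled outputs back in; it serves as an empirical upper bound on
short-window predictability rather than as a mechanistic model.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _lstm
from .dynamics import DEFAULT_TR, DynamicalSystem, propagator, simulate_batch


@dataclass(frozen=True)
class EstimatorConfig:
    hidden_size: int = 64
    n_layers: int = 1
    learning_rate: float = 3e-3
    n_epochs: int = 300
    batch_size: int = 32
    warmup: int = 10
    seed: int = 0
    grad_clip: float = 5.0
    patience: int = 30
    distributional: bool = False

    def __post_init__(self) -> None:
        for name in ("hidden_size", "n_layers", "n_epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_layers != 1:
            raise ValueError("only single-layer LSTMs are implemented")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.warmup < 0:
            raise ValueError("warmup must be >= 0")


def system_fingerprint(system: DynamicalSystem) -> dict:
    """Identity of the (k, W) pair an estimator is bound to."""
    from .dynamics import system_matrix

    M = np.ascontiguousarray(system_matrix(system))
    return {
        "kind": system.kind,
        "k": float(system.params.k) if system.params is not None else None,
        "state_dim": int(system.state_dim),
        "matrix_sha256": hashlib.sha256(M.tobytes()).hexdigest(),
    }


@dataclass
class TrainedEstimator:
    """An LSTM bound to one specific dynamical system."""

    config: EstimatorConfig
    system: DynamicalSystem
    params: dict
    training_loss_curve: list[float] = field(default_factory=list)

    @property
    def warmup(self) -> int:
        return self.config.warmup


def _stack_segments(segments: list[np.ndarray], state_dim: int) -> np.ndarray:
    """Region×length windows -> (B, T, n) batch, validating dimensions."""
    if not segments:
        raise ValueError("no training segments provided")
    arrs = []
    for s in segments:
        s = np.asarray(s, dtype=float)
        if s.ndim != 2 or s.shape[0] != state_dim:
            raise ValueError(
                f"segment shape {s.shape} does not match state_dim {state_dim}"
            )
        arrs.append(s.T)
    T = arrs[0].shape[0]
    if any(a.shape[0] != T for a in arrs):
        raise ValueError("all segments must share the same length")
    return np.stack(arrs)


def _loss_and_grad(
    params: dict, X: np.ndarray, P: np.ndarray, warmup: int, distributional: bool
) -> tuple[float, dict]:
    """One-step prediction loss over a teacher-forced forward pass.

    Scored timepoints are ``t in [warmup, T-2]``; at each, the emitted state
    is propagated one sampling interval through ``P`` (point head) or read as
    a Gaussian over the next observation (distributional head) and compared
    with the observation at ``t + 1``.
    """
    B, T, n = X.shape
    if T - 1 <= warmup:
        raise ValueError(f"segments of length {T} too short for warmup {warmup}")
    Y, cache = _lstm.forward(params, X)
    sl = slice(warmup, T - 1)
    target = X[:, warmup + 1:, :]
    count = target.size
    dY = np.zeros_like(Y)
    if distributional:
        mu, logvar = Y[:, sl, :n], np.clip(Y[:, sl, n:], -10.0, 10.0)
        var = np.exp(logvar)
        resid = mu - target
        loss = float(np.mean(0.5 * (logvar + resid**2 / var)))
        dY[:, sl, :n] = resid / var / count
        dY[:, sl, n:] = 0.5 * (1.0 - resid**2 / var) / count
    else:
        pred = Y[:, sl, :] @ P.T
        resid = pred - target
        loss = float(np.mean(resid**2))
        dY[:, sl, :] = (2.0 / count) * resid @ P
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite training loss; diverged")
    grads = _lstm.backward(params, cache, dY)
    return loss, grads


def train(
    segments: list[np.ndarray],
    system: DynamicalSystem,
    config: EstimatorConfig = EstimatorConfig(),
    sampling_interval: float = DEFAULT_TR,
) -> TrainedEstimator:
    """Train an initial-condition estimator for one (k, W) system.

    Deterministic given ``config.seed``.  Training stops early when the
    epoch loss has not improved for ``config.patience`` epochs.
    """
    X = _stack_segments(segments, system.state_dim)
    n = system.state_dim
    n_out = 2 * n if config.distributional else n
    if config.distributional and system.kind != "ar":
        raise ValueError("the distributional head is reserved for the inference null (ar)")
    P = propagator(system, sampling_interval)
    rng = np.random.default_rng(config.seed)
    params = _lstm.init_params(n, config.hidden_size, n_out, rng)
    opt = _lstm.Adam(params, lr=config.learning_rate)
    curve: list[float] = []
    best = np.inf
    stale = 0
    for _epoch in range(config.n_epochs):
        order = rng.permutation(X.shape[0])
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, X.shape[0], config.batch_size):
            batch = X[order[start:start + config.batch_size]]
            loss, grads = _loss_and_grad(
                params, batch, P, config.warmup, config.distributional
            )
            _lstm.clip_grad_norm(grads, config.grad_clip)
            opt.step(params, grads)
            epoch_loss += loss
            n_batches += 1
        curve.append(epoch_loss / n_batches)
        if curve[-1] < best * (1.0 - 1e-4):
            best = curve[-1]
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    return TrainedEstimator(
        config=config, system=system, params=params, training_loss_curve=curve
    )


def estimate_ic(est: TrainedEstimator, prefix: np.ndarray) -> np.ndarray:
    """System state at the final time of an observed region×t prefix."""
    prefix = np.asarray(prefix, dtype=float)
    if prefix.ndim != 2 or prefix.shape[1] < 1:
        raise ValueError("prefix must be a region×t matrix with t >= 1")
    return estimate_ic_batch(est, prefix.T[None, :, :])[0]


def estimate_ic_batch(est: TrainedEstimator, prefixes: np.ndarray) -> np.ndarray:
    """Vectorized ``estimate_ic`` over (B, t, n) prefixes; returns (B, n)."""
    prefixes = np.asarray(prefixes, dtype=float)
    if prefixes.shape[2] != est.system.state_dim:
        raise ValueError(
            f"prefix dim {prefixes.shape[2]} does not match system "
            f"state_dim {est.system.state_dim}"
        )
    Y, _ = _lstm.forward(est.params, prefixes)
    out = Y[:, -1, :]
    if est.config.distributional:
        out = out[:, :est.system.state_dim]
    return out


def predict_horizon(
    est: TrainedEstimator,
    system: DynamicalSystem,
    segment: np.ndarray,
    t_index: int,
    horizon: int,
    sigma: float = 0.0,
    seed: int | None = 0,
    sampling_interval: float = DEFAULT_TR,
) -> np.ndarray:
    """Estimate the state at ``t_index`` and integrate ``horizon`` steps.

    Returns a (horizon, n) array aligned with
    ``segment[:, t_index+1 : t_index+horizon+1]``.  With ``sigma = 0`` the
    exact propagator is iterated (matching the training loss at horizon 1);
    with noise, Euler-Maruyama integration is used.
    """
    segment = np.asarray(segment, dtype=float)
    if t_index < est.warmup:
        raise ValueError(f"t_index {t_index} is inside the warmup ({est.warmup})")
    if t_index + horizon >= segment.shape[1]:
        raise ValueError("horizon extends past the end of the segment")
    x0 = estimate_ic(est, segment[:, :t_index + 1])
    if sigma == 0.0:
        P = propagator(system, sampling_interval)
        out = np.empty((horizon, system.state_dim))
        x = x0
        for h in range(horizon):
            x = P @ x
            out[h] = x
        return out
    noisy = system.with_sigma(sigma)
    return simulate_batch(
        noisy, x0[None, :], horizon, seed=seed, sampling_interval=sampling_interval
    )[0]


def inference_rollout(
    est: TrainedEstimator,
    prefix: np.ndarray,
    horizon: int,
    seed: int | None = 0,
) -> np.ndarray:
    """Autoregressive rollout of the distributional (inference null) estimator.

    After consuming the prefix, each next input is sampled from the
    network's predicted Gaussian over the next observation.  Returns
    (horizon, n); stochastic across seeds, deterministic given one.
    """
    if not est.config.distributional:
        raise ValueError("inference_rollout requires a distributional estimator")
    prefix = np.asarray(prefix, dtype=float)
    n = est.system.state_dim
    if prefix.shape[0] != n:
        raise ValueError("prefix dim mismatch")
    if horizon == 0:
        return np.empty((0, n))
    rng = np.random.default_rng(seed)
    p = est.params
    H = p["Wh"].shape[0]
    h = np.zeros(H)
    c = np.zeros(H)

    def step(x, h, c):
        z = x @ p["Wx"] + h @ p["Wh"] + p["b"]
        i = _lstm._sigmoid(z[:H])
        f = _lstm._sigmoid(z[H:2 * H])
        g = np.tanh(z[2 * H:3 * H])
        o = _lstm._sigmoid(z[3 * H:])
        c = f * c + i * g
        h = o * np.tanh(c)
        y = h @ p["Wo"] + p["bo"]
        return y, h, c

    y = np.zeros(2 * n)
    for t in range(prefix.shape[1]):
        y, h, c = step(prefix[:, t], h, c)
    out = np.empty((horizon, n))
    for t in range(horizon):
        mu, logvar = y[:n], np.clip(y[n:], -10.0, 10.0)
        x = mu + np.exp(0.5 * logvar) * rng.standard_normal(n)
        out[t] = x
        y, h, c = step(x, h, c)
    return out


def save_estimator(est: TrainedEstimator, path) -> None:
    """Single-file checkpoint embedding config and system fingerprint."""
    meta = {
        "config": asdict(est.config),
        "fingerprint": system_fingerprint(est.system),
        "loss_curve": est.training_loss_curve,
    }
    with open(path, "wb") as fh:
        np.savez(fh, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **est.params)


def load_estimator(path, system: DynamicalSystem) -> TrainedEstimator:
    """Load a checkpoint; refuses a system whose fingerprint does not match."""
    with np.load(path) as blob:
        meta = json.loads(bytes(blob["__meta__"]).decode())
        params = {k: blob[k] for k in blob.files if k != "__meta__"}
    fp = system_fingerprint(system)
    if fp != meta["fingerprint"]:
        raise ValueError(
            "checkpoint was trained for a different system "
            f"(stored {meta['fingerprint']}, requested {fp})"
        )
    return TrainedEstimator(
        config=EstimatorConfig(**meta["config"]),
        system=system,
        params=params,
        training_loss_curve=list(meta["loss_curve"]),
    )
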