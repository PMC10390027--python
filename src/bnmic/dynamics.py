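"""Dynamical systems: the firing rate model, its null variants, and the
2-D spiral benchmark, with stochastic integration and closed-form oracles.

The firing rate model (FRM) is the linear network SDE

    dx = (-x + k W x) dt + sigma dB

on a spectrally normalized structural connectome ``W``.  For ``k < 1`` the
noiseless system decays to the origin; noise keeps it fluctuating around the
origin with a spatial covariance shaped by ``W``.  Null variants: ``ar``
(connectivity = identity, k = 1, drift identically zero, i.e. the forecast
x(n+1) = x(n)) and ``exp_decay`` (k = 0, pure relaxation).  ``spiral`` is an
arbitrary 2-D linear system ``dx = A x dt`` used for ground-truth validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.linalg import expm

from .connectome import StructuralConnectome

#: default sampling interval in seconds (fMRI repetition time)
DEFAULT_TR = 0.72
#: Euler-Maruyama substeps per sampled interval
DEFAULT_SUBSTEPS = 10
#: state magnitude beyond which the integration is declared divergent
OVERFLOW_GUARD = 1e6

SystemKind = Literal["frm", "ar", "exp_decay", "spiral"]


@dataclass(frozen=True)
class FRMParams:
    """Firing rate model parameters.

    ``k`` is the dimensionless global coupling; ``sigma`` the noise standard
    deviation per unit time (signal units / sqrt(s)); ``per_region_sigma``
    optionally overrides ``sigma`` region-by-region (area-scaled noise).
    """

    k: float
    sigma: float = 0.0
    per_region_sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.per_region_sigma is not None:
            prs = np.asarray(self.per_region_sigma, dtype=float)
            if np.any(prs < 0):
                raise ValueError("per_region_sigma must be >= 0")
            object.__setattr__(self, "per_region_sigma", prs)


@dataclass(frozen=True)
class DynamicalSystem:
    """A drift specification with optional connectome binding."""

    kind: SystemKind
    params: FRMParams | None = None
    connectome: StructuralConnectome | None = None
    matrix: np.ndarray | None = None  # spiral only: 2x2 system matrix A
    state_dim: int = 0

    def __post_init__(self) -> None:
        if self.kind == "frm":
            if self.params is None or self.connectome is None:
                raise ValueError("frm requires params and connectome")
            object.__setattr__(self, "state_dim", self.connectome.n_regions)
        elif self.kind in ("ar", "exp_decay"):
            if self.state_dim < 1:
                raise ValueError(f"{self.kind} requires state_dim >= 1")
        elif self.kind == "spiral":
            A = np.asarray(self.matrix, dtype=float)
            if A.shape != (2, 2):
                raise ValueError("spiral requires a 2x2 matrix")
            object.__setattr__(self, "matrix", A)
            object.__setattr__(self, "state_dim", 2)
        else:
            raise ValueError(f"unknown system kind {self.kind!r}")

    @property
    def sigma(self) -> float:
        return self.params.sigma if self.params is not None else 0.0

    def sigma_vector(self) -> np.ndarray:
        """Per-region noise std, honoring any area-scaled override."""
        if self.params is None:
            return np.zeros(self.state_dim)
        if self.params.per_region_sigma is not None:
            return np.broadcast_to(
                self.params.per_region_sigma, (self.state_dim,)
            ).astype(float)
        return np.full(self.state_dim, self.params.sigma)

    def with_sigma(self, sigma: float) -> "DynamicalSystem":
        """Same drift, different noise amplitude."""
        params = FRMParams(k=self.params.k if self.params else 0.0, sigma=sigma)
        return DynamicalSystem(
            kind=self.kind,
            params=params,
            connectome=self.connectome,
            matrix=self.matrix,
            state_dim=self.state_dim,
        )


def frm_system(
    conn: StructuralConnectome, k: float, sigma: float = 0.0,
    per_region_sigma: np.ndarray | None = None,
) -> DynamicalSystem:
    return DynamicalSystem(
        kind="frm",
        params=FRMParams(k=k, sigma=sigma, per_region_sigma=per_region_sigma),
        connectome=conn,
    )


def ar_system(state_dim: int, sigma: float = 0.0) -> DynamicalSystem:
    """Autoregressive null: connectivity = identity with k = 1, drift == 0."""
    return DynamicalSystem(kind="ar", params=FRMParams(k=1.0, sigma=sigma),
                           state_dim=state_dim)


def exp_decay_system(state_dim: int, sigma: float = 0.0) -> DynamicalSystem:
    """Zero-coupling null: dx = -x dt (+ noise)."""
    return DynamicalSystem(kind="exp_decay", params=FRMParams(k=0.0, sigma=sigma),
                           state_dim=state_dim)


def spiral_system(A: np.ndarray) -> DynamicalSystem:
    return DynamicalSystem(kind="spiral", matrix=A)


def system_matrix(system: DynamicalSystem) -> np.ndarray:
    """The drift matrix M such that the noiseless drift is M @ x."""
    n = system.state_dim
    if system.kind == "frm":
        return system.params.k * system.connectome.weights - np.eye(n)
    if system.kind == "ar":
        return np.zeros((n, n))
    if system.kind == "exp_decay":
        return -np.eye(n)
    return system.matrix  # spiral


def drift(system: DynamicalSystem, x: np.ndarray) -> np.ndarray:
    """Instantaneous deterministic rate of change at state ``x``."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != system.state_dim:
        raise ValueError(
            f"state has dim {x.shape[-1]}, system expects {system.state_dim}"
        )
    if system.kind == "ar":
        return np.zeros_like(x)
    if system.kind == "exp_decay":
        return -x
    return x @ system_matrix(system).T


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled state sequence, stored time-major ``(T, n)``."""

    states: np.ndarray
    sampling_interval: float = DEFAULT_TR
    t0: float = 0.0

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype=float)
        if states.ndim != 2 or states.shape[0] < 1:
            raise ValueError("states must be a (T, n) array with T >= 1")
        if not np.isfinite(states).all():
            raise ValueError("trajectory contains non-finite states")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        object.__setattr__(self, "states", states)

    @property
    def n_steps(self) -> int:
        return self.states.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.sampling_interval * np.arange(self.n_steps)


class DivergenceError(RuntimeError):
    """Raised when the integration overflows the stability guard."""

    def __init__(self, step: int):
        super().__init__(
            f"state magnitude exceeded {OVERFLOW_GUARD:g} at sampled step {step}; "
            "the parameterization is unstable (is W spectrally normalized and k < 1?)"
        )
        self.step = step


def simulate(
    system: DynamicalSystem,
    x0: np.ndarray,
    n_steps: int,
    seed: int | None = 0,
    sampling_interval: float = DEFAULT_TR,
    substeps: int = DEFAULT_SUBSTEPS,
    include_initial: bool = True,
) -> Trajectory:
    """Stochastic integration, one emitted state per sampling interval.

    Exponential Euler-Maruyama: the linear drift is integrated exactly over
    each substep and noise is added per substep as
    ``sigma * sqrt(dt_sub) * N(0, 1)``, so ``sigma`` is interpreted per unit
    time.  ``sigma = 0`` gives the deterministic closed-form path; results
    are reproducible given ``seed``.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    x0 = np.asarray(x0, dtype=float)
    batch = simulate_batch(
        system, x0[None, :], n_steps, seed=seed,
        sampling_interval=sampling_interval, substeps=substeps,
    )
    states = batch[0]
    if include_initial:
        states = np.vstack([x0, states])
    return Trajectory(states=states, sampling_interval=sampling_interval)


def simulate_batch(
    system: DynamicalSystem,
    x0: np.ndarray,
    n_steps: int,
    seed: int | None = 0,
    sampling_interval: float = DEFAULT_TR,
    substeps: int = DEFAULT_SUBSTEPS,
) -> np.ndarray:
    """Integrate many initial states at once; returns ``(m, n_steps, n)``.

    The emitted sequence starts at the state one sampling interval after
    ``x0`` (the initial state itself is not included).
    """
    X = np.atleast_2d(np.asarray(x0, dtype=float))
    if X.shape[1] != system.state_dim:
        raise ValueError(
            f"x0 has dim {X.shape[1]}, system expects {system.state_dim}"
        )
    M = system_matrix(system)
    dt = sampling_interval / substeps
    # exponential Euler-Maruyama: the linear drift is propagated exactly per
    # substep (expm is cheap, computed once), the diffusion term enters as
    # sigma * sqrt(dt) * N(0,1) per substep.  For sigma = 0 this reproduces
    # the closed-form flow to machine precision.
    Phi = np.eye(system.state_dim) if system.kind == "ar" else expm(M * dt)
    sig = system.sigma_vector() * np.sqrt(dt)
    noisy = np.any(sig > 0)
    rng = np.random.default_rng(seed) if noisy else None
    out = np.empty((X.shape[0], n_steps, system.state_dim))
    x = X.copy()
    for step in range(n_steps):
        for _ in range(substeps):
            x = x @ Phi.T
            if noisy:
                x = x + sig * rng.standard_normal(x.shape)
        if np.abs(x).max() > OVERFLOW_GUARD:
            raise DivergenceError(step + 1)
        out[:, step, :] = x
    return out


def closed_form_linear(
    system: DynamicalSystem, x0: np.ndarray, t: float
) -> np.ndarray:
    """Exact noiseless solution ``expm(M t) @ x0`` for linear systems.

    Serves as the oracle for the Euler-Maruyama integrator.  The ``ar`` null
    is excluded: its forecast rule x(n+1) = x(n) is a discrete-time
    convention, not the flow of its (zero) drift field.
    """
    if system.kind == "ar":
        raise ValueError("closed_form_linear is unsupported for the ar null")
    x0 = np.asarray(x0, dtype=float)
    return expm(system_matrix(system) * t) @ x0


def propagator(system: DynamicalSystem, dt: float = DEFAULT_TR) -> np.ndarray:
    """Exact one-sampling-interval noiseless propagator ``expm(M dt)``.

    For the ``ar`` null this is the identity (x(n+1) = x(n)), matching its
    forecast rule rather than the matrix exponential of its zero drift.
    """
    if system.kind == "ar":
        return np.eye(system.state_dim)
    return expm(system_matrix(system) * dt)


#: mean parcel surface area of the reference cortical parcellation, mm²
MEAN_PARCEL_AREA = 858.0
#: noise std of a mean-area parcel (per unit time, signal units)
REFERENCE_SIGMA = 0.35


def area_scaled_sigma(surface_area: float | np.ndarray) -> float | np.ndarray:
    """Cortical noise amplitude as a linear function of parcel surface area.

    A parcel of the mean area (858 mm²) receives sigma = 0.35; noise scales
    proportionally with area, making sigma a property of the cortex rather
    than of any particular network model.
    """
    area = np.asarray(surface_area, dtype=float)
    if np.any(area <= 0):
        raise ValueError("surface_area must be positive")
    out = REFERENCE_SIGMA * (area / MEAN_PARCEL_AREA)
    return float(out) if out.ndim == 0 else out


def write_trajectory(traj: Trajectory, path) -> None:
    """Region×time TSV with a header line carrying the sampling interval."""
    import pandas as pd

    with open(path, "w") as fh:
        fh.write(f"# sampling_interval={traj.sampling_interval!r} t0={traj.t0!r}\n")
        pd.DataFrame(traj.states.T).to_csv(fh, sep="\t", header=False, index=False,
                                           float_format="%.17g")


def read_trajectory(path) -> Trajectory:
    import pandas as pd

    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing sampling-interval header line")
        meta = dict(tok.split("=") for tok in header[1:].split())
        data = pd.read_csv(fh, sep="\t", header=None).to_numpy(dtype=float)
    return Trajectory(
        states=data.T,
        sampling_interval=float(meta["sampling_interval"]),
        t0=float(meta.get("t0", 0.0)),
    )
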