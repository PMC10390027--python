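"""Structural connectome construction, normalization, perturbation and I/O.

A structural connectome is a symmetric, nonnegative, zero-diagonal weight
matrix over cortical regions (tractography fiber counts, optionally divided
by the surface area of the receiving region).  Before simulation the matrix
is spectrally normalized -- divided by its largest eigenvalue -- so that the
effective system matrix ``k*W - I`` of the firing rate model is strictly
stable for any global coupling ``k < 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

SYMMETRY_TOL = 1e-10
SPECTRAL_TOL = 1e-8


@dataclass(frozen=True)
class StructuralConnectome:
    """Symmetric weighted region graph.

    Parameters
    ----------
    weights
        ``(n, n)`` symmetric nonnegative matrix with zero diagonal.
    region_labels
        One label per region; defaults to ``R000..`` style names.
    surface_areas
        Optional per-region cortical surface areas in mm², used for
        area-scaled noise assignment.
    normalized
        True once the matrix has been divided by its largest eigenvalue.
    """

    weights: np.ndarray
    region_labels: tuple[str, ...] = field(default=())
    surface_areas: np.ndarray | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be square, got shape {w.shape}")
        asym = np.abs(w - w.T).max() if w.size else 0.0
        if asym > SYMMETRY_TOL:
            i, j = np.unravel_index(np.argmax(np.abs(w - w.T)), w.shape)
            raise ValueError(
                f"weights not symmetric: max |W - W.T| = {asym:.3g} at ({i}, {j})"
            )
        if np.any(np.diag(w) != 0.0):
            raise ValueError("diagonal must be zero (self-coupling lives in the dynamics)")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        # symmetrize exactly so downstream eigensolvers see a symmetric matrix
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        w.flags.writeable = False
        object.__setattr__(self, "weights", w)
        labels = tuple(self.region_labels) or tuple(
            f"R{i:03d}" for i in range(w.shape[0])
        )
        if len(labels) != w.shape[0]:
            raise ValueError("region_labels length must match matrix size")
        object.__setattr__(self, "region_labels", labels)
        if self.surface_areas is not None:
            areas = np.asarray(self.surface_areas, dtype=float)
            if areas.shape != (w.shape[0],):
                raise ValueError("surface_areas must have one entry per region")
            if np.any(areas <= 0):
                raise ValueError("surface_areas must be positive")
            object.__setattr__(self, "surface_areas", areas)
        if self.normalized:
            lam = spectral_radius(w)
            if abs(lam - 1.0) > SPECTRAL_TOL:
                raise ValueError(
                    f"normalized flag set but largest eigenvalue is {lam!r}"
                )

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def n_edges(self) -> int:
        """Number of nonzero upper-triangle edges."""
        iu = np.triu_indices(self.n_regions, k=1)
        return int(np.count_nonzero(self.weights[iu]))


@dataclass(frozen=True)
class PerturbationSpec:
    """Fraction of existing edges to swap onto currently-empty node pairs."""

    fraction: float
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"fraction must be in [0, 1], got {self.fraction}")


def spectral_radius(weights: np.ndarray) -> float:
    """Largest eigenvalue of a symmetric matrix (= spectral radius here)."""
    return float(np.linalg.eigvalsh(weights)[-1])


def normalize_spectral(conn: StructuralConnectome) -> StructuralConnectome:
    """Divide the weight matrix by its largest eigenvalue.

    After normalization the largest eigenvalue is exactly 1, so ``k*W - I``
    has only negative eigenvalues for every ``k < 1`` (noiseless decay).
    Idempotent and scale-invariant.
    """
    lam = spectral_radius(conn.weights)
    if lam <= 0.0:
        raise ValueError("cannot normalize: matrix has no positive eigenvalue")
    return replace(conn, weights=conn.weights / lam, normalized=True)


def stability_margin(conn: StructuralConnectome, k: float) -> float:
    """Largest eigenvalue of ``k*W - I``; negative iff noiseless decay is stable."""
    return k * spectral_radius(conn.weights) - 1.0


def perturb_edges(
    conn: StructuralConnectome, spec: PerturbationSpec
) -> StructuralConnectome:
    """Swap a fraction of edges to currently-unconnected node pairs.

    A uniformly chosen set of existing upper-triangle edges is removed and
    their weights placed on uniformly chosen currently-empty off-diagonal
    pairs (mirrored to keep symmetry).  Edge count and the multiset of edge
    weights are preserved; self-loops and doubled edges never arise.
    Deterministic given ``spec.seed``.
    """
    n = conn.n_regions
    iu = np.triu_indices(n, k=1)
    vals = conn.weights[iu]
    edge_idx = np.flatnonzero(vals > 0)
    empty_idx = np.flatnonzero(vals == 0)
    n_swap = int(round(spec.fraction * edge_idx.size))
    if n_swap > empty_idx.size:
        feasible = empty_idx.size / edge_idx.size if edge_idx.size else 0.0
        raise ValueError(
            f"cannot swap {n_swap} edges: only {empty_idx.size} empty pairs "
            f"available (feasible maximum fraction {feasible:.3f})"
        )
    if n_swap == 0:
        return conn
    rng = np.random.default_rng(spec.seed)
    moved = rng.choice(edge_idx, size=n_swap, replace=False)
    target = rng.choice(empty_idx, size=n_swap, replace=False)
    new_vals = vals.copy()
    new_vals[target] = new_vals[moved]
    new_vals[moved] = 0.0
    w = np.zeros_like(conn.weights)
    w[iu] = new_vals
    w = w + w.T
    return StructuralConnectome(
        weights=w,
        region_labels=conn.region_labels,
        surface_areas=conn.surface_areas,
        normalized=False,
    )


def synth_connectome(
    n_regions: int = 66,
    density: float = 0.3,
    seed: int = 0,
    bilateral: bool = True,
    weight_scale: float = 1.0,
) -> StructuralConnectome:
    """Random symmetric weighted connectome emulating a bilateral parcellation.

    With ``bilateral=True`` the graph has two mirrored hemisphere blocks of
    ``n_regions / 2`` regions each (same intra-hemisphere topology and
    weights), homotopic inter-hemisphere edges, plus a sparse scattering of
    heterotopic callosal edges.  Weights are log-normal, mimicking the heavy
    tail of tractography fiber counts.  Returned unnormalized.
    """
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    if not 0.0 < density <= 1.0:
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    if not bilateral:
        w = np.zeros((n_regions, n_regions))
        iu = np.triu_indices(n_regions, k=1)
        mask = rng.random(iu[0].size) < density
        # force at least one edge so the matrix has a positive eigenvalue
        if not mask.any():
            mask[rng.integers(iu[0].size)] = True
        vals = np.where(mask, rng.lognormal(0.0, 0.8, iu[0].size), 0.0)
        w[iu] = weight_scale * vals
        w = w + w.T
        return StructuralConnectome(weights=w)
    if n_regions % 2:
        raise ValueError("n_regions must be even for a bilateral connectome")
    half = n_regions // 2
    hemi = synth_connectome(
        half, density=density, seed=int(rng.integers(2**31)), bilateral=False,
        weight_scale=weight_scale,
    ).weights
    w = np.zeros((n_regions, n_regions))
    w[:half, :half] = hemi
    w[half:, half:] = hemi
    homotopic = weight_scale * rng.lognormal(0.0, 0.8, half)
    cross = np.diag(homotopic)
    # sparse heterotopic callosal edges at ~1/4 the intra-hemisphere density
    mask = rng.random((half, half)) < density / 4.0
    np.fill_diagonal(mask, False)
    cross = cross + np.where(mask, weight_scale * rng.lognormal(-1.0, 0.8, (half, half)), 0.0)
    w[:half, half:] = cross
    w[half:, :half] = cross.T
    labels = tuple(f"L{i:03d}" for i in range(half)) + tuple(
        f"R{i:03d}" for i in range(half)
    )
    return StructuralConnectome(weights=(w + w.T) / 2.0, region_labels=labels)


def write_connectome(conn: StructuralConnectome, path: str | Path) -> None:
    """Write as a labeled square table; TSV unless the suffix is .csv."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.DataFrame(conn.weights, index=conn.region_labels, columns=conn.region_labels)
    df.to_csv(path, sep=sep, float_format="%.17g")


def read_connectome(path: str | Path) -> StructuralConnectome:
    """Read a square numeric table (TSV/CSV, optional label header/index)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path) as fh:
        first_token = fh.readline().split(sep)[0].strip()
    try:
        float(first_token)
        headerless = True
    except ValueError:
        headerless = False
    if headerless:
        df = pd.read_csv(path, sep=sep, header=None)
        values = df.to_numpy(dtype=float)
        labels: Sequence[str] = ()
    else:
        df = pd.read_csv(path, sep=sep, index_col=0)
        values = df.to_numpy(dtype=float)
        labels = [str(c) for c in df.columns]
    if np.isnan(values).any():
        raise ValueError(f"{path}: ragged or non-numeric table")
    if values.shape[0] != values.shape[1]:
        raise ValueError(f"{path}: table is not square, shape {values.shape}")
    asym = np.abs(values - values.T)
    if asym.max() > SYMMETRY_TOL:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise ValueError(
            f"{path}: asymmetric beyond tolerance at indices ({i}, {j}): "
            f"{values[i, j]!r} vs {values[j, i]!r}"
        )
    return StructuralConnectome(weights=values, region_labels=tuple(labels))


def read_surface_areas(path: str | Path, conn: StructuralConnectome) -> StructuralConnectome:
    """Attach a (label, mm²) sidecar table of surface areas to a connectome."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, header=None, names=["label", "area"])
    table = dict(zip(df["label"].astype(str), df["area"].astype(float)))
    try:
        areas = np.array([table[lab] for lab in conn.region_labels])
    except KeyError as exc:
        raise ValueError(f"{path}: missing surface area for region {exc}") from exc
    return replace(conn, surface_areas=areas)
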