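"""ROI-timeseries conditioning chain for BOLD-like data.

The chain mirrors standard resting-state pipelines: band-pass filter
(0.0008-0.125 Hz), global signal regression against the mean of all cortical
parcels, per-region z-scoring, and segmentation into fixed-length windows
(50 timepoints, trailing remainder dropped).  It is applied identically to
measured and surrogate data.

All functions take region×time matrices (regions as rows).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

from .dynamics import DEFAULT_TR

BAND_LO_HZ = 0.0008
BAND_HI_HZ = 0.125
SEGMENT_LENGTH = 50


def bandpass(
    ts: np.ndarray,
    fs: float,
    lo: float = BAND_LO_HZ,
    hi: float = BAND_HI_HZ,
) -> np.ndarray:
    """Zero-phase band-pass via a hard spectral mask.

    The mean (DC) is removed, the real FFT computed along time, components
    outside ``[lo, hi]`` zeroed and the series inverted.  A spectral mask is
    used instead of an IIR realization because the lower band edge sits at
    ~1e-3 of Nyquist, where Butterworth poles are numerically on the unit
    circle and forward-backward filtering no longer achieves its nominal
    stop-band attenuation on windows of practical length.
    """
    ts = np.asarray(ts, dtype=float)
    if not 0.0 < lo < hi:
        raise ValueError("need 0 < lo < hi")
    if hi >= fs / 2.0:
        raise ValueError(f"hi={hi} must be below the Nyquist frequency {fs / 2}")
    T = ts.shape[-1]
    x = ts - ts.mean(axis=-1, keepdims=True)
    spec = np.fft.rfft(x, axis=-1)
    f = np.fft.rfftfreq(T, d=1.0 / fs)
    spec[..., (f < lo) | (f > hi)] = 0.0
    return np.fft.irfft(spec, n=T, axis=-1)


def regress_global_signal(ts: np.ndarray) -> np.ndarray:
    """Residualize each region on [intercept, mean-across-regions series].

    The global signal is the mean timeseries over all regions; each region is
    replaced by the residual of its least-squares fit on the global signal
    plus an intercept, leaving residuals orthogonal to the global signal.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.shape[0] < 2:
        raise ValueError("global signal regression requires >= 2 regions")
    g = ts.mean(axis=0)
    if np.ptp(g) == 0.0:
        raise ValueError("global signal is constant: degenerate regressor")
    X = np.column_stack([np.ones_like(g), g])
    beta, *_ = np.linalg.lstsq(X, ts.T, rcond=None)
    return ts - (X @ beta).T


def zscore_regions(ts: np.ndarray, ddof: int = 0) -> np.ndarray:
    """Per-region standardization to mean 0, std 1 (population denominator)."""
    ts = np.asarray(ts, dtype=float)
    mu = ts.mean(axis=-1, keepdims=True)
    sd = ts.std(axis=-1, ddof=ddof, keepdims=True)
    dead = np.flatnonzero(sd.ravel() == 0.0)
    if dead.size:
        raise ValueError(f"zero-variance region(s): {dead.tolist()}")
    return (ts - mu) / sd


def segment(ts: np.ndarray, length: int = SEGMENT_LENGTH) -> list[np.ndarray]:
    """Split into consecutive non-overlapping region×length windows.

    The trailing remainder (``T mod length`` timepoints) is dropped.
    """
    ts = np.asarray(ts, dtype=float)
    T = ts.shape[-1]
    if length < 2:
        raise ValueError("segment length must be >= 2")
    if T < length:
        raise ValueError(f"timeseries length {T} shorter than segment length {length}")
    n_seg = T // length
    return [ts[:, i * length:(i + 1) * length].copy() for i in range(n_seg)]


def preprocess_chain(
    ts: np.ndarray,
    fs: float = 1.0 / DEFAULT_TR,
    lo: float = BAND_LO_HZ,
    hi: float = BAND_HI_HZ,
) -> np.ndarray:
    """Band-pass, then global signal regression, then per-region z-score."""
    return zscore_regions(regress_global_signal(bandpass(ts, fs, lo, hi)))


@dataclass
class TimeseriesDataset:
    """A collection of region×time matrices sharing one sampling grid."""

    subjects: list[np.ndarray]
    sampling_interval: float = DEFAULT_TR
    segment_length: int = SEGMENT_LENGTH
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.subjects:
            raise ValueError("dataset needs at least one subject")
        self.subjects = [np.asarray(s, dtype=float) for s in self.subjects]
        n = self.subjects[0].shape[0]
        if any(s.shape[0] != n for s in self.subjects):
            raise ValueError("all subjects must share the region count")
        if self.segment_length < 2:
            raise ValueError("segment_length must be >= 2")

    @property
    def n_regions(self) -> int:
        return self.subjects[0].shape[0]

    def segments(self) -> list[np.ndarray]:
        """All fixed-length windows pooled across subjects."""
        out: list[np.ndarray] = []
        for s in self.subjects:
            out.extend(segment(s, self.segment_length))
        return out

    def segments_by_subject(self) -> list[list[np.ndarray]]:
        return [segment(s, self.segment_length) for s in self.subjects]


def interleave_segments(
    a: Iterable[np.ndarray], b: Iterable[np.ndarray]
) -> list[np.ndarray]:
    """Alternate windows from two datasets (e.g. task and rest) for training."""
    out: list[np.ndarray] = []
    ia, ib = list(a), list(b)
    for i in range(max(len(ia), len(ib))):
        if i < len(ia):
            out.append(ia[i])
        if i < len(ib):
            out.append(ib[i])
    return out


def write_dataset(ds: TimeseriesDataset, directory: str | Path, stem: str = "subject") -> Path:
    """Write each subject as region×time TSV plus a YAML manifest; returns manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    for i, s in enumerate(ds.subjects):
        fname = f"{stem}{i:03d}.tsv"
        np.savetxt(directory / fname, s, delimiter="\t", fmt="%.17g")
        files.append(fname)
    manifest = {
        "sampling_interval": ds.sampling_interval,
        "segment_length": ds.segment_length,
        "provenance": ds.provenance,
        "subjects": files,
    }
    path = directory / "manifest.yaml"
    path.write_text(yaml.safe_dump(manifest))
    return path


def read_dataset(manifest_path: str | Path) -> TimeseriesDataset:
    manifest_path = Path(manifest_path)
    manifest = yaml.safe_load(manifest_path.read_text())
    subjects = [
        np.loadtxt(manifest_path.parent / f, delimiter="\t", ndmin=2)
        for f in manifest["subjects"]
    ]
    return TimeseriesDataset(
        subjects=subjects,
        sampling_interval=float(manifest["sampling_interval"]),
        segment_length=int(manifest["segment_length"]),
        provenance=manifest.get("provenance", {}),
    )
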