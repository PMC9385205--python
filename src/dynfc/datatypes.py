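"""Core containers shared across the pipeline.

All containers validate their invariants on construction so that a stage
receiving one of these objects can rely on them without re-checking:
finiteness, symmetry, value ranges, and label/shape consistency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RoiTimeSeries",
    "PhaseSeries",
    "ConnectivityTensor",
    "StaticFC",
    "StructuralConnectome",
]

#: Absolute tolerance used when checking symmetry / range invariants.
SYMMETRY_ATOL = 1e-10


def _as_float_array(values, name: str, ndim: int) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != ndim:
        raise ValueError(f"{name} must be {ndim}-dimensional, got shape {arr.shape}")
    return arr


def _check_labels(labels, n: int, what: str) -> list:
    labels = list(labels)
    if len(labels) != n:
        raise ValueError(f"{what}: expected {n} labels, got {len(labels)}")
    if len(set(labels)) != len(labels):
        raise ValueError(f"{what}: duplicate labels")
    return labels


@dataclass
class RoiTimeSeries:
    """Region x time signal matrix sampled at a fixed repetition interval.

    Parameters
    ----------
    values : (n_rois, n_samples) array
        Real-valued signal, one row per region.
    dt : float
        Sampling interval in seconds (the fMRI repetition time).
    roi_labels : list of str
        Region names, one per row.
    subject_id, group : str
        Cohort bookkeeping; ``group`` may be ``None`` for unlabelled data.
    """

    values: np.ndarray
    dt: float
    roi_labels: list
    subject_id: str = ""
    group: str | None = None

    def __post_init__(self):
        self.values = _as_float_array(self.values, "values", 2)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite entries")
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        self.roi_labels = _check_labels(self.roi_labels, self.values.shape[0], "roi_labels")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class PhaseSeries:
    """Instantaneous phases in radians, wrapped to (-pi, pi]."""

    phases: np.ndarray
    dt: float
    roi_labels: list
    subject_id: str = ""
    group: str | None = None

    def __post_init__(self):
        self.phases = _as_float_array(self.phases, "phases", 2)
        if not np.all(np.isfinite(self.phases)):
            raise ValueError("phase series contains non-finite entries")
        if np.any(self.phases <= -np.pi) or np.any(self.phases > np.pi):
            raise ValueError("phases must lie in (-pi, pi]")
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        self.roi_labels = _check_labels(self.roi_labels, self.phases.shape[0], "roi_labels")

    @property
    def n_rois(self) -> int:
        return self.phases.shape[0]

    @property
    def n_samples(self) -> int:
        return self.phases.shape[1]


@dataclass
class ConnectivityTensor:
    """Region x region x time stack of non-negative phase-connectivity frames.

    Every frame is symmetric with zero diagonal and entries in [0, 1].
    """

    frames: np.ndarray
    dt: float
    roi_labels: list
    subject_id: str = ""
    group: str | None = None

    def __post_init__(self):
        self.frames = _as_float_array(self.frames, "frames", 3)
        n, m, _ = self.frames.shape
        if n != m:
            raise ValueError(f"frames must be square per time point, got {self.frames.shape}")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("tensor contains non-finite entries")
        if np.any(self.frames < -SYMMETRY_ATOL) or np.any(self.frames > 1 + SYMMETRY_ATOL):
            raise ValueError("tensor entries must lie in [0, 1]")
        asym = np.abs(self.frames - self.frames.transpose(1, 0, 2)).max()
        if asym > 1e-8:
            raise ValueError(f"frames not symmetric (max asymmetry {asym:g})")
        diag = np.abs(self.frames[np.arange(n), np.arange(n), :]).max() if n else 0.0
        if diag > 1e-8:
            raise ValueError(f"frames must have zero diagonal (max |diag| {diag:g})")
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        self.roi_labels = _check_labels(self.roi_labels, n, "roi_labels")

    @property
    def n_rois(self) -> int:
        return self.frames.shape[0]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[2]


@dataclass
class StaticFC:
    """Full Pearson correlation matrix of the narrowband time courses."""

    matrix: np.ndarray
    roi_labels: list

    def __post_init__(self):
        self.matrix = _as_float_array(self.matrix, "matrix", 2)
        n, m = self.matrix.shape
        if n != m:
            raise ValueError("static FC must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise ValueError("static FC must be symmetric")
        if not np.allclose(np.diag(self.matrix), 1.0, atol=1e-8):
            raise ValueError("static FC diagonal must be 1")
        if np.any(self.matrix < -1 - 1e-8) or np.any(self.matrix > 1 + 1e-8):
            raise ValueError("correlations must lie in [-1, 1]")
        self.roi_labels = _check_labels(self.roi_labels, n, "roi_labels")

    @property
    def n_rois(self) -> int:
        return self.matrix.shape[0]


@dataclass
class StructuralConnectome:
    """Symmetric non-negative anatomical weight matrix with zero diagonal."""

    weights: np.ndarray
    roi_labels: list

    def __post_init__(self):
        self.weights = _as_float_array(self.weights, "weights", 2)
        n, m = self.weights.shape
        if n != m:
            raise ValueError("connectome must be square")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("connectome contains non-finite entries")
        if np.any(self.weights < 0):
            raise ValueError("connectome weights must be non-negative")
        if not np.allclose(self.weights, self.weights.T, atol=SYMMETRY_ATOL):
            raise ValueError("connectome must be symmetric")
        if np.any(np.abs(np.diag(self.weights)) > SYMMETRY_ATOL):
            raise ValueError("connectome diagonal must be zero")
        self.roi_labels = _check_labels(self.roi_labels, n, "roi_labels")

    @property
    def n_rois(self) -> int:
        return self.weights.shape[0]

    def strengths(self) -> np.ndarray:
        """Node strengths (weighted degrees)."""
        return self.weights.sum(axis=1)
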