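"""Structural eigenmodes and their expression in time-resolved connectivity.

The anatomical network's hidden spatial patterns are the eigenvectors of
the symmetric-normalized graph Laplacian of the structural connectome,

    Q_SC = K^{-1/2} (K - SC) K^{-1/2},

with K the diagonal strength matrix.  Each functional connectivity frame
FC(t) is mapped onto this basis: building the frame's own normalized
Laplacian Q_FC(t), the per-eigenmode weighting coefficients are

    P_i(t) = u_i^T Q_FC(t) u_i,

and the eigenmode prediction of the frame is

    FC(t) ~ K_FC(t) - K_FC^{1/2}(t) U P(t) U^T K_FC^{1/2}(t).

Fluctuation of the coefficients over time — the modulation strength — is
the summed absolute coefficient difference over all ordered time-point
pairs, evaluated separately for the dominant (low spatial frequency,
integrative) and non-dominant (high spatial frequency, segregated) halves
of the spectrum.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as _linalg
from scipy import stats as _stats

from .datatypes import ConnectivityTensor, StructuralConnectome

__all__ = [
    "EigenmodeBasis",
    "EigenExpressionSeries",
    "graph_laplacian",
    "eigenmode_basis",
    "normalized_laplacian_of_frame",
    "eigenmode_expression",
    "expression_series",
    "predict_fc",
    "goodness_of_fit",
    "modulation_strength",
    "dominant_indices",
    "non_dominant_indices",
]

logger = logging.getLogger(__name__)

#: Floor applied to a zero-strength node's incident entries before normalization.
ZERO_STRENGTH_EPS = 1e-9


def graph_laplacian(sc: StructuralConnectome) -> np.ndarray:
    """Symmetric-normalized graph Laplacian Q_SC of the connectome.

    Q_SC = K^{-1/2} (K - SC) K^{-1/2} = I - K^{-1/2} SC K^{-1/2}.  Requires
    every node to have positive strength; an isolated node has no defined
    normalization and is reported by name.
    """
    s = sc.strengths()
    dead = np.nonzero(s <= 0)[0]
    if dead.size:
        raise ValueError(f"isolated node '{sc.roi_labels[dead[0]]}' has zero strength")
    d = 1.0 / np.sqrt(s)
    q = -d[:, None] * sc.weights * d[None, :]
    np.fill_diagonal(q, 1.0)
    return 0.5 * (q + q.T)


@dataclass
class EigenmodeBasis:
    """Eigenvectors (columns of U) and ascending eigenvalues of Q_SC.

    Eigenvector signs are fixed so the largest-magnitude entry of each
    column is positive; the quadratic-form coefficients are sign-invariant
    but the stored basis must be deterministic.
    """

    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    source_fingerprint: str = ""

    def __post_init__(self):
        u = np.asarray(self.eigenvectors, dtype=float)
        lam = np.asarray(self.eigenvalues, dtype=float)
        if u.ndim != 2 or u.shape[0] != u.shape[1]:
            raise ValueError("eigenvector matrix must be square")
        if lam.shape != (u.shape[0],):
            raise ValueError("eigenvalue count must match basis size")
        gram_err = np.abs(u.T @ u - np.eye(u.shape[0])).max()
        if gram_err > 1e-8:
            raise ValueError(f"basis not orthonormal (max deviation {gram_err:g})")
        if np.any(np.diff(lam) < -1e-10):
            raise ValueError("eigenvalues must be sorted ascending")
        if lam[0] < -1e-8 or lam[-1] > 2 + 1e-8:
            raise ValueError("normalized-Laplacian eigenvalues must lie in [0, 2]")
        self.eigenvectors = u
        self.eigenvalues = lam

    @property
    def n_modes(self) -> int:
        return self.eigenvectors.shape[0]


def dominant_indices(n_modes: int) -> np.ndarray:
    """Indices of the dominant (low spatial frequency) half of the spectrum.

    Even n: the first n/2 modes.  Odd n: the middle mode joins the dominant
    set, keeping the two subsets disjoint.
    """
    return np.arange((n_modes + 1) // 2)


def non_dominant_indices(n_modes: int) -> np.ndarray:
    """Indices of the non-dominant (high spatial frequency) half."""
    return np.arange((n_modes + 1) // 2, n_modes)


def eigenmode_basis(laplacian: np.ndarray, fingerprint: str | None = None) -> EigenmodeBasis:
    """Full eigendecomposition of a symmetric normalized Laplacian."""
    q = np.asarray(laplacian, dtype=float)
    if q.ndim != 2 or q.shape[0] != q.shape[1]:
        raise ValueError("laplacian must be square")
    if not np.allclose(q, q.T, atol=1e-8):
        raise ValueError("laplacian must be symmetric")
    lam, u = _linalg.eigh(q)
    lam = np.clip(lam, 0.0, 2.0)  # numerical guard at the spectral bounds
    # deterministic sign: largest-magnitude entry of each eigenvector positive
    pivot = np.argmax(np.abs(u), axis=0)
    signs = np.sign(u[pivot, np.arange(u.shape[1])])
    signs[signs == 0] = 1.0
    u = u * signs[None, :]
    if fingerprint is None:
        fingerprint = hashlib.sha256(np.ascontiguousarray(q).tobytes()).hexdigest()[:16]
    return EigenmodeBasis(u, lam, fingerprint)


def normalized_laplacian_of_frame(frame: np.ndarray,
                                  eps: float = ZERO_STRENGTH_EPS) -> np.ndarray:
    """Symmetric-normalized Laplacian of a single connectivity frame.

    A node whose strength vanishes in a sparse frame has an undefined
    normalization; its incident off-diagonal entries are floored at ``eps``
    (logged) so K^{-1/2} exists.
    """
    w = np.asarray(frame, dtype=float)
    s = w.sum(axis=1)
    dead = np.nonzero(s <= 0)[0]
    if dead.size:
        logger.warning("flooring incident entries of %d zero-strength node(s) at %g",
                       dead.size, eps)
        w = w.copy()
        off = ~np.eye(w.shape[0], dtype=bool)
        for i in dead:
            w[i, off[i]] = np.maximum(w[i, off[i]], eps)
            w[off[:, i], i] = w[i, off[i]]
        s = w.sum(axis=1)
    d = 1.0 / np.sqrt(s)
    q = -d[:, None] * w * d[None, :]
    np.fill_diagonal(q, 1.0)
    return 0.5 * (q + q.T)


def eigenmode_expression(fc_frame: np.ndarray, basis: EigenmodeBasis,
                         eps: float = ZERO_STRENGTH_EPS) -> np.ndarray:
    """Per-eigenmode weighting coefficients diag(P(t)) for one frame.

    Builds the frame's normalized Laplacian Q_FC(t) and projects it on the
    structural basis: coefficient i is the quadratic form u_i^T Q_FC u_i.
    By construction the coefficients sum to trace(Q_FC).
    """
    q = normalized_laplacian_of_frame(fc_frame, eps=eps)
    if q.shape[0] != basis.n_modes:
        raise ValueError("frame size does not match basis")
    u = basis.eigenvectors
    return np.einsum("ji,jk,ki->i", u, q, u, optimize=True)


def predict_fc(fc_frame: np.ndarray, basis: EigenmodeBasis,
               coefficients: np.ndarray) -> np.ndarray:
    """Eigenmode prediction of a frame from its own strength profile.

    FC_hat = K - K^{1/2} U diag(p) U^T K^{1/2} with K the frame's diagonal
    strength matrix.
    """
    w = np.asarray(fc_frame, dtype=float)
    p = np.asarray(coefficients, dtype=float)
    if w.shape[0] != basis.n_modes or p.shape != (basis.n_modes,):
        raise ValueError("frame/coefficient dimensions do not match basis")
    k = w.sum(axis=1)
    k_sqrt = np.sqrt(k)
    u = basis.eigenvectors
    core = (u * p[None, :]) @ u.T
    pred = np.diag(k) - k_sqrt[:, None] * core * k_sqrt[None, :]
    return 0.5 * (pred + pred.T)


def goodness_of_fit(empirical: np.ndarray, predicted: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-frame Pearson correlation between empirical and predicted frames.

    Correlation is taken over the strictly upper-triangular entries.
    Frames with a constant upper triangle in either input are skipped (NaN
    in the per-frame series, excluded from the mean) and logged.
    Returns ``(per_frame_r, mean_r)``.
    """
    emp = np.asarray(empirical, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if emp.shape != pred.shape:
        raise ValueError(f"shape mismatch {emp.shape} vs {pred.shape}")
    if emp.ndim == 2:
        emp = emp[:, :, None]
        pred = pred[:, :, None]
    iu = np.triu_indices(emp.shape[0], k=1)
    rs = np.full(emp.shape[2], np.nan)
    for t in range(emp.shape[2]):
        x = emp[iu[0], iu[1], t]
        y = pred[iu[0], iu[1], t]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.warning("frame %d skipped: constant upper triangle", t)
            continue
        rs[t] = _stats.pearsonr(x, y)[0]
    valid = rs[np.isfinite(rs)]
    mean_r = float(valid.mean()) if valid.size else float("nan")
    return rs, mean_r


def modulation_strength(coefficients: np.ndarray, subset) -> tuple[float, float]:
    """Eigenmode modulation strength over a subset of modes.

    ``coefficients`` is (n_modes, T).  The raw statistic is the sum over all
    ordered time-point pairs (t_k, t_j) and subset modes of
    |P_i(t_k) - P_i(t_j)|; the normalized form divides by T^2 times the
    subset size so differently trimmed recordings remain comparable.
    Returns ``(raw, normalized)``.
    """
    coeff = np.asarray(coefficients, dtype=float)
    if coeff.ndim != 2:
        raise ValueError("coefficients must be (n_modes, T)")
    n_modes, t = coeff.shape
    if t < 2:
        raise ValueError("modulation strength requires at least 2 time points")
    idx = np.asarray(subset, dtype=int)
    if idx.size == 0:
        raise ValueError("empty eigenmode subset")
    sub = np.sort(coeff[idx, :], axis=1)
    # sum over unordered pairs of |x_a - x_b| via the sorted-prefix identity,
    # doubled for ordered pairs
    weights = 2 * np.arange(t) - (t - 1)
    raw = 2.0 * float((sub * weights[None, :]).sum())
    return raw, raw / (t * t * idx.size)


@dataclass
class EigenExpressionSeries:
    """Eigenmode weighting coefficients over time, with fit and modulation.

    ``coefficients`` holds diag(P(t)) as columns (one per retained frame);
    ``fit`` is the per-frame goodness-of-fit correlation.
    """

    coefficients: np.ndarray
    fit: np.ndarray
    mean_fit: float
    delta_dominant_raw: float
    delta_dominant: float
    delta_non_dominant_raw: float
    delta_non_dominant: float
    subject_id: str = ""
    group: str | None = None

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.fit = np.asarray(self.fit, dtype=float)
        if self.coefficients.ndim != 2:
            raise ValueError("coefficients must be (n_modes, T)")
        if self.fit.shape != (self.coefficients.shape[1],):
            raise ValueError("fit series length must equal number of frames")
        finite = self.fit[np.isfinite(self.fit)]
        if finite.size and (finite.min() < -1 - 1e-8 or finite.max() > 1 + 1e-8):
            raise ValueError("goodness-of-fit must lie in [-1, 1]")


def expression_series(tensor: ConnectivityTensor, basis: EigenmodeBasis,
                      eps: float = ZERO_STRENGTH_EPS) -> EigenExpressionSeries:
    """Run the eigenmode mapping over every frame of a subject's tensor.

    Computes diag(P(t)) per frame, the eigenmode-predicted frame and its
    goodness-of-fit, and the dominant / non-dominant modulation strengths.
    """
    n, t = tensor.n_rois, tensor.n_frames
    if n != basis.n_modes:
        raise ValueError("tensor region count does not match basis")
    coeffs = np.empty((n, t))
    preds = np.empty_like(tensor.frames)
    for k in range(t):
        frame = tensor.frames[:, :, k]
        coeffs[:, k] = eigenmode_expression(frame, basis, eps=eps)
        preds[:, :, k] = predict_fc(frame, basis, coeffs[:, k])
    fit, mean_fit = goodness_of_fit(tensor.frames, preds)
    dom_raw, dom = modulation_strength(coeffs, dominant_indices(n))
    non_raw, non = modulation_strength(coeffs, non_dominant_indices(n))
    return EigenExpressionSeries(coeffs, fit, mean_fit, dom_raw, dom, non_raw, non,
                                 tensor.subject_id, tensor.group)
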