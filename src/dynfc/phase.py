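"""Narrowband filtering, instantaneous phase, synchrony, and phase connectivity.

The time-resolved connectivity estimate is built from the instantaneous
phase of each region's narrowband signal (analytic signal via the Hilbert
transform).  Global synchrony at each volume is summarized by the Kuramoto
order parameter

    R(t) = | (1/N) sum_k exp(i phi_k(t)) |

and its standard deviation over time serves as the metastability proxy.
Pairwise connectivity at time t is the cosine of the instantaneous phase
difference, clipped at zero so that downstream non-negative factorization
and Laplacian constructions are well defined; the signed cosine is available
separately for diagnostics.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as _signal
from scipy import stats as _stats

from .datatypes import (
    ConnectivityTensor,
    PhaseSeries,
    RoiTimeSeries,
    StaticFC,
    StructuralConnectome,
)

__all__ = [
    "bandpass_filter",
    "instantaneous_phase",
    "kuramoto_order_parameter",
    "metastability",
    "signed_phase_cosine",
    "phase_connectivity_tensor",
    "static_fc",
    "static_structure_function_coupling",
    "DEFAULT_BAND",
    "DEFAULT_EDGE_TRIM",
]

#: Default narrowband edges in Hz for BOLD-like signals sampled at TR = 2 s.
DEFAULT_BAND = (0.01, 0.09)

#: Default number of samples cropped from each end after the Hilbert transform.
DEFAULT_EDGE_TRIM = 10


def bandpass_filter(ts: RoiTimeSeries, low_hz: float, high_hz: float,
                    order: int = 2) -> RoiTimeSeries:
    """Zero-phase Butterworth band-pass applied per region.

    A second-order Butterworth is applied forward and backward
    (``filtfilt``), preserving length and phase.  The band must sit strictly
    inside (0, Nyquist); an upper edge at or beyond Nyquist (0.5/dt) is a
    configuration error, not something to silently clip.
    """
    nyquist = 0.5 / ts.dt
    if not (0 < low_hz < high_hz):
        raise ValueError(f"band edges must satisfy 0 < low < high, got ({low_hz}, {high_hz})")
    if high_hz >= nyquist:
        raise ValueError(
            f"upper band edge {high_hz} Hz is not below Nyquist {nyquist} Hz for dt={ts.dt} s"
        )
    sos = _signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=1.0 / ts.dt,
                         output="sos")
    filtered = _signal.sosfiltfilt(sos, ts.values, axis=1)
    return RoiTimeSeries(filtered, ts.dt, list(ts.roi_labels), ts.subject_id, ts.group)


def instantaneous_phase(ts: RoiTimeSeries, edge_trim: int = DEFAULT_EDGE_TRIM) -> PhaseSeries:
    """Analytic-signal phase per region, wrapped to (-pi, pi].

    ``edge_trim`` samples are removed from each end of the record to
    suppress Hilbert-transform edge artefacts.  Input should already be
    narrowband for the phase to be interpretable.
    """
    if edge_trim < 0:
        raise ValueError("edge_trim must be non-negative")
    if ts.n_samples - 2 * edge_trim < 2:
        raise ValueError(f"edge_trim={edge_trim} leaves fewer than 2 samples of T={ts.n_samples}")
    variances = ts.values.var(axis=1)
    flat = np.nonzero(variances == 0)[0]
    if flat.size:
        raise ValueError(f"constant signal in region '{ts.roi_labels[flat[0]]}'")
    analytic = _signal.hilbert(ts.values, axis=1)
    phases = np.angle(analytic)
    # np.angle can return exactly -pi; fold onto the (-pi, pi] convention
    phases = np.where(phases <= -np.pi, phases + 2 * np.pi, phases)
    if edge_trim:
        phases = phases[:, edge_trim:-edge_trim]
    return PhaseSeries(phases, ts.dt, list(ts.roi_labels), ts.subject_id, ts.group)


def kuramoto_order_parameter(ph: PhaseSeries) -> np.ndarray:
    """Modulus of the mean unit phasor across regions, per time point.

    Returns a length-T vector with values in [0, 1]: 1 means all regions are
    phase-locked at that volume, values near 0 mean incoherence.
    """
    if ph.n_rois < 2:
        raise ValueError("order parameter requires at least 2 regions")
    r = np.abs(np.exp(1j * ph.phases).mean(axis=0))
    return np.clip(r, 0.0, 1.0)


def metastability(ph: PhaseSeries) -> float:
    """Sample standard deviation over time of the Kuramoto order parameter."""
    r = kuramoto_order_parameter(ph)
    if r.size < 2:
        raise ValueError("metastability requires at least 2 time points")
    return float(np.std(r, ddof=1))


def signed_phase_cosine(ph: PhaseSeries) -> np.ndarray:
    """cos(phase difference) for every region pair and time point (unclipped).

    Diagnostic companion of :func:`phase_connectivity_tensor`; antiphase
    pairs show up as -1 here rather than being clipped to 0.
    """
    c = np.cos(ph.phases)
    s = np.sin(ph.phases)
    # cos(a-b) = cos a cos b + sin a sin b
    return np.einsum("it,jt->ijt", c, c) + np.einsum("it,jt->ijt", s, s)


def phase_connectivity_tensor(ph: PhaseSeries) -> ConnectivityTensor:
    """Instantaneous phase connectivity: max(0, cos(delta phi)) per pair.

    Produces the region x region x time tensor consumed by the
    non-negative factorization and eigenmode stages: each frame is
    symmetric, has zero diagonal, and entries in [0, 1].
    """
    frames = np.clip(signed_phase_cosine(ph), 0.0, 1.0)
    idx = np.arange(ph.n_rois)
    frames[idx, idx, :] = 0.0
    # enforce exact symmetry against floating-point einsum noise
    frames = 0.5 * (frames + frames.transpose(1, 0, 2))
    return ConnectivityTensor(frames, ph.dt, list(ph.roi_labels), ph.subject_id, ph.group)


def static_fc(ts: RoiTimeSeries) -> StaticFC:
    """Pearson correlation matrix of the (narrowband) region time courses."""
    if ts.n_samples < 3:
        raise ValueError("static FC requires at least 3 time points")
    variances = ts.values.var(axis=1)
    flat = np.nonzero(variances == 0)[0]
    if flat.size:
        raise ValueError(f"zero-variance region '{ts.roi_labels[flat[0]]}'")
    corr = np.corrcoef(ts.values)
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(0.5 * (corr + corr.T), -1.0, 1.0)
    return StaticFC(corr, list(ts.roi_labels))


def static_structure_function_coupling(fc: StaticFC, sc: StructuralConnectome) -> float:
    """Pearson correlation of static FC with the structural connectome.

    Computed over the strictly upper-triangular entries of both matrices,
    i.e. corr(FCstatic, SC) in the structure-function coupling sense.
    """
    if fc.roi_labels != sc.roi_labels:
        raise ValueError("FC and SC region sets differ")
    iu = np.triu_indices(fc.n_rois, k=1)
    x = fc.matrix[iu]
    y = sc.weights[iu]
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("constant upper triangle: correlation undefined")
    return float(_stats.pearsonr(x, y)[0])
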