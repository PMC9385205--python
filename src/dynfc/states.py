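"""Network states from seeded non-negative tensor factorization.

The concatenated phase-connectivity tensor (regions x regions x time,
pooled over subjects) is decomposed into L rank-one network states

    FC ~ sum_l  a_l (x) b_l (x) c_l,

where a_l, b_l are non-negative spatial factors (their symmetrized outer
product is the state's connectivity pattern) and c_l is the non-negative
temporal loading over the concatenated time axis.  Spatial factors are
initialized from membership vectors of expected resting-state networks plus
a uniform residual component that soaks up unexplained variance; the
optimizer is free to reshape them.  Updates are hierarchical alternating
least squares (HALS) for non-negative CP/PARAFAC.

Downstream statistics: the per-subject winner timeline (argmax over
component loadings), dwell times (run lengths of the winner), and the
excursions-from-median nonstationarity statistic on each loading series.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .datatypes import ConnectivityTensor

__all__ = [
    "SeedNetworks",
    "TensorComponents",
    "StateTimeline",
    "NonstationarityStat",
    "concatenate_tensors",
    "nntf_decompose",
    "spatial_pattern",
    "split_loadings",
    "state_timeline",
    "dwell_times",
    "excursions_from_median",
]

logger = logging.getLogger(__name__)

DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 500


@dataclass
class SeedNetworks:
    """Named non-negative region-membership vectors plus a residual slot.

    ``membership`` is (n_seeds, n_rois); the residual component is appended
    by the factorization with a uniform profile, so L = n_seeds + 1.
    """

    names: list
    membership: np.ndarray
    residual_name: str = "residual"

    def __post_init__(self):
        self.membership = np.asarray(self.membership, dtype=float)
        if self.membership.ndim != 2:
            raise ValueError("membership must be (n_seeds, n_rois)")
        if len(self.names) != self.membership.shape[0]:
            raise ValueError("one name per seed required")
        if len(set(self.names) | {self.residual_name}) != len(self.names) + 1:
            raise ValueError("seed names must be unique and distinct from the residual")
        if np.any(self.membership < 0):
            raise ValueError("membership vectors must be non-negative")
        if np.any(self.membership.sum(axis=1) == 0):
            raise ValueError("every seed needs at least one nonzero entry")

    @property
    def n_seeds(self) -> int:
        return self.membership.shape[0]

    @property
    def n_components(self) -> int:
        return self.n_seeds + 1

    @property
    def n_rois(self) -> int:
        return self.membership.shape[1]


@dataclass
class TensorComponents:
    """Fitted CP factors with names, subject boundaries and diagnostics.

    ``spatial_a`` / ``spatial_b`` are (n_rois, L); ``temporal`` is (T, L)
    over the concatenated time axis.  ``boundaries`` are the cumulative
    subject end offsets, the last equal to T.  ``diagnostics`` records
    iterations, the relative-error history, convergence, and each
    component's correlation with its own seed (drift).
    """

    spatial_a: np.ndarray
    spatial_b: np.ndarray
    temporal: np.ndarray
    names: list
    residual_index: int
    boundaries: list
    subject_ids: list
    dt: float
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        for arr, what in ((self.spatial_a, "spatial_a"), (self.spatial_b, "spatial_b"),
                          (self.temporal, "temporal")):
            if np.any(np.asarray(arr) < 0):
                raise ValueError(f"{what} contains negative entries")
        if self.spatial_a.shape != self.spatial_b.shape:
            raise ValueError("spatial factor shapes differ")
        if self.temporal.shape[1] != self.spatial_a.shape[1]:
            raise ValueError("component count mismatch between factors")
        if len(self.names) != self.spatial_a.shape[1]:
            raise ValueError("one name per component required")
        b = list(self.boundaries)
        if b != sorted(set(b)) or (b and b[-1] != self.temporal.shape[0]):
            raise ValueError("boundaries must be strictly increasing and end at T")

    @property
    def n_components(self) -> int:
        return self.spatial_a.shape[1]


@dataclass
class StateTimeline:
    """Winner component per time point for one subject, with run lengths."""

    subject_id: str
    winners: np.ndarray          # component index per time point
    runs: dict                    # component index -> list of run lengths (samples)
    names: list
    dt: float
    group: str | None = None

    def __post_init__(self):
        total = sum(length for lengths in self.runs.values() for length in lengths)
        if total != self.winners.size:
            raise ValueError("run lengths must sum to the subject's sample count")


@dataclass
class NonstationarityStat:
    """Excursions-from-median statistic for one loading series.

    ``excursions`` inventories each maximal run strictly above or below the
    median as ``(side, start, length, peak)`` with peak the maximum absolute
    deviation from the median inside the run.  The scalar statistic is
    sum(length**length_exp * peak**peak_exp) / T.
    """

    statistic: float
    excursions: list
    median: float
    n_samples: int
    length_exp: float = 1.0
    peak_exp: float = 1.0

    def __post_init__(self):
        if self.statistic < 0:
            raise ValueError("excursion statistic must be non-negative")


# ---------------------------------------------------------------------------
# concatenation


def concatenate_tensors(tensors: list) -> tuple[ConnectivityTensor, list, list]:
    """Concatenate per-subject tensors along time, recording boundaries.

    All subjects and groups are pooled so the factorization converges to a
    single shared set of states.  Returns ``(tensor, boundaries, subject_ids)``
    where boundaries are cumulative end offsets.
    """
    if not tensors:
        raise ValueError("no tensors to concatenate")
    labels = tensors[0].roi_labels
    for tensor in tensors[1:]:
        if tensor.roi_labels != labels:
            bad = next(
                (a for a, b in zip(tensor.roi_labels, labels) if a != b),
                tensor.roi_labels[min(len(labels), len(tensor.roi_labels)) - 1],
            )
            raise ValueError(f"region mismatch at '{bad}' for subject '{tensor.subject_id}'")
    frames = np.concatenate([t.frames for t in tensors], axis=2)
    boundaries = list(np.cumsum([t.n_frames for t in tensors]))
    merged = ConnectivityTensor(frames, tensors[0].dt, list(labels), subject_id="concatenated")
    return merged, boundaries, [t.subject_id for t in tensors]


# ---------------------------------------------------------------------------
# non-negative CP via HALS


def _tensor_sq_norm(x: np.ndarray) -> float:
    return float(np.einsum("ijk,ijk->", x, x))


def _model_diagonal(factors: list) -> np.ndarray:
    """(n, T) diagonal of the current CP model, sum_l a_il b_il c_tl."""
    a, b, c = factors
    return (a * b) @ c.T


def _mttkrp(x: np.ndarray, factors: list, mode: int) -> np.ndarray:
    """Matricized tensor times Khatri-Rao product for a 3-way tensor."""
    a, b, c = factors
    if mode == 0:
        return np.einsum("ijk,jl,kl->il", x, b, c, optimize=True)
    if mode == 1:
        return np.einsum("ijk,il,kl->jl", x, a, c, optimize=True)
    return np.einsum("ijk,il,jl->kl", x, a, b, optimize=True)


def _relative_error(x: np.ndarray, factors: list, denom_sq: float) -> float:
    """Relative residual ||X - M||_F / denom via Gram cross terms."""
    a, b, c = factors
    # <X, recon> = sum_l c_l . (X x1 a_l x2 b_l)
    inner = float((_mttkrp(x, factors, 2) * c).sum())
    gram = (a.T @ a) * (b.T @ b) * (c.T @ c)
    resid_sq = max(_tensor_sq_norm(x) - 2.0 * inner + float(gram.sum()), 0.0)
    return np.sqrt(resid_sq) / np.sqrt(denom_sq) if denom_sq > 0 else 0.0


def _hals_update(factor: np.ndarray, gram: np.ndarray, mttkrp: np.ndarray) -> None:
    """In-place HALS sweep over components for one factor matrix."""
    for l in range(factor.shape[1]):
        denom = gram[l, l]
        if denom <= 1e-15:
            continue
        update = factor[:, l] + (mttkrp[:, l] - factor @ gram[:, l]) / denom
        factor[:, l] = np.maximum(update, 0.0)


def nntf_decompose(tensor: ConnectivityTensor, seeds: SeedNetworks,
                   tol: float = DEFAULT_TOL, max_iter: int = DEFAULT_MAX_ITER,
                   seed: int = 0, boundaries: list | None = None,
                   subject_ids: list | None = None) -> TensorComponents:
    """Seeded non-negative CP decomposition of a connectivity tensor.

    Both spatial modes of each non-residual component start from the same
    seed membership vector (the states are connectivity patterns, reported
    symmetrized); the residual starts uniform at 1/N; temporal loadings
    start random non-negative under ``seed``.  HALS alternating updates run
    until the relative reconstruction error changes by less than ``tol`` or
    ``max_iter`` sweeps.  The error history is checked to be non-increasing.

    The frames' structurally-zero diagonal is not part of the data: those
    entries are treated as missing and imputed with the current model each
    sweep (an EM step, which keeps the observed-entry error monotone), so
    the reported relative error refers to the off-diagonal entries only.

    After fitting, components are renamed by maximal spatial correlation
    with the seed set (drift is reported in diagnostics, never suppressed).
    """
    if seeds.n_rois != tensor.n_rois:
        raise ValueError("seed vectors do not match tensor region count")
    x = tensor.frames
    if np.any(x < 0):
        raise ValueError("tensor must be non-negative")
    n, t = tensor.n_rois, tensor.n_frames
    L = seeds.n_components
    rng = np.random.default_rng(seed)

    init_spatial = np.zeros((n, L))
    init_spatial[:, : seeds.n_seeds] = seeds.membership.T
    init_spatial[:, -1] = 1.0 / n
    # normalize seed columns so components start on comparable scales
    init_spatial /= np.maximum(np.linalg.norm(init_spatial, axis=0), 1e-12)[None, :]
    a = init_spatial.copy()
    b = init_spatial.copy()
    c = rng.uniform(0.0, 1.0, size=(t, L))

    observed_sq = _tensor_sq_norm(x)  # diagonal of every frame is zero
    errors = []
    diag_idx = np.arange(n)
    if observed_sq == 0:
        c[:] = 0.0
        errors = [0.0]
        converged = True
        n_iter = 0
    else:
        x_work = x.copy()  # diagonal entries are imputed in place
        converged = False
        n_iter = 0
        prev = np.inf
        for n_iter in range(1, max_iter + 1):
            for mode, factor in ((2, c), (0, a), (1, b)):
                others = [f for m, f in ((0, a), (1, b), (2, c)) if m != mode]
                gram = (others[0].T @ others[0]) * (others[1].T @ others[1])
                _hals_update(factor, gram, _mttkrp(x_work, [a, b, c], mode))
            x_work[diag_idx, diag_idx, :] = _model_diagonal([a, b, c])
            err = _relative_error(x_work, [a, b, c], observed_sq)
            errors.append(err)
            if prev - err < -1e-9:
                raise AssertionError(
                    f"reconstruction error increased at iteration {n_iter}: {prev} -> {err}")
            if prev - err < tol:
                converged = True
                break
            prev = err
        if not converged:
            warnings.warn(f"NNTF did not converge within {max_iter} iterations "
                          f"(last error {errors[-1]:.3e})", RuntimeWarning)

    names, seed_corr = _assign_names(a, b, seeds)
    boundaries = list(boundaries) if boundaries is not None else [t]
    subject_ids = list(subject_ids) if subject_ids is not None else [tensor.subject_id]
    diagnostics = {
        "iterations": n_iter,
        "final_relative_error": errors[-1] if errors else 0.0,
        "error_history": errors,
        "converged": converged,
        "seed_correlation": seed_corr,
        "tol": tol,
        "seed": seed,
    }
    return TensorComponents(a, b, c, names, L - 1, boundaries, subject_ids,
                            tensor.dt, diagnostics)


def _assign_names(a: np.ndarray, b: np.ndarray, seeds: SeedNetworks):
    """Name fitted components by maximal spatial correlation with the seeds.

    The residual slot keeps its name; the remaining components are matched
    one-to-one to seed names by maximizing total correlation of the mean
    spatial factor with the membership vectors (Hungarian assignment).
    Returns ``(names, drift)`` where drift maps each assigned name to the
    correlation between the fitted factor and the seed it was named after.
    """
    mean_spatial = 0.5 * (a + b)
    n_seeds = seeds.n_seeds
    corr = np.zeros((n_seeds, n_seeds))
    for l in range(n_seeds):
        for m in range(n_seeds):
            fitted = mean_spatial[:, l]
            member = seeds.membership[m]
            if fitted.std() == 0 or member.std() == 0:
                corr[l, m] = 0.0
            else:
                corr[l, m] = np.corrcoef(fitted, member)[0, 1]
    rows, cols = linear_sum_assignment(-corr)
    names = [None] * (n_seeds + 1)
    drift = {}
    for l, m in zip(rows, cols):
        names[l] = seeds.names[m]
        drift[seeds.names[m]] = float(corr[l, m])
    names[-1] = seeds.residual_name
    return names, drift


# ---------------------------------------------------------------------------
# per-component statistics


def spatial_pattern(components: TensorComponents, l: int) -> np.ndarray:
    """Symmetrized connectivity pattern of component l: (a b^T + b a^T)/2."""
    if not 0 <= l < components.n_components:
        raise IndexError(f"component index {l} out of range")
    a = components.spatial_a[:, l]
    b = components.spatial_b[:, l]
    pattern = 0.5 * (np.outer(a, b) + np.outer(b, a))
    np.fill_diagonal(pattern, 0.0)
    return pattern


def split_loadings(components: TensorComponents) -> dict:
    """Per-subject temporal loadings c_l^ind keyed by subject id.

    Concatenating the outputs in subject order reproduces the pooled
    temporal factor exactly.
    """
    out = {}
    start = 0
    for sid, end in zip(components.subject_ids, components.boundaries):
        out[sid] = components.temporal[start:end, :]
        start = end
    return out


def state_timeline(loadings: np.ndarray, subject_id: str = "", names: list | None = None,
                   dt: float = 1.0, group: str | None = None) -> StateTimeline:
    """Winner-take-all state sequence from a subject's loading matrix (T, L).

    Ties resolve to the lowest component index (deterministic; a
    measure-zero event for continuous loadings).
    """
    arr = np.asarray(loadings, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 1:
        raise ValueError("loadings must be (T, L) with L >= 1")
    winners = np.argmax(arr, axis=1)
    if names is None:
        names = [f"component_{l}" for l in range(arr.shape[1])]
    runs = {l: [] for l in range(arr.shape[1])}
    for value, length in _run_length_encode(winners):
        runs[int(value)].append(int(length))
    return StateTimeline(subject_id, winners, runs, list(names), dt, group)


def _run_length_encode(values: np.ndarray):
    if values.size == 0:
        return
    change = np.nonzero(np.diff(values) != 0)[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [values.size]))
    for s, e in zip(starts, ends):
        yield values[s], e - s


def dwell_times(timeline: StateTimeline) -> dict:
    """Dwell statistics per component for one subject.

    For each component: run lengths in samples and seconds, the mean dwell
    (0 with ``never_wins=True`` when the component never takes the maximum),
    in both units.
    """
    out = {}
    for l, lengths in timeline.runs.items():
        seconds = [length * timeline.dt for length in lengths]
        never = len(lengths) == 0
        out[timeline.names[l]] = {
            "runs_samples": list(lengths),
            "runs_seconds": seconds,
            "mean_samples": float(np.mean(lengths)) if lengths else 0.0,
            "mean_seconds": float(np.mean(seconds)) if seconds else 0.0,
            "never_wins": never,
        }
    return out


def excursions_from_median(series, length_exp: float = 1.0,
                           peak_exp: float = 1.0) -> NonstationarityStat:
    """Nonstationarity of a loading series as excursions from its median.

    The median m is computed; maximal runs of samples strictly above or
    strictly below m are excursions (samples equal to m belong to none).
    Each excursion contributes length**length_exp * peak**peak_exp, with
    peak the maximum |series - m| inside the run; the statistic is the sum
    divided by the series length.  Zero for a constant series; invariant to
    adding a constant; scales linearly with the series for the default
    exponents.
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 3:
        raise ValueError("excursion statistic requires at least 3 samples")
    m = float(np.median(x))
    side = np.sign(x - m)  # +1 above, -1 below, 0 on the median
    inventory = []
    total = 0.0
    for value_len in _runs_of_sides(side):
        s, start, length = value_len
        if s == 0:
            continue
        peak = float(np.max(np.abs(x[start:start + length] - m)))
        inventory.append(("above" if s > 0 else "below", int(start), int(length), peak))
        total += (length ** length_exp) * (peak ** peak_exp)
    return NonstationarityStat(total / x.size, inventory, m, x.size, length_exp, peak_exp)


def _runs_of_sides(side: np.ndarray):
    start = 0
    for value, length in _run_length_encode(side):
        yield value, start, length
        start += length
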