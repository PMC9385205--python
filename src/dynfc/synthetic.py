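"""Synthetic cohorts with the statistical structure the analysis assumes.

Four generators make every downstream stage testable without any imaging
data:

* modular weighted connectomes (block-structured, connected, symmetric);
* oscillatory BOLD-like cohorts from Kuramoto phase oscillators coupled
  through the connectome, with per-group global coupling K — the healthy
  group sits near the synchronization transition (large synchrony
  fluctuations), the patient groups deeper in the locked regime, emulating
  the healthy-control / MCS / UWS contrast of dynamics progressively more
  fixed to the anatomical scaffold;
* connectivity tensors with planted non-negative spatial patterns and
  temporal loadings (ground truth for the tensor factorization);
* FC frame series with planted eigenmode expression coefficients (ground
  truth for the eigenmode mapping), built by inverting the prediction
  identity FC(t) = K^{1/2} (I - U P(t) U^T) K^{1/2} around the structural
  strength profile.

All generators are deterministic under their seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components

from .datatypes import ConnectivityTensor, RoiTimeSeries, StructuralConnectome
from .eigenmodes import EigenmodeBasis, eigenmode_basis, graph_laplacian
from .states import SeedNetworks

__all__ = [
    "SyntheticConnectomeSpec",
    "OscillatorCohortSpec",
    "PlantedTensorTruth",
    "PlantedExpressionSpec",
    "generate_structural_connectome",
    "simulate_oscillator_cohort",
    "generate_planted_tensor",
    "generate_eigenmode_fc_series",
    "default_seed_networks",
    "make_planted_truth",
    "DEFAULT_GROUP_COUPLINGS",
]

#: Per-group global coupling strengths for the three-group study design.
#: All three sit at or above the synchronization transition of the noisy
#: Kuramoto system for the default narrow frequency band: the healthy
#: group is closest to criticality (largest synchrony fluctuations), the
#: patient groups are pushed deeper into the locked regime, emulating
#: dynamics increasingly "fixed" to the anatomical scaffold.  Mean
#: metastability and dominant-mode modulation then order UWS < MCS < HC,
#: and both track each other across subjects within a group.
DEFAULT_GROUP_COUPLINGS = {"HC": 0.10, "MCS": 0.15, "UWS": 0.25}


@dataclass
class SyntheticConnectomeSpec:
    """Modular weighted connectome: block means plus truncated Gaussian noise."""

    n_rois: int
    n_modules: int
    intra_weight: float
    inter_weight: float
    weight_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_rois < 1 or self.n_modules < 1:
            raise ValueError("n_rois and n_modules must be positive")
        if self.n_modules > self.n_rois:
            raise ValueError("n_modules must not exceed n_rois")
        if not (self.intra_weight >= self.inter_weight >= 0):
            raise ValueError("require intra_weight >= inter_weight >= 0")
        if self.weight_noise_sd < 0:
            raise ValueError("weight_noise_sd must be non-negative")


def generate_structural_connectome(spec: SyntheticConnectomeSpec,
                                   max_retries: int = 20) -> StructuralConnectome:
    """Block-modular symmetric connectome, regenerated until connected.

    Regions are split into ``n_modules`` contiguous blocks; off-diagonal
    weights are drawn Normal(intra or inter mean, sd) truncated at zero and
    symmetrized.  If the positive-weight graph is disconnected the draw is
    repeated (fresh stream) up to ``max_retries`` times.
    """
    n = spec.n_rois
    module_of = np.repeat(np.arange(spec.n_modules),
                          np.diff(np.linspace(0, n, spec.n_modules + 1).astype(int)))
    means = np.where(module_of[:, None] == module_of[None, :],
                     spec.intra_weight, spec.inter_weight)
    rng = np.random.default_rng(spec.seed)
    labels = [f"roi_{i:03d}" for i in range(n)]
    for _ in range(max_retries):
        noise = rng.normal(0.0, spec.weight_noise_sd, size=(n, n)) if spec.weight_noise_sd else 0.0
        w = np.maximum(means + noise, 0.0)
        w = np.triu(w, k=1)
        w = w + w.T
        if n == 1 or connected_components((w > 0).astype(int), directed=False)[0] == 1:
            return StructuralConnectome(w, labels)
    raise RuntimeError(f"connectome disconnected after {max_retries} draws for spec {spec}")


@dataclass
class OscillatorCohortSpec:
    """Kuramoto cohort: groups differing only in global coupling strength.

    ``group_couplings`` maps group label to K; ``subjects_per_group`` gives
    the cohort size per group.  Natural frequencies are drawn uniformly in
    ``freq_band`` (Hz); phases evolve under Euler-Maruyama with dynamic
    noise of standard deviation ``noise_sd`` (rad/sqrt(s)); the observed
    BOLD-like signal is sin(phase) sampled every ``tr`` seconds after a
    burn-in of ``burn_in_periods`` slowest oscillation periods.
    """

    group_couplings: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_COUPLINGS))
    subjects_per_group: int = 10
    freq_band: tuple = (0.048, 0.052)
    noise_sd: float = 0.3
    tr: float = 2.0
    n_samples: int = 300
    seed: int = 0
    integration_dt: float = 0.2
    burn_in_periods: float = 10.0
    #: width of the uniform initial-phase distribution (radians); 0 starts
    #: every region at phase 0 (useful for the uncoupled-identical check)
    init_phase_spread: float = 2 * np.pi

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.init_phase_spread < 0:
            raise ValueError("init_phase_spread must be non-negative")
        if self.tr <= 0 or self.integration_dt <= 0:
            raise ValueError("time steps must be positive")
        if any(k < 0 for k in self.group_couplings.values()):
            raise ValueError("couplings must be non-negative")
        if not (0 < self.freq_band[0] <= self.freq_band[1]):
            raise ValueError("frequency band must be positive and ordered")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.subjects_per_group < 1:
            raise ValueError("subjects_per_group must be >= 1")


def simulate_oscillator_cohort(sc: StructuralConnectome,
                               spec: OscillatorCohortSpec) -> list:
    """Simulate one RoiTimeSeries per subject on the given connectome.

    Phase dynamics per region i:

        dphi_i = [omega_i + (K / <s>) sum_j W_ij sin(phi_j - phi_i)] dt
                 + noise_sd dW,

    with W the connectome weights and <s> the mean node strength (so K is
    comparable across connectomes).  Each subject gets an independent
    substream of the cohort seed.
    """
    n = sc.n_rois
    w = sc.weights
    mean_strength = w.sum(axis=1).mean()
    if mean_strength <= 0:
        raise ValueError("connectome has zero total weight")
    w_scaled = w / mean_strength

    dt = spec.integration_dt
    steps_per_sample = max(int(round(spec.tr / dt)), 1)
    burn_time = spec.burn_in_periods / spec.freq_band[0]
    burn_steps = int(np.ceil(burn_time / dt))
    root = np.random.SeedSequence(spec.seed)
    groups = sorted(spec.group_couplings)
    children = root.spawn(len(groups) * spec.subjects_per_group)

    cohort = []
    idx = 0
    for group in groups:
        coupling = spec.group_couplings[group]
        for s in range(spec.subjects_per_group):
            rng = np.random.default_rng(children[idx])
            idx += 1
            omega = 2 * np.pi * rng.uniform(*spec.freq_band, size=n)
            half = spec.init_phase_spread / 2.0
            phi = rng.uniform(-half, half, size=n) if half > 0 else np.zeros(n)
            noise_scale = spec.noise_sd * np.sqrt(dt)
            signal = np.empty((n, spec.n_samples))
            total_steps = burn_steps + spec.n_samples * steps_per_sample
            sample_at = burn_steps + steps_per_sample * np.arange(spec.n_samples)
            pointer = 0
            for step in range(total_steps + 1):
                if pointer < spec.n_samples and step == sample_at[pointer]:
                    signal[:, pointer] = np.sin(phi)
                    pointer += 1
                sin_phi = np.sin(phi)
                cos_phi = np.cos(phi)
                coupling_term = coupling * (cos_phi * (w_scaled @ sin_phi)
                                            - sin_phi * (w_scaled @ cos_phi))
                phi = phi + dt * (omega + coupling_term)
                if spec.noise_sd:
                    phi = phi + noise_scale * rng.standard_normal(n)
            if not np.all(np.isfinite(signal)):
                raise FloatingPointError(f"non-finite signal for subject {group}_{s:02d}")
            cohort.append(RoiTimeSeries(signal, spec.tr, list(sc.roi_labels),
                                        subject_id=f"{group}_{s:02d}", group=group))
    return cohort


@dataclass
class PlantedTensorTruth:
    """Ground truth for the tensor factorization closed loop.

    ``patterns`` is (L, n_rois) non-negative spatial vectors; ``loadings``
    is (L, T) non-negative temporal vectors; ``winner_timeline`` is the
    argmax of the loadings per time point (lowest index on ties).
    """

    patterns: np.ndarray
    loadings: np.ndarray
    noise_sd: float = 0.0
    winner_timeline: np.ndarray | None = None

    def __post_init__(self):
        self.patterns = np.asarray(self.patterns, dtype=float)
        self.loadings = np.asarray(self.loadings, dtype=float)
        if self.patterns.ndim != 2 or self.loadings.ndim != 2:
            raise ValueError("patterns and loadings must be 2-D")
        if self.patterns.shape[0] != self.loadings.shape[0]:
            raise ValueError("component count mismatch between patterns and loadings")
        if np.any(self.patterns < 0) or np.any(self.loadings < 0):
            raise ValueError("planted factors must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.winner_timeline is None:
            self.winner_timeline = np.argmax(self.loadings, axis=0)
        else:
            self.winner_timeline = np.asarray(self.winner_timeline, dtype=int)
            if self.winner_timeline.shape != (self.loadings.shape[1],):
                raise ValueError("winner timeline length must equal the time axis")


def generate_planted_tensor(truth: PlantedTensorTruth, dt: float = 2.0,
                            seed: int = 0) -> ConnectivityTensor:
    """Connectivity tensor with planted rank-one structure plus clipped noise.

    Frame t is sum_l c_l(t) * sym(a_l a_l^T) with zero diagonal; symmetric
    Gaussian noise of sd ``truth.noise_sd`` is added and the result is
    truncated into [0, 1] to preserve the tensor invariants (noise-free
    frames must already lie in [0, 1]).
    """
    L, n = truth.patterns.shape
    t = truth.loadings.shape[1]
    frames = np.zeros((n, n, t))
    for l in range(L):
        outer = np.outer(truth.patterns[l], truth.patterns[l])
        outer = 0.5 * (outer + outer.T)
        np.fill_diagonal(outer, 0.0)
        frames += outer[:, :, None] * truth.loadings[l][None, None, :]
    if frames.max() > 1 + 1e-9:
        raise ValueError(f"noise-free planted frames exceed 1 (max {frames.max():g}); "
                         "rescale the planted factors")
    if truth.noise_sd:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, truth.noise_sd, size=(n, n, t))
        noise = 0.5 * (noise + noise.transpose(1, 0, 2))
        frames = np.clip(frames + noise, 0.0, 1.0)
        idx = np.arange(n)
        frames[idx, idx, :] = 0.0
    labels = [f"roi_{i:03d}" for i in range(n)]
    return ConnectivityTensor(frames, dt, labels, subject_id="planted")


def make_planted_truth(n_rois: int, n_components: int = 2, n_samples: int = 60,
                       noise_sd: float = 0.0, pattern_scale: float = 0.9,
                       seed: int = 0) -> PlantedTensorTruth:
    """Convenience truth: orthogonal-support patterns with block loadings.

    Regions are split into ``n_components`` disjoint supports; loadings are
    contiguous blocks of activation (one component dominant at a time) with
    a small floor so every component is always weakly present.
    """
    rng = np.random.default_rng(seed)
    supports = np.array_split(np.arange(n_rois), n_components)
    patterns = np.zeros((n_components, n_rois))
    for l, sup in enumerate(supports):
        patterns[l, sup] = rng.uniform(0.6, 1.0, size=sup.size)
        patterns[l] *= np.sqrt(pattern_scale) / patterns[l].max()
    loadings = np.full((n_components, n_samples), 0.05)
    blocks = np.array_split(np.arange(n_samples), n_components)
    for l, blk in enumerate(blocks):
        loadings[l, blk] = 1.0
    return PlantedTensorTruth(patterns, loadings, noise_sd)


@dataclass
class PlantedExpressionSpec:
    """Planted eigenmode-coefficient dynamics for the FC-frame generator.

    Coefficients start from the structural eigenvalues; the modes listed in
    ``modulated_modes`` oscillate sinusoidally around them with relative
    amplitude ``amplitude`` and random phases/frequencies under ``seed``.
    The null mode (index 0) is never modulated, which keeps every frame's
    strength profile equal to the structural one.

    Frame validity (non-negative off-diagonals) bounds the amplitude from
    above: the perturbation must not exceed the connectome's smallest
    off-diagonal weight, so use a dense connectome (positive weight floor)
    and modest amplitudes; infeasible settings raise rather than clip.
    """

    n_samples: int = 60
    dt: float = 2.0
    modulated_modes: np.ndarray | None = None
    amplitude: float = 0.05
    seed: int = 0
    negativity_tol: float = 1e-8

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not 0 <= self.amplitude:
            raise ValueError("amplitude must be non-negative")
        if self.modulated_modes is not None:
            self.modulated_modes = np.asarray(self.modulated_modes, dtype=int)
            if np.any(self.modulated_modes == 0):
                raise ValueError("the null mode (index 0) cannot be modulated")


def generate_eigenmode_fc_series(sc: StructuralConnectome,
                                 spec: PlantedExpressionSpec):
    """FC frame series with planted eigenmode expression coefficients.

    The connectome is rescaled so entries fit [0, 1]; frames are built by
    inverting the eigenmode prediction around the structural strength
    profile K:

        FC(t) = K - K^{1/2} U P(t) U^T K^{1/2}
              = SC - K^{1/2} U (P(t) - Lambda) U^T K^{1/2}.

    Because the planted coefficients keep the null mode at 0, the
    perturbation is orthogonal to K^{1/2} 1 and every frame's row sums stay
    at the structural strengths (up to the zeroed diagonal).  Frames whose
    off-diagonal entries would go negative beyond ``negativity_tol`` raise
    with a diagnostic; tiny negatives within tolerance are clipped.

    Returns ``(tensor, planted_coefficients (n_rois, T), basis, sc_scaled)``.
    """
    scale = sc.weights.max()
    if scale <= 0:
        raise ValueError("connectome has no weight")
    w = sc.weights / (scale / 0.8)  # headroom below 1 for the perturbation
    sc_scaled = StructuralConnectome(w, list(sc.roi_labels))
    basis = eigenmode_basis(graph_laplacian(sc_scaled))
    n = sc_scaled.n_rois
    lam = basis.eigenvalues
    u = basis.eigenvectors
    k = sc_scaled.strengths()
    k_sqrt = np.sqrt(k)

    rng = np.random.default_rng(spec.seed)
    if spec.modulated_modes is None:
        modes = np.arange(1, max(2, n // 4))
    else:
        modes = spec.modulated_modes
    t_axis = np.arange(spec.n_samples) * spec.dt
    planted = np.tile(lam[:, None], (1, spec.n_samples))
    freqs = rng.uniform(0.01, 0.05, size=modes.size)
    phases = rng.uniform(0, 2 * np.pi, size=modes.size)
    for j, mode in enumerate(modes):
        wave = 1.0 + spec.amplitude * np.sin(2 * np.pi * freqs[j] * t_axis + phases[j])
        planted[mode, :] = lam[mode] * wave
    planted = np.maximum(planted, 0.0)
    planted[0, :] = 0.0

    frames = np.empty((n, n, spec.n_samples))
    off_mask = ~np.eye(n, dtype=bool)
    for ti in range(spec.n_samples):
        d = planted[:, ti] - lam
        pert = k_sqrt[:, None] * ((u * d[None, :]) @ u.T) * k_sqrt[None, :]
        frame = w - pert
        neg = frame[off_mask].min()
        if neg < -spec.negativity_tol:
            raise ValueError(
                f"frame {ti}: planted coefficients produce negative off-diagonal "
                f"mass {neg:g} beyond tolerance; reduce the modulation amplitude")
        frame = np.maximum(frame, 0.0)
        np.fill_diagonal(frame, 0.0)
        frames[:, :, ti] = 0.5 * (frame + frame.T)
    if frames.max() > 1:
        raise ValueError("planted frames exceed 1; reduce amplitude or rescale")
    tensor = ConnectivityTensor(frames, spec.dt, list(sc_scaled.roi_labels),
                                subject_id="planted_eigenmode")
    return tensor, planted, basis, sc_scaled


def default_seed_networks(n_rois: int) -> SeedNetworks:
    """Six canonical resting-state seed networks over a synthetic parcellation.

    Regions are split into six contiguous blocks standing in for the
    salience, frontoparietal, default mode, subcortical, sensorimotor and
    visual networks; the residual slot is added by the factorization.
    """
    names = ["salience", "FPN", "DMN", "subcortical", "sensorimotor", "visual"]
    if n_rois < len(names):
        raise ValueError(f"need at least {len(names)} regions")
    membership = np.zeros((len(names), n_rois))
    for l, block in enumerate(np.array_split(np.arange(n_rois), len(names))):
        membership[l, block] = 1.0
    return SeedNetworks(names, membership)
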