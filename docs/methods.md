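# Methods

This note documents the models, estimators, and numerical choices behind
`dynfc`, and what the synthetic generators do and do not emulate.

## Phase connectivity and metastability

Regional signals are band-pass filtered with a second-order Butterworth
applied forward and backward (`scipy.signal.sosfiltfilt`), i.e. zero-phase.
Default band edges are 0.01–0.09 Hz; at a repetition time of 2 s the
Nyquist frequency is 0.25 Hz, so any upper edge at or above Nyquist is a
configuration error and is rejected rather than clipped. The instantaneous
phase is the angle of the analytic signal (Hilbert transform), wrapped to
(−π, π]; 10 samples are trimmed from each end by default to suppress the
transform's edge artefacts (the trim length is configurable and trimming
only crops — interior phases are unchanged).

The Kuramoto order parameter R(t) is the modulus of the mean unit phasor
across regions; metastability is the *sample* standard deviation (ddof = 1)
of R(t) over time, hence bounded by 0.5 for a [0, 1] series.

Pairwise instantaneous connectivity is cos(Δφ_jk(t)) clipped at zero. The
cosine kernel keeps in-phase pairs at 1 and orthogonal phases at 0; the
clip enforces the non-negativity that both the tensor factorization and
the Laplacian/degree constructions downstream require. Antiphase
information is not discarded silently: the signed cosine is available as a
diagnostic (`signed_phase_cosine`). Frames carry a structurally zero
diagonal. Static FC is the plain Pearson matrix of the narrowband series;
structure–function coupling correlates the strictly upper triangles of
static FC and the connectome.

## Non-negative tensor factorization into network states

The concatenated tensor (all subjects, time axis pooled) is decomposed as
non-negative CP/PARAFAC with hierarchical alternating least squares
(HALS). Design choices:

- **Seeding.** Both spatial modes of each non-residual component are
  initialized with the same seed-network membership vector (normalized to
  unit norm); the residual starts uniform at 1/N; temporal loadings start
  uniform-random non-negative under the decomposition seed. Seeds are
  initial conditions only — the optimizer is free to reshape them, and
  after fitting each component is (re)named by maximal spatial correlation
  with the seed set (Hungarian assignment); the achieved correlation is
  reported as "drift" in the diagnostics and never suppressed.
- **Zero diagonal as missing data.** The frames' diagonal is structural
  (always zero), not signal, and a non-negative low-rank model cannot fit
  it. Diagonal entries are therefore treated as missing and imputed with
  the current model between sweeps (an EM step). This keeps the
  observed-entry relative error monotonically non-increasing — asserted on
  every run — and lets a noise-free planted tensor reach ~1e−6 relative
  error.
- **Stopping.** Relative-error change below 1e−6 or 500 sweeps; hitting
  the iteration cap records a warning in the diagnostics, not an error.
- **Tie-breaking.** The winner state per volume is the argmax of the
  loadings with ties resolved to the lowest component index — a
  deterministic rule for a measure-zero event.

Dwell times are run lengths of the winner sequence, reported both in
samples and seconds (the field is not consistent about the unit, so both
are emitted); a component that never wins gets an empty run list, a mean
of 0, and an explicit flag.

The nonstationarity statistic of a loading series is built from excursions
from the median: maximal runs strictly above or strictly below the median
(samples equal to the median belong to no excursion). Each excursion
contributes length^p · peak^q with peak the maximum absolute deviation
inside the run; the statistic is the sum divided by the series length.
The exponents default to p = q = 1 (configurable and recorded in output),
making the statistic invariant to additive shifts and homogeneous of
degree one under positive scaling.

## Eigenmode expression of time-resolved connectivity

The structural basis is the eigendecomposition of the symmetric-normalized
Laplacian Q_SC = K^{−1/2}(K − SC)K^{−1/2} (eigenvalues in [0, 2], the null
mode proportional to K^{1/2}·1). Eigenvector signs are fixed by making the
largest-magnitude entry positive: the quadratic-form coefficients are
sign-invariant, but the stored basis must be byte-reproducible.

Per frame, the weighting coefficients are P_i(t) = u_i^T Q_FC(t) u_i with
Q_FC(t) the frame's own normalized Laplacian; by construction
Σ_i P_i(t) = trace(Q_FC(t)), which is asserted as an invariant. A node
with zero strength in a sparse frame has no defined normalization; its
incident off-diagonal entries are floored at ε = 1e−9 and the event is
logged. The frame prediction uses the frame's own strength profile
(Eq. above); goodness-of-fit is the Pearson correlation of the strictly
upper triangles, with constant-triangle frames skipped and logged.

Modulation strength sums |P_i(t_k) − P_i(t_j)| over *all ordered*
time-point pairs and the chosen mode subset (the two-point series {0, 1}
yields a raw sum of 2). Both the raw double sum and a normalized form
(divided by T² × subset size) are emitted; group statistics default to the
normalized form so subjects with different trim lengths stay comparable.
The dominant set is the first half of the ascending spectrum (107 of 214);
for odd N the middle mode joins the dominant set so the split is disjoint.

## Surrogates

Circular time-shift surrogates rotate each region's series by an
independent uniform offset in {1, …, T−1} (zero is excluded so every
rotation is genuine; a shift common to all regions would preserve all
cross-correlations and make the null vacuous). Rotation is a permutation,
so per-region sample multisets and periodograms are preserved exactly
while cross-region phase relations are destroyed. Offsets and seeds are
recorded for exact replay. The default of 20 realizations is configurable.

## Group statistics

Mann–Whitney U counts pairs with x > y plus half-ties. For small samples
(min(n, m) ≤ 8, and at most 1e5 labelings) the two-sided p-value is exact,
from full enumeration of group labelings with the deviation-from-n·m/2
criterion (valid under ties); larger samples use the tie-corrected normal
approximation with continuity correction. FDR correction is
Benjamini–Hochberg step-up, applied jointly across the whole ledger; the
ledger layout is one row per metric × pairwise group contrast plus one per
eigenmode-family metric × group for the genuine-vs-surrogate contrasts —
(2·7 + 5)·3 + 3·3 = 66 rows for the full design. Surrogate contrasts are
unpaired for uniformity with the group contrasts. The
metastability–modulation relation within each group is reported as Pearson
(primary) and Spearman (companion) correlations.

## Synthetic study conditions

The generators define the conditions under which the pipeline is
validated; they emulate the *statistical structure* the analysis assumes,
not the biophysics of BOLD:

- **Connectomes** are block-modular with truncated-Gaussian weights,
  regenerated until connected. Dense variants (high inter-module floor)
  are used where the eigenmode frame generator needs headroom for its
  perturbations.
- **Cohorts** are Kuramoto phase oscillators on the connectome, integrated
  with Euler–Maruyama (dt = 0.2 s), natural frequencies uniform in a
  narrow 0.048–0.052 Hz band, dynamic noise 0.3 rad/√s, observed as
  sin(phase) sampled at TR = 2 s after a burn-in of 10 slowest periods.
  Kuramoto oscillators (rather than Hopf/Stuart–Landau) are the natural
  choice because the metastability proxy *is* the Kuramoto order
  parameter. Group couplings (HC 0.10, MCS 0.15, UWS 0.25) place the
  healthy group near the synchronization transition and the patient groups
  deeper in the locked regime. In that regime noise-driven desynchrony
  excursions simultaneously raise metastability and eigenmode-expression
  modulation, so the groups reproduce — by construction — the qualitative
  pattern of interest: metastability and dominant-mode modulation ordered
  UWS < MCS < HC, positive within-group association between the two, and
  dynamics of the most impaired group most "fixed" to the anatomical
  scaffold. Defaults were fixed once from a pilot scan of the coupling
  axis and are part of the study conditions, not tuning knobs.
- **Planted tensors** superpose rank-one symmetric patterns with block
  temporal loadings plus symmetric zero-truncated noise, clipped into
  [0, 1]; noise-free frames must already satisfy the tensor invariants or
  the generator rejects the truth object.
- **Planted eigenmode frames** invert the prediction identity around the
  structural strength profile: FC(t) = SC − K^{1/2} U (P(t) − Λ) U^T
  K^{1/2} with the null-mode coefficient pinned at 0, which keeps every
  frame's row sums exactly structural, so the closed loop is near-exact.
  Feasibility bounds the modulation amplitude (default 0.05 relative);
  amplitudes that would drive off-diagonal entries negative raise with a
  diagnostic rather than clipping.

What passing tests on these cohorts shows: the estimators recover planted
ground truth, the statistics match independent oracles, and the pipeline
reproduces the expected qualitative orderings under a controlled
generative model. What they do not show: anything about haemodynamics,
preprocessing artefacts, head motion, lesion effects, or the true
generative process of patient data — the oscillator model is a stand-in
with matched statistical structure, not a biophysical claim.

## Problem sizes and determinism

Tests and the acceptance script run on 20–50-region connectomes, cohorts
of 10–20 subjects per group, and 150-volume recordings — sizes chosen so
the full suite completes in minutes while every statistical check retains
its intended power (20 seeds/subjects wherever a distributional claim is
made). Every stochastic step is seeded: generators take explicit seeds,
per-subject streams are spawned from the cohort seed, and surrogate
offsets are recorded for replay; identical config + seed reproduces
byte-identical pipeline outputs.

## Known limitations

- The cosine-clip connectivity kernel discards antiphase structure by
  design; the signed kernel is exposed for diagnostics only.
- Non-negative CP is non-convex: convergence is to a local optimum, and
  recovery guarantees in the tests hold for the seeded initialization.
- The number of components is fixed by the seed set (no automatic rank
  selection), and sliding-window connectivity is deliberately absent.
- Frames whose nodes lose all strength after clipping are regularized by
  an ε floor, which slightly biases that frame's coefficients; events are
  logged.
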