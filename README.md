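# dynfc

Time-resolved functional connectivity analysis for resting-state cohorts:
phase-based dynamic connectivity and metastability, seeded non-negative
tensor factorization into network states, and structural-eigenmode
prediction of moment-to-moment connectivity — with nonparametric group
statistics, circular-shift surrogate nulls, and synthetic generators so
the whole pipeline runs and is testable without any imaging data.

The package is aimed at researchers studying how large-scale brain
dynamics reorganize in altered states of consciousness (e.g. comparing
healthy controls with minimally conscious and unresponsive-wakefulness
patients), but the machinery applies to any ROI-level time-series cohort
with a structural connectome.

## What it computes

**Phase connectivity and metastability.** Each region's narrowband BOLD
signal is mapped to its instantaneous phase φ_k(t) (Hilbert transform).
Global synchrony per volume is the Kuramoto order parameter

    R(t) = | (1/N) Σ_k exp(i φ_k(t)) |,

and its standard deviation over time is the metastability proxy. Pairwise
connectivity at time t is cos(φ_j(t) − φ_k(t)) clipped at zero, stacked
into a regions × regions × time connectivity tensor.

**Network states.** The tensors of all subjects are concatenated in time
and decomposed by non-negative CP factorization (HALS updates),

    FC ≈ Σ_l  a_l ⊗ b_l ⊗ c_l,

with the spatial factors seeded from six canonical resting-state networks
(salience, FPN, DMN, subcortical, sensorimotor, visual) plus a uniform
residual — seven components in total, free to reshape during fitting. Per
subject, the winner state per volume (argmax of c_l), dwell times (run
lengths of the winner), and excursions-from-median nonstationarity of each
loading series are derived.

**Structural eigenmodes.** From the structural connectome SC the
symmetric-normalized graph Laplacian Q_SC = K^{−1/2}(K − SC)K^{−1/2} is
diagonalized into eigenmodes U. Each connectivity frame is projected onto
this basis, P_i(t) = u_i^T Q_FC(t) u_i, predicted back as

    FC(t) ≈ K_FC(t) − K_FC^{1/2}(t) U P(t) U^T K_FC^{1/2}(t),

and scored by the Pearson correlation between predicted and empirical
frames. Fluctuation of the coefficients — the modulation strength
Δ_eigenmode = Σ_{t_k,t_j} |P(t_k) − P(t_j)| — is evaluated separately for
the dominant (first half of the spectrum, integrative) and non-dominant
(second half, segregated) modes.

**Statistics.** Every subject-level metric is compared between groups with
two-sided Mann–Whitney U tests; eigenmode-family metrics are additionally
compared genuine-vs-surrogate (circular time-shift surrogates) within each
group; all p-values are corrected jointly with Benjamini–Hochberg FDR.
With seven network states and three groups the design has exactly 66
tests.

## Worked example

```python
import dynfc as d

# modular connectome and a three-group cohort of coupled phase oscillators
sc = d.generate_structural_connectome(
    d.SyntheticConnectomeSpec(n_rois=50, n_modules=5, intra_weight=1.0,
                              inter_weight=0.3, weight_noise_sd=0.1, seed=7))
spec = d.OscillatorCohortSpec(subjects_per_group=5, n_samples=150, seed=11)
cohort = d.simulate_oscillator_cohort(sc, spec)

basis = d.eigenmode_basis(d.graph_laplacian(sc))
for ts in cohort[:1] + [cohort[5]] + [cohort[10]]:
    filtered = d.bandpass_filter(ts, 0.01, 0.09)
    phases = d.instantaneous_phase(filtered, edge_trim=10)
    tensor = d.phase_connectivity_tensor(phases)
    series = d.expression_series(tensor, basis)
    print(f"{ts.subject_id}: metastability={d.metastability(phases):.4f}  "
          f"eigenmode fit={series.mean_fit:.3f}  "
          f"delta_dominant={series.delta_dominant:.4f}")
```

prints

```
HC_00: metastability=0.1002  eigenmode fit=0.594  delta_dominant=0.0293
MCS_00: metastability=0.0605  eigenmode fit=0.679  delta_dominant=0.0138
UWS_00: metastability=0.0259  eigenmode fit=0.666  delta_dominant=0.0043
```

The three synthetic groups differ only in the global coupling of the phase
oscillators to the anatomical network: the healthy-control group sits near
the synchronization transition (large synchrony fluctuations → high
metastability and strongly modulated eigenmode expression), the patient
groups are locked progressively deeper into the anatomical scaffold (lower
metastability, near-constant eigenmode weighting).

A full cohort run — filtering through the test ledger — is available both
as a library call (`dynfc.analyze_cohort` / `dynfc.run_pipeline`) and as a
CLI:

```sh
dynfc simulate --n-rois 50 --subjects-per-group 10 --out cohort/
dynfc run-all --config pipeline.yaml
```

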