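"""End-to-end orchestration: cohort in, metric table and test ledger out.

Stages: band-pass filter -> instantaneous phase -> phase-connectivity
tensor per subject -> concatenated non-negative tensor factorization ->
state timelines / dwell times / excursion statistics; in parallel the
structural Laplacian eigenmode basis -> per-frame expression, fit and
modulation strengths; circular-shift surrogates feed the null rows; all
subject-level metrics are pooled into a long-format table and compared with
the Mann-Whitney + FDR ledger.

Identical config + seed yields byte-identical outputs (fixed float
formatting, seeded RNG substreams per stage).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import RoiTimeSeries, StructuralConnectome
from . import io as _io
from .eigenmodes import eigenmode_basis, expression_series, graph_laplacian, dominant_indices
from .phase import (
    DEFAULT_BAND,
    DEFAULT_EDGE_TRIM,
    bandpass_filter,
    instantaneous_phase,
    metastability,
    phase_connectivity_tensor,
    static_fc,
    static_structure_function_coupling,
)
from .states import (
    SeedNetworks,
    concatenate_tensors,
    dwell_times,
    excursions_from_median,
    nntf_decompose,
    split_loadings,
    state_timeline,
)
from .stats import build_test_ledger, metastability_modulation_correlation
from .surrogates import SurrogateSpec, circular_shift_surrogate

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "analyze_cohort"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and subject id."""

    def __init__(self, stage: str, subject: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed for subject '{subject}': {cause}")
        self.stage = stage
        self.subject = subject
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, loadable from YAML.

    ``time_series_dir`` holds one delimited file per subject named
    ``<subject>.tsv``; ``group_table`` is a CSV with columns
    ``subject,group``; ``sc_path`` the structural connectome;
    ``seeds_path`` a labelled matrix of seed-network membership rows.
    """

    time_series_dir: str = ""
    group_table: str = ""
    sc_path: str = ""
    seeds_path: str = ""
    output_dir: str = "dynfc_output"
    tr: float = 2.0
    band: tuple = DEFAULT_BAND
    edge_trim: int = DEFAULT_EDGE_TRIM
    nntf_tol: float = 1e-6
    nntf_max_iter: int = 500
    excursion_length_exp: float = 1.0
    excursion_peak_exp: float = 1.0
    n_surrogates: int = 1
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if isinstance(cfg.band, list):
            cfg.band = tuple(cfg.band)
        return cfg

    def validate(self) -> None:
        for name in ("time_series_dir", "group_table", "sc_path", "seeds_path"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"config path '{name}' missing or does not exist: {p!r}")
        nyq = 0.5 / self.tr
        if not (0 < self.band[0] < self.band[1] < nyq):
            raise ValueError(f"band {self.band} invalid for tr={self.tr} (Nyquist {nyq} Hz)")

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_cohort(config: PipelineConfig) -> list:
    groups = pd.read_csv(config.group_table)
    if not {"subject", "group"} <= set(groups.columns):
        raise ValueError("group table needs 'subject' and 'group' columns")
    cohort = []
    for _, row in groups.iterrows():
        path = Path(config.time_series_dir) / f"{row['subject']}.tsv"
        if not path.exists():
            raise FileNotFoundError(f"time series for subject '{row['subject']}' not at {path}")
        cohort.append(_io.read_time_series(path, config.tr, subject_id=str(row["subject"]),
                                           group=str(row["group"])))
    return cohort


def _load_seeds(path) -> SeedNetworks:
    labels, values = _io.read_matrix(path)
    # file layout: header = seed names in column 1..; rows = one per seed?
    # convention here: header row = ROI labels; each body row = one seed,
    # with a companion names file <path>.names listing one name per row
    names_path = Path(str(path) + ".names")
    if names_path.exists():
        names = [line.strip() for line in open(names_path) if line.strip()]
    else:
        names = [f"seed_{i}" for i in range(values.shape[0])]
    return SeedNetworks(names, values)


def analyze_cohort(cohort: list, sc: StructuralConnectome, seeds: SeedNetworks,
                   config: PipelineConfig) -> dict:
    """Run every analysis stage in memory; returns all intermediate results.

    This is the library entry point the CLI wraps; ``cohort`` is a list of
    RoiTimeSeries with group labels.
    """
    results: dict = {"subjects": [ts.subject_id for ts in cohort]}
    tensors = []
    metric_rows = []

    basis = eigenmode_basis(graph_laplacian(sc))
    results["basis"] = basis
    results["n_dominant"] = dominant_indices(basis.n_modes).size

    phase_series = {}
    for ts in cohort:
        try:
            filtered = bandpass_filter(ts, *config.band)
            ph = instantaneous_phase(filtered, config.edge_trim)
            phase_series[ts.subject_id] = ph
            tensors.append(phase_connectivity_tensor(ph))
            meta = metastability(ph)
            fc = static_fc(filtered)
            coupling = static_structure_function_coupling(fc, sc)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError("phase_dynamics", ts.subject_id, exc) from exc
        metric_rows += [
            {"subject": ts.subject_id, "group": ts.group, "metric": "metastability",
             "value": meta, "is_surrogate": False},
            {"subject": ts.subject_id, "group": ts.group, "metric": "corr_fcstatic_sc",
             "value": coupling, "is_surrogate": False},
        ]

    try:
        merged, boundaries, subject_ids = concatenate_tensors(tensors)
        components = nntf_decompose(merged, seeds, tol=config.nntf_tol,
                                    max_iter=config.nntf_max_iter, seed=config.seed,
                                    boundaries=boundaries, subject_ids=subject_ids)
    except Exception as exc:
        raise StageError("network_states", "cohort", exc) from exc
    results["components"] = components

    group_of = {ts.subject_id: ts.group for ts in cohort}
    loadings = split_loadings(components)
    timelines = {}
    for sid, load in loadings.items():
        timeline = state_timeline(load, sid, components.names, components.dt, group_of[sid])
        timelines[sid] = timeline
        dwell = dwell_times(timeline)
        for l, name in enumerate(components.names):
            stat = excursions_from_median(load[:, l], config.excursion_length_exp,
                                          config.excursion_peak_exp)
            metric_rows += [
                {"subject": sid, "group": group_of[sid], "metric": f"excursion_{name}",
                 "value": stat.statistic, "is_surrogate": False},
                {"subject": sid, "group": group_of[sid], "metric": f"dwell_{name}",
                 "value": dwell[name]["mean_seconds"], "is_surrogate": False},
            ]
    results["timelines"] = timelines

    expressions = {}
    for tensor in tensors:
        try:
            series = expression_series(tensor, basis)
        except Exception as exc:
            raise StageError("eigenmodes", tensor.subject_id, exc) from exc
        expressions[tensor.subject_id] = series
        metric_rows += [
            {"subject": tensor.subject_id, "group": tensor.group,
             "metric": "corr_fc_eigenmodes", "value": series.mean_fit, "is_surrogate": False},
            {"subject": tensor.subject_id, "group": tensor.group,
             "metric": "delta_dominant", "value": series.delta_dominant, "is_surrogate": False},
            {"subject": tensor.subject_id, "group": tensor.group,
             "metric": "delta_non_dominant", "value": series.delta_non_dominant,
             "is_surrogate": False},
        ]
    results["expressions"] = expressions

    surrogate_manifest = {}
    for ts in cohort:
        try:
            spec = SurrogateSpec(config.n_surrogates,
                                 seed=_derive_seed(config.seed, ts.subject_id))
            surr_set = circular_shift_surrogate(ts, spec)
            surrogate_manifest[ts.subject_id] = {"seed": spec.seed,
                                                 "offsets": surr_set.offsets.tolist()}
            for surr in surr_set.series:
                filtered = bandpass_filter(surr, *config.band)
                ph = instantaneous_phase(filtered, config.edge_trim)
                tensor = phase_connectivity_tensor(ph)
                series = expression_series(tensor, basis)
                metric_rows += [
                    {"subject": surr.subject_id, "group": surr.group,
                     "metric": "corr_fc_eigenmodes", "value": series.mean_fit,
                     "is_surrogate": True},
                    {"subject": surr.subject_id, "group": surr.group,
                     "metric": "delta_dominant", "value": series.delta_dominant,
                     "is_surrogate": True},
                    {"subject": surr.subject_id, "group": surr.group,
                     "metric": "delta_non_dominant", "value": series.delta_non_dominant,
                     "is_surrogate": True},
                ]
        except Exception as exc:
            raise StageError("surrogates", ts.subject_id, exc) from exc
    results["surrogate_manifest"] = surrogate_manifest

    table = pd.DataFrame(metric_rows)
    results["metric_table"] = table
    try:
        ledger = build_test_ledger(table, alpha=config.alpha)
    except Exception as exc:
        raise StageError("group_stats", "cohort", exc) from exc
    results["ledger"] = ledger
    correlations = []
    for group in sorted({ts.group for ts in cohort if ts.group}):
        try:
            correlations.append(metastability_modulation_correlation(table, group))
        except ValueError:
            logger.warning("skipping metastability-modulation correlation for group %s", group)
    results["correlations"] = pd.DataFrame(correlations)
    return results


def _derive_seed(base: int, token: str) -> int:
    digest = hashlib.sha256(f"{base}:{token}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def run_pipeline(config: PipelineConfig) -> Path:
    """Validate, execute and persist the full pipeline; returns the output dir."""
    t0 = time.time()
    config.validate()
    cohort = _load_cohort(config)
    sc = _io.read_connectome(config.sc_path)
    seeds = _load_seeds(config.seeds_path)
    results = analyze_cohort(cohort, sc, seeds, config)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results["metric_table"].to_csv(out / "metric_table.csv", index=False,
                                   float_format="%.12g")
    results["ledger"].to_csv(out / "test_ledger.csv", index=False, float_format="%.12g")
    if len(results["correlations"]):
        results["correlations"].to_csv(out / "metastability_modulation.csv", index=False,
                                       float_format="%.12g")
    components = results["components"]
    from .states import spatial_pattern
    for l, name in enumerate(components.names):
        _io.write_matrix(out / f"pattern_{name}.tsv", cohort[0].roi_labels,
                         spatial_pattern(components, l))
    loadings = split_loadings(components)
    loading_frames = []
    for sid, load in loadings.items():
        df = pd.DataFrame(load, columns=components.names)
        df.insert(0, "subject", sid)
        loading_frames.append(df)
    pd.concat(loading_frames, ignore_index=True).to_csv(out / "temporal_loadings.csv",
                                                        index=False, float_format="%.12g")
    _io.write_matrix(out / "eigenmode_basis.tsv", cohort[0].roi_labels,
                     results["basis"].eigenvectors)
    _io.write_matrix(out / "eigenvalues.tsv", ["eigenvalue"],
                     results["basis"].eigenvalues[:, None])
    _io.write_manifest(out / "provenance.json", {
        "config": asdict(config),
        "config_hash": config.content_hash(),
        "package_version": __version__,
        "n_subjects": len(cohort),
        "elapsed_seconds": round(time.time() - t0, 3),
        "nntf_diagnostics": {k: v for k, v in components.diagnostics.items()
                             if k != "error_history"},
        "surrogates": results["surrogate_manifest"],
    })
    logger.info("pipeline finished in %.1f s -> %s", time.time() - t0, out)
    return out
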