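"""Delimited-text readers/writers and the tensor container format.

Matrices travel as delimited text with a header row of region labels;
connectivity tensors are stored as compressed ``.npz`` arrays with a JSON
sidecar carrying dt, labels and provenance.  All readers fail loudly with
the offending line number.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ConnectivityTensor, RoiTimeSeries, StructuralConnectome

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_time_series",
    "write_time_series",
    "read_connectome",
    "write_connectome",
    "save_tensor",
    "load_tensor",
    "write_manifest",
]


def _detect_sep(header: str) -> str:
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    return None  # whitespace


def read_matrix(path) -> tuple[list, np.ndarray]:
    """Read a labelled matrix: header row of labels, numeric body.

    Accepts tab-, comma- or whitespace-delimited text.  Ragged rows,
    non-numeric cells and duplicate labels are rejected with the line
    number (1-based).
    """
    path = Path(path)
    with open(path) as fh:
        lines = [line.rstrip("\n") for line in fh if line.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    sep = _detect_sep(lines[0])
    labels = [cell.strip() for cell in (lines[0].split(sep) if sep else lines[0].split())]
    if len(set(labels)) != len(labels):
        raise ValueError(f"{path}:1: duplicate labels in header")
    n_cols = len(labels)
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split(sep) if sep else line.split()
        if len(cells) != n_cols:
            raise ValueError(f"{path}:{lineno}: expected {n_cols} cells, got {len(cells)}")
        try:
            rows.append([float(cell) for cell in cells])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    return labels, np.asarray(rows, dtype=float)


def write_matrix(path, labels, values, sep: str = "\t", fmt: str = "%.12g") -> None:
    """Write a labelled matrix as delimited text (header row of labels)."""
    values = np.asarray(values, dtype=float)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(sep.join(labels) + "\n")
        for row in np.atleast_2d(values):
            fh.write(sep.join(fmt % v for v in row) + "\n")


def read_time_series(path, dt: float, subject_id: str = "",
                     group: str | None = None) -> RoiTimeSeries:
    """Read a region x time matrix (regions as columns in the file).

    The header row names the regions; each subsequent row is one volume.
    """
    labels, values = read_matrix(path)
    return RoiTimeSeries(values.T, dt, labels, subject_id=subject_id, group=group)


def write_time_series(path, ts: RoiTimeSeries) -> None:
    write_matrix(path, ts.roi_labels, ts.values.T)


def read_connectome(path) -> StructuralConnectome:
    labels, values = read_matrix(path)
    if values.shape != (len(labels), len(labels)):
        raise ValueError(f"{path}: connectome body must be square with one row per label")
    return StructuralConnectome(values, labels)


def write_connectome(path, sc: StructuralConnectome) -> None:
    write_matrix(path, sc.roi_labels, sc.weights)


def save_tensor(path, tensor: ConnectivityTensor, provenance: dict | None = None) -> None:
    """Store a tensor as compressed npz plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, frames=tensor.frames)
    sidecar = {
        "dt": tensor.dt,
        "roi_labels": list(tensor.roi_labels),
        "subject_id": tensor.subject_id,
        "group": tensor.group,
        "provenance": provenance or {},
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_tensor(path) -> ConnectivityTensor:
    path = Path(path)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
        frames = data["frames"]
    with open(path.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    return ConnectivityTensor(frames, sidecar["dt"], sidecar["roi_labels"],
                              subject_id=sidecar.get("subject_id", ""),
                              group=sidecar.get("group"))


def write_seed_networks(path, seeds) -> None:
    """Write seed membership vectors: labelled matrix + ``.names`` sidecar."""
    labels = [f"roi_{i:03d}" for i in range(seeds.n_rois)]
    write_matrix(path, labels, seeds.membership)
    with open(str(path) + ".names", "w") as fh:
        fh.write("\n".join(seeds.names) + "\n")


def write_manifest(path, payload: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
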