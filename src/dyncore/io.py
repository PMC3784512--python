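"""Text-based file formats: TSV matrices with JSON sidecars/manifests.

All writers produce diff-able plain text; writers and readers round-trip to
full float precision (repr-level formatting).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataFormatError
from .netbuild import AdjacencyTensor, TimeSeriesSet

__all__ = [
    "write_timeseries",
    "read_timeseries",
    "write_tensor",
    "read_tensor",
    "write_partition",
    "read_partition",
    "write_json",
    "read_json",
]

def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    p = Path(path)
    if not p.exists():
        raise DataFormatError(f"missing file: {p}")
    try:
        return json.loads(p.read_text())
    except json.JSONDecodeError as exc:
        raise DataFormatError(f"{p}: invalid JSON ({exc})") from exc


def write_timeseries(ts: TimeSeriesSet, prefix: str | Path) -> tuple[Path, Path]:
    """Write a TimeSeriesSet as ``<prefix>.tsv`` (rows = regions, header row
    of sample indices, first column region labels) plus ``<prefix>.json``."""
    prefix = Path(prefix)
    tsv = prefix.with_suffix(".tsv")
    sidecar = prefix.with_suffix(".json")
    df = pd.DataFrame(ts.values, index=ts.region_labels,
                      columns=[str(i) for i in range(ts.n_samples)])
    df.to_csv(tsv, sep="\t", index_label="region")
    meta = {
        "sampling_interval_s": ts.sampling_interval,
        "blocks": [{"start": int(s), "end": int(e)} for s, e in ts.blocks],
    }
    if ts.block_types is not None:
        meta["block_types"] = list(ts.block_types)
    write_json(meta, sidecar)
    return tsv, sidecar


def read_timeseries(prefix: str | Path) -> TimeSeriesSet:
    prefix = Path(prefix)
    tsv = prefix.with_suffix(".tsv")
    sidecar = prefix.with_suffix(".json")
    if not tsv.exists():
        raise DataFormatError(f"missing file: {tsv}")
    df = pd.read_csv(tsv, sep="\t", index_col=0, float_precision="round_trip")
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        row, col = np.argwhere(np.isnan(values))[0]
        raise DataFormatError(f"{tsv}: NaN cell at row {df.index[row]!r}, column {col}")
    meta = read_json(sidecar)
    blocks = [(b["start"], b["end"]) for b in meta["blocks"]]
    return TimeSeriesSet(
        values=values,
        region_labels=[str(x) for x in df.index],
        sampling_interval=float(meta["sampling_interval_s"]),
        blocks=blocks,
        block_types=meta.get("block_types"),
    )


def write_tensor(tensor: AdjacencyTensor, directory: str | Path) -> Path:
    """Write per-layer square TSV matrices plus ``manifest.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    layer_files = []
    for l in range(tensor.n_layers):
        name = f"layer_{l + 1:03d}.tsv"
        df = pd.DataFrame(tensor.weights[:, :, l], index=tensor.region_labels,
                          columns=tensor.region_labels)
        df.to_csv(directory / name, sep="\t", index_label="region")
        layer_files.append(name)
    manifest = {
        "region_labels": list(tensor.region_labels),
        "layers": layer_files,
        "layer_meta": list(tensor.layer_meta),
        "meta": tensor.meta,
    }
    write_json(manifest, directory / "manifest.json")
    return directory


def read_tensor(directory: str | Path) -> AdjacencyTensor:
    directory = Path(directory)
    manifest = read_json(directory / "manifest.json")
    labels = manifest["region_labels"]
    layers = []
    for name in manifest["layers"]:
        path = directory / name
        if not path.exists():
            raise DataFormatError(f"manifest lists missing layer file: {path}")
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        mat = df.to_numpy(dtype=float)
        if mat.shape[0] != mat.shape[1]:
            raise DataFormatError(f"{path}: matrix is not square ({mat.shape})")
        if np.isnan(mat).any():
            i, j = np.argwhere(np.isnan(mat))[0]
            raise DataFormatError(f"{path}: NaN cell at ({labels[i]}, {labels[j]})")
        asym = np.abs(mat - mat.T)
        if asym.max() > 1e-9:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise DataFormatError(
                f"{path}: asymmetric entry at ({labels[i]}, {labels[j]}): "
                f"{mat[i, j]!r} vs {mat[j, i]!r}"
            )
        layers.append(mat)
    return AdjacencyTensor(
        weights=np.stack(layers, axis=2),
        region_labels=[str(x) for x in labels],
        layer_meta=list(manifest.get("layer_meta", [])),
        meta=manifest.get("meta", {}),
    )


def write_partition(labels: np.ndarray, region_labels: list[str], path: str | Path) -> Path:
    """Partition TSV: rows = regions, columns = layers, integer labels."""
    path = Path(path)
    df = pd.DataFrame(labels, index=region_labels,
                      columns=[f"layer_{l + 1:03d}" for l in range(labels.shape[1])])
    df.to_csv(path, sep="\t", index_label="region")
    return path


def read_partition(path: str | Path) -> tuple[np.ndarray, list[str]]:
    path = Path(path)
    if not path.exists():
        raise DataFormatError(f"missing file: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        raise DataFormatError(f"{path}: partition labels must be integers")
    return arr, [str(x) for x in df.index]
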