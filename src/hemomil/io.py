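"""Readers/writers for on-disk artifacts.

Tables (manifest, predictions, sweep) are CSV with documented, named
columns — probability columns are named by coarse class, never indexed,
so a class-order mismatch cannot pass silently through a file boundary.
Bags are stored in a single ``.npz`` container keyed by patient id (rows
= cells, columns = embedding dimensions); reports are JSON.  Every
writer can attach a provenance record (config hash, seeds, package
version).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hierarchy import LabelHierarchy
from .simulate import CellBag

__all__ = [
    "write_manifest",
    "read_manifest",
    "write_bags",
    "read_bags",
    "write_predictions",
    "read_predictions",
    "write_json_report",
    "provenance_record",
]

_MANIFEST_REQUIRED = ("patient_id", "coarse_class", "hemoglobin")


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _MANIFEST_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing required columns {missing}")
    return df


def write_bags(bags: Sequence[CellBag], path: str | Path) -> None:
    """All bags in one compressed container keyed by patient id."""
    arrays: dict[str, np.ndarray] = {}
    for bag in bags:
        arrays[f"emb_{bag.patient_id}"] = bag.embeddings
        if bag.cell_types is not None:
            arrays[f"types_{bag.patient_id}"] = np.asarray(bag.cell_types, dtype=str)
    np.savez_compressed(path, **arrays)


def read_bags(path: str | Path) -> list[CellBag]:
    bags = []
    with np.load(path, allow_pickle=False) as npz:
        pids = sorted(k[len("emb_"):] for k in npz.files if k.startswith("emb_"))
        for pid in pids:
            types_key = f"types_{pid}"
            bags.append(
                CellBag(
                    patient_id=pid,
                    embeddings=npz[f"emb_{pid}"],
                    cell_types=npz[types_key] if types_key in npz.files else None,
                )
            )
    return bags


def write_predictions(predictions: pd.DataFrame, path: str | Path) -> None:
    predictions.to_csv(path, index=False)


def read_predictions(path: str | Path, h: LabelHierarchy) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    required = ["patient_id"] + [f"p_{c}" for c in h.coarse_classes]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"predictions table {path} missing columns {missing}")
    return df


def write_json_report(report: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=1, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def provenance_record(config: Mapping, seeds: Mapping[str, int]) -> dict:
    """Reproducibility stamp attached to every CLI artifact."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "package_version": __version__,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seeds": dict(seeds),
    }
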