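"""File I/O: NIfTI volumes with echo-time sidecars, voxel tables as TSV."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .orientation import VOXEL_TABLE_COLUMNS, validate_voxel_table


def save_nifti(data: np.ndarray, path, affine: np.ndarray | None = None) -> Path:
    path = Path(path)
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    nib.save(img, str(path))
    return path


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine


def save_echo_volume(values: np.ndarray, echo_TEs, path, affine=None) -> Path:
    """4-D echo-train volume (echoes on the last axis) with a BIDS-style
    sidecar JSON carrying the echo times in seconds."""
    path = save_nifti(values, path, affine)
    sidecar = path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" else path.with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump({"EchoTime": [te / 1000.0 for te in np.asarray(echo_TEs, float)]}, fh, indent=2)
    return path


def load_echo_volume(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Returns (values, echo_TEs_ms, affine)."""
    data, affine = load_nifti(path)
    path = Path(path)
    sidecar = path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" else path.with_suffix(".json")
    with open(sidecar) as fh:
        tes_s = json.load(fh)["EchoTime"]
    return data, np.asarray(tes_s, dtype=float) * 1000.0, affine


def save_voxel_table(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    validate_voxel_table(table)
    table.to_csv(path, sep="\t", index=False)
    return path


def load_voxel_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in VOXEL_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"voxel table at {path} missing columns: {missing}")
    return validate_voxel_table(table)
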