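"""File I/O: NIfTI volumes and label maps, JSON sidecars, CSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .acquisition import AcquisitionGrid

__all__ = [
    "save_volume", "load_volume", "save_labels", "load_labels",
    "save_grid_sidecar", "load_grid_sidecar", "save_table", "load_table",
    "save_json", "load_json",
]


def _affine(grid: AcquisitionGrid) -> np.ndarray:
    dx, dy, dz = grid.voxel_size_mm
    return np.diag([dx, dy, dz, 1.0])


def save_volume(path, volume5d: np.ndarray, grid: AcquisitionGrid) -> None:
    """Write a (x, y, z, n_te, n_b) signal volume as NIfTI.

    The two grid axes are serialized as one trailing dimension in row-major
    (te, b) order; the sidecar (``save_grid_sidecar``) records the grid
    needed to refold it.
    """
    volume5d = np.asarray(volume5d)
    x, y, z, n_te, n_b = volume5d.shape
    img = nib.Nifti1Image(volume5d.reshape(x, y, z, n_te * n_b).astype(np.float32),
                          _affine(grid))
    nib.save(img, str(path))


def load_volume(path, grid: AcquisitionGrid) -> np.ndarray:
    vol = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    n_te, n_b = grid.shape
    if vol.shape[-1] != n_te * n_b:
        raise ValueError(f"volume at {path} has {vol.shape[-1]} frames; grid "
                         f"expects {n_te * n_b}")
    return vol.reshape(vol.shape[:3] + (n_te, n_b))


def save_labels(path, labels: np.ndarray, grid: AcquisitionGrid) -> None:
    img = nib.Nifti1Image(np.asarray(labels).astype(np.int16), _affine(grid))
    nib.save(img, str(path))


def load_labels(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj).astype(np.int16)


def save_grid_sidecar(path, grid: AcquisitionGrid, extra: dict | None = None) -> None:
    payload = grid.to_dict()
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2))


def load_grid_sidecar(path) -> AcquisitionGrid:
    return AcquisitionGrid.from_dict(json.loads(Path(path).read_text()))


def save_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def load_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_json(path) -> dict:
    return json.loads(Path(path).read_text())
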