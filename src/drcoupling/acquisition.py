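"""Acquisition grid and gridded signal containers.

The acquisition is a full factorial (TE, b) grid with a per-cell number of
excitations (NEX): each stored image is the average of NEX repeated magnitude
acquisitions, so its noise SD is the single-shot SD divided by sqrt(NEX).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AcquisitionGrid", "SignalArray", "default_grid"]


@dataclass(frozen=True)
class AcquisitionGrid:
    """The (TE, b, NEX) sampling scheme plus scan geometry.

    ``nex[i, j]`` is the number of excitations for echo time ``tes[i]`` and
    diffusion weighting ``bvals[j]``.  Geometry fields describe the image
    matrix the grid is acquired on.
    """

    tes: tuple  # ms, strictly increasing
    bvals: tuple  # s/mm^2, strictly increasing, first is 0
    nex: tuple  # tuple of rows, shape (len(tes), len(bvals)), ints >= 1
    matrix_shape: tuple = (128, 128)
    n_slices: int = 20
    fov_mm: tuple = (192.0, 192.0)
    slice_thickness_mm: float = 4.0

    def __post_init__(self) -> None:
        tes = np.asarray(self.tes, dtype=float)
        bvals = np.asarray(self.bvals, dtype=float)
        nex = np.asarray(self.nex)
        if tes.size < 2 or np.any(np.diff(tes) <= 0):
            raise ValueError("tes must be strictly increasing with >= 2 entries")
        if bvals.size < 2 or np.any(np.diff(bvals) <= 0):
            raise ValueError("bvals must be strictly increasing with >= 2 entries")
        if bvals[0] != 0:
            raise ValueError("bvals[0] must be 0 (non-diffusion-weighted reference)")
        if nex.shape != (tes.size, bvals.size):
            raise ValueError(f"nex table shape {nex.shape} does not match "
                             f"({tes.size}, {bvals.size})")
        if np.any(nex < 1) or not np.issubdtype(nex.dtype, np.integer):
            raise ValueError("all nex entries must be integers >= 1")

    @property
    def te_array(self) -> np.ndarray:
        return np.asarray(self.tes, dtype=float)

    @property
    def b_array(self) -> np.ndarray:
        return np.asarray(self.bvals, dtype=float)

    @property
    def nex_array(self) -> np.ndarray:
        return np.asarray(self.nex, dtype=int)

    @property
    def shape(self) -> tuple:
        """(n_te, n_b) of the signal grid."""
        return (len(self.tes), len(self.bvals))

    @property
    def voxel_size_mm(self) -> tuple:
        return (self.fov_mm[0] / self.matrix_shape[0],
                self.fov_mm[1] / self.matrix_shape[1],
                self.slice_thickness_mm)

    def to_dict(self) -> dict:
        return {
            "tes_ms": list(self.tes),
            "bvals_s_per_mm2": list(self.bvals),
            "nex": [list(row) for row in self.nex],
            "matrix_shape": list(self.matrix_shape),
            "n_slices": self.n_slices,
            "fov_mm": list(self.fov_mm),
            "slice_thickness_mm": self.slice_thickness_mm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionGrid":
        return cls(
            tes=tuple(d["tes_ms"]),
            bvals=tuple(d["bvals_s_per_mm2"]),
            nex=tuple(tuple(int(n) for n in row) for row in d["nex"]),
            matrix_shape=tuple(d.get("matrix_shape", (128, 128))),
            n_slices=int(d.get("n_slices", 20)),
            fov_mm=tuple(d.get("fov_mm", (192.0, 192.0))),
            slice_thickness_mm=float(d.get("slice_thickness_mm", 4.0)),
        )


def default_grid(matrix_shape=(64, 64), n_slices=5) -> AcquisitionGrid:
    """The study protocol: TEs {53, 71, 89} ms, b {0, 500, 1000} s/mm^2,
    NEX table 3/3/3, 2/4/8, 4/8/16 indexed (te, b).

    The geometry defaults to a desk-scale 64 x 64 x 5 phantom matrix; pass
    ``matrix_shape=(128, 128), n_slices=20`` for the full-size scan geometry.
    """
    return AcquisitionGrid(
        tes=(53.0, 71.0, 89.0),
        bvals=(0.0, 500.0, 1000.0),
        nex=((3, 2, 4),
             (3, 4, 8),
             (3, 8, 16)),
        matrix_shape=tuple(matrix_shape),
        n_slices=n_slices,
    )


@dataclass
class SignalArray:
    """Magnitude signal of one voxel or ROI mean on the (TE, b) grid.

    ``values[i, j]`` is the signal at ``grid.tes[i]``, ``grid.bvals[j]``.
    """

    values: np.ndarray
    grid: AcquisitionGrid
    label: str = ""
    n_voxels: int = field(default=1)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(f"values shape {self.values.shape} does not match grid "
                             f"shape {self.grid.shape}")
        if np.any(self.values < 0):
            raise ValueError("magnitude signal must be >= 0")

    def decay_over_b(self, te_index: int) -> np.ndarray:
        """Signal vs b at a fixed TE (an ADC decay series)."""
        return self.values[te_index, :]

    def decay_over_te(self, b_index: int) -> np.ndarray:
        """Signal vs TE at a fixed b (an R2 decay series)."""
        return self.values[:, b_index]
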