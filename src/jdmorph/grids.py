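"""Lightweight in-memory containers for volumes, warps and Jacobian maps.

Everything lives on a regular isotropic grid with a RAS affine. Images are
float32 arrays; warps store one 3-vector (mm) per voxel as a ``(3, nx, ny,
nz)`` array. These containers deliberately carry no processing logic beyond
grid bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ScalarVolume",
    "LabelVolume",
    "DisplacementField",
    "JacobianMap",
    "make_affine",
]


def make_affine(voxel_size_mm: float, shape: tuple[int, int, int]) -> np.ndarray:
    """RAS affine with isotropic spacing, origin at the grid centre."""
    aff = np.diag([voxel_size_mm] * 3 + [1.0])
    aff[:3, 3] = -0.5 * voxel_size_mm * (np.asarray(shape) - 1)
    return aff


def _check_grid(a, b) -> None:
    if a.shape3 != b.shape3 or not np.allclose(a.affine, b.affine, atol=1e-6):
        raise ValueError(
            f"grid mismatch: {a.shape3} vs {b.shape3} or differing affines"
        )


@dataclass
class ScalarVolume:
    """3-D intensity image with mm spacing and world affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("ScalarVolume expects a 3-D array")
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape3(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size_mm(self) -> float:
        return float(np.abs(self.affine[0, 0]))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def same_grid(self, other) -> None:
        _check_grid(self, other)

    def copy(self) -> "ScalarVolume":
        return ScalarVolume(self.data.copy(), self.affine.copy())


@dataclass
class LabelVolume:
    """Integer anatomical labels plus a label table.

    ``table`` maps label id -> (name, tissue class). Classes partition the
    brain mask into {gyrus, sulcus, subcortical-GM, WM, CSF}; label 0 is
    background by convention.
    """

    data: np.ndarray
    affine: np.ndarray
    table: dict[int, tuple[str, str]] = field(default_factory=dict)

    VALID_CLASSES = ("gyrus", "sulcus", "subcortical-GM", "WM", "CSF", "background")

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.int16)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        present = set(np.unique(self.data).tolist())
        missing = present - set(self.table)
        if missing:
            raise ValueError(f"labels without table entry: {sorted(missing)}")
        for lab, (name, cls) in self.table.items():
            if cls not in self.VALID_CLASSES:
                raise ValueError(f"label {lab} ({name}): unknown class {cls!r}")

    @property
    def shape3(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size_mm(self) -> float:
        return float(np.abs(self.affine[0, 0]))

    def same_grid(self, other) -> None:
        _check_grid(self, other)

    def ids_of_class(self, *classes: str) -> list[int]:
        return sorted(k for k, (_, c) in self.table.items() if c in classes)

    def mask_of_class(self, *classes: str) -> np.ndarray:
        """Boolean mask of all voxels whose label class is in ``classes``."""
        unknown = set(classes) - set(self.VALID_CLASSES)
        if unknown:
            raise ValueError(f"unknown class name(s): {sorted(unknown)}")
        ids = self.ids_of_class(*classes)
        return np.isin(self.data, ids)

    @property
    def brain_mask(self) -> np.ndarray:
        return self.data > 0


@dataclass
class DisplacementField:
    """Voxelwise displacement u(x) in mm; the warp is phi(x) = x + u(x).

    Convention: the field maps baseline coordinates toward follow-up, so a
    contraction (atrophy) has Jacobian determinant < 1.
    """

    data: np.ndarray  # (3, nx, ny, nz), mm
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4 or self.data.shape[0] != 3:
            raise ValueError("DisplacementField expects a (3, nx, ny, nz) array")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite displacement values")

    @property
    def shape3(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def voxel_size_mm(self) -> float:
        return float(np.abs(self.affine[0, 0]))

    def same_grid(self, other) -> None:
        _check_grid(self, other)


@dataclass
class JacobianMap:
    """Voxelwise volume-change ratio of a warp (unitless, > 0).

    Values < 1 mean local volume loss baseline -> follow-up. ``annualized``
    records whether the map has been interval-corrected; ``interval_years``
    is the inter-scan interval the raw map spans.
    """

    data: np.ndarray
    affine: np.ndarray
    annualized: bool = False
    interval_years: float = 1.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape3(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size_mm(self) -> float:
        return float(np.abs(self.affine[0, 0]))

    def same_grid(self, other) -> None:
        _check_grid(self, other)

    def as_volume(self) -> ScalarVolume:
        return ScalarVolume(self.data, self.affine)
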