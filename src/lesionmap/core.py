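"""Reference-grid handling, lesion-mask I/O and geometry, and clinical tables.

All masks in a cohort must live on a single shared :class:`ReferenceGrid`.
Voxel indices are 0-based; the world coordinate of a voxel is the coordinate
of its *center*; centroids and geometry are reported in world millimetres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "ReferenceGrid",
    "LesionMask",
    "LesionStack",
    "GridMismatchError",
    "read_mask",
    "write_mask",
    "mask_volume",
    "mask_centroid",
    "mask_discrepancy",
    "merge_masks",
    "build_stack",
    "read_clinical",
    "write_clinical",
    "validate_clinical",
    "geometry_report",
]

#: absolute tolerance (mm) when comparing voxel sizes / origins of two grids
GRID_TOL_MM = 1e-4

#: values strictly above this threshold are treated as foreground on read
BINARIZE_THRESHOLD = 0.5

CLINICAL_REQUIRED_COLUMNS = ("patient_id", "age", "sex", "kps", "time", "event", "subgroup")
VALID_SEX = frozenset({"male", "female"})
VALID_SUBGROUPS = frozenset({"GBM", "astrocytoma"})


class GridMismatchError(ValueError):
    """Raised when a mask's grid does not match the cohort reference grid."""


@dataclass(frozen=True)
class ReferenceGrid:
    """A shared 3-D sampling grid: shape, voxel size, and world origin.

    Parameters
    ----------
    shape
        Number of voxels along each axis (all >= 1).
    voxel_size_mm
        Edge length of a voxel along each axis, in mm (all > 0).
    origin_mm
        World coordinate (mm) of the *center* of voxel (0, 0, 0).
    orientation
        Axis-orientation convention identifier (informational).
    """

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: str = "RAS"

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm))
        object.__setattr__(self, "origin_mm", tuple(float(v) for v in self.origin_mm))
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"grid shape must be 3 positive integers, got {self.shape}")
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"voxel sizes must be 3 positive reals, got {self.voxel_size_mm}")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (diagonal, center convention)."""
        aff = np.diag(list(self.voxel_size_mm) + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    @classmethod
    def from_image(cls, img: nib.spatialimages.SpatialImage) -> "ReferenceGrid":
        """Derive a grid from a NIfTI image's shape and affine."""
        aff = np.asarray(img.affine, dtype=float)
        sizes = tuple(float(np.linalg.norm(aff[:3, i])) for i in range(3))
        return cls(shape=tuple(img.shape[:3]), voxel_size_mm=sizes, origin_mm=tuple(aff[:3, 3]))

    def matches(self, other: "ReferenceGrid", tol: float = GRID_TOL_MM) -> bool:
        return (
            self.shape == other.shape
            and all(abs(a - b) <= tol for a, b in zip(self.voxel_size_mm, other.voxel_size_mm))
            and all(abs(a - b) <= tol for a, b in zip(self.origin_mm, other.origin_mm))
        )

    def world_from_index(self, indices: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel centers for integer indices (..., 3)."""
        idx = np.asarray(indices, dtype=float)
        return idx * np.asarray(self.voxel_size_mm) + np.asarray(self.origin_mm)

    def index_from_world(self, points_mm: np.ndarray) -> np.ndarray:
        """Containing-voxel indices for world points (floor-to-voxel rule)."""
        pts = np.asarray(points_mm, dtype=float)
        cont = (pts - np.asarray(self.origin_mm)) / np.asarray(self.voxel_size_mm)
        return np.floor(cont + 0.5).astype(int)

    def contains_world(self, point_mm: Sequence[float]) -> bool:
        idx = self.index_from_world(np.asarray(point_mm))
        return bool(np.all(idx >= 0) and np.all(idx < np.asarray(self.shape)))


@dataclass
class LesionMask:
    """One patient's binary lesion mask on a reference grid."""

    patient_id: str
    grid: ReferenceGrid
    voxels: np.ndarray

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError(f"mask for {self.patient_id!r} must be 3-D, got ndim={vox.ndim}")
        if tuple(vox.shape) != self.grid.shape:
            raise GridMismatchError(
                f"mask shape {vox.shape} does not match grid shape {self.grid.shape}"
            )
        uniq = np.unique(vox)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask for {self.patient_id!r} is not binary (values {uniq[:5]}...)")
        self.voxels = vox.astype(np.uint8)

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())

    def __repr__(self) -> str:  # pragma: no cover
        return f"LesionMask({self.patient_id!r}, {self.n_foreground} voxels)"


@dataclass
class LesionStack:
    """Cohort lesion data: one binary row per patient, voxels linearized C-order."""

    grid: ReferenceGrid
    patient_ids: list[str]
    data: np.ndarray  # (n_patients, n_voxels) uint8

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.uint8)
        if self.data.ndim != 2:
            raise ValueError("stack data must be 2-D (patients x voxels)")
        if self.data.shape[0] != len(self.patient_ids):
            raise ValueError("row count does not match patient_ids")
        if self.data.shape[0] < 2:
            raise ValueError("a lesion stack needs at least 2 patients")
        if self.data.shape[1] != self.grid.n_voxels:
            raise ValueError("column count does not match grid voxel count")

    @property
    def n_patients(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def lesion_counts(self) -> np.ndarray:
        """Per-voxel number of patients with a lesion (length n_voxels)."""
        return self.data.sum(axis=0, dtype=np.int64)

    def volume_3d(self, row: int) -> np.ndarray:
        return self.data[row].reshape(self.grid.shape)


# ---------------------------------------------------------------------------
# mask I/O


def read_mask(path: str | Path, expected_grid: ReferenceGrid, patient_id: str | None = None) -> LesionMask:
    """Read a NIfTI volume, binarize it (> 0.5), and validate its grid.

    Raises
    ------
    GridMismatchError
        If the file's grid differs from ``expected_grid`` in shape, voxel
        size, or origin (tolerance ``GRID_TOL_MM``).
    ValueError
        If the image is not 3-D.
    """
    path = Path(path)
    img = nib.load(str(path))
    shape = img.shape
    if len(shape) == 4 and shape[3] == 1:
        img = nib.funcs.squeeze_image(img)
        shape = img.shape
    if len(shape) != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {shape}")
    grid = ReferenceGrid.from_image(img)
    if not grid.matches(expected_grid):
        raise GridMismatchError(
            f"{path}: grid mismatch — file grid {grid.shape} @ {grid.voxel_size_mm} mm "
            f"origin {grid.origin_mm} vs expected {expected_grid.shape} @ "
            f"{expected_grid.voxel_size_mm} mm origin {expected_grid.origin_mm}"
        )
    data = np.asarray(img.get_fdata())
    vox = (data > BINARIZE_THRESHOLD).astype(np.uint8)
    pid = patient_id if patient_id is not None else path.name.removesuffix(".gz").removesuffix(".nii")
    return LesionMask(patient_id=pid, grid=expected_grid, voxels=vox)


def write_mask(mask: LesionMask, path: str | Path) -> Path:
    """Write a binary mask as NIfTI (uint8) on the mask's grid."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), mask.grid.affine)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# geometry


def mask_volume(mask: LesionMask) -> float:
    """Lesion volume in cm^3 (foreground count x voxel volume / 1000)."""
    n = mask.n_foreground
    if n == 0:
        warnings.warn(f"mask {mask.patient_id!r} is empty; volume is 0", stacklevel=2)
    return n * mask.grid.voxel_volume_mm3 / 1000.0


def mask_centroid(mask: LesionMask) -> np.ndarray:
    """Mean world coordinate (mm) of all foreground voxel centers."""
    if mask.n_foreground == 0:
        raise ValueError(f"mask {mask.patient_id!r} is empty: centroid undefined")
    idx = np.argwhere(mask.voxels > 0)
    return mask.grid.world_from_index(idx).mean(axis=0)


def mask_discrepancy(a: LesionMask, b: LesionMask) -> float:
    """Symmetric relative volume difference: |v_a - v_b| / mean(v_a, v_b)."""
    if not a.grid.matches(b.grid):
        raise GridMismatchError("masks are on different grids")
    va, vb = a.n_foreground, b.n_foreground
    if va == 0 and vb == 0:
        raise ValueError("both masks are empty: discrepancy undefined")
    return abs(va - vb) / ((va + vb) / 2.0)


def merge_masks(a: LesionMask, b: LesionMask, max_discrepancy: float = 0.05) -> LesionMask:
    """Voxelwise union of two rater masks, refused above the discrepancy bound.

    Raises
    ------
    ValueError
        If the volume discrepancy is >= ``max_discrepancy`` — such pairs
        need third-party adjudication rather than automatic merging.
    """
    disc = mask_discrepancy(a, b)
    if disc >= max_discrepancy:
        raise ValueError(
            f"mask discrepancy {disc:.4f} >= {max_discrepancy:.4f} for "
            f"{a.patient_id!r}/{b.patient_id!r}: refusing to merge (needs adjudication)"
        )
    merged = np.logical_or(a.voxels, b.voxels).astype(np.uint8)
    return LesionMask(patient_id=a.patient_id, grid=a.grid, voxels=merged)


# ---------------------------------------------------------------------------
# stacking


def build_stack(masks: Iterable[LesionMask], clinical: pd.DataFrame) -> LesionStack:
    """Assemble a per-patient lesion matrix ordered by the clinical table.

    Every ``patient_id`` in ``clinical`` must have exactly one mask; extra
    masks are an error too, so silent drop-outs cannot go unnoticed.
    """
    masks = list(masks)
    by_id: dict[str, LesionMask] = {}
    dupes = []
    for m in masks:
        if m.patient_id in by_id:
            dupes.append(m.patient_id)
        by_id[m.patient_id] = m
    if dupes:
        raise ValueError(f"duplicate masks for patients: {sorted(set(dupes))}")
    wanted = list(clinical["patient_id"].astype(str))
    missing = [pid for pid in wanted if pid not in by_id]
    if missing:
        raise ValueError(f"missing masks for patients: {missing}")
    extra = sorted(set(by_id) - set(wanted))
    if extra:
        raise ValueError(f"masks without clinical rows: {extra}")
    grid = by_id[wanted[0]].grid
    for pid in wanted:
        if not by_id[pid].grid.matches(grid):
            raise GridMismatchError(f"mask for {pid!r} is not on the cohort grid")
    data = np.stack([by_id[pid].voxels.reshape(-1) for pid in wanted])
    return LesionStack(grid=grid, patient_ids=wanted, data=data)


# ---------------------------------------------------------------------------
# clinical tables


def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a clinical table (required columns, domains)."""
    missing = [c for c in CLINICAL_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing required columns: {missing}")
    df = df.copy()
    df["patient_id"] = df["patient_id"].astype(str)
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"duplicate patient_id values: {dup}")
    for col in ("age", "kps", "time", "event"):
        if df[col].isna().any():
            bad = df.loc[df[col].isna(), "patient_id"].tolist()
            raise ValueError(f"missing {col} for patients: {bad}")
    bad_sex = sorted(set(df["sex"]) - VALID_SEX)
    if bad_sex:
        raise ValueError(f"sex must be one of {sorted(VALID_SEX)}, got {bad_sex}")
    bad_sub = sorted(set(df["subgroup"]) - VALID_SUBGROUPS)
    if bad_sub:
        raise ValueError(f"subgroup must be one of {sorted(VALID_SUBGROUPS)}, got {bad_sub}")
    kps = df["kps"].to_numpy()
    if np.any((kps < 0) | (kps > 100) | (kps % 10 != 0)):
        raise ValueError("kps values must be multiples of 10 in [0, 100]")
    if np.any(df["time"].to_numpy() <= 0):
        raise ValueError("survival times must be > 0")
    if not set(np.unique(df["event"])) <= {0, 1}:
        raise ValueError("event must be 0 (censored) or 1 (death)")
    df["event"] = df["event"].astype(int)
    df["kps"] = df["kps"].astype(int)
    return df.reset_index(drop=True)


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a TSV/CSV clinical table (separator inferred from extension)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return validate_clinical(pd.read_csv(path, sep=sep))


def write_clinical(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df.to_csv(path, sep=sep, index=False, float_format="%.6f")
    return path


def geometry_report(masks: Iterable[LesionMask]) -> pd.DataFrame:
    """Per-patient volume (cm^3) and world centroid (mm) table."""
    rows = []
    for m in masks:
        cx, cy, cz = mask_centroid(m)
        rows.append(
            {
                "patient_id": m.patient_id,
                "volume_cm3": mask_volume(m),
                "centroid_x_mm": cx,
                "centroid_y_mm": cy,
                "centroid_z_mm": cz,
            }
        )
    return pd.DataFrame(rows)
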