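"""Overlap between significant-voxel regions and atlas tract masks.

Report convention: the overlap fraction is overlap/structure truncated
(floored) to 2 decimals; full precision is kept internally.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GridMismatchError, ReferenceGrid, read_mask
from .vlsm import ROIMask

__all__ = [
    "AtlasTract",
    "OverlapRow",
    "tract_overlap",
    "overlap_table",
    "overlap_dataframe",
    "label_at_point",
    "read_atlas_dir",
    "read_labeled_atlas",
    "truncate_fraction",
]


@dataclass
class AtlasTract:
    """A named binary tract mask on the reference grid."""

    name: str
    grid: ReferenceGrid
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = (np.asarray(self.mask) > 0).astype(np.uint8)
        if tuple(self.mask.shape) != self.grid.shape:
            raise GridMismatchError(f"tract {self.name!r} shape does not match its grid")
        if self.mask.sum() < 1:
            raise ValueError(f"tract {self.name!r} has no foreground voxels")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class OverlapRow:
    tract_name: str
    overlap_voxels: int
    structure_voxels: int
    overlap_fraction: float  # full precision
    overlap_fraction_reported: float  # floor-truncated to 2 decimals


def truncate_fraction(fraction: float, decimals: int = 2) -> float:
    """Floor-truncate a fraction for report parity (0.0297 -> 0.02)."""
    scale = 10**decimals
    return math.floor(fraction * scale) / scale


def tract_overlap(roi: ROIMask, tract: AtlasTract) -> OverlapRow:
    """Voxel overlap between an ROI and one tract, with the truncated fraction."""
    if not roi.grid.matches(tract.grid):
        raise GridMismatchError(f"ROI {roi.label!r} and tract {tract.name!r} grids differ")
    overlap = int(np.logical_and(roi.mask, tract.mask).sum())
    structure = tract.voxel_count
    frac = overlap / structure
    return OverlapRow(
        tract_name=tract.name,
        overlap_voxels=overlap,
        structure_voxels=structure,
        overlap_fraction=frac,
        overlap_fraction_reported=truncate_fraction(frac),
    )


def overlap_table(
    roi: ROIMask, tracts: Sequence[AtlasTract], min_overlap: int = 1
) -> list[OverlapRow]:
    """One row per tract with overlap >= min_overlap, largest structures first."""
    rows = [tract_overlap(roi, t) for t in tracts]
    rows = [r for r in rows if r.overlap_voxels >= min_overlap]
    rows.sort(key=lambda r: (-r.structure_voxels, r.tract_name))
    return rows


def overlap_dataframe(roi: ROIMask, tracts: Sequence[AtlasTract], min_overlap: int = 1) -> pd.DataFrame:
    rows = overlap_table(roi, tracts, min_overlap=min_overlap)
    return pd.DataFrame(
        [
            {
                "roi_label": roi.label,
                "tract_name": r.tract_name,
                "overlap_voxels": r.overlap_voxels,
                "structure_voxels": r.structure_voxels,
                "overlap_fraction": r.overlap_fraction_reported,
            }
            for r in rows
        ],
        columns=["roi_label", "tract_name", "overlap_voxels", "structure_voxels", "overlap_fraction"],
    )


def label_at_point(
    point_mm: Sequence[float],
    labels: np.ndarray,
    grid: ReferenceGrid,
    names: dict[int, str],
) -> str:
    """Region name at a world point (floor-to-containing-voxel; 0 = background)."""
    idx = grid.index_from_world(np.asarray(point_mm, dtype=float))
    if np.any(idx < 0) or np.any(idx >= np.asarray(grid.shape)):
        raise ValueError(f"point {tuple(point_mm)} mm lies outside the grid")
    lab = int(labels[tuple(idx)])
    if lab == 0:
        return "background"
    return names.get(lab, f"label_{lab}")


def read_atlas_dir(path: str | Path, grid: ReferenceGrid) -> list[AtlasTract]:
    """Read a directory of binary NIfTI tract masks (name = filename stem)."""
    path = Path(path)
    tracts = []
    for f in sorted(path.glob("*.nii")) + sorted(path.glob("*.nii.gz")):
        mask = read_mask(f, grid)
        tracts.append(AtlasTract(name=mask.patient_id, grid=grid, mask=mask.voxels))
    if not tracts:
        raise ValueError(f"no NIfTI tract masks found in {path}")
    return tracts


def read_labeled_atlas(
    nifti_path: str | Path, names_path: str | Path, grid: ReferenceGrid
) -> tuple[np.ndarray, dict[int, str]]:
    """Read an integer-labeled volume plus a JSON {label: name} map."""
    import nibabel as nib

    img = nib.load(str(nifti_path))
    g = ReferenceGrid.from_image(img)
    if not g.matches(grid):
        raise GridMismatchError(f"{nifti_path}: labeled atlas grid differs from reference grid")
    labels = np.asarray(img.get_fdata()).astype(int)
    raw = json.loads(Path(names_path).read_text())
    names = {int(k): str(v) for k, v in raw.items()}
    return labels, names
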