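"""Synthetic lesion cohorts with a known ground-truth effect region.

The generative model couples lesion location to outcome through a single
ellipsoidal "effect region": patients whose lesion touches it get a mean
shift in functional score and a multiplicative bump in event hazard.
Everything is driven by one integer seed, so identical configs reproduce
byte-identical cohorts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import AtlasTract
from .core import LesionMask, ReferenceGrid, write_clinical, write_mask

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_atlas",
    "write_cohort",
    "DEFAULT_GRID",
]

DEFAULT_GRID = ReferenceGrid(shape=(40, 48, 40), voxel_size_mm=(4.0, 4.0, 4.0))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Effect sizes: ``kps_effect`` (<= 0) shifts mean functional score for
    patients whose lesion overlaps the effect region; ``os_log_hazard_effect``
    (>= 0) is the log hazard ratio of overlap on survival. Survival times are
    exponential; independent exponential censoring is tuned so roughly
    ``censor_rate`` of patients are censored.
    """

    n_patients: int = 120
    seed: int = 0
    grid: ReferenceGrid = DEFAULT_GRID
    effect_center_mm: tuple[float, float, float] | None = None  # None -> grid center
    effect_radii_mm: tuple[float, float, float] = (20.0, 20.0, 20.0)
    lesion_radius_range_mm: tuple[float, float] = (12.0, 28.0)
    lesion_center_sd_mm: float = 28.0
    kps_effect: float = -20.0
    os_log_hazard_effect: float = math.log(2.0)
    baseline_kps_mean: float = 85.0
    baseline_kps_sd: float = 13.0
    baseline_hazard: float = 1.0 / 14.0  # per month; median OS ~ 10 months
    censor_rate: float = 0.2
    age_mean: float = 58.0
    age_sd: float = 15.0
    male_fraction: float = 0.55
    subgroup: str = "GBM"
    time_unit: str = "months"

    def __post_init__(self) -> None:
        if self.n_patients < 10:
            raise ValueError("n_patients must be >= 10")
        if not (0.0 <= self.censor_rate < 1.0):
            raise ValueError("censor_rate must be in [0, 1)")
        if self.kps_effect > 0:
            raise ValueError("kps_effect must be <= 0 (adverse direction)")
        if self.os_log_hazard_effect < 0:
            raise ValueError("os_log_hazard_effect must be >= 0 (adverse direction)")
        lo, hi = self.lesion_radius_range_mm
        if not (0 < lo <= hi):
            raise ValueError("lesion_radius_range_mm must satisfy 0 < min <= max")
        center = np.asarray(self.resolved_effect_center())
        radii = np.asarray(self.effect_radii_mm)
        extent = np.asarray(self.grid.shape) * np.asarray(self.grid.voxel_size_mm)
        origin = np.asarray(self.grid.origin_mm)
        if np.any(center - radii < origin) or np.any(center + radii > origin + extent):
            raise ValueError("effect region does not fit inside the grid")

    def resolved_effect_center(self) -> tuple[float, float, float]:
        if self.effect_center_mm is not None:
            return self.effect_center_mm
        g = self.grid
        c = np.asarray(g.origin_mm) + (np.asarray(g.shape) - 1) * np.asarray(g.voxel_size_mm) / 2.0
        return tuple(float(x) for x in c)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid"] = {
            "shape": list(self.grid.shape),
            "voxel_size_mm": list(self.grid.voxel_size_mm),
            "origin_mm": list(self.grid.origin_mm),
        }
        return d


@dataclass
class GroundTruth:
    """What the simulator actually did: effect mask, per-patient overlap, effects."""

    effect_region: np.ndarray  # binary 3-D
    overlap: np.ndarray  # bool per patient, cohort order
    kps_effect: float
    os_log_hazard_effect: float
    config: SimulationConfig

    @property
    def n_overlapping(self) -> int:
        return int(self.overlap.sum())


def _voxel_center_grids(grid: ReferenceGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axes = [
        grid.origin_mm[i] + np.arange(grid.shape[i]) * grid.voxel_size_mm[i] for i in range(3)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid_mask(grid: ReferenceGrid, center: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Voxelize an ellipsoid by center-inclusion: voxel in iff its center is inside."""
    gx, gy, gz = _voxel_center_grids(grid)
    d = (
        ((gx - center[0]) / radii[0]) ** 2
        + ((gy - center[1]) / radii[1]) ** 2
        + ((gz - center[2]) / radii[2]) ** 2
    )
    return (d <= 1.0).astype(np.uint8)


def _brain_region(grid: ReferenceGrid) -> tuple[np.ndarray, np.ndarray]:
    """Ellipsoidal 'brain' envelope inscribed in the grid: (center, semi-axes)."""
    extent = np.asarray(grid.shape) * np.asarray(grid.voxel_size_mm)
    center = np.asarray(grid.origin_mm) + (np.asarray(grid.shape) - 1) * np.asarray(grid.voxel_size_mm) / 2.0
    semi = 0.45 * extent
    return center, semi


def generate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, list[LesionMask], GroundTruth]:
    """Simulate one cohort: clinical table, per-patient lesion masks, ground truth.

    Per patient: one ellipsoidal lesion (center ~ truncated Gaussian around
    the brain center, per-axis radii jittered +-25%), an overlap flag, KPS
    drawn from a Gaussian shifted by ``kps_effect`` when overlapping and
    discretized to the 0..100-by-10 scale, and exponential survival with
    hazard multiplied by ``exp(os_log_hazard_effect)`` when overlapping.
    """
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    eff_center = np.asarray(config.resolved_effect_center())
    eff_radii = np.asarray(config.effect_radii_mm, dtype=float)
    effect_region = _ellipsoid_mask(grid, eff_center, eff_radii)

    brain_center, brain_semi = _brain_region(grid)
    gx, gy, gz = _voxel_center_grids(grid)

    masks: list[LesionMask] = []
    overlap = np.zeros(config.n_patients, dtype=bool)
    rows = []
    lo, hi = config.lesion_radius_range_mm

    for i in range(config.n_patients):
        pid = f"P{i + 1:04d}"
        # rejection-sample a lesion center inside the brain envelope
        while True:
            c = brain_center + rng.normal(0.0, config.lesion_center_sd_mm, size=3)
            if np.sum(((c - brain_center) / brain_semi) ** 2) <= 1.0:
                break
        base_r = rng.uniform(lo, hi)
        radii = base_r * (1.0 + rng.uniform(-0.25, 0.25, size=3))
        d = (
            ((gx - c[0]) / radii[0]) ** 2
            + ((gy - c[1]) / radii[1]) ** 2
            + ((gz - c[2]) / radii[2]) ** 2
        )
        vox = (d <= 1.0).astype(np.uint8)
        if vox.sum() == 0:  # tiny lesion between voxel centers: keep nearest voxel
            vox.flat[int(np.argmin(d))] = 1
        mask = LesionMask(patient_id=pid, grid=grid, voxels=vox)
        masks.append(mask)
        hit = bool(np.any(vox & effect_region))
        overlap[i] = hit

        # covariates
        while True:
            age = rng.normal(config.age_mean, config.age_sd)
            if age >= 18.0:
                break
        sex = "male" if rng.random() < config.male_fraction else "female"

        kps_raw = rng.normal(config.baseline_kps_mean, config.baseline_kps_sd)
        if hit:
            kps_raw += config.kps_effect
        kps = int(np.clip(np.round(kps_raw / 10.0) * 10.0, 0.0, 100.0))

        hazard = config.baseline_hazard * math.exp(config.os_log_hazard_effect * hit)
        t_event = rng.exponential(1.0 / hazard)
        if config.censor_rate > 0.0:
            cens_hazard = config.baseline_hazard * config.censor_rate / (1.0 - config.censor_rate)
            t_cens = rng.exponential(1.0 / cens_hazard)
        else:
            t_cens = math.inf
        time = min(t_event, t_cens)
        event = int(t_event <= t_cens)

        rows.append(
            {
                "patient_id": pid,
                "age": round(float(age), 6),
                "sex": sex,
                "kps": kps,
                "time": round(float(time), 6),
                "event": event,
                "subgroup": config.subgroup,
                "tumor_volume_cm3": round(vox.sum() * grid.voxel_volume_mm3 / 1000.0, 6),
            }
        )

    clinical = pd.DataFrame(rows)
    truth = GroundTruth(
        effect_region=effect_region,
        overlap=overlap,
        kps_effect=config.kps_effect,
        os_log_hazard_effect=config.os_log_hazard_effect,
        config=config,
    )
    return clinical, masks, truth


def generate_atlas(grid: ReferenceGrid, n_tracts: int, seed: int) -> list[AtlasTract]:
    """Generate ``n_tracts`` synthetic tube-shaped tract masks named tract_01...

    Each tract is a cylinder along one grid axis with a jittered center line
    and a radius of 6-14 mm, guaranteed non-empty.
    """
    if n_tracts < 1:
        raise ValueError("n_tracts must be >= 1")
    rng = np.random.default_rng(seed)
    center, semi = _brain_region(grid)
    gxyz = _voxel_center_grids(grid)
    tracts: list[AtlasTract] = []
    for k in range(n_tracts):
        axis = int(rng.integers(0, 3))
        others = [a for a in range(3) if a != axis]
        radius = rng.uniform(6.0, 14.0)
        line = center.copy()
        for a in others:
            line[a] += rng.uniform(-0.5, 0.5) * semi[a]
        d2 = sum((gxyz[a] - line[a]) ** 2 for a in others)
        along = np.abs(gxyz[axis] - center[axis])
        vox = ((d2 <= radius**2) & (along <= semi[axis])).astype(np.uint8)
        if vox.sum() == 0:
            idx = grid.index_from_world(line)
            vox[tuple(np.clip(idx, 0, np.asarray(grid.shape) - 1))] = 1
        tracts.append(AtlasTract(name=f"tract_{k + 1:02d}", grid=grid, mask=vox))
    return tracts


def write_cohort(
    clinical: pd.DataFrame,
    masks: list[LesionMask],
    truth: GroundTruth,
    outdir: str | Path,
) -> dict[str, str]:
    """Write masks (NIfTI), clinical table (TSV), and ground truth (NIfTI + JSON)."""
    outdir = Path(outdir)
    masks_dir = outdir / "masks"
    masks_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    for m in masks:
        p = write_mask(m, masks_dir / f"{m.patient_id}.nii")
        files[m.patient_id] = str(p)
    files["clinical"] = str(write_clinical(clinical, outdir / "clinical.tsv"))
    grid = truth.config.grid
    effect = LesionMask(patient_id="effect_region", grid=grid, voxels=truth.effect_region)
    files["effect_region"] = str(write_mask(effect, outdir / "effect_region.nii"))
    sidecar = {
        "kps_effect": truth.kps_effect,
        "os_log_hazard_effect": truth.os_log_hazard_effect,
        "n_overlapping": truth.n_overlapping,
        "overlap": [bool(x) for x in truth.overlap],
        "config": truth.config.to_dict(),
    }
    sidecar_path = outdir / "ground_truth.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    files["ground_truth"] = str(sidecar_path)
    return files
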