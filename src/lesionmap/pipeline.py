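"""End-to-end orchestration: simulate -> map -> overlap -> validate.

One global seed deterministically spawns per-stage seeds (fixed stage
indices fed to ``numpy.random.SeedSequence``), so any stage can be re-run
in isolation and two runs from the same config are byte-identical. The run
manifest is written atomically and only on success.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import AtlasTract, overlap_dataframe, read_atlas_dir
from .core import (
    LesionMask,
    ReferenceGrid,
    build_stack,
    read_clinical,
    read_mask,
    write_mask,
)
from .simulate import SimulationConfig, generate_atlas, generate_cohort, write_cohort
from .survival import assign_risk_groups, cox_hazard_ratio, km_estimate, logrank_test, roc_at_horizon
from .vlsm import DesignSpec, ROIMask, run_vlsm

__all__ = ["PipelineConfig", "load_config", "run_discovery", "run_validation", "run_all", "stage_seed"]

log = logging.getLogger("lesionmap")

#: fixed stage indices used to spawn per-stage seeds from the global seed
STAGE_INDEX = {"simulate": 0, "atlas": 1, "vlsm_kps": 2, "vlsm_os": 3, "roc": 4}

_ALLOWED_KEYS = {
    "seed",
    "output_dir",
    "masks_dir",
    "clinical_table",
    "atlas_dir",
    "n_atlas_tracts",
    "outcomes",
    "covariates",
    "n_permutations",
    "alpha",
    "min_lesion_count",
    "threshold_rule",
    "permutation_scheme",
    "horizon",
    "n_boot",
    "log_level",
    "simulation",
}

_ALLOWED_SIM_KEYS = {
    "n_patients",
    "grid_shape",
    "voxel_size_mm",
    "effect_center_mm",
    "effect_radii_mm",
    "lesion_radius_range_mm",
    "lesion_center_sd_mm",
    "kps_effect",
    "os_log_hazard_effect",
    "baseline_kps_mean",
    "baseline_kps_sd",
    "baseline_hazard",
    "censor_rate",
    "age_mean",
    "age_sd",
    "male_fraction",
    "subgroup",
    "time_unit",
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: SeedSequence([global_seed, stage_index])."""
    idx = STAGE_INDEX[stage]
    return int(np.random.SeedSequence([int(global_seed), idx]).generate_state(1)[0])


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "lesionmap_out"
    masks_dir: str | None = None
    clinical_table: str | None = None
    atlas_dir: str | None = None
    n_atlas_tracts: int = 5
    outcomes: tuple[str, ...] = ("kps", "os")
    covariates: tuple[str, ...] = ("age", "sex", "volume")
    n_permutations: int = 500
    alpha: float = 0.05
    min_lesion_count: int | None = None
    threshold_rule: str = "pervoxel"
    permutation_scheme: str = "simple"
    horizon: float = 12.0
    n_boot: int = 1000
    log_level: str = "INFO"
    simulation: dict | None = None

    def design_spec(self, outcome: str) -> DesignSpec:
        return DesignSpec(
            outcome=outcome,
            covariates=tuple(self.covariates),
            min_lesion_count=self.min_lesion_count,
            alpha=self.alpha,
            n_permutations=self.n_permutations,
            seed=stage_seed(self.seed, f"vlsm_{outcome}"),
            threshold_rule=self.threshold_rule,
            permutation_scheme=self.permutation_scheme,
        )

    def simulation_config(self) -> SimulationConfig:
        if self.simulation is None:
            raise ValueError("config has no simulation block")
        sim = dict(self.simulation)
        grid_kwargs = {}
        if "grid_shape" in sim or "voxel_size_mm" in sim:
            shape = tuple(sim.pop("grid_shape", (40, 48, 40)))
            vox = sim.pop("voxel_size_mm", (4.0, 4.0, 4.0))
            if np.isscalar(vox):
                vox = (float(vox),) * 3
            grid_kwargs["grid"] = ReferenceGrid(shape=shape, voxel_size_mm=tuple(vox))
        for key in ("effect_center_mm", "effect_radii_mm", "lesion_radius_range_mm"):
            if key in sim and sim[key] is not None:
                sim[key] = tuple(sim[key])
        return SimulationConfig(seed=stage_seed(self.seed, "simulate"), **grid_kwargs, **sim)

    def to_dict(self) -> dict:
        d = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        return d


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline config; unknown keys are errors."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _ALLOWED_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "simulation" in raw and raw["simulation"] is not None:
        bad = set(raw["simulation"]) - _ALLOWED_SIM_KEYS
        if bad:
            raise ValueError(f"unknown simulation keys: {sorted(bad)}")
    for key in ("outcomes", "covariates"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)


# ---------------------------------------------------------------------------
# helpers


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(outdir: Path, manifest: dict) -> Path:
    """Atomic manifest write: tmp file + rename, only called on success."""
    target = outdir / "manifest.json"
    tmp = outdir / ".manifest.json.tmp"
    tmp.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    os.replace(tmp, target)
    return target


def _checksum_outputs(outdir: Path, files: Sequence[Path]) -> dict[str, str]:
    return {str(Path(f).relative_to(outdir)): _sha256(Path(f)) for f in files}


def infer_grid(mask_path: str | Path) -> ReferenceGrid:
    """Reference grid of a NIfTI file (used to anchor a cohort)."""
    return ReferenceGrid.from_image(nib.load(str(mask_path)))


def load_cohort(masks_dir: str | Path, clinical_table: str | Path) -> tuple[pd.DataFrame, list[LesionMask], ReferenceGrid]:
    clinical = read_clinical(clinical_table)
    masks_dir = Path(masks_dir)
    paths = sorted(masks_dir.glob("*.nii")) + sorted(masks_dir.glob("*.nii.gz"))
    if not paths:
        raise ValueError(f"no NIfTI masks in {masks_dir}")
    grid = infer_grid(paths[0])
    masks = [read_mask(p, grid) for p in paths]
    return clinical, masks, grid


def _resolve_cohort(config: PipelineConfig, outdir: Path) -> tuple[pd.DataFrame, list[LesionMask], ReferenceGrid, dict]:
    """Load the configured cohort, simulating one first if requested."""
    info: dict[str, Any] = {}
    if config.simulation is not None:
        sim_cfg = config.simulation_config()
        clinical, masks, truth = generate_cohort(sim_cfg)
        sim_dir = outdir / "sim"
        write_cohort(clinical, masks, truth, sim_dir)
        info["simulated"] = True
        info["sim_seed"] = sim_cfg.seed
        info["n_overlapping_truth"] = truth.n_overlapping
        return clinical, masks, sim_cfg.grid, info
    if not config.masks_dir or not config.clinical_table:
        raise ValueError("config needs either a simulation block or masks_dir + clinical_table")
    clinical, masks, grid = load_cohort(config.masks_dir, config.clinical_table)
    info["simulated"] = False
    return clinical, masks, grid, info


def _load_atlas(config: PipelineConfig, grid: ReferenceGrid) -> list[AtlasTract]:
    if config.atlas_dir:
        return read_atlas_dir(config.atlas_dir, grid)
    return generate_atlas(grid, config.n_atlas_tracts, seed=stage_seed(config.seed, "atlas"))


def _save_map(volume: np.ndarray, grid: ReferenceGrid, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float64), grid.affine), str(path))
    return path


# ---------------------------------------------------------------------------
# stages


def run_discovery(config: PipelineConfig) -> dict:
    """Discovery arm: cohort -> voxelwise maps -> ROIs -> atlas overlap tables.

    Returns the manifest dict; also writes it (atomically) plus per-outcome
    t-maps, p-maps, ROI masks, and overlap TSVs under ``config.output_dir``.
    """
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    clinical, masks, grid, info = _resolve_cohort(config, outdir)
    if len(clinical) < 10:
        raise ValueError(f"cohort has {len(clinical)} patients; at least 10 required")
    stack = build_stack(masks, clinical)
    atlas = _load_atlas(config, grid)

    outputs: list[Path] = []
    stages: dict[str, Any] = {}
    rois: list[ROIMask] = []
    roi_labels = {"kps": "ROI1", "os": "ROI2"}
    for outcome in config.outcomes:
        stage_t0 = time.time()
        spec = config.design_spec(outcome)
        label = roi_labels.get(outcome, "custom")
        statmap, null, roi = run_vlsm(stack, clinical, spec, label=label)
        rois.append(roi)

        pmap = np.full(grid.shape, np.nan)
        pmap.reshape(-1)[statmap.analyzed.reshape(-1).astype(bool)] = null.pvalues
        outputs.append(_save_map(statmap.t_adv, grid, outdir / f"tmap_{outcome}.nii"))
        outputs.append(_save_map(pmap, grid, outdir / f"pmap_{outcome}.nii"))
        outputs.append(
            write_mask(LesionMask(patient_id=label, grid=grid, voxels=roi.mask), outdir / f"roi_{outcome}.nii")
        )
        ov = overlap_dataframe(roi, atlas)
        ov_path = outdir / f"overlap_{outcome}.tsv"
        ov.to_csv(ov_path, sep="\t", index=False)
        outputs.append(ov_path)
        stages[f"vlsm_{outcome}"] = {
            "seed": spec.seed,
            "n_analyzed": roi.provenance["n_analyzed"],
            "n_roi": roi.n_voxels,
            "df": statmap.df,
            "wall_s": round(time.time() - stage_t0, 3),
        }
        log.info("outcome %s: %d analyzed voxels, %d in ROI", outcome, roi.provenance["n_analyzed"], roi.n_voxels)

    manifest = {
        "kind": "discovery",
        "version": __version__,
        "config": config.to_dict(),
        "cohort": {"n_patients": len(clinical), **info},
        "stages": stages,
        "wall_s": round(time.time() - t0, 3),
        "checksums": _checksum_outputs(outdir, outputs),
    }
    _write_manifest(outdir, manifest)
    manifest["_rois"] = rois
    manifest["_masks"] = masks
    manifest["_clinical"] = clinical
    return manifest


def run_validation(
    config: PipelineConfig,
    rois: Sequence[ROIMask],
    masks: Sequence[LesionMask] | None = None,
    clinical: pd.DataFrame | None = None,
) -> dict:
    """Validation arm: risk groups -> KM/log-rank/Cox -> fixed-horizon ROC."""
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if masks is None or clinical is None:
        clinical, masks, _, _ = _resolve_cohort(config, outdir)

    assignment = assign_risk_groups(masks, rois)
    merged = clinical.merge(assignment.table, on="patient_id", validate="one_to_one")
    risk_path = outdir / "risk_assignment.tsv"
    assignment.table.to_csv(risk_path, sep="\t", index=False)
    outputs = [risk_path]

    stats: dict[str, Any] = {"horizon": config.horizon}
    high = merged[merged["risk_group"] == "high"]
    low = merged[merged["risk_group"] == "low"]
    degenerate = len(high) == 0 or len(low) == 0
    if degenerate:
        log.warning(
            "degenerate risk assignment (%d high / %d low): survival stats skipped",
            len(high),
            len(low),
        )
        stats["degenerate_assignment"] = True
    else:
        km_rows = []
        for name, grp in (("high", high), ("low", low)):
            curve = km_estimate(grp["time"], grp["event"])
            for tt, s, nar in zip(curve.times, curve.survival, curve.at_risk):
                km_rows.append({"risk_group": name, "time": tt, "survival": s, "at_risk": nar})
        km_path = outdir / "km_curves.tsv"
        pd.DataFrame(km_rows).to_csv(km_path, sep="\t", index=False)
        outputs.append(km_path)

        lr = logrank_test(high["time"], high["event"], low["time"], low["event"])
        stats["logrank_p"] = lr.p_value
        stats["logrank_chi2"] = lr.statistic

        try:
            cox = cox_hazard_ratio(
                merged["time"], merged["event"], (merged["risk_group"] == "low").astype(int)
            )
            stats["hr"] = cox.hazard_ratio
            stats["hr_ci"] = [cox.ci_lower, cox.ci_upper]
            stats["hr_p"] = cox.p_value
            stats["hr_orientation"] = cox.orientation
        except ValueError as exc:
            log.warning("Cox model skipped: %s", exc)
            stats["hr_skipped"] = str(exc)

        overlap_cols = [c for c in merged.columns if c.startswith("n_overlap_")]
        marker = merged[overlap_cols].sum(axis=1).to_numpy(dtype=float)
        try:
            roc = roc_at_horizon(
                marker,
                merged["time"],
                merged["event"],
                horizon=config.horizon,
                n_boot=config.n_boot,
                seed=stage_seed(config.seed, "roc"),
            )
            stats["auc"] = roc.auc
            stats["auc_ci"] = [roc.ci_lower, roc.ci_upper]
            stats["n_cases"] = roc.n_cases
            stats["n_controls"] = roc.n_controls
            stats["n_excluded_censored"] = roc.n_excluded_censored
        except ValueError as exc:
            log.warning("horizon ROC skipped: %s", exc)
            stats["auc_skipped"] = str(exc)

    stats_path = outdir / "stats.json"
    stats_path.write_text(json.dumps(stats, indent=2, sort_keys=True))
    outputs.append(stats_path)

    manifest = {
        "kind": "validation",
        "version": __version__,
        "config": config.to_dict(),
        "n_high": int(len(high)),
        "n_low": int(len(low)),
        "stats": stats,
        "wall_s": round(time.time() - t0, 3),
        "checksums": _checksum_outputs(outdir, outputs),
    }
    _write_manifest(outdir, manifest)
    return manifest


def run_all(config: PipelineConfig) -> dict:
    """Discovery followed by validation on the same cohort; combined manifest."""
    discovery = run_discovery(config)
    rois = discovery.pop("_rois")
    masks = discovery.pop("_masks")
    clinical = discovery.pop("_clinical")
    validation = run_validation(config, rois, masks=masks, clinical=clinical)
    outdir = Path(config.output_dir)
    combined = {
        "kind": "run_all",
        "version": __version__,
        "config": config.to_dict(),
        "discovery": {k: v for k, v in discovery.items() if k != "config"},
        "validation": {k: v for k, v in validation.items() if k != "config"},
    }
    _write_manifest(outdir, combined)
    return combined
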