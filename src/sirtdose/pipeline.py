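"""Per-case and cohort orchestration.

One case runs: load → resample to the reference grid (the simulation
count map's grid by default) → small-lesion exclusion → VOI derivation →
self-calibration of both arms → LDM dose maps → per-VOI metric panel and
TNR, emitted as one flat record. A cohort run aggregates records into the
four standard agreement tables. Case-level failures are isolated: a
corrupt case is logged and skipped, never aborting the cohort.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import grids
from .dosimetry import ActivityBudget, PhysicsConstants, build_dose_maps
from .grids import MIN_LESION_ML, ScalarMap, VoxelGrid, derive_vois, exclude_small_lesions
from .metrics import metrics_panel
from .stats import TL_VOLUME_THRESHOLD_ML, table1, table2, table3, table4

logger = logging.getLogger("sirtdose")


@dataclass
class PatientCase:
    """Paired simulation/therapy count maps, contours and metadata."""

    case_id: str
    sim_counts: ScalarMap
    ther_counts: ScalarMap
    liver: np.ndarray
    lobe: np.ndarray
    lesions: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)
    #: grids the masks live on, when different from the map grids
    mask_grid: VoxelGrid | None = None

    def budget(self, apply_lsf: bool = False, use_residual: bool = True) -> ActivityBudget:
        return ActivityBudget(
            A_injected_GBq=float(self.meta["a_injected_gbq"]),
            A_residual_GBq=float(self.meta.get("a_residual_gbq", 0.0)),
            LSF=float(self.meta.get("lsf_percent", 0.0)) / 100.0,
            apply_lsf=apply_lsf,
            use_residual=use_residual,
        )


@dataclass
class RunConfig:
    """Batch-run configuration; round-trips through YAML unchanged."""

    calibration_region: str = "liver"     # "liver" or "fov"
    apply_lsf: bool = False
    use_residual: bool = True
    min_lesion_ml: float = MIN_LESION_ML
    strata_threshold_ml: float = TL_VOLUME_THRESHOLD_ML
    paired_test: bool = False
    clip_lobe_to_liver: bool = True
    t_half_h: float = 64.1
    e_mean_mev: float = 0.93
    density_g_ml: float = 1.05
    output_dir: str = "out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.calibration_region not in ("liver", "fov"):
            raise ValueError("calibration_region must be 'liver' or 'fov'")
        if self.strata_threshold_ml <= 0:
            raise ValueError("strata threshold must be positive")

    @property
    def constants(self) -> PhysicsConstants:
        return PhysicsConstants(T_half_h=self.t_half_h, E_mean_MeV=self.e_mean_mev,
                                density_g_ml=self.density_g_ml)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def load_case(row: Mapping, base_dir: str | Path = ".") -> PatientCase:
    """Build a case from one manifest row of file paths + metadata.

    Expected columns: case_id, sim_path, ther_path, liver_path, lobe_path,
    lesion_paths (';'-separated), a_injected_gbq, a_residual_gbq,
    lsf_percent, treated_lobe, waiting_days.
    """
    base = Path(base_dir)
    sim = grids.load_map(base / str(row["sim_path"]), "counts")
    ther = grids.load_map(base / str(row["ther_path"]), "counts")
    liver, mask_grid = grids.load_mask(base / str(row["liver_path"]))
    lobe, _ = grids.load_mask(base / str(row["lobe_path"]))
    lesions: dict[str, np.ndarray] = {}
    lesion_paths = str(row.get("lesion_paths", "") or "")
    for i, p in enumerate(x for x in lesion_paths.split(";") if x):
        lesions[f"lesion_{i + 1:02d}"], _ = grids.load_mask(base / p)
    meta = {k: row[k] for k in row.keys()
            if not str(k).endswith("_path") and k != "lesion_paths"}
    return PatientCase(str(row["case_id"]), sim, ther, liver, lobe, lesions,
                       meta=dict(meta), mask_grid=mask_grid)


def run_case(case: PatientCase, config: RunConfig = RunConfig()) -> dict:
    """Execute the full dosimetry chain for one case; returns a flat record."""
    ref = case.sim_counts.grid
    sim = case.sim_counts
    ther = grids.resample_to_reference(case.ther_counts, ref, "trilinear")
    mask_grid = case.mask_grid or ref
    liver = grids.resample_mask_to_reference(case.liver, mask_grid, ref)
    lobe = grids.resample_mask_to_reference(case.lobe, mask_grid, ref)
    lesions = {k: grids.resample_mask_to_reference(m, mask_grid, ref)
               for k, m in case.lesions.items()}

    retained, excluded = exclude_small_lesions(lesions, ref, config.min_lesion_ml)
    vois = derive_vois(liver, lobe, retained, ref)
    if not config.clip_lobe_to_liver:
        vois.masks["NTLt"] = lobe & ~vois["TL"]

    budget = case.budget(apply_lsf=config.apply_lsf, use_residual=config.use_residual)
    region = vois["liver"] if config.calibration_region == "liver" else np.ones(ref.shape, bool)
    dose_maps = build_dose_maps(sim, ther, region, budget, config.constants)
    panels, tnrs = metrics_panel(dose_maps, vois, budget.A_net_GBq, config.density_g_ml)

    record: dict = {
        "case_id": case.case_id,
        "a_injected_gbq": budget.A_injected_GBq,
        "a_residual_gbq": budget.A_residual_GBq,
        "a_net_gbq": budget.A_net_GBq,
        "lsf_percent": case.meta.get("lsf_percent", np.nan),
        "treated_lobe": case.meta.get("treated_lobe", ""),
        "waiting_days": case.meta.get("waiting_days", np.nan),
        "sex": case.meta.get("sex", ""),
        "n_lesions": len(retained),
        "n_excluded_lesions": len(excluded),
        "tl_excluded": not vois["TL"].any(),
        "liver_volume_ml": vois.volume_ml("liver"),
        "tl_volume_ml": vois.volume_ml("TL"),
        "ntlt_volume_ml": vois.volume_ml("NTLt"),
        "ntlw_volume_ml": vois.volume_ml("NTLw"),
    }
    if record["tl_excluded"]:
        logger.warning("case %s: all lesions under %.1f ml; TL metrics absent",
                       case.case_id, config.min_lesion_ml)
    for p in panels:
        for x, v in p.d_per_gbq.items():
            record[f"{p.voi_label}_D{x}_{p.arm}_per_gbq"] = v
            record[f"{p.voi_label}_D{x}_{p.arm}_gy"] = p.d_gy[x]
        for x, v in p.v_pct.items():
            record[f"{p.voi_label}_V{x}_{p.arm}_pct"] = v
        record[f"{p.voi_label}_MAD_{p.arm}_per_gbq"] = p.mad_per_gbq
        record[f"{p.voi_label}_MAD_{p.arm}_gy"] = p.mad_gy
    for key, res in tnrs.items():
        record[key] = res.tnr if res.tnr is not None else np.nan
    return record


@dataclass
class CohortResult:
    records: pd.DataFrame
    tables: dict[str, pd.DataFrame]
    failures: dict[str, str]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out / "records.csv", index=False)
        for name, tab in self.tables.items():
            tab.to_csv(out / f"{name}.csv", index=False)
        (out / "run_log.json").write_text(json.dumps(
            {"n_cases": len(self.records), "failures": self.failures}, indent=2))


def run_cohort(cases: Sequence[PatientCase], config: RunConfig = RunConfig()) -> CohortResult:
    """Run every case, aggregate records, and build the cohort tables.

    Individual case failures are recorded and skipped; at least two
    successful cases are required for the agreement statistics.
    """
    records: list[dict] = []
    failures: dict[str, str] = {}
    for case in cases:
        try:
            records.append(run_case(case, config))
        except Exception as exc:  # noqa: BLE001 - failure isolation by design
            failures[case.case_id] = str(exc)
            logger.error("case %s failed: %s", case.case_id, exc)
    if len(records) < 2:
        raise ValueError(f"cohort statistics need >= 2 successful cases, got {len(records)}")
    df = pd.DataFrame.from_records(records).sort_values("case_id").reset_index(drop=True)
    analysable = df[~df["tl_excluded"]].reset_index(drop=True)
    tables = {
        "table1_cohort": table1(df),
        "table2_metrics": table2(analysable),
        "table3_volume_strata": table3(analysable, config.strata_threshold_ml),
        "table4_tnr": table4(analysable, config.strata_threshold_ml),
    }
    return CohortResult(df, tables, failures)


def run_manifest(manifest_path: str | Path, config: RunConfig = RunConfig()) -> CohortResult:
    """Run a cohort described by a CSV manifest (one row per case)."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    base = manifest_path.parent
    cases: list[PatientCase] = []
    failures: dict[str, str] = {}
    for _, row in manifest.iterrows():
        try:
            cases.append(load_case(row, base))
        except Exception as exc:  # noqa: BLE001
            failures[str(row.get("case_id", "?"))] = str(exc)
            logger.error("case %s could not be loaded: %s", row.get("case_id", "?"), exc)
    result = run_cohort(cases, config)
    result.failures.update(failures)
    return result


def write_case_files(case: PatientCase, out_dir: str | Path) -> dict:
    """Write one case's volumes/masks to disk; returns its manifest row."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cid = case.case_id
    grids.save_map(case.sim_counts, out / f"{cid}_sim.nii.gz")
    grids.save_map(case.ther_counts, out / f"{cid}_ther.nii.gz")
    grid = case.mask_grid or case.sim_counts.grid
    grids.save_mask(case.liver, grid, out / f"{cid}_liver.nii.gz")
    grids.save_mask(case.lobe, grid, out / f"{cid}_lobe.nii.gz")
    lesion_paths = []
    for name, m in case.lesions.items():
        p = out / f"{cid}_{name}.nii.gz"
        grids.save_mask(m, grid, p)
        lesion_paths.append(p.name)
    row = dict(case.meta)
    row.update({
        "case_id": cid,
        "sim_path": f"{cid}_sim.nii.gz",
        "ther_path": f"{cid}_ther.nii.gz",
        "liver_path": f"{cid}_liver.nii.gz",
        "lobe_path": f"{cid}_lobe.nii.gz",
        "lesion_paths": ";".join(lesion_paths),
    })
    return row
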