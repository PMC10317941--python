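"""Self-calibrated activity maps and local-deposition (LDM) dose maps.

The model: ⁹⁰Y microspheres are permanently trapped (physical decay only,
no biological clearance), all of the net administered activity stays in
the liver (no extra-hepatic shunt), and each voxel absorbs the full beta
energy emitted within it (local energy deposition, no cross-voxel
transport). Under these assumptions a SPECT count map, which carries no
absolute calibration of its own, is *self-calibrated*: voxel counts are
scaled so the summed activity over a reference region (the whole liver by
default) equals the net administered ⁹⁰Y activity. The absorbed dose per
voxel is then

    D_v = Ã_v · E_mean · (J/MeV) / m_voxel,   Ã_v = A_v · T_half / ln 2,

with Ã_v the time-integrated activity of the permanently trapped source
and m_voxel the voxel mass at constant liver density.

Both arms of a treatment are converted identically: the pre-therapy
⁹⁹ᵐTc-MAA count map serves purely as a spatial surrogate for the ⁹⁰Y
microsphere distribution and is calibrated to the same ⁹⁰Y net activity
and decay constants — no ⁹⁹ᵐTc physics enters anywhere.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .grids import LIVER_DENSITY_G_ML, ScalarMap

logger = logging.getLogger("sirtdose")

SECONDS_PER_HOUR = 3600.0
JOULES_PER_MEV = 1.602176634e-13


@dataclass(frozen=True)
class PhysicsConstants:
    """⁹⁰Y decay and tissue constants.

    T_half_h : physical half-life, hours (64.1 h).
    E_mean_MeV : mean beta energy released per decay, MeV (0.93).
    density_g_ml : liver tissue density, g/cm^3 (1.05).
    """

    T_half_h: float = 64.1
    E_mean_MeV: float = 0.93
    density_g_ml: float = LIVER_DENSITY_G_ML
    joules_per_MeV: float = JOULES_PER_MEV

    def __post_init__(self) -> None:
        for name in ("T_half_h", "E_mean_MeV", "density_g_ml", "joules_per_MeV"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class ActivityBudget:
    """Administered-activity bookkeeping for one treatment.

    A_net = (A_injected − A_residual) · (1 − LSF·[apply_lsf]); the residual
    is the activity measured left in the delivery vial. The lung-shunt
    correction is off by default (the no-shunt assumption of the dose
    model); both toggles are exposed.
    """

    A_injected_GBq: float
    A_residual_GBq: float = 0.0
    LSF: float = 0.0
    apply_lsf: bool = False
    use_residual: bool = True

    def __post_init__(self) -> None:
        if self.A_injected_GBq <= 0:
            raise ValueError("injected activity must be positive")
        if not 0.0 <= self.A_residual_GBq < self.A_injected_GBq:
            raise ValueError(
                f"residual activity {self.A_residual_GBq} GBq must be in "
                f"[0, injected {self.A_injected_GBq} GBq)"
            )
        if not 0.0 <= self.LSF < 1.0:
            raise ValueError("LSF must be a fraction in [0, 1)")

    @property
    def A_net_GBq(self) -> float:
        a = self.A_injected_GBq - (self.A_residual_GBq if self.use_residual else 0.0)
        if self.apply_lsf:
            a *= 1.0 - self.LSF
        return a


def net_activity(budget: ActivityBudget) -> float:
    """Net ⁹⁰Y activity reaching the liver, GBq."""
    a = budget.A_net_GBq
    logger.info(
        "net activity: %.4f GBq (injected %.4f, residual %.4f, LSF %.3f applied=%s)",
        a, budget.A_injected_GBq, budget.A_residual_GBq, budget.LSF, budget.apply_lsf,
    )
    return a


def self_calibrate(counts: ScalarMap, region: np.ndarray, A_net_GBq: float) -> ScalarMap:
    """Scale a count map so region activity sums to the net activity.

    A_v = counts_v / Σ_region counts · A_net·1e9 Bq for voxels inside the
    calibration region; voxels outside the region get zero activity
    (counts there are treated as extra-hepatic signal outside the model).
    """
    region = np.asarray(region, dtype=bool)
    if region.shape != counts.grid.shape:
        raise ValueError("calibration region does not match the count-map grid")
    total = float(counts.values[region].sum())
    if total <= 0.0:
        raise ValueError("zero total counts in the calibration region")
    activity = np.zeros(counts.grid.shape, dtype=np.float64)
    activity[region] = counts.values[region] * (A_net_GBq * 1e9 / total)
    return ScalarMap(counts.grid, activity, "activity_Bq")


def dose_factor(constants: PhysicsConstants = PhysicsConstants()) -> float:
    """LDM conversion factor, Gy·kg per GBq of permanently trapped ⁹⁰Y.

    (T_half/ln 2) · E_mean · (J/MeV) · 1e9 ≈ 49.6 Gy·kg/GBq at defaults.
    """
    t_half_s = constants.T_half_h * SECONDS_PER_HOUR
    return (t_half_s / math.log(2.0)) * constants.E_mean_MeV * constants.joules_per_MeV * 1e9


def ldm_dose_map(activity: ScalarMap, constants: PhysicsConstants = PhysicsConstants()) -> ScalarMap:
    """Absorbed-dose map (Gy) from an activity map (Bq), local deposition.

    Each voxel's dose depends only on that voxel's activity — no energy
    cross-talk between voxels.
    """
    if activity.kind != "activity_Bq":
        raise ValueError(f"expected an activity map, got kind={activity.kind!r}")
    voxel_mass_kg = activity.grid.voxel_volume_ml * constants.density_g_ml / 1000.0
    gy_per_bq = dose_factor(constants) * 1e-9 / voxel_mass_kg
    return ScalarMap(activity.grid, activity.values * gy_per_bq, "dose_Gy")


def build_dose_maps(
    sim_counts: ScalarMap,
    ther_counts: ScalarMap,
    calibration_region: np.ndarray,
    budget: ActivityBudget,
    constants: PhysicsConstants = PhysicsConstants(),
) -> dict[str, ScalarMap]:
    """Calibrate both arms to the same ⁹⁰Y net activity and convert to dose.

    Returns ``{"sim_activity", "ther_activity", "sim_dose", "ther_dose"}``.
    Because calibration removes any global count scale, identical count
    distributions give identical dose maps regardless of absolute counts.
    """
    a_net = net_activity(budget)
    sim_activity = self_calibrate(sim_counts, calibration_region, a_net)
    ther_activity = self_calibrate(ther_counts, calibration_region, a_net)
    return {
        "sim_activity": sim_activity,
        "ther_activity": ther_activity,
        "sim_dose": ldm_dose_map(sim_activity, constants),
        "ther_dose": ldm_dose_map(ther_activity, constants),
    }
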