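"""Per-VOI dose metrics: mean absorbed dose, cumulative DVH, Dx, Vx, TNR.

Definitions (voxel doses d_1..d_N within a VOI, uniform voxel volume):

* MAD — arithmetic mean of the voxel doses, Gy.
* Cumulative DVH — F(d) = percentage of the VOI volume receiving at least
  d Gy; an exact right-continuous step function of the voxel doses.
* Dx — the minimum dose received by the hottest x% of the volume,
  evaluated on the exact step DVH as sup{d : F(d) >= x}, i.e. the
  ceil(x·N/100)-th largest voxel dose. No interpolation (a linearly
  interpolated variant is available for plot parity).
* Vx — 100 · #{v : d_v >= x} / N, the percentage of the volume receiving
  at least x Gy.
* TNR — ratio of specific activities, (A_TL/M_TL) / (A_NTL/M_NTL), with
  activities summed from the activity map and masses from voxel counting
  at constant density. Invariant to any global rescaling of the activity
  map, so it needs no absolute calibration.

The standard panel reports MAD and D50/D70/D95 for every VOI, V120/V205
for tumoral liver (therapy-response cutoffs) and V20/V50/V90 for
non-tumoral liver (normal-tissue limits), in absolute Gy and normalized
Gy per GBq of net administered activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import LIVER_DENSITY_G_ML, ScalarMap, VOISet, VoxelGrid, voi_mass_kg

D_LEVELS = (50, 70, 95)
V_LEVELS_TL = (120, 205)
V_LEVELS_NTL = (20, 50, 90)


def _voi_doses(dose_map: ScalarMap, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dose_map.grid.shape:
        raise ValueError("mask does not match the dose-map grid")
    if not mask.any():
        raise ValueError("empty mask")
    return dose_map.values[mask]


def mean_absorbed_dose(dose_map: ScalarMap, mask: np.ndarray) -> float:
    """Mean absorbed dose over the VOI, Gy."""
    return float(_voi_doses(dose_map, mask).mean())


@dataclass
class DVH:
    """Exact cumulative dose-volume histogram of one VOI.

    ``doses_desc`` holds the voxel doses sorted descending; F(d) is the
    percentage of voxels with dose >= d.
    """

    doses_desc: np.ndarray

    @property
    def n(self) -> int:
        return self.doses_desc.size

    def volume_pct_at(self, dose: float | np.ndarray) -> np.ndarray | float:
        """F(d): percent of the VOI receiving at least ``dose`` Gy."""
        d = np.asarray(dose, dtype=float)
        asc = self.doses_desc[::-1]
        count = self.n - np.searchsorted(asc, d, side="left")
        out = 100.0 * count / self.n
        return float(out) if out.ndim == 0 else out

    def dose_at(self, x: float, interpolate: bool = False) -> float:
        """Dx: sup{d : F(d) >= x} == the ceil(x·N/100)-th largest dose."""
        if not 0.0 < x <= 100.0:
            raise ValueError(f"x must be in (0, 100], got {x}")
        if not interpolate:
            k = int(np.ceil(x * self.n / 100.0))
            return float(self.doses_desc[k - 1])
        # plot-parity variant: linear interpolation between sorted doses
        ranks = 100.0 * (np.arange(1, self.n + 1)) / self.n
        return float(np.interp(x, ranks, self.doses_desc))

    def binned(self, bin_width_gy: float = 1.0) -> pd.DataFrame:
        """Binned export for plotting (never used for metric computation)."""
        top = float(self.doses_desc[0]) if self.n else 0.0
        edges = np.arange(0.0, top + 2 * bin_width_gy, bin_width_gy)
        return pd.DataFrame({"dose_Gy": edges, "volume_pct": self.volume_pct_at(edges)})


def cumulative_dvh(dose_map: ScalarMap, mask: np.ndarray) -> DVH:
    doses = _voi_doses(dose_map, mask)
    return DVH(np.sort(doses)[::-1].copy())


def dose_at_volume(dose_map: ScalarMap, mask: np.ndarray, x: float, interpolate: bool = False) -> float:
    """Dx in Gy: minimum dose received by the hottest x% of the VOI."""
    return cumulative_dvh(dose_map, mask).dose_at(x, interpolate=interpolate)


def volume_at_dose(dose_map: ScalarMap, mask: np.ndarray, x_gy: float) -> float:
    """Vx in %: fraction of the VOI receiving at least x Gy."""
    if x_gy < 0:
        raise ValueError(f"dose threshold must be >= 0, got {x_gy}")
    doses = _voi_doses(dose_map, mask)
    return float(100.0 * np.count_nonzero(doses >= x_gy) / doses.size)


@dataclass
class TNRResult:
    """Tumour-to-normal ratio of specific activity and its ingredients."""

    tnr: float | None
    A_TL_Bq: float
    A_NTL_Bq: float
    M_TL_kg: float
    M_NTL_kg: float


def tnr(
    activity_map: ScalarMap,
    tl_mask: np.ndarray,
    ntl_mask: np.ndarray,
    density_g_ml: float = LIVER_DENSITY_G_ML,
) -> TNRResult:
    """TNR = (A_TL/M_TL) / (A_NTL/M_NTL); ``tnr=None`` when A_NTL is zero."""
    tl_mask = np.asarray(tl_mask, dtype=bool)
    ntl_mask = np.asarray(ntl_mask, dtype=bool)
    if not tl_mask.any() or not ntl_mask.any():
        raise ValueError("TNR requires non-empty TL and NTL masks")
    grid = activity_map.grid
    a_tl = float(activity_map.values[tl_mask].sum())
    a_ntl = float(activity_map.values[ntl_mask].sum())
    m_tl = voi_mass_kg(tl_mask, grid, density_g_ml)
    m_ntl = voi_mass_kg(ntl_mask, grid, density_g_ml)
    if a_ntl <= 0.0:
        value = None  # undefined, reported as missing downstream
    else:
        value = (a_tl / m_tl) / (a_ntl / m_ntl)
    return TNRResult(value, a_tl, a_ntl, m_tl, m_ntl)


@dataclass
class DoseMetrics:
    """Panel of dose metrics for one VOI in one arm."""

    voi_label: str
    arm: str
    mad_gy: float
    mad_per_gbq: float
    d_gy: dict[int, float] = field(default_factory=dict)
    d_per_gbq: dict[int, float] = field(default_factory=dict)
    v_pct: dict[int, float] = field(default_factory=dict)
    voxel_count: int = 0
    volume_ml: float = 0.0

    def to_records(self) -> list[dict]:
        rows = [dict(voi=self.voi_label, arm=self.arm, metric="MAD",
                     value_gy=self.mad_gy, value_per_gbq=self.mad_per_gbq, value_pct=None)]
        for x in sorted(self.d_gy):
            rows.append(dict(voi=self.voi_label, arm=self.arm, metric=f"D{x}",
                             value_gy=self.d_gy[x], value_per_gbq=self.d_per_gbq[x], value_pct=None))
        for x in sorted(self.v_pct):
            rows.append(dict(voi=self.voi_label, arm=self.arm, metric=f"V{x}",
                             value_gy=None, value_per_gbq=None, value_pct=self.v_pct[x]))
        return rows


def _panel_one(dose_map: ScalarMap, mask: np.ndarray, voi: str, arm: str,
               a_net_gbq: float, v_levels: tuple[int, ...]) -> DoseMetrics:
    dvh = cumulative_dvh(dose_map, mask)
    mad = float(dvh.doses_desc.mean())
    d_gy = {x: dvh.dose_at(x) for x in D_LEVELS}
    v_pct = {x: float(dvh.volume_pct_at(float(x))) for x in v_levels}
    grid = dose_map.grid
    n = int(np.count_nonzero(mask))
    return DoseMetrics(
        voi_label=voi, arm=arm,
        mad_gy=mad, mad_per_gbq=mad / a_net_gbq,
        d_gy=d_gy, d_per_gbq={x: v / a_net_gbq for x, v in d_gy.items()},
        v_pct=v_pct, voxel_count=n, volume_ml=n * grid.voxel_volume_ml,
    )


def metrics_panel(
    dose_maps: dict[str, ScalarMap],
    vois: VOISet,
    a_net_gbq: float,
    density_g_ml: float = LIVER_DENSITY_G_ML,
) -> tuple[list[DoseMetrics], dict[str, TNRResult]]:
    """Full per-VOI metric panel for both arms, plus the four TNR values.

    ``dose_maps`` is the output of :func:`sirtdose.dosimetry.build_dose_maps`.
    TL uses V120/V205; NTLt and NTLw use V20/V50/V90. Normalized values are
    Gy per GBq of net activity. VOIs that are empty (e.g. TL when all
    lesions were excluded) are skipped.
    """
    if a_net_gbq <= 0:
        raise ValueError("A_net must be positive")
    panels: list[DoseMetrics] = []
    for arm in ("sim", "ther"):
        dose = dose_maps[f"{arm}_dose"]
        for voi, v_levels in (("TL", V_LEVELS_TL), ("NTLt", V_LEVELS_NTL), ("NTLw", V_LEVELS_NTL)):
            if voi in vois and vois[voi].any():
                panels.append(_panel_one(dose, vois[voi], voi, arm, a_net_gbq, v_levels))
    tnrs: dict[str, TNRResult] = {}
    if "TL" in vois and vois["TL"].any():
        for arm in ("sim", "ther"):
            act = dose_maps[f"{arm}_activity"]
            for ntl in ("NTLt", "NTLw"):
                if ntl in vois and vois[ntl].any():
                    tnrs[f"tnr_{ntl.lower()}_{arm}"] = tnr(act, vois["TL"], vois[ntl], density_g_ml)
    return panels, tnrs


def absolute_from_normalized(value_per_gbq: float, a_gbq: float) -> float:
    """Rescale a normalized metric (Gy/GBq) to absolute Gy at a given activity."""
    return value_per_gbq * a_gbq
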