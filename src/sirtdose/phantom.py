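"""Synthetic paired-case generator for simulation/therapy SPECT dosimetry.

Each case emulates one radioembolization treatment: an ellipsoidal liver
on a 64^3 grid of 4-mm voxels, a half-space targeted lobe, spherical
lesions, and a latent specific-uptake map u(v) in which tumour voxels
take, on average, TNR_true times the normal-tissue uptake. Voxel-scale
heterogeneity is multiplicative mean-corrected lognormal (mu = -sigma^2/2,
so the expected uptake is unbiased and TNR_true is the expected
specific-uptake ratio), with tumour tissue more heterogeneous than normal
tissue.

The therapy count map is Poisson(count_scale · normalize(blur(u, PSF)));
the isotropic Gaussian PSF models imaging blur applied to the expected
counts before counting noise. The simulation (⁹⁹ᵐTc-MAA) map starts from
a discordant latent u·ε, with ε voxelwise mean-corrected lognormal
discordance (SD ``tau_tumor`` in tumour, ``tau_normal`` elsewhere), imaged
through the same PSF; the tumour-specific overestimation is then applied
to the *expected count map* as a redistribution at fixed total: tumour
voxels are multiplied by ``bias_tumor`` and all other voxels by the
compensating factor. Two properties motivate this definition. First,
self-calibration pins both arms to the same net activity, so only a
redistribution (not a global rescaling) is observable. Second, applying
the bias after the PSF makes ``bias_tumor`` the *measured* discordance:
the expected tumour dose ratio simulation/therapy equals ``bias_tumor``
exactly, so the parameter is recoverable by the pipeline at high counts
and e.g. 1.26 yields a ~26% mean tumour overestimation. (With the PSF
disabled this is identical to biasing the latent uptake itself.)

Cohort generation draws per-case parameters (administered activity,
tumour burden spanning the 200-ml strata, TNR, per-case tumour bias with
lognormal spread) from distributions shaped like the cohort the analysis
protocol expects, and is bit-reproducible from a single seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .dosimetry import ActivityBudget, PhysicsConstants, ldm_dose_map, self_calibrate
from .grids import MIN_LESION_ML, ScalarMap, VOISet, VoxelGrid, derive_vois, exclude_small_lesions
from .metrics import DoseMetrics, TNRResult, metrics_panel
from .pipeline import PatientCase

FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class PhantomParams:
    """Generator settings for one synthetic treatment."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    liver_semi_axes_mm: tuple[float, float, float] = (95.0, 75.0, 55.0)
    #: x-position of the lobar split plane, as a fraction of the liver
    #: x-extent from its left edge; the right lobe is the larger side.
    lobe_split_fraction: float = 0.35
    treated_lobe: str = "right"
    #: lesions as (centre_mm, radius_mm) in physical coordinates
    tumors: tuple[tuple[tuple[float, float, float], float], ...] = (((170.0, 128.0, 128.0), 30.0),)
    tnr_true: float = 2.5
    sigma_normal: float = 0.3
    sigma_tumor: float = 0.5
    tau_normal: float = 0.15
    tau_tumor: float = 0.35
    bias_tumor: float = 1.26
    psf_fwhm_mm: float = 12.0
    #: therapy-arm PSF; None = same as simulation (a larger value mimics
    #: the poorer resolution of bremsstrahlung SPECT)
    psf_fwhm_mm_ther: float | None = None
    count_scale: float = 2.0e6
    poisson: bool = True
    A_injected_GBq: float = 2.6
    residual_fraction: float = 0.02
    lsf_percent: float = 8.0
    waiting_days: int = 21
    sex: str = "F"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tnr_true <= 0 or self.bias_tumor <= 0 or self.count_scale <= 0:
            raise ValueError("tnr_true, bias_tumor and count_scale must be positive")
        for name in ("sigma_normal", "sigma_tumor", "tau_normal", "tau_tumor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.treated_lobe not in ("left", "right"):
            raise ValueError("treated_lobe must be 'left' or 'right'")
        if not 0.0 < self.lobe_split_fraction < 1.0:
            raise ValueError("lobe_split_fraction must be in (0, 1)")

    @property
    def grid(self) -> VoxelGrid:
        return VoxelGrid(self.shape, self.spacing_mm)


@dataclass
class GroundTruth:
    """Noise-free reference for recovery tests."""

    latent_uptake: ScalarMap          # therapy-arm latent u(v), arbitrary units
    sim_latent_uptake: ScalarMap      # discordant simulation-arm latent
    tnr_param: float                  # the TNR_true parameter
    tnr_latent: float                 # realized specific-uptake ratio of u(v)
    bias_tumor: float
    vois: VOISet
    a_net_gbq: float


def _coords(grid: VoxelGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axes = [np.arange(n) * s for n, s in zip(grid.shape, grid.spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(grid: VoxelGrid, center: Sequence[float], semi_axes: Sequence[float]) -> np.ndarray:
    x, y, z = _coords(grid)
    q = sum(((c - c0) / a) ** 2 for c, c0, a in zip((x, y, z), center, semi_axes))
    return q <= 1.0


def _sphere(grid: VoxelGrid, center: Sequence[float], radius: float) -> np.ndarray:
    return _ellipsoid(grid, center, (radius, radius, radius))


def _mean_corrected_lognormal(rng: np.random.Generator, sigma: float, n: int) -> np.ndarray:
    """Multiplicative noise with E[factor] = 1 (mu = -sigma^2/2)."""
    if sigma == 0.0:
        return np.ones(n)
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n))


def _blur(values: np.ndarray, fwhm_mm: float, spacing: Sequence[float]) -> np.ndarray:
    if fwhm_mm <= 0.0:
        return values
    sigma_vox = [fwhm_mm / FWHM_TO_SIGMA / s for s in spacing]
    return gaussian_filter(values, sigma=sigma_vox, mode="constant")


def _expected_counts(latent: np.ndarray, params: PhantomParams, fwhm_mm: float) -> np.ndarray:
    blurred = _blur(latent, fwhm_mm, params.spacing_mm)
    total = blurred.sum()
    if total <= 0:
        raise ValueError("degenerate geometry: no uptake anywhere")
    return params.count_scale * blurred / total


def _redistribute_tumor_bias(values: np.ndarray, tl: np.ndarray, region: np.ndarray,
                             bias: float) -> np.ndarray:
    """Multiply tumour voxels by ``bias`` and compensate within ``region``.

    The total over ``region`` (the liver, i.e. the self-calibration
    region) is preserved exactly, so the operation commutes with
    calibration and ``bias`` equals the expected tumour dose ratio
    between the two arms.
    """
    if bias == 1.0 or not tl.any():
        return values
    rest = region & ~tl
    s_reg = float(values[region].sum())
    s_tl = float(values[tl].sum())
    if s_tl <= 0 or s_reg - s_tl <= 0:
        return values
    kappa = max((s_reg - bias * s_tl) / (s_reg - s_tl), 0.02)
    out = values.copy()
    out[tl] *= bias
    out[rest] *= kappa
    return out


def generate_case(params: PhantomParams, case_id: str = "phantom") -> tuple[PatientCase, GroundTruth]:
    """Generate one paired simulation/therapy case with ground truth.

    Deterministic for fixed ``params`` (including ``params.seed``).
    """
    grid = params.grid
    rng = np.random.default_rng(params.seed)
    center = tuple((n - 1) * s / 2.0 for n, s in zip(grid.shape, grid.spacing))
    liver = _ellipsoid(grid, center, params.liver_semi_axes_mm)
    if not liver.any():
        raise ValueError("degenerate geometry: empty liver")

    x, _, _ = _coords(grid)
    x_min = center[0] - params.liver_semi_axes_mm[0]
    x_split = x_min + params.lobe_split_fraction * 2.0 * params.liver_semi_axes_mm[0]
    right = x >= x_split
    lobe = right if params.treated_lobe == "right" else ~right

    lesions: dict[str, np.ndarray] = {}
    for i, (c, r) in enumerate(params.tumors):
        m = _sphere(grid, c, r)
        if not m.any():
            raise ValueError(f"tumour {i + 1} covers no voxels (radius {r} mm)")
        if (m & ~liver).any():
            raise ValueError(f"tumour {i + 1} extends outside the liver")
        lesions[f"lesion_{i + 1:02d}"] = m
    tl = np.zeros(grid.shape, dtype=bool)
    for m in lesions.values():
        tl |= m
    ntl = liver & ~tl

    # latent specific uptake: unbiased lognormal heterogeneity per tissue
    u = np.zeros(grid.shape)
    u[ntl] = _mean_corrected_lognormal(rng, params.sigma_normal, int(ntl.sum()))
    u[tl] = params.tnr_true * _mean_corrected_lognormal(rng, params.sigma_tumor, int(tl.sum()))

    # simulation-arm voxelwise discordance (tumour tissue more discordant)
    n_tl, n_ntl = int(tl.sum()), int(ntl.sum())
    u_sim = u.copy()
    u_sim[tl] *= _mean_corrected_lognormal(rng, params.tau_tumor, n_tl)
    u_sim[ntl] *= _mean_corrected_lognormal(rng, params.tau_normal, n_ntl)

    fwhm_sim = params.psf_fwhm_mm
    fwhm_ther = params.psf_fwhm_mm_ther if params.psf_fwhm_mm_ther is not None else fwhm_sim
    ther_expected = _expected_counts(u, params, fwhm_ther)
    sim_expected = _expected_counts(u_sim, params, fwhm_sim)
    sim_expected = _redistribute_tumor_bias(sim_expected, tl, liver, params.bias_tumor)
    u_sim = _redistribute_tumor_bias(u_sim, tl, liver, params.bias_tumor)  # PSF-free reference
    if params.poisson:
        ther_counts = rng.poisson(ther_expected).astype(np.float64)
        sim_counts = rng.poisson(sim_expected).astype(np.float64)
    else:
        ther_counts, sim_counts = ther_expected, sim_expected

    meta = {
        "case_id": case_id,
        "a_injected_gbq": params.A_injected_GBq,
        "a_residual_gbq": params.A_injected_GBq * params.residual_fraction,
        "lsf_percent": params.lsf_percent,
        "treated_lobe": params.treated_lobe,
        "waiting_days": params.waiting_days,
        "sex": params.sex,
        "seed": params.seed,
    }
    case = PatientCase(
        case_id=case_id,
        sim_counts=ScalarMap(grid, sim_counts, "counts"),
        ther_counts=ScalarMap(grid, ther_counts, "counts"),
        liver=liver, lobe=lobe, lesions=lesions,
        meta=meta,
    )
    budget = ActivityBudget(params.A_injected_GBq, meta["a_residual_gbq"])
    vois = derive_vois(liver, lobe, lesions, grid)
    a_tl = float(u[tl].sum()) if n_tl else 0.0
    a_ntl = float(u[ntl].sum())
    tnr_latent = (a_tl / n_tl) / (a_ntl / n_ntl) if n_tl and a_ntl > 0 else float("nan")
    truth = GroundTruth(
        latent_uptake=ScalarMap(grid, u, "counts"),
        sim_latent_uptake=ScalarMap(grid, u_sim, "counts"),
        tnr_param=params.tnr_true, tnr_latent=tnr_latent,
        bias_tumor=params.bias_tumor, vois=vois,
        a_net_gbq=budget.A_net_GBq,
    )
    return case, truth


def ground_truth_metrics(
    truth: GroundTruth,
    constants: PhysicsConstants = PhysicsConstants(),
    min_lesion_ml: float = MIN_LESION_ML,
) -> tuple[list[DoseMetrics], dict[str, TNRResult]]:
    """Metric panel from the noiseless latent map under exact calibration.

    This is the recovery target: the pipeline run on noisy counts should
    approach these values as counts grow and the PSF narrows.
    """
    vois = truth.vois
    grid = truth.latent_uptake.grid
    lesion_masks = {k: vois[k] for k in vois.labels() if k.startswith("lesion_")}
    retained, _ = exclude_small_lesions(lesion_masks, grid, min_lesion_ml)
    clean_vois = derive_vois(vois["liver"], vois["lobe"], retained, grid)
    activity = self_calibrate(truth.latent_uptake, clean_vois["liver"], truth.a_net_gbq)
    dose = ldm_dose_map(activity, constants)
    maps = {"sim_activity": activity, "ther_activity": activity,
            "sim_dose": dose, "ther_dose": dose}
    return metrics_panel(maps, clean_vois, truth.a_net_gbq, constants.density_g_ml)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortDistributions:
    """Per-case parameter distributions for synthetic cohorts.

    Location/scale choices follow the cohort structure the analysis
    expects: administered activity lognormal around 2.6 GBq, tumour burden
    right-skewed with substantial mass on both sides of the 200-ml
    stratification cut, TNR around 2.5, mostly single lesions, and a
    per-case lognormal spread of the tumour bias so that case-level
    tumour-dose relative differences scatter widely around the mean, as a
    real cohort's do.
    """

    a_injected_median_gbq: float = 2.6
    a_injected_sigma_log: float = 0.35
    a_injected_range_gbq: tuple[float, float] = (0.7, 6.0)
    residual_fraction_range: tuple[float, float] = (0.01, 0.05)
    lsf_median_pct: float = 8.0
    lsf_sigma_log: float = 0.5
    lsf_range_pct: tuple[float, float] = (0.5, 21.0)
    waiting_days_mean: float = 21.0
    waiting_days_sd: float = 7.0
    p_right_lobe: float = 0.76
    p_male: float = 0.18
    n_lesions_probs: tuple[float, ...] = (0.77, 0.09, 0.14)  # 1, 2, 3 lesions
    tl_volume_median_ml: float = 180.0
    tl_volume_sigma_log: float = 1.0
    tl_volume_range_ml: tuple[float, float] = (6.0, 450.0)
    tnr_median: float = 2.5
    tnr_sigma_log: float = 0.4
    tnr_range: tuple[float, float] = (1.2, 8.0)
    #: case-level lognormal spread of the tumour bias (mean-corrected, so
    #: the cohort-mean bias stays at PhantomParams.bias_tumor)
    bias_sigma_log: float = 0.25
    liver_scale_sigma_log: float = 0.08


def _clipped_lognormal(rng: np.random.Generator, median: float, sigma: float,
                       lo: float, hi: float) -> float:
    return float(np.clip(median * np.exp(rng.normal(0.0, sigma)), lo, hi))


def _place_tumors(
    rng: np.random.Generator,
    grid: VoxelGrid,
    center: tuple[float, float, float],
    semi_axes: tuple[float, float, float],
    x_split: float,
    treated_right: bool,
    volumes_ml: Sequence[float],
) -> tuple[tuple[tuple[float, float, float], float], ...]:
    """Spheres inside the liver ellipsoid, preferentially in the treated lobe."""
    from scipy.ndimage import distance_transform_edt

    coords = _coords(grid)
    liver = _ellipsoid(grid, center, semi_axes)
    # distance (mm) from each interior voxel to the liver boundary: a
    # sphere of radius r centred where dist > r + margin stays inside
    dist = distance_transform_edt(liver, sampling=grid.spacing)
    out = []
    margin = max(grid.spacing)
    for vol in volumes_ml:
        radius = (3.0 * vol * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
        radius = min(radius, float(dist.max()) - margin)
        for attempt in range(60):
            allowed = dist > radius + margin
            if attempt < 30:  # prefer the treated lobe; relax if it cannot fit
                side = coords[0] >= x_split + radius if treated_right else coords[0] <= x_split - radius
                allowed &= side
            idx = np.flatnonzero(allowed)
            if idx.size:
                flat = int(rng.choice(idx))
                ijk = np.unravel_index(flat, grid.shape)
                c = tuple(float(i * s) for i, s in zip(ijk, grid.spacing))
                out.append((c, float(radius)))
                break
            radius *= 0.9
        else:
            raise ValueError(f"could not place a tumour of {vol:.0f} ml inside the liver")
    return tuple(out)


def draw_case_params(
    rng: np.random.Generator,
    base: PhantomParams = PhantomParams(),
    dists: CohortDistributions = CohortDistributions(),
) -> PhantomParams:
    """Draw one case's parameters from the cohort distributions."""
    d = dists
    scale = float(np.exp(rng.normal(0.0, d.liver_scale_sigma_log)))
    semi_axes = tuple(a * scale for a in base.liver_semi_axes_mm)
    treated = "right" if rng.random() < d.p_right_lobe else "left"
    grid = base.grid
    center = tuple((n - 1) * s / 2.0 for n, s in zip(grid.shape, grid.spacing))
    x_split = center[0] - semi_axes[0] + base.lobe_split_fraction * 2.0 * semi_axes[0]

    n_lesions = int(rng.choice(np.arange(1, len(d.n_lesions_probs) + 1), p=d.n_lesions_probs))
    tl_total = _clipped_lognormal(rng, d.tl_volume_median_ml, d.tl_volume_sigma_log,
                                  *d.tl_volume_range_ml)
    weights = rng.dirichlet(np.full(n_lesions, 2.0))
    volumes = np.maximum(tl_total * weights, 5.0)
    tumors = _place_tumors(rng, grid, center, semi_axes, x_split,
                           treated == "right", volumes)

    bias = base.bias_tumor * float(
        np.exp(rng.normal(-0.5 * d.bias_sigma_log**2, d.bias_sigma_log))
    )
    return replace(
        base,
        liver_semi_axes_mm=semi_axes,
        treated_lobe=treated,
        tumors=tumors,
        tnr_true=_clipped_lognormal(rng, d.tnr_median, d.tnr_sigma_log, *d.tnr_range),
        bias_tumor=bias,
        A_injected_GBq=_clipped_lognormal(rng, d.a_injected_median_gbq,
                                          d.a_injected_sigma_log, *d.a_injected_range_gbq),
        residual_fraction=float(rng.uniform(*d.residual_fraction_range)),
        lsf_percent=_clipped_lognormal(rng, d.lsf_median_pct, d.lsf_sigma_log, *d.lsf_range_pct),
        waiting_days=int(np.clip(round(rng.normal(d.waiting_days_mean, d.waiting_days_sd)), 7, 47)),
        sex="M" if rng.random() < d.p_male else "F",
        seed=int(rng.integers(2**31)),
    )


def generate_cohort(
    n: int,
    seed: int = 0,
    base: PhantomParams = PhantomParams(),
    dists: CohortDistributions = CohortDistributions(),
) -> list[tuple[PatientCase, GroundTruth]]:
    """Generate ``n`` independent synthetic cases, reproducible from ``seed``."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        params = draw_case_params(rng, base, dists)
        out.append(generate_case(params, case_id=f"case_{i + 1:03d}"))
    return out
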