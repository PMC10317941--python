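"""Simulation-vs-therapy agreement statistics.

Cohort protocol: per metric and VOI the simulation (⁹⁹ᵐTc-MAA) and therapy
(⁹⁰Y) values are compared with the unpaired Mann–Whitney U (rank-sum)
test at α = 0.05, Pearson correlation with qualitative strength bands,
ordinary least-squares regression, per-case relative differences
100·(sim − ther)/ther (undefined when therapy is zero), Bland–Altman bias
with 95% limits of agreement, and Kruskal–Wallis tests for discrete
covariates. The tumour panel is additionally stratified by tumoral-liver
volume at 200 ml (≤ 200 ml inclusive in the small stratum). Voxel-wise
agreement within a VOI is summarised as a 2-D joint histogram with a
fitted regression line.

Notes on orientation and test choice:

* The primary two-sample test is the *unpaired* Mann–Whitney U applied to
  the two arms; a paired Wilcoxon signed-rank variant is available via
  ``paired=True`` for users who prefer a matched-pairs test.
* Regression is therapy (y) on simulation (x); because under tumour
  overestimation this slope drops below one, the result also carries the
  opposite orientation (``slope_sim_on_ther``), which exceeds one exactly
  when simulation overestimates therapy.
* Bland–Altman differences are therapy − simulation, so a negative bias
  means the simulation overestimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05

#: Half-open Pearson-|r| strength bands, exhaustive on [0, 1].
R_CATEGORIES = (
    (0.0, 0.3, "very weak"),
    (0.3, 0.5, "weak"),
    (0.5, 0.7, "moderate"),
    (0.7, 0.9, "strong"),
    (0.9, 1.0 + 1e-12, "very strong"),
)

#: Tumoral-liver volume cut separating the small/large strata, ml.
TL_VOLUME_THRESHOLD_ML = 200.0

#: Largest tie-free combined sample size handled by exact Mann-Whitney
#: enumeration; larger or tied samples use the tie- and continuity-
#: corrected normal approximation.
MW_EXACT_MAX_N = 12


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

def relative_difference_pct(sim, ther) -> np.ndarray | float:
    """100·(sim − ther)/ther; NaN where therapy is zero (undefined)."""
    sim = np.asarray(sim, dtype=float)
    ther = np.asarray(ther, dtype=float)
    out = np.full(np.broadcast(sim, ther).shape, np.nan)
    ok = ther != 0
    out[ok] = 100.0 * (np.broadcast_to(sim, out.shape)[ok] - np.broadcast_to(ther, out.shape)[ok]) \
        / np.broadcast_to(ther, out.shape)[ok]
    return float(out) if out.ndim == 0 else out


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test; returns (U of x, p).

    Exact null enumeration is used for small tie-free samples
    (m + n <= 12); otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    if tie_free and x.size + y.size <= MW_EXACT_MAX_N:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def categorize_r(r: float) -> str:
    """Strength label from |r| using half-open bands."""
    a = abs(float(r))
    if not np.isfinite(a) or a > 1.0 + 1e-9:
        raise ValueError(f"|r| must be in [0, 1], got {r}")
    for lo, hi, label in R_CATEGORIES:
        if lo <= a < hi:
            return label
    return "very strong"


def pearson_with_category(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, str]:
    """Sample Pearson r, its two-sided p, and the strength category."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for constant input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p), categorize_r(r)


def linear_fit(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Ordinary least squares of y on x with intercept; (slope, intercept)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("linear fit needs n >= 2")
    if np.ptp(x) == 0:
        raise ValueError("linear fit undefined for constant x")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept)


def bland_altman(sim: Sequence[float], ther: Sequence[float]) -> tuple[float, tuple[float, float]]:
    """Bland–Altman bias and 95% limits of agreement on d = ther − sim.

    bias = mean(d); limits = bias ± 1.96·SD(d) with the n−1 sample SD.
    """
    sim = np.asarray(sim, dtype=float)
    ther = np.asarray(ther, dtype=float)
    if sim.size != ther.size or sim.size < 2:
        raise ValueError("Bland–Altman needs paired samples with n >= 2")
    d = ther - sim
    bias = float(d.mean())
    half = 1.96 * float(d.std(ddof=1))
    return bias, (bias - half, bias + half)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and chi-squared p (k−1 df)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("Kruskal–Wallis needs >= 2 non-empty groups")
    if all(np.array_equal(g, groups[0]) for g in groups):
        return 0.0, 1.0  # identical groups: H is exactly 0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def stratify_by_tumor_volume(
    volumes_ml: Sequence[float],
    threshold_ml: float = TL_VOLUME_THRESHOLD_ML,
) -> dict[str, np.ndarray]:
    """Index masks for the small (≤ threshold, inclusive) / large strata."""
    v = np.asarray(volumes_ml, dtype=float)
    return {"small": v <= threshold_ml, "large": v > threshold_ml}


# ---------------------------------------------------------------------------
# Paired-metric comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    """Cohort agreement summary for one (VOI, metric) pair."""

    metric_id: str
    n_valid: int
    sim_mean: float
    sim_sd: float
    ther_mean: float
    ther_sd: float
    wilcoxon_p: float
    significant: bool
    pearson_r: float
    pearson_p: float
    r_category: str
    slope: float              # therapy on simulation
    intercept: float
    slope_sim_on_ther: float  # opposite orientation; > 1 under sim overestimation
    mean_rel_diff_pct: float
    rel_diff_range: tuple[float, float]
    rel_diff_defined: bool    # False when any case had a zero-therapy denominator
    bland_altman_bias: float
    bland_altman_limits: tuple[float, float]


def compare_paired(
    sim: Sequence[float],
    ther: Sequence[float],
    metric_id: str = "",
    paired: bool = False,
) -> ComparisonResult:
    """Full agreement panel for one metric across the cohort.

    Cases where either arm is missing (NaN) are dropped. ``paired=True``
    swaps the unpaired rank-sum test for the Wilcoxon signed-rank test.
    The per-case relative differences are averaged over the cases where
    they are defined; if any case is undefined the metric is flagged so
    tables can print "–".
    """
    sim = np.asarray(sim, dtype=float)
    ther = np.asarray(ther, dtype=float)
    if sim.size != ther.size:
        raise ValueError("sim and ther must be the same length")
    valid = np.isfinite(sim) & np.isfinite(ther)
    s, t = sim[valid], ther[valid]
    if s.size < 2:
        raise ValueError("need at least 2 valid paired cases")
    if paired:
        if np.allclose(s, t):
            p = 1.0
        else:
            p = float(sps.wilcoxon(s, t).pvalue)
    else:
        _, p = mann_whitney_u(s, t)
    degenerate = np.ptp(s) == 0 or np.ptp(t) == 0
    if degenerate:  # e.g. a Vx metric that is zero in every case
        r = rp = float("nan")
        cat = "undefined"
    elif s.size >= 3:
        r, rp, cat = pearson_with_category(s, t)
    else:  # two points: r is ±1 by construction, p carries no information
        r = float(np.sign((s[1] - s[0]) * (t[1] - t[0]))) or float("nan")
        rp = float("nan")
        cat = categorize_r(r) if np.isfinite(r) else "undefined"
    slope, intercept = linear_fit(s, t) if np.ptp(s) else (float("nan"), float("nan"))
    slope_rev = linear_fit(t, s)[0] if np.ptp(t) else float("nan")
    rd = relative_difference_pct(s, t)
    defined = np.isfinite(rd)
    if defined.any():
        rd_mean = float(np.mean(rd[defined]))
        rd_range = (float(np.min(rd[defined])), float(np.max(rd[defined])))
    else:
        rd_mean, rd_range = float("nan"), (float("nan"), float("nan"))
    bias, limits = bland_altman(s, t)
    return ComparisonResult(
        metric_id=metric_id, n_valid=int(s.size),
        sim_mean=float(s.mean()), sim_sd=float(s.std(ddof=1)),
        ther_mean=float(t.mean()), ther_sd=float(t.std(ddof=1)),
        wilcoxon_p=p, significant=p < ALPHA,
        pearson_r=r, pearson_p=rp, r_category=cat,
        slope=slope, intercept=intercept, slope_sim_on_ther=slope_rev,
        mean_rel_diff_pct=rd_mean, rel_diff_range=rd_range,
        rel_diff_defined=bool(defined.all()),
        bland_altman_bias=bias, bland_altman_limits=limits,
    )


# ---------------------------------------------------------------------------
# Voxel-wise joint histogram
# ---------------------------------------------------------------------------

@dataclass
class JointHistogram:
    """2-D histogram of paired voxel doses within a mask, plus OLS fits."""

    hist: np.ndarray
    sim_edges: np.ndarray
    ther_edges: np.ndarray
    slope: float              # therapy on simulation
    intercept: float
    slope_sim_on_ther: float
    n_voxels: int


def voxelwise_joint(sim_map, ther_map, mask: np.ndarray, n_bins: int = 64) -> JointHistogram:
    """Joint histogram of (sim, ther) voxel doses and fitted lines.

    The histogram mass equals the number of mask voxels; the line is OLS
    of the therapy voxel dose on the simulation voxel dose (with the
    opposite orientation carried alongside).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    xs = sim_map.values[mask]
    ys = ther_map.values[mask]
    hist, xe, ye = np.histogram2d(xs, ys, bins=n_bins)
    slope, intercept = linear_fit(xs, ys)
    slope_rev, _ = linear_fit(ys, xs)
    return JointHistogram(hist, xe, ye, slope, intercept, slope_rev, int(mask.sum()))


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

TABLE2_METRICS = {
    "TL": ("MAD", "D50", "D70", "D95", "V120", "V205"),
    "NTLt": ("MAD", "D50", "D70", "D95", "V20", "V50", "V90"),
    "NTLw": ("MAD", "D50", "D70", "D95", "V20", "V50", "V90"),
}
TABLE3_METRICS = ("MAD", "D50", "D70", "V120")


def _metric_columns(voi: str, metric: str) -> tuple[str, str]:
    unit = "pct" if metric.startswith("V") else "per_gbq"
    return f"{voi}_{metric}_sim_{unit}", f"{voi}_{metric}_ther_{unit}"


def _comparison_row(records: pd.DataFrame, voi: str, metric: str) -> dict:
    col_s, col_t = _metric_columns(voi, metric)
    res = compare_paired(records[col_s].to_numpy(), records[col_t].to_numpy(),
                         metric_id=f"{voi}/{metric}")
    return {
        "segment": voi, "metric": metric, "n": res.n_valid,
        "sim_mean": res.sim_mean, "sim_sd": res.sim_sd,
        "ther_mean": res.ther_mean, "ther_sd": res.ther_sd,
        "wilcoxon_p": res.wilcoxon_p, "significant": res.significant,
        "pearson_r": res.pearson_r, "pearson_p": res.pearson_p,
        "r_category": res.r_category,
        "slope": res.slope, "intercept": res.intercept,
        "slope_sim_on_ther": res.slope_sim_on_ther,
        "rel_diff_mean": res.mean_rel_diff_pct,
        "rel_diff_min": res.rel_diff_range[0], "rel_diff_max": res.rel_diff_range[1],
        "rel_diff_defined": res.rel_diff_defined,
        "ba_bias": res.bland_altman_bias,
        "ba_lower": res.bland_altman_limits[0], "ba_upper": res.bland_altman_limits[1],
    }


def table2(records: pd.DataFrame) -> pd.DataFrame:
    """Per-VOI metric comparison over all cases (normalized Gy/GBq or %)."""
    rows = [
        _comparison_row(records, voi, metric)
        for voi, metrics in TABLE2_METRICS.items()
        for metric in metrics
        if _metric_columns(voi, metric)[0] in records.columns
    ]
    return pd.DataFrame(rows)


def table3(records: pd.DataFrame, threshold_ml: float = TL_VOLUME_THRESHOLD_ML) -> pd.DataFrame:
    """TL metric comparison split by tumoral-liver volume strata."""
    strata = stratify_by_tumor_volume(records["tl_volume_ml"].to_numpy(), threshold_ml)
    rows = []
    for name, idx in strata.items():
        sub = records.loc[idx]
        label = f"TL <= {threshold_ml:g} ml" if name == "small" else f"TL > {threshold_ml:g} ml"
        if int(idx.sum()) < 2:
            rows.append({"stratum": label, "segment": "TL", "metric": None, "n": int(idx.sum())})
            continue
        for metric in TABLE3_METRICS:
            row = _comparison_row(sub, "TL", metric)
            rows.append({"stratum": label, **row})
    return pd.DataFrame(rows)


def table4(records: pd.DataFrame, threshold_ml: float = TL_VOLUME_THRESHOLD_ML) -> pd.DataFrame:
    """TNR comparison (overall and per volume stratum) with Bland–Altman."""
    strata: dict[str, np.ndarray] = {"all": np.ones(len(records), dtype=bool)}
    strata.update(stratify_by_tumor_volume(records["tl_volume_ml"].to_numpy(), threshold_ml))
    labels = {"all": "TL", "small": f"TL <= {threshold_ml:g} ml", "large": f"TL > {threshold_ml:g} ml"}
    rows = []
    for name, idx in strata.items():
        sub = records.loc[idx]
        if len(sub) < 2:
            rows.append({"stratum": labels[name], "tnr": None, "n": len(sub)})
            continue
        for ntl in ("ntlt", "ntlw"):
            res = compare_paired(sub[f"tnr_{ntl}_sim"].to_numpy(),
                                 sub[f"tnr_{ntl}_ther"].to_numpy(),
                                 metric_id=f"TNR-{ntl.upper()}/{name}")
            rows.append({
                "stratum": labels[name], "tnr": f"TL/{ntl.upper().replace('NTL', 'NTL')}",
                "n": res.n_valid,
                "sim_mean": res.sim_mean, "sim_sd": res.sim_sd,
                "ther_mean": res.ther_mean, "ther_sd": res.ther_sd,
                "wilcoxon_p": res.wilcoxon_p, "significant": res.significant,
                "pearson_r": res.pearson_r, "pearson_p": res.pearson_p,
                "r_category": res.r_category,
                "ba_bias": res.bland_altman_bias,
                "ba_lower": res.bland_altman_limits[0], "ba_upper": res.bland_altman_limits[1],
            })
    return pd.DataFrame(rows)


def _median_range(x: pd.Series) -> str:
    x = x.dropna().astype(float)
    return f"{x.median():.2f} [{x.min():.2f}-{x.max():.2f}]"


def table1(records: pd.DataFrame) -> pd.DataFrame:
    """Cohort summary (median [range] for continuous, n (%) for discrete)."""
    n = len(records)
    rows: list[dict] = [{"characteristic": "n cases", "value": str(n)}]
    for col, label in (
        ("tl_volume_ml", "TL (ml)"),
        ("ntlt_volume_ml", "NTLt (ml)"),
        ("ntlw_volume_ml", "NTLw (ml)"),
        ("liver_volume_ml", "Whole liver (ml)"),
        ("a_injected_gbq", "90Y activity (GBq)"),
        ("lsf_percent", "LSF (%)"),
        ("waiting_days", "Waiting period (d)"),
    ):
        if col in records.columns:
            rows.append({"characteristic": label, "value": _median_range(records[col])})
    for col, label in (("treated_lobe", "Treated lobe"), ("sex", "Sex"), ("n_lesions", "Number of lesions")):
        if col in records.columns:
            counts = records[col].value_counts()
            for level, c in counts.items():
                rows.append({"characteristic": f"{label} = {level}",
                             "value": f"{c} ({100.0 * c / n:.1f}%)"})
    return pd.DataFrame(rows)


def format_table2(t2: pd.DataFrame) -> pd.DataFrame:
    """Human-readable table with mean ± SD strings, stars, and "–" cells."""
    out = []
    for _, r in t2.iterrows():
        star = "*" if r["significant"] else ""
        if r["rel_diff_defined"]:
            rel = f"{r['rel_diff_mean']:.2f} [{r['rel_diff_min']:.2f}-{r['rel_diff_max']:.2f}]"
        else:
            rel = "–"
        out.append({
            "segment": r["segment"], "metric": r["metric"],
            "sim": f"{r['sim_mean']:.2f} ± {r['sim_sd']:.2f}",
            "ther": f"{r['ther_mean']:.2f} ± {r['ther_sd']:.2f}",
            "wilcoxon_p": f"{r['wilcoxon_p']:.3g}{star}",
            "pearson": f"{r['pearson_r']:.2f} (p={r['pearson_p']:.2g}, {r['r_category']})",
            "rel_diff_pct": rel,
        })
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Plots (optional; matplotlib imported lazily)
# ---------------------------------------------------------------------------

def plot_bland_altman(sim, ther, ax=None, title: str = ""):
    import matplotlib.pyplot as plt

    sim = np.asarray(sim, dtype=float)
    ther = np.asarray(ther, dtype=float)
    bias, (lo, hi) = bland_altman(sim, ther)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((sim + ther) / 2.0, ther - sim, s=12)
    for y, style in ((bias, "-"), (lo, "--"), (hi, "--")):
        ax.axhline(y, linestyle=style, color="k", linewidth=0.8)
    ax.set_xlabel("mean of arms")
    ax.set_ylabel("therapy − simulation")
    ax.set_title(title)
    return ax


def plot_joint_histogram(jh: JointHistogram, ax=None, title: str = ""):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.pcolormesh(jh.sim_edges, jh.ther_edges, np.log1p(jh.hist.T))
    xs = np.array([jh.sim_edges[0], jh.sim_edges[-1]])
    ax.plot(xs, jh.slope * xs + jh.intercept, "r-", linewidth=1)
    ax.plot(xs, xs, "w--", linewidth=0.8)
    ax.set_xlabel("simulation dose (Gy)")
    ax.set_ylabel("therapy dose (Gy)")
    ax.set_title(title)
    return ax
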