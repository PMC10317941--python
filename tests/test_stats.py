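"""Agreement statistics against enumeration and hand-computed oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from sirtdose import (
    bland_altman,
    categorize_r,
    compare_paired,
    kruskal_wallis,
    linear_fit,
    mann_whitney_u,
    pearson_with_category,
    relative_difference_pct,
    stratify_by_tumor_volume,
    table2,
    table4,
    voxelwise_joint,
)
from sirtdose.stats import ComparisonResult


def mw_exact_oracle(x, y):
    """Exact two-sided Mann-Whitney p by full enumeration of arrangements."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    m = x.size
    pooled = np.concatenate([x, y])
    n_tot = pooled.size

    def u_of(xs, ys):
        return sum(1.0 for a in xs for b in ys if a > b) + \
            0.5 * sum(1 for a in xs for b in ys if a == b)

    u_obs = u_of(x, y)
    mn = m * (n_tot - m)
    # two-sided: arrangements at least as extreme in either tail
    stat_obs = min(u_obs, mn - u_obs)
    count = 0
    total = 0
    for idx in itertools.combinations(range(n_tot), m):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        u = u_of(xs, ys)
        if min(u, mn - u) <= stat_obs + 1e-12:
            count += 1
        total += 1
    return count / total


class TestRelativeDifference:
    def test_tumour_overestimation_worked_example(self):
        # cohort-mean TL MAD values, sim vs therapy, in Gy/GBq
        rd = relative_difference_pct(85.36, 67.55)
        assert rd == pytest.approx(26.4, abs=0.05)
        assert round(rd) == 26

    def test_identity_and_undefined(self):
        assert relative_difference_pct(5.0, 5.0) == 0.0
        assert math.isnan(relative_difference_pct(3.0, 0.0))

    def test_vectorised_mixed(self):
        out = relative_difference_pct([2.0, 3.0, 1.0], [1.0, 0.0, 4.0])
        assert out[0] == pytest.approx(100.0)
        assert math.isnan(out[1])
        assert out[2] == pytest.approx(-75.0)


class TestMannWhitney:
    def test_separated_pairs_exact(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(2 / 6, rel=1e-12)

    def test_fully_separated_five(self):
        _, p = mann_whitney_u(list(range(1, 6)), list(range(6, 11)))
        assert p == pytest.approx(2 / 252, rel=1e-12)
        assert p < 0.05

    def test_identical_samples_not_significant(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p > 0.9

    def test_exact_matches_enumeration_all_small_sizes(self, rng):
        # every tie-free (m, n) with m + n <= 10, random values
        for m in range(1, 10):
            for n in range(1, 11 - m):
                vals = rng.permutation(np.arange(1.0, m + n + 1.0) * 1.37)
                x, y = vals[:m], vals[m:]
                _, p = mann_whitney_u(x, y)
                assert p == pytest.approx(min(mw_exact_oracle(x, y), 1.0), rel=1e-9), (m, n)

    def test_exact_close_to_asymptotic_for_moderate_n(self, rng):
        # sanity bound: both paths agree within 0.02 for n >= 10 tie-free
        from scipy.stats import mannwhitneyu

        for _ in range(20):
            x = rng.normal(0, 1, 6)
            y = rng.normal(0.3, 1, 6)
            p_exact = mannwhitneyu(x, y, method="exact").pvalue
            p_asym = mannwhitneyu(x, y, method="asymptotic", use_continuity=True).pvalue
            assert abs(p_exact - p_asym) <= 0.02

    def test_rank_invariance_under_monotone_transform(self, rng):
        x = rng.normal(0, 1, 8)
        y = rng.normal(1, 1, 9)
        _, p1 = mann_whitney_u(x, y)
        _, p2 = mann_whitney_u(np.exp(x), np.exp(y))
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestPearsonCategories:
    def test_perfect_lines(self):
        x = np.arange(5.0)
        r, p, cat = pearson_with_category(x, 2 * x)
        assert r == pytest.approx(1.0)
        assert cat == "very strong"
        r, _, cat = pearson_with_category(x, -x)
        assert r == pytest.approx(-1.0)
        assert cat == "very strong"  # category from |r|

    @pytest.mark.parametrize("r,expected", [
        (0.0, "very weak"), (0.29, "very weak"), (0.3, "weak"), (0.49, "weak"),
        (0.5, "moderate"), (0.69, "moderate"), (0.7, "strong"), (0.86, "strong"),
        (0.89, "strong"), (0.9, "very strong"), (1.0, "very strong"),
        (-0.86, "strong"),
    ])
    def test_band_edges_half_open_and_exhaustive(self, r, expected):
        assert categorize_r(r) == expected

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_category([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestLinearFit:
    def test_exact_lines(self):
        x = np.arange(5.0)
        assert linear_fit(x, 2 * x + 1) == (pytest.approx(2.0), pytest.approx(1.0))
        assert linear_fit(x, x) == (pytest.approx(1.0), pytest.approx(0.0, abs=1e-12))

    def test_hand_normal_equations(self):
        # (0,0),(1,1),(2,0): slope 0, intercept 1/3 by the normal equations
        slope, intercept = linear_fit([0, 1, 2], [0, 1, 0])
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert intercept == pytest.approx(1 / 3)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            linear_fit([1.0, 1.0], [0.0, 1.0])


class TestBlandAltman:
    def test_identical_arms(self):
        bias, (lo, hi) = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert bias == 0.0 and lo == 0.0 and hi == 0.0

    def test_hand_computed_limits(self):
        # d = {-1, +1}: SD = sqrt(2), limits = +-1.96*sqrt(2) = +-2.772
        bias, (lo, hi) = bland_altman([0.0, 0.0], [-1.0, 1.0])
        assert bias == 0.0
        assert hi == pytest.approx(1.96 * math.sqrt(2.0), rel=1e-12)
        assert lo == pytest.approx(-hi)

    def test_constant_shift_moves_bias_only(self, rng):
        sim = rng.normal(10, 2, 30)
        ther = sim + rng.normal(0, 1, 30)
        b1, (lo1, hi1) = bland_altman(sim, ther)
        b2, (lo2, hi2) = bland_altman(sim, ther + 5.0)
        assert b2 == pytest.approx(b1 + 5.0)
        assert (hi2 - lo2) == pytest.approx(hi1 - lo1)

    def test_limits_cover_95pct_of_normal_differences(self):
        rng = np.random.default_rng(2024)
        d = rng.normal(0.0, 1.0, 10_000)
        bias, (lo, hi) = bland_altman(np.zeros_like(d), d)
        coverage = np.mean((d >= lo) & (d <= hi))
        assert coverage == pytest.approx(0.95, abs=0.01)


class TestKruskalWallis:
    def test_identical_groups(self):
        h, p = kruskal_wallis([[1.0, 2.0], [1.0, 2.0]])
        assert h == 0.0 and p == 1.0

    def test_hand_rank_formula(self):
        # {1,2},{3,4},{5,6}: ranks 1..6, H = 12/(6*7)*(9/2+49/2+121/2) - 21
        h, p = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        expected = 12.0 / 42.0 * ((3**2 + 7**2 + 11**2) / 2.0) - 3 * 7
        assert h == pytest.approx(expected, rel=1e-12)
        assert 0 < p < 1

    def test_monotone_transform_invariance(self, rng):
        groups = [rng.normal(i, 1, 7) for i in range(3)]
        h1, _ = kruskal_wallis(groups)
        h2, _ = kruskal_wallis([np.exp(g) for g in groups])
        assert h1 == pytest.approx(h2, rel=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0]])


class TestStratification:
    def test_threshold_inclusive_in_small_stratum(self):
        strata = stratify_by_tumor_volume([150.0, 200.0, 250.0])
        assert strata["small"].tolist() == [True, True, False]
        assert strata["large"].tolist() == [False, False, True]

    def test_empty_stratum_allowed(self):
        strata = stratify_by_tumor_volume([300.0, 400.0])
        assert strata["small"].sum() == 0


class TestComparePaired:
    def test_identical_arms(self, rng):
        x = rng.gamma(3, 10, 20)
        res = compare_paired(x, x.copy(), "id")
        assert res.mean_rel_diff_pct == 0.0
        assert res.pearson_r == pytest.approx(1.0)
        assert res.bland_altman_bias == 0.0
        assert res.slope == pytest.approx(1.0)
        assert not res.significant

    def test_two_case_hand_computation(self):
        sim = np.array([10.0, 30.0])
        ther = np.array([8.0, 24.0])
        res = compare_paired(sim, ther)
        assert res.n_valid == 2
        assert res.sim_mean == 20.0 and res.ther_mean == 16.0
        assert res.mean_rel_diff_pct == pytest.approx(25.0)  # both cases +25%
        assert res.rel_diff_range == (pytest.approx(25.0), pytest.approx(25.0))
        assert res.slope == pytest.approx(0.8)          # ther = 0.8 * sim
        assert res.slope_sim_on_ther == pytest.approx(1.25)
        assert res.bland_altman_bias == pytest.approx(-4.0)  # sim overestimates

    def test_zero_denominator_flags_metric(self):
        res = compare_paired([1.0, 2.0, 3.0], [1.0, 0.0, 3.0])
        assert not res.rel_diff_defined
        assert res.mean_rel_diff_pct == pytest.approx(0.0)  # mean over defined cases

    def test_nan_pairs_dropped(self):
        res = compare_paired([1.0, np.nan, 3.0, 4.0], [1.1, 2.0, np.nan, 4.2])
        assert res.n_valid == 2


class TestVoxelwiseJoint:
    def test_identical_and_scaled_maps(self, grid4, rng):
        from conftest import make_map

        vals = rng.random(grid4.shape) + 0.1
        m1 = make_map(grid4, vals, "dose_Gy")
        mask = np.ones(grid4.shape, bool)
        jh = voxelwise_joint(m1, m1, mask)
        assert jh.slope == pytest.approx(1.0)
        assert jh.n_voxels == mask.sum()
        assert jh.hist.sum() == mask.sum()
        m2 = make_map(grid4, 0.63 * vals, "dose_Gy")
        jh = voxelwise_joint(m1, m2, mask)
        assert jh.slope == pytest.approx(0.63, rel=1e-9)
        assert jh.slope_sim_on_ther == pytest.approx(1 / 0.63, rel=1e-9)


class TestCohortTables:
    def _records(self, n=6, discordant=False, rng=None):
        rng = rng or np.random.default_rng(0)
        rows = []
        for i in range(n):
            base = {"case_id": f"c{i}", "tl_volume_ml": float(50 + 60 * i)}
            for voi, metrics in (("TL", ("MAD", "D50", "D70", "D95", "V120", "V205")),
                                 ("NTLt", ("MAD", "D50", "D70", "D95", "V20", "V50", "V90")),
                                 ("NTLw", ("MAD", "D50", "D70", "D95", "V20", "V50", "V90"))):
                for m in metrics:
                    unit = "pct" if m.startswith("V") else "per_gbq"
                    v = float(rng.uniform(5, 80))
                    fac = float(rng.uniform(0.8, 1.2)) if discordant else 1.0
                    base[f"{voi}_{m}_sim_{unit}"] = v
                    base[f"{voi}_{m}_ther_{unit}"] = v * fac
            for ntl in ("ntlt", "ntlw"):
                t = float(rng.uniform(1.5, 4.0))
                base[f"tnr_{ntl}_sim"] = t
                base[f"tnr_{ntl}_ther"] = t if not discordant else t * 0.8
            rows.append(base)
        return pd.DataFrame(rows)

    def test_identical_arms_give_null_table(self):
        t2 = table2(self._records())
        assert (t2["rel_diff_mean"] == 0).all()
        assert np.allclose(t2["pearson_r"], 1.0)
        assert not t2["significant"].any()
        t4 = table4(self._records())
        assert np.allclose(t4["ba_bias"].astype(float), 0.0)

    def test_two_case_toy_cohort_matches_hand_values(self):
        df = pd.DataFrame([
            {"case_id": "a", "tl_volume_ml": 100.0,
             "TL_MAD_sim_per_gbq": 10.0, "TL_MAD_ther_per_gbq": 8.0},
            {"case_id": "b", "tl_volume_ml": 300.0,
             "TL_MAD_sim_per_gbq": 30.0, "TL_MAD_ther_per_gbq": 24.0},
        ])
        t2 = table2(df)
        row = t2.iloc[0]
        assert row["sim_mean"] == 20.0 and row["ther_mean"] == 16.0
        assert row["rel_diff_mean"] == pytest.approx(25.0)
        assert row["ba_bias"] == pytest.approx(-4.0)

    def test_null_denominator_emits_missing_marker(self):
        from sirtdose.stats import format_table2

        df = pd.DataFrame([
            {"case_id": "a", "tl_volume_ml": 100.0,
             "TL_V205_sim_pct": 5.0, "TL_V205_ther_pct": 0.0},
            {"case_id": "b", "tl_volume_ml": 300.0,
             "TL_V205_sim_pct": 10.0, "TL_V205_ther_pct": 4.0},
        ])
        t2 = table2(df)
        assert not t2.iloc[0]["rel_diff_defined"]
        formatted = format_table2(t2)
        assert formatted.iloc[0]["rel_diff_pct"] == "–"
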