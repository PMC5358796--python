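import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from osteochondral.stats import (
    icc,
    independent_t,
    linear_regression,
    one_way_anova,
    reproduce_study,
    significance_marker,
    tukey_hsd,
)
from osteochondral.synthetic import generate_study_table


def icc31_oracle(r):
    """Explicit two-way ANOVA decomposition with python loops."""
    n, k = r.shape
    grand = sum(r[i, j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(r[i, j] for j in range(k)) / k for i in range(n)]
    col_means = [sum(r[i, j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_tot = sum((r[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ms_rows = ss_rows / (n - 1)
    ms_err = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)


class TestIcc:
    def test_identical_raters_give_one(self):
        r = np.array([[0, 0], [1, 1], [2, 2], [3, 3]], dtype=float)
        assert icc(r) == pytest.approx(1.0, abs=1e-12)

    def test_toy_matrix_matches_sums_of_squares_oracle(self):
        r = np.array([[1.0, 2.0], [3.0, 3.0], [0.0, 1.0], [2.0, 4.0]])
        assert icc(r) == pytest.approx(icc31_oracle(r), abs=1e-10)

    def test_matches_pingouin_icc3(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(0)
        r = rng.normal(size=(12, 3)) + rng.normal(size=(12, 1)) * 2.0
        long = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(12), 3),
                "raters": np.tile(np.arange(3), 12),
                "scores": r.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(
            long, targets="targets", raters="raters", ratings="scores"
        )
        mask = ref["Type"].isin(["ICC3", "ICC(C,1)"])  # label differs by version
        icc3 = ref.loc[mask, "ICC"].iloc[0]
        assert icc(r) == pytest.approx(icc3, abs=1e-10)

    def test_invariant_to_shift_and_positive_scale(self):
        rng = np.random.default_rng(1)
        r = rng.normal(size=(10, 3)) + rng.normal(size=(10, 1))
        assert icc(r) == pytest.approx(icc(r + 5.0), abs=1e-10)
        assert icc(r) == pytest.approx(icc(r * 3.0), abs=1e-10)

    def test_no_between_sample_variance_is_undefined(self):
        r = np.ones((5, 3))
        with pytest.warns(UserWarning, match="between-sample"):
            assert math.isnan(icc(r))

    def test_bad_shapes_rejected(self):
        with pytest.raises(ValueError):
            icc(np.ones((1, 3)))
        with pytest.raises(ValueError):
            icc(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        f, p = one_way_anova([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_two_groups_f_equals_t_squared(self):
        a = [4.1, 5.2, 6.0, 5.5]
        b = [7.2, 6.8, 8.1, 7.7]
        f, p_f = one_way_anova([a, b])
        t, p_t = independent_t(a, b, equal_var=True)
        assert f == pytest.approx(t**2, abs=1e-10)
        assert p_f == pytest.approx(p_t, abs=1e-10)

    def test_matches_sums_of_squares_oracle(self):
        groups = [[2.0, 3.0, 1.0, 4.0, 2.5], [5.0, 6.5, 5.5, 7.0, 6.0], [3.0, 2.0, 4.5, 3.5, 3.0]]
        f, p = one_way_anova(groups)
        flat = [v for g in groups for v in g]
        grand = sum(flat) / len(flat)
        ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
        ss_within = sum((v - sum(g) / len(g)) ** 2 for g in groups for v in g)
        df_b = len(groups) - 1
        df_w = len(flat) - len(groups)
        f_oracle = (ss_between / df_b) / (ss_within / df_w)
        assert f == pytest.approx(f_oracle, abs=1e-10)
        assert p == pytest.approx(sps.f.sf(f_oracle, df_b, df_w), abs=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            one_way_anova([[1.0, 2.0], []])


class TestTukey:
    def test_identical_groups_not_significant(self):
        out = tukey_hsd([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert (out["p_adjusted"] > 0.999).all()

    def test_two_groups_equal_pooled_t(self):
        a = [4.1, 5.2, 6.0, 5.5]
        b = [7.2, 6.8, 8.1, 7.7]
        out = tukey_hsd([a, b])
        _, p_t = independent_t(a, b, equal_var=True)
        assert out.loc[0, "p_adjusted"] == pytest.approx(p_t, abs=1e-10)

    def test_three_groups_match_studentized_range_oracle(self):
        groups = [[2.0, 3.0, 1.0, 4.0], [5.0, 6.5, 5.5, 7.0], [3.0, 2.0, 4.5, 3.5]]
        out = tukey_hsd(groups)
        flat = [v for g in groups for v in g]
        k, n = len(groups), len(flat)
        ms_within = sum(
            (v - sum(g) / len(g)) ** 2 for g in groups for v in g
        ) / (n - k)
        for _, row in out.iterrows():
            a = groups[int(row["group_a"])]
            b = groups[int(row["group_b"])]
            q = abs(sum(a) / len(a) - sum(b) / len(b)) / math.sqrt(
                ms_within / 2 * (1 / len(a) + 1 / len(b))
            )
            p_oracle = sps.studentized_range.sf(q, k, n - k)
            assert row["p_adjusted"] == pytest.approx(p_oracle, abs=1e-8)

    def test_ranking_consistent_with_separation(self):
        near = [[0.0, 0.1, -0.1], [0.2, 0.3, 0.1], [5.0, 5.1, 4.9]]
        out = tukey_hsd(near)
        p01 = out.set_index(["group_a", "group_b"]).loc[(0, 1), "p_adjusted"]
        p02 = out.set_index(["group_a", "group_b"]).loc[(0, 2), "p_adjusted"]
        assert p02 < p01


class TestIndependentT:
    def test_equal_samples_give_zero_t(self):
        t, p = independent_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_t_grows_as_jitter_shrinks(self):
        prev = 0.0
        for eps in (1e-1, 1e-2, 1e-3):
            a = [1.0 - eps, 1.0 + eps]
            b = [2.0 - eps, 2.0 + eps]
            t, _ = independent_t(a, b)
            assert abs(t) > abs(prev)
            prev = t

    def test_matches_welch_closed_form(self):
        a = [4.2, 5.1, 6.3, 5.0, 4.8, 5.9]
        b = [7.1, 6.5, 8.2, 7.8, 6.9, 7.4]
        t, p = independent_t(a, b)
        ma, mb = np.mean(a), np.mean(b)
        va, vb = np.var(a, ddof=1) / len(a), np.var(b, ddof=1) / len(b)
        t_oracle = (ma - mb) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        p_oracle = 2 * sps.t.sf(abs(t_oracle), df)
        assert t == pytest.approx(t_oracle, abs=1e-10)
        assert p == pytest.approx(p_oracle, abs=1e-10)

    def test_double_zero_variance_undefined(self):
        with pytest.warns(UserWarning, match="zero variance"):
            t, p = independent_t([1.0, 1.0], [1.0, 1.0])
        assert math.isnan(t)


class TestLinearRegression:
    def test_exact_line_recovered(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        res = linear_regression(x, 2 * x + 1)
        assert res.slope == pytest.approx(2.0, abs=1e-12)
        assert res.intercept == pytest.approx(1.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_uncorrelated_noise_has_vanishing_r2(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 6, 5000)
        y = 3.0 + rng.normal(0, 1, 5000)
        assert linear_regression(x, y).r_squared < 0.01

    def test_matches_normal_equations_oracle(self):
        x = np.array([0.5, 1.0, 2.0, 3.5, 4.0, 5.5])
        y = np.array([1.2, 0.8, 2.5, 2.9, 4.1, 4.0])
        res = linear_regression(x, y)
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        intercept = y.mean() - slope * x.mean()
        resid = y - (slope * x + intercept)
        r2 = 1 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()
        assert res.slope == pytest.approx(slope, abs=1e-10)
        assert res.intercept == pytest.approx(intercept, abs=1e-10)
        assert res.r_squared == pytest.approx(r2, abs=1e-10)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError, match="all equal"):
            linear_regression([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestReproduceStudy:
    def test_missing_columns_listed(self):
        with pytest.raises(ValueError, match="thickness_plate_um"):
            reproduce_study(pd.DataFrame({"sample_id": ["a"], "oarsi": [1.0]}))

    def test_synthetic_study_report_structure_and_directions(self):
        table = generate_study_table(n_patients=60, seed=8)
        report = reproduce_study(table)
        # descriptor-grade coupling built into the generator must surface
        ent = report["interface_descriptors"]["entropy"]["regression_on_oarsi"]
        hom = report["interface_descriptors"]["homogeneity"]["regression_on_oarsi"]
        assert ent["slope"] > 0
        assert hom["slope"] < 0
        assert 0 <= ent["r_squared"] <= 1
        # worn grade-3 samples never enter the descriptor group tests
        assert 3 not in report["interface_descriptors"]["entropy"]["group_n"]
        assert report["icc"]["n_raters"] == 3
        assert 0 < report["icc"]["value"] <= 1
        folds = report["plate_fold_change_vs_grade_0"]
        assert folds[1]["ratio"] < folds[2]["ratio"] < folds[3]["ratio"]
        excl = report["exclusions"]
        assert excl["no_descriptors_oarsi_cutoff"] == int(
            table["entropy_bits"].isna().sum()
        )

    def test_mean_oarsi_by_grade_tracks_profiles(self):
        table = generate_study_table(n_patients=400, seed=9)
        report = reproduce_study(table)
        means = {g: v["mean"] for g, v in report["oarsi_by_bone_grade"].items()}
        assert means[0] < means[1] < means[2] < means[3]


def test_significance_markers_follow_figure_convention():
    assert significance_marker(0.0001) == "***"
    assert significance_marker(0.01) == "*"
    assert significance_marker(0.2) == "ns"
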