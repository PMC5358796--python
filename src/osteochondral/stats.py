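"""Grading statistics: rater agreement, group tests and regressions.

The statistical layer of the study design: intraclass correlation for the
repeatability of the ordinal subchondral bone grade, one-way ANOVA with
Tukey's HSD post hoc across grade groups, independent t-tests between
severity groups, ordinary least-squares regression of the interface
descriptors on OARSI grade, and a report generator that runs the whole
battery on a study table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RegressionResult",
    "icc",
    "one_way_anova",
    "tukey_hsd",
    "independent_t",
    "linear_regression",
    "reproduce_study",
]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


def icc(ratings: np.ndarray, model: str = "two_way_mixed_consistency") -> float:
    """Intraclass correlation for consistency of single ratings, ICC(3,1).

    ``ratings`` is an n_samples x n_raters matrix with no missing cells;
    the same fixed raters score every sample, so the two-way mixed model
    applies. From the two-way ANOVA decomposition,

        ICC(3,1) = (MS_rows - MS_error) / (MS_rows + (k - 1) * MS_error)

    where MS_rows is the between-sample mean square and MS_error the
    residual after removing the rater effect. Returns NaN (with a warning)
    when there is no between-sample variance to apportion.
    """
    if model != "two_way_mixed_consistency":
        raise ValueError(f"unsupported ICC model {model!r}")
    r = np.asarray(ratings, dtype=float)
    if r.ndim != 2 or r.shape[0] < 2 or r.shape[1] < 2:
        raise ValueError("ratings must be an n x k matrix with n >= 2, k >= 2")
    if not np.all(np.isfinite(r)):
        raise ValueError("ratings must have no missing cells")
    n, k = r.shape
    grand = r.mean()
    row_means = r.mean(axis=1)
    col_means = r.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((r - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    denom = ms_rows + (k - 1) * ms_err
    if denom == 0:
        warnings.warn(
            "no between-sample variance; ICC is undefined", UserWarning, stacklevel=2
        )
        return float("nan")
    return float((ms_rows - ms_err) / denom)


def _check_groups(groups: list) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if g.size == 0:
            raise ValueError(f"group {i} is empty")
    if sum(g.size for g in arrays) <= len(arrays):
        raise ValueError("total observations must exceed the number of groups")
    return arrays


def one_way_anova(groups: list) -> tuple[float, float]:
    """Classical one-way ANOVA F test across the groups: (F, p)."""
    arrays = _check_groups(groups)
    res = sps.f_oneway(*arrays)
    return float(res.statistic), float(res.pvalue)


def tukey_hsd(groups: list) -> pd.DataFrame:
    """Tukey's honestly-significant-difference pairwise comparisons.

    Studentized-range adjusted p-values using the pooled within-group mean
    square; returns one row per unordered group pair.
    """
    arrays = _check_groups(groups)
    res = sps.tukey_hsd(*arrays)
    rows = []
    means = [g.mean() for g in arrays]
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            rows.append(
                {
                    "group_a": i,
                    "group_b": j,
                    "mean_difference": means[i] - means[j],
                    "p_adjusted": float(res.pvalue[i, j]),
                }
            )
    return pd.DataFrame(rows)


def independent_t(
    a, b, equal_var: bool = False
) -> tuple[float, float]:
    """Two-sided independent-samples t-test: (t, p). Welch by default."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    if np.var(a) == 0 and np.var(b) == 0:
        warnings.warn(
            "both groups have zero variance; t statistic is undefined",
            UserWarning,
            stacklevel=2,
        )
        return float("nan"), float("nan")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def linear_regression(x, y) -> RegressionResult:
    """Ordinary least squares of ``y`` on ``x`` with R^2 = 1 - SSres/SStot."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least three points")
    if np.ptp(x) == 0:
        raise ValueError("x values are all equal; slope is undefined")
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=int(x.size),
    )


def significance_marker(p: float) -> str:
    """Figure-style annotation: *** p<0.001, * p<0.05, otherwise 'ns'."""
    if p < 0.001:
        return "***"
    if p < 0.05:
        return "*"
    return "ns"


_REQUIRED_COLUMNS = (
    "sample_id",
    "oarsi",
    "bone_grade",
    "thickness_uncalc_um",
    "thickness_calc_um",
    "thickness_plate_um",
    "entropy_bits",
    "homogeneity",
)


def reproduce_study(
    table: pd.DataFrame,
    fold_reference_grade: int = 0,
    lbp_exclude_grade: int = 3,
    oarsi_cutoff: float = 5.0,
) -> dict:
    """Run the full statistical battery on a study table.

    Emits per-bone-grade mean OARSI, per-grade thickness summaries (mean
    +/- SE) with fold changes of the plate versus the reference grade,
    entropy/homogeneity group comparisons with the worn smooth-surface
    grade excluded (``lbp_exclude_grade``) and rows without interface
    descriptors (OARSI at or above ``oarsi_cutoff``) dropped, OLS
    regressions of both descriptors on OARSI, and the inter-rater ICC from
    any ``rater_*`` columns. All exclusions are counted in the report.
    """
    from .morphometry import fold_change, summarize_by_grade

    missing = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"study table is missing columns: {missing}")

    report: dict = {"n_samples": int(len(table))}
    report["oarsi_overall"] = {
        "mean": float(table["oarsi"].mean()),
        "sd": float(table["oarsi"].std()),
    }
    report["bone_grade_overall"] = {
        "mean": float(table["bone_grade"].mean()),
        "sd": float(table["bone_grade"].std()),
    }
    report["oarsi_by_bone_grade"] = {
        int(g): {"n": int(r["n"]), "mean": float(r["mean"]), "se": float(r["se"])}
        for g, r in summarize_by_grade(table, "oarsi").iterrows()
    }

    thickness = {}
    for col, name in (
        ("thickness_uncalc_um", "uncalcified_cartilage"),
        ("thickness_calc_um", "calcified_cartilage"),
        ("thickness_plate_um", "subchondral_plate"),
    ):
        summary = summarize_by_grade(table, col)
        thickness[name] = {
            int(g): {
                "n": int(r["n"]),
                "mean_um": float(r["mean"]),
                "sd_um": float(r["sd"]) if np.isfinite(r["sd"]) else None,
                "se_um": float(r["se"]) if np.isfinite(r["se"]) else None,
            }
            for g, r in summary.iterrows()
        }
    report["thickness_by_bone_grade"] = thickness

    plate = thickness["subchondral_plate"]
    if fold_reference_grade in plate:
        ref = plate[fold_reference_grade]["mean_um"]
        report["plate_fold_change_vs_grade_%d" % fold_reference_grade] = {
            int(g): {
                "ratio": fold_change(ref, v["mean_um"]).ratio,
                "rounded": fold_change(ref, v["mean_um"]).rounded,
            }
            for g, v in plate.items()
            if g != fold_reference_grade
        }

    # Interface descriptors: only samples with remaining cartilage carry
    # them, and the smooth worn top grade is excluded from group tests.
    has_lbp = table.dropna(subset=["entropy_bits", "homogeneity"])
    lbp = has_lbp[has_lbp["bone_grade"] != lbp_exclude_grade]
    report["exclusions"] = {
        "no_descriptors_oarsi_cutoff": int(len(table) - len(has_lbp)),
        "lbp_excluded_grade": int(len(has_lbp) - len(lbp)),
        "oarsi_cutoff": float(oarsi_cutoff),
        "excluded_bone_grade": int(lbp_exclude_grade),
    }

    descriptors = {}
    grades_present = sorted(lbp["bone_grade"].unique())
    for col, name in (("entropy_bits", "entropy"), ("homogeneity", "homogeneity")):
        block: dict = {
            "group_n": {
                int(g): int((lbp["bone_grade"] == g).sum()) for g in grades_present
            },
            "group_means": {
                int(g): float(lbp.loc[lbp["bone_grade"] == g, col].mean())
                for g in grades_present
            },
        }
        groups = [
            lbp.loc[lbp["bone_grade"] == g, col].to_numpy() for g in grades_present
        ]
        if len(groups) >= 2 and all(len(g) >= 2 for g in groups):
            f, p = one_way_anova(groups)
            block["anova"] = {"F": f, "p": p, "marker": significance_marker(p)}
            block["tukey"] = [
                {
                    "grade_a": int(grades_present[int(r["group_a"])]),
                    "grade_b": int(grades_present[int(r["group_b"])]),
                    "mean_difference": float(r["mean_difference"]),
                    "p_adjusted": float(r["p_adjusted"]),
                }
                for _, r in tukey_hsd(groups).iterrows()
            ]
        reg = linear_regression(has_lbp["oarsi"], has_lbp[col])
        block["regression_on_oarsi"] = {
            "slope": reg.slope,
            "intercept": reg.intercept,
            "r_squared": reg.r_squared,
            "n": reg.n,
        }
        descriptors[name] = block
    report["interface_descriptors"] = descriptors

    rater_cols = [c for c in table.columns if c.startswith("rater_")]
    if len(rater_cols) >= 2:
        report["icc"] = {
            "value": icc(table[rater_cols].to_numpy()),
            "n_samples": int(len(table)),
            "n_raters": len(rater_cols),
            "model": "two-way mixed, single rating, consistency (ICC(3,1))",
            "label": "inter-rater consistency",
        }
    return report
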