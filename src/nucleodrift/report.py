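"""Aggregate group reports: descriptives, t-tests, Mann-Whitney U, regression.

Per-comparison p-values are reported unadjusted. Tests on a/b ratios are
performed on log2-transformed values; septum-position ratios use the
Mann-Whitney U test; velocities and RMS amplitudes use non-paired two-tailed
t-tests.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import velocity_position_regression

__all__ = ["group_descriptives", "pairwise_tests", "build_report"]


def group_descriptives(df: pd.DataFrame, group_col: str, value_col: str) -> pd.DataFrame:
    out = df.groupby(group_col)[value_col].agg(["count", "mean", "std"])
    return out.rename(columns={"count": "n", "mean": "mean", "std": "sd"})


def pairwise_tests(df: pd.DataFrame, group_col: str, value_col: str,
                   test: str = "ttest", log2: bool = False) -> pd.DataFrame:
    """All pairwise two-group comparisons of ``value_col`` between groups.

    ``test`` is ``"ttest"`` (non-paired, two-tailed) or ``"mannwhitney"``.
    ``log2=True`` transforms values before a t-test (for ratio data).
    """
    groups = {k: v[value_col].dropna().to_numpy(dtype=float)
              for k, v in df.groupby(group_col)}
    rows = []
    for (ka, a), (kb, b) in itertools.combinations(groups.items(), 2):
        if len(a) < 2 or len(b) < 2:
            rows.append({"group_a": ka, "group_b": kb, "test": test,
                         "statistic": np.nan, "p_value": np.nan,
                         "note": "singleton group"})
            continue
        xa, xb = (np.log2(a), np.log2(b)) if log2 else (a, b)
        if test == "ttest":
            res = stats.ttest_ind(xa, xb)
        elif test == "mannwhitney":
            res = stats.mannwhitneyu(xa, xb, alternative="two-sided")
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append({"group_a": ka, "group_b": kb, "test": test,
                     "statistic": float(res.statistic),
                     "p_value": float(res.pvalue), "note": ""})
    return pd.DataFrame(rows)


def build_report(summary: pd.DataFrame, group_col: str = "mode") -> str:
    """Plain-text aggregate report of a per-cell summary table."""
    lines = []
    n_groups = summary[group_col].nunique()
    for col, label in [("net_velocity_nm_min", "net velocity (nm/min)"),
                       ("ratio_s_total", "centering s/(s+l)"),
                       ("ab_ratio", "a/b ratio"),
                       ("rms_um", "detrended RMS (um)")]:
        if col not in summary.columns or summary[col].dropna().empty:
            continue
        lines.append(f"== {label} ==")
        lines.append(group_descriptives(summary, group_col, col).to_string())
        if n_groups > 1:
            if col == "ratio_s_total":
                tests = pairwise_tests(summary, group_col, col, "mannwhitney")
            elif col == "ab_ratio":
                tests = pairwise_tests(summary, group_col, col, "ttest", log2=True)
            else:
                tests = pairwise_tests(summary, group_col, col, "ttest")
            lines.append(tests.to_string(index=False))
        lines.append("")

    if {"frac_dist_start", "net_velocity_nm_min"} <= set(summary.columns):
        lines.append("== net velocity vs fractional start distance (OLS) ==")
        for key, sub in summary.groupby(group_col):
            sub = sub.dropna(subset=["frac_dist_start", "net_velocity_nm_min"])
            if len(sub) < 3 or sub["frac_dist_start"].nunique() < 2:
                lines.append(f"{key}: too few cells for regression")
                continue
            r = velocity_position_regression(sub["frac_dist_start"],
                                             sub["net_velocity_nm_min"])
            lines.append(f"{key}: slope={r.slope:.1f} nm/min per unit, "
                         f"r2={r.r2:.3f}, P={r.p_value:.4g}, n={r.n}")
        lines.append("")
    return "\n".join(lines)
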