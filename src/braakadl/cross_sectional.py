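"""Baseline (cross-sectional) association models.

Group-level descriptives and comparisons (Kruskal–Wallis / chi-square /
one-way ANOVA with Tukey HSD post-hocs) and covariate-adjusted linear
models of functional scores on either the simplified stage groups or a
continuous Braak-ROI SUVR composite. Adjustment is for age, sex and
neocortical amyloid-PET SUVR; no multiple-testing correction is applied
across instruments (significance at P < 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable
from .regression import DEFAULT_COVARIATES, RegressionResult, fit_adjusted_ols, zscore
from .staging import STAGE_GROUPS

__all__ = [
    "zscore",
    "fit_stage_model",
    "fit_roi_suvr_model",
    "compare_groups",
    "describe_cohort",
    "GroupComparison",
    "INSTRUMENT_COLUMNS",
]

#: Instrument name -> derived score column.
INSTRUMENT_COLUMNS = {
    "faq": "faq_total",
    "ecog": "ecog_mean",
    "cdrsbf": "cdrsbf_total",
}


def _baseline_frame(data) -> pd.DataFrame:
    df = data.data if isinstance(data, CohortTable) else data
    if "visit" in df.columns:
        df = df[df["visit"] == "baseline"]
    return df


def fit_stage_model(
    data,
    outcome: str,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    adjust_diagnosis: bool = False,
    zscore_whole_sample: bool = False,
) -> RegressionResult:
    """OLS of a z-scored functional score on stage groups plus covariates.

    Stage groups are dummy-coded against group 0, so each stage beta is the
    adjusted difference (in outcome SD units) between that group and stage 0.

    ``outcome`` may be an instrument name (``faq``/``ecog``/``cdrsbf``) or a
    column name. ``adjust_diagnosis`` adds clinical diagnosis (vs CU) to the
    adjustment set (exploratory model). ``zscore_whole_sample`` scales
    continuous variables on the full baseline table rather than the model's
    complete cases.
    """
    df = _baseline_frame(data)
    outcome = INSTRUMENT_COLUMNS.get(outcome, outcome)
    covs = covariates + (("diagnosis",) if adjust_diagnosis else ())
    return fit_adjusted_ols(
        df,
        outcome,
        predictors={"stage_group": "group"},
        covariates=covs,
        zscore_sample=df if zscore_whole_sample else None,
    )


def fit_roi_suvr_model(
    data,
    outcome: str,
    roi_suvr: str,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    adjust_diagnosis: bool = False,
    zscore_whole_sample: bool = False,
) -> RegressionResult:
    """OLS of a z-scored functional score on a continuous ROI SUVR composite."""
    df = _baseline_frame(data)
    outcome = INSTRUMENT_COLUMNS.get(outcome, outcome)
    covs = covariates + (("diagnosis",) if adjust_diagnosis else ())
    return fit_adjusted_ols(
        df,
        outcome,
        predictors={roi_suvr: "continuous"},
        covariates=covs,
        zscore_sample=df if zscore_whole_sample else None,
    )


@dataclass
class GroupComparison:
    """One-way ANOVA across stage groups with Tukey HSD pairwise post-hocs."""

    anova_f: float
    anova_p: float
    pairwise: pd.DataFrame  # columns: group1, group2, mean_diff, p_adj


def compare_groups(data, outcome: str, group_col: str = "stage_group") -> GroupComparison:
    """Compare a functional score across stage groups (ANOVA + Tukey HSD)."""
    df = _baseline_frame(data)
    outcome = INSTRUMENT_COLUMNS.get(outcome, outcome)
    df = df[[group_col, outcome]].dropna()
    levels = [g for g in STAGE_GROUPS if g in set(df[group_col])]
    if len(levels) < 2:
        raise ValueError("need at least two stage groups with observations")
    samples = {g: df.loc[df[group_col] == g, outcome].to_numpy() for g in levels}
    for g, v in samples.items():
        if len(v) < 2:
            raise ValueError(f"stage group {g!r} has fewer than two observations")
    f, p = stats.f_oneway(*samples.values())
    tk = stats.tukey_hsd(*samples.values())
    rows = [
        {
            "group1": g1,
            "group2": g2,
            "mean_diff": samples[g2].mean() - samples[g1].mean(),
            "p_adj": float(tk.pvalue[i, j]),
        }
        for (i, g1), (j, g2) in combinations(enumerate(levels), 2)
    ]
    return GroupComparison(float(f), float(p), pd.DataFrame(rows))


_CONTINUOUS_DESC = [
    "age",
    "education",
    "mmse",
    "abeta_suvr",
    "faq_total",
    "ecog_mean",
    "cdrsbf_total",
]
_CATEGORICAL_DESC = ["sex", "diagnosis"]


def describe_cohort(data, group_col: str = "stage_group") -> pd.DataFrame:
    """Per-stage-group descriptive table with omnibus p-values.

    Continuous variables: per-group "mean (SD)" and a Kruskal–Wallis
    p-value; categorical variables: per-group "n (%)" of each level and a
    chi-square p-value. Variables that are constant (or absent) are kept in
    the table with the reason in place of a p-value. Missing-data counts
    are reported per variable.
    """
    df = _baseline_frame(data)
    groups = [g for g in STAGE_GROUPS if g in set(df[group_col].dropna())]
    rows = []
    for var in _CONTINUOUS_DESC:
        if var not in df.columns or df[var].dropna().empty:
            continue
        row = {"variable": var, "type": "continuous",
               "n_missing": int(df[var].isna().sum())}
        samples = []
        for g in groups:
            v = df.loc[df[group_col] == g, var].dropna().to_numpy(dtype=float)
            row[g] = f"{v.mean():.2f} ({v.std(ddof=1):.2f})" if len(v) > 1 else "-"
            if len(v) > 0:
                samples.append(v)
        pooled = np.concatenate(samples) if samples else np.array([])
        if len(np.unique(pooled)) < 2:
            row["p"] = np.nan
            row["note"] = "test skipped: variable is constant"
        else:
            row["p"] = float(stats.kruskal(*samples).pvalue)
            row["note"] = "Kruskal-Wallis"
        rows.append(row)
    for var in _CATEGORICAL_DESC:
        if var not in df.columns or df[var].dropna().empty:
            continue
        sub = df[[group_col, var]].dropna()
        table = pd.crosstab(sub[var], sub[group_col])
        table = table[[g for g in groups if g in table.columns]]
        row = {"variable": var, "type": "categorical",
               "n_missing": int(df[var].isna().sum())}
        for g in table.columns:
            parts = [
                f"{lvl}: {table.loc[lvl, g]} ({100 * table.loc[lvl, g] / table[g].sum():.1f}%)"
                for lvl in table.index
            ]
            row[g] = "; ".join(parts)
        if table.shape[0] < 2 or table.shape[1] < 2:
            row["p"] = np.nan
            row["note"] = "test skipped: fewer than two levels or groups"
        else:
            row["p"] = float(stats.chi2_contingency(table.to_numpy()).pvalue)
            row["note"] = "chi-square"
        rows.append(row)
    return pd.DataFrame(rows)
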