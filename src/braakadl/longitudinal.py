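"""Annual rate of functional change and models predicting it from baseline stage.

The annual change of an instrument score is (follow-up − baseline) /
years between visits, computed per participant from their single
follow-up. Rates further than k SD (default 2.5, two-sided) from the
whole-sample mean are flagged as outliers — a single pass, no iteration
— and excluded from downstream models with a logged reason. The change
models reuse the covariate-adjusted machinery of the cross-sectional
module with the z-scored rate as outcome.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .cross_sectional import INSTRUMENT_COLUMNS
from .regression import DEFAULT_COVARIATES, RegressionResult, fit_adjusted_ols

__all__ = [
    "annual_change",
    "compute_annual_changes",
    "flag_outliers",
    "fit_change_model",
]

logger = logging.getLogger(__name__)


def annual_change(baseline_score, followup_score, years_between):
    """(follow-up − baseline) / years; years must be strictly positive."""
    years = np.asarray(years_between, dtype=float)
    if np.any(years <= 0):
        raise ValueError("years_between must be > 0")
    return (np.asarray(followup_score, dtype=float) - np.asarray(baseline_score, dtype=float)) / years


def compute_annual_changes(
    cohort, instruments: tuple[str, ...] = ("faq", "ecog", "cdrsbf")
) -> pd.DataFrame:
    """Per-participant annual rates of change for each instrument.

    Returns one row per participant with a follow-up visit: ``id``,
    ``followup_years`` and one ``rate_<instrument>`` column each (missing
    when either visit lacks the score — skipped, not imputed).
    """
    df = cohort.data if isinstance(cohort, CohortTable) else cohort
    cols = {k: INSTRUMENT_COLUMNS.get(k, k) for k in instruments}
    base = df[df["visit"] == "baseline"].set_index("id")
    fu = df[df["visit"] == "followup"].set_index("id")
    fu = fu[fu["time_years"] > 0]
    ids = [i for i in fu.index if i in base.index]
    out = pd.DataFrame({"id": ids})
    out["followup_years"] = fu.loc[ids, "time_years"].to_numpy(dtype=float)
    for name, col in cols.items():
        b = base.loc[ids, col].to_numpy(dtype=float)
        f = fu.loc[ids, col].to_numpy(dtype=float)
        rate = np.where(
            np.isfinite(b) & np.isfinite(f),
            (f - b) / out["followup_years"].to_numpy(),
            np.nan,
        )
        n_skip = int(np.sum(~(np.isfinite(b) & np.isfinite(f))))
        if n_skip:
            logger.info("%d participants skipped for %s rate: missing score", n_skip, name)
        out[f"rate_{name}"] = rate
    return out


def flag_outliers(rates, k: float = 2.5, two_sided: bool = True) -> np.ndarray:
    """Flag rates further than k SD from the whole-sample mean (single pass).

    ``two_sided=False`` flags only the low tail (rate < mean − k SD).
    Missing values are never flagged. Zero SD yields no outliers (with a
    warning). Requires at least three finite rates.
    """
    x = np.asarray(rates, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 3:
        raise ValueError("outlier flagging requires at least three finite rates")
    mu = x[finite].mean()
    sd = x[finite].std(ddof=1)
    if sd == 0:
        logger.warning("zero SD among rates; no outliers flagged")
        return np.zeros_like(x, dtype=bool)
    dev = x - mu
    flags = (np.abs(dev) > k * sd) if two_sided else (dev < -k * sd)
    return np.where(finite, flags, False)


def fit_change_model(
    rates_with_stage: pd.DataFrame,
    outcome: str,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    outlier_k: float | None = 2.5,
    adjust_diagnosis: bool = False,
    zscore_whole_sample: bool = False,
) -> RegressionResult:
    """OLS of a z-scored annual rate on baseline stage groups plus covariates.

    ``rates_with_stage`` is the output of :func:`compute_annual_changes`
    merged with baseline ``stage_group`` and covariates. Outliers (per
    :func:`flag_outliers` on the rate column across the whole sample) are
    excluded before fitting; pass ``outlier_k=None`` to keep them.
    """
    col = f"rate_{outcome}" if f"rate_{outcome}" in rates_with_stage.columns else outcome
    df = rates_with_stage
    if outlier_k is not None:
        flags = flag_outliers(df[col].to_numpy(), k=outlier_k)
        if flags.any():
            excluded = df.loc[flags, ["id", col]] if "id" in df.columns else df.loc[flags, [col]]
            logger.info("excluding %d outlier rates for %s:\n%s",
                        int(flags.sum()), col, excluded.to_string())
        df = df.loc[~flags]
    covs = covariates + (("diagnosis",) if adjust_diagnosis else ())
    return fit_adjusted_ols(
        df,
        col,
        predictors={"stage_group": "group"},
        covariates=covs,
        zscore_sample=df if zscore_whole_sample else None,
    )
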