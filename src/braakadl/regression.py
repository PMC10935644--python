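"""Shared covariate-adjusted linear-model machinery.

All continuous variables entering a model are z-scored (mean 0, SD 1,
n-1 denominator); sex enters as a binary male indicator and stage groups
are dummy-coded against the reference group 0. Coefficients are
therefore on the scale "z-scored-outcome units per z-scored-predictor
unit (or per dummy contrast)", 95% CIs come from the t distribution with
residual degrees of freedom, and models are fitted on complete cases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .staging import STAGE_GROUPS

__all__ = ["RegressionResult", "zscore", "fit_adjusted_ols", "DEFAULT_COVARIATES"]

DEFAULT_COVARIATES = ("age", "sex", "abeta_suvr")


def zscore(values, ddof: int = 1) -> np.ndarray:
    """Standardise a vector to mean 0, SD 1 (n-1 denominator).

    Missing entries propagate as missing and are excluded from the mean/SD.
    Raises ``ValueError`` on zero variance or fewer than two finite values.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise ValueError("z-scoring requires at least two finite values")
    mu = x[finite].mean()
    sd = x[finite].std(ddof=ddof)
    if sd == 0:
        raise ValueError("z-scoring undefined for a zero-variance vector")
    out = np.full_like(x, np.nan, dtype=float)
    out[finite] = (x[finite] - mu) / sd
    return out


@dataclass
class RegressionResult:
    """Per-term estimates plus model-level fit summaries of one OLS model."""

    terms: pd.DataFrame  # index: term; columns: beta, ci_low, ci_high, t, p
    adj_r2: float
    f_stat: float
    f_pvalue: float
    n_used: int
    df_resid: float
    outcome: str = ""

    def term(self, name: str) -> pd.Series:
        return self.terms.loc[name]

    def to_frame(self, model: str = "") -> pd.DataFrame:
        """Tidy one-row-per-term table suitable for CSV export."""
        out = self.terms.reset_index().rename(columns={"index": "term"})
        out.insert(0, "model", model or self.outcome)
        out["adj_r2"] = self.adj_r2
        out["f_stat"] = self.f_stat
        out["n"] = self.n_used
        return out


def _zstats(series: pd.Series, sample: pd.Series | None):
    ref = series if sample is None else sample
    ref = ref.astype(float)
    mu = ref.mean()
    sd = ref.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError(f"zero variance in {series.name!r}; cannot z-score")
    return (series.astype(float) - mu) / sd


def fit_adjusted_ols(
    data: pd.DataFrame,
    outcome: str,
    predictors: dict[str, str],
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    zscore_sample: pd.DataFrame | None = None,
) -> RegressionResult:
    """Fit OLS of a z-scored outcome on predictors plus standard covariates.

    Parameters
    ----------
    data:
        Source table; the model uses complete cases of the involved columns.
    outcome:
        Column holding the (continuous) outcome; z-scored before fitting.
    predictors:
        Mapping column -> kind, where kind is ``"group"`` (stage-group factor
        dummy-coded against group 0) or ``"continuous"`` (z-scored).
    covariates:
        Adjustment set; ``sex`` becomes a male=1 indicator, continuous
        covariates are z-scored, and a ``diagnosis`` covariate is dummy-coded
        against CU.
    zscore_sample:
        If given, z-scoring means/SDs are computed on this table ("whole
        sample" scaling) instead of the model's complete cases (default).
    """
    cols = [outcome, *predictors, *covariates]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"columns not in data: {missing}")
    df = data[cols].dropna().copy()
    n_params_guess = 1 + len(predictors) + len(covariates) + 3
    if len(df) < n_params_guess + 2:
        raise ValueError(
            f"only {len(df)} complete cases for outcome {outcome!r}; too few"
        )

    zs = (lambda c: None) if zscore_sample is None else (
        lambda c: zscore_sample[c].dropna() if c in zscore_sample else None
    )

    X = pd.DataFrame(index=df.index)
    for col, kind in predictors.items():
        if kind == "group":
            levels = [g for g in STAGE_GROUPS if g in set(df[col])]
            if "0" not in levels:
                raise ValueError(
                    f"reference stage group '0' absent from {col!r}; cannot fit"
                )
            if len(levels) < 2:
                raise ValueError(f"{col!r} has fewer than two levels present")
            for g in levels[1:]:
                X[f"stage {g}"] = (df[col] == g).astype(float)
        elif kind == "continuous":
            X[col] = _zstats(df[col], zs(col))
        else:
            raise ValueError(f"unknown predictor kind {kind!r}")

    for cov in covariates:
        if cov == "sex":
            bad = set(df["sex"]) - {"female", "male"}
            if bad:
                raise ValueError(f"unknown sex labels: {sorted(bad)}")
            X["sex (male)"] = (df["sex"] == "male").astype(float)
        elif cov == "diagnosis":
            for lvl in ("MCI", "AD"):
                if lvl in set(df[cov]):
                    X[f"diagnosis {lvl}"] = (df[cov] == lvl).astype(float)
        else:
            X[cov] = _zstats(df[cov], zs(cov))

    y = _zstats(df[outcome], zs(outcome))
    X = sm.add_constant(X, prepend=True)

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify offending columns via incremental rank growth
        collinear, seen = [], np.empty((len(X), 0))
        for c in X.columns:
            cand = np.column_stack([seen, X[c].to_numpy()])
            if np.linalg.matrix_rank(cand) == seen.shape[1]:
                collinear.append(c)
            else:
                seen = cand
        raise ValueError(f"design matrix is rank deficient; collinear terms: {collinear}")

    fit = sm.OLS(y.to_numpy(), X).fit()
    ci = fit.conf_int(alpha=0.05)
    terms = pd.DataFrame(
        {
            "beta": fit.params,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    ).drop(index="const")
    return RegressionResult(
        terms=terms,
        adj_r2=float(fit.rsquared_adj),
        f_stat=float(fit.fvalue),
        f_pvalue=float(fit.f_pvalue),
        n_used=int(fit.nobs),
        df_resid=float(fit.df_resid),
        outcome=outcome,
    )
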