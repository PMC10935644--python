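"""Cohort data model and CSV readers/writers.

The cohort is held as a tidy table with one row per participant-visit.
Canonical columns (all optional unless noted):

``id`` (required), ``visit`` (required; ``baseline``/``followup``),
``time_years`` (or ``visit_date``, ISO dates converted at 365.25 d/yr),
``age``, ``sex`` (``female``/``male``), ``diagnosis`` (``CU``/``MCI``/``AD``),
``education``, ``mmse``, ``faq_01..faq_10``, ``ecog_01..ecog_39``,
``cdrf_community``, ``cdrf_home``, ``cdrf_personal``, ``abeta_suvr``,
``suvr_braak_1..suvr_braak_6``.

On read, instrument totals (``faq_total``, ``ecog_mean``, ``cdrsbf_total``)
are derived only when every item of an instrument is present — no
imputation — and ``amyloid_status`` is derived from the baseline amyloid
SUVR. Rows failing validation are collected into a rejects table with a
reason, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .instruments import (
    AMYLOID_SUVR_CUTOFF,
    classify_amyloid,
    score_cdrsbf,
    score_ecog,
    score_faq,
)

__all__ = ["CohortTable", "read_cohort", "write_cohort", "derive_scores"]

DAYS_PER_YEAR = 365.25

FAQ_COLS = [f"faq_{i:02d}" for i in range(1, 11)]
ECOG_COLS = [f"ecog_{i:02d}" for i in range(1, 40)]
CDRF_COLS = ["cdrf_community", "cdrf_home", "cdrf_personal"]
BRAAK_SUVR_COLS = [f"suvr_braak_{i}" for i in range(1, 7)]

_SCORE_COLS = ("faq_total", "ecog_mean", "cdrsbf_total")


@dataclass
class CohortTable:
    """Validated participant-visit table plus the rows that failed validation."""

    data: pd.DataFrame
    rejects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["id", "visit", "reason"])
    )

    @property
    def n_participants(self) -> int:
        return self.data["id"].nunique()

    def baseline(self) -> pd.DataFrame:
        return self.data[self.data["visit"] == "baseline"].reset_index(drop=True)

    def followup(self) -> pd.DataFrame:
        return self.data[self.data["visit"] == "followup"].reset_index(drop=True)


def derive_scores(df: pd.DataFrame) -> pd.DataFrame:
    """Attach instrument totals and amyloid status to a validated table.

    A score column is filled only for rows whose items are all present;
    otherwise it is left missing (records without a score are excluded
    per-analysis downstream, not dropped from the cohort).
    """
    df = df.copy()

    def _score_row(row, cols, scorer):
        vals = [row.get(c) for c in cols]
        if any(pd.isna(v) for v in vals) or any(c not in row for c in cols):
            return np.nan
        return scorer(vals)

    have = set(df.columns)
    df["faq_total"] = (
        df.apply(lambda r: _score_row(r, FAQ_COLS, score_faq), axis=1)
        if set(FAQ_COLS) <= have
        else np.nan
    )
    df["ecog_mean"] = (
        df.apply(lambda r: _score_row(r, ECOG_COLS, score_ecog), axis=1)
        if set(ECOG_COLS) <= have
        else np.nan
    )
    df["cdrsbf_total"] = (
        df.apply(lambda r: _score_row(r, CDRF_COLS, score_cdrsbf), axis=1)
        if set(CDRF_COLS) <= have
        else np.nan
    )

    if "abeta_suvr" in have:
        base = df[df["visit"] == "baseline"].set_index("id")["abeta_suvr"]
        df["amyloid_status"] = [
            classify_amyloid(base[i]) if i in base.index and pd.notna(base[i]) else np.nan
            for i in df["id"]
        ]
    return df


def _validate_row(row: pd.Series) -> str | None:
    """Return a rejection reason for a row, or None if it is valid."""
    visit = row.get("visit")
    if visit not in ("baseline", "followup"):
        return f"unknown visit label {visit!r}"
    t = row.get("time_years")
    if pd.notna(t):
        if t < 0:
            return "negative visit time"
        if visit == "followup" and t <= 0:
            return "followup visit_time must be > 0"
    elif visit == "followup":
        return "followup without visit time"
    for c in FAQ_COLS:
        v = row.get(c)
        if pd.notna(v) and (float(v) not in (0.0, 1.0, 2.0, 3.0)):
            return "faq item out of range"
    for c in ECOG_COLS:
        v = row.get(c)
        if pd.notna(v) and (float(v) not in (1.0, 2.0, 3.0, 4.0)):
            return "ecog item out of range"
    for c in CDRF_COLS:
        v = row.get(c)
        if pd.notna(v) and float(v) not in (0.0, 0.5, 1.0, 2.0, 3.0):
            return "cdr functional box value not in {0, 0.5, 1, 2, 3}"
    for c in ("age", "abeta_suvr") + tuple(BRAAK_SUVR_COLS):
        v = row.get(c)
        if pd.notna(v) and (not np.isfinite(float(v)) or float(v) < 0):
            return f"non-finite or negative value in {c}"
    mmse = row.get("mmse")
    if pd.notna(mmse) and not 0 <= float(mmse) <= 30:
        return "mmse out of range"
    sex = row.get("sex")
    if pd.notna(sex) and sex not in ("female", "male"):
        return f"unknown sex label {sex!r}"
    dx = row.get("diagnosis")
    if pd.notna(dx) and dx not in ("CU", "MCI", "AD"):
        return f"unknown diagnosis label {dx!r}"
    return None


def read_cohort(
    path,
    column_dictionary: dict[str, str] | None = None,
    amyloid_cutoff: float = AMYLOID_SUVR_CUTOFF,
) -> CohortTable:
    """Read a participant-visit CSV into a validated :class:`CohortTable`.

    Parameters
    ----------
    path:
        CSV file with a header row, one row per participant-visit.
    column_dictionary:
        Optional mapping from file headers to canonical column names.
    amyloid_cutoff:
        Neocortical amyloid SUVR positivity cutoff (strict ``>``).

    Raises
    ------
    ValueError
        If the mandatory ``id``/``visit`` columns are absent.
    """
    df = pd.read_csv(path, dtype={"id": str})
    if column_dictionary:
        df = df.rename(columns=column_dictionary)
    missing = {"id", "visit"} - set(df.columns)
    if missing:
        raise ValueError(f"mandatory columns missing from {path}: {sorted(missing)}")

    if "time_years" not in df.columns and "visit_date" in df.columns:
        dates = pd.to_datetime(df["visit_date"])
        base = (
            pd.DataFrame({"id": df["id"], "date": dates})
            .loc[df["visit"] == "baseline"]
            .set_index("id")["date"]
        )
        df["time_years"] = [
            (d - base[i]).days / DAYS_PER_YEAR if i in base.index else np.nan
            for i, d in zip(df["id"], dates)
        ]

    reasons = df.apply(_validate_row, axis=1)

    # one baseline per participant, at most one follow-up
    for pid, grp in df.groupby("id"):
        n_base = (grp["visit"] == "baseline").sum()
        n_fu = (grp["visit"] == "followup").sum()
        if n_base != 1:
            reasons.loc[grp.index] = reasons.loc[grp.index].fillna(
                f"participant has {n_base} baseline visits (expected 1)"
            )
        elif n_fu > 1:
            bad = grp.index[grp["visit"] == "followup"]
            reasons.loc[bad] = reasons.loc[bad].fillna("more than one followup visit")

    ok = reasons.isna()
    rejects = df.loc[~ok, ["id", "visit"]].copy()
    rejects["reason"] = reasons[~ok].values
    data = df.loc[ok].reset_index(drop=True)
    data = derive_scores(data)
    if "amyloid_status" in data.columns and amyloid_cutoff != AMYLOID_SUVR_CUTOFF:
        base = data[data["visit"] == "baseline"].set_index("id")["abeta_suvr"]
        data["amyloid_status"] = [
            classify_amyloid(base[i], amyloid_cutoff)
            if i in base.index and pd.notna(base[i])
            else np.nan
            for i in data["id"]
        ]
    return CohortTable(data=data, rejects=rejects.reset_index(drop=True))


def write_cohort(cohort: CohortTable, path, include_derived: bool = False) -> None:
    """Write the cohort back to CSV (derived score columns omitted by default)."""
    df = cohort.data
    if not include_derived:
        drop = [c for c in (*_SCORE_COLS, "amyloid_status") if c in df.columns]
        df = df.drop(columns=drop)
    df.to_csv(path, index=False)
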