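"""PET-based Braak staging from regional tau-PET SUVR.

A participant's tau-PET SUVR is summarised in six composite regions of
interest corresponding to Braak's neuropathological stages I–VI of
neurofibrillary-tangle spread. Each ROI has an abnormality threshold
estimated from a young cognitively-unimpaired reference sample (mean +
k x SD, default k = 2.5, sample SD with n-1 denominator). A participant
is assigned the *latest* (highest) stage whose ROI is abnormal — stage 0
if none — and the stages are binned into the simplified groups
0, I–II, III–IV and V–VI.

Abnormality spreading out of anatomical order (e.g. ROI V abnormal while
I–IV are normal) does not occur under the classical model; such skip
patterns are still staged by the literal latest-abnormal rule, but are
flagged by the ``contiguous`` diagnostic and logged as warnings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import BRAAK_SUVR_COLS, CohortTable

__all__ = [
    "ROIS",
    "STAGE_GROUPS",
    "StageThresholds",
    "StageAssignment",
    "estimate_thresholds",
    "flag_abnormal",
    "assign_stage",
    "stage_cohort",
    "stage_to_group",
    "group_counts",
]

logger = logging.getLogger(__name__)

#: Braak ROIs in anatomical order (I = transentorhinal ... VI = primary cortices).
ROIS = ("I", "II", "III", "IV", "V", "VI")
#: Simplified stage groups, in severity order.
STAGE_GROUPS = ("0", "I-II", "III-IV", "V-VI")

_ROI_TO_COL = dict(zip(ROIS, BRAAK_SUVR_COLS))


def stage_to_group(stage: int) -> str:
    """Map a numeric stage 0–6 to its simplified group label."""
    if stage == 0:
        return "0"
    if stage <= 2:
        return "I-II"
    if stage <= 4:
        return "III-IV"
    return "V-VI"


@dataclass
class StageThresholds:
    """Per-ROI abnormality cutoffs with reference-sample provenance."""

    thresholds: dict[str, float]
    reference_mean: dict[str, float]
    reference_sd: dict[str, float]
    reference_n: dict[str, int]
    sd_multiplier: float = 2.5

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi": list(ROIS),
                "threshold": [self.thresholds[r] for r in ROIS],
                "ref_mean": [self.reference_mean[r] for r in ROIS],
                "ref_sd": [self.reference_sd[r] for r in ROIS],
                "ref_n": [self.reference_n[r] for r in ROIS],
                "multiplier": self.sd_multiplier,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StageThresholds":
        df = pd.read_csv(path).set_index("roi")
        return cls(
            thresholds=df["threshold"].to_dict(),
            reference_mean=df["ref_mean"].to_dict(),
            reference_sd=df["ref_sd"].to_dict(),
            reference_n=df["ref_n"].astype(int).to_dict(),
            sd_multiplier=float(df["multiplier"].iloc[0]),
        )


def estimate_thresholds(
    reference,
    sd_multiplier: float = 2.5,
    age_limit: float | None = 26.0,
) -> StageThresholds:
    """Estimate per-ROI abnormality thresholds from a young reference sample.

    Parameters
    ----------
    reference:
        Either a mapping ROI -> sequence of SUVR values, or a DataFrame with
        the canonical ``suvr_braak_1..6`` columns (and optionally ``age``,
        filtered to ``age < age_limit`` when present).
    sd_multiplier:
        k in threshold = mean + k x SD (sample SD, n-1 denominator).
    age_limit:
        Upper age bound (exclusive) applied when the reference is a table
        with an ``age`` column; ``None`` disables the filter.
    """
    if isinstance(reference, pd.DataFrame):
        df = reference
        if age_limit is not None and "age" in df.columns:
            df = df[df["age"] < age_limit]
        samples = {roi: df[_ROI_TO_COL[roi]].dropna().to_numpy() for roi in ROIS}
    else:
        samples = {roi: np.asarray(list(reference[roi]), dtype=float) for roi in ROIS}

    thresholds, means, sds, ns = {}, {}, {}, {}
    for roi in ROIS:
        vals = np.asarray(samples[roi], dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 2:
            raise ValueError(
                f"reference sample for ROI {roi} has {len(vals)} values (need >= 2)"
            )
        if np.any(vals <= 0):
            raise ValueError(f"reference SUVR values for ROI {roi} must be positive")
        m, s = float(np.mean(vals)), float(np.std(vals, ddof=1))
        means[roi], sds[roi], ns[roi] = m, s, int(len(vals))
        thresholds[roi] = m + sd_multiplier * s
    return StageThresholds(thresholds, means, sds, ns, sd_multiplier)


def flag_abnormal(
    profile: Mapping[str, float], thresholds: StageThresholds
) -> dict[str, bool]:
    """Flag each ROI abnormal iff its SUVR strictly exceeds its threshold."""
    flags = {}
    for roi in ROIS:
        if roi not in profile or pd.isna(profile[roi]):
            raise ValueError(f"SUVR profile is missing ROI {roi}")
        v = float(profile[roi])
        if not np.isfinite(v):
            raise ValueError(f"non-finite SUVR for ROI {roi}: {v!r}")
        flags[roi] = v > thresholds.thresholds[roi]
    return flags


@dataclass
class StageAssignment:
    """Result of the latest-abnormal staging rule for one participant."""

    flags: dict[str, bool]
    stage: int  # 0..6
    group: str  # one of STAGE_GROUPS
    contiguous: bool


def assign_stage(flags: Mapping[str, bool]) -> StageAssignment:
    """Assign the latest (highest) abnormal stage; 0 if all ROIs are normal.

    ``contiguous`` is True iff every ROI below the assigned stage is also
    abnormal; skip patterns are logged as warnings, never errors.
    """
    missing = set(ROIS) - set(flags)
    if missing:
        raise ValueError(f"flags missing ROIs: {sorted(missing)}")
    abnormal = [i + 1 for i, roi in enumerate(ROIS) if bool(flags[roi])]
    stage = max(abnormal, default=0)
    contiguous = len(abnormal) == stage
    if not contiguous:
        logger.warning(
            "non-contiguous abnormality pattern %s staged as %d by the "
            "latest-abnormal rule",
            {r: bool(flags[r]) for r in ROIS},
            stage,
        )
    return StageAssignment(
        flags={r: bool(flags[r]) for r in ROIS},
        stage=stage,
        group=stage_to_group(stage),
        contiguous=contiguous,
    )


def stage_cohort(cohort: CohortTable, thresholds: StageThresholds) -> CohortTable:
    """Assign a PET-based Braak stage to every participant from baseline SUVRs.

    Adds ``stage``, ``stage_group`` and ``stage_contiguous`` columns to all
    rows of the cohort (the assignment is made once, at baseline).
    Participants with incomplete baseline profiles are excluded with a
    logged reason and left unstaged (missing values).
    """
    df = cohort.data.copy()
    base = df[df["visit"] == "baseline"]
    assignments: dict[str, StageAssignment] = {}
    for _, row in base.iterrows():
        profile = {roi: row.get(_ROI_TO_COL[roi]) for roi in ROIS}
        if any(pd.isna(v) for v in profile.values()):
            logger.info("participant %s excluded from staging: incomplete SUVR profile",
                        row["id"])
            continue
        assignments[row["id"]] = assign_stage(flag_abnormal(profile, thresholds))

    df["stage"] = [
        assignments[i].stage if i in assignments else np.nan for i in df["id"]
    ]
    df["stage_group"] = [
        assignments[i].group if i in assignments else np.nan for i in df["id"]
    ]
    df["stage_contiguous"] = [
        assignments[i].contiguous if i in assignments else np.nan for i in df["id"]
    ]
    return CohortTable(data=df, rejects=cohort.rejects)


def group_counts(staged: CohortTable | pd.DataFrame) -> pd.Series:
    """Participant counts per simplified stage group, in severity order."""
    df = staged.data if isinstance(staged, CohortTable) else staged
    base = df[df["visit"] == "baseline"] if "visit" in df.columns else df
    counts = base["stage_group"].value_counts()
    return counts.reindex(STAGE_GROUPS, fill_value=0).astype(int)
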