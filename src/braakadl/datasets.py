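"""Published summary tables bundled as example data.

Small summary tables from a published tau-PET Braak-staging cohort of
291 adults across the Alzheimer's disease continuum, included so the
bookkeeping and ratio operations can be exercised against real printed
numbers. Participant-level data are not public; everything here is
aggregate.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "stage_group_sizes",
    "stage_group_female_counts",
    "stage_group_cu_counts",
    "trial_sizes_per_arm",
]


def stage_group_sizes() -> pd.Series:
    """Participants per simplified PET-based Braak stage group (total 291)."""
    return pd.Series({"0": 112, "I-II": 78, "III-IV": 35, "V-VI": 66}, name="n")


def stage_group_female_counts() -> pd.Series:
    """Female participants per stage group (cohort total 183 of 291)."""
    return pd.Series({"0": 68, "I-II": 55, "III-IV": 22, "V-VI": 38}, name="n_female")


def stage_group_cu_counts() -> pd.Series:
    """Cognitively unimpaired participants per stage group (total 181)."""
    return pd.Series({"0": 108, "I-II": 56, "III-IV": 17, "V-VI": 0}, name="n_cu")


def trial_sizes_per_arm() -> pd.DataFrame:
    """Published per-arm sample sizes (rows: stage group; columns: instrument).

    Per-arm n required to observe a 25% slowing of functional decline at
    80% power when recruiting at each baseline stage group, per instrument.
    """
    return pd.DataFrame(
        {
            "faq": {"I-II": 3951, "III-IV": 1170, "V-VI": 78},
            "ecog": {"I-II": 6925, "III-IV": 565, "V-VI": 265},
            "cdrsbf": {"I-II": 4020, "III-IV": 8204, "V-VI": 288},
        }
    ).loc[["I-II", "III-IV", "V-VI"]]
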