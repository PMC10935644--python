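"""Scoring of the functional instruments and amyloid-PET positivity.

Three informant-based instruments quantify performance in activities of
daily living (ADL):

* FAQ — Functional Activities Questionnaire: 10 instrumental-ADL items,
  each rated 0 (normal) to 3 (dependent); total 0–30, higher = worse.
* ECog — Everyday Cognition: 39 items rated 1 (better or no change) to
  4 (consistently much worse); the score is the mean item response, so
  it lives on [1, 4], higher = worse.
* CDR-SB-F — the sum of the three *functional* boxes of the Clinical
  Dementia Rating (community affairs, home and hobbies, personal care),
  each in {0, 0.5, 1, 2, 3}; total 0–9.

Amyloid-beta status is a dichotomisation of the neocortical amyloid-PET
SUVR at a fixed cutoff (default 1.55, strictly greater-than).
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

__all__ = [
    "score_faq",
    "score_ecog",
    "score_cdrsbf",
    "classify_amyloid",
    "FAQ_N_ITEMS",
    "ECOG_N_ITEMS",
    "CDR_FUNCTIONAL_BOXES",
    "CDR_BOX_VALUES",
    "AMYLOID_SUVR_CUTOFF",
]

FAQ_N_ITEMS = 10
ECOG_N_ITEMS = 39
CDR_FUNCTIONAL_BOXES = ("community", "home", "personal")
#: Allowed per-box values of the standard CDR instrument.
CDR_BOX_VALUES = (0.0, 0.5, 1.0, 2.0, 3.0)
#: Neocortical amyloid-PET SUVR positivity cutoff (strict ``>``).
AMYLOID_SUVR_CUTOFF = 1.55


def _as_int_items(items: Sequence, n: int, lo: int, hi: int, name: str) -> list[int]:
    items = list(items)
    if len(items) != n:
        raise ValueError(f"{name} requires exactly {n} items, got {len(items)}")
    out = []
    for i, v in enumerate(items):
        try:
            f = float(v)
        except (TypeError, ValueError):
            raise ValueError(f"{name} item {i + 1} is not numeric: {v!r}") from None
        if not math.isfinite(f) or not f.is_integer() or not lo <= f <= hi:
            raise ValueError(
                f"{name} item {i + 1} out of range: {v!r} (allowed integers {lo}..{hi})"
            )
        out.append(int(f))
    return out


def score_faq(items: Iterable) -> int:
    """Total FAQ score: the sum of the 10 item ratings (0–30)."""
    return sum(_as_int_items(items, FAQ_N_ITEMS, 0, 3, "FAQ"))


def score_ecog(items: Iterable) -> float:
    """ECog score: the arithmetic mean of the 39 item ratings (1–4)."""
    return sum(_as_int_items(items, ECOG_N_ITEMS, 1, 4, "ECog")) / ECOG_N_ITEMS


def score_cdrsbf(boxes: Iterable) -> float:
    """CDR-SB-F: the sum of the three functional box scores (0–9).

    Each box must take one of the standard CDR values {0, 0.5, 1, 2, 3};
    anything else (e.g. 1.5) raises ``ValueError``.
    """
    boxes = list(boxes)
    if len(boxes) != len(CDR_FUNCTIONAL_BOXES):
        raise ValueError(
            f"CDR-SB-F requires exactly {len(CDR_FUNCTIONAL_BOXES)} box scores, "
            f"got {len(boxes)}"
        )
    total = 0.0
    for i, v in enumerate(boxes):
        try:
            f = float(v)
        except (TypeError, ValueError):
            raise ValueError(f"CDR box {i + 1} is not numeric: {v!r}") from None
        if f not in CDR_BOX_VALUES:
            raise ValueError(
                f"CDR box {i + 1} has disallowed value {v!r} "
                f"(allowed: {CDR_BOX_VALUES})"
            )
        total += f
    return total


def classify_amyloid(neocortical_suvr: float, cutoff: float = AMYLOID_SUVR_CUTOFF) -> str:
    """Dichotomise neocortical amyloid-PET SUVR into 'positive'/'negative'.

    Positivity requires the SUVR to be *strictly* greater than ``cutoff``;
    a value exactly at the cutoff is negative.
    """
    try:
        f = float(neocortical_suvr)
    except (TypeError, ValueError):
        raise ValueError(f"amyloid SUVR is not numeric: {neocortical_suvr!r}") from None
    if not math.isfinite(f) or f <= 0:
        raise ValueError(f"amyloid SUVR must be finite and positive, got {neocortical_suvr!r}")
    return "positive" if f > cutoff else "negative"
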