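"""Data model for the 24-item moral-dilemma battery and participant scales.

The battery crosses two factors — whether a norm prohibits or favors the
described action, and whether its benefits outweigh its costs — giving four
scenario categories with six stories each:

    ``PB``  norm-prohibited, benefits > costs   (the classic trolley cell)
    ``PC``  norm-prohibited, costs > benefits
    ``AB``  norm-allowed,    benefits > costs
    ``AC``  norm-allowed,    costs > benefits

"Norm-allowed" is read prescriptively (the norm favors acting), matching the
standard published scenario set.  Participants rate acceptability of each
action on a 1-6 Likert scale; the dichotomized analyses recode 4-6 as
approval and 1-3 as disapproval.

Participant-level scales handled here: the 10/14-item Perceived Stress Scale
(items 0-4, reverse-keyed positives), a 13-item yes/no social-desirability
scale, plus acute-stress and attention-check screening flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "NORM_KIND",
    "CONSEQUENCE_KIND",
    "PSS10_REVERSE_ITEMS",
    "PSS14_REVERSE_ITEMS",
    "CategoryProfile",
    "default_battery",
    "validate_battery",
    "recode_rating",
    "score_pss",
    "score_social_desirability",
    "screen_participants",
    "aggregate_profile",
    "aggregate_profiles",
    "median_split",
    "cronbach_alpha",
]

#: Category codes, in the fixed column order used throughout the package.
CATEGORIES: tuple[str, ...] = ("PB", "PC", "AB", "AC")

NORM_KIND: Mapping[str, str] = {
    "PB": "prohibited",
    "PC": "prohibited",
    "AB": "allowed",
    "AC": "allowed",
}
CONSEQUENCE_KIND: Mapping[str, str] = {
    "PB": "benefits_gt_costs",
    "PC": "costs_gt_benefits",
    "AB": "benefits_gt_costs",
    "AC": "costs_gt_benefits",
}

# Standard instrument keying (1-based item positions that are reverse-scored).
PSS10_REVERSE_ITEMS: tuple[int, ...] = (4, 5, 7, 8)
PSS14_REVERSE_ITEMS: tuple[int, ...] = (4, 5, 6, 7, 9, 10, 13)


@dataclass(frozen=True)
class DilemmaItem:
    """One scenario of the battery."""

    item_id: str
    story_id: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")

    @property
    def norm_kind(self) -> str:
        return NORM_KIND[self.category]

    @property
    def consequence_kind(self) -> str:
        return CONSEQUENCE_KIND[self.category]


@dataclass
class CategoryProfile:
    """A participant's four per-category response summaries.

    ``values`` holds acceptance proportions (binary mode, each in [0, 1]) or
    mean raw ratings (continuous mode, each in [1, 6]); ``counts`` the number
    of trials behind each value.
    """

    participant_id: str
    mode: str  # "binary" | "continuous"
    values: dict[str, float] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)

    def as_array(self) -> np.ndarray:
        """Values in fixed ``CATEGORIES`` order."""
        return np.array([self.values[c] for c in CATEGORIES], dtype=float)


def default_battery(items_per_category: int = 6) -> pd.DataFrame:
    """Construct the standard 2x2 battery layout.

    Six stories appear once per category (items_per_category=6); presentation
    order cycles through the stories so that no two adjacent scenarios share a
    story, mirroring the pre-randomized administration order.
    """
    n_stories = items_per_category
    rows = []
    order = 0
    for rep in range(4):
        for s in range(n_stories):
            cat = CATEGORIES[(s + rep) % 4]
            story = f"S{s + 1}"
            rows.append(
                {
                    "item_id": f"{cat}_{story}_{rep}" if items_per_category != 6 else f"{cat}_{story}",
                    "story_id": story,
                    "category": cat,
                    "presentation_order": order,
                }
            )
            order += 1
    battery = pd.DataFrame(rows)
    if items_per_category == 6:
        validate_battery(battery)
    return battery


def validate_battery(battery: pd.DataFrame) -> None:
    """Check the 24-item battery invariants; raise ``ValueError`` on failure."""
    required = {"item_id", "story_id", "category", "presentation_order"}
    missing = required - set(battery.columns)
    if missing:
        raise ValueError(f"battery missing columns: {sorted(missing)}")
    counts = battery["category"].value_counts()
    for cat in CATEGORIES:
        if counts.get(cat, 0) != 6:
            raise ValueError(f"category {cat} has {counts.get(cat, 0)} items, expected 6")
    if len(battery) != 24 or battery["item_id"].duplicated().any():
        raise ValueError("battery must contain 24 unique items")
    ordered = battery.sort_values("presentation_order")["story_id"].to_numpy()
    if (ordered[1:] == ordered[:-1]).any():
        raise ValueError("adjacent items share a story")


def recode_rating(rating):
    """Dichotomize 1-6 acceptability ratings: 4-6 -> approve (1), 1-3 -> reject (0).

    Accepts scalars or arrays; validates that every rating is an integer in 1..6.
    """
    arr = np.asarray(rating)
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError("ratings must be numeric")
    if np.any((arr < 1) | (arr > 6)) or np.any(arr != np.floor(arr)):
        raise ValueError("ratings must be integers in 1..6")
    accept = (arr >= 4).astype(int)
    return accept if arr.ndim else int(accept)


def score_pss(items, version: int = 10, reverse_items: Sequence[int] | None = None):
    """Score the Perceived Stress Scale.

    Parameters
    ----------
    items
        Item responses in 0..4; a length-``version`` sequence, or a 2-d array
        (participants x items) for vectorized scoring.
    version
        10 or 14.
    reverse_items
        1-based positions to reverse-score (x -> 4 - x).  Defaults to the
        standard keying for each version.

    Returns
    -------
    Total score (int) in [0, 40] for PSS-10 or [0, 56] for PSS-14; an integer
    array when ``items`` is 2-d.
    """
    if version not in (10, 14):
        raise ValueError("version must be 10 or 14")
    if reverse_items is None:
        reverse_items = PSS10_REVERSE_ITEMS if version == 10 else PSS14_REVERSE_ITEMS
    arr = np.atleast_2d(np.asarray(items))
    if arr.shape[-1] != version:
        raise ValueError(f"expected {version} items, got {arr.shape[-1]}")
    if np.any((arr < 0) | (arr > 4)) or np.any(arr != np.floor(arr)):
        raise ValueError("item scores must be integers in 0..4")
    if any(p < 1 or p > version for p in reverse_items):
        raise ValueError("reverse_items positions out of range")
    scored = arr.copy().astype(int)
    idx = [p - 1 for p in reverse_items]
    scored[:, idx] = 4 - scored[:, idx]
    totals = scored.sum(axis=1)
    return totals if np.asarray(items).ndim == 2 else int(totals[0])


def score_social_desirability(responses, key: Sequence[int]):
    """Count responses matching the socially desirable keyed direction (0..13)."""
    key_arr = np.asarray(key)
    resp = np.atleast_2d(np.asarray(responses))
    if key_arr.shape[0] != resp.shape[-1]:
        raise ValueError(
            f"key length {key_arr.shape[0]} does not match {resp.shape[-1]} responses"
        )
    if not (np.isin(resp, (0, 1)).all() and np.isin(key_arr, (0, 1)).all()):
        raise ValueError("responses and key must be binary")
    totals = (resp == key_arr).sum(axis=1)
    return totals if np.asarray(responses).ndim == 2 else int(totals[0])


def screen_participants(
    records: pd.DataFrame,
    responses: pd.DataFrame,
    n_items: int = 24,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the exclusion rules, in order: recent acute stress, failed
    attention check, incomplete dilemma battery.

    Each excluded participant is logged once, with the first matching reason.

    Returns
    -------
    (retained_ids, exclusion_log) where the log has columns
    ``participant_id`` and ``reason``.
    """
    item_counts = responses.groupby("participant_id")["item_id"].nunique()
    retained: list[str] = []
    log_rows = []
    for _, rec in records.iterrows():
        pid = rec["participant_id"]
        if rec.get("acute_stress", 0) == 1:
            log_rows.append({"participant_id": pid, "reason": "acute_stress"})
        elif rec.get("attention_pass", 1) == 0:
            log_rows.append({"participant_id": pid, "reason": "attention_check"})
        elif item_counts.get(pid, 0) < n_items:
            log_rows.append({"participant_id": pid, "reason": "incomplete"})
        else:
            retained.append(pid)
    log = pd.DataFrame(log_rows, columns=["participant_id", "reason"])
    return retained, log


def _category_summary(group: pd.DataFrame, mode: str) -> float:
    if mode == "binary":
        if "accept" in group:
            vals = group["accept"].to_numpy()
        else:
            vals = recode_rating(group["rating"].to_numpy())
        return float(np.mean(vals))
    return float(group["rating"].mean())


def aggregate_profile(responses: pd.DataFrame, mode: str = "binary") -> CategoryProfile:
    """Summarize one participant's responses into a :class:`CategoryProfile`.

    Binary mode averages recoded (or native) accept/reject indicators per
    category; continuous mode averages the raw 1-6 ratings.
    """
    if mode not in ("binary", "continuous"):
        raise ValueError("mode must be 'binary' or 'continuous'")
    pids = responses["participant_id"].unique()
    if len(pids) != 1:
        raise ValueError("aggregate_profile expects responses of a single participant")
    if mode == "continuous" and "rating" not in responses:
        raise ValueError("continuous mode requires a rating column")
    profile = CategoryProfile(participant_id=str(pids[0]), mode=mode)
    grouped = dict(tuple(responses.groupby("category")))
    for cat in CATEGORIES:
        if cat not in grouped or len(grouped[cat]) == 0:
            raise ValueError(f"no responses in category {cat}")
        profile.values[cat] = _category_summary(grouped[cat], mode)
        profile.counts[cat] = len(grouped[cat])
    return profile


def aggregate_profiles(responses: pd.DataFrame, mode: str = "binary") -> pd.DataFrame:
    """Vectorized per-participant category summaries.

    Returns a frame indexed by participant with value columns ``PB..AC`` and
    trial-count columns ``n_PB..n_AC``.
    """
    if mode == "binary":
        df = responses.copy()
        if "accept" not in df:
            df["accept"] = recode_rating(df["rating"].to_numpy())
        value_col = "accept"
    else:
        if "rating" not in responses:
            raise ValueError("continuous mode requires a rating column")
        df = responses
        value_col = "rating"
    g = df.groupby(["participant_id", "category"])[value_col]
    values = g.mean().unstack("category")
    counts = g.count().unstack("category")
    missing = [c for c in CATEGORIES if c not in values.columns]
    if missing or values.isna().any().any():
        raise ValueError(f"some participants lack responses in categories {missing or 'present'}")
    out = values[list(CATEGORIES)].astype(float)
    for cat in CATEGORIES:
        out[f"n_{cat}"] = counts[cat].astype(int)
    return out


def median_split(
    scores: pd.Series, tie_policy: str = "low"
) -> tuple[pd.Series, pd.DataFrame]:
    """Split participants into high/low groups at the sample median.

    Scores strictly above the median go to ``high``, strictly below to
    ``low``; scores equal to the median follow ``tie_policy`` ("low" by
    default, or "high").  This dichotomization step exists to reproduce the
    practice the analyses critique; prefer the continuous score.

    Returns
    -------
    (labels, summary) — labels is a Series of {"high","low"}; summary has one
    row per group with columns M, SD, N.
    """
    if tie_policy not in ("low", "high"):
        raise ValueError("tie_policy must be 'low' or 'high'")
    if len(scores) < 2:
        raise ValueError("median split needs at least 2 scores")
    if scores.nunique() == 1:
        raise ValueError("degenerate split: all scores equal")
    med = scores.median()
    labels = pd.Series(
        np.where(scores > med, "high", np.where(scores < med, "low", tie_policy)),
        index=scores.index,
        name="stress_group",
    )
    summary = (
        pd.DataFrame({"score": scores, "group": labels})
        .groupby("group")["score"]
        .agg(M="mean", SD="std", N="count")
        .reindex(["high", "low"])
    )
    return labels, summary


def cronbach_alpha(items: np.ndarray) -> float:
    """Descriptive internal-consistency alpha for an items matrix (rows = persons)."""
    arr = np.asarray(items, dtype=float)
    k = arr.shape[1]
    item_var = arr.var(axis=0, ddof=1).sum()
    total_var = arr.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total variance")
    return k / (k - 1) * (1 - item_var / total_var)
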