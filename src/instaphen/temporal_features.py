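"""Posting-rate and temporal-distribution features.

Timestamps are binned into four times of day — night [0, 6), morning [6, 12),
afternoon [12, 18), evening [18, 24) — and seven weekdays (Monday first, ISO
convention).  Usage duration is the span between the first and the last post;
a month is 30.44 days throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime

import numpy as np

from .archive_io import MediaPost

#: mean Gregorian month length in days; single conversion used everywhere
DAYS_PER_MONTH = 30.44

TIME_OF_DAY_BINS = ("night", "morning", "afternoon", "evening")
WEEKDAYS = ("mon", "tue", "wed", "thu", "fri", "sat", "sun")

TEMPORAL_FEATURES = (
    "usage_months",
    "posts_per_month",
    *(f"prop_{b}" for b in TIME_OF_DAY_BINS),
    *(f"prop_{d}" for d in WEEKDAYS),
)


def time_of_day_bin(t: datetime) -> str:
    """Bin a local-clock timestamp into night/morning/afternoon/evening.

    Bins are half-open with the lower bound inclusive, so 06:00 is morning
    and 00:00 is night.
    """
    return TIME_OF_DAY_BINS[t.hour // 6]


def usage_months(posts: list[MediaPost]) -> float:
    """Months (30.44-day) between the first and the last post."""
    if len(posts) < 2:
        raise ValueError("usage duration needs at least 2 posts")
    span = posts[-1].timestamp - posts[0].timestamp
    return span.total_seconds() / 86400.0 / DAYS_PER_MONTH


@dataclass(frozen=True)
class TemporalFeatures:
    usage_months: float
    posts_per_month: float
    prop_by_timeofday: tuple[float, float, float, float]
    prop_by_weekday: tuple[float, ...]

    def __post_init__(self) -> None:
        for vec in (self.prop_by_timeofday, self.prop_by_weekday):
            if abs(sum(vec) - 1.0) > 1e-9 or min(vec) < 0 or max(vec) > 1:
                raise ValueError(f"invalid proportion vector {vec}")

    def as_dict(self) -> dict[str, float]:
        out = {
            "usage_months": self.usage_months,
            "posts_per_month": self.posts_per_month,
        }
        out.update(zip((f"prop_{b}" for b in TIME_OF_DAY_BINS), self.prop_by_timeofday))
        out.update(zip((f"prop_{d}" for d in WEEKDAYS), self.prop_by_weekday))
        return out


def temporal_profile(posts: list[MediaPost]) -> TemporalFeatures:
    """Posting rate plus time-of-day and weekday proportion vectors."""
    if len(posts) < 2:
        raise ValueError("temporal profile needs at least 2 posts")
    months = usage_months(posts)
    tod = np.zeros(4)
    wd = np.zeros(7)
    for post in posts:
        tod[post.timestamp.hour // 6] += 1
        wd[post.timestamp.weekday()] += 1
    n = len(posts)
    return TemporalFeatures(
        usage_months=months,
        posts_per_month=n / months,
        prop_by_timeofday=tuple(tod / n),
        prop_by_weekday=tuple(wd / n),
    )
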