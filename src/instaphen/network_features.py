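"""Connection statistics: absolute, duration-normalized and relative metrics.

The follower/following ratio is scale-invariant in the counts and therefore
insensitive to how long an account has existed, which is why it is preferred
over raw counts; ratios with a zero denominator are *missing* (NaN), never
zero or infinite, and are dropped pairwise downstream with a logged count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .archive_io import CONNECTION_TYPES, ConnectionLists

logger = logging.getLogger("instaphen")

#: short feature keys per connection type, in report order
CONNECTION_KEYS = {
    "followers": "follower",
    "following": "following",
    "requested": "request",
    "hashtag_follows": "hashtag",
    "blocked": "blocked",
    "close_friends": "close",
    "restricted": "restricted",
}

NETWORK_FEATURES = (
    *CONNECTION_KEYS.values(),
    *(f"{k}_per_month" for k in CONNECTION_KEYS.values()),
    "follower_following_ratio",
    "request_following_ratio",
)


@dataclass(frozen=True)
class NetworkFeatures:
    """All connection metrics for one participant."""

    counts: dict[str, int]
    usage_months: float
    normalized: dict[str, float]
    follower_following_ratio: float
    request_following_ratio: float

    def as_dict(self) -> dict[str, float]:
        out = {CONNECTION_KEYS[k]: float(v) for k, v in self.counts.items()}
        out.update(
            {f"{CONNECTION_KEYS[k]}_per_month": v for k, v in self.normalized.items()}
        )
        out["follower_following_ratio"] = self.follower_following_ratio
        out["request_following_ratio"] = self.request_following_ratio
        return out


def connection_stats(conn: ConnectionLists, usage_months: float) -> NetworkFeatures:
    """Compute absolute, per-month and ratio connection metrics.

    ``usage_months`` must be positive (it is the participant's posting span
    in 30.44-day months).  When ``following`` is zero both ratios are NaN.
    """
    if usage_months <= 0:
        raise ValueError(f"usage_months must be > 0, got {usage_months}")
    counts = {name: conn.count(name) for name in CONNECTION_TYPES}
    normalized = {name: counts[name] / usage_months for name in CONNECTION_TYPES}
    if counts["following"] == 0:
        logger.info("following count is 0; ratio metrics flagged missing")
        ff = rf = math.nan
    else:
        ff = counts["followers"] / counts["following"]
        rf = counts["requested"] / counts["following"]
    return NetworkFeatures(
        counts=counts,
        usage_months=usage_months,
        normalized=normalized,
        follower_following_ratio=ff,
        request_following_ratio=rf,
    )
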