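"""Reading and writing per-participant social-media archive exports.

An *archive* is the directory a participant obtains by requesting their data
export from the platform: a media-metadata document (one record per posted
image, with a timestamp and a file reference), connection lists (followers,
following, pending requests, ...) and a demographics record added by the study
team.  Real export schemas changed repeatedly over the study window, so this
module defines one documented *canonical* JSON dialect plus a small adapter
registry under which further dialects can be registered.

Canonical dialect layout::

    root/
      demographics.json   {"participant_id", "group", "age", "sex", "race", "ethnicity"}
      media.json          {"media": [{"post_id", "taken_at": ISO-8601,
                                      "path": "images/<f>.png", "width", "height"}, ...]}
      connections.json    {"followers": [...], "following": [...], "requested": [...],
                           "hashtag_follows": [...], "blocked": [...],
                           "close_friends": [...], "restricted": [...]}
      faces.json          optional sidecar {"<post_id>": ground-truth face count}
      images/             PNG/JPEG rasters

Non-image media (videos, unknown extensions) are dropped with a counted log
message; unreadable image files are kept as posts flagged ``missing_image``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Callable, NamedTuple

from PIL import Image

logger = logging.getLogger("instaphen")

#: eligibility window in years for participant age
DEFAULT_AGE_RANGE = (15.0, 35.0)

#: file suffixes treated as analyzable still images
IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}

GROUPS = ("HV", "SSD")
SEXES = ("female", "male")
#: categorical race levels used throughout (4 levels)
RACE_LEVELS = ("African American", "Native American", "Other/mixed", "White")

CONNECTION_TYPES = (
    "followers",
    "following",
    "requested",
    "hashtag_follows",
    "blocked",
    "close_friends",
    "restricted",
)


class ArchiveParseError(Exception):
    """Raised when an archive directory cannot be parsed."""


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MediaPost:
    """One posted image: identity, timestamp and raster reference."""

    post_id: str
    timestamp: datetime
    image_path: Path | None
    width: int
    height: int
    missing_image: bool = False

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError(
                f"post {self.post_id}: width/height must be >= 1 "
                f"(got {self.width}x{self.height})"
            )


@dataclass(frozen=True)
class ConnectionLists:
    """Connection counts per type, with optional member lists.

    ``followers`` are inward subscriptions, ``following`` outward; ``requested``
    are outward requests not yet confirmed.  Remaining types are opaque counts
    taken from the export.  When a member list is present its length must equal
    the count.
    """

    followers: int
    following: int
    requested: int = 0
    hashtag_follows: int = 0
    blocked: int = 0
    close_friends: int = 0
    restricted: int = 0
    members: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in CONNECTION_TYPES:
            count = getattr(self, name)
            if count < 0:
                raise ValueError(f"negative {name} count: {count}")
            if name in self.members and len(self.members[name]) != count:
                raise ValueError(
                    f"{name}: count {count} != member list length "
                    f"{len(self.members[name])}"
                )

    def count(self, name: str) -> int:
        return int(getattr(self, name))


@dataclass(frozen=True)
class DemographicRecord:
    """Study-team demographics: group label plus matching covariates."""

    participant_id: str
    group: str
    age: float
    sex: str
    race: str
    ethnicity: str = "Non-Hispanic"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.age < 0:
            raise ValueError("age must be non-negative")

    def in_age_window(self, age_range: tuple[float, float] = DEFAULT_AGE_RANGE) -> bool:
        return age_range[0] <= self.age <= age_range[1]


@dataclass(frozen=True)
class ParticipantArchive:
    """One participant's parsed export (posts sorted ascending, unique ids)."""

    demographics: DemographicRecord
    posts: tuple[MediaPost, ...]
    connections: ConnectionLists
    n_dropped_media: int = 0
    face_truth: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.post_id for p in self.posts]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate post_id in archive")
        stamps = [p.timestamp for p in self.posts]
        if stamps != sorted(stamps):
            raise ValueError("posts must be sorted ascending by timestamp")

    @property
    def participant_id(self) -> str:
        return self.demographics.participant_id

    @property
    def group(self) -> str:
        return self.demographics.group


class InclusionResult(NamedTuple):
    included: bool
    reason: str

    def __bool__(self) -> bool:  # allows `if inclusion_filter(a): ...`
        return self.included


# ---------------------------------------------------------------------------
# Canonical dialect
# ---------------------------------------------------------------------------


def _read_json(path: Path) -> dict:
    if not path.exists():
        raise ArchiveParseError(f"missing metadata document: {path}")
    with open(path) as fh:
        return json.load(fh)


def _parse_canonical(root: Path, utc_offset_hours: float) -> ParticipantArchive:
    demo_raw = _read_json(root / "demographics.json")
    media_raw = _read_json(root / "media.json")
    conn_raw = _read_json(root / "connections.json")

    demographics = DemographicRecord(
        participant_id=str(demo_raw["participant_id"]),
        group=str(demo_raw["group"]),
        age=float(demo_raw["age"]),
        sex=str(demo_raw["sex"]),
        race=str(demo_raw["race"]),
        ethnicity=str(demo_raw.get("ethnicity", "Non-Hispanic")),
    )

    posts: list[MediaPost] = []
    n_dropped = 0
    for rec in media_raw.get("media", []):
        post_id = str(rec.get("post_id", "?"))
        rel = rec.get("path", "")
        if Path(rel).suffix.lower() not in IMAGE_SUFFIXES:
            n_dropped += 1
            continue
        try:
            stamp = datetime.fromisoformat(rec["taken_at"])
        except (KeyError, ValueError) as exc:
            raise ArchiveParseError(
                f"post {post_id}: unparseable timestamp {rec.get('taken_at')!r}"
            ) from exc
        if utc_offset_hours:
            stamp = stamp + timedelta(hours=utc_offset_hours)
        img_path = root / rel
        width = int(rec.get("width", 0))
        height = int(rec.get("height", 0))
        missing = True
        if img_path.exists():
            try:
                with Image.open(img_path) as im:
                    width, height = im.size
                missing = False
            except OSError:
                logger.warning("unreadable image for post %s: %s", post_id, img_path)
        else:
            logger.warning("image file absent for post %s: %s", post_id, img_path)
        posts.append(
            MediaPost(
                post_id=post_id,
                timestamp=stamp,
                image_path=img_path if not missing else None,
                width=max(width, 1),
                height=max(height, 1),
                missing_image=missing,
            )
        )
    if n_dropped:
        logger.info("%s: dropped %d non-image media records", root, n_dropped)
    posts.sort(key=lambda p: (p.timestamp, p.post_id))

    members = {
        name: tuple(str(m) for m in conn_raw[name])
        for name in CONNECTION_TYPES
        if isinstance(conn_raw.get(name), list)
    }
    counts = {
        name: (
            len(members[name])
            if name in members
            else int(conn_raw.get(name, 0) or 0)
        )
        for name in CONNECTION_TYPES
    }
    connections = ConnectionLists(**counts, members=members)

    face_truth: dict[str, int] = {}
    faces_path = root / "faces.json"
    if faces_path.exists():
        face_truth = {str(k): int(v) for k, v in _read_json(faces_path).items()}

    return ParticipantArchive(
        demographics=demographics,
        posts=tuple(posts),
        connections=connections,
        n_dropped_media=n_dropped,
        face_truth=face_truth,
    )


#: dialect name -> parser(root, utc_offset_hours) -> ParticipantArchive
DIALECTS: dict[str, Callable[[Path, float], ParticipantArchive]] = {
    "canonical": _parse_canonical,
}


def register_dialect(name: str, parser: Callable[[Path, float], ParticipantArchive]) -> None:
    """Register an additional export-schema adapter."""
    DIALECTS[name] = parser


def parse_archive(
    root: str | Path,
    dialect: str = "canonical",
    utc_offset_hours: float = 0.0,
    age_range: tuple[float, float] = DEFAULT_AGE_RANGE,
) -> ParticipantArchive:
    """Parse one participant's archive directory into the data model.

    Timestamps are kept in the archive's recorded local time; a fixed UTC
    offset (hours) can be applied.  Raises :class:`ArchiveParseError` for a
    missing metadata document or unparseable timestamp; unreadable image
    files are non-fatal (flagged ``missing_image``).
    """
    root = Path(root)
    if dialect not in DIALECTS:
        raise ArchiveParseError(
            f"unknown archive dialect {dialect!r}; known: {sorted(DIALECTS)}"
        )
    archive = DIALECTS[dialect](root, utc_offset_hours)
    if not archive.demographics.in_age_window(age_range):
        raise ArchiveParseError(
            f"participant {archive.participant_id}: age "
            f"{archive.demographics.age} outside eligibility window {age_range}"
        )
    return archive


def write_archive(
    archive: ParticipantArchive,
    root: str | Path,
    images: dict[str, "object"] | None = None,
) -> Path:
    """Write an archive to disk in the canonical dialect.

    ``images`` optionally maps post_id -> HxWx3 uint8 array to be saved as
    PNG under ``images/``; posts without a supplied raster are written as
    metadata-only records (they re-parse as ``missing_image``).
    """
    import numpy as np  # local: only needed when rasters are written

    root = Path(root)
    (root / "images").mkdir(parents=True, exist_ok=True)
    demo = archive.demographics
    with open(root / "demographics.json", "w") as fh:
        json.dump(
            {
                "participant_id": demo.participant_id,
                "group": demo.group,
                "age": demo.age,
                "sex": demo.sex,
                "race": demo.race,
                "ethnicity": demo.ethnicity,
            },
            fh,
            indent=1,
        )
    media = []
    for post in archive.posts:
        rel = f"images/{post.post_id}.png"
        media.append(
            {
                "post_id": post.post_id,
                "taken_at": post.timestamp.isoformat(timespec="seconds"),
                "path": rel,
                "width": post.width,
                "height": post.height,
            }
        )
        if images is not None and post.post_id in images:
            arr = np.asarray(images[post.post_id], dtype=np.uint8)
            Image.fromarray(arr).save(root / rel)
    with open(root / "media.json", "w") as fh:
        json.dump({"media": media}, fh, indent=1)
    conn = archive.connections
    payload: dict[str, object] = {}
    for name in CONNECTION_TYPES:
        if name in conn.members:
            payload[name] = list(conn.members[name])
        else:
            payload[name] = conn.count(name)
    with open(root / "connections.json", "w") as fh:
        json.dump(payload, fh, indent=1)
    if archive.face_truth:
        with open(root / "faces.json", "w") as fh:
            json.dump(archive.face_truth, fh, indent=1)
    return root


# ---------------------------------------------------------------------------
# Inclusion filter
# ---------------------------------------------------------------------------


def inclusion_filter(
    archive: ParticipantArchive,
    min_posts: int = 5,
    min_span_days: float = 90.0,
) -> InclusionResult:
    """Study inclusion rule: enough posts over a long-enough timespan.

    A participant is included iff they have at least ``min_posts`` posts and
    the span between first and last post is at least ``min_span_days`` days
    (the default operationalizes "3 months" as 90 days).
    """
    if not archive.posts:
        return InclusionResult(False, "no posts")
    if len(archive.posts) < min_posts:
        return InclusionResult(
            False, f"post count {len(archive.posts)} < {min_posts}"
        )
    span = archive.posts[-1].timestamp - archive.posts[0].timestamp
    if span < timedelta(days=min_span_days):
        return InclusionResult(
            False,
            f"span {span.total_seconds() / 86400.0:.1f} d < {min_span_days} d",
        )
    return InclusionResult(True, "included")
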