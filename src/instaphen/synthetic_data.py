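"""Synthetic two-group cohorts: archives, images, connections, timestamps.

No real patient archives can be shared, so every pipeline stage is exercised
on generated stand-ins.  The generator states one explicit world per config:

* participant-level image color structure (HSV means) is drawn from per-group
  normal distributions whose means and SDs are the published group summaries
  of the case-control study this package models (case group lower saturation,
  value and face count; control group higher follower counts);
* per-image pixel colors are sampled around the participant target and
  rendered as PNG-able RGB arrays, with frontal-face patches composited in
  and their count recorded as ground truth;
* connection counts are heavy-tailed (lognormal for follower/following,
  negative-binomial for the small count types);
* timestamps follow a weekly intensity with a configurable weekend uplift
  and a 4-bin time-of-day weighting.

Image counts and resolutions default to a scaled-down regime (6-20 posts of
48x48 px per participant) so that full-pipeline simulations fit in CI; the
participant-level (between-subject) structure that drives all group
statistics is at full scale.  Every generative parameter is recorded per
participant for recovery tests, and generation is fully deterministic given
(config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from skimage import color as _skcolor
from skimage.transform import resize

from .archive_io import (
    ConnectionLists,
    DemographicRecord,
    MediaPost,
    ParticipantArchive,
    write_archive,
)
from .temporal_features import DAYS_PER_MONTH

#: fixed calendar anchor for synthetic timelines (after the aspect cutoff)
EPOCH = datetime(2016, 6, 1)

_GROUPS = ("HV", "SSD")


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Generative parameters for a two-group cohort.

    Per-group dictionaries are keyed 'HV' (controls) and 'SSD' (cases).
    HSV triplets are (hue [0,180), saturation [0,255], value [0,255]).
    """

    n_per_group: int = 34
    #: posts per participant for rendered archives (uniform int range, scaled down)
    posts_per_participant: tuple[int, int] = (6, 20)
    #: usage span in 30.44-day months (uniform range; study range 3-91)
    months_span: tuple[float, float] = (3.1, 91.0)
    image_size: tuple[int, int] = (48, 48)
    face_patch_px: int = 12

    #: group-level mean HSV of participant targets
    hsv_means: dict = field(
        default_factory=lambda: {
            "HV": (30.98, 83.90, 138.82),
            "SSD": (25.30, 77.63, 132.06),
        }
    )
    #: between-participant SD of the HSV targets
    hsv_between_sd: dict = field(
        default_factory=lambda: {
            "HV": (14.66, 9.88, 12.26),
            "SSD": (15.79, 13.53, 17.78),
        }
    )
    #: image-to-image jitter of per-image HSV targets around the participant target
    hsv_within_sd: tuple[float, float, float] = (5.0, 5.0, 5.0)
    #: pixel-level HSV spread within an image (S/V from the published
    #: per-image SD summaries; hue spread chosen to give a colorful scene)
    pixel_hsv_sd: dict = field(
        default_factory=lambda: {
            "HV": (25.0, 50.10, 65.34),
            "SSD": (25.0, 47.34, 65.11),
        }
    )

    #: group mean of the per-participant Poisson face rate
    face_lambda: dict = field(default_factory=lambda: {"HV": 2.38, "SSD": 1.46})
    #: between-participant SD of the face rate
    face_lambda_sd: dict = field(default_factory=lambda: {"HV": 1.01, "SSD": 0.79})

    #: (mean, sd) of follower / following counts -> lognormal moments
    follower_params: dict = field(
        default_factory=lambda: {"HV": (906.94, 1565.53), "SSD": (416.00, 352.87)}
    )
    following_params: dict = field(
        default_factory=lambda: {"HV": (640.82, 464.31), "SSD": (599.91, 697.23)}
    )
    #: (mean, sd) per remaining connection type -> negative binomial / Poisson
    connection_params: dict = field(
        default_factory=lambda: {
            "requested": {"HV": (9.97, 16.49), "SSD": (12.09, 12.88)},
            "hashtag_follows": {"HV": (0.76, 2.32), "SSD": (4.35, 11.32)},
            "blocked": {"HV": (5.82, 9.71), "SSD": (8.03, 16.86)},
            "close_friends": {"HV": (10.91, 33.03), "SSD": (2.50, 8.25)},
            "restricted": {"HV": (0.03, 0.17), "SSD": (0.03, 0.17)},
        }
    )

    #: multiplicative posting-rate factor for Saturday/Sunday
    weekend_uplift: float = 1.5
    #: relative posting weight of (night, morning, afternoon, evening)
    timeofday_weights: tuple[float, float, float, float] = (0.15, 0.15, 0.35, 0.35)
    #: probability that a post is non-square, per group
    p_nonsquare: dict = field(default_factory=lambda: {"HV": 0.57, "SSD": 0.66})
    #: aspect ratios drawn for non-square posts
    nonsquare_aspects: tuple[float, ...] = (0.8, 1.25)

    #: (mean, sd) of posts-per-month -> lognormal; full-scale temporal layer
    posts_per_month: dict = field(
        default_factory=lambda: {"HV": (3.6, 6.4), "SSD": (6.0, 13.5)}
    )

    #: demographics: mean/sd age, P(female), race probabilities (4 levels)
    age_params: dict = field(
        default_factory=lambda: {"HV": (23.5, 3.8), "SSD": (23.6, 4.4)}
    )
    p_female: dict = field(default_factory=lambda: {"HV": 16 / 34, "SSD": 12 / 34})
    race_probs: dict = field(
        default_factory=lambda: {
            "HV": (7 / 34, 10 / 34, 3 / 34, 14 / 34),
            "SSD": (15 / 34, 6 / 34, 3 / 34, 10 / 34),
        }
    )
    p_hispanic: dict = field(default_factory=lambda: {"HV": 5 / 34, "SSD": 4 / 34})

    def null_world(self) -> "SyntheticCohortConfig":
        """A copy with all group differences removed (control parameters for both)."""
        def flat(d: dict) -> dict:
            return {g: d["HV"] for g in _GROUPS}

        return replace(
            self,
            hsv_means=flat(self.hsv_means),
            hsv_between_sd=flat(self.hsv_between_sd),
            pixel_hsv_sd=flat(self.pixel_hsv_sd),
            face_lambda=flat(self.face_lambda),
            face_lambda_sd=flat(self.face_lambda_sd),
            follower_params=flat(self.follower_params),
            following_params=flat(self.following_params),
            connection_params={
                k: flat(v) for k, v in self.connection_params.items()
            },
            p_nonsquare=flat(self.p_nonsquare),
            posts_per_month=flat(self.posts_per_month),
            age_params=flat(self.age_params),
            p_female=flat(self.p_female),
            race_probs=flat(self.race_probs),
            p_hispanic=flat(self.p_hispanic),
        )


@dataclass(frozen=True)
class SyntheticParticipant:
    """A generated archive plus its in-memory rasters and generative truth."""

    archive: ParticipantArchive
    images: dict[str, np.ndarray]
    #: per-participant generative parameters (targets, rates, counts)
    params: dict[str, float]


# ---------------------------------------------------------------------------
# Faces
# ---------------------------------------------------------------------------

_FACE_TEMPLATE: np.ndarray | None = None


def face_template() -> np.ndarray:
    """A license-free frontal-face RGB patch, extracted once per process.

    The patch is the face region of scikit-image's bundled ``astronaut``
    portrait, located with the package's own cascade detector so that
    composited copies remain re-detectable by the real detector path.
    """
    global _FACE_TEMPLATE
    if _FACE_TEMPLATE is None:
        from skimage.data import astronaut

        from .image_features import CascadeFaceDetector

        img = astronaut()
        det = CascadeFaceDetector()
        raw = det._cascade.detect_multi_scale(
            img=img,
            scale_factor=det.scale_factor,
            step_ratio=det.step_ratio,
            min_size=(60, 60),
            max_size=img.shape[:2],
        )
        best = max(raw, key=lambda d: d["width"] * d["height"])
        _FACE_TEMPLATE = img[
            best["r"]: best["r"] + best["height"],
            best["c"]: best["c"] + best["width"],
        ].copy()
    return _FACE_TEMPLATE


def _face_patch(px: int) -> np.ndarray:
    patch = resize(face_template(), (px, px), anti_aliasing=True)
    return (patch * 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------


def generate_image(
    target_hsv: tuple[float, float, float],
    pixel_sd: tuple[float, float, float],
    n_faces: int,
    size: tuple[int, int],
    rng: np.random.Generator,
    face_patch_px: int = 12,
) -> np.ndarray:
    """Render one HxWx3 uint8 image with known color structure and face count.

    Pixel hue is sampled normally around the target and wrapped mod 180;
    saturation and value are sampled normally and clipped to [0, 255]
    (clipping biases measured means slightly toward mid-range near the
    edges).  ``n_faces`` face patches are composited on a non-overlapping
    grid; a count that does not fit raises ``ValueError``.
    """
    w, h = int(size[0]), int(size[1])
    hue = np.mod(rng.normal(target_hsv[0], pixel_sd[0], (h, w)), 180.0)
    sat = np.clip(rng.normal(target_hsv[1], pixel_sd[1], (h, w)), 0, 255)
    val = np.clip(rng.normal(target_hsv[2], pixel_sd[2], (h, w)), 0, 255)
    hsv = np.stack([hue / 180.0, sat / 255.0, val / 255.0], axis=-1)
    img = (_skcolor.hsv2rgb(hsv) * 255).round().astype(np.uint8)

    if n_faces:
        px = face_patch_px
        cols, rows = w // px, h // px
        slots = cols * rows
        if n_faces > slots:
            raise ValueError(
                f"{n_faces} faces of {px}px do not fit in a {w}x{h} image"
            )
        patch = _face_patch(px)
        chosen = rng.choice(slots, size=n_faces, replace=False)
        for s in chosen:
            r, c = (int(s) // cols) * px, (int(s) % cols) * px
            img[r: r + px, c: c + px] = patch
    return img


# ---------------------------------------------------------------------------
# Timestamps
# ---------------------------------------------------------------------------


def _weekday_probs(uplift: float) -> np.ndarray:
    w = np.array([1.0] * 5 + [uplift] * 2)
    return w / w.sum()


def _sample_timestamps(
    n: int,
    span_months: float,
    uplift: float,
    tod_weights: np.ndarray,
    rng: np.random.Generator,
    start: datetime = EPOCH,
) -> list[datetime]:
    """``n`` timestamps over a span, first/last day pinned to the endpoints.

    Days are drawn by weekday-weighted sampling over the span; the
    time-of-day bin is drawn from ``tod_weights`` with a uniform clock time
    inside the bin.
    """
    span_days = int(round(span_months * DAYS_PER_MONTH))
    days = np.arange(span_days + 1)
    weekdays = (start.weekday() + days) % 7
    w = np.where(weekdays >= 5, uplift, 1.0).astype(float)
    w /= w.sum()
    mid = rng.choice(days, size=max(n - 2, 0), p=w)
    chosen = np.concatenate([[0], np.sort(mid), [span_days]]) if n >= 2 else days[:n]
    bins = rng.choice(4, size=len(chosen), p=tod_weights)
    out = []
    for day, b in zip(chosen, bins):
        seconds = int((int(b) * 6 + rng.uniform(0, 6)) * 3600.0)
        out.append(start + timedelta(days=int(day), seconds=seconds))
    return sorted(out)


# ---------------------------------------------------------------------------
# Count distributions
# ---------------------------------------------------------------------------


def _lognormal_count(mean: float, sd: float, rng: np.random.Generator) -> int:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return int(round(rng.lognormal(mu, math.sqrt(sigma2))))


def _overdispersed_count(mean: float, sd: float, rng: np.random.Generator) -> int:
    """Negative-binomial count matched to (mean, sd); Poisson if var <= mean."""
    var = sd**2
    if mean <= 0:
        return 0
    if var <= mean:
        return int(rng.poisson(mean))
    size = mean**2 / (var - mean)
    p = size / (size + mean)
    return int(rng.negative_binomial(size, p))


# ---------------------------------------------------------------------------
# Participants and cohorts
# ---------------------------------------------------------------------------


def _sample_demographics(
    group: str, pid: str, config: SyntheticCohortConfig, rng: np.random.Generator
) -> DemographicRecord:
    from .archive_io import RACE_LEVELS

    mean, sd = config.age_params[group]
    age = float(np.clip(rng.normal(mean, sd), 15.0, 35.0))
    sex = "female" if rng.random() < config.p_female[group] else "male"
    race = RACE_LEVELS[int(rng.choice(4, p=np.asarray(config.race_probs[group])))]
    eth = "Hispanic" if rng.random() < config.p_hispanic[group] else "Non-Hispanic"
    return DemographicRecord(
        participant_id=pid, group=group, age=round(age, 1), sex=sex, race=race,
        ethnicity=eth,
    )


def generate_participant(
    group: str,
    config: SyntheticCohortConfig,
    rng: np.random.Generator,
    participant_id: str = "P000",
) -> SyntheticParticipant:
    """Generate one participant: archive, rasters and ground-truth manifest."""
    if group not in _GROUPS:
        raise ValueError(f"group must be one of {_GROUPS}")
    demo = _sample_demographics(group, participant_id, config, rng)

    n_posts = int(rng.integers(config.posts_per_participant[0],
                               config.posts_per_participant[1] + 1))
    months = float(rng.uniform(*config.months_span))
    stamps = _sample_timestamps(
        n_posts, months, config.weekend_uplift,
        np.asarray(config.timeofday_weights, float) /
        np.sum(config.timeofday_weights), rng,
    )

    mu = np.asarray(config.hsv_means[group], float)
    between = np.asarray(config.hsv_between_sd[group], float)
    target = mu + between * rng.standard_normal(3)
    target[0] = target[0] % 180.0
    target[1:] = np.clip(target[1:], 5.0, 250.0)

    lam = max(float(rng.normal(config.face_lambda[group],
                               config.face_lambda_sd[group])), 0.0)

    w_img, h_img = config.image_size
    max_faces = (w_img // config.face_patch_px) * (h_img // config.face_patch_px)
    within = np.asarray(config.hsv_within_sd, float)
    pixel_sd = tuple(config.pixel_hsv_sd[group])

    posts: list[MediaPost] = []
    images: dict[str, np.ndarray] = {}
    truth: dict[str, int] = {}
    for i, stamp in enumerate(stamps):
        post_id = f"{participant_id}_{i:04d}"
        img_target = target + within * rng.standard_normal(3)
        img_target[0] %= 180.0
        img_target[1:] = np.clip(img_target[1:], 0.0, 255.0)
        n_faces = min(int(rng.poisson(lam)), max_faces)
        if rng.random() < config.p_nonsquare[group]:
            aspect = float(rng.choice(config.nonsquare_aspects))
        else:
            aspect = 1.0
        w = w_img if aspect <= 1.0 else int(round(h_img * aspect))
        h = h_img if aspect >= 1.0 else int(round(w_img / aspect))
        img = generate_image(
            tuple(img_target), pixel_sd, n_faces, (w, h), rng,
            face_patch_px=config.face_patch_px,
        )
        posts.append(
            MediaPost(
                post_id=post_id,
                timestamp=stamp,
                image_path=None,
                width=img.shape[1],
                height=img.shape[0],
                missing_image=True,  # in-memory until written to disk
            )
        )
        images[post_id] = img
        truth[post_id] = n_faces

    conn_counts = {
        "followers": _lognormal_count(*config.follower_params[group], rng),
        "following": _lognormal_count(*config.following_params[group], rng),
    }
    for name, per_group in config.connection_params.items():
        conn_counts[name] = _overdispersed_count(*per_group[group], rng)
    connections = ConnectionLists(**conn_counts)

    archive = ParticipantArchive(
        demographics=demo,
        posts=tuple(posts),
        connections=connections,
        face_truth=truth,
    )
    params = {
        "participant_id": participant_id,
        "group": group,
        "n_posts": n_posts,
        "months_span": months,
        "target_H": float(target[0]),
        "target_S": float(target[1]),
        "target_V": float(target[2]),
        "face_lambda": lam,
        **{f"count_{k}": float(v) for k, v in conn_counts.items()},
    }
    return SyntheticParticipant(archive=archive, images=images, params=params)


def generate_cohort(
    config: SyntheticCohortConfig, seed: int
) -> list[SyntheticParticipant]:
    """Generate ``n_per_group`` participants per group, deterministically.

    Each participant gets an independent child random stream derived from
    ``seed``, so the cohort is reproducible and insensitive to generation
    order.
    """
    streams = np.random.SeedSequence(seed).spawn(2 * config.n_per_group)
    cohort = []
    idx = 0
    for group in _GROUPS:
        for i in range(config.n_per_group):
            rng = np.random.default_rng(streams[idx])
            pid = f"{group}{i:03d}"
            cohort.append(generate_participant(group, config, rng, pid))
            idx += 1
    return cohort


def write_cohort(
    cohort: list[SyntheticParticipant], out_dir: str | Path
) -> pd.DataFrame:
    """Write archives in the canonical dialect plus a ground-truth manifest.

    Returns the manifest (one row of generative parameters per participant),
    also saved as ``manifest.csv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sp in cohort:
        root = out_dir / sp.archive.participant_id
        write_archive(sp.archive, root, images=sp.images)
        rows.append(sp.params)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


# ---------------------------------------------------------------------------
# Full-scale feature/timestamp layers (used by calibration simulations)
# ---------------------------------------------------------------------------


def sample_participant_hsv(
    group: str, n: int, config: SyntheticCohortConfig, rng: np.random.Generator
) -> np.ndarray:
    """(n, 3) participant-level HSV targets: the generator's between layer.

    This is exactly the distribution from which :func:`generate_participant`
    draws its participant color targets; sampling it directly lets
    calibration studies run thousands of replicates without rendering
    pixels (the within-image layer only adds variance shared by both
    groups and does not change test calibration).
    """
    mu = np.asarray(config.hsv_means[group], float)
    sd = np.asarray(config.hsv_between_sd[group], float)
    out = mu + sd * rng.standard_normal((n, 3))
    out[:, 0] %= 180.0
    out[:, 1:] = np.clip(out[:, 1:], 5.0, 250.0)
    return out


def sample_temporal_profiles(
    group: str,
    n: int,
    config: SyntheticCohortConfig,
    rng: np.random.Generator,
    uplift: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-participant (weekday (n,7), time-of-day (n,4)) proportion matrices.

    Uses the full-scale posting volume (posts-per-month x months drawn from
    the configured heavy-tailed distributions, minimum 5 posts) with weekday
    weights uniform except for the weekend uplift — the same intensity model
    that drives :func:`generate_participant`'s timestamps, without
    materializing calendar datetimes.
    """
    if uplift is None:
        uplift = config.weekend_uplift
    mean, sd = config.posts_per_month[group]
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    ppm = rng.lognormal(mu, math.sqrt(sigma2), size=n)
    months = rng.uniform(*config.months_span, size=n)
    n_posts = np.maximum(np.round(ppm * months), 5).astype(int)
    pw = _weekday_probs(uplift)
    pt = np.asarray(config.timeofday_weights, float)
    pt = pt / pt.sum()
    weekday = np.vstack(
        [rng.multinomial(m, pw) / m for m in n_posts]
    )
    tod = np.vstack([rng.multinomial(m, pt) / m for m in n_posts])
    return weekday, tod


def images_of(cohort: list[SyntheticParticipant]) -> Mapping[str, np.ndarray]:
    """Merged post_id -> raster mapping for an in-memory cohort."""
    merged: dict[str, np.ndarray] = {}
    for sp in cohort:
        merged.update(sp.images)
    return merged
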