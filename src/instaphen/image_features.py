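"""Per-image colorimetry, colorfulness and face-count features.

Every feature is computed per image and then averaged per participant (the
participant mean is the unit of statistical analysis).  Channel conventions
follow the 8-bit hexcone model: R, G, B, S, V on [0, 255] and hue on the
half-degree scale [0, 180) (hue is angular, so its central tendency is a
circular mean and no SD/skew is computed for it).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime
from pathlib import Path
from typing import Protocol

import numpy as np
from PIL import Image
from skimage import color as _skcolor

from .archive_io import MediaPost

#: non-square tolerance on |aspect_ratio - 1| (absorbs 1-px rounding)
NONSQUARE_TOL = 0.005

#: posts before this date are excluded from aspect-ratio aggregation
#: (the platform allowed only square uploads before then)
ASPECT_CUTOFF = date(2016, 1, 1)

#: resultant length below which the circular hue mean is undefined
CIRCULAR_EPS = 1e-9

CHANNELS = ("R", "G", "B", "S", "V")

#: participant-level image feature names, in report order
IMAGE_FEATURES = (
    "face_count",
    "width",
    "height",
    "aspect_ratio",
    "pct_nonsquare",
    "mean_R",
    "mean_G",
    "mean_B",
    "sd_R",
    "sd_G",
    "sd_B",
    "skew_R",
    "skew_G",
    "skew_B",
    "mean_H",
    "mean_S",
    "mean_V",
    "sd_S",
    "sd_V",
    "skew_S",
    "skew_V",
    "colorfulness",
)


def load_image(path: str | Path) -> np.ndarray:
    """Load a raster as an HxWx3 uint8 RGB array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.uint8)


def _validate(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3 or img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError(f"expected HxWx3 RGB image, got shape {img.shape}")
    return img


def hsv_channels(img: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hue on [0, 180), saturation and value on [0, 255], as float arrays."""
    img = _validate(img)
    hsv = _skcolor.rgb2hsv(img.astype(np.float64) / 255.0)
    hue = hsv[..., 0] * 180.0
    hue = np.where(hue >= 180.0, hue - 180.0, hue)
    return hue, hsv[..., 1] * 255.0, hsv[..., 2] * 255.0


def channel_values(img: np.ndarray, channel: str) -> np.ndarray:
    """Flattened pixel values of one of the R, G, B, S, V channels."""
    img = _validate(img)
    if channel in ("R", "G", "B"):
        return img[..., "RGB".index(channel)].astype(np.float64).ravel()
    if channel in ("S", "V"):
        _, s, v = hsv_channels(img)
        return (s if channel == "S" else v).ravel()
    raise ValueError(f"channel must be one of {CHANNELS}, got {channel!r}")


def _moments(values: np.ndarray) -> tuple[float, float, float]:
    values = np.asarray(values, dtype=np.float64).ravel()
    mean = float(values.mean())
    m2 = float(np.mean((values - mean) ** 2))
    sd = float(np.sqrt(m2))
    if sd == 0.0:
        return mean, 0.0, 0.0
    m3 = float(np.mean((values - mean) ** 3))
    return mean, sd, m3 / m2**1.5


def channel_moments(img: np.ndarray, channel: str) -> tuple[float, float, float]:
    """Population mean, SD and skew of one channel over all pixels.

    The skew is the third standardized moment m3/m2^1.5 and is defined as 0
    for a zero-variance (flat) channel.
    """
    return _moments(channel_values(img, channel))


def circular_mean_hue(hues: np.ndarray) -> float:
    """Circular mean of hues on the [0, 180) scale; NaN when undefined.

    Hue h is mapped to the angle 2h degrees (so the scale wraps correctly),
    the resultant-vector mean angle is computed and halved back to hue units.
    An (anti-podal) resultant shorter than ``CIRCULAR_EPS`` has no meaningful
    mean and yields NaN.
    """
    hues = np.asarray(hues, dtype=np.float64).ravel()
    if hues.size == 0:
        return float("nan")
    ang = np.deg2rad(2.0 * hues)
    z = np.exp(1j * ang).mean()
    if abs(z) < CIRCULAR_EPS:
        return float("nan")
    mean_ang = np.angle(z)  # (-pi, pi]
    hue = np.rad2deg(mean_ang) / 2.0
    return float(hue % 180.0)


def circular_hue_mean(img: np.ndarray) -> float:
    """Circular mean hue of an image on [0, 180); NaN for a zero resultant."""
    hue, _, _ = hsv_channels(img)
    return circular_mean_hue(hue)


def colorfulness(img: np.ndarray) -> float:
    """Opponent-color colorfulness score (Hasler–Süsstrunk).

    With rg = R - G and yb = (R + G)/2 - B per pixel, the score is
    sqrt(sd_rg^2 + sd_yb^2) + 0.3 * sqrt(mean_rg^2 + mean_yb^2), using
    population SDs.  Zero for any uniform gray image.
    """
    img = _validate(img).astype(np.float64)
    rg = img[..., 0] - img[..., 1]
    yb = 0.5 * (img[..., 0] + img[..., 1]) - img[..., 2]
    sd = np.sqrt(rg.var() + yb.var())
    mag = np.sqrt(rg.mean() ** 2 + yb.mean() ** 2)
    return float(sd + 0.3 * mag)


def aspect_features(
    post: MediaPost,
    cutoff: date = ASPECT_CUTOFF,
    tol: float = NONSQUARE_TOL,
) -> tuple[float, bool, bool]:
    """(aspect_ratio, is_nonsquare, in_aspect_window) for one post.

    ``in_aspect_window`` is False for posts before ``cutoff``; such posts are
    excluded from participant-level aspect aggregation because non-square
    uploads were not generally available before then.
    """
    if post.height == 0:
        raise ValueError(f"post {post.post_id}: zero height")
    ratio = post.width / post.height
    nonsquare = abs(ratio - 1.0) > tol
    stamp = post.timestamp.date() if isinstance(post.timestamp, datetime) else post.timestamp
    return ratio, nonsquare, stamp >= cutoff


# ---------------------------------------------------------------------------
# Face detection
# ---------------------------------------------------------------------------


class FaceDetector(Protocol):
    """Returns a non-negative face count for an image (post_id for stubs)."""

    def count(self, img: np.ndarray | None, post_id: str | None = None) -> int: ...


class CascadeFaceDetector:
    """Frontal-face cascade detector with pinned, deterministic parameters.

    Uses the OpenCV-format LBP frontal-face cascade bundled with
    scikit-image.  Overlapping raw detections are merged (greedy IoU
    suppression) so that one face yields one count.
    """

    def __init__(
        self,
        scale_factor: float = 1.1,
        step_ratio: int = 1,
        min_size: tuple[int, int] = (24, 24),
        iou_threshold: float = 0.4,
    ) -> None:
        try:
            from skimage.data import lbp_frontal_face_cascade_filename
            from skimage.feature import Cascade
        except ImportError as exc:  # pragma: no cover
            raise RuntimeError("scikit-image cascade detector unavailable") from exc
        self._cascade = Cascade(lbp_frontal_face_cascade_filename())
        self.scale_factor = scale_factor
        self.step_ratio = step_ratio
        self.min_size = min_size
        self.iou_threshold = iou_threshold

    @staticmethod
    def _iou(a: dict, b: dict) -> float:
        ax0, ay0 = a["c"], a["r"]
        ax1, ay1 = ax0 + a["width"], ay0 + a["height"]
        bx0, by0 = b["c"], b["r"]
        bx1, by1 = bx0 + b["width"], by0 + b["height"]
        iw = max(0, min(ax1, bx1) - max(ax0, bx0))
        ih = max(0, min(ay1, by1) - max(ay0, by0))
        inter = iw * ih
        union = a["width"] * a["height"] + b["width"] * b["height"] - inter
        return inter / union if union else 0.0

    def count(self, img: np.ndarray | None, post_id: str | None = None) -> int:
        if img is None:
            return 0
        img = _validate(img)
        h, w = img.shape[:2]
        if h < self.min_size[0] or w < self.min_size[1]:
            return 0
        raw = self._cascade.detect_multi_scale(
            img=img,
            scale_factor=self.scale_factor,
            step_ratio=self.step_ratio,
            min_size=self.min_size,
            max_size=(h, w),
        )
        kept: list[dict] = []
        for det in sorted(raw, key=lambda d: (-d["width"] * d["height"], d["r"], d["c"])):
            if all(self._iou(det, k) <= self.iou_threshold for k in kept):
                kept.append(det)
        return len(kept)


class StubFaceDetector:
    """Ground-truth detector reading embedded counts from a manifest.

    Used with synthetic archives, whose generator records the number of face
    patches composited into each image; guarantees determinism in tests.
    """

    def __init__(self, truth: dict[str, int]) -> None:
        self.truth = dict(truth)

    def count(self, img: np.ndarray | None, post_id: str | None = None) -> int:
        if post_id is None or post_id not in self.truth:
            raise KeyError(f"no ground-truth face count for post {post_id!r}")
        return int(self.truth[post_id])


def count_faces(img: np.ndarray | None, detector: FaceDetector, post_id: str | None = None) -> int:
    """Number of faces the configured detector accepts in the image."""
    n = detector.count(img, post_id)
    if n < 0:
        raise ValueError("detector returned a negative count")
    return n


# ---------------------------------------------------------------------------
# Per-image record and participant aggregation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImageFeatureRecord:
    """All per-image features for one post (hue has no SD/skew: it is angular)."""

    post_id: str
    post_timestamp: datetime
    width: int
    height: int
    aspect_ratio: float
    is_nonsquare: bool
    in_aspect_window: bool
    mean_R: float
    sd_R: float
    skew_R: float
    mean_G: float
    sd_G: float
    skew_G: float
    mean_B: float
    sd_B: float
    skew_B: float
    mean_H: float
    mean_S: float
    sd_S: float
    skew_S: float
    mean_V: float
    sd_V: float
    skew_V: float
    colorfulness: float
    face_count: int


def extract_features(
    img: np.ndarray,
    post: MediaPost,
    detector: FaceDetector,
    cutoff: date = ASPECT_CUTOFF,
) -> ImageFeatureRecord:
    """Compute the full per-image feature vector for one post."""
    img = _validate(img)
    ratio, nonsquare, in_window = aspect_features(post, cutoff=cutoff)
    vals = {}
    for ch in ("R", "G", "B"):
        vals[f"mean_{ch}"], vals[f"sd_{ch}"], vals[f"skew_{ch}"] = channel_moments(img, ch)
    hue, s, v = hsv_channels(img)
    for ch, arr in (("S", s), ("V", v)):
        vals[f"mean_{ch}"], vals[f"sd_{ch}"], vals[f"skew_{ch}"] = _moments(arr)
    return ImageFeatureRecord(
        post_id=post.post_id,
        post_timestamp=post.timestamp,
        width=img.shape[1],
        height=img.shape[0],
        aspect_ratio=ratio,
        is_nonsquare=nonsquare,
        in_aspect_window=in_window,
        mean_H=circular_mean_hue(hue),
        colorfulness=colorfulness(img),
        face_count=count_faces(img, detector, post.post_id),
        **vals,
    )


def aggregate_images(records: list[ImageFeatureRecord]) -> dict[str, float]:
    """Participant-level means of every image feature.

    Plain features are arithmetic means across the participant's images; hue
    is aggregated by the circular mean of the per-image circular means;
    aspect-ratio features (aspect_ratio, pct_nonsquare, width, height) are
    averaged only over posts inside the aspect window and are NaN when no
    post qualifies.
    """
    if not records:
        raise ValueError("cannot aggregate zero image records")

    out: dict[str, float] = {}
    mean = lambda xs: float(np.mean(xs)) if xs else float("nan")

    out["face_count"] = mean([r.face_count for r in records])
    for name in (
        "mean_R", "sd_R", "skew_R",
        "mean_G", "sd_G", "skew_G",
        "mean_B", "sd_B", "skew_B",
        "mean_S", "sd_S", "skew_S",
        "mean_V", "sd_V", "skew_V",
        "colorfulness",
    ):
        out[name] = mean([getattr(r, name) for r in records])
    hues = [r.mean_H for r in records if np.isfinite(r.mean_H)]
    out["mean_H"] = circular_mean_hue(np.array(hues)) if hues else float("nan")

    in_window = [r for r in records if r.in_aspect_window]
    out["width"] = mean([r.width for r in in_window])
    out["height"] = mean([r.height for r in in_window])
    out["aspect_ratio"] = mean([r.aspect_ratio for r in in_window])
    out["pct_nonsquare"] = (
        100.0 * float(np.mean([r.is_nonsquare for r in in_window]))
        if in_window
        else float("nan")
    )
    return {name: out[name] for name in IMAGE_FEATURES}
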