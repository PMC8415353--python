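"""Shared fixtures: a hand-written canonical archive and small synthetic cohorts."""

from __future__ import annotations

import json
from datetime import datetime, timedelta

import numpy as np
import pytest
from PIL import Image

from instaphen import SyntheticCohortConfig, generate_cohort


def write_fixture_archive(root, n_posts=6, corrupt_post=None, video=False):
    """Write a small canonical-dialect archive by hand (6 posts, 3 member lists)."""
    root.mkdir(parents=True, exist_ok=True)
    (root / "images").mkdir(exist_ok=True)
    rng = np.random.default_rng(42)
    media = []
    t0 = datetime(2017, 3, 1, 9, 30)
    for i in range(n_posts):
        post_id = f"fx{i:02d}"
        rel = f"images/{post_id}.png"
        media.append(
            {
                "post_id": post_id,
                "taken_at": (t0 + timedelta(days=30 * i, hours=i)).isoformat(),
                "path": rel,
                "width": 32,
                "height": 32,
            }
        )
        if corrupt_post == i:
            (root / rel).write_bytes(b"not a png")
        else:
            arr = rng.integers(0, 256, (32, 32, 3), dtype=np.uint8)
            Image.fromarray(arr).save(root / rel)
    if video:
        media.append(
            {"post_id": "vid0", "taken_at": t0.isoformat(), "path": "images/clip.mp4"}
        )
    (root / "media.json").write_text(json.dumps({"media": media}))
    (root / "connections.json").write_text(
        json.dumps(
            {
                "followers": [f"fan{i}" for i in range(10)],
                "following": [f"idol{i}" for i in range(5)],
                "requested": [f"req{i}" for i in range(2)],
                "blocked": 1,
                "close_friends": 0,
                "hashtag_follows": 0,
                "restricted": 0,
            }
        )
    )
    (root / "demographics.json").write_text(
        json.dumps(
            {
                "participant_id": "FX01",
                "group": "HV",
                "age": 24,
                "sex": "female",
                "race": "White",
                "ethnicity": "Non-Hispanic",
            }
        )
    )
    return root


@pytest.fixture
def fixture_archive(tmp_path):
    return write_fixture_archive(tmp_path / "FX01")


@pytest.fixture(scope="session")
def tiny_config():
    """Small, fast cohort: 6 per group, few small images."""
    return SyntheticCohortConfig(
        n_per_group=6, posts_per_participant=(6, 9), months_span=(3.2, 24.0),
        image_size=(32, 32), face_patch_px=8,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config, seed=17)
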