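"""Shared fixtures: small seeded synthetic cohorts and frame stores.

Everything is generated at test time; nothing is read from disk.
"""

import numpy as np
import pytest

from euscv.cohort import (
    CohortSpec,
    default_crop_box,
    generate_cohort,
    scaled_spec,
    simulate_endoscopists,
)
from euscv.imaging import FrameStore


@pytest.fixture(scope="session")
def tiny_spec() -> CohortSpec:
    """A few patients with short, small videos — enough structure for the
    imaging and split machinery without meaningful runtime."""
    return CohortSpec(
        n_positive=6,
        n_negative=4,
        videos_per_patient=(1, 2),
        frames_per_video=(4, 7),
        frame_height=64,
        frame_width=72,
        effect_size=1.5,
        seed=101,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    cohort = generate_cohort(tiny_spec)
    simulate_endoscopists(cohort, seed=102)
    return cohort


@pytest.fixture(scope="session")
def tiny_store(tiny_spec, tiny_cohort) -> FrameStore:
    crop = default_crop_box(tiny_spec.frame_height, tiny_spec.frame_width)
    return FrameStore.from_cohort(tiny_cohort, crop_box=crop)


@pytest.fixture(scope="session")
def desk_cohort():
    """Full cohort structure (61 PDAC / 24 AIP) at desk scale, with a
    clear class signal and a rated endoscopist panel."""
    spec = scaled_spec(seed=11, effect_size=2.0)
    cohort = generate_cohort(spec)
    simulate_endoscopists(cohort, seed=12)
    return spec, cohort


@pytest.fixture(scope="session")
def desk_store(desk_cohort) -> FrameStore:
    spec, cohort = desk_cohort
    crop = default_crop_box(spec.frame_height, spec.frame_width)
    return FrameStore.from_cohort(cohort, crop_box=crop)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def synthetic_store(labels: dict[str, int], n_frames: int = 5, side: int = 48,
                    seed: int = 0) -> FrameStore:
    """Hand-built FrameStore whose per-class frames differ in brightness,
    for classifier tests needing a separable signal or exact patient sets."""
    rng = np.random.default_rng(seed)
    frames = {}
    for pid, label in labels.items():
        base = 60 if label == 0 else 190
        stack = np.clip(
            base + rng.normal(0, 12, size=(n_frames, side, side)), 0, 255
        ).astype(np.uint8)
        frames[pid] = [("V00", stack)]
    return FrameStore(frames, labels)
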