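"""Frame preprocessing and quasi-RGB composition.

A *quasi-RGB image* stacks three temporally distinct grayscale frames of
one patient as the red/green/blue channels of a 224x224 color image, so a
channel-wise convolutional network sees temporal variation as color
variation.  This module provides the uniform crop applied to raw frames,
the composition and resizing, the optional training-time augmentations,
and the two sampling schemes used by the cross-validation framework:

* ``sample_epoch``: ~1000 images per training epoch, split almost evenly
  between the two classes regardless of cohort imbalance, with per-patient
  counts within each class differing by at most one;
* ``sample_test_set``: a fixed number of images (default 300) per test
  patient, whose scores are later averaged into one patient-level score.

All sampling is reproducible from the supplied generator, and every
composed image is patient-consistent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from skimage.transform import resize as _sk_resize
from skimage.transform import rotate as _sk_rotate

from .cohort import PatientRecord

__all__ = [
    "CropBox",
    "GrayFrame",
    "QuasiRGBImage",
    "AugmentConfig",
    "SamplingConfig",
    "FrameStore",
    "PlanItem",
    "FrameRef",
    "crop_frame",
    "compose_quasi_rgb",
    "resize_image",
    "augment",
    "hflip",
    "sample_epoch",
    "sample_epoch_plan",
    "sample_test_set",
    "sample_test_plan",
    "sample_frame_triplet",
    "materialize",
]

#: Network input side length (images are resized to TARGET x TARGET).
TARGET = 224

#: Standard crop size of raw frames, (height, width) = 489 x 465 pixels.
STANDARD_CROP = (489, 465)


class CropBox(NamedTuple):
    """0-based, top-left origin, half-open crop window."""

    top: int
    left: int
    height: int
    width: int


class FrameRef(NamedTuple):
    """One source frame: (video_id, 0-based temporal frame index)."""

    video_id: str
    frame_index: int


@dataclass(frozen=True)
class GrayFrame:
    """A single preprocessed grayscale frame with provenance."""

    pixels: np.ndarray  # 2-D uint8
    patient_id: str
    video_id: str
    frame_index: int


@dataclass(frozen=True)
class QuasiRGBImage:
    """Three temporally distinct frames of one patient stacked as channels.

    ``pixels`` is (224, 224, 3) float32 in [0, 255]; channel order follows
    ascending temporal order (video_id, then frame index) of the three
    source frames, which by construction share one patient.
    """

    pixels: np.ndarray
    patient_id: str
    frame_refs: tuple[FrameRef, FrameRef, FrameRef]
    label: int

    @property
    def video_id(self) -> str:
        """Source video id (unique under same-video sampling, the default)."""
        vids = sorted({r.video_id for r in self.frame_refs})
        return vids[0] if len(vids) == 1 else "+".join(vids)

    @property
    def frame_indices(self) -> tuple[int, int, int]:
        return tuple(r.frame_index for r in self.frame_refs)  # type: ignore[return-value]


@dataclass(frozen=True)
class AugmentConfig:
    """Training-time augmentations; all identity when disabled."""

    enabled: bool = False
    hflip_prob: float = 0.5
    max_rotation_deg: float = 10.0
    max_brightness_frac: float = 0.10


@dataclass(frozen=True)
class SamplingConfig:
    """Quasi-RGB sampling scheme parameters."""

    n_per_epoch: int = 1000
    n_test_per_patient: int = 300
    same_video_only: bool = True
    augment: AugmentConfig = field(default_factory=AugmentConfig)

    def validate(self) -> None:
        if self.n_per_epoch < 2:
            raise ValueError("n_per_epoch must be >= 2")
        if self.n_test_per_patient < 1:
            raise ValueError("n_test_per_patient must be >= 1")


class PlanItem(NamedTuple):
    """Provenance of one planned quasi-RGB image (pixels not yet built)."""

    patient_id: str
    frame_refs: tuple[FrameRef, FrameRef, FrameRef]
    label: int


def crop_frame(raw: np.ndarray, crop_box: CropBox | tuple[int, int, int, int]) -> np.ndarray:
    """Crop ``raw`` to ``crop_box`` = (top, left, height, width).

    The box must lie fully inside the raw frame; out-of-bounds boxes raise
    rather than silently clamping, since the crop must be uniform across a
    whole run.
    """
    top, left, height, width = crop_box
    if height <= 0 or width <= 0:
        raise ValueError(f"crop box has non-positive size: {crop_box}")
    H, W = raw.shape[:2]
    if top < 0 or left < 0 or top + height > H or left + width > W:
        raise ValueError(f"crop box {crop_box} exceeds raw frame bounds {(H, W)}")
    return np.ascontiguousarray(raw[top : top + height, left : left + width])


def resize_image(img: np.ndarray, target: int = TARGET) -> np.ndarray:
    """Bilinear resize to ``target x target`` (per channel), float32.

    An input already at the target size is returned unchanged (bit-exact).
    """
    if img.size == 0:
        raise ValueError("empty image")
    arr = np.asarray(img, dtype=np.float32)
    if arr.shape[:2] == (target, target):
        return arr
    if arr.ndim == 2:
        out = _sk_resize(arr, (target, target), order=1, mode="edge",
                         anti_aliasing=False, preserve_range=True)
        return out.astype(np.float32)
    chans = [
        _sk_resize(arr[..., c], (target, target), order=1, mode="edge",
                   anti_aliasing=False, preserve_range=True)
        for c in range(arr.shape[2])
    ]
    return np.stack(chans, axis=-1).astype(np.float32)


class FrameStore:
    """Cropped frames of a cohort, indexed by patient and video.

    Frames are materialized once (generated lazily by each ``Video`` and
    cropped uniformly), because the sampling schemes revisit frames many
    times.  Per-frame 224x224 resizes are cached on demand, so composing a
    quasi-RGB image reduces to stacking three cached channels (bilinear
    resize acts per channel, so resize-then-stack equals stack-then-resize).
    """

    def __init__(
        self,
        frames: Mapping[str, list[tuple[str, np.ndarray]]],
        labels: Mapping[str, int],
    ):
        # frames: patient_id -> [(video_id, stack (n, H, W) uint8), ...]
        self._frames = {pid: list(v) for pid, v in frames.items()}
        self.labels = dict(labels)
        self._resized: dict[tuple[str, str], np.ndarray] = {}

    @classmethod
    def from_cohort(
        cls,
        cohort: Sequence[PatientRecord],
        crop_box: CropBox | tuple[int, int, int, int] | None = None,
    ) -> "FrameStore":
        frames: dict[str, list[tuple[str, np.ndarray]]] = {}
        labels: dict[str, int] = {}
        for p in cohort:
            vids = []
            for v in p.videos:
                stack = v.frame_stack()
                if crop_box is not None:
                    top, left, height, width = crop_box
                    crop_frame(stack[0], crop_box)  # bounds check once
                    stack = stack[:, top : top + height, left : left + width]
                vids.append((v.video_id, np.ascontiguousarray(stack)))
            frames[p.patient_id] = vids
            labels[p.patient_id] = p.label
        return cls(frames, labels)

    @property
    def patient_ids(self) -> list[str]:
        return sorted(self._frames)

    def videos(self, patient_id: str) -> list[tuple[str, np.ndarray]]:
        return self._frames[patient_id]

    def video_stack(self, patient_id: str, video_id: str) -> np.ndarray:
        for vid, stack in self._frames[patient_id]:
            if vid == video_id:
                return stack
        raise KeyError(f"{patient_id}/{video_id}")

    def resized_stack(self, patient_id: str, video_id: str) -> np.ndarray:
        """(n, 224, 224) float32 per-frame bilinear resizes, cached."""
        key = (patient_id, video_id)
        if key not in self._resized:
            stack = self.video_stack(patient_id, video_id)
            self._resized[key] = np.stack([resize_image(f) for f in stack])
        return self._resized[key]


def sample_frame_triplet(
    store: FrameStore,
    patient_id: str,
    rng: np.random.Generator,
    same_video_only: bool = True,
) -> tuple[FrameRef, FrameRef, FrameRef]:
    """Pick three distinct frames of one patient, in temporal order.

    With ``same_video_only`` (default) the frames come from one uniformly
    chosen video with >= 3 frames; otherwise they are drawn uniformly
    without replacement from the patient-wide frame pool (and may span
    videos).  Temporal order is (video_id, frame_index); videos are
    chronological within a session.
    """
    videos = store.videos(patient_id)
    if same_video_only:
        eligible = [(vid, stack.shape[0]) for vid, stack in videos if stack.shape[0] >= 3]
        if not eligible:
            raise ValueError(
                f"patient {patient_id} has no video with >= 3 frames; "
                "cannot compose a quasi-RGB image"
            )
        vid, n = eligible[int(rng.integers(len(eligible)))]
        idx = np.sort(rng.choice(n, size=3, replace=False))
        return tuple(FrameRef(vid, int(i)) for i in idx)  # type: ignore[return-value]
    pool = [FrameRef(vid, i) for vid, stack in videos for i in range(stack.shape[0])]
    if len(pool) < 3:
        raise ValueError(f"patient {patient_id} has fewer than 3 frames in total")
    picks = rng.choice(len(pool), size=3, replace=False)
    refs = sorted(pool[int(i)] for i in picks)
    return tuple(refs)  # type: ignore[return-value]


def materialize(store: FrameStore, item: PlanItem) -> QuasiRGBImage:
    """Build the pixel array for a planned image from cached resizes."""
    chans = [
        store.resized_stack(item.patient_id, ref.video_id)[ref.frame_index]
        for ref in item.frame_refs
    ]
    return QuasiRGBImage(
        pixels=np.stack(chans, axis=-1),
        patient_id=item.patient_id,
        frame_refs=item.frame_refs,
        label=item.label,
    )


def compose_quasi_rgb(
    store: FrameStore,
    patient_id: str,
    rng: np.random.Generator,
    same_video_only: bool = True,
) -> QuasiRGBImage:
    """Sample three distinct frames of one patient and stack them as the
    channels of a 224x224 quasi-RGB image (channel order = ascending
    temporal order)."""
    refs = sample_frame_triplet(store, patient_id, rng, same_video_only)
    return materialize(store, PlanItem(patient_id, refs, store.labels[patient_id]))


def hflip(img: np.ndarray) -> np.ndarray:
    """Horizontal mirror; its own inverse."""
    return np.ascontiguousarray(img[:, ::-1, ...])


def augment(img: np.ndarray, config: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    """Apply the configured augmentation suite; identity when disabled.

    Suite: horizontal flip (p = hflip_prob), rotation uniform within
    +-max_rotation_deg, brightness scaling uniform within
    +-max_brightness_frac.  Output dimensions are unchanged.
    """
    if not config.enabled:
        return img
    out = np.asarray(img, dtype=np.float32)
    if config.hflip_prob > 0 and rng.random() < config.hflip_prob:
        out = hflip(out)
    if config.max_rotation_deg > 0:
        angle = rng.uniform(-config.max_rotation_deg, config.max_rotation_deg)
        out = _sk_rotate(out, angle, order=1, mode="edge", preserve_range=True).astype(
            np.float32
        )
    if config.max_brightness_frac > 0:
        scale = 1.0 + rng.uniform(-config.max_brightness_frac, config.max_brightness_frac)
        out = np.clip(out * scale, 0.0, 255.0)
    return out


def _balanced_class_counts(n: int) -> tuple[int, int]:
    """Split n images between the classes; an odd extra goes to class 1."""
    n1 = n // 2 + n % 2
    return n - n1, n1


def _per_patient_counts(n: int, pids: list[str], rng: np.random.Generator) -> dict[str, int]:
    """Round-robin n images over pids: counts differ by at most one; the
    patients receiving an extra image are chosen by a seeded shuffle."""
    base, extra = divmod(n, len(pids))
    order = list(rng.permutation(pids))
    return {pid: base + (1 if order.index(pid) < extra else 0) for pid in pids}


def sample_epoch_plan(
    store: FrameStore,
    training_pids: Iterable[str],
    config: SamplingConfig,
    rng: np.random.Generator,
) -> list[PlanItem]:
    """Plan one training epoch: ``n_per_epoch`` patient-consistent images,
    class counts differing by at most one, per-patient counts within a
    class differing by at most one."""
    config.validate()
    pids = sorted(training_pids)
    by_class = {0: [p for p in pids if store.labels[p] == 0],
                1: [p for p in pids if store.labels[p] == 1]}
    for cls, members in by_class.items():
        if not members:
            raise ValueError(f"class {cls} absent from training groups")
    n0, n1 = _balanced_class_counts(config.n_per_epoch)
    plan: list[PlanItem] = []
    for cls, n_cls in ((0, n0), (1, n1)):
        counts = _per_patient_counts(n_cls, by_class[cls], rng)
        for pid in by_class[cls]:
            for _ in range(counts[pid]):
                refs = sample_frame_triplet(store, pid, rng, config.same_video_only)
                plan.append(PlanItem(pid, refs, cls))
    order = rng.permutation(len(plan))
    return [plan[i] for i in order]


def sample_epoch(
    store: FrameStore,
    training_pids: Iterable[str],
    config: SamplingConfig,
    rng: np.random.Generator,
) -> list[QuasiRGBImage]:
    """Materialized form of :func:`sample_epoch_plan` (with augmentation
    applied when enabled)."""
    plan = sample_epoch_plan(store, training_pids, config, rng)
    images = []
    for item in plan:
        img = materialize(store, item)
        if config.augment.enabled:
            img = QuasiRGBImage(
                pixels=augment(img.pixels, config.augment, rng),
                patient_id=img.patient_id,
                frame_refs=img.frame_refs,
                label=img.label,
            )
        images.append(img)
    return images


def sample_test_plan(
    store: FrameStore,
    patient_id: str,
    config: SamplingConfig,
    rng: np.random.Generator,
) -> list[PlanItem]:
    """Plan ``n_test_per_patient`` images for one test patient."""
    config.validate()
    label = store.labels[patient_id]
    return [
        PlanItem(patient_id, sample_frame_triplet(store, patient_id, rng, config.same_video_only), label)
        for _ in range(config.n_test_per_patient)
    ]


def sample_test_set(
    store: FrameStore,
    patient_id: str,
    config: SamplingConfig,
    rng: np.random.Generator,
) -> list[QuasiRGBImage]:
    """Materialized form of :func:`sample_test_plan` (never augmented)."""
    return [materialize(store, item) for item in sample_test_plan(store, patient_id, config, rng)]
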