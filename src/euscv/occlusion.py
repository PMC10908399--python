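"""Occlusion-sensitivity heatmaps.

A sliding patch is replaced by a baseline intensity (all channels at
once) and the drop in the model's post-link score is recorded:
``delta = score(original) - score(occluded)``.  Each pixel's heatmap value
is the mean delta over all patches covering it, so positive values mark
pixels whose content supports the prediction (rendered red) and negative
values mark counter-evidence (rendered blue).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
from matplotlib import colormaps
from PIL import Image

__all__ = ["OcclusionConfig", "Heatmap", "occlusion_map", "render_heatmap", "head_scorer"]


@dataclass(frozen=True)
class OcclusionConfig:
    """Sliding-patch parameters.

    ``baseline_value`` may be a scalar intensity or a full image array
    (occluding with the image's own pixels yields an all-zero map, a
    useful self-check).
    """

    patch_height: int = 16
    patch_width: int = 16
    stride: int = 8
    baseline_value: float | np.ndarray = 0.0

    def validate(self, image_shape: tuple[int, ...]) -> None:
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.patch_height > image_shape[0] or self.patch_width > image_shape[1]:
            raise ValueError(
                f"patch {(self.patch_height, self.patch_width)} larger than image {image_shape[:2]}"
            )


@dataclass(frozen=True)
class Heatmap:
    """Per-pixel relevance at image resolution; positive = supports the
    prediction, negative = counter-evidence."""

    values: np.ndarray


def occlusion_map(
    scorer: Callable[[np.ndarray], float],
    image: np.ndarray,
    config: OcclusionConfig = OcclusionConfig(),
) -> Heatmap:
    """Occlusion-sensitivity map of a deterministic scorer on one image.

    Patch positions run on the stride grid from the top-left corner,
    including a final row/column flushed to the image edge so every pixel
    is covered.  The occluded patch spans all channels.
    """
    img = np.asarray(image, dtype=np.float64)
    config.validate(img.shape)
    H, W = img.shape[:2]
    ph, pw, s = config.patch_height, config.patch_width, config.stride

    def _grid(extent: int, patch: int) -> list[int]:
        pos = list(range(0, extent - patch + 1, s))
        if pos[-1] != extent - patch:
            pos.append(extent - patch)
        return pos

    base = np.asarray(config.baseline_value, dtype=np.float64)
    score0 = float(scorer(img))
    acc = np.zeros((H, W))
    cnt = np.zeros((H, W))
    for top in _grid(H, ph):
        for left in _grid(W, pw):
            occluded = img.copy()
            if base.ndim == 0:
                occluded[top : top + ph, left : left + pw, ...] = base
            else:
                occluded[top : top + ph, left : left + pw, ...] = base[
                    top : top + ph, left : left + pw, ...
                ]
            delta = score0 - float(scorer(occluded))
            acc[top : top + ph, left : left + pw] += delta
            cnt[top : top + ph, left : left + pw] += 1
    values = np.divide(acc, cnt, out=np.zeros_like(acc), where=cnt > 0)
    return Heatmap(values=values)


def render_heatmap(
    heatmap: Heatmap,
    underlay: np.ndarray,
    path: str | Path,
    alpha: float = 0.55,
) -> np.ndarray:
    """Render the heatmap over a grayscale underlay and write a PNG.

    Diverging blue-white-red colormap with a symmetric scale about zero
    (red = positive/relevant, blue = negative/irrelevant).  Written via
    Pillow with no metadata, so repeated renders are byte-identical.
    Returns the rendered uint8 RGB array.
    """
    h = heatmap.values
    under = np.asarray(underlay, dtype=np.float64)
    if under.ndim == 3:
        under = under.mean(axis=-1)
    if under.shape != h.shape:
        raise ValueError(f"heatmap {h.shape} and underlay {under.shape} dims differ")
    vmax = float(np.max(np.abs(h)))
    norm = np.full_like(h, 0.5) if vmax == 0 else 0.5 + 0.5 * h / vmax
    cmap = colormaps["bwr"]
    overlay = cmap(norm)[..., :3]
    gray = (under - under.min()) / (np.ptp(under) or 1.0)
    blended = (1 - alpha) * gray[..., None] + alpha * overlay
    rgb = np.clip(np.round(blended * 255), 0, 255).astype(np.uint8)
    Image.fromarray(rgb, mode="RGB").save(path, format="PNG")
    return rgb


def head_scorer(extractor, head) -> Callable[[np.ndarray], float]:
    """Scorer closure for :func:`occlusion_map` from a frozen extractor
    and a trained head (post-link score in [0, 1])."""

    def _score(img: np.ndarray) -> float:
        feats = extractor.apply(img[None])
        return float(head.score(feats)[0])

    return _score
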