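#!/usr/bin/env python
"""Occlusion-sensitivity maps for trained heads on synthetic lesions.

Trains one head on a high-separation synthetic cohort, picks one test
patient per class, and computes the occlusion heatmap of a quasi-RGB
image of each (16x16 patch, stride 8, zero baseline).  The heatmap
should concentrate on the lesion region, since that is where the class
signal lives.  Stride-grid heatmap matrices are written as text under
results/occlusion/; full-resolution maps and rendered overlays go to
scratch/.
"""

from pathlib import Path

import numpy as np

from euscv.classifier import RandomProjectionExtractor, TrainConfig, train_head
from euscv.cohort import default_crop_box, generate_cohort, scaled_spec, simulate_endoscopists
from euscv.imaging import FrameStore, SamplingConfig, compose_quasi_rgb
from euscv.occlusion import Heatmap, OcclusionConfig, head_scorer, occlusion_map, render_heatmap

OUT = Path("results/occlusion")
SEED = 11


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    scratch = Path("scratch")
    scratch.mkdir(exist_ok=True)

    cohort = generate_cohort(scaled_spec(seed=SEED, effect_size=2.0))
    simulate_endoscopists(cohort, seed=SEED + 1)
    store = FrameStore.from_cohort(cohort, crop_box=default_crop_box(96, 96))
    pids = sorted(store.labels)
    train_p = [p for i, p in enumerate(pids) if i % 5 != 0]
    val_p = [p for i, p in enumerate(pids) if i % 5 == 0]

    extractor = RandomProjectionExtractor(seed=0, output_dim=128)
    head = train_head(
        extractor, store, train_p, val_p,
        TrainConfig(epochs=10, sampling=SamplingConfig(n_per_epoch=200, n_test_per_patient=10),
                    val_images_per_class=30, seed=SEED),
    )
    print(f"trained head: best validation AUROC {head.best_val_auroc:.3f} "
          f"at epoch {head.best_epoch}")

    scorer = head_scorer(extractor, head)
    cfg = OcclusionConfig(patch_height=16, patch_width=16, stride=8, baseline_value=0.0)
    rng = np.random.default_rng(SEED)
    for pid, cls in (("P000", "pdac"), ("P070", "aip")):
        img = compose_quasi_rgb(store, pid, rng)
        hm = occlusion_map(scorer, img.pixels, cfg)
        # compact stride-grid summary (mean per 8x8 cell) as the text artifact
        grid = hm.values.reshape(28, 8, 28, 8).mean(axis=(1, 3))
        np.savetxt(OUT / f"heatmap_grid_{cls}_{pid}.txt", grid, fmt="%.5e")
        np.savetxt(scratch / f"heatmap_full_{cls}_{pid}.txt", hm.values, fmt="%.5e")
        render_heatmap(Heatmap(hm.values), img.pixels, scratch / f"overlay_{cls}_{pid}.png")
        peak = np.unravel_index(np.argmax(np.abs(hm.values)), hm.values.shape)
        print(f"  {cls.upper()} patient {pid}: score {scorer(img.pixels):.3f}, "
              f"|heatmap| peak at {peak}, range [{hm.values.min():+.4f}, {hm.values.max():+.4f}]")
    print(f"heatmap matrices in {OUT}, rendered overlays in scratch/")


if __name__ == "__main__":
    main()
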