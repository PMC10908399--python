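"""Frozen extractor, head training, checkpointing, ensembling, CV."""

import numpy as np
import pytest
from scipy.special import logit

from euscv.classifier import (
    RandomProjectionExtractor,
    TrainConfig,
    TrainedHead,
    _plan_features,
    ensemble_median,
    extract_features,
    predict_patient,
    run_cross_validation,
    select_best_epoch,
    train_head,
)
from euscv.evaluation import auroc
from euscv.imaging import SamplingConfig, materialize, sample_epoch, sample_epoch_plan
from euscv.splits import divide, order_patients

from conftest import synthetic_store

import pandas as pd


def _const_head(c: float, dim: int) -> TrainedHead:
    """Head whose score is the constant c regardless of features."""
    eps = 1e-9
    return TrainedHead(
        weights=np.zeros(dim),
        bias=float(logit(np.clip(c, eps, 1 - eps))),
        best_val_auroc=0.5,
        best_epoch=1,
        history=pd.DataFrame(),
    )


class TestExtractor:
    def test_duplicate_images_give_identical_rows(self, rng):
        ext = RandomProjectionExtractor(seed=1, output_dim=16)
        img = rng.random((224, 224, 3)) * 255
        feats = ext.apply(np.stack([img, img]))
        np.testing.assert_array_equal(feats[0], feats[1])

    def test_empty_batch(self):
        ext = RandomProjectionExtractor(seed=1, output_dim=16)
        assert extract_features(ext, []).shape == (0, 16)

    def test_matches_explicit_matrix_product_oracle(self, rng):
        """Features equal the dense matrix product of the centred pooled
        pixel vector with the stored projection, computed independently."""
        ext = RandomProjectionExtractor(seed=3, output_dim=8, pool=8)
        img = rng.random((224, 224, 3)) * 255
        # independent pooling: explicit loops over 8x8 blocks, channel-major
        pooled = np.empty(3 * 28 * 28)
        k = 0
        for c in range(3):
            for i in range(28):
                for j in range(28):
                    pooled[k] = img[8 * i : 8 * i + 8, 8 * j : 8 * j + 8, c].mean()
                    k += 1
        oracle = (pooled / 255.0 - 0.5) @ ext.projection
        np.testing.assert_allclose(ext.apply(img[None])[0], oracle, rtol=1e-10)

    def test_wrong_shape_rejected(self):
        ext = RandomProjectionExtractor(seed=1, output_dim=16)
        with pytest.raises(ValueError):
            ext.apply(np.zeros((2, 100, 100, 3)))

    def test_fast_path_equals_materialized_path(self, tiny_store, rng):
        ext = RandomProjectionExtractor(seed=2, output_dim=32)
        cfg = SamplingConfig(n_per_epoch=20, n_test_per_patient=1)
        plan = sample_epoch_plan(tiny_store, tiny_store.patient_ids, cfg, np.random.default_rng(4))
        fast = _plan_features(ext, tiny_store, plan)
        imgs = [materialize(tiny_store, item) for item in plan]
        slow = extract_features(ext, imgs)
        np.testing.assert_allclose(fast, slow, rtol=1e-8)


class TestTrainHead:
    def test_separable_classes_reach_high_training_accuracy(self):
        """Bright-vs-dark synthetic patients are linearly separable in
        pooled-pixel space; the logistic probe fits them within 20 epochs."""
        labels = {f"P{i}": int(i >= 4) for i in range(8)}
        store = synthetic_store(labels, n_frames=5, seed=1)
        ext = RandomProjectionExtractor(seed=0, output_dim=32, side=224)
        cfg = TrainConfig(
            epochs=20,
            seed=5,
            sampling=SamplingConfig(n_per_epoch=100, n_test_per_patient=5),
            val_images_per_class=20,
        )
        head = train_head(ext, store, list(labels), list(labels)[:2] + list(labels)[-2:], cfg)
        imgs = sample_epoch(store, list(labels), cfg.sampling, np.random.default_rng(6))
        scores = head.score(extract_features(ext, imgs))
        y = np.array([img.label for img in imgs])
        acc = np.mean((scores >= 0.5) == y)
        assert acc >= 0.95

    def test_checkpoint_selects_peak_epoch_of_injected_sequence(self):
        seq = [0.5, 0.55, 0.6, 0.58, 0.62, 0.61, 0.70, 0.65, 0.64, 0.6]
        assert select_best_epoch(seq) == 7

    def test_checkpoint_tie_goes_to_earliest_epoch(self):
        assert select_best_epoch([0.6, 0.7, 0.7, 0.5]) == 2

    def test_stored_parameters_correspond_to_best_epoch(self):
        labels = {f"P{i}": int(i % 2) for i in range(6)}
        store = synthetic_store(labels, n_frames=4, seed=2)
        ext = RandomProjectionExtractor(seed=0, output_dim=16)
        cfg = TrainConfig(
            epochs=6, seed=7,
            sampling=SamplingConfig(n_per_epoch=30, n_test_per_patient=2),
            val_images_per_class=10,
        )
        head = train_head(ext, store, list(labels), list(labels), cfg)
        assert head.best_val_auroc == head.history["val_auroc"].max()
        assert head.best_epoch == int(head.history["val_auroc"].idxmax()) + 1

    def test_no_signal_cohort_best_val_auroc_near_chance(self, rng):
        """effect_size = 0: even the best epoch's validation AUROC stays
        in a chance band over seeded runs."""
        from euscv.cohort import default_crop_box, generate_cohort, scaled_spec, simulate_endoscopists
        from euscv.imaging import FrameStore

        spec = scaled_spec(seed=5, effect_size=0.0, n_positive=20, n_negative=16,
                           frames_per_video=(4, 8), frame_height=64, frame_width=64)
        cohort = generate_cohort(spec)
        simulate_endoscopists(cohort, seed=6)
        store = FrameStore.from_cohort(cohort, crop_box=default_crop_box(64, 64))
        pids = sorted(store.labels)
        train_p = [p for i, p in enumerate(pids) if i % 3 != 0]
        val_p = [p for i, p in enumerate(pids) if i % 3 == 0]
        ext = RandomProjectionExtractor(seed=0)
        for seed in (3, 4, 5):
            cfg = TrainConfig(epochs=20, seed=seed,
                              sampling=SamplingConfig(n_per_epoch=120, n_test_per_patient=10),
                              val_images_per_class=100)
            head = train_head(ext, store, train_p, val_p, cfg)
            assert 0.35 <= head.best_val_auroc <= 0.65

    def test_single_class_training_rejected(self):
        labels = {"A": 1, "B": 1}
        store = synthetic_store(labels, n_frames=4)
        ext = RandomProjectionExtractor(seed=0, output_dim=8)
        cfg = TrainConfig(epochs=1, sampling=SamplingConfig(n_per_epoch=10, n_test_per_patient=1))
        with pytest.raises(ValueError, match="class 0"):
            train_head(ext, store, ["A", "B"], ["A"], cfg)


class TestEnsemble:
    def test_even_median_is_mean_of_middle_pair(self):
        assert ensemble_median([0.1, 0.2, 0.8, 0.9]) == pytest.approx(0.5)

    def test_constant_scores(self):
        assert ensemble_median([0.7, 0.7, 0.7, 0.7]) == pytest.approx(0.7)

    def test_permutation_invariance(self):
        import itertools

        for perm in itertools.permutations((0.1, 0.4, 0.6, 1.0)):
            assert ensemble_median(perm) == pytest.approx(0.5)

    @pytest.mark.parametrize("bad", [[0.5] * 3, [0.5] * 5, []])
    def test_wrong_count_rejected(self, bad):
        with pytest.raises(ValueError):
            ensemble_median(bad)

    def test_bounded_by_members_and_middle_value_rule(self, rng):
        for _ in range(50):
            s = rng.random(4)
            m = ensemble_median(s)
            assert s.min() <= m <= s.max()
        # 3-of-4 agreement -> median equals the agreed value
        assert ensemble_median([0.3, 0.3, 0.3, 0.9]) == pytest.approx(0.3)


class TestPredictPatient:
    def _setup(self):
        store = synthetic_store({"PA": 1}, n_frames=5)
        ext = RandomProjectionExtractor(seed=0, output_dim=8)
        cfg = SamplingConfig(n_per_epoch=10, n_test_per_patient=20)
        return store, ext, cfg

    def test_constant_heads_propagate(self):
        store, ext, cfg = self._setup()
        heads = [_const_head(0.8, 8)] * 4
        score = predict_patient(heads, ext, store, "PA", cfg, np.random.default_rng(1))
        assert score == pytest.approx(0.8, abs=1e-6)

    def test_split_constant_heads_give_half(self):
        store, ext, cfg = self._setup()
        heads = [_const_head(0.0, 8), _const_head(0.0, 8), _const_head(1.0, 8), _const_head(1.0, 8)]
        score = predict_patient(heads, ext, store, "PA", cfg, np.random.default_rng(1))
        assert score == pytest.approx(0.5, abs=1e-6)

    def test_seeded_determinism(self):
        store, ext, cfg = self._setup()
        heads = [_const_head(0.3, 8)] * 4
        a = predict_patient(heads, ext, store, "PA", cfg, np.random.default_rng(7))
        b = predict_patient(heads, ext, store, "PA", cfg, np.random.default_rng(7))
        assert a == b

    def test_requires_four_heads(self):
        store, ext, cfg = self._setup()
        with pytest.raises(ValueError):
            predict_patient([_const_head(0.5, 8)] * 3, ext, store, "PA", cfg, np.random.default_rng(0))


@pytest.fixture(scope="module")
def small_cv(desk_cohort, desk_store):
    _, cohort = desk_cohort
    division = divide(order_patients(cohort, "CHR"), 5, "balanced", factor="CHR")
    ext = RandomProjectionExtractor(seed=0, output_dim=64)
    cfg = TrainConfig(epochs=3,
                      sampling=SamplingConfig(n_per_epoch=60, n_test_per_patient=8),
                      val_images_per_class=15)
    return run_cross_validation(desk_store, division, ext, cfg, seed=99)


class TestCrossValidation:
    def test_twenty_training_sessions(self, small_cv):
        assert small_cv.n_training_sessions == 20
        assert all(len(f.validation_groups) == 4 for f in small_cv.folds)

    def test_every_patient_tested_exactly_once(self, small_cv, desk_store):
        tested = [pid for f in small_cv.folds for pid in f.patient_ids]
        assert sorted(tested) == desk_store.patient_ids

    def test_leakage_audit_passes_on_every_fold(self, small_cv):
        assert all(f.leakage.passed for f in small_cv.folds)

    def test_checkpoints_recorded(self, small_cv):
        for f in small_cv.folds:
            assert all(1 <= e <= 3 for e in f.best_epochs)

    def test_frozen_extractor_unchanged_by_training(self, desk_store, desk_cohort):
        ext = RandomProjectionExtractor(seed=0, output_dim=16)
        before = ext.projection.copy()
        pids = sorted(desk_store.labels)
        train_p = [p for i, p in enumerate(pids) if i % 3 != 0]
        val_p = [p for i, p in enumerate(pids) if i % 3 == 0]
        cfg = TrainConfig(epochs=1, sampling=SamplingConfig(n_per_epoch=20, n_test_per_patient=2),
                          val_images_per_class=5)
        train_head(ext, desk_store, train_p, val_p, cfg)
        np.testing.assert_array_equal(ext.projection, before)

    def test_label_permutation_null_gives_chance_level(self, desk_cohort):
        """Shuffling patient labels destroys the class signal: mean test
        AUROC falls in the chance band."""
        from euscv.cohort import default_crop_box
        from euscv.imaging import FrameStore

        spec, cohort = desk_cohort
        store = FrameStore.from_cohort(cohort, crop_box=default_crop_box(spec.frame_height, spec.frame_width))
        rng = np.random.default_rng(13)
        values = np.array([store.labels[p] for p in sorted(store.labels)])
        store.labels = dict(zip(sorted(store.labels), (int(v) for v in rng.permutation(values))))
        division = divide(order_patients(cohort, "AGE"), 5, "balanced", factor="AGE")
        ext = RandomProjectionExtractor(seed=0, output_dim=64)
        cfg = TrainConfig(epochs=4, sampling=SamplingConfig(n_per_epoch=80, n_test_per_patient=8),
                          val_images_per_class=15)
        cv = run_cross_validation(store, division, ext, cfg, seed=123)
        mean_auc = np.mean([auroc(f.scores, f.labels) for f in cv.folds])
        assert 0.35 <= mean_auc <= 0.65
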