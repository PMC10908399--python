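"""Transfer learning with a frozen feature extractor and median-of-4
ensembling over validation-group rotations.

The model is a pretrained convolutional feature extractor whose parameters
are never updated ("frozen"), with only the final classifier layer
retrained: a single linear layer with a logistic link, fit by stochastic
gradient descent on the logistic loss.  Each training session lasts a
fixed number of epochs; after every epoch the validation AUROC is computed
on a fixed seeded sample of quasi-RGB images from the validation patients,
and the parameters of the best-validation-AUROC epoch are kept (earliest
epoch on ties).

For each test group of a 5-group division there are four choices of
validation group, hence four trained heads; a test image's final score is
the median of the four head scores, and a patient's score is the mean of
its per-image medians.

The default extractor is a deterministic seeded random projection of the
(block-pooled) pixel vector — a linear map, so a logistic head on top of
it is a linear probe in pooled pixel space.  A deep pretrained extractor
(e.g. ResNet-family penultimate features) satisfies the same contract and
can be plugged in; nothing in this package requires one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from ._seeding import derive_rng, derive_seed
from .evaluation import auroc
from .imaging import (
    FrameStore,
    PlanItem,
    QuasiRGBImage,
    SamplingConfig,
    materialize,
    sample_epoch_plan,
    sample_test_plan,
)
from .splits import GroupDivision, LeakageReport, check_leakage, enumerate_allotments

__all__ = [
    "FeatureExtractor",
    "RandomProjectionExtractor",
    "TrainConfig",
    "TrainedHead",
    "FoldResult",
    "CVResult",
    "extract_features",
    "train_head",
    "select_best_epoch",
    "ensemble_median",
    "predict_patient",
    "run_cross_validation",
]


class FeatureExtractor(Protocol):
    """Frozen feature extractor contract: a deterministic map from a batch
    of 224x224x3 images to fixed-length feature vectors."""

    name: str
    output_dim: int

    def apply(self, images: np.ndarray) -> np.ndarray:
        """(n, 224, 224, 3) -> (n, output_dim); order preserved."""
        ...


class RandomProjectionExtractor:
    """Seeded random-projection test double for the frozen extractor.

    Pipeline: per-channel ``pool x pool`` block-mean pooling of the
    224x224x3 input, channel-major flattening, centering (pixels scaled to
    [0,1] minus 0.5), then a fixed Gaussian projection scaled by
    ``1/sqrt(input_dim)``.  Entirely linear and deterministic, so feature
    rows can be cross-checked against an explicit matrix product, and a
    logistic head on these features is a linear probe on pooled pixels.
    """

    def __init__(self, seed: int = 0, output_dim: int = 128, pool: int = 8, side: int = 224):
        if side % pool != 0:
            raise ValueError("pool must divide the image side")
        self.name = f"randproj-{output_dim}d-seed{seed}"
        self.seed = seed
        self.output_dim = output_dim
        self.pool = pool
        self.side = side
        self.grid = side // pool
        self.channel_dim = self.grid * self.grid  # pooled values per channel
        input_dim = 3 * self.channel_dim
        rng = np.random.default_rng(seed)
        self.projection = rng.standard_normal((input_dim, output_dim)) / np.sqrt(input_dim)

    # -- contract -----------------------------------------------------
    def apply(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 3:
            images = images[None]
        n = images.shape[0]
        if images.shape[1:] != (self.side, self.side, 3):
            raise ValueError(
                f"expected (n, {self.side}, {self.side}, 3) images, got {images.shape}"
            )
        g, p = self.grid, self.pool
        pooled = images.reshape(n, g, p, g, p, 3).mean(axis=(2, 4))  # (n, g, g, 3)
        flat = np.moveaxis(pooled, -1, 1).reshape(n, 3 * self.channel_dim)
        return self.project_pooled(flat)

    # -- fast path helpers (exactly the same arithmetic) ---------------
    def pool_frame(self, frame: np.ndarray) -> np.ndarray:
        """Block-mean pool one 224x224 channel to a flat vector."""
        g, p = self.grid, self.pool
        return np.asarray(frame, dtype=np.float64).reshape(g, p, g, p).mean(axis=(1, 3)).ravel()

    def project_pooled(self, pooled_concat: np.ndarray) -> np.ndarray:
        """Project channel-major concatenated pooled vectors (n, 3*g*g)."""
        x = np.atleast_2d(np.asarray(pooled_concat, dtype=np.float64)) / 255.0 - 0.5
        return x @ self.projection


def extract_features(extractor: FeatureExtractor, images: Sequence[QuasiRGBImage] | np.ndarray) -> np.ndarray:
    """Apply the frozen extractor to a batch; one row per image."""
    if isinstance(images, np.ndarray):
        batch = images
    else:
        if len(images) == 0:
            return np.empty((0, extractor.output_dim))
        batch = np.stack([img.pixels for img in images])
    if batch.size == 0:
        return np.empty((0, extractor.output_dim))
    return extractor.apply(batch)


@dataclass(frozen=True)
class TrainConfig:
    """Head-training hyperparameters.

    The learning rate, optimizer (plain SGD), batch size and validation
    sampling size are this package's own defaults; the study design fixes
    only the epoch count (20), the per-epoch class-balanced sampling and
    the best-validation-AUROC checkpoint rule.
    """

    epochs: int = 20
    learning_rate: float = 0.5
    batch_size: int = 32
    val_images_per_class: int = 100
    seed: int = 0
    sampling: SamplingConfig = field(default_factory=SamplingConfig)

    def validate(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class TrainedHead:
    """Retrained classifier layer: logistic score over frozen features.

    Stored parameters are those of ``best_epoch`` (1-based), the epoch of
    maximal validation AUROC; ``history`` logs (epoch, train_loss,
    val_auroc) for every epoch.
    """

    weights: np.ndarray
    bias: float
    best_val_auroc: float
    best_epoch: int
    history: pd.DataFrame

    def score(self, features: np.ndarray) -> np.ndarray:
        """Logistic probability of class 1 (PDAC) per feature row."""
        return expit(np.atleast_2d(features) @ self.weights + self.bias)


def select_best_epoch(val_aurocs: Sequence[float]) -> int:
    """1-based index of the maximal validation AUROC (earliest on ties)."""
    if len(val_aurocs) == 0:
        raise ValueError("empty validation metric sequence")
    arr = np.asarray(val_aurocs, dtype=float)
    return int(np.argmax(arr)) + 1


def _plan_features(extractor, store: FrameStore, plan: Sequence[PlanItem]) -> np.ndarray:
    """Features for a plan, via cached pooled frames when the extractor
    exposes the linear fast path, else by materializing pixels."""
    if hasattr(extractor, "pool_frame") and hasattr(extractor, "project_pooled"):
        cache: dict[tuple[str, str], np.ndarray] = getattr(store, "_pooled_cache", None)
        if cache is None:
            cache = {}
            store._pooled_cache = cache  # type: ignore[attr-defined]
        rows = np.empty((len(plan), 3 * extractor.channel_dim))
        for i, item in enumerate(plan):
            parts = []
            for ref in item.frame_refs:
                key = (item.patient_id, ref.video_id)
                if key not in cache:
                    stack = store.resized_stack(item.patient_id, ref.video_id)
                    cache[key] = np.stack([extractor.pool_frame(f) for f in stack])
                parts.append(cache[key][ref.frame_index])
            rows[i] = np.concatenate(parts)
        return extractor.project_pooled(rows)
    images = [materialize(store, item) for item in plan]
    return extract_features(extractor, images)


def _validation_sample_plan(
    store: FrameStore,
    val_pids: Sequence[str],
    n_per_class: int,
    sampling: SamplingConfig,
    rng: np.random.Generator,
) -> list[PlanItem]:
    """Fixed validation sample: up to n_per_class images per class, drawn
    with the same balanced round-robin scheme as training epochs."""
    labels = {pid: store.labels[pid] for pid in val_pids}
    present = sorted({v for v in labels.values()})
    plan: list[PlanItem] = []
    from .imaging import _per_patient_counts, sample_frame_triplet  # local to avoid cycle noise

    for cls in present:
        members = sorted(p for p, l in labels.items() if l == cls)
        counts = _per_patient_counts(n_per_class, members, rng)
        for pid in members:
            for _ in range(counts[pid]):
                refs = sample_frame_triplet(store, pid, rng, sampling.same_video_only)
                plan.append(PlanItem(pid, refs, cls))
    return plan


def train_head(
    extractor: FeatureExtractor,
    store: FrameStore,
    training_pids: Sequence[str],
    validation_pids: Sequence[str],
    config: TrainConfig,
) -> TrainedHead:
    """Train the classifier layer on frozen features.

    Per epoch: a fresh class-balanced quasi-RGB sample from the training
    patients, SGD steps on the logistic loss (head parameters only), then
    validation AUROC on a fixed seeded validation image sample.  Returns
    the parameters of the best-validation-AUROC epoch.
    """
    config.validate()
    if not validation_pids:
        raise ValueError("validation group is empty")

    val_rng = derive_rng(config.seed, "validation-sample")
    val_plan = _validation_sample_plan(
        store, validation_pids, config.val_images_per_class, config.sampling, val_rng
    )
    val_X = _plan_features(extractor, store, val_plan)
    val_y = np.array([item.label for item in val_plan])
    val_defined = len(np.unique(val_y)) == 2

    dim = extractor.output_dim
    w = np.zeros(dim)
    b = 0.0
    sgd_rng = derive_rng(config.seed, "sgd")
    records = []
    snapshots: list[tuple[np.ndarray, float]] = []
    for epoch in range(1, config.epochs + 1):
        epoch_rng = derive_rng(config.seed, "epoch", epoch)
        plan = sample_epoch_plan(store, training_pids, config.sampling, epoch_rng)
        X = _plan_features(extractor, store, plan)
        y = np.array([item.label for item in plan])

        order = sgd_rng.permutation(len(plan))
        losses = []
        for start in range(0, len(order), config.batch_size):
            sel = order[start : start + config.batch_size]
            Xb, yb = X[sel], y[sel]
            z = Xb @ w + b
            p = expit(z)
            losses.append(float(np.mean(np.logaddexp(0.0, z) - yb * z)))
            grad_w = Xb.T @ (p - yb) / len(sel)
            grad_b = float(np.mean(p - yb))
            w -= config.learning_rate * grad_w
            b -= config.learning_rate * grad_b

        # validation AUROC on the fixed sample; 0.5 if the validation
        # group happens to hold a single class (no ranking signal)
        val_auroc = auroc(expit(val_X @ w + b), val_y) if val_defined else 0.5
        records.append((epoch, float(np.mean(losses)), float(val_auroc)))
        snapshots.append((w.copy(), b))

    history = pd.DataFrame(records, columns=["epoch", "train_loss", "val_auroc"])
    best = select_best_epoch(history["val_auroc"].to_numpy())
    best_w, best_b = snapshots[best - 1]
    return TrainedHead(
        weights=best_w,
        bias=best_b,
        best_val_auroc=float(history["val_auroc"].iloc[best - 1]),
        best_epoch=best,
        history=history,
    )


def ensemble_median(scores: Sequence[float]) -> float:
    """Median of exactly four member scores (mean of the middle pair)."""
    arr = np.asarray(scores, dtype=float)
    if arr.shape != (4,):
        raise ValueError(f"expected exactly 4 scores, got shape {arr.shape}")
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("scores must lie in [0, 1]")
    return float(np.median(arr))


def predict_patient(
    heads: Sequence[TrainedHead],
    extractor: FeatureExtractor,
    store: FrameStore,
    patient_id: str,
    sampling: SamplingConfig,
    rng: np.random.Generator,
) -> float:
    """Patient-level score: sample the test images once, score them with
    all four heads, take the per-image ensemble median, then the mean."""
    if len(heads) != 4:
        raise ValueError("the framework always yields 4 heads per test group")
    plan = sample_test_plan(store, patient_id, sampling, rng)
    X = _plan_features(extractor, store, plan)
    member_scores = np.stack([h.score(X) for h in heads])  # (4, n_images)
    medians = np.array([ensemble_median(member_scores[:, i]) for i in range(X.shape[0])])
    return float(np.mean(medians))


@dataclass(frozen=True)
class FoldResult:
    """Scores for one test group."""

    test_group: int
    patient_ids: tuple[str, ...]
    scores: np.ndarray
    labels: np.ndarray
    validation_groups: tuple[int, ...]
    best_epochs: tuple[int, ...]
    best_val_aurocs: tuple[float, ...]
    leakage: LeakageReport


@dataclass(frozen=True)
class CVResult:
    """Full 5-fold cross-validation outcome (20 training sessions)."""

    division_factor: str
    division_mode: str
    folds: tuple[FoldResult, ...]
    n_training_sessions: int

    def all_scores(self) -> tuple[np.ndarray, np.ndarray]:
        scores = np.concatenate([f.scores for f in self.folds])
        labels = np.concatenate([f.labels for f in self.folds])
        return scores, labels


def run_cross_validation(
    store: FrameStore,
    division: GroupDivision,
    extractor: FeatureExtractor,
    train_config: TrainConfig,
    seed: int = 0,
) -> CVResult:
    """Run the full framework on one division: for each of the k test
    groups, train the k-1 validation-rotation heads (k*(k-1) sessions in
    total), score every test patient with the median-of-4 ensemble, and
    audit every fold for patient-level leakage.
    """
    k = division.k
    allotments = enumerate_allotments(k)
    heads: dict[tuple[int, int], TrainedHead] = {}
    train_plans_used: dict[tuple[int, int], list[PlanItem]] = {}

    folds = []
    n_sessions = 0
    for test_g in range(k):
        group_allotments = [a for a in allotments if a.test_group == test_g]
        fold_heads = []
        val_groups = []
        test_pids = division.group_members(test_g)
        fold_report: LeakageReport | None = None
        for allot in group_allotments:
            train_pids = [
                pid for g in allot.training_groups for pid in division.group_members(g)
            ]
            val_pids = division.group_members(allot.validation_group)
            # within one session the three roles must be patient-disjoint;
            # across sessions the validation group legitimately rotates
            report = check_leakage(
                division,
                allot,
                {"training": train_pids, "validation": val_pids, "test": test_pids},
            )
            if not report.passed:
                raise RuntimeError(
                    f"leakage in session (test={test_g}, val={allot.validation_group}): "
                    f"{report.offending}"
                )
            fold_report = report
            cfg = TrainConfig(
                epochs=train_config.epochs,
                learning_rate=train_config.learning_rate,
                batch_size=train_config.batch_size,
                val_images_per_class=train_config.val_images_per_class,
                seed=derive_seed(seed, "session", test_g, allot.validation_group),
                sampling=train_config.sampling,
            )
            head = train_head(extractor, store, train_pids, val_pids, cfg)
            heads[(test_g, allot.validation_group)] = head
            fold_heads.append(head)
            val_groups.append(allot.validation_group)
            n_sessions += 1

        scores = []
        for pid in test_pids:
            rng = derive_rng(seed, "test-sample", test_g, pid)
            scores.append(
                predict_patient(fold_heads, extractor, store, pid, train_config.sampling, rng)
            )
        labels = np.array([store.labels[pid] for pid in test_pids])

        folds.append(
            FoldResult(
                test_group=test_g,
                patient_ids=tuple(test_pids),
                scores=np.array(scores),
                labels=labels,
                validation_groups=tuple(val_groups),
                best_epochs=tuple(h.best_epoch for h in fold_heads),
                best_val_aurocs=tuple(h.best_val_auroc for h in fold_heads),
                leakage=fold_report,
            )
        )
    return CVResult(
        division_factor=division.factor,
        division_mode=division.mode,
        folds=tuple(folds),
        n_training_sessions=n_sessions,
    )
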