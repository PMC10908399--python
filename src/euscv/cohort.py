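"""Synthetic endoscopic-ultrasound (EUS) cohort generator.

The study design this package implements needs a cohort of patients, each
with one or more short EUS video clips of a pancreatic lesion, a binary
diagnosis (0 = localized autoimmune pancreatitis, AIP; 1 = pancreatic
ductal adenocarcinoma, PDAC), clinical covariates used as split factors,
and a panel of human raters whose per-patient diagnostic accuracy defines
the EDA factor.  Real EUS images of this kind are private patient data, so
this module generates a statistically analogous cohort from a seed:

* frames are 8-bit grayscale, a smooth low-frequency background carrying an
  elliptical lesion, degraded by multiplicative Rayleigh speckle;
* the two diagnostic classes differ in lesion-interior mean intensity and
  speckle heterogeneity, separated by a tunable ``effect_size`` (0 means
  the classes are statistically indistinguishable);
* consecutive frames of a video are correlated: the underlying scene is
  shifted by a small random walk while the speckle is redrawn per frame;
* frames carry a dark bottom band (where ultrasound does not reach) and
  bright corner annotation marks, so the cropping stage has real foreign
  features to remove;
* a latent per-patient ``diagnosability`` (a logistic transform of the
  realized class-typical texture separation) drives a simulated rater
  panel, from which the per-patient EDA score (fraction of raters correct)
  is derived rather than set directly.

Everything is a pure function of (spec, seed): the same spec reproduces the
cohort bit-for-bit.  Frames are generated lazily per video from a derived
seed, so metadata-only uses never pay the imaging cost.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.special import expit

from ._seeding import derive_rng, derive_seed

__all__ = [
    "CohortSpec",
    "CovariateParams",
    "SkillParams",
    "PatientRecord",
    "Video",
    "EndoscopistPanel",
    "SpecValidationError",
    "generate_cohort",
    "simulate_endoscopists",
    "cohort_metadata",
    "alcohol_category",
    "default_crop_box",
    "write_cohort",
    "scaled_spec",
]

# Geometry of the decorations the preprocessing stage must remove,
# as fractions of the raw frame size.
TOP_MARGIN_FRAC = 0.06
BOTTOM_BAND_FRAC = 0.08
SIDE_MARGIN_FRAC = 0.04

#: Maximum per-video scene translation (pixels) of the frame random walk.
MAX_SHIFT = 3

#: Base multiplicative speckle contrast (fraction of local intensity).
SPECKLE_CONTRAST = 0.30

#: Lesion-interior intensity shift: ``-(_LESION_BASE + _LESION_SLOPE * z)``
#: where ``z`` is the patient's latent texture parameter.  The slope times
#: the class separation in ``z`` is the learnable image signal.
_LESION_BASE = 0.06
_LESION_SLOPE = 0.035

_RAYLEIGH_MEAN = float(np.sqrt(np.pi / 2.0))


class SpecValidationError(ValueError):
    """Raised when a cohort spec violates an invariant; names the field."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


def alcohol_category(g_per_day: float) -> str:
    """Drinker category from daily ethanol intake (g/day).

    Light < 20, moderate 20-60, heavy >= 60.
    """
    if g_per_day < 20:
        return "light"
    if g_per_day < 60:
        return "moderate"
    return "heavy"


@dataclass(frozen=True)
class CovariateParams:
    """Distributions of the clinical covariates (split factors).

    Defaults emulate the reported cohort: ages around 70 years, BMI around
    22 kg/m^2, mostly light drinkers, sessions spread over 2016-2022.
    Covariates are independent of the diagnostic label unless a confounder
    is requested on the spec.
    """

    age_mean: float = 69.5
    age_sd: float = 9.0
    age_range: tuple[float, float] = (40.0, 90.0)
    bmi_mean: float = 22.0
    bmi_sd: float = 2.6
    bmi_range: tuple[float, float] = (15.0, 38.0)
    # light / moderate / heavy probabilities (56/85, 23/85, 6/85 overall)
    alcohol_probs: tuple[float, float, float] = (56 / 85, 23 / 85, 6 / 85)
    alcohol_heavy_max: float = 120.0
    date_start: int = _dt.date(2016, 2, 1).toordinal()
    date_end: int = _dt.date(2022, 7, 31).toordinal()


@dataclass(frozen=True)
class SkillParams:
    """Map from patient diagnosability to a rater's probability of a
    correct call: ``p = clip(0.5 + slope * (d - 0.5), 0, 1)``.

    ``slope = 1`` is the identity mapping.  Experts must be at least as
    skilled as novices.
    """

    expert_slope: float = 0.9
    novice_slope: float = 0.5

    def prob_correct(self, diagnosability: np.ndarray, expert: bool) -> np.ndarray:
        slope = self.expert_slope if expert else self.novice_slope
        return np.clip(0.5 + slope * (np.asarray(diagnosability) - 0.5), 0.0, 1.0)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.  Defaults reproduce the study
    conditions: 61 PDAC vs 24 AIP patients, 1-3 videos each, 100-300
    frames per video, raw frames large enough for the 465x489 crop."""

    n_positive: int = 61
    n_negative: int = 24
    videos_per_patient: tuple[int, int] = (1, 3)
    frames_per_video: tuple[int, int] = (100, 300)
    frame_height: int = 576
    frame_width: int = 512
    effect_size: float = 1.0
    covariate_params: CovariateParams = field(default_factory=CovariateParams)
    n_experts: int = 4
    n_novices: int = 3
    seed: int = 0
    #: optionally correlate one covariate with the label (for split studies)
    confound_factor: str | None = None
    confound_strength: float = 0.0

    # Minimum crop size the raw frames must accommodate; the full-scale
    # defaults accommodate the standard 489x465 crop.
    min_crop: tuple[int, int] = (0, 0)

    def validate(self) -> None:
        if self.n_positive < 1:
            raise SpecValidationError("n_positive", "must be >= 1")
        if self.n_negative < 1:
            raise SpecValidationError("n_negative", "must be >= 1")
        lo, hi = self.videos_per_patient
        if not (1 <= lo <= hi):
            raise SpecValidationError("videos_per_patient", "need 1 <= lo <= hi")
        flo, fhi = self.frames_per_video
        if flo < 3:
            raise SpecValidationError(
                "frames_per_video", "lower bound must be >= 3 (a quasi-RGB needs three frames)"
            )
        if fhi < flo:
            raise SpecValidationError("frames_per_video", "upper bound below lower bound")
        if self.effect_size < 0:
            raise SpecValidationError("effect_size", "must be nonnegative")
        ch, cw = self.min_crop
        if self.frame_height < ch or self.frame_width < cw:
            raise SpecValidationError(
                "frame_height/frame_width", f"raw dims must be >= crop dims {self.min_crop}"
            )
        if self.n_experts < 0 or self.n_novices < 0:
            raise SpecValidationError("n_experts/n_novices", "must be nonnegative")
        if self.confound_factor is not None and self.confound_factor not in (
            "age",
            "bmi",
            "alcohol",
            "session_date",
        ):
            raise SpecValidationError("confound_factor", f"unknown factor {self.confound_factor!r}")


@dataclass(frozen=True)
class Video:
    """One EUS video clip: frames are generated lazily and deterministically
    from the stored seed and scene parameters."""

    patient_id: str
    video_id: str
    n_frames: int
    height: int
    width: int
    seed: int
    lesion_center: tuple[float, float]  # (row, col) fractions of frame dims
    lesion_axes: tuple[float, float]  # semi-axes as fractions of min dim
    lesion_shift: float  # intensity shift inside the lesion
    lesion_speckle_gain: float  # extra speckle contrast inside the lesion

    def frame_stack(self) -> np.ndarray:
        """Generate the full ``(n_frames, height, width)`` uint8 stack.

        Pure function of the stored fields: repeated calls are identical.
        """
        rng = np.random.default_rng(self.seed)
        h, w, m = self.height, self.width, MAX_SHIFT
        ch, cw = h + 2 * m, w + 2 * m

        yy, xx = np.mgrid[0:ch, 0:cw].astype(np.float64)
        bg = 0.42 + 0.10 * (yy / ch)
        for _ in range(3):
            amp = rng.uniform(0.01, 0.03)
            ky, kx = rng.integers(1, 5, size=2)
            phase = rng.uniform(0, 2 * np.pi)
            bg += amp * np.cos(2 * np.pi * (kx * xx / cw + ky * yy / ch) + phase)

        cy = self.lesion_center[0] * h + m
        cx = self.lesion_center[1] * w + m
        a = self.lesion_axes[0] * min(h, w)
        b = self.lesion_axes[1] * min(h, w)
        r2 = ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2
        mask = (r2 <= 1.0).astype(np.float64)
        scene = bg + self.lesion_shift * mask

        steps = rng.integers(-1, 2, size=(self.n_frames, 2))
        shifts = np.clip(np.cumsum(steps, axis=0), -m, m)

        band = max(1, int(round(BOTTOM_BAND_FRAC * h)))
        mark = max(2, int(round(0.03 * min(h, w))))

        frames = np.empty((self.n_frames, h, w), dtype=np.uint8)
        for t in range(self.n_frames):
            dy, dx = int(shifts[t, 0]), int(shifts[t, 1])
            view = scene[m + dy : m + dy + h, m + dx : m + dx + w]
            mview = mask[m + dy : m + dy + h, m + dx : m + dx + w]
            speck = rng.rayleigh(1.0, size=(h, w)) / _RAYLEIGH_MEAN
            contrast = SPECKLE_CONTRAST * (1.0 + self.lesion_speckle_gain * mview)
            img = view * (1.0 + contrast * (speck - 1.0))
            # static overlays: unreachable bottom band and corner marks
            img[-band:, :] = 0.02 + 0.02 * rng.random((band, w))
            for col in (1, w // 2 - mark // 2, w - mark - 1):
                img[1 : 1 + mark, col : col + mark] = 0.95
            frames[t] = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
        return frames


@dataclass
class PatientRecord:
    """One patient: diagnosis, covariates, latent ground truth, videos."""

    patient_id: str
    label: int  # 0 = AIP, 1 = PDAC
    age_years: float
    bmi: float
    alcohol_g_per_day: float
    session_date: int  # proleptic Gregorian ordinal
    texture_param: float  # latent z: class-typical texture coordinate
    diagnosability: float  # in [0, 1]; increasing in realized separation
    videos: list[Video] = field(default_factory=list)
    eda_score: float | None = None  # filled by simulate_endoscopists

    @property
    def alcohol_category(self) -> str:
        return alcohol_category(self.alcohol_g_per_day)

    def frame_count(self) -> int:
        return sum(v.n_frames for v in self.videos)


@dataclass(frozen=True)
class EndoscopistPanel:
    """Result of a simulated rater panel.

    ``diagnoses`` is a raters x patients DataFrame of binary calls
    (0 = AIP, 1 = PDAC); expert rater ids start with ``expert``.
    """

    diagnoses: pd.DataFrame
    eda_score: pd.Series
    expert_ids: tuple[str, ...]
    novice_ids: tuple[str, ...]


_CONFOUND_SCALE = {"age": 9.0, "bmi": 2.6, "alcohol": 18.0, "session_date": 400.0}


def generate_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Generate the synthetic cohort described by ``spec``.

    Returns exactly ``n_positive + n_negative`` patients; positives carry
    label 1 (PDAC-like), negatives label 0 (AIP-like).  Deterministic in
    ``spec`` (including its seed).
    """
    spec.validate()
    cp = spec.covariate_params
    records: list[PatientRecord] = []
    labels = [1] * spec.n_positive + [0] * spec.n_negative
    for idx, label in enumerate(labels):
        pid = f"P{idx:03d}"
        rng = derive_rng(spec.seed, "patient", pid)

        z = rng.normal(loc=spec.effect_size * (label - 0.5), scale=1.0)
        lesion_shift = -(_LESION_BASE + _LESION_SLOPE * z)
        speckle_gain = 0.25 * (1.0 + np.tanh(z)) / 2.0
        separation = z * (2 * label - 1)
        diagnosability = float(expit(1.2 * separation))

        age = float(np.clip(rng.normal(cp.age_mean, cp.age_sd), *cp.age_range))
        bmi = float(np.clip(rng.normal(cp.bmi_mean, cp.bmi_sd), *cp.bmi_range))
        cat = rng.choice(3, p=cp.alcohol_probs)
        if cat == 0:
            alcohol = float(rng.uniform(0.0, 20.0))
        elif cat == 1:
            alcohol = float(rng.uniform(20.0, 60.0))
        else:
            alcohol = float(rng.uniform(60.0, cp.alcohol_heavy_max))
        date = int(rng.integers(cp.date_start, cp.date_end + 1))

        if spec.confound_factor is not None and spec.confound_strength != 0.0:
            bump = spec.confound_strength * (label - 0.5) * _CONFOUND_SCALE[spec.confound_factor]
            if spec.confound_factor == "age":
                age = float(np.clip(age + bump, *cp.age_range))
            elif spec.confound_factor == "bmi":
                bmi = float(np.clip(bmi + bump, *cp.bmi_range))
            elif spec.confound_factor == "alcohol":
                alcohol = float(np.clip(alcohol + bump, 0.0, cp.alcohol_heavy_max))
            else:
                date = int(np.clip(date + bump, cp.date_start, cp.date_end))

        base_center = rng.uniform(0.38, 0.58, size=2)
        base_axes = rng.uniform(0.12, 0.20, size=2)

        n_videos = int(rng.integers(spec.videos_per_patient[0], spec.videos_per_patient[1] + 1))
        videos = []
        for v in range(n_videos):
            vid = f"V{v:02d}"
            n_frames = int(rng.integers(spec.frames_per_video[0], spec.frames_per_video[1] + 1))
            center = np.clip(base_center + rng.normal(0, 0.02, size=2), 0.30, 0.66)
            axes = np.clip(base_axes * rng.uniform(0.9, 1.1, size=2), 0.10, 0.22)
            videos.append(
                Video(
                    patient_id=pid,
                    video_id=vid,
                    n_frames=n_frames,
                    height=spec.frame_height,
                    width=spec.frame_width,
                    seed=derive_seed(spec.seed, "frames", pid, vid),
                    lesion_center=(float(center[0]), float(center[1])),
                    lesion_axes=(float(axes[0]), float(axes[1])),
                    lesion_shift=float(lesion_shift),
                    lesion_speckle_gain=float(speckle_gain),
                )
            )

        records.append(
            PatientRecord(
                patient_id=pid,
                label=label,
                age_years=round(age, 1),
                bmi=round(bmi, 1),
                alcohol_g_per_day=round(alcohol, 1),
                session_date=date,
                texture_param=float(z),
                diagnosability=diagnosability,
                videos=videos,
            )
        )
    return records


def simulate_endoscopists(
    cohort: list[PatientRecord],
    n_experts: int = 4,
    n_novices: int = 3,
    skill: SkillParams = SkillParams(),
    seed: int = 0,
) -> EndoscopistPanel:
    """Simulate a rater panel and write per-patient EDA scores back.

    Each rater makes one binary call per patient, correct with probability
    ``skill(diagnosability)``; the patient's EDA score is the fraction of
    raters whose call matches the true label.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    if n_experts + n_novices == 0:
        raise ValueError("n_experts + n_novices must be >= 1")
    if skill.expert_slope < skill.novice_slope:
        raise ValueError("experts must be at least as skilled as novices")

    pids = [p.patient_id for p in cohort]
    labels = np.array([p.label for p in cohort])
    diag = np.array([p.diagnosability for p in cohort])

    rater_ids = [f"expert_{i}" for i in range(n_experts)] + [
        f"novice_{i}" for i in range(n_novices)
    ]
    rows = []
    for rid in rater_ids:
        rng = derive_rng(seed, "rater", rid)
        p_correct = skill.prob_correct(diag, expert=rid.startswith("expert"))
        correct = rng.random(len(cohort)) < p_correct
        rows.append(np.where(correct, labels, 1 - labels))
    diagnoses = pd.DataFrame(rows, index=rater_ids, columns=pids)
    eda = (diagnoses.to_numpy() == labels[None, :]).mean(axis=0)
    eda_score = pd.Series(eda, index=pids, name="eda_score")
    for rec in cohort:
        rec.eda_score = float(eda_score[rec.patient_id])
    return EndoscopistPanel(
        diagnoses=diagnoses,
        eda_score=eda_score,
        expert_ids=tuple(rater_ids[:n_experts]),
        novice_ids=tuple(rater_ids[n_experts:]),
    )


def cohort_metadata(cohort: list[PatientRecord], synthetic: bool = True) -> pd.DataFrame:
    """Patient-metadata table (one row per patient).

    ``diagnosability`` (latent ground truth) is included only in synthetic
    mode; real metadata has no such column.
    """
    rows = []
    for p in cohort:
        row = {
            "patient_id": p.patient_id,
            "label": p.label,
            "age_years": p.age_years,
            "bmi": p.bmi,
            "alcohol_g_per_day": p.alcohol_g_per_day,
            "alcohol_category": p.alcohol_category,
            "session_date": p.session_date,
            "eda_score": p.eda_score,
        }
        if synthetic:
            row["diagnosability"] = p.diagnosability
        rows.append(row)
    return pd.DataFrame(rows)


def default_crop_box(frame_height: int, frame_width: int) -> tuple[int, int, int, int]:
    """Interior crop box ``(top, left, height, width)`` that removes the
    synthetic corner marks, side margins, and bottom unreachable band."""
    top = int(np.ceil(TOP_MARGIN_FRAC * frame_height))
    left = int(np.ceil(SIDE_MARGIN_FRAC * frame_width))
    bottom = int(np.ceil(BOTTOM_BAND_FRAC * frame_height))
    height = frame_height - top - bottom
    width = frame_width - 2 * left
    return (top, left, height, width)


def write_cohort(cohort: list[PatientRecord], out_dir: str | Path, frames: bool = True) -> Path:
    """Write metadata.csv and (optionally) per-video PNG frame trees under
    ``patients/<patient_id>/videos/<video_id>/frame_<jjjj>.png``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_metadata(cohort).to_csv(out / "metadata.csv", index=False)
    if frames:
        for p in cohort:
            for v in p.videos:
                vdir = out / "patients" / p.patient_id / "videos" / v.video_id
                vdir.mkdir(parents=True, exist_ok=True)
                stack = v.frame_stack()
                for j in range(v.n_frames):
                    Image.fromarray(stack[j], mode="L").save(vdir / f"frame_{j:04d}.png")
    return out


def scaled_spec(**overrides) -> CohortSpec:
    """A desk-scale spec: same cohort structure (61 PDAC / 24 AIP, 1-3
    videos per patient) but short videos and small frames, so full
    cross-validation runs complete in seconds-to-minutes on one CPU."""
    params = dict(
        n_positive=61,
        n_negative=24,
        videos_per_patient=(1, 3),
        frames_per_video=(6, 12),
        frame_height=96,
        frame_width=96,
    )
    params.update(overrides)
    return CohortSpec(**params)
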