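"""Synthetic knee-OA cohort generation with known ground truth.

A one-dimensional latent osteoarthritis severity per knee (standard
normal) drives everything observable:

* image geometry and texture (joint-space narrowing, osteophyte bumps,
  subchondral sclerosis) via :mod:`kneestudy.render`;
* the 36 ordinal reader grades, each with its own signal strength
  (loading); zero-loading features are pure noise, emulating grades that
  carry no pain information;
* a persistent-pain propensity through a logistic link (with optional BMI
  and sex terms), observed three times with independent transient flips;
* a widespread-pain subgroup whose pain probability is a constant,
  independent of severity.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .grading import (
    DEFAULT_GRADE_QUANTILES,
    DEFAULT_LOADINGS,
    GRADE_COLUMNS,
    GRADE_FEATURES,
)
from .landmarks import PA, LandmarkSet, write_points
from .outcomes import PainRecord
from .render import MIN_IMAGE_SIZE, render_knee


@dataclass(frozen=True)
class DemoParams:
    """Demographic marginals (study-cohort defaults: age 62.3 (SD 8),
    BMI 30.7 (SD 5.9), 60% female)."""

    age_mean: float = 62.3
    age_sd: float = 8.0
    bmi_mean: float = 30.7
    bmi_sd: float = 5.9
    prop_female: float = 0.6


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int
    view: str = PA
    image_size: int = 192
    severity_grade_loadings: np.ndarray = field(
        default_factory=lambda: DEFAULT_LOADINGS.copy()
    )
    grade_noise_sd: float = 0.6
    pain_intercept: float = -0.85
    pain_slope: float = 2.5
    pain_bmi_coef: float = 0.55
    pain_sex_coef: float = 0.45
    transient_flip_prob: float = 0.15
    widespread_fraction: float = 0.5
    widespread_pain_prob: float = 0.45
    demo_params: DemoParams = field(default_factory=DemoParams)
    shape_jitter_scale: float = 1.0
    render_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "severity_grade_loadings",
            np.asarray(self.severity_grade_loadings, dtype=float),
        )
        self.validate()

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if self.view not in ("PA", "LATERAL"):
            raise ValueError(f"view must be PA or LATERAL, got {self.view!r}")
        if self.image_size < MIN_IMAGE_SIZE:
            raise ValueError(
                f"image_size must be >= {MIN_IMAGE_SIZE}, got {self.image_size}"
            )
        w = self.severity_grade_loadings
        if w.shape != (len(GRADE_FEATURES),):
            raise ValueError(
                f"severity_grade_loadings must have length {len(GRADE_FEATURES)}, "
                f"got shape {w.shape}"
            )
        if np.any((w < 0) | (w > 1)):
            raise ValueError("severity_grade_loadings entries must lie in [0, 1]")
        if self.grade_noise_sd < 0:
            raise ValueError(f"grade_noise_sd must be >= 0, got {self.grade_noise_sd}")
        if not 0 <= self.transient_flip_prob < 0.5:
            raise ValueError(
                f"transient_flip_prob must be in [0, 0.5), got {self.transient_flip_prob}"
            )
        for name in ("widespread_fraction", "widespread_pain_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0 <= self.demo_params.prop_female <= 1:
            raise ValueError(
                f"demo_params.prop_female must be in [0, 1], "
                f"got {self.demo_params.prop_female}"
            )
        for name in ("age_sd", "bmi_sd"):
            if getattr(self.demo_params, name) < 0:
                raise ValueError(f"demo_params.{name} must be >= 0")

    def with_(self, **kwargs) -> "CohortConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class LatentSubject:
    """Unobserved disease state plus demographics for one knee/subject."""

    severity: float
    persistent_pain: int
    widespread: int
    age: float
    bmi: float
    sex: int  # 1 = female, 0 = male


@dataclass
class SyntheticKnee:
    subject: LatentSubject
    grades: np.ndarray            # (36,) ints
    pain: PainRecord
    image: np.ndarray | None = None
    true_landmarks: LandmarkSet | None = None


def sample_latent(config: CohortConfig) -> list[LatentSubject]:
    """Draw the latent layer: severity, demographics, persistent pain.

    Non-widespread subjects get pain propensity
    ``logistic(intercept + slope*severity + bmi_coef*z_bmi + sex_coef*female)``;
    widespread subjects get the flat ``widespread_pain_prob``.
    """
    rng = np.random.default_rng(config.seed)
    return _sample_latent_with_rng(config, rng)


def _sample_latent_with_rng(
    config: CohortConfig, rng: np.random.Generator
) -> list[LatentSubject]:
    n = config.n_subjects
    d = config.demo_params
    severity = rng.standard_normal(n)
    widespread = (rng.random(n) < config.widespread_fraction).astype(int)
    age = d.age_mean + d.age_sd * rng.standard_normal(n)
    bmi = d.bmi_mean + d.bmi_sd * rng.standard_normal(n)
    sex = (rng.random(n) < d.prop_female).astype(int)
    z_bmi = (bmi - d.bmi_mean) / d.bmi_sd if d.bmi_sd > 0 else np.zeros(n)
    p = expit(
        config.pain_intercept
        + config.pain_slope * severity
        + config.pain_bmi_coef * z_bmi
        + config.pain_sex_coef * sex
    )
    p = np.where(widespread == 1, config.widespread_pain_prob, p)
    pain = (rng.random(n) < p).astype(int)
    return [
        LatentSubject(
            severity=float(severity[i]),
            persistent_pain=int(pain[i]),
            widespread=int(widespread[i]),
            age=float(age[i]),
            bmi=float(bmi[i]),
            sex=int(sex[i]),
        )
        for i in range(n)
    ]


from functools import lru_cache


@lru_cache(maxsize=4096)
def _grade_thresholds(loading: float, noise_sd: float, max_grade: int) -> np.ndarray:
    """Ordinal bin thresholds at fixed quantiles of the marginal latent.

    The per-feature latent is ``w*Z + eps`` with marginal SD
    ``sqrt(w^2 + noise_sd^2)``, so fixed marginal quantiles are closed-form
    normal quantiles.
    """
    q = np.array(DEFAULT_GRADE_QUANTILES[max_grade])
    sd = float(np.hypot(loading, noise_sd))
    if sd == 0:
        # degenerate: latent identically zero; all thresholds above it
        return np.full(len(q), np.inf)
    return sd * norm.ppf(q)


def severity_to_grades(
    subject: LatentSubject, config: CohortConfig, rng: np.random.Generator
) -> np.ndarray:
    """The 36 ordinal reader grades for one knee.

    Feature k with loading w_k bins ``w_k*severity + N(0, grade_noise_sd)``
    at fixed marginal quantiles; w_k = 0 gives a chance-level grade.
    """
    w = config.severity_grade_loadings
    noise = config.grade_noise_sd * rng.standard_normal(len(w))
    latent = w * subject.severity + noise
    grades = np.empty(len(w), dtype=int)
    for k, feat in enumerate(GRADE_FEATURES):
        thr = _grade_thresholds(float(w[k]), float(config.grade_noise_sd), feat.max_grade)
        grades[k] = int(np.searchsorted(thr, latent[k], side="left"))
    return grades


def severity_to_pain(
    subject: LatentSubject, config: CohortConfig, rng: np.random.Generator
) -> PainRecord:
    """Three binary pain reports: persistent pain with independent
    transient flips, plus the copied widespread flag."""
    flips = rng.random(3) < config.transient_flip_prob
    reports = [int(subject.persistent_pain) ^ int(f) for f in flips]
    return PainRecord(
        tscreen=reports[0],
        saq=reports[1],
        clinic=reports[2],
        widespread=subject.widespread,
    )


def generate_cohort(
    config: CohortConfig,
    out_dir: str | Path | None = None,
    render: bool = True,
) -> tuple[list[SyntheticKnee], pd.DataFrame]:
    """Generate the full cohort; optionally write images/points/CSV.

    Returns the knee list and the manifest table (one row per knee).
    Outputs are byte-identical for identical config+seed.
    """
    rng = np.random.default_rng(config.seed)
    subjects = _sample_latent_with_rng(config, rng)
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        (out_path / "images").mkdir(parents=True, exist_ok=True)
        (out_path / "points").mkdir(parents=True, exist_ok=True)

    knees: list[SyntheticKnee] = []
    rows: list[dict] = []
    for i, subj in enumerate(subjects):
        kid = f"knee_{i:05d}"
        grades = severity_to_grades(subj, config, rng)
        pain = severity_to_pain(subj, config, rng)
        knee = SyntheticKnee(subject=subj, grades=grades, pain=pain)
        image_rel = ""
        if render:
            img, lms = render_knee(
                subj.severity,
                config.view,
                config.image_size,
                rng,
                shape_jitter_scale=config.shape_jitter_scale,
                noise_sd=config.render_noise_sd,
            )
            knee.image = img
            knee.true_landmarks = lms
            if out_path is not None:
                image_rel = f"images/{kid}.png"
                iio.imwrite(
                    out_path / image_rel,
                    (np.round(img * 255)).astype(np.uint8),
                )
                write_points(out_path / "points" / f"{kid}.pts", lms)
        knees.append(knee)
        row = {
            "id": kid,
            "view": config.view,
            "image": image_rel,
            **{col: int(g) for col, g in zip(GRADE_COLUMNS, grades)},
            "tscreen": pain.tscreen,
            "saq": pain.saq,
            "clinic": pain.clinic,
            "widespread": pain.widespread,
            "age": round(subj.age, 6),
            "bmi": round(subj.bmi, 6),
            "sex": subj.sex,
            "severity": round(subj.severity, 6),
            "persistent_pain": subj.persistent_pain,
        }
        rows.append(row)
    manifest = pd.DataFrame(rows).set_index("id")
    if out_path is not None:
        manifest.to_csv(out_path / "cohort.csv", float_format="%.6f")
    return knees, manifest


def generate_cohort_table(config: CohortConfig) -> pd.DataFrame:
    """Tabular-only cohort (grades, pain, demographics) — no rendering."""
    _, manifest = generate_cohort(config, out_dir=None, render=False)
    return manifest
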