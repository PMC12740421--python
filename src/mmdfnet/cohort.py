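"""Synthetic multimodal COPD cohort generator.

Generates case/control cohorts whose group-conditional statistics match a
published sample-characteristics table for a COPD case/control study
(n = 358 cases, n = 200 controls by default): spirometry (FEV1/FVC %),
smoking prevalence and pack-years, PM2.5 exposure and exposure years, a
binary SERPINA1-variant susceptibility flag, age and sex.  Continuous
variables are truncated Gaussians (FEV1/FVC on (0, 100], exposures on
[0, inf)); binary traits are Bernoulli.  Disease stage for cases follows a
configurable mild/moderate/severe mix, and lung-like grayscale images are
rendered procedurally with stage-dependent lesion load so that every
downstream modality carries signal.

The defaults ARE the study conditions; experiments that need different
informativeness per modality build their own spec (see ``scenarios``).
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage, stats

__all__ = [
    "GroupParams", "CohortSpec", "PatientRecord", "SyntheticImageParams",
    "CohortSpecError", "generate_cohort", "render_image", "mask_environment",
    "cohort_to_dataframe", "write_cohort_csv", "read_cohort_csv",
    "render_cohort_images", "write_image_png", "read_image_png",
]

STAGES = ("mild", "moderate", "severe")


class CohortSpecError(ValueError):
    """Raised when a cohort specification field is invalid."""


@dataclass(frozen=True)
class GroupParams:
    """Distribution parameters for one study group (cases or controls)."""

    age_mean: float
    age_sd: float
    male_fraction: float
    smoking_prevalence: float
    smoking_years_mean: float
    smoking_years_sd: float
    fev1_fvc_mean: float
    fev1_fvc_sd: float
    pm25_mean: float
    pm25_sd: float
    exposure_years_mean: float
    exposure_years_sd: float
    gene_variant_prevalence: float

    def validate(self, group: str) -> None:
        for name in ("age_sd", "smoking_years_sd", "fev1_fvc_sd",
                     "pm25_sd", "exposure_years_sd"):
            if getattr(self, name) <= 0:
                raise CohortSpecError(f"{group}.{name} must be > 0")
        for name in ("male_fraction", "smoking_prevalence",
                     "gene_variant_prevalence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise CohortSpecError(f"{group}.{name} must be in [0, 1]")


#: Case-group parameters of the reference characteristics table.
COPD_GROUP = GroupParams(
    age_mean=65.3, age_sd=8.7, male_fraction=214 / 358,
    smoking_prevalence=0.788, smoking_years_mean=35.2, smoking_years_sd=18.5,
    fev1_fvc_mean=58.4, fev1_fvc_sd=6.2,
    pm25_mean=42.5, pm25_sd=11.3,
    exposure_years_mean=15.4, exposure_years_sd=5.2,
    gene_variant_prevalence=0.249,
)

#: Control-group parameters of the reference characteristics table.
CONTROL_GROUP = GroupParams(
    age_mean=63.1, age_sd=7.9, male_fraction=112 / 200,
    smoking_prevalence=0.225, smoking_years_mean=4.5, smoking_years_sd=2.1,
    fev1_fvc_mean=75.6, fev1_fvc_sd=4.8,
    pm25_mean=28.6, pm25_sd=8.7,
    exposure_years_mean=10.1, exposure_years_sd=4.8,
    gene_variant_prevalence=0.060,
)


@dataclass(frozen=True)
class CohortSpec:
    """Full cohort specification; defaults reproduce the reference table.

    ``stage_fev1_shift`` moves FEV1/FVC by stage; the shifts are re-centered
    against ``stage_mix`` at generation time so the case-group mean remains
    ``copd.fev1_fvc_mean``.  ``pm25_smoker_shift`` couples PM2.5 to smoking
    within each group, likewise centered so group means are preserved.
    """

    n_copd: int = 358
    n_control: int = 200
    copd: GroupParams = field(default_factory=lambda: COPD_GROUP)
    control: GroupParams = field(default_factory=lambda: CONTROL_GROUP)
    stage_mix: tuple[float, float, float] = (0.4, 0.4, 0.2)
    stage_fev1_shift: tuple[float, float, float] = (5.0, 0.0, -10.0)
    pm25_smoker_shift: float = 5.0
    env_missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_copd < 0:
            raise CohortSpecError("n_copd must be >= 0")
        if self.n_control < 0:
            raise CohortSpecError("n_control must be >= 0")
        self.copd.validate("copd")
        self.control.validate("control")
        if len(self.stage_mix) != 3 or any(p < 0 for p in self.stage_mix):
            raise CohortSpecError("stage_mix must be three non-negative weights")
        if abs(sum(self.stage_mix) - 1.0) > 1e-9:
            raise CohortSpecError("stage_mix must sum to 1")
        if not 0.0 <= self.env_missing_rate <= 1.0:
            raise CohortSpecError("env_missing_rate must be in [0, 1]")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CohortSpec":
        raw = json.loads(text)
        for key in ("copd", "control"):
            if key in raw:
                raw[key] = GroupParams(**raw[key])
        for key in ("stage_mix", "stage_fev1_shift"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class PatientRecord:
    """One subject: label, stage, clinical and environmental variables.

    ``pm25`` and ``exposure_years`` are None when the environmental modality
    is missing (``env_missing`` is then True).  ``lesion_scale`` is a
    rendering hook multiplying the lesion intensity for this subject; the
    default 1.0 leaves the stage-driven lesion model untouched.
    """

    id: str
    label: str                       # "COPD" | "control"
    stage: str                       # "mild" | "moderate" | "severe" | "none"
    age: float
    sex: str                         # "male" | "female"
    smoker: bool
    smoking_years: float
    fev1_fvc: float
    pm25: float | None
    exposure_years: float | None
    gene_variant: bool
    image_path: str | None = None
    env_missing: bool = False
    lesion_scale: float = 1.0

    def validate(self) -> None:
        if self.label not in ("COPD", "control"):
            raise ValueError(f"invalid label {self.label!r}")
        if not 0.0 < self.fev1_fvc <= 100.0:
            raise ValueError("fev1_fvc must be in (0, 100]")
        if self.pm25 is not None and self.pm25 < 0:
            raise ValueError("pm25 must be >= 0 when present")
        if (self.stage == "none") != (self.label == "control"):
            raise ValueError("stage must be 'none' iff label is 'control'")


@dataclass(frozen=True)
class SyntheticImageParams:
    """Rendering parameters for procedurally generated lung-like rasters.

    Lesion count and intensity are per-stage lookup tables; intensity must be
    monotone non-decreasing in stage severity (none <= mild <= moderate <=
    severe).  Intensities are fractions of the full dynamic range.
    """

    height: int = 64
    width: int = 64
    base_texture_scale: float = 3.0
    background: float = 0.35
    noise_sd: float = 0.03
    lesion_count: dict = field(default_factory=lambda: {
        "none": 0, "mild": 2, "moderate": 4, "severe": 7})
    lesion_intensity: dict = field(default_factory=lambda: {
        "none": 0.0, "mild": 0.18, "moderate": 0.30, "severe": 0.45})
    lesion_radius: float = 3.0
    #: amplitude of emphysema-like speckle texture per point of FEV1/FVC
    #: deficit below 75% (continuous severity signal in the image; 0 = off)
    fev1_texture_gain: float = 0.0

    def validate(self) -> None:
        if self.height < 16 or self.width < 16:
            raise CohortSpecError("image height and width must be >= 16")
        order = ("none", "mild", "moderate", "severe")
        vals = [self.lesion_intensity[s] for s in order]
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise CohortSpecError(
                "lesion_intensity must be monotone non-decreasing in severity")
        if any(self.lesion_count[s] < 0 for s in order):
            raise CohortSpecError("lesion_count values must be >= 0")
        if self.noise_sd < 0:
            raise CohortSpecError("noise_sd must be >= 0")


def _trunc_normal(rng: np.random.Generator, mean, sd, lo, hi, size) -> np.ndarray:
    mean = np.broadcast_to(np.asarray(mean, dtype=float), (size,))
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def _sample_group(rng: np.random.Generator, params: GroupParams, n: int,
                  label: str, spec: CohortSpec, id_offset: int
                  ) -> list[PatientRecord]:
    if n == 0:
        return []
    if label == "COPD":
        stages = rng.choice(STAGES, size=n, p=np.asarray(spec.stage_mix))
        shifts = np.asarray(spec.stage_fev1_shift, dtype=float)
        shifts = shifts - np.dot(spec.stage_mix, shifts)  # preserve group mean
        stage_shift = shifts[[STAGES.index(s) for s in stages]]
    else:
        stages = np.array(["none"] * n)
        stage_shift = np.zeros(n)

    age = rng.normal(params.age_mean, params.age_sd, size=n)
    sex = np.where(rng.random(n) < params.male_fraction, "male", "female")
    smoker = rng.random(n) < params.smoking_prevalence
    smoking_years = np.where(
        smoker,
        _trunc_normal(rng, params.smoking_years_mean, params.smoking_years_sd,
                      0.0, np.inf, n),
        0.0)
    fev1 = _trunc_normal(rng, params.fev1_fvc_mean + stage_shift,
                         params.fev1_fvc_sd, 0.0, 100.0, n)
    pm_loc = params.pm25_mean + spec.pm25_smoker_shift * (
        smoker.astype(float) - params.smoking_prevalence)
    pm25 = _trunc_normal(rng, pm_loc, params.pm25_sd, 0.0, np.inf, n)
    exp_years = _trunc_normal(rng, params.exposure_years_mean,
                              params.exposure_years_sd, 0.0, np.inf, n)
    gene = rng.random(n) < params.gene_variant_prevalence

    records = []
    for i in range(n):
        rec = PatientRecord(
            id=f"P{id_offset + i:04d}", label=label, stage=str(stages[i]),
            age=float(age[i]), sex=str(sex[i]), smoker=bool(smoker[i]),
            smoking_years=float(smoking_years[i]), fev1_fvc=float(fev1[i]),
            pm25=float(pm25[i]), exposure_years=float(exp_years[i]),
            gene_variant=bool(gene[i]))
        rec.validate()
        records.append(rec)
    return records


def generate_cohort(spec: CohortSpec, out_dir: str | Path | None = None
                    ) -> list[PatientRecord]:
    """Sample a cohort from ``spec``; deterministic given ``spec.seed``.

    When ``out_dir`` is given the cohort table is written there as
    ``cohort.csv`` (UTF-8, missing values as empty fields).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    records = _sample_group(rng, spec.copd, spec.n_copd, "COPD", spec, 0)
    records += _sample_group(rng, spec.control, spec.n_control, "control",
                             spec, spec.n_copd)
    if spec.env_missing_rate > 0:
        records = mask_environment(records, spec.env_missing_rate,
                                   seed=spec.seed + 1)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_cohort_csv(records, out_dir / "cohort.csv")
    return records


def mask_environment(records: list[PatientRecord], rate: float,
                     seed: int) -> list[PatientRecord]:
    """Return a copy with exactly round(rate*n) records' environment masked.

    Masking is completely at random; observed records are returned unchanged
    (same field values, fresh objects).
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    n = len(records)
    n_mask = int(round(rate * n))
    rng = np.random.default_rng(seed)
    mask_idx = set(rng.choice(n, size=n_mask, replace=False).tolist()) if n else set()
    out = []
    for i, rec in enumerate(records):
        rec = dataclasses.replace(rec)
        if i in mask_idx:
            rec.pm25 = None
            rec.exposure_years = None
            rec.env_missing = True
        out.append(rec)
    return out


# -- image rendering ------------------------------------------------------

def _record_rng(seed: int, record_id: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(record_id.encode())])


def render_image(record: PatientRecord,
                 params: SyntheticImageParams | None = None,
                 seed: int = 0) -> np.ndarray:
    """Render a 16-bit grayscale lung-like raster for one record.

    The scene is a bright thorax background with two darker elliptical lung
    fields, smoothed multiplicative texture, additive Gaussian noise, and
    ``lesion_count[stage]`` bright Gaussian blobs of amplitude
    ``lesion_intensity[stage] * record.lesion_scale`` inside the lung fields.
    Deterministic given (record.id, seed).
    """
    params = params or SyntheticImageParams()
    params.validate()
    h, w = params.height, params.width
    rng = _record_rng(seed, record.id)

    yy, xx = np.mgrid[0:h, 0:w]
    img = np.full((h, w), params.background + 0.25, dtype=np.float64)
    for cx in (0.32, 0.68):  # two lung fields, darker than the mediastinum
        ell = (((xx - cx * w) / (0.18 * w)) ** 2
               + ((yy - 0.5 * h) / (0.36 * h)) ** 2) <= 1.0
        img[ell] = params.background

    texture = rng.normal(0.0, 1.0, size=(h, w))
    texture = ndimage.gaussian_filter(texture, params.base_texture_scale)
    tsd = texture.std()
    if tsd > 0:
        img = img * (1.0 + 0.12 * texture / tsd)

    stage = record.stage
    amp = params.lesion_intensity[stage] * record.lesion_scale
    for _ in range(params.lesion_count[stage]):
        side = rng.choice([0.32, 0.68])
        cx = (side + rng.normal(0, 0.06)) * w
        cy = (0.5 + rng.normal(0, 0.18)) * h
        r = params.lesion_radius * (0.7 + 0.6 * rng.random())
        blob = np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * r * r)))
        img += amp * blob

    if params.fev1_texture_gain > 0:
        deficit = max(0.0, 75.0 - record.fev1_fvc) / 25.0
        speckle = rng.normal(0.0, 1.0, size=(h, w))
        speckle = ndimage.gaussian_filter(speckle, 0.8)
        ssd = speckle.std()
        if ssd > 0:
            img += params.fev1_texture_gain * deficit * speckle / ssd

    img += rng.normal(0.0, params.noise_sd, size=(h, w))
    img = np.clip(img, 0.0, 1.0)
    return np.round(img * 65535.0).astype(np.uint16)


def render_cohort_images(records: list[PatientRecord],
                         params: SyntheticImageParams | None = None,
                         seed: int = 0,
                         out_dir: str | Path | None = None) -> np.ndarray:
    """Render all records; returns array (n, H, W) uint16.

    With ``out_dir``, each image is also written as ``<id>.png`` (16-bit
    grayscale) and ``record.image_path`` is set.
    """
    params = params or SyntheticImageParams()
    imgs = np.empty((len(records), params.height, params.width), dtype=np.uint16)
    for i, rec in enumerate(records):
        imgs[i] = render_image(rec, params, seed=seed)
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            path = out_dir / f"{rec.id}.png"
            write_image_png(imgs[i], path)
            rec.image_path = str(path)
    return imgs


def write_image_png(img: np.ndarray, path: str | Path) -> None:
    Image.fromarray(img.astype(np.uint16), mode="I;16").save(str(path))


def read_image_png(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(str(path)), dtype=np.uint16)


# -- cohort table I/O -----------------------------------------------------

_COLUMNS = ["id", "label", "stage", "age", "sex", "smoker", "smoking_years",
            "fev1_fvc", "pm25", "exposure_years", "gene_variant",
            "image_path", "env_missing", "lesion_scale"]


def cohort_to_dataframe(records: list[PatientRecord]) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in records]
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_cohort_csv(records: list[PatientRecord], path: str | Path) -> None:
    # shortest-roundtrip repr keeps double-precision values exact in text
    cohort_to_dataframe(records).to_csv(path, index=False, encoding="utf-8",
                                        float_format=lambda v: repr(float(v)))


def read_cohort_csv(path: str | Path) -> list[PatientRecord]:
    df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    records = []
    for row in df.itertuples(index=False):
        records.append(PatientRecord(
            id=str(row.id), label=str(row.label), stage=str(row.stage),
            age=float(row.age), sex=str(row.sex), smoker=bool(row.smoker),
            smoking_years=float(row.smoking_years), fev1_fvc=float(row.fev1_fvc),
            pm25=None if pd.isna(row.pm25) else float(row.pm25),
            exposure_years=(None if pd.isna(row.exposure_years)
                            else float(row.exposure_years)),
            gene_variant=bool(row.gene_variant),
            image_path=None if pd.isna(row.image_path) else str(row.image_path),
            env_missing=bool(row.env_missing),
            lesion_scale=float(row.lesion_scale)))
    return records
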