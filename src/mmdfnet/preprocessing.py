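"""Deterministic image and tabular preprocessing.

* Discrete histogram equalization: the monotone gray-level remapping
  q = round((qk - q0) * (cum(p) - H(p)/2) / (M*N)) + q0, i.e. the midpoint
  discretization of the cumulative-histogram brightness transform.  The
  midpoint convention makes an exactly uniform histogram a fixed point of
  the mapping (identity ramp) while remaining monotone non-decreasing.
* Image standardization: (I - mu) / sigma with scalar training-set moments.
* Tabular encoding: Z-score for continuous variables, one-hot for
  categorical variables, with the schema (training moments and level lists)
  frozen as a JSON artifact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["histogram_equalize", "standardize_image", "TabularSchema",
           "encode_tabular", "histogram_mapping"]


def histogram_mapping(image: np.ndarray, levels: int = 256,
                      out_range: tuple[int, int] | None = None) -> np.ndarray:
    """Return the per-level equalization lookup table T(p) for ``image``.

    ``levels`` is the number of input gray levels (pixel values must lie in
    [0, levels)).  The output range defaults to the same [0, levels - 1].
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("image must be non-empty")
    if levels < 2:
        raise ValueError("levels must be >= 2")
    if image.min() < 0 or image.max() >= levels:
        raise ValueError("pixel values must lie in [0, levels)")
    q0, qk = out_range if out_range is not None else (0, levels - 1)
    counts = np.bincount(image.ravel().astype(np.int64), minlength=levels)
    cum = np.cumsum(counts)
    mid = cum - counts / 2.0
    mapping = np.floor((qk - q0) * mid / image.size + 0.5) + q0
    return mapping.astype(np.int64)


def histogram_equalize(image: np.ndarray, levels: int = 256,
                       out_range: tuple[int, int] | None = None) -> np.ndarray:
    """Equalize a grayscale integer raster over ``levels`` gray levels.

    The mapping is monotone non-decreasing, so pixel ordering is preserved;
    the output cumulative histogram tracks the ideal uniform ramp to within
    the mass of a single input level (discrete ties cannot be split).
    """
    image = np.asarray(image)
    mapping = histogram_mapping(image, levels, out_range)
    out = mapping[image.astype(np.int64)]
    return out.astype(image.dtype if image.dtype.kind in "ui" else np.int64)


def standardize_image(image: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """(image - mu) / sigma with scalar training-set moments; sigma > 0."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return (np.asarray(image, dtype=np.float64) - mu) / sigma


CONTINUOUS_VARS = ("age", "smoking_years", "fev1_fvc")
CATEGORICAL_VARS = {"sex": ("female", "male"),
                    "smoker": ("False", "True"),
                    "gene_variant": ("False", "True")}
ENV_VARS = ("pm25", "exposure_years")


@dataclass
class TabularSchema:
    """Frozen tabular encoding: per-variable kind, training moments, levels.

    Continuous variables are Z-scored with the training split's mean and sd;
    categorical variables are one-hot over the (lexicographically sorted)
    level list seen at fit time.  Unseen levels at transform time raise.
    """

    continuous: dict = field(default_factory=dict)   # name -> (mu, sigma)
    categorical: dict = field(default_factory=dict)  # name -> [levels]

    @classmethod
    def fit(cls, df: pd.DataFrame,
            continuous: tuple[str, ...] = CONTINUOUS_VARS,
            categorical: dict | None = None) -> "TabularSchema":
        categorical = dict(categorical or CATEGORICAL_VARS)
        schema = cls()
        for name in continuous:
            col = df[name].astype(float)
            mu = float(col.mean())
            sigma = float(col.std(ddof=0))
            if sigma <= 0:
                raise ValueError(f"continuous variable {name!r} has sd <= 0")
            schema.continuous[name] = (mu, sigma)
        for name, fixed_levels in categorical.items():
            if fixed_levels is None:
                levels = sorted({str(v) for v in df[name]})
            else:
                levels = sorted(str(v) for v in fixed_levels)
            if not levels or len(set(levels)) != len(levels):
                raise ValueError(f"invalid level list for {name!r}")
            schema.categorical[name] = levels
        return schema

    @property
    def width(self) -> int:
        return len(self.continuous) + sum(len(v) for v in self.categorical.values())

    @property
    def feature_names(self) -> list[str]:
        names = [f"{k}_z" for k in self.continuous]
        for name, levels in self.categorical.items():
            names += [f"{name}={lv}" for lv in levels]
        return names

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        cols = []
        for name, (mu, sigma) in self.continuous.items():
            cols.append((df[name].astype(float).to_numpy() - mu) / sigma)
        for name, levels in self.categorical.items():
            values = df[name].astype(str).to_numpy()
            unseen = set(values) - set(levels)
            if unseen:
                raise ValueError(
                    f"unseen level(s) {sorted(unseen)} for variable {name!r}")
            for lv in levels:
                cols.append((values == lv).astype(np.float64))
        return np.column_stack(cols) if cols else np.empty((len(df), 0))

    def to_json(self) -> str:
        return json.dumps({"continuous": self.continuous,
                           "categorical": self.categorical}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TabularSchema":
        raw = json.loads(text)
        schema = cls()
        schema.continuous = {k: (float(v[0]), float(v[1]))
                             for k, v in raw["continuous"].items()}
        schema.categorical = {k: list(v) for k, v in raw["categorical"].items()}
        return schema

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "TabularSchema":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


def encode_tabular(df: pd.DataFrame, schema: TabularSchema) -> np.ndarray:
    """Encode records as a numeric matrix under a fitted schema."""
    return schema.transform(df)
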