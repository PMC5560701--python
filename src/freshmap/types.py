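"""Core raster and sample containers shared across the pipeline.

All rasters are plain numpy arrays in row-major (row, col) order with an
affine geotransform ``(x0, dx, y0, dy)``: the centre of pixel (r, c) sits at
``(x0 + (c + 0.5) * dx, y0 + (r + 0.5) * dy)``. The synthetic scenes use an
identity transform (one map unit per pixel), so window sizes and stratum
buffers are expressed directly in pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Spectral band order used everywhere (Landsat-like subset).
BANDS: tuple[str, ...] = ("red", "nir", "swir1", "swir2")

#: The 12 spectral-temporal feature names, grouped by temporal statistic:
#: per-band median, mean over the lowest-NDVI decile, mean over the
#: highest-NDVI decile.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{stat}.{band}" for stat in ("med", "minNDVI", "maxNDVI") for band in BANDS
)

GeoTransform = tuple[float, float, float, float]

IDENTITY_TRANSFORM: GeoTransform = (0.0, 1.0, 0.0, 1.0)


def pixel_centers(shape: tuple[int, int], transform: GeoTransform = IDENTITY_TRANSFORM):
    """Map coordinates of every pixel centre as two (H, W) arrays (x, y)."""
    x0, dx, y0, dy = transform
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    return x0 + (cols + 0.5) * dx, y0 + (rows + 0.5) * dy


@dataclass
class ObservationStack:
    """Multi-date 4-band surface reflectance with a per-observation mask.

    reflectance : float array (H, W, T, 4), bands ordered as :data:`BANDS`,
        values in [0, 1] where valid.
    valid : bool array (H, W, T); False marks clouded / flagged observations.
    dates : strictly increasing observation times (day offsets).
    """

    reflectance: np.ndarray
    valid: np.ndarray
    dates: np.ndarray
    transform: GeoTransform = IDENTITY_TRANSFORM
    crs: str = "pixel"

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.dates = np.asarray(self.dates)
        if self.reflectance.ndim != 4 or self.reflectance.shape[3] != len(BANDS):
            raise ValueError("reflectance must be (H, W, T, 4)")
        if self.valid.shape != self.reflectance.shape[:3]:
            raise ValueError("valid mask must be (H, W, T)")
        if len(self.dates) != self.reflectance.shape[2]:
            raise ValueError("dates length must match the time axis")
        if len(self.dates) > 1 and not np.all(np.diff(self.dates) > 0):
            raise ValueError("dates must be strictly increasing")
        if not np.all(np.isfinite(self.reflectance[self.valid])):
            raise ValueError("reflectance must be finite where valid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.reflectance.shape[:2]

    @property
    def n_dates(self) -> int:
        return self.reflectance.shape[2]


@dataclass
class LabelImage:
    """Categorical raster with a legend and an explicit nodata code."""

    labels: np.ndarray
    legend: dict[int, str]
    nodata: int = 0
    transform: GeoTransform = IDENTITY_TRANSFORM

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D raster")
        present = set(np.unique(self.labels).tolist()) - {self.nodata}
        unknown = present - set(self.legend)
        if unknown:
            raise ValueError(f"labels outside legend: {sorted(unknown)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def copy_with(self, labels: np.ndarray) -> "LabelImage":
        return LabelImage(labels, dict(self.legend), self.nodata, self.transform)

    def mask(self) -> np.ndarray:
        """Boolean mask of pixels carrying a real label."""
        return self.labels != self.nodata


@dataclass
class FeatureImage:
    """12-band spectral-temporal composite (see :data:`FEATURE_NAMES`)."""

    data: np.ndarray  # (H, W, 12)
    nodata_mask: np.ndarray  # (H, W) bool, True where the pixel is nodata
    n_valid: np.ndarray  # (H, W) int, clear observations per pixel
    transform: GeoTransform = IDENTITY_TRANSFORM
    band_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.data.ndim != 3 or self.data.shape[2] != len(FEATURE_NAMES):
            raise ValueError("feature image must have exactly 12 bands")
        if self.nodata_mask.shape != self.data.shape[:2]:
            raise ValueError("nodata mask shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    def vectors(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return self.data[rows, cols, :]


@dataclass
class MembershipImage:
    """Per-pixel class-membership vectors (random-forest vote fractions)."""

    probs: np.ndarray  # (H, W, n_classes)
    classes: tuple[int, ...]
    nodata_mask: np.ndarray  # (H, W) bool
    transform: GeoTransform = IDENTITY_TRANSFORM

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.probs.shape[2] != len(self.classes):
            raise ValueError("class axis must match the class list")
        ok = ~self.nodata_mask
        if ok.any():
            sums = self.probs[ok].sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("membership vectors must sum to 1")
            if (self.probs[ok] < -1e-12).any():
                raise ValueError("membership probabilities must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.probs.shape[:2]


@dataclass
class ConfidenceImage:
    """Per-pixel ERP confidence in [1/n, 1]."""

    erp: np.ndarray
    nodata_mask: np.ndarray
    transform: GeoTransform = IDENTITY_TRANSFORM

    def __post_init__(self) -> None:
        self.erp = np.asarray(self.erp, dtype=float)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.erp.shape != self.nodata_mask.shape:
            raise ValueError("confidence/nodata shape mismatch")


@dataclass
class TrainingSet:
    """Sampled training pixels: 12-feature vectors plus bookkeeping columns."""

    X: np.ndarray  # (n, 12)
    y: np.ndarray  # (n,) class ids
    stratum: np.ndarray  # (n,) stratum ids
    rows: np.ndarray
    cols: np.ndarray
    reliable: np.ndarray = field(default=None)  # type: ignore[assignment]
    post_ci_filter: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.y)
        if self.reliable is None:
            self.reliable = np.ones(n, dtype=bool)
        if self.post_ci_filter is None:
            self.post_ci_filter = np.ones(n, dtype=bool)
        if self.X.shape != (n, len(FEATURE_NAMES)):
            raise ValueError("X must be (n, 12)")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature vectors must be free of nodata")
        key = self.rows.astype(np.int64) * (self.cols.max(initial=0) + 1) + self.cols
        if len(np.unique(key)) != n:
            raise ValueError("duplicate pixels in training set")

    def __len__(self) -> int:
        return len(self.y)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.X, columns=list(FEATURE_NAMES))
        frame.insert(0, "col", self.cols)
        frame.insert(0, "row", self.rows)
        frame.insert(0, "stratum", self.stratum)
        frame.insert(0, "class", self.y)
        frame["reliable"] = self.reliable
        frame["post_ci_filter"] = self.post_ci_filter
        return frame

    @classmethod
    def concat(cls, parts: Sequence["TrainingSet"]) -> "TrainingSet":
        parts = [p for p in parts if len(p)]
        if not parts:
            raise ValueError("no training rows to concatenate")
        return cls(
            X=np.vstack([p.X for p in parts]),
            y=np.concatenate([p.y for p in parts]),
            stratum=np.concatenate([p.stratum for p in parts]),
            rows=np.concatenate([p.rows for p in parts]),
            cols=np.concatenate([p.cols for p in parts]),
            reliable=np.concatenate([p.reliable for p in parts]),
            post_ci_filter=np.concatenate([p.post_ci_filter for p in parts]),
        )
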