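"""Seeded synthetic agricultural scenes.

The generator emulates the inputs of the mapping scheme: a multi-date 4-band
surface-reflectance stack with cloud gaps, a true land cover map organised
into rectangular fields, stratum polygons, and a degraded "outdated" copy of
the truth carrying the two error types an old map accumulates — uniform
label flips (classification error) and whole fields relabeled (land cover
change).

Class spectra are driven by a seasonal NDVI trajectory (sinusoid with a
class-specific baseline, amplitude and phase). Red and NIR are back-computed
from the trajectory so that the noise-free NDVI of a pixel matches its
class curve exactly; croplands get a high-amplitude curve with a bare-soil
minimum (bright red/SWIR at season start), grassland a moderate curve, water
low NIR throughout. SWIR bands follow class-specific brightness curves that
dip with green-up (canopy moisture) for vegetated classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import box

from .types import BANDS, IDENTITY_TRANSFORM, LabelImage, ObservationStack

# Working legend: a simplified nine-class land cover nomenclature.
DEFAULT_LEGEND: dict[int, str] = {
    1: "cropland",
    2: "irrigated cropland",
    3: "grassland",
    4: "shrubland",
    5: "forest",
    6: "water",
    7: "built-up",
    8: "bare",
    9: "wetland",
}

CROPLAND_CLASSES: frozenset[int] = frozenset({1, 2})


@dataclass
class ClassProfile:
    """Seasonal spectral behaviour of one land cover class.

    NDVI follows ``base + amplitude * sin(2*pi*(t - phase))`` over a unit
    season t in [0, 1); ``brightness`` scales red+NIR total irradiance and
    the two SWIR curves interpolate between ``swir_hi`` (senescent/bare) and
    ``swir_lo`` (peak canopy moisture) as NDVI moves from its minimum to its
    maximum.
    """

    ndvi_base: float
    ndvi_amplitude: float
    phase: float
    brightness: float = 0.45
    swir_hi: tuple[float, float] = (0.30, 0.22)
    swir_lo: tuple[float, float] = (0.14, 0.08)

    def curves(self, season: np.ndarray) -> np.ndarray:
        """Noise-free (T, 4) reflectance curve for observation times in [0,1)."""
        ndvi = self.ndvi_base + self.ndvi_amplitude * np.sin(
            2.0 * np.pi * (season - self.phase)
        )
        ndvi = np.clip(ndvi, -0.95, 0.95)
        total = self.brightness  # red + nir
        nir = total * (1.0 + ndvi) / 2.0
        red = total * (1.0 - ndvi) / 2.0
        lo, hi = ndvi.min(), ndvi.max()
        w = (ndvi - lo) / (hi - lo) if hi > lo else np.zeros_like(ndvi)
        swir1 = self.swir_hi[0] + w * (self.swir_lo[0] - self.swir_hi[0])
        swir2 = self.swir_hi[1] + w * (self.swir_lo[1] - self.swir_hi[1])
        out = np.stack([red, nir, swir1, swir2], axis=-1)
        return np.clip(out, 0.0, 1.0)


def default_class_profiles() -> dict[int, ClassProfile]:
    """Profiles for the nine-class legend.

    Cropland has the largest seasonal NDVI swing (bare soil at planting,
    dense canopy at peak); irrigated cropland peaks higher and slightly
    later; grassland is moderate; water stays at strongly negative NDVI with
    dark SWIR; built-up and bare are flat and bright.
    """
    return {
        1: ClassProfile(0.45, 0.40, 0.00, 0.50, (0.34, 0.26), (0.16, 0.09)),
        2: ClassProfile(0.55, 0.38, 0.12, 0.46, (0.28, 0.20), (0.10, 0.05)),
        3: ClassProfile(0.40, 0.18, 0.05, 0.40, (0.26, 0.18), (0.18, 0.11)),
        4: ClassProfile(0.30, 0.10, 0.10, 0.38, (0.28, 0.21), (0.21, 0.14)),
        5: ClassProfile(0.75, 0.08, 0.00, 0.42, (0.18, 0.10), (0.12, 0.06)),
        6: ClassProfile(-0.40, 0.05, 0.00, 0.12, (0.04, 0.03), (0.02, 0.01)),
        7: ClassProfile(0.12, 0.03, 0.00, 0.52, (0.30, 0.27), (0.27, 0.24)),
        8: ClassProfile(0.08, 0.02, 0.00, 0.60, (0.42, 0.36), (0.38, 0.32)),
        9: ClassProfile(0.35, 0.22, 0.30, 0.30, (0.14, 0.08), (0.07, 0.04)),
    }


# Landscape composition: relative abundance of each class when assigning
# fields. Cropland-heavy to mimic an agricultural study area.
DEFAULT_CLASS_WEIGHTS: dict[int, float] = {
    1: 0.28, 2: 0.08, 3: 0.24, 4: 0.12, 5: 0.08,
    6: 0.04, 7: 0.05, 8: 0.07, 9: 0.04,
}


@dataclass
class SceneConfig:
    width: int = 128
    height: int = 128
    n_dates: int = 24
    class_profiles: dict[int, ClassProfile] = field(default_factory=default_class_profiles)
    class_weights: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS))
    legend: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LEGEND))
    noise_sd: float = 0.02
    cloud_fraction: float = 0.25
    field_size_range: tuple[int, int] = (8, 24)
    stratum_count: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.width < 32 or self.height < 32:
            raise ValueError("scene extent must be at least 32x32 pixels")
        if self.n_dates < 10:
            raise ValueError("need at least 10 observation dates")
        if not self.class_profiles:
            raise ValueError("at least one class profile is required")
        if not (0.0 <= self.cloud_fraction < 1.0):
            raise ValueError("cloud_fraction must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        lo, hi = self.field_size_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid field_size_range")
        if self.stratum_count < 1:
            raise ValueError("stratum_count must be >= 1")
        for cid, profile in self.class_profiles.items():
            curve = profile.curves(np.linspace(0, 1, 8, endpoint=False))
            if curve.min() < 0 or curve.max() > 1:
                raise ValueError(f"profile of class {cid} leaves [0, 1]")


@dataclass
class Field:
    """One rectangular field with its class label, in pixel coordinates."""

    row0: int
    row1: int
    col0: int
    col1: int
    class_id: int

    @property
    def polygon(self):
        return box(self.col0, self.row0, self.col1, self.row1)


@dataclass
class SceneBundle:
    stack: ObservationStack
    truth: LabelImage
    fields: list[Field]
    strata: list  # shapely polygons, index = stratum id

    @property
    def shape(self) -> tuple[int, int]:
        return self.truth.shape


def _jittered_edges(extent: int, size_range: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Cut positions along one axis: random cell widths within size_range."""
    lo, hi = size_range
    edges = [0]
    while edges[-1] < extent:
        edges.append(edges[-1] + int(rng.integers(lo, hi + 1)))
    edges[-1] = extent
    # collapse a possible sliver shorter than lo at the end
    if len(edges) > 2 and edges[-1] - edges[-2] < lo:
        del edges[-2]
    return np.asarray(edges)


def _tile_fields(config: SceneConfig, rng: np.random.Generator) -> list[Field]:
    classes = sorted(config.class_profiles)
    weights = np.array([config.class_weights.get(c, 1.0) for c in classes], dtype=float)
    weights /= weights.sum()
    row_edges = _jittered_edges(config.height, config.field_size_range, rng)
    fields: list[Field] = []
    for r0, r1 in zip(row_edges[:-1], row_edges[1:]):
        col_edges = _jittered_edges(config.width, config.field_size_range, rng)
        for c0, c1 in zip(col_edges[:-1], col_edges[1:]):
            cid = int(rng.choice(classes, p=weights))
            fields.append(Field(int(r0), int(r1), int(c0), int(c1), cid))
    return fields


def make_strata(config: SceneConfig) -> list:
    """Vertical bands of equal width across the scene, as shapely boxes."""
    edges = np.linspace(0, config.width, config.stratum_count + 1)
    return [box(edges[i], 0, edges[i + 1], config.height) for i in range(config.stratum_count)]


def generate_scene(config: SceneConfig) -> SceneBundle:
    """Build a full synthetic scene; identical (config, seed) pairs are
    bit-identical."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    fields = _tile_fields(config, rng)
    labels = np.zeros((config.height, config.width), dtype=np.int16)
    for f in fields:
        labels[f.row0 : f.row1, f.col0 : f.col1] = f.class_id
    truth = LabelImage(labels, dict(config.legend), nodata=0)

    season = np.linspace(0.0, 1.0, config.n_dates, endpoint=False)
    dates = np.round(season * 365.0).astype(int)
    curves = {cid: p.curves(season) for cid, p in config.class_profiles.items()}

    refl = np.empty((config.height, config.width, config.n_dates, len(BANDS)))
    for cid, curve in curves.items():
        refl[labels == cid] = curve
    if config.noise_sd > 0:
        refl = refl + rng.normal(0.0, config.noise_sd, refl.shape)
        refl = np.clip(refl, 0.0, 1.0)

    valid = rng.random((config.height, config.width, config.n_dates)) >= config.cloud_fraction
    stack = ObservationStack(refl, valid, dates, IDENTITY_TRANSFORM)
    return SceneBundle(stack=stack, truth=truth, fields=fields, strata=make_strata(config))


def make_outdated_map(
    truth: LabelImage,
    flip_rate: float,
    change_fraction: float,
    seed: int,
    fields: list[Field] | None = None,
) -> LabelImage:
    """Degrade a truth map into an "outdated" label source.

    Two error modes: (i) ``flip_rate`` of labeled pixels are relabeled
    uniformly to a different legend class (isolated classification errors);
    (ii) ``change_fraction`` of field polygons are wholly relabeled
    (spatially coherent land cover change). Nodata is preserved.
    """
    if not (0.0 <= flip_rate < 1.0 and 0.0 <= change_fraction < 1.0):
        raise ValueError("flip_rate and change_fraction must lie in [0, 1)")
    classes = sorted(set(truth.legend))
    if len(classes) < 2 and (flip_rate > 0 or change_fraction > 0):
        raise ValueError("cannot inject label errors with a single-class legend")
    rng = np.random.default_rng(seed)
    labels = truth.labels.copy()

    if change_fraction > 0:
        if not fields:
            raise ValueError("change_fraction > 0 requires the field list")
        n_change = int(round(change_fraction * len(fields)))
        for idx in rng.choice(len(fields), size=n_change, replace=False):
            f = fields[idx]
            others = [c for c in classes if c != f.class_id]
            labels[f.row0 : f.row1, f.col0 : f.col1] = int(rng.choice(others))

    if flip_rate > 0:
        data = truth.mask()
        flat = np.flatnonzero(data)
        n_flip = int(round(flip_rate * flat.size))
        chosen = rng.choice(flat, size=n_flip, replace=False)
        current = labels.reshape(-1)[chosen]
        # draw a uniformly different class: offset 1..k-1 around the legend
        arr = np.asarray(classes)
        pos = np.searchsorted(arr, current)
        offset = rng.integers(1, len(arr), size=n_flip)
        labels.reshape(-1)[chosen] = arr[(pos + offset) % len(arr)]

    return truth.copy_with(labels)


def simulate_memberships(
    truth: LabelImage,
    classes: list[int] | None = None,
    signal: float = 2.0,
    noise_sd: float = 1.2,
    seed: int = 0,
):
    """Noisy soft classification of a label map, for filter experiments.

    Per pixel, class logits are a one-hot bump of height ``signal`` on the
    true class plus Gaussian noise; a softmax turns them into a membership
    vector. Wrong argmax decisions are isolated (speckle) and, because they
    arise from near-ties, carry systematically lower confidence — the
    structure confidence-weighted filtering exploits.
    Returns a :class:`MembershipImage`.
    """
    from .types import MembershipImage

    if classes is None:
        classes = sorted(truth.legend)
    rng = np.random.default_rng(seed)
    h, w = truth.shape
    index = {c: i for i, c in enumerate(classes)}
    logits = rng.normal(0.0, noise_sd, (h, w, len(classes)))
    for c, i in index.items():
        logits[..., i][truth.labels == c] += signal
    logits -= logits.max(axis=2, keepdims=True)
    probs = np.exp(logits)
    probs /= probs.sum(axis=2, keepdims=True)
    nodata = ~truth.mask()
    probs[nodata] = 1.0 / len(classes)
    return MembershipImage(probs, tuple(classes), nodata, truth.transform)
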