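"""Reliable-pixel harvesting from an outdated land cover map.

An outdated map carries two kinds of wrong labels: original classification
errors and pixels whose cover has changed since the map was made. The
harvesting procedure keeps only pixels whose outdated label is corroborated
by their spectral-temporal signature:

1. a class-wise erosion removes all boundary pixels (co-registration guard);
2. per focal class, a sample of up to 5,000 focal pixels is merged with up
   to 10,000 pixels of the remaining classes and clustered with a
   self-organizing map; focal pixels in clusters whose focal-class purity is
   at least 75% are flagged reliable;
3. reliable rows deviating from the class distribution (outside the 95%
   interval in any of the 12 feature bands) are dropped;
4. the stratum training set is rebuilt to the outdated map's class
   proportions (target 5,000 rows) with a greedy farthest-point selection
   that maximises intra-class dissimilarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .som import SelfOrganizingMap, default_som_shape
from .types import FeatureImage, LabelImage, TrainingSet

PURITY_THRESHOLD = 0.75
FOCAL_SAMPLE = 5_000
OTHER_SAMPLE = 10_000
TRAINING_TARGET = 5_000


@dataclass
class PurityRow:
    cluster: int
    size: int
    focal_count: int

    @property
    def purity(self) -> float:
        return self.focal_count / self.size


@dataclass
class PuritySummary:
    """Per-cluster composition for one focal class."""

    focal_class: int
    rows: list[PurityRow] = field(default_factory=list)

    def purity_of(self, cluster: int) -> float:
        for row in self.rows:
            if row.cluster == cluster:
                return row.purity
        raise KeyError(cluster)


def erode_class_boundaries(labels: LabelImage) -> LabelImage:
    """Remove, for every class, pixels 8-adjacent to any other label or to
    nodata (the outside of the image counts as nodata)."""
    out = np.full_like(labels.labels, labels.nodata)
    structure = np.ones((3, 3), dtype=bool)
    for cid in sorted(set(labels.legend)):
        mask = labels.labels == cid
        if not mask.any():
            continue
        interior = ndimage.binary_erosion(mask, structure=structure, border_value=0)
        out[interior] = cid
    return labels.copy_with(out)


def cluster_features(
    sample: np.ndarray,
    som_shape: tuple[int, int] | None = None,
    seed: int = 0,
    n_iterations: int = 1000,
) -> np.ndarray:
    """Cluster feature vectors with a seeded SOM; returns node assignments.

    Features are standardized internally (zero mean, unit variance per band;
    constant bands left untouched) so that bright bands do not dominate the
    Euclidean metric.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.ndim != 2 or len(sample) == 0:
        raise ValueError("sample must be a non-empty (n, d) matrix")
    if som_shape is None:
        som_shape = default_som_shape(len(sample))
    if som_shape[0] * som_shape[1] > len(sample):
        raise ValueError("SOM grid larger than the sample")
    mu = sample.mean(axis=0)
    sd = sample.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (sample - mu) / sd
    som = SelfOrganizingMap(som_shape, n_iterations=n_iterations, seed=seed)
    return som.fit_predict(Z)


def select_reliable(
    features: FeatureImage,
    outdated: LabelImage,
    class_c: int,
    seed: int = 0,
    purity_threshold: float = PURITY_THRESHOLD,
    focal_sample: int = FOCAL_SAMPLE,
    other_sample: int = OTHER_SAMPLE,
    som_shape: tuple[int, int] | None = None,
    pre_eroded: bool = False,
) -> tuple[np.ndarray, PuritySummary]:
    """Flag reliable pixels of one focal class.

    Returns a boolean raster (True where a class_c pixel was corroborated)
    and the cluster purity summary. The outdated map is eroded first unless
    ``pre_eroded`` is set. An absent class yields an empty mask plus a
    warning rather than an error.
    """
    eroded = outdated if pre_eroded else erode_class_boundaries(outdated)
    usable = eroded.mask() & ~features.nodata_mask
    focal = usable & (eroded.labels == class_c)
    other = usable & (eroded.labels != class_c)

    reliable = np.zeros(outdated.shape, dtype=bool)
    summary = PuritySummary(focal_class=class_c)
    if not focal.any():
        warnings.warn(f"class {class_c} absent after erosion", stacklevel=2)
        return reliable, summary

    rng = np.random.default_rng(seed)
    focal_idx = _sample_indices(focal, focal_sample, rng)
    other_idx = _sample_indices(other, other_sample, rng)
    idx = np.concatenate([focal_idx, other_idx])
    is_focal = np.zeros(len(idx), dtype=bool)
    is_focal[: len(focal_idx)] = True

    rows, cols = np.unravel_index(idx, outdated.shape)
    X = features.data[rows, cols, :]
    shape = som_shape
    if shape is not None and shape[0] * shape[1] > len(X):
        shape = default_som_shape(len(X))  # shrink for small strata
    assignments = cluster_features(
        X, som_shape=shape, seed=int(rng.integers(0, 2**31 - 1))
    )

    for cluster in np.unique(assignments):
        members = assignments == cluster
        size = int(members.sum())
        focal_count = int((members & is_focal).sum())
        summary.rows.append(PurityRow(int(cluster), size, focal_count))
        if focal_count / size >= purity_threshold:
            sel = members & is_focal
            reliable[rows[sel], cols[sel]] = True
    return reliable, summary


def _sample_indices(mask: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    flat = np.flatnonzero(mask)
    if len(flat) <= n:
        return flat
    return rng.choice(flat, size=n, replace=False)


def filter_ci(
    X: np.ndarray, keep_min: int = 20, lower: float = 2.5, upper: float = 97.5
) -> np.ndarray:
    """Boolean keep-mask dropping rows outside the empirical [2.5, 97.5]
    percentile interval of the class in ANY feature band.

    With fewer than ``keep_min`` rows the interval is too noisy to trust and
    everything passes through (with a warning).
    """
    X = np.asarray(X, dtype=float)
    if len(X) < keep_min:
        if len(X):
            warnings.warn("too few rows for the confidence-interval filter", stacklevel=2)
        return np.ones(len(X), dtype=bool)
    lo = np.percentile(X, lower, axis=0)
    hi = np.percentile(X, upper, axis=0)
    return np.all((X >= lo) & (X <= hi), axis=1)


def class_proportions(labels: LabelImage) -> dict[int, float]:
    """Class share of the labeled area of a map."""
    mask = labels.mask()
    total = int(mask.sum())
    if total == 0:
        raise ValueError("label map is empty")
    return {
        int(c): int((labels.labels == c).sum()) / total
        for c in np.unique(labels.labels[mask])
    }


def largest_remainder_quotas(proportions: dict[int, float], n_total: int) -> dict[int, int]:
    """Integer quotas summing exactly to n_total (largest-remainder method)."""
    classes = sorted(proportions)
    shares = np.array([proportions[c] for c in classes], dtype=float)
    shares = shares / shares.sum()
    raw = shares * n_total
    quotas = np.floor(raw).astype(int)
    remainder = n_total - quotas.sum()
    order = np.argsort(-(raw - quotas))
    quotas[order[:remainder]] += 1
    return {c: int(q) for c, q in zip(classes, quotas)}


def farthest_point_selection(X: np.ndarray, k: int, start: int | None = None) -> np.ndarray:
    """Greedy max-min selection of k row indices in standardized space.

    The first pick is the row nearest the centroid; each further pick
    maximises the minimum distance to the rows already chosen, spreading the
    subset across the class's spectral variability. Duplicate rows are only
    revisited once all distinct rows are exhausted (their min-distance is 0).
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    if k >= n:
        return np.arange(n)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    if start is None:
        start = int(np.argmin(((Z - Z.mean(axis=0)) ** 2).sum(axis=1)))
    chosen = [start]
    min_d2 = ((Z - Z[start]) ** 2).sum(axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(min_d2))
        chosen.append(nxt)
        min_d2 = np.minimum(min_d2, ((Z - Z[nxt]) ** 2).sum(axis=1))
    return np.asarray(chosen)


def build_training_set(
    reliable_by_class: dict[int, TrainingSet],
    proportions: dict[int, float],
    n_total: int = TRAINING_TARGET,
    seed: int = 0,
) -> TrainingSet:
    """Assemble the stratum training set at the target class proportions.

    Per-class quotas follow the largest-remainder rounding of
    ``proportions`` x ``n_total``; within a class the quota is filled by
    greedy farthest-point selection. Classes with fewer reliable rows than
    their quota contribute everything they have (the total may then fall
    short of ``n_total``).
    """
    present = {c: ts for c, ts in reliable_by_class.items() if len(ts)}
    if not present:
        raise ValueError("no reliable rows in any class")
    props = {c: proportions.get(c, 0.0) for c in present}
    if sum(props.values()) <= 0:
        props = {c: 1.0 for c in present}
    quotas = largest_remainder_quotas(props, n_total)

    parts: list[TrainingSet] = []
    for c, ts in sorted(present.items()):
        quota = quotas.get(c, 0)
        if quota == 0:
            continue
        if quota >= len(ts):
            parts.append(ts)
            continue
        pick = farthest_point_selection(ts.X, quota)
        parts.append(
            TrainingSet(
                X=ts.X[pick],
                y=ts.y[pick],
                stratum=ts.stratum[pick],
                rows=ts.rows[pick],
                cols=ts.cols[pick],
                reliable=ts.reliable[pick],
                post_ci_filter=ts.post_ci_filter[pick],
            )
        )
    if not parts:
        raise ValueError("all class quotas were zero")
    return TrainingSet.concat(parts)


def harvest_training_set(
    features: FeatureImage,
    outdated: LabelImage,
    stratum_id: int = 0,
    stratum_mask: np.ndarray | None = None,
    n_total: int = TRAINING_TARGET,
    seed: int = 0,
    proportions: dict[int, float] | None = None,
    som_shape: tuple[int, int] | None = None,
) -> tuple[TrainingSet, dict[int, PuritySummary]]:
    """Full harvesting chain for one stratum: erosion, per-class reliable
    pixel selection, confidence-interval filtering and proportional
    re-sampling. Returns the TrainingSet and the purity summaries."""
    if stratum_mask is not None:
        masked = outdated.labels.copy()
        masked[~stratum_mask] = outdated.nodata
        outdated = outdated.copy_with(masked)

    eroded = erode_class_boundaries(outdated)
    usable = eroded.mask() & ~features.nodata_mask
    if not usable.any():
        raise ValueError("no usable pixels in stratum after erosion")
    if proportions is None:
        proportions = class_proportions(
            eroded.copy_with(np.where(usable, eroded.labels, eroded.nodata))
        )

    rng = np.random.default_rng(seed)
    summaries: dict[int, PuritySummary] = {}
    by_class: dict[int, TrainingSet] = {}
    for cid in sorted(proportions):
        reliable, summary = select_reliable(
            features,
            eroded,
            cid,
            seed=int(rng.integers(0, 2**31 - 1)),
            som_shape=som_shape,
            pre_eroded=True,
        )
        summaries[cid] = summary
        rows, cols = np.nonzero(reliable)
        if len(rows) == 0:
            continue
        X = features.data[rows, cols, :]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            keep = filter_ci(X)
        rows, cols, X = rows[keep], cols[keep], X[keep]
        if len(rows) == 0:
            continue
        by_class[cid] = TrainingSet(
            X=X,
            y=np.full(len(rows), cid, dtype=int),
            stratum=np.full(len(rows), stratum_id, dtype=int),
            rows=rows,
            cols=cols,
        )
    if not by_class:
        raise ValueError("harvesting produced no reliable rows")
    training = build_training_set(by_class, proportions, n_total=n_total, seed=seed)
    return training, summaries
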