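"""Stratum-specific random forests, soft-output fusion and ERP confidence.

Each stratum is classified by its own 500-tree random forest (3 candidate
split variables per node, the square root of the 12 input features). The
forests emit per-pixel class memberships — the fraction of trees voting for
each class. Where buffered strata overlap, the overlapping membership
vectors are fused with a componentwise geometric mean and renormalized; the
final label follows the maximum-membership rule.

The Equivalent Reference Probability (ERP) condenses a membership vector
into a scalar confidence in [1/n, 1]: it is the probability M such that a
reference distribution with one class at M and the remaining mass spread
uniformly over the other n-1 classes has the same Shannon entropy as the
vector. ERP equals max(p) for vectors already of that reference shape, 1/n
for the uniform vector and 1 for a degenerate one.
"""

from __future__ import annotations

import numpy as np
from shapely import contains_xy
from sklearn.ensemble import RandomForestClassifier

from .types import (
    ConfidenceImage,
    FeatureImage,
    LabelImage,
    MembershipImage,
    TrainingSet,
    pixel_centers,
)

N_TREES = 500
EPS_FLOOR = 1e-6


def train_stratum_rf(training: TrainingSet, seed: int = 0) -> RandomForestClassifier:
    """Fit the stratum forest: 500 trees, sqrt(12)=3 split candidates,
    out-of-bag scoring enabled so noise robustness can be inspected."""
    classes = np.unique(training.y)
    if len(classes) < 2:
        raise ValueError("training set must contain at least 2 classes")
    model = RandomForestClassifier(
        n_estimators=N_TREES,
        max_features="sqrt",
        oob_score=True,
        n_jobs=1,
        random_state=seed,
    )
    model.fit(training.X, training.y)
    return model


def predict_memberships(
    model: RandomForestClassifier,
    features: FeatureImage,
    stratum_polygon=None,
    buffer: float = 0.0,
) -> MembershipImage:
    """Per-pixel class memberships inside the buffered stratum polygon.

    Pixels outside the buffered polygon, and nodata feature pixels, are
    nodata in the output. ``buffer`` is in map units (pixels for synthetic
    scenes; one third of a degree is the convention for geographic grids).
    """
    if model.n_features_in_ != features.data.shape[2]:
        raise ValueError("model/feature band mismatch")
    h, w = features.shape
    inside = np.ones((h, w), dtype=bool)
    if stratum_polygon is not None:
        geom = stratum_polygon.buffer(buffer) if buffer else stratum_polygon
        xs, ys = pixel_centers((h, w), features.transform)
        inside = contains_xy(geom, xs.ravel(), ys.ravel()).reshape(h, w)
    usable = inside & ~features.nodata_mask

    classes = tuple(int(c) for c in model.classes_)
    probs = np.zeros((h, w, len(classes)))
    rows, cols = np.nonzero(usable)
    if len(rows):
        probs[rows, cols, :] = model.predict_proba(features.data[rows, cols, :])
    nodata = ~usable
    probs[nodata] = 1.0 / len(classes)  # placeholder; masked as nodata
    return MembershipImage(probs, classes, nodata, features.transform)


def align_classes(
    memberships: list[MembershipImage], classes: tuple[int, ...] | None = None
) -> list[MembershipImage]:
    """Expand membership images onto a common class list.

    Strata can train on different class subsets; before fusion every image
    is widened to the union of classes, with zero membership for classes a
    stratum's model never saw.
    """
    if classes is None:
        union: set[int] = set()
        for m in memberships:
            union |= set(m.classes)
        classes = tuple(sorted(union))
    out = []
    for m in memberships:
        if m.classes == classes:
            out.append(m)
            continue
        h, w = m.shape
        probs = np.zeros((h, w, len(classes)))
        for i, c in enumerate(m.classes):
            probs[..., classes.index(c)] = m.probs[..., i]
        nodata = m.nodata_mask
        probs[nodata] = 1.0 / len(classes)
        out.append(MembershipImage(probs, classes, nodata, m.transform))
    return out


def fuse_memberships(memberships: list[MembershipImage]) -> MembershipImage:
    """Geometric-mean fusion of overlapping stratum classifications.

    Pixels covered by a single source are copied unchanged; pixels covered
    by several get the componentwise geometric mean of their vectors,
    renormalized to sum 1. Zero memberships are floored at 1e-6 before the
    mean so a single zero vote cannot annihilate a class. Pixels covered by
    no source stay nodata.
    """
    if not memberships:
        raise ValueError("nothing to fuse")
    classes = memberships[0].classes
    for m in memberships[1:]:
        if m.classes != classes:
            raise ValueError("class order differs between sources")
    h, w = memberships[0].shape
    n = len(classes)

    log_sum = np.zeros((h, w, n))
    count = np.zeros((h, w), dtype=int)
    for m in memberships:
        ok = ~m.nodata_mask
        p = np.clip(m.probs, EPS_FLOOR, None)
        log_sum[ok] += np.log(p[ok])
        count[ok] += 1

    nodata = count == 0
    covered = ~nodata
    fused = np.full((h, w, n), 1.0 / n)
    with np.errstate(all="ignore"):
        g = np.exp(log_sum[covered] / count[covered, None])
        fused[covered] = g / g.sum(axis=1, keepdims=True)

    # single coverage: copy the source vector verbatim (no epsilon floor)
    single = count == 1
    if single.any():
        for m in memberships:
            take = single & ~m.nodata_mask
            fused[take] = m.probs[take]
    return MembershipImage(fused, classes, nodata, memberships[0].transform)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _reference_entropy(M: float, n: int) -> float:
    """Entropy of the reference distribution (M, (1-M)/(n-1), ...)."""
    rest = (1.0 - M) / (n - 1)
    h = 0.0
    if M > 0:
        h -= M * np.log(M)
    if rest > 0:
        h -= (n - 1) * rest * np.log(rest)
    return h


def compute_erp(p: np.ndarray, tol: float = 1e-8) -> float:
    """Equivalent Reference Probability of one membership vector.

    Solves H_ref(M) = H(p) for M in [1/n, 1] by bisection; H_ref is strictly
    decreasing on that interval (from log n at M = 1/n to 0 at M = 1), so
    the root is unique. Uses the 0*log 0 = 0 convention.
    """
    p = np.asarray(p, dtype=float)
    n = p.size
    if n < 2:
        raise ValueError("need at least 2 classes")
    if (p < -1e-12).any() or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("p must be a probability vector")
    target = _entropy(p)
    lo, hi = 1.0 / n, 1.0
    if target >= np.log(n) - 1e-15:
        return lo
    if target <= 0.0:
        return hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _reference_entropy(mid, n) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def erp_image(memberships: MembershipImage, tol: float = 1e-8) -> ConfidenceImage:
    """ERP confidence raster for a membership image."""
    h, w = memberships.shape
    erp = np.full((h, w), np.nan)
    rows, cols = np.nonzero(~memberships.nodata_mask)
    vecs = memberships.probs[rows, cols, :]
    # dedupe via entropy binning is overkill at these sizes; loop directly
    for r, c, p in zip(rows, cols, vecs):
        erp[r, c] = compute_erp(p, tol=tol)
    return ConfidenceImage(erp, memberships.nodata_mask.copy(), memberships.transform)


def argmax_label(
    memberships: MembershipImage, legend: dict[int, str] | None = None, nodata: int = 0
) -> tuple[LabelImage, int]:
    """Maximum-membership labeling; exact ties go to the lowest class id.

    Returns the label map and the number of tied pixels.
    """
    classes = np.asarray(memberships.classes)
    order = np.argsort(classes)  # ensures lowest-id preference among ties
    probs = memberships.probs[..., order]
    sorted_classes = classes[order]
    best = np.argmax(probs, axis=2)  # argmax returns the first (lowest id) max
    labels = sorted_classes[best].astype(np.int16)
    top = np.take_along_axis(probs, best[..., None], axis=2)[..., 0]
    ties = int(((probs == top[..., None]).sum(axis=2) > 1)[~memberships.nodata_mask].sum())
    labels[memberships.nodata_mask] = nodata
    if legend is None:
        legend = {int(c): str(c) for c in memberships.classes}
    return LabelImage(labels, legend, nodata, memberships.transform), ties
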