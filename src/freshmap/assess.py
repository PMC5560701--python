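"""Accuracy assessment: global scores, local (spatially constrained)
accuracy surfaces, confidence separation and feature-importance ranking.

Global accuracy is summarised by the confusion matrix, overall accuracy
(OA) with its binomial standard error, and per-class F-scores — the
harmonic mean of user's accuracy (precision) and producer's accuracy
(recall). Local accuracy repeats the same computation inside square windows
centred on a regular grid of points and interpolates the point scores with
inverse-distance weighting. A Mann-Whitney-Wilcoxon test checks whether
correctly classified cropland pixels carry higher ERP confidence than
misclassified ones. Per-stratum Gini importances are compared across strata
with a Friedman test (tie-corrected) and a post-hoc Nemenyi critical
difference on the mean feature ranks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .sampler import erode_class_boundaries
from .types import ConfidenceImage, LabelImage


@dataclass
class AccuracyReport:
    classes: tuple[int, ...]
    matrix: np.ndarray  # rows = reference, cols = predicted
    n: int

    @property
    def oa(self) -> float:
        return float(np.trace(self.matrix)) / self.n

    @property
    def se_oa(self) -> float:
        oa = self.oa
        return float(np.sqrt(oa * (1.0 - oa) / self.n))

    def users_accuracy(self, cls: int) -> float:
        i = self.classes.index(cls)
        col = self.matrix[:, i].sum()
        return float(self.matrix[i, i] / col) if col else np.nan

    def producers_accuracy(self, cls: int) -> float:
        i = self.classes.index(cls)
        row = self.matrix[i, :].sum()
        return float(self.matrix[i, i] / row) if row else np.nan

    def f_score(self, cls: int) -> float:
        ua = self.users_accuracy(cls)
        pa = self.producers_accuracy(cls)
        if not np.isfinite(ua) or not np.isfinite(pa) or ua + pa == 0:
            return np.nan
        return 2.0 * ua * pa / (ua + pa)


def confusion_and_scores(
    predicted: LabelImage, reference: LabelImage, erode_edges: bool = False
) -> AccuracyReport:
    """Confusion matrix and accuracy scores over jointly valid pixels.

    ``erode_edges`` discards reference boundary pixels (same class-wise
    erosion as the training sampler) before counting, removing the mixed
    pixels that co-registration errors contaminate.
    """
    if predicted.shape != reference.shape:
        raise ValueError("predicted and reference must share the grid")
    if erode_edges:
        reference = erode_class_boundaries(reference)
    both = predicted.mask() & reference.mask()
    n = int(both.sum())
    if n == 0:
        raise ValueError("no jointly valid pixels")
    classes = tuple(
        sorted(set(np.unique(reference.labels[both])) | set(np.unique(predicted.labels[both])))
    )
    index = {c: i for i, c in enumerate(classes)}
    ref = np.vectorize(index.get)(reference.labels[both])
    pred = np.vectorize(index.get)(predicted.labels[both])
    matrix = np.zeros((len(classes), len(classes)), dtype=np.int64)
    np.add.at(matrix, (ref, pred), 1)
    return AccuracyReport(classes, matrix, n)


@dataclass
class AccuracySurface:
    xs: np.ndarray  # grid point x coordinates (masked points excluded)
    ys: np.ndarray
    oa: np.ndarray
    fs_c: np.ndarray
    fs_nc: np.ndarray
    counts: np.ndarray
    raster_oa: np.ndarray | None = None  # IDW-interpolated OA surface


def local_accuracy(
    predicted: LabelImage,
    reference: LabelImage,
    spacing: float,
    window: float,
    min_count: int = 500,
    cropland_class: int = 1,
    interpolate: bool = True,
) -> AccuracySurface:
    """Accuracy scores on a regular grid of points, each computed from the
    reference pixels inside a centred square window (side ``window``), plus
    an IDW (power 2) interpolation of the point OA back to the raster grid.

    Distances are in map units; with the identity transform of synthetic
    scenes that means pixels. Points with fewer than ``min_count`` reference
    pixels are masked out.
    """
    if spacing <= 0 or window <= 0:
        raise ValueError("spacing and window must be positive")
    x0, dx, y0, dy = predicted.transform
    if window < min(abs(dx), abs(dy)):
        raise ValueError("window smaller than one pixel")
    h, w = predicted.shape
    extent_x, extent_y = w * dx, h * dy
    gx = np.arange(spacing / 2.0, extent_x, spacing)
    gy = np.arange(spacing / 2.0, extent_y, spacing)

    both = predicted.mask() & reference.mask()
    half = window / 2.0
    pts = []
    for yc in gy:
        for xc in gx:
            c0 = max(int(np.floor((xc - half - x0) / dx)), 0)
            c1 = min(int(np.ceil((xc + half - x0) / dx)), w)
            r0 = max(int(np.floor((yc - half - y0) / dy)), 0)
            r1 = min(int(np.ceil((yc + half - y0) / dy)), h)
            sub = both[r0:r1, c0:c1]
            count = int(sub.sum())
            if count < min_count:
                continue
            ref = reference.labels[r0:r1, c0:c1][sub]
            pred = predicted.labels[r0:r1, c0:c1][sub]
            oa = float((ref == pred).mean())
            fs_c = _binary_f(ref, pred, cropland_class)
            fs_nc = _binary_f(ref, pred, cropland_class, invert=True)
            pts.append((xc, yc, oa, fs_c, fs_nc, count))
    if not pts:
        return AccuracySurface(*(np.array([]) for _ in range(6)))
    arr = np.array(pts, dtype=float)
    surface = AccuracySurface(
        xs=arr[:, 0], ys=arr[:, 1], oa=arr[:, 2], fs_c=arr[:, 3],
        fs_nc=arr[:, 4], counts=arr[:, 5].astype(int),
    )
    if interpolate:
        from .types import pixel_centers

        px, py = pixel_centers((h, w), predicted.transform)
        surface.raster_oa = idw_interpolate(
            surface.xs, surface.ys, surface.oa, px.ravel(), py.ravel()
        ).reshape(h, w)
    return surface


def _binary_f(ref: np.ndarray, pred: np.ndarray, cls: int, invert: bool = False) -> float:
    ref_pos = (ref == cls) != invert
    pred_pos = (pred == cls) != invert
    tp = int((ref_pos & pred_pos).sum())
    fp = int((~ref_pos & pred_pos).sum())
    fn = int((ref_pos & ~pred_pos).sum())
    if 2 * tp + fp + fn == 0:
        return np.nan
    return 2.0 * tp / (2.0 * tp + fp + fn)


def idw_interpolate(
    xs: np.ndarray, ys: np.ndarray, values: np.ndarray,
    qx: np.ndarray, qy: np.ndarray, power: float = 2.0,
) -> np.ndarray:
    """Inverse-distance-weighted interpolation; exact at the data points and
    bounded by their extrema."""
    d2 = (qx[:, None] - xs[None, :]) ** 2 + (qy[:, None] - ys[None, :]) ** 2
    out = np.empty(len(qx))
    exact = d2.min(axis=1) == 0.0
    out[exact] = values[np.argmin(d2[exact], axis=1)]
    rest = ~exact
    if rest.any():
        wgt = 1.0 / d2[rest] ** (power / 2.0)
        out[rest] = (wgt * values[None, :]).sum(axis=1) / wgt.sum(axis=1)
    return out


@dataclass
class SeparationTest:
    applicable: bool
    statistic: float = np.nan
    p_value: float = np.nan
    n_correct: int = 0
    n_wrong: int = 0
    direction: str = ""  # "correct_higher" / "wrong_higher" / "none"


def confidence_separation(
    confidence: ConfidenceImage,
    predicted: LabelImage,
    reference: LabelImage,
    cls: int = 1,
    min_group: int = 20,
) -> SeparationTest:
    """Two-sided Mann-Whitney-Wilcoxon test comparing the ERP of correctly
    vs incorrectly classified pixels of one class (cropland by default)."""
    both = predicted.mask() & reference.mask() & ~confidence.nodata_mask
    of_class = both & (reference.labels == cls)
    correct = confidence.erp[of_class & (predicted.labels == cls)]
    wrong_mask = both & (predicted.labels == cls) & (reference.labels != cls)
    wrong = np.concatenate(
        [confidence.erp[of_class & (predicted.labels != cls)], confidence.erp[wrong_mask]]
    )
    if len(correct) < min_group or len(wrong) < min_group:
        return SeparationTest(applicable=False, n_correct=len(correct), n_wrong=len(wrong))
    return rank_sum_separation(correct, wrong)


def rank_sum_separation(correct: np.ndarray, wrong: np.ndarray) -> SeparationTest:
    """Mann-Whitney test on two confidence samples (midrank convention)."""
    if np.ptp(np.concatenate([correct, wrong])) == 0:
        # all values tied: no evidence either way
        return SeparationTest(True, len(correct) * len(wrong) / 2.0, 1.0,
                              len(correct), len(wrong), "none")
    res = stats.mannwhitneyu(correct, wrong, alternative="two-sided", method="asymptotic")
    direction = "correct_higher" if res.statistic > len(correct) * len(wrong) / 2.0 else "wrong_higher"
    return SeparationTest(True, float(res.statistic), float(res.pvalue),
                          len(correct), len(wrong), direction)


@dataclass
class FriedmanNemenyi:
    statistic: float
    p_value: float
    mean_ranks: np.ndarray  # per feature, averaged over strata (rank 1 = most important)
    critical_difference: float
    significant: np.ndarray  # (k, k) bool, |rank_i - rank_j| >= CD
    k: int
    n: int


def friedman_statistic(ranks: np.ndarray) -> float:
    """Tie-corrected Friedman chi-squared from an (N, k) midrank table."""
    n, k = ranks.shape
    rank_sums = ranks.sum(axis=0)
    chi = 12.0 / (n * k * (k + 1)) * (rank_sums**2).sum() - 3.0 * n * (k + 1)
    # tie correction: scale by 1 - sum(t^3 - t) / (n (k^3 - k))
    ties = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        ties += float((counts**3 - counts).sum())
    denom = 1.0 - ties / (n * (k**3 - k))
    if denom <= 0:
        return 0.0
    return chi / denom


def feature_importance_stats(
    importance: np.ndarray, alpha: float = 0.05, df: float = np.inf
) -> FriedmanNemenyi:
    """Friedman test + Nemenyi critical difference on an (N strata, k
    features) importance table.

    Features are ranked within each stratum with midranks for ties, rank 1
    being the most important. CD = q_{alpha,k} / sqrt(2) * sqrt(k(k+1)/(6N))
    with q from the studentized-range distribution (df defaults to
    infinity; exposed because published CD values sometimes use a finite-df
    convention).
    """
    importance = np.asarray(importance, dtype=float)
    if importance.ndim != 2:
        raise ValueError("importance must be (n_strata, n_features)")
    n, k = importance.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 strata and 2 features")
    if not np.all(np.isfinite(importance)):
        raise ValueError("importances must be finite")
    # most important feature gets rank 1
    ranks = np.vstack([stats.rankdata(-row, method="average") for row in importance])
    statistic = friedman_statistic(ranks)
    p_value = float(stats.chi2.sf(statistic, k - 1))
    mean_ranks = ranks.mean(axis=0)
    q = float(stats.studentized_range.ppf(1.0 - alpha, k, df))
    cd = q / np.sqrt(2.0) * np.sqrt(k * (k + 1) / (6.0 * n))
    diff = np.abs(mean_ranks[:, None] - mean_ranks[None, :])
    significant = diff >= cd
    np.fill_diagonal(significant, False)
    return FriedmanNemenyi(statistic, p_value, mean_ranks, float(cd), significant, k, n)
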