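"""Speckle removal and binarization.

Two 3x3 moving-window relabeling filters: the conventional majority filter
M(s) = argmax_i sum_j I(h_j(s) = i), and a confidence-weighted variant
M_w(s) = argmax_i sum_j w_j I(h_j(s) = i) whose weights w_j are the ERP
confidence values normalized to sum 1 within the window. Equal confidences
reduce the weighted filter to the conventional one. Ties keep the centre
label; windows are truncated at image borders and nodata members are
excluded from both the votes and the weight normalization.
"""

from __future__ import annotations

import numpy as np

from .scene_sim import CROPLAND_CLASSES
from .types import ConfidenceImage, LabelImage

BINARY_LEGEND = {1: "cropland", 2: "non-cropland"}


def _check_window(window: int) -> int:
    if window % 2 == 0 or window < 1:
        raise ValueError("window size must be odd and positive")
    return window // 2


def majority_filter(labels: LabelImage, window: int = 3) -> LabelImage:
    """Conventional majority relabeling over a (window x window) block."""
    return _windowed_filter(labels, None, window)


def weighted_majority_filter(
    labels: LabelImage, confidence: ConfidenceImage, window: int = 3
) -> LabelImage:
    """Confidence-weighted majority relabeling (window-normalized ERP)."""
    if confidence.erp.shape != labels.shape:
        raise ValueError("labels and confidence must share the grid")
    finite = np.isfinite(confidence.erp) & ~confidence.nodata_mask
    vals = confidence.erp[finite]
    if vals.size and (vals.min() < 0.0 or vals.max() > 1.0):
        raise ValueError("confidence values must lie in [0, 1]")
    return _windowed_filter(labels, confidence, window)


def _windowed_filter(
    labels: LabelImage, confidence: ConfidenceImage | None, window: int
) -> LabelImage:
    radius = _check_window(window)
    lab = labels.labels
    h, w = lab.shape
    classes = np.asarray(sorted(set(labels.legend)))
    class_index = {int(c): i for i, c in enumerate(classes)}
    data = labels.mask()
    if confidence is None:
        weight = data.astype(float)
    else:
        weight = np.where(data & ~confidence.nodata_mask, confidence.erp, 0.0)
        weight = np.nan_to_num(weight, nan=0.0)

    # accumulate per-class weighted votes by shifting the image over the
    # window offsets; normalization within a window rescales all scores by
    # the same positive factor and never changes the argmax, so it is
    # omitted from the score accumulation.
    scores = np.zeros((h, w, len(classes)))
    lab_idx = np.zeros_like(lab, dtype=np.int64)
    for c, i in class_index.items():
        lab_idx[lab == c] = i
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            shifted_w = _shift(weight, dr, dc)
            shifted_i = _shift(lab_idx, dr, dc)
            valid = _shift(data.astype(float), dr, dc) > 0
            np.put_along_axis(
                scores,
                shifted_i[..., None],
                np.take_along_axis(scores, shifted_i[..., None], axis=2)
                + np.where(valid, shifted_w, 0.0)[..., None],
                axis=2,
            )

    best = np.argmax(scores, axis=2)
    top = np.take_along_axis(scores, best[..., None], axis=2)[..., 0]
    n_max = (np.isclose(scores, top[..., None], rtol=0, atol=1e-12)).sum(axis=2)
    out = classes[best].astype(lab.dtype)
    tie_or_empty = (n_max > 1) | (top <= 0)
    out[tie_or_empty] = lab[tie_or_empty]  # ties keep the centre label
    out[~data] = labels.nodata  # nodata centre stays nodata
    return labels.copy_with(out)


def _shift(a: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Shift so that position (r, c) reads a[r+dr, c+dc]; outside -> 0."""
    out = np.zeros_like(a)
    src_r = slice(max(dr, 0), a.shape[0] + min(dr, 0))
    src_c = slice(max(dc, 0), a.shape[1] + min(dc, 0))
    dst_r = slice(max(-dr, 0), a.shape[0] + min(-dr, 0))
    dst_c = slice(max(-dc, 0), a.shape[1] + min(-dc, 0))
    out[dst_r, dst_c] = a[src_r, src_c]
    return out


def filter_window_bruteforce(
    window_labels: np.ndarray,
    window_weights: np.ndarray | None,
    centre: tuple[int, int],
    nodata: int = 0,
) -> int:
    """Direct per-window evaluation of the (weighted) majority rule.

    Independent oracle for the shifted-accumulation implementation: builds
    the vote tally explicitly for a single window. ``window_weights`` of
    None means the unweighted filter.
    """
    centre_label = int(window_labels[centre])
    if centre_label == nodata:
        return nodata
    votes: dict[int, float] = {}
    total_w = 0.0
    for r in range(window_labels.shape[0]):
        for c in range(window_labels.shape[1]):
            lab = int(window_labels[r, c])
            if lab == nodata:
                continue
            wgt = 1.0 if window_weights is None else float(window_weights[r, c])
            votes[lab] = votes.get(lab, 0.0) + wgt
            total_w += wgt
    if total_w <= 0:
        return centre_label
    best_score = max(votes.values())
    winners = [lab for lab, s in votes.items() if abs(s - best_score) <= 1e-12]
    return centre_label if len(winners) > 1 else winners[0]


def binarize(
    labels: LabelImage, cropland_classes: set[int] | frozenset[int] = CROPLAND_CLASSES
) -> LabelImage:
    """Collapse the working legend into {1: cropland, 2: non-cropland}."""
    if not cropland_classes:
        raise ValueError("cropland class set must be non-empty")
    unknown = set(cropland_classes) - set(labels.legend)
    if unknown:
        raise ValueError(f"cropland classes outside legend: {sorted(unknown)}")
    out = np.full_like(labels.labels, 2)
    crop = np.isin(labels.labels, list(cropland_classes))
    out[crop] = 1
    out[~labels.mask()] = labels.nodata
    return LabelImage(out, dict(BINARY_LEGEND), labels.nodata, labels.transform)
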