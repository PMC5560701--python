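"""Spectral-temporal feature extraction.

Each pixel's masked time series is collapsed into twelve features: the
per-band median over all clear observations, the per-band mean reflectance
of observations in the lowest decile of the pixel's NDVI values, and the
same for the highest decile. Compositing on NDVI deciles rather than single
extreme dates makes the minimum-vegetation and peak-vegetation targets
robust to residual cloud and noise.
"""

from __future__ import annotations

import numpy as np

from .types import BANDS, FeatureImage, ObservationStack

DEFAULT_MIN_VALID = 3


def compute_ndvi(red: np.ndarray, nir: np.ndarray) -> np.ndarray:
    """NDVI = (NIR - red) / (NIR + red), NaN where the denominator is zero.

    Inputs must be non-negative reflectances; a zero denominator (both bands
    zero) is flagged invalid rather than raising.
    """
    red = np.asarray(red, dtype=float)
    nir = np.asarray(nir, dtype=float)
    if np.any(red[np.isfinite(red)] < 0) or np.any(nir[np.isfinite(nir)] < 0):
        raise ValueError("reflectance must be non-negative")
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        ndvi = np.where(denom > 0, (nir - red) / np.where(denom > 0, denom, 1.0), np.nan)
    return ndvi


def extract_features(stack: ObservationStack, min_valid: int = DEFAULT_MIN_VALID) -> FeatureImage:
    """Compute the 12-band composite from a masked reflectance stack.

    Per pixel, only clear observations enter the statistics; observations
    whose NDVI is undefined are excluded from decile selection but still
    contribute to the medians. Pixels with fewer than ``min_valid`` clear
    observations are set to nodata.
    """
    if min_valid < 1:
        raise ValueError("min_valid must be >= 1")
    if stack.n_dates == 0:
        raise ValueError("stack has no observation dates")

    refl = stack.reflectance  # (H, W, T, 4)
    valid = stack.valid  # (H, W, T)
    h, w, t, _ = refl.shape

    masked = np.where(valid[..., None], refl, np.nan)
    n_valid = valid.sum(axis=2)
    nodata = n_valid < min_valid

    with np.errstate(all="ignore"):
        med = np.nanmedian(masked, axis=2)  # (H, W, 4)

        ndvi = compute_ndvi(masked[..., 0], masked[..., 1])  # NaN where invalid
        q_lo = np.nanquantile(ndvi, 0.1, axis=2, keepdims=True)
        q_hi = np.nanquantile(ndvi, 0.9, axis=2, keepdims=True)
        # inclusive membership guarantees at least one observation per decile
        in_lo = ndvi <= q_lo
        in_hi = ndvi >= q_hi
        min_comp = _masked_mean(masked, in_lo)
        max_comp = _masked_mean(masked, in_hi)

    data = np.concatenate([med, min_comp, max_comp], axis=2)
    # a pixel whose every NDVI is undefined has empty deciles -> nodata
    nodata |= ~np.isfinite(data).all(axis=2)
    data = np.where(nodata[..., None], np.nan, data)
    return FeatureImage(data, nodata, n_valid, stack.transform)


def _masked_mean(masked: np.ndarray, member: np.ndarray) -> np.ndarray:
    """Mean over the time axis of observations selected by ``member``."""
    sel = np.where(member[..., None], masked, np.nan)
    with np.errstate(all="ignore"):
        return np.nanmean(sel, axis=2)


def extract_features_naive(stack: ObservationStack, min_valid: int = DEFAULT_MIN_VALID) -> FeatureImage:
    """Reference per-pixel loop implementation; used as a cross-check oracle."""
    h, w = stack.shape
    data = np.full((h, w, len(BANDS) * 3), np.nan)
    n_valid = stack.valid.sum(axis=2)
    nodata = np.ones((h, w), dtype=bool)
    for r in range(h):
        for c in range(w):
            obs = stack.reflectance[r, c][stack.valid[r, c]]
            if obs.shape[0] < min_valid:
                continue
            ndvi = compute_ndvi(obs[:, 0], obs[:, 1])
            defined = np.isfinite(ndvi)
            if not defined.any():
                continue
            q10 = np.quantile(ndvi[defined], 0.1)
            q90 = np.quantile(ndvi[defined], 0.9)
            lo = defined & (ndvi <= q10)
            hi = defined & (ndvi >= q90)
            data[r, c, 0:4] = np.median(obs, axis=0)
            data[r, c, 4:8] = obs[lo].mean(axis=0)
            data[r, c, 8:12] = obs[hi].mean(axis=0)
            nodata[r, c] = False
    return FeatureImage(data, nodata, n_valid, stack.transform)
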