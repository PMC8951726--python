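"""Phasor-map conditioning: photon-count threshold and median smoothing.

Mirrors the two calibration filters of the vendor phasor workflow: a
photon threshold (default 100) that discards stray low-count phasor
points, and a median filter (default 5×5 window) applied to the G and S
coordinate images to tighten phasor clusters.  Thresholding is applied
before median filtering so unreliable pixels never contaminate the
smoothing windows.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from pydantic import BaseModel, field_validator

from .phasor import PhasorImage

__all__ = ["FilterParams", "threshold_filter", "median_filter_phasor", "apply_filters"]


class FilterParams(BaseModel):
    """Filter settings; defaults follow the optimized acquisition protocol."""

    min_photons: int = 100
    median_size: int = 5
    passes: int = 1

    @field_validator("min_photons")
    @classmethod
    def _thr(cls, v: int) -> int:
        if v < 0:
            raise ValueError("min_photons must be >= 0")
        return v

    @field_validator("median_size")
    @classmethod
    def _odd(cls, v: int) -> int:
        if v < 1 or v % 2 == 0:
            raise ValueError("median_size must be odd and >= 1")
        return v

    @field_validator("passes")
    @classmethod
    def _passes(cls, v: int) -> int:
        if v < 0:
            raise ValueError("passes must be >= 0")
        return v


def threshold_filter(image: PhasorImage, min_photons: int = 100) -> PhasorImage:
    """Mask out pixels with fewer than ``min_photons`` total photons.

    Only the validity mask changes; G, S and intensity are untouched.
    """
    if min_photons < 0:
        raise ValueError("min_photons must be >= 0")
    mask = image.mask & (image.intensity >= min_photons)
    meta = dict(image.metadata)
    meta["filters"] = list(meta.get("filters", [])) + [{"threshold": int(min_photons)}]
    return image.replace(mask=mask, metadata=meta)


def _masked_lower_median(values: np.ndarray, size: int) -> np.ndarray:
    """Sliding-window lower median ignoring NaN entries; NaN where no sample.

    ``values`` must already be padded is not required — reflective padding
    is applied here.  The lower median (element ``(m-1)//2`` of the sorted
    ``m`` valid samples) is used so even-count windows are deterministic.
    """
    pad = size // 2
    padded = np.pad(values, pad, mode="reflect")
    win = sliding_window_view(padded, (size, size))
    flat = win.reshape(*values.shape, size * size)
    order = np.sort(np.where(np.isnan(flat), np.inf, flat), axis=-1)
    count = np.isfinite(order).sum(axis=-1)
    idx = np.clip((count - 1) // 2, 0, size * size - 1)
    med = np.take_along_axis(order, idx[..., None], axis=-1)[..., 0]
    return np.where(count > 0, med, np.nan)


def median_filter_phasor(
    image: PhasorImage, median_size: int = 5, passes: int = 1
) -> PhasorImage:
    """Median-filter the G and S images over a square window.

    Masked pixels are excluded from every window sample (never zero-filled);
    borders are handled by reflection.  Intensity and the mask are left
    unchanged.  A pixel whose window contains no valid sample keeps its
    original value.
    """
    if median_size < 1 or median_size % 2 == 0:
        raise ValueError("median_size must be odd and >= 1")
    if passes < 0:
        raise ValueError("passes must be >= 0")
    G = image.G.copy()
    S = image.S.copy()
    for _ in range(passes):
        g_in = np.where(image.mask, G, np.nan)
        s_in = np.where(image.mask, S, np.nan)
        g_med = _masked_lower_median(g_in, median_size)
        s_med = _masked_lower_median(s_in, median_size)
        G = np.where(np.isfinite(g_med), g_med, G)
        S = np.where(np.isfinite(s_med), s_med, S)
    meta = dict(image.metadata)
    meta["filters"] = list(meta.get("filters", [])) + [
        {"median_size": int(median_size), "passes": int(passes)}
    ]
    return image.replace(G=G, S=S, metadata=meta)


def apply_filters(image: PhasorImage, params: FilterParams) -> PhasorImage:
    """Threshold then median-filter, with all parameters logged in metadata."""
    out = threshold_filter(image, params.min_photons)
    if params.passes > 0 and params.median_size > 1:
        out = median_filter_phasor(out, params.median_size, params.passes)
    return out
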