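"""Tissue-mask construction and per-stain thresholding.

The fibrous-tissue mask is built from the collagen (blue-green) stain-amount
channel: a Gaussian blur (sigma 2 px by default) bleeds stain across the
natural unstained cracks between collagen bundles, an iterative-intermeans
("Default") auto-threshold separates tissue from bright background — with
gray level 0 excluded from the histogram ("ignore black") — and a binary
closing consolidates the area.  Each stain channel is then thresholded the
same way and restricted to the mask with a pixelwise AND.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import (
    DegenerateHistogram,
    DimensionMismatch,
    EmptyRegion,
    InvalidSigma,
)

_STRUCT_3X3 = np.ones((3, 3), dtype=bool)


def gaussian_blur(channel: np.ndarray, sigma: float = 2.0) -> np.ndarray:
    """Gaussian-filter an 8-bit channel (reflective boundaries).

    Output is re-quantized to ``uint8``; a constant image is preserved
    exactly and total brightness is conserved up to rounding.
    """
    if sigma <= 0:
        raise InvalidSigma(f"sigma must be > 0, got {sigma}")
    out = ndimage.gaussian_filter(
        np.asarray(channel, dtype=np.float64), sigma=sigma, mode="reflect"
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def build_histogram(
    channel: np.ndarray,
    region: np.ndarray | None = None,
    ignore_black: bool = False,
) -> np.ndarray:
    """256-bin histogram of an 8-bit channel, optionally region-restricted.

    ``ignore_black`` zeroes bin 0 before returning, mirroring the "ignore
    black" thresholding option: gray level 0 encodes "no stain at all" and
    would otherwise dominate the histogram of a mostly-background image.
    """
    channel = np.asarray(channel)
    if region is not None:
        region = np.asarray(region, dtype=bool)
        if region.shape != channel.shape:
            raise DimensionMismatch("region shape does not match channel")
        vals = channel[region]
    else:
        vals = channel.ravel()
    if vals.size == 0:
        raise EmptyRegion("histogram region contains no pixels")
    counts = np.bincount(vals.astype(np.intp), minlength=256)[:256]
    if ignore_black:
        counts[0] = 0
    return counts.astype(np.int64)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def default_threshold(hist: np.ndarray) -> int:
    """Iterative-intermeans ("Default") threshold of a 256-bin histogram.

    Starting from the midpoint of the occupied range, iterate

        t  <-  round((mean of values <= t  +  mean of values > t) / 2)

    (round half up) to a fixed point.  Foreground is defined downstream as
    values strictly greater than ``t``.  Candidates are clamped to keep both
    sides of the split non-empty; a cycle (possible only on pathological
    histograms) terminates at the current value.

    Raises
    ------
    DegenerateHistogram
        If fewer than two bins are occupied.
    """
    counts = np.asarray(hist, dtype=np.int64)
    if counts.shape != (256,):
        raise ValueError("expected a 256-bin histogram")
    occupied = np.flatnonzero(counts)
    if occupied.size < 2:
        raise DegenerateHistogram("need at least two occupied bins")
    first, last = int(occupied[0]), int(occupied[-1])

    csum = np.cumsum(counts)
    cmass = np.cumsum(counts * np.arange(256, dtype=np.int64))
    total, tmass = int(csum[-1]), int(cmass[-1])

    def step(t: int) -> int:
        lo_n, lo_m = int(csum[t]), int(cmass[t])
        mu_lo = lo_m / lo_n
        mu_hi = (tmass - lo_m) / (total - lo_n)
        return _round_half_up((mu_lo + mu_hi) / 2.0)

    t = (first + last) // 2
    seen: set[int] = set()
    while t not in seen:
        seen.add(t)
        nxt = min(max(step(t), first), last - 1)
        if nxt == t:
            break
        t = nxt
    return int(t)


def apply_threshold(
    channel: np.ndarray, t: int, region: np.ndarray | None = None
) -> np.ndarray:
    """Boolean mask of pixels with stain amount strictly above ``t``."""
    if not 0 <= int(t) <= 255:
        raise ValueError(f"threshold must be in [0, 255], got {t}")
    channel = np.asarray(channel)
    mask = channel > int(t)
    if region is not None:
        region = np.asarray(region, dtype=bool)
        if region.shape != channel.shape:
            raise DimensionMismatch("region shape does not match channel")
        mask &= region
    return mask


def binary_closing(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    """Morphological closing: n dilations then n erosions, 3x3 square element.

    Outside-image pixels count as background for the dilation; the erosion
    treats them as foreground so the closing is extensive (output contains
    the input) right up to the image border.
    """
    if iterations < 1:
        raise ValueError(f"iterations must be >= 1, got {iterations}")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    dilated = ndimage.binary_dilation(
        mask, structure=_STRUCT_3X3, iterations=iterations, border_value=0
    )
    return ndimage.binary_erosion(
        dilated, structure=_STRUCT_3X3, iterations=iterations, border_value=1
    )


def build_tissue_mask(
    blue_channel: np.ndarray,
    sigma: float = 2.0,
    iterations: int = 1,
    return_threshold: bool = False,
):
    """Fibrous-tissue mask from the collagen channel.

    Pipeline: Gaussian blur -> whole-image histogram with bin 0 ignored ->
    iterative-intermeans threshold -> binarize -> binary closing.

    Returns the boolean mask, or ``(mask, threshold)`` when
    ``return_threshold`` is set (thresholds are worth logging: they are
    image-dependent and otherwise invisible).
    """
    blurred = gaussian_blur(blue_channel, sigma=sigma)
    hist = build_histogram(blurred, ignore_black=True)
    t = default_threshold(hist)
    mask = binary_closing(apply_threshold(blurred, t), iterations=iterations)
    if return_threshold:
        return mask, t
    return mask


def combine_and(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pixelwise conjunction of two masks of identical shape."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise DimensionMismatch(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a & b
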