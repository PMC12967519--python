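"""Calibrated histomorphometric features per image and stain.

For each image the pipeline measures, inside the AND of the tissue mask with
each stain's thresholded region: calibrated areas (pixels / (px_per_mm)^2),
area ratios in percent, and the gray-level distribution of the stain-amount
channel (mean, median, SD, min, max, skewness, excess kurtosis).

Conventions: SD uses the n-1 denominator while skewness and kurtosis use
population moments (n), matching common image-measurement tools; kurtosis is
excess (normal = 0, so a flat/platykurtic distribution is negative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateHistogram, EmptyRegion
from .segmentation import (
    apply_threshold,
    build_histogram,
    build_tissue_mask,
    combine_and,
    default_threshold,
)
from .stain_model import StainBasis, concentration_to_channel, deconvolve


@dataclass(frozen=True)
class Calibration:
    """Spatial calibration: image pixels per millimetre (default 473)."""

    px_per_mm: float = 473.0

    def __post_init__(self) -> None:
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be > 0")


def area_mm2(pixel_count: int, calib: Calibration) -> float:
    """Convert a pixel count to square millimetres."""
    if pixel_count < 0:
        raise ValueError("pixel_count must be >= 0")
    return pixel_count / calib.px_per_mm**2


@dataclass(frozen=True)
class RegionIntensityStats:
    """Gray-level distribution summary of one region of an 8-bit channel."""

    mean: float
    median: float
    sd: float
    min: float
    max: float
    skewness: float
    kurtosis_excess: float
    n: int


def _empty_stats() -> RegionIntensityStats:
    nan = float("nan")
    return RegionIntensityStats(nan, nan, nan, nan, nan, nan, nan, 0)


def region_stats(channel: np.ndarray, region: np.ndarray) -> RegionIntensityStats:
    """Distribution statistics of ``channel`` over the pixels in ``region``.

    Skewness is ``m3 / m2**1.5`` and excess kurtosis ``m4 / m2**2 - 3`` with
    population central moments ``m_k``; both are NaN for a constant region.
    """
    channel = np.asarray(channel)
    region = np.asarray(region, dtype=bool)
    if region.shape != channel.shape:
        raise ValueError("region shape does not match channel")
    vals = channel[region].astype(np.float64)
    n = vals.size
    if n == 0:
        raise EmptyRegion("region_stats on an empty region")
    mean = float(vals.mean())
    dev = vals - mean
    m2 = float(np.mean(dev**2))
    if m2 > 0:
        skew = float(np.mean(dev**3)) / m2**1.5
        kurt = float(np.mean(dev**4)) / m2**2 - 3.0
    else:
        skew = kurt = float("nan")
    sd = float(math.sqrt(float(np.sum(dev**2)) / (n - 1))) if n > 1 else 0.0
    return RegionIntensityStats(
        mean=mean,
        median=float(np.median(vals)),
        sd=sd,
        min=float(vals.min()),
        max=float(vals.max()),
        skewness=skew,
        kurtosis_excess=kurt,
        n=int(n),
    )


@dataclass(frozen=True)
class PipelineParams:
    """Tunable knobs of the measurement pipeline.

    ``threshold_scope`` picks the histogram used for per-stain thresholds:
    ``"image"`` (whole image, then AND with the mask — the default ordering)
    or ``"mask"`` (histogram restricted to the tissue mask).
    """

    sigma: float = 2.0
    closing_iterations: int = 1
    threshold_scope: str = "image"

    def __post_init__(self) -> None:
        if self.threshold_scope not in ("image", "mask"):
            raise ValueError("threshold_scope must be 'image' or 'mask'")


@dataclass(frozen=True)
class FeatureRecord:
    """All measured quantities for one image x one stain."""

    image_id: str
    stain_label: str
    mask_area_mm2: float
    thresholded_area_mm2: float
    thresholded_to_mask_pct: float
    mask_to_image_pct: float
    intensity: RegionIntensityStats
    threshold: int | None = None          # chosen stain threshold (for logs)
    mask_threshold: int | None = None     # chosen tissue-mask threshold


@dataclass(frozen=True)
class PairedRecord:
    """Cross-stain ratios for one image (paired by image_id)."""

    image_id: str
    red_to_blue_area_ratio_pct: float
    sum_to_mask_ratio_pct: float


def _stain_region(channel, tissue_mask, scope):
    """Thresholded-AND region for one stain channel; empty if degenerate."""
    region = tissue_mask if scope == "mask" else None
    try:
        hist = build_histogram(channel, region=region, ignore_black=True)
        t = default_threshold(hist)
    except (DegenerateHistogram, EmptyRegion):
        return np.zeros_like(tissue_mask), None
    return combine_and(apply_threshold(channel, t), tissue_mask), t


def extract_features(
    rgb: np.ndarray,
    basis: StainBasis | None = None,
    calib: Calibration | None = None,
    params: PipelineParams | None = None,
    image_id: str = "image",
) -> tuple[FeatureRecord, FeatureRecord, PairedRecord]:
    """Run the full measurement pipeline on one RGB photomicrograph.

    Steps: color deconvolution -> 8-bit stain channels -> tissue mask from
    the blue-green channel -> per-stain auto-threshold -> AND with the mask
    -> calibrated areas, ratios and intensity statistics per stain.

    Returns ``(blue_record, red_record, paired_record)``.  A stain whose
    channel is entirely black (e.g. a fixture with no red dye) yields a zero
    thresholded area and NaN intensity statistics.
    """
    basis = basis or StainBasis.masson_default()
    calib = calib or Calibration()
    params = params or PipelineParams()

    conc = deconvolve(rgb, basis)
    channels = {
        basis.stain1.label: concentration_to_channel(conc[..., 0]),
        basis.stain2.label: concentration_to_channel(conc[..., 1]),
    }
    blue_label, red_label = basis.labels

    tissue, mask_t = build_tissue_mask(
        channels[blue_label],
        sigma=params.sigma,
        iterations=params.closing_iterations,
        return_threshold=True,
    )
    n_pixels = tissue.size
    mask_count = int(tissue.sum())
    mask_area = area_mm2(mask_count, calib)

    records = {}
    areas = {}
    for label, channel in channels.items():
        and_mask, t = _stain_region(channel, tissue, params.threshold_scope)
        count = int(and_mask.sum())
        stats = region_stats(channel, and_mask) if count else _empty_stats()
        area = area_mm2(count, calib)
        areas[label] = area
        records[label] = FeatureRecord(
            image_id=image_id,
            stain_label=label,
            mask_area_mm2=mask_area,
            thresholded_area_mm2=area,
            thresholded_to_mask_pct=100.0 * count / mask_count if mask_count else float("nan"),
            mask_to_image_pct=100.0 * mask_count / n_pixels,
            intensity=stats,
            threshold=t,
            mask_threshold=mask_t,
        )

    blue_area, red_area = areas[blue_label], areas[red_label]
    paired = PairedRecord(
        image_id=image_id,
        red_to_blue_area_ratio_pct=(
            100.0 * red_area / blue_area if blue_area > 0 else float("nan")
        ),
        sum_to_mask_ratio_pct=(
            100.0 * (blue_area + red_area) / mask_area if mask_area > 0 else float("nan")
        ),
    )
    return records[blue_label], records[red_label], paired


#: Column order of the tidy features table (one row per image x stain).
FEATURE_COLUMNS = [
    "image_id", "stain", "mask_area_mm2", "thresh_area_mm2",
    "thresh_to_mask_pct", "mask_to_image_pct", "mean", "median", "sd",
    "min", "max", "skewness", "kurtosis",
]

PAIRED_COLUMNS = ["image_id", "red_to_blue_area_ratio_pct", "sum_to_mask_ratio_pct"]


def records_to_frame(records: list[FeatureRecord]) -> pd.DataFrame:
    """Tidy DataFrame of feature records with the canonical column order."""
    rows = []
    for r in records:
        s = r.intensity
        rows.append({
            "image_id": r.image_id,
            "stain": r.stain_label,
            "mask_area_mm2": r.mask_area_mm2,
            "thresh_area_mm2": r.thresholded_area_mm2,
            "thresh_to_mask_pct": r.thresholded_to_mask_pct,
            "mask_to_image_pct": r.mask_to_image_pct,
            "mean": s.mean,
            "median": s.median,
            "sd": s.sd,
            "min": s.min,
            "max": s.max,
            "skewness": s.skewness,
            "kurtosis": s.kurtosis_excess,
        })
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def paired_to_frame(records: list[PairedRecord]) -> pd.DataFrame:
    rows = [
        {
            "image_id": r.image_id,
            "red_to_blue_area_ratio_pct": r.red_to_blue_area_ratio_pct,
            "sum_to_mask_ratio_pct": r.sum_to_mask_ratio_pct,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=PAIRED_COLUMNS)
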