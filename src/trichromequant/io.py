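"""File formats: images, masks, ROI definitions, CSV tables, run configs.

Coordinate conventions are 0-based with the origin at the top-left corner;
rectangles are half-open in both axes (``x <= col < x + width``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .errors import IOFailure, MissingROI
from .features import FEATURE_COLUMNS, PAIRED_COLUMNS
from .stain_model import StainVector

# --- images ------------------------------------------------------------------


def read_image(path) -> np.ndarray:
    """Read a TIFF/PNG/JPEG image as an (H, W, 3) uint8 RGB array.

    Grayscale inputs are replicated across channels; an alpha channel is
    dropped; 16-bit data is rescaled to 8 bits.
    """
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises several backend-specific types
        raise IOFailure(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3:
        raise IOFailure(f"unsupported image layout {arr.shape} in {path}")
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.shape[-1] != 3:
        raise IOFailure(f"expected 1, 3 or 4 channels in {path}")
    if arr.dtype == np.uint16:
        arr = (arr.astype(np.float64) / 257.0).round().astype(np.uint8)
    elif arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return arr


def write_image(path, rgb: np.ndarray) -> None:
    iio.imwrite(Path(path), np.asarray(rgb, dtype=np.uint8))


def write_mask_png(path, mask: np.ndarray) -> None:
    """Serialize a boolean mask as an 8-bit PNG (0 = out, 255 = in)."""
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_mask_png(path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0


# --- run-length mask serialization ------------------------------------------


def mask_to_rle(mask: np.ndarray) -> pd.DataFrame:
    """Row-wise run-length encoding: columns row, start, length."""
    mask = np.asarray(mask, dtype=bool)
    rows, starts, lengths = [], [], []
    for r in range(mask.shape[0]):
        line = mask[r]
        diff = np.diff(line.astype(np.int8))
        run_starts = np.flatnonzero(diff == 1) + 1
        run_ends = np.flatnonzero(diff == -1) + 1
        if line[0]:
            run_starts = np.r_[0, run_starts]
        if line[-1]:
            run_ends = np.r_[run_ends, line.size]
        for s, e in zip(run_starts, run_ends):
            rows.append(r)
            starts.append(int(s))
            lengths.append(int(e - s))
    return pd.DataFrame({"row": rows, "start": starts, "length": lengths})


def rle_to_mask(rle: pd.DataFrame, shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for _, run in rle.iterrows():
        mask[int(run["row"]), int(run["start"]):int(run["start"] + run["length"])] = True
    return mask


def write_mask_rle_csv(path, mask: np.ndarray) -> None:
    mask_to_rle(mask).to_csv(path, index=False)


def read_mask_rle_csv(path, shape: tuple[int, int]) -> np.ndarray:
    return rle_to_mask(pd.read_csv(path), shape)


# --- ROI files ---------------------------------------------------------------


@dataclass(frozen=True)
class RectROI:
    """Named axis-aligned rectangle (0-based, top-left origin, half-open)."""

    label: str
    x: int
    y: int
    width: int
    height: int

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        mask[self.y:self.y + self.height, self.x:self.x + self.width] = True
        return mask


@dataclass(frozen=True)
class PolygonROI:
    """Named polygon given as an (N, 2) array of (x, y) vertices."""

    label: str
    vertices: np.ndarray

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        from skimage.draw import polygon

        v = np.asarray(self.vertices, dtype=np.float64)
        rr, cc = polygon(v[:, 1], v[:, 0], shape=shape)
        mask = np.zeros(shape, dtype=bool)
        mask[rr, cc] = True
        return mask


def parse_roi_file(path) -> dict:
    """Parse a plain-text ROI file into ``{label: ROI}``.

    One ROI per non-comment line, either::

        label x y width height
        label poly x1 y1 x2 y2 x3 y3 ...
    """
    rois: dict = {}
    text = Path(path).read_text()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        label = parts[0]
        try:
            if len(parts) >= 2 and parts[1] == "poly":
                nums = [float(v) for v in parts[2:]]
                if len(nums) < 6 or len(nums) % 2:
                    raise ValueError("polygon needs >= 3 (x, y) vertex pairs")
                rois[label] = PolygonROI(label, np.array(nums).reshape(-1, 2))
            elif len(parts) == 5:
                x, y, w, h = (int(v) for v in parts[1:])
                if w <= 0 or h <= 0:
                    raise ValueError("rectangle width/height must be > 0")
                rois[label] = RectROI(label, x, y, w, h)
            else:
                raise ValueError("expected 'label x y w h' or 'label poly ...'")
        except ValueError as exc:
            raise IOFailure(f"{path}:{lineno}: {exc}") from exc
    return rois


def require_rois(rois: dict, *labels: str) -> None:
    missing = [lab for lab in labels if lab not in rois]
    if missing:
        raise MissingROI(f"ROI file is missing required ROIs: {missing}")


# --- stain-vector CSV --------------------------------------------------------


def write_vectors_csv(path, vectors: list[StainVector]) -> None:
    """Write stain vectors as a CSV with columns label, R, G, B."""
    pd.DataFrame(
        [{"label": v.label, "R": v.v[0], "G": v.v[1], "B": v.v[2]} for v in vectors]
    ).to_csv(path, index=False, float_format="%.4f")


def read_vectors_csv(path) -> list[StainVector]:
    df = pd.read_csv(path)
    return [
        StainVector.from_raw(row["label"], (row["R"], row["G"], row["B"]))
        for _, row in df.iterrows()
    ]


# --- feature tables ----------------------------------------------------------


def write_features_csv(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False, columns=FEATURE_COLUMNS)


def read_features_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_paired_csv(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False, columns=PAIRED_COLUMNS)


# --- run configuration -------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Batch-run configuration with built-in defaults.

    Precedence is CLI flag > config file > these defaults (the default
    stain vectors, blur sigma 2.0, 1 closing iteration, 473 px/mm,
    alpha 0.05).
    """

    stain1: tuple = (0.8001, 0.4070, 0.4407)
    stain2: tuple = (0.4311, 0.7154, 0.5498)
    stain1_label: str = "blue_green"
    stain2_label: str = "red_pink"
    sigma: float = 2.0
    closing_iterations: int = 1
    px_per_mm: float = 473.0
    alpha: float = 0.05
    threshold_scope: str = "image"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be > 0")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


def load_run_config(path) -> RunConfig:
    """Load a YAML config file; keys mirror `RunConfig` field names."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise IOFailure(f"unknown config keys in {path}: {sorted(unknown)}")
    for key in ("stain1", "stain2"):
        if key in data:
            data[key] = tuple(float(v) for v in data[key])
    return RunConfig(**data)


def merge_config(cfg: RunConfig, **overrides) -> RunConfig:
    """Apply non-None CLI overrides on top of a config."""
    updates = {k: v for k, v in overrides.items() if v is not None}
    return replace(cfg, **updates) if updates else cfg
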