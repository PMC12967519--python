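"""Beer-Lambert stain separation for brightfield trichrome micrographs.

A dye on a brightfield slide attenuates the three camera channels
multiplicatively, so each pixel is moved to optical-density (OD) space,

    od_c = -log10((I_c + 1) / 256),        c in {R, G, B},

where the ``+1``/``/256`` offsets keep the transform finite at ``I = 0``.
In OD space the contributions of co-localised dyes add linearly (the
Beer-Lambert approximation): a pixel carrying amounts ``a`` and ``b`` of two
dyes with unit absorbance directions ``v1`` and ``v2`` has

    od = a * v1 + b * v2.

Color deconvolution is the per-pixel solve of that linear system.  A third,
orthogonal "residual" axis completes the 3x3 matrix so it is invertible; its
coefficient absorbs everything the two dyes cannot explain.

Note the counter-intuitive channel order of absorbance: a blue-green dye
absorbs mostly *red* light, hence its vector leads with a large R component
(e.g. the Masson's-trichrome collagen vector (0.8001, 0.4070, 0.4407)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    CollinearVectors,
    DegenerateROI,
    EmptyROI,
    SingularBasis,
)

#: Largest optical density representable by an 8-bit channel: -log10(1/256).
MAX_OD = float(np.log10(256.0))

#: Default Masson's-trichrome absorbance directions (unit RGB-OD vectors),
#: estimated from dermal collagen (blue-green, aniline blue) and panniculus
#: carnosus muscle (red-pink, Biebrich scarlet / acid fuchsin) reference
#: regions.
BLUE_GREEN_RGB = (0.8001, 0.4070, 0.4407)
RED_PINK_RGB = (0.4311, 0.7154, 0.5498)


# --- RGB <-> optical density ----------------------------------------------

def _check_rgb(rgb: np.ndarray) -> None:
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError(f"expected an HxWx3 RGB array, got shape {rgb.shape}")
    if rgb.min() < 0 or rgb.max() > 255:
        raise ValueError("RGB intensities must lie in [0, 255]")


def rgb_to_od(rgb: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to per-channel optical density.

    Parameters
    ----------
    rgb
        ``(H, W, 3)`` integer array with values in ``[0, 255]``.

    Returns
    -------
    ``(H, W, 3)`` float64 array with values in ``[0, MAX_OD]``.
    """
    rgb = np.asarray(rgb)
    _check_rgb(rgb)
    return -np.log10((rgb.astype(np.float64) + 1.0) / 256.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Render optical densities back to 8-bit RGB (inverse of `rgb_to_od`).

    Negative inputs (floating-point residue of a round trip) are treated as
    zero absorbance; densities beyond `MAX_OD` clamp to black.
    """
    od = np.asarray(od, dtype=np.float64)
    vals = np.rint(256.0 * np.power(10.0, -np.clip(od, 0.0, None)) - 1.0)
    return np.clip(vals, 0, 255).astype(np.uint8)


# --- stain vectors and bases -----------------------------------------------

@dataclass(frozen=True)
class StainVector:
    """Unit 3-vector of per-channel optical densities for one dye."""

    label: str
    v: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.v, dtype=np.float64).reshape(3)
        norm = float(np.linalg.norm(v))
        if abs(norm - 1.0) > 1e-6:
            raise ValueError(
                f"stain vector {self.label!r} is not unit length (|v|={norm:.6f})"
            )
        if not (v > 0).any():
            raise ValueError(f"stain vector {self.label!r} has no positive component")
        object.__setattr__(self, "v", v)

    @classmethod
    def from_raw(cls, label: str, components) -> "StainVector":
        """Normalize an arbitrary non-zero 3-vector into a `StainVector`."""
        v = np.asarray(components, dtype=np.float64).reshape(3)
        norm = float(np.linalg.norm(v))
        if norm <= 1e-6:
            raise DegenerateROI(f"cannot normalize near-zero vector for {label!r}")
        return cls(label, v / norm)


def estimate_stain_vector(
    od: np.ndarray, roi: np.ndarray | None = None, label: str = "stain"
) -> StainVector:
    """Estimate a dye's absorbance direction from an ROI of an OD image.

    The direction is the unit-normalized mean OD triplet over the ROI, the
    convention used when deriving custom vectors from a reference region
    (dermal collagen, muscle) instead of trusting software presets.

    Parameters
    ----------
    od
        ``(H, W, 3)`` optical-density image.
    roi
        Boolean ``(H, W)`` mask of the pixels to average, or ``None`` for the
        whole image.

    Raises
    ------
    EmptyROI
        If the ROI selects no pixels.
    DegenerateROI
        If the mean OD is numerically zero (a blank/white region).
    """
    od = np.asarray(od, dtype=np.float64)
    if od.ndim != 3 or od.shape[-1] != 3:
        raise ValueError("expected an HxWx3 OD array")
    if roi is None:
        sel = od.reshape(-1, 3)
    else:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != od.shape[:2]:
            raise ValueError("ROI shape does not match image")
        sel = od[roi]
    if sel.shape[0] == 0:
        raise EmptyROI(f"ROI for {label!r} selects no pixels")
    mean = sel.mean(axis=0)
    norm = float(np.linalg.norm(mean))
    if norm <= 1e-6:
        raise DegenerateROI(
            f"ROI for {label!r} is blank (mean OD norm {norm:.2e})"
        )
    return StainVector(label, mean / norm)


def complement_vector(v1: StainVector, v2: StainVector) -> StainVector:
    """Unit cross product of two stain vectors: the residual third axis.

    Negative components are allowed — this axis is a mathematical complement,
    never rendered as a stain.
    """
    cross = np.cross(v1.v, v2.v)
    norm = float(np.linalg.norm(cross))
    if norm < 1e-6:
        raise CollinearVectors(
            f"stain vectors {v1.label!r} and {v2.label!r} are collinear"
        )
    cross = cross / norm
    # Orientation is irrelevant (only the span matters for unmixing the two
    # real stains); pick the sign with a positive component so the vector
    # satisfies the shared StainVector contract.
    if not (cross > 0).any():
        cross = -cross
    return StainVector("complement", cross)


@dataclass(frozen=True)
class StainBasis:
    """Two named stain vectors plus their computed orthogonal complement.

    ``matrix`` stacks the three unit vectors as rows; a pixel's OD relates to
    its concentrations by ``od = matrix.T @ conc``.
    """

    stain1: StainVector
    stain2: StainVector
    complement: StainVector = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.complement is None:
            object.__setattr__(
                self, "complement", complement_vector(self.stain1, self.stain2)
            )

    @property
    def matrix(self) -> np.ndarray:
        return np.vstack([self.stain1.v, self.stain2.v, self.complement.v])

    @property
    def labels(self) -> tuple[str, str]:
        return (self.stain1.label, self.stain2.label)

    @classmethod
    def from_vectors(cls, stain1: StainVector, stain2: StainVector) -> "StainBasis":
        return cls(stain1, stain2)

    @classmethod
    def masson_default(cls) -> "StainBasis":
        """The default Masson's-trichrome basis (collagen + muscle vectors)."""
        return cls(
            StainVector.from_raw("blue_green", BLUE_GREEN_RGB),
            StainVector.from_raw("red_pink", RED_PINK_RGB),
        )


# --- deconvolution ----------------------------------------------------------

def deconvolve_od(od: np.ndarray, basis: StainBasis) -> np.ndarray:
    """Unmix an OD image into per-stain concentration planes.

    Solves ``matrix.T @ conc = od`` per pixel. Small negative concentrations
    (cross-talk noise) are preserved, keeping the solve exactly linear;
    clipping happens only at 8-bit rendering.
    """
    od = np.asarray(od, dtype=np.float64)
    m = basis.matrix
    if np.linalg.cond(m) > 1e12:
        raise SingularBasis("stain matrix is numerically singular")
    flat = od.reshape(-1, 3)
    conc = np.linalg.solve(m.T, flat.T).T
    return conc.reshape(od.shape)


def deconvolve(rgb: np.ndarray, basis: StainBasis) -> np.ndarray:
    """Color deconvolution: 8-bit RGB image -> (H, W, 3) concentration image.

    Plane 0 is ``basis.stain1``, plane 1 is ``basis.stain2``, plane 2 the
    residual along the complement axis.
    """
    return deconvolve_od(rgb_to_od(rgb), basis)


def concentration_to_channel(conc_plane: np.ndarray) -> np.ndarray:
    """Render one concentration plane as an 8-bit stain-amount channel.

    The dye's ideal transmittance is ``T = 255 * 10**(-c)``; the channel
    stores ``255 - T`` so that larger values mean more stain (a fully
    saturated pixel, ``c >= ~2.71``, reads 255; no stain reads 0). Negative
    concentrations clamp to 0.
    """
    c = np.asarray(conc_plane, dtype=np.float64)
    t = np.clip(np.rint(255.0 * np.power(10.0, -c)), 0, 255)
    return (255 - t).astype(np.uint8)


def recompose(conc: np.ndarray, basis: StainBasis) -> np.ndarray:
    """Rebuild the RGB image implied by a concentration image (round trip)."""
    conc = np.asarray(conc, dtype=np.float64)
    od = conc.reshape(-1, 3) @ basis.matrix
    return od_to_rgb(od.reshape(conc.shape))
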