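"""Synthetic trichrome-stained skin scenes with known ground truth.

Each scene emulates a full-thickness rodent-skin photomicrograph stained
with Masson's trichrome, laid out top to bottom: bright (unstained)
background, a thin red-staining epidermis, a dermis band of blue-green
collagen bundles separated by unstained "cracks" and pierced by elliptical
unstained adnexal voids (follicles), a red-pink panniculus-carnosus muscle
band, and background again.  Concentration fields for the two dyes are
composed to RGB through the Beer-Lambert model (``od = c1*v1 + c2*v2``)
and additive Gaussian sensor noise is applied in RGB space.

Ground truth (band masks, bundle mask, the true collagen fraction of the
dermis, and both concentration fields) is returned alongside the image so
that pipeline measurements can be checked against construction.

Randomness: a single integer seed drives one generator; the draw order is
fixed (1 bundle texture field, 2 cytoplasm texture field, 3 crack paths,
4 follicle geometry, 5 sensor noise) so scenes are stable across versions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import InvalidParams, IOFailure
from .stain_model import StainBasis, od_to_rgb


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic scene.

    Defaults mirror the acquisition geometry of the emulated study
    (1832 x 1321 px, 8-bit RGB) and a mid-range dermal composition: the
    dermis occupies ~45 % of image height (the tissue mask then covers
    roughly 40 % of the image), collagen bundles fill 60 % of the dermis,
    and the peak collagen dye concentration of 3.0 saturates the 8-bit
    stain channel (gray value 255) inside the densest bundles.
    """

    width_px: int = 1832
    height_px: int = 1321
    dermis_fraction: float = 0.45
    collagen_fill: float = 0.6
    crack_width_px: int = 3
    muscle_band_fraction: float = 0.12
    n_follicles: int = 6
    peak_blue_conc: float = 3.0
    peak_red_conc: float = 2.2
    noise_sd: float = 2.0
    seed: int = 0
    # secondary texture knobs
    epidermis_fraction: float = 0.03
    interbundle_blue_conc: float = 0.28
    dermis_red_fill: float = 0.12
    texture_sigma: float = 6.0

    def validate(self) -> None:
        if self.width_px < 64 or self.height_px < 64:
            raise InvalidParams("image dimensions must be at least 64 px")
        for name in ("dermis_fraction", "collagen_fill", "muscle_band_fraction",
                     "epidermis_fraction", "dermis_red_fill"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParams(f"{name} must lie in [0, 1], got {v}")
        if self.dermis_fraction + self.muscle_band_fraction + self.epidermis_fraction > 1.0:
            raise InvalidParams("tissue bands exceed the image height")
        for name in ("peak_blue_conc", "peak_red_conc", "interbundle_blue_conc"):
            if getattr(self, name) < 0:
                raise InvalidParams(f"{name} must be >= 0")
        if self.noise_sd < 0:
            raise InvalidParams("noise_sd must be >= 0")
        if self.crack_width_px < 0 or self.n_follicles < 0:
            raise InvalidParams("crack_width_px and n_follicles must be >= 0")
        if self.texture_sigma <= 0:
            raise InvalidParams("texture_sigma must be > 0")


@dataclass(frozen=True)
class GroundTruth:
    """Construction-time truth for one scene."""

    dermis_mask: np.ndarray     # dermis band minus follicle voids
    bundle_mask: np.ndarray     # stained collagen bundles (subset of dermis)
    muscle_mask: np.ndarray
    follicle_mask: np.ndarray
    true_collagen_fraction_of_dermis: float
    conc_blue: np.ndarray
    conc_red: np.ndarray


def _carve_cracks(rng, shape, r0, r1, width):
    """Thin random-walk polylines of unstained pixels through the dermis."""
    h, w = shape
    crack = np.zeros(shape, dtype=bool)
    if width <= 0 or r1 <= r0:
        return crack
    n_cracks = max(2, w // 120)
    rows = np.arange(r0, r1)
    for _ in range(n_cracks):
        x0 = rng.uniform(0, w)
        path = x0 + np.cumsum(rng.normal(0.0, 1.2, size=rows.size))
        cols = np.rint(path).astype(int)
        for off in range(-(width // 2), width - width // 2):
            cc = np.clip(cols + off, 0, w - 1)
            crack[rows, cc] = True
    return crack


def _place_follicles(rng, shape, r0, r1, n):
    """Elliptical unstained voids inside the dermis band."""
    h, w = shape
    foll = np.zeros(shape, dtype=bool)
    band_h = r1 - r0
    if n <= 0 or band_h < 8:
        return foll
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n):
        cy = rng.uniform(r0 + 0.15 * band_h, r1 - 0.15 * band_h)
        cx = rng.uniform(0.05 * w, 0.95 * w)
        a = rng.uniform(0.05, 0.10) * band_h          # vertical semi-axis
        b = a * rng.uniform(0.7, 1.6)                 # horizontal semi-axis
        ell = ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0
        foll |= ell
    foll[:r0] = False
    foll[r1:] = False
    return foll


def generate_scene(
    params: SceneParams, basis: StainBasis | None = None
) -> tuple[np.ndarray, GroundTruth]:
    """Generate one synthetic trichrome scene and its ground truth.

    Deterministic for a fixed ``params.seed``.  Bundles are the top
    ``collagen_fill`` quantile of a Gaussian-smoothed white-noise field over
    the dermis (cracks excluded), which pins the true collagen fraction of
    the dermis to ``collagen_fill`` exactly (up to one pixel).  Bundle dye
    concentration ramps with the texture field up to ``peak_blue_conc``;
    inter-bundle dermis carries a light ground-substance blue (absent when
    ``collagen_fill`` is zero, i.e. no collagen at all), and scattered
    cytoplasm patches carry red.  The muscle band is red with its own
    texture; the epidermis is uniformly red (keratin).
    """
    p = params
    p.validate()
    basis = basis or StainBasis.masson_default()
    rng = np.random.default_rng(p.seed)
    h, w = p.height_px, p.width_px

    # band geometry (rows), vertical layout centred in the frame
    e = int(round(h * p.epidermis_fraction))
    d = int(round(h * p.dermis_fraction))
    m = int(round(h * p.muscle_band_fraction))
    top = max(0, (h - e - d - m) // 2)
    r_e0, r_e1 = top, top + e
    r_d0, r_d1 = top + e, top + e + d
    r_m0, r_m1 = r_d1, min(h, r_d1 + m)

    rows = np.arange(h)[:, None]
    dermis_band = np.broadcast_to((rows >= r_d0) & (rows < r_d1), (h, w))
    muscle_mask = np.broadcast_to((rows >= r_m0) & (rows < r_m1), (h, w)).copy()
    epi_mask = np.broadcast_to((rows >= r_e0) & (rows < r_e1), (h, w))

    # draws, in documented order
    z = ndimage.gaussian_filter(rng.standard_normal((h, w)), p.texture_sigma)
    z2 = ndimage.gaussian_filter(rng.standard_normal((h, w)), p.texture_sigma)
    crack = _carve_cracks(rng, (h, w), r_d0, r_d1, p.crack_width_px)
    follicle = _place_follicles(rng, (h, w), r_d0, r_d1, p.n_follicles)

    dermis_mask = dermis_band & ~follicle
    n_dermis = int(dermis_mask.sum())

    # bundles: exact top-quantile selection of the texture field
    eligible = dermis_mask & ~crack
    k = int(round(p.collagen_fill * n_dermis))
    k = min(k, int(eligible.sum()))
    bundle = np.zeros((h, w), dtype=bool)
    if k > 0:
        flat_idx = np.flatnonzero(eligible)
        zvals = z.ravel()[flat_idx]
        order = np.argpartition(zvals, zvals.size - k)[zvals.size - k:]
        bundle.ravel()[flat_idx[order]] = True
    true_frac = k / n_dermis if n_dermis else 0.0

    # concentration fields
    conc_blue = np.zeros((h, w))
    if p.collagen_fill > 0:
        ground = dermis_mask & ~bundle & ~crack
        conc_blue[ground] = p.interbundle_blue_conc
    if k > 0 and p.peak_blue_conc > 0:
        zb = z[bundle]
        lo = min(1.0, 0.45 * p.peak_blue_conc)
        span = zb.max() - zb.min()
        t = (zb - zb.min()) / span if span > 0 else np.ones_like(zb)
        conc_blue[bundle] = lo + (p.peak_blue_conc - lo) * t

    conc_red = np.zeros((h, w))
    conc_red[epi_mask] = 0.6 * p.peak_red_conc
    if muscle_mask.any() and p.peak_red_conc > 0:
        zm = z[muscle_mask]
        span = zm.max() - zm.min()
        t = (zm - zm.min()) / span if span > 0 else np.ones_like(zm)
        conc_red[muscle_mask] = p.peak_red_conc * (0.55 + 0.45 * t)
    # scattered strongly-red cytoplasm patches inside the dermis, drawn from
    # an independent texture field (may overlap bundles: dyes add in OD)
    cyto_candidates = dermis_mask & ~crack
    if p.dermis_red_fill > 0 and cyto_candidates.any():
        zc = z2[cyto_candidates]
        thr = np.quantile(zc, 1.0 - p.dermis_red_fill)
        cyto = np.zeros((h, w), dtype=bool)
        cyto[cyto_candidates] = zc >= thr
        conc_red[cyto] = 0.6 * p.peak_red_conc

    # Beer-Lambert composition + sensor noise in RGB space
    od = (conc_blue[..., None] * basis.stain1.v
          + conc_red[..., None] * basis.stain2.v)
    rgb = od_to_rgb(od).astype(np.float64)
    if p.noise_sd > 0:
        rgb += rng.normal(0.0, p.noise_sd, size=rgb.shape)
    rgb8 = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)

    truth = GroundTruth(
        dermis_mask=dermis_mask,
        bundle_mask=bundle,
        muscle_mask=muscle_mask & ~dermis_mask,
        follicle_mask=follicle,
        true_collagen_fraction_of_dermis=float(true_frac),
        conc_blue=conc_blue,
        conc_red=conc_red,
    )
    return rgb8, truth


# --- fixture suite ----------------------------------------------------------

def _band_image(h, w, conc_blue_band=None, conc_red_band=None,
                basis: StainBasis | None = None):
    """Noise-free image with uniform horizontal/vertical stain bands."""
    basis = basis or StainBasis.masson_default()
    cb = np.zeros((h, w))
    cr = np.zeros((h, w))
    if conc_blue_band is not None:
        sl, conc = conc_blue_band
        cb[sl] = conc
    if conc_red_band is not None:
        sl, conc = conc_red_band
        cr[sl] = conc
    od = cb[..., None] * basis.stain1.v + cr[..., None] * basis.stain2.v
    return od_to_rgb(od)


def make_fixture_suite(out_dir, scene_size=(360, 480)) -> dict:
    """Write a standard fixture suite with ground-truth sidecars.

    Contents: a noise-free single-stain band image, a two-stain disjoint
    image, realistic skin scenes at collagen fills {0.3, 0.5, 0.7} x seeds
    {1, 2, 3}, and a degenerate all-white image — 12 images in total, plus
    per-scene ground-truth mask PNGs, JSON sidecars and a manifest.
    """
    from . import io as tio  # local import to avoid a cycle at import time

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOFailure(f"cannot create fixture directory {out}: {exc}") from exc

    h, w = scene_size
    manifest: dict = {"images": []}

    def _add(name, **meta):
        manifest["images"].append({"file": name, **meta})

    try:
        # 1. noise-free single stain (blue band)
        img = _band_image(256, 256, conc_blue_band=(np.s_[64:192, :], 1.0))
        tio.write_image(out / "single_stain_blue.png", img)
        _add("single_stain_blue.png", kind="single_stain",
             stain="blue_green", conc=1.0, band_rows=[64, 192])

        # 2. two-stain disjoint halves
        img = _band_image(
            256, 256,
            conc_blue_band=(np.s_[64:192, :128], 1.0),
            conc_red_band=(np.s_[64:192, 128:], 1.0),
        )
        tio.write_image(out / "two_stain_disjoint.png", img)
        _add("two_stain_disjoint.png", kind="two_stain_disjoint", conc=1.0)

        # 3. realistic scenes: 3 fills x 3 seeds
        for fill in (0.3, 0.5, 0.7):
            for seed in (1, 2, 3):
                params = SceneParams(
                    width_px=w, height_px=h, collagen_fill=fill, seed=seed
                )
                rgb, truth = generate_scene(params)
                stem = f"scene_fill{int(round(fill * 100)):03d}_seed{seed}"
                tio.write_image(out / f"{stem}.png", rgb)
                tio.write_mask_png(out / f"{stem}_dermis.png", truth.dermis_mask)
                tio.write_mask_png(out / f"{stem}_bundles.png", truth.bundle_mask)
                sidecar = {
                    "params": asdict(params),
                    "true_collagen_fraction_of_dermis":
                        truth.true_collagen_fraction_of_dermis,
                }
                (out / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
                _add(f"{stem}.png", kind="scene", seed=seed, collagen_fill=fill,
                     sidecar=f"{stem}.json")

        # 4. degenerate all-white image
        tio.write_image(out / "all_white.png",
                        np.full((256, 256, 3), 255, dtype=np.uint8))
        _add("all_white.png", kind="degenerate_white")

        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    except OSError as exc:
        raise IOFailure(f"failed writing fixture suite to {out}: {exc}") from exc
    return manifest
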