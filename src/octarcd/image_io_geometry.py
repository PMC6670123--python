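"""En-face image I/O, physical calibration, and circular/annular region masks.

Conventions (fixed so that pixel counts are bit-stable across platforms):

* pixel (0, 0) is the top-left corner, coordinates are 0-based;
* a pixel is a unit square whose *center* sits at ``(col + 0.5, row + 0.5)``;
* a pixel belongs to a disc iff the distance from the disc center to the
  pixel center is ``<=`` the radius (inclusive boundary).

Intensities are stored as floats on the 8-bit scale ``[0, 255]``; higher bit
depths are rescaled on load and interpolation output is clipped rather than
re-quantized, so no banding is introduced ahead of thresholding.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image
from skimage.transform import resize

__all__ = [
    "EnFaceImage",
    "Calibration",
    "RegionMask",
    "load_enface",
    "upsample_bicubic",
    "make_disc_mask",
    "make_annulus_mask",
]

#: Recognized retinal slab tags. The slab definitions themselves (depth
#: ranges relative to ILM/IPL) live upstream in the acquisition device and
#: are carried here as metadata only.
LAYERS = ("SRCL", "DRCL", "unknown")


@dataclass(frozen=True)
class Calibration:
    """Physical pixel calibration of a square en-face scan."""

    px_per_mm: float

    def __post_init__(self) -> None:
        if not self.px_per_mm > 0:
            raise ValueError(f"px_per_mm must be positive, got {self.px_per_mm}")

    def mm_to_px(self, mm: float) -> float:
        return mm * self.px_per_mm

    def px_to_mm(self, px: float) -> float:
        return px / self.px_per_mm


@dataclass
class EnFaceImage:
    """A calibrated grayscale en-face angiogram.

    Parameters
    ----------
    pixels
        2-D float array with intensities in ``[0, 255]``.
    extent_mm
        Physical side length of the (square) acquisition field.
    layer
        Retinal slab tag: ``"SRCL"``, ``"DRCL"`` or ``"unknown"``.
    source_id
        Free-text provenance (typically the source file name).
    """

    pixels: np.ndarray
    extent_mm: float = 3.0
    layer: str = "unknown"
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if self.pixels.size == 0:
            raise ValueError("pixels must be non-empty")
        if self.extent_mm <= 0:
            raise ValueError("extent_mm must be positive")
        if self.layer not in LAYERS:
            raise ValueError(f"layer must be one of {LAYERS}, got {self.layer!r}")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < 0 or hi > 255:
            raise ValueError(f"intensities must lie in [0, 255], got [{lo}, {hi}]")
        if self.height_px != self.width_px:
            warnings.warn(
                f"non-square image ({self.height_px}x{self.width_px}); "
                "calibration uses width",
                stacklevel=2,
            )

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def px_per_mm(self) -> float:
        return self.width_px / self.extent_mm

    @property
    def calibration(self) -> Calibration:
        return Calibration(px_per_mm=self.px_per_mm)

    @property
    def center_px(self) -> tuple[float, float]:
        """Geometric center of the field in (row, col) pixel coordinates."""
        return (self.height_px / 2.0, self.width_px / 2.0)


@dataclass(frozen=True)
class RegionMask:
    """A boolean region congruent with an :class:`EnFaceImage`."""

    mask: np.ndarray
    descriptor: str = "freeform"
    center_px: tuple[float, float] | None = None
    inner_radius_mm: float | None = None
    outer_radius_mm: float | None = None
    px_per_mm: float | None = None
    warnings_: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.descriptor not in ("disc", "annulus", "freeform"):
            raise ValueError(f"unknown descriptor {self.descriptor!r}")

    @property
    def n_px(self) -> int:
        return int(self.mask.sum())

    def to_png(self, path: str | os.PathLike) -> None:
        """Write the mask as an 8-bit 0/255 PNG."""
        Image.fromarray(self.mask.astype(np.uint8) * 255).save(path)


def load_enface(
    path: str | os.PathLike, extent_mm: float = 3.0, layer: str = "unknown"
) -> EnFaceImage:
    """Load an en-face angiogram from a PNG file.

    RGB images are converted to luminance; 16-bit images are rescaled onto
    the 8-bit range (65535 maps to 255).

    Raises
    ------
    IOError
        If the file does not exist or cannot be decoded, with the offending
        path in the message.
    """
    try:
        with Image.open(path) as im:
            im.load()
            mode = im.mode
            if mode in ("RGB", "RGBA", "P"):
                im = im.convert("L")
                arr = np.asarray(im, dtype=np.float64)
            elif mode in ("I", "I;16", "I;16B", "I;16L"):
                arr = np.asarray(im, dtype=np.float64) / 257.0
            elif mode == "L":
                arr = np.asarray(im, dtype=np.float64)
            elif mode == "F":
                arr = np.clip(np.asarray(im, dtype=np.float64), 0, 255)
            else:
                arr = np.asarray(im.convert("L"), dtype=np.float64)
    except (OSError, SyntaxError) as exc:
        raise IOError(f"cannot read en-face image {os.fspath(path)!r}: {exc}") from exc
    arr = np.clip(arr, 0.0, 255.0)
    return EnFaceImage(
        pixels=arr,
        extent_mm=extent_mm,
        layer=layer,
        source_id=os.path.basename(os.fspath(path)),
    )


def save_enface(img: EnFaceImage, path: str | os.PathLike) -> None:
    """Write an en-face image as an 8-bit grayscale PNG (rounded)."""
    Image.fromarray(np.clip(np.rint(img.pixels), 0, 255).astype(np.uint8)).save(path)


def upsample_bicubic(img: EnFaceImage, target_px: int = 1024) -> EnFaceImage:
    """Bicubically upsample an image to ``target_px`` on a side.

    The physical extent is unchanged, so ``px_per_mm`` scales by
    ``target_px / source_px``. Interpolated intensities are clipped back to
    ``[0, 255]`` (bicubic overshoot) but kept as reals.
    """
    if target_px < max(img.height_px, img.width_px):
        raise ValueError(
            f"target_px={target_px} smaller than source "
            f"{img.height_px}x{img.width_px}; downsampling is not supported"
        )
    if target_px == img.height_px == img.width_px:
        return replace(img, pixels=img.pixels.copy())
    out = resize(
        img.pixels,
        (target_px, target_px),
        order=3,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return EnFaceImage(
        pixels=np.clip(out, 0.0, 255.0),
        extent_mm=img.extent_mm,
        layer=img.layer,
        source_id=img.source_id,
    )


def _pixel_center_distances(
    shape: tuple[int, int], center_px: tuple[float, float]
) -> np.ndarray:
    rows = np.arange(shape[0], dtype=np.float64)[:, None] + 0.5
    cols = np.arange(shape[1], dtype=np.float64)[None, :] + 0.5
    return np.hypot(rows - center_px[0], cols - center_px[1])


def make_disc_mask(
    img: EnFaceImage, center_px: tuple[float, float], radius_mm: float
) -> RegionMask:
    """Boolean disc mask: pixel centers within ``radius_mm`` of the center.

    The disc must lie fully inside the field; the analysis zone is only
    meaningful when completely imaged.
    """
    if radius_mm <= 0:
        raise ValueError(f"radius_mm must be positive, got {radius_mm}")
    r_px = img.calibration.mm_to_px(radius_mm)
    cy, cx = center_px
    if not (0 <= cy <= img.height_px and 0 <= cx <= img.width_px):
        raise ValueError(f"center {center_px} outside image bounds")
    if (
        cy - r_px < 0
        or cx - r_px < 0
        or cy + r_px > img.height_px
        or cx + r_px > img.width_px
    ):
        raise ValueError(
            f"disc of radius {radius_mm} mm ({r_px:.1f} px) at {center_px} "
            "extends beyond the image bounds"
        )
    dist = _pixel_center_distances(img.pixels.shape, center_px)
    return RegionMask(
        mask=dist <= r_px,
        descriptor="disc",
        center_px=(float(cy), float(cx)),
        inner_radius_mm=0.0,
        outer_radius_mm=float(radius_mm),
        px_per_mm=img.px_per_mm,
    )


def make_annulus_mask(
    img: EnFaceImage,
    center_px: tuple[float, float],
    inner_radius_mm: float = 0.3,
    outer_radius_mm: float = 1.25,
) -> RegionMask:
    """Annular analysis-zone mask: outer disc minus inner disc.

    Defaults give the 2.5 mm diameter macular zone with the fixed 0.6 mm
    central exclusion disc removed.
    """
    if inner_radius_mm <= 0:
        raise ValueError("inner_radius_mm must be positive")
    if inner_radius_mm >= outer_radius_mm:
        raise ValueError(
            f"inner radius ({inner_radius_mm}) must be smaller than outer "
            f"({outer_radius_mm})"
        )
    outer = make_disc_mask(img, center_px, outer_radius_mm)
    r_in = img.calibration.mm_to_px(inner_radius_mm)
    dist = _pixel_center_distances(img.pixels.shape, center_px)
    return RegionMask(
        mask=outer.mask & (dist > r_in),
        descriptor="annulus",
        center_px=outer.center_px,
        inner_radius_mm=float(inner_radius_mm),
        outer_radius_mm=float(outer_radius_mm),
        px_per_mm=img.px_per_mm,
    )
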