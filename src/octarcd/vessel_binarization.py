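"""Binary perfusion maps: all vessels, large vessels, small vessels.

Two binarizations are combined. A *global* threshold derived from the
signal statistics of the central avascular baseline disc (mean + k*SD)
keeps only strongly perfused pixels, which after a width-based purification
retains the large vessels. An *adaptive* (local-mean) threshold keeps all
perfused structure down to capillary scale. Subtracting the large-vessel
map from the all-vessel map leaves the capillary-only map.

The subtraction identity ``small == all & ~large`` is guaranteed pixelwise:
the large map is harmonized (intersected with the all map) first, so
``|small| + |all & large| == |all|`` holds on every input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology

from octarcd.image_io_geometry import EnFaceImage, RegionMask

__all__ = [
    "ThresholdSpec",
    "VesselMaps",
    "global_threshold_large",
    "adaptive_threshold_all",
    "subtract_maps",
    "binarize_vessels",
]


@dataclass(frozen=True)
class ThresholdSpec:
    """Constants of the two-threshold scheme.

    ``k_noise`` sets the global cut at ``baseline mean + k_noise * SD``.
    ``min_large_width_px`` drops globally-thresholded components whose
    median skeleton width is below a large-vessel caliber (6 px at
    1024 px / 3 mm is about 18 um). ``adaptive_window_px`` / ``adaptive_offset``
    parameterize the local-mean threshold; ``min_object_px`` despeckles.
    """

    k_noise: float = 2.0
    adaptive_window_px: int = 51
    adaptive_offset: float = 3.0
    min_object_px: int = 200
    min_large_width_px: float = 10.0
    min_large_area_px: int = 10000
    fill_hole_px: int = 16

    def __post_init__(self) -> None:
        if self.adaptive_window_px < 3 or self.adaptive_window_px % 2 == 0:
            raise ValueError("adaptive_window_px must be odd and >= 3")
        if self.min_object_px < 0 or self.min_large_area_px < 0:
            raise ValueError("object/area minima must be >= 0")

    def scaled(self, factor: float) -> "ThresholdSpec":
        """Rescale all pixel-unit fields for a different working resolution."""
        window = max(3, int(round(self.adaptive_window_px * factor)) | 1)
        return ThresholdSpec(
            k_noise=self.k_noise,
            adaptive_window_px=window,
            adaptive_offset=self.adaptive_offset,
            min_object_px=int(round(self.min_object_px * factor**2)),
            min_large_width_px=self.min_large_width_px * factor,
            min_large_area_px=int(round(self.min_large_area_px * factor**2)),
            fill_hole_px=int(round(self.fill_hole_px * factor**2)),
        )


@dataclass(frozen=True)
class VesselMaps:
    """The three binary perfusion maps plus threshold provenance."""

    all_map: np.ndarray
    large_map: np.ndarray
    small_map: np.ndarray
    threshold_global: float
    provenance: ThresholdSpec

    def __post_init__(self) -> None:
        shapes = {self.all_map.shape, self.large_map.shape, self.small_map.shape}
        if len(shapes) != 1:
            raise ValueError(f"map shapes differ: {shapes}")


def _purify_large(mask: np.ndarray, spec: ThresholdSpec) -> np.ndarray:
    """Keep only wide, extended structure (the large-vessel calibre).

    Four stages, each needed in practice:

    1. enclosed holes below ``fill_hole_px`` are filled — speckle punches
       pixel-scale holes into wide vessels, and the erosion step below is
       extremely hole-sensitive (one hole voids a whole disk neighborhood);
    2. morphological opening with a disk of ``min_large_width_px`` diameter
       erases everything thinner than a large-vessel calibre — a dense
       capillary mesh percolates into one component fused with the trunks,
       which a purely component-wise test could never split;
    3. components smaller than ``min_large_area_px`` are dropped — chance
       capillary crossings survive the opening as compact blobs, whereas a
       real trunk runs across the field and is orders of magnitude larger;
    4. surviving components must have a median skeleton width (twice the
       Euclidean distance from skeleton to boundary) of at least
       ``min_large_width_px``.
    """
    if spec.min_large_width_px <= 0 or not mask.any():
        return mask.copy()
    if spec.fill_hole_px > 1:
        mask = morphology.remove_small_holes(mask, max_size=spec.fill_hole_px)
    mask = morphology.opening(mask, morphology.disk(spec.min_large_width_px / 2.0))
    if spec.min_large_area_px > 1:
        mask = morphology.remove_small_objects(
            mask, max_size=spec.min_large_area_px - 1
        )
    if not mask.any():
        return mask
    labels, n = ndi.label(mask, structure=ndi.generate_binary_structure(2, 2))
    dist = ndi.distance_transform_edt(mask)
    skel = morphology.skeletonize(mask)
    out = np.zeros_like(mask)
    for lab in range(1, n + 1):
        comp = labels == lab
        sk = skel & comp
        ref = sk if sk.any() else comp  # tiny blobs may skeletonize to nothing
        width = 2.0 * np.median(dist[ref])
        if width >= spec.min_large_width_px:
            out |= comp
    return out


def global_threshold_large(
    img: EnFaceImage,
    baseline: RegionMask,
    spec: ThresholdSpec | None = None,
    within: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Large-vessel map via a global cut anchored to the noise baseline.

    Threshold is ``mean + k_noise * SD`` of the intensities inside the
    baseline disc; pixels strictly above it are kept, then structure
    thinner than a large-vessel calibre (capillaries bright enough to clear
    a purely global cut) is removed by :func:`_purify_large`.

    Before purification the thresholded map is intersected with an
    auxiliary boxcar local-mean map (``within``, computed internally when
    not given): the above-noise blur halo between capillaries would
    otherwise bridge the mesh into plate-like blobs no opening can
    distinguish from a genuine trunk. A boxcar mean is used here — not the
    Gaussian mean of :func:`adaptive_threshold_all` — because its window
    spans whole trunks and so keeps their interiors solid.

    Returns the binary map and the threshold value used.
    """
    if spec is None:
        spec = ThresholdSpec()
    if baseline.mask.shape != img.pixels.shape:
        raise ValueError("baseline mask shape does not match image")
    vals = img.pixels[baseline.mask]
    if vals.size == 0:
        raise ValueError("baseline mask is empty")
    mu = float(vals.mean())
    sd = float(vals.std(ddof=0))
    if sd == 0.0 and spec.k_noise > 0:
        warnings.warn(
            "baseline SD is zero; global threshold falls back to the mean",
            stacklevel=2,
        )
    threshold = mu + spec.k_noise * sd
    raw = img.pixels > threshold
    if within is None:
        boxcar = ndi.uniform_filter(
            img.pixels, size=spec.adaptive_window_px, mode="nearest"
        )
        within = img.pixels > boxcar + spec.adaptive_offset
    raw = raw & np.asarray(within, dtype=bool)
    large = _purify_large(raw, spec)
    return large, threshold


def adaptive_threshold_all(
    img: EnFaceImage,
    spec: ThresholdSpec | None = None,
    exclude: np.ndarray | None = None,
) -> np.ndarray:
    """All-vessel map: intensity above the local mean plus an offset.

    The local mean is Gaussian-weighted over an ``adaptive_window_px``
    neighborhood (sigma = window/5, edge-replicated) — a boxcar mean tracks
    dense mesh too closely and systematically under-segments thin vessels.
    Objects smaller than ``min_object_px`` are then removed as background
    speckle; the positive ``adaptive_offset`` keeps pure speckle (which sits
    above its own local mean half the time) from ever forming vessels.

    ``exclude`` masks pixels out of the local-mean estimate (normalized
    convolution): a bright trunk otherwise inflates the local mean in its
    neighborhood and suppresses the capillaries beside it.
    """
    if spec is None:
        spec = ThresholdSpec()
    if spec.adaptive_window_px > min(img.pixels.shape):
        raise ValueError(
            f"adaptive window {spec.adaptive_window_px} exceeds image size "
            f"{img.pixels.shape}"
        )
    sigma = spec.adaptive_window_px / 5.0
    if exclude is None:
        local_mean = ndi.gaussian_filter(img.pixels, sigma=sigma, mode="nearest")
    else:
        keep = (~np.asarray(exclude, dtype=bool)).astype(np.float64)
        weight = np.maximum(ndi.gaussian_filter(keep, sigma=sigma, mode="nearest"),
                            1e-9)
        local_mean = (
            ndi.gaussian_filter(img.pixels * keep, sigma=sigma, mode="nearest")
            / weight
        )
    raw = img.pixels > local_mean + spec.adaptive_offset
    if spec.min_object_px > 0:
        raw = morphology.remove_small_objects(raw, max_size=spec.min_object_px - 1)
    return raw


def subtract_maps(all_map: np.ndarray, large_map: np.ndarray) -> np.ndarray:
    """Small-vessel map: ``all_map AND NOT large_map``."""
    all_map = np.asarray(all_map, dtype=bool)
    large_map = np.asarray(large_map, dtype=bool)
    if all_map.shape != large_map.shape:
        raise ValueError(
            f"map shapes differ: {all_map.shape} vs {large_map.shape}"
        )
    return all_map & ~large_map


def binarize_vessels(
    img: EnFaceImage, baseline: RegionMask, spec: ThresholdSpec | None = None
) -> VesselMaps:
    """Run both thresholds and the subtraction, returning all three maps."""
    if spec is None:
        spec = ThresholdSpec()
    large, threshold = global_threshold_large(img, baseline, spec)
    all_map = adaptive_threshold_all(img, spec, exclude=large)
    # harmonize upward: the all-vessel map must contain the large vessels
    # (the adaptive stage under-segments wide trunk interiors), making
    # large_map a subset of all_map by construction
    all_map = all_map | large
    return VesselMaps(
        all_map=all_map,
        large_map=large,
        small_map=subtract_maps(all_map, large),
        threshold_global=threshold,
        provenance=spec,
    )
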