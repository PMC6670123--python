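"""The RCD endpoint: perfused fraction of the annular macular zone.

RCD (%) is the proportion of the analysis zone occupied by perfused-vessel
pixels, computed over a 2.5 mm diameter zone with a fixed 0.6 mm central
exclusion disc. The layer dictates which map carries the density:

* SRCL: the small-vessel map (large vessels removed before measuring), so
  the large superficial trunks do not mask capillary dropout;
* DRCL: the despeckled all-vessel map (the deep slab has no large trunks
  to remove).

``quantify_image`` chains the full per-image pipeline: bicubic upsampling,
FAZ detection (or a user override mask), baseline disc, both thresholds,
map subtraction, and the zone density.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np

from octarcd.faz_detection import (
    FazBoundary,
    LevelSetParams,
    detect_faz,
    faz_from_mask,
    noise_baseline_disc,
)
from octarcd.image_io_geometry import EnFaceImage, RegionMask, make_annulus_mask, upsample_bicubic
from octarcd.vessel_binarization import ThresholdSpec, VesselMaps, binarize_vessels

__all__ = ["QuantifyConfig", "RcdResult", "compute_rcd", "quantify_image"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class QuantifyConfig:
    """End-to-end configuration of the per-image pipeline.

    ``zone_anchor`` selects what the analysis zone is centered on: the
    detected FAZ centroid (``"faz"``, default — the scan is fovea-centered
    but the fovea is rarely dead-center) or the image center (``"image"``).
    """

    extent_mm: float = 3.0
    target_px: int = 1024
    zone_outer_diameter_mm: float = 2.5
    faz_exclusion_diameter_mm: float = 0.6
    zone_anchor: str = "faz"
    level_set: LevelSetParams = field(default_factory=LevelSetParams)
    thresholds: ThresholdSpec = field(default_factory=ThresholdSpec)

    def __post_init__(self) -> None:
        if self.zone_anchor not in ("faz", "image"):
            raise ValueError("zone_anchor must be 'faz' or 'image'")
        if not 0 < self.faz_exclusion_diameter_mm < self.zone_outer_diameter_mm:
            raise ValueError("exclusion disc must be smaller than the zone")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class RcdResult:
    """Density statistic with pixel-count provenance."""

    layer: str
    rcd_percent: float
    n_vessel_px: int
    n_zone_px: int
    zone_center: tuple[float, float]
    faz_area_mm2: float | None = None
    config_digest: str = ""

    def __post_init__(self) -> None:
        if self.n_zone_px <= 0:
            raise ValueError("zone must contain pixels")
        if self.n_vessel_px > self.n_zone_px:
            raise ValueError("vessel pixels cannot exceed zone pixels")
        expected = 100.0 * self.n_vessel_px / self.n_zone_px
        if abs(self.rcd_percent - expected) > 1e-9:
            raise ValueError("rcd_percent inconsistent with pixel counts")

    def to_dict(self) -> dict:
        return {
            "layer": self.layer,
            "rcd_percent": self.rcd_percent,
            "rcd_percent_1dp": round(self.rcd_percent, 1),
            "n_vessel_px": self.n_vessel_px,
            "n_zone_px": self.n_zone_px,
            "zone_center": list(self.zone_center),
            "faz_area_mm2": self.faz_area_mm2,
            "config_digest": self.config_digest,
        }


def compute_rcd(
    vessel_map: np.ndarray,
    zone: RegionMask,
    layer: str = "unknown",
    faz_area_mm2: float | None = None,
    config_digest: str = "",
) -> RcdResult:
    """Density of set pixels inside the zone, as a percentage."""
    vessel_map = np.asarray(vessel_map, dtype=bool)
    if vessel_map.shape != zone.mask.shape:
        raise ValueError(
            f"vessel map shape {vessel_map.shape} does not match zone "
            f"{zone.mask.shape}"
        )
    n_zone = int(zone.mask.sum())
    if n_zone == 0:
        raise ValueError("analysis zone is empty")
    n_vessel = int((vessel_map & zone.mask).sum())
    center = zone.center_px if zone.center_px is not None else (np.nan, np.nan)
    return RcdResult(
        layer=layer,
        rcd_percent=100.0 * n_vessel / n_zone,
        n_vessel_px=n_vessel,
        n_zone_px=n_zone,
        zone_center=center,
        faz_area_mm2=faz_area_mm2,
        config_digest=config_digest,
    )


def quantify_image(
    img: EnFaceImage,
    layer: str | None = None,
    config: QuantifyConfig | None = None,
    faz_override_mask: np.ndarray | None = None,
    return_intermediates: bool = False,
):
    """Run the full per-image pipeline and return the :class:`RcdResult`.

    Parameters
    ----------
    img
        The en-face angiogram (any resolution; it is upsampled to
        ``config.target_px`` first).
    layer
        ``"SRCL"`` or ``"DRCL"``; defaults to the image's own layer tag.
    faz_override_mask
        Optional binary FAZ mask at the *working* resolution, bypassing
        detection (stands in for manual boundary correction).
    return_intermediates
        If true, also return a dict with the working image, FAZ boundary,
        baseline disc, vessel maps and zone mask for QC.
    """
    if config is None:
        config = QuantifyConfig(extent_mm=img.extent_mm)
    layer = layer or img.layer
    if layer not in ("SRCL", "DRCL"):
        raise ValueError(f"layer must be SRCL or DRCL, got {layer!r}")

    work = upsample_bicubic(img, target_px=config.target_px)

    if faz_override_mask is not None:
        faz: FazBoundary = faz_from_mask(faz_override_mask, work)
    else:
        faz = detect_faz(work, config.level_set)
        if not faz.converged:
            log.warning(
                "FAZ evolution hit the iteration cap for %s", img.source_id
            )

    baseline = noise_baseline_disc(
        faz, work, diameter_mm=config.faz_exclusion_diameter_mm
    )
    # pixel-unit threshold fields are expressed at the 1024 px reference
    thresholds = config.thresholds.scaled(config.target_px / 1024.0)
    maps: VesselMaps = binarize_vessels(work, baseline, thresholds)

    anchor = faz.centroid_px if config.zone_anchor == "faz" else work.center_px
    zone = make_annulus_mask(
        work,
        anchor,
        inner_radius_mm=config.faz_exclusion_diameter_mm / 2.0,
        outer_radius_mm=config.zone_outer_diameter_mm / 2.0,
    )

    density_map = maps.small_map if layer == "SRCL" else maps.all_map
    result = compute_rcd(
        density_map,
        zone,
        layer=layer,
        faz_area_mm2=faz.area_mm2,
        config_digest=config.digest(),
    )
    if return_intermediates:
        return result, {
            "work": work,
            "faz": faz,
            "baseline": baseline,
            "maps": maps,
            "zone": zone,
        }
    return result
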