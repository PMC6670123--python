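"""Synthetic stand-ins for study data: phantom angiograms and cohorts.

``generate_phantom`` draws an OCT-A-like en-face image with fully known
geometry — a central avascular zone, optional large vessel trunks, a
capillary random-walk meshwork placed to hit a target annular density, and
multiplicative speckle noise — together with the ground-truth masks needed
to validate every pipeline stage.

``generate_cohort`` draws per-eye records (group label, covariates, and
per-layer RCD values) whose marginal group means/SDs match a parameter
table, with an optional age->RCD slope injected so regression and subgroup
analyses have a recoverable signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from octarcd.image_io_geometry import EnFaceImage

__all__ = [
    "PhantomSpec",
    "Phantom",
    "CohortSpec",
    "GroupStat",
    "generate_phantom",
    "generate_cohort",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one phantom angiogram.

    ``capillary_target_density`` is the capillary-mask fraction of the
    analysis annulus (inner/outer radii below), hit to within +/- 0.005.
    ``noise_sd`` is the relative SD of the multiplicative speckle factor
    (gamma-distributed, unit mean).
    """

    size_px: int = 512
    extent_mm: float = 3.0
    faz_shape: str = "circle"
    faz_radii_mm: tuple[float, ...] = (0.3,)
    n_large_vessels: int = 3
    large_width_px: int = 10
    capillary_target_density: float = 0.44
    capillary_width_px: tuple[int, int] = (2, 3)
    vessel_intensity: float = 180.0
    background_intensity: float = 40.0
    noise_sd: float = 0.15
    ring_vessel: bool = True
    render_blur_px: float = 0.5
    annulus_inner_mm: float = 0.3
    annulus_outer_mm: float = 1.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.faz_shape not in ("circle", "ellipse"):
            raise ValueError("faz_shape must be 'circle' or 'ellipse'")
        n_radii = 1 if self.faz_shape == "circle" else 2
        if len(self.faz_radii_mm) != n_radii:
            raise ValueError(f"{self.faz_shape} needs {n_radii} radius value(s)")
        if any(r <= 0 for r in self.faz_radii_mm):
            raise ValueError("FAZ radii must be positive")
        if not 0.0 < self.capillary_target_density < 0.9:
            raise ValueError("capillary_target_density must be in (0, 0.9)")
        if self.large_width_px <= 0 or self.size_px <= 0:
            raise ValueError("sizes and widths must be positive")
        lo, hi = self.capillary_width_px
        if not (1 <= lo <= hi):
            raise ValueError("capillary_width_px must be an increasing pair >= 1")

    @property
    def px_per_mm(self) -> float:
        return self.size_px / self.extent_mm


@dataclass(frozen=True)
class Phantom:
    """A phantom image plus its ground truth."""

    image: EnFaceImage
    truth_large: np.ndarray
    truth_capillary: np.ndarray
    truth_faz: np.ndarray
    true_zone_density: float
    spec: PhantomSpec


def _faz_mask(spec: PhantomSpec) -> np.ndarray:
    n = spec.size_px
    c = n / 2.0
    yy = np.arange(n)[:, None] + 0.5 - c
    xx = np.arange(n)[None, :] + 0.5 - c
    if spec.faz_shape == "circle":
        r = spec.faz_radii_mm[0] * spec.px_per_mm
        return yy**2 + xx**2 <= r**2
    a = spec.faz_radii_mm[0] * spec.px_per_mm  # semi-axis along rows
    b = spec.faz_radii_mm[1] * spec.px_per_mm
    return (yy / a) ** 2 + (xx / b) ** 2 <= 1.0


def _disk_offsets(radius: float) -> np.ndarray:
    r = int(math.ceil(radius))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dy**2 + dx**2 <= radius**2
    return np.stack([dy[keep], dx[keep]], axis=1)


def _stamp(mask: np.ndarray, points: np.ndarray, width_px: int) -> None:
    """Set disks of diameter ``width_px`` at integer points, in place."""
    if points.size == 0:
        return
    offsets = _disk_offsets(max(width_px / 2.0, 0.5))
    n = mask.shape[0]
    for dy, dx in offsets:
        rr = points[:, 0] + dy
        cc = points[:, 1] + dx
        ok = (rr >= 0) & (rr < n) & (cc >= 0) & (cc < n)
        mask[rr[ok], cc[ok]] = True


def _large_vessel_mask(spec: PhantomSpec, rng: np.random.Generator, avoid: np.ndarray) -> np.ndarray:
    """Thick smooth trunks crossing the field, routed around the FAZ."""
    n = spec.size_px
    mask = np.zeros((n, n), dtype=bool)
    c = n / 2.0
    faz_r = max(spec.faz_radii_mm) * spec.px_per_mm
    for _ in range(spec.n_large_vessels):
        theta = rng.uniform(0, 2 * np.pi)
        # chord at a perpendicular distance that clears the FAZ + margin
        d = rng.uniform(faz_r + spec.large_width_px + 5, 0.47 * n)
        side = rng.choice([-1.0, 1.0])
        # line direction and normal
        ux, uy = np.cos(theta), np.sin(theta)
        nx, ny = -uy, ux
        t = np.linspace(-n, n, 4 * n)
        wiggle = 0.03 * n * np.sin(t / (0.15 * n) + rng.uniform(0, 2 * np.pi))
        rr = c + side * d * ny + t * uy + wiggle * ny
        cc = c + side * d * nx + t * ux + wiggle * nx
        pts = np.stack([np.rint(rr), np.rint(cc)], axis=1).astype(int)
        inb = (pts[:, 0] >= 0) & (pts[:, 0] < n) & (pts[:, 1] >= 0) & (pts[:, 1] < n)
        _stamp(mask, pts[inb], spec.large_width_px)
    mask &= ~avoid
    return mask


def _capillary_strand(
    spec: PhantomSpec,
    rng: np.random.Generator,
    forbidden: np.ndarray,
    n_steps: int,
) -> tuple[np.ndarray, int]:
    """One random-walk strand; returns integer points and its width."""
    n = spec.size_px
    for _ in range(20):  # resample starts that land in forbidden territory
        r0 = rng.uniform(2, n - 2)
        c0 = rng.uniform(2, n - 2)
        if not forbidden[int(r0), int(c0)]:
            break
    else:
        return np.empty((0, 2), dtype=int), spec.capillary_width_px[0]
    heading = rng.uniform(0, 2 * np.pi)
    step = 1.5
    pts = []
    r, c = r0, c0
    for _ in range(n_steps):
        heading += rng.normal(0.0, 0.35)
        r += step * math.sin(heading)
        c += step * math.cos(heading)
        ri, ci = int(round(r)), int(round(c))
        if not (0 <= ri < n and 0 <= ci < n) or forbidden[ri, ci]:
            break
        pts.append((ri, ci))
    width = int(rng.integers(spec.capillary_width_px[0], spec.capillary_width_px[1] + 1))
    return np.array(pts, dtype=int).reshape(-1, 2), width


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Draw a phantom angiogram with ground-truth masks.

    Capillary strands are added until the capillary fraction of the
    analysis annulus is within 0.005 of ``capillary_target_density``
    (strand length shrinks as the target nears so the last increments are
    fine-grained). Identical spec -> identical phantom.

    Raises
    ------
    RuntimeError
        If the target density is unreachable within the attempt budget.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.size_px
    c = n / 2.0

    faz = _faz_mask(spec)
    faz_buffer = ndi.binary_dilation(faz, iterations=max(spec.capillary_width_px))

    large = _large_vessel_mask(spec, rng, avoid=faz_buffer)

    yy = np.arange(n)[:, None] + 0.5 - c
    xx = np.arange(n)[None, :] + 0.5 - c
    dist = np.hypot(yy, xx)
    annulus = (dist > spec.annulus_inner_mm * spec.px_per_mm) & (
        dist <= spec.annulus_outer_mm * spec.px_per_mm
    )
    n_annulus = int(annulus.sum())

    cap = np.zeros((n, n), dtype=bool)
    if spec.ring_vessel:
        # perifoveal arcade: a closed capillary hugging the avascular rim
        width = spec.capillary_width_px[1]
        if spec.faz_shape == "circle":
            a = b = spec.faz_radii_mm[0] * spec.px_per_mm
        else:
            a = spec.faz_radii_mm[0] * spec.px_per_mm
            b = spec.faz_radii_mm[1] * spec.px_per_mm
        off = width / 2.0 + 0.5
        tt = np.linspace(0, 2 * np.pi, int(8 * max(a, b)), endpoint=False)
        wig = 0.8 * np.sin(3 * tt + rng.uniform(0, 2 * np.pi))
        rr = np.rint(c + (a + off + wig) * np.sin(tt)).astype(int)
        cc = np.rint(c + (b + off + wig) * np.cos(tt)).astype(int)
        _stamp(cap, np.stack([rr, cc], axis=1), width)
        cap &= ~faz  # the arcade must not intrude into the avascular zone
    target = spec.capillary_target_density
    tol = 0.005
    max_strands = 20000

    def annulus_density() -> float:
        return float((cap & ~large & annulus).sum()) / n_annulus

    density_at_last_check = 0.0
    for i in range(max_strands):
        d = annulus_density()
        if d >= target - tol:
            break
        if i % 300 == 299:  # stall detection: the width budget is exhausted
            if d - density_at_last_check < 5e-4:
                raise RuntimeError(
                    f"capillary density stalled at {d:.3f} while targeting "
                    f"{target}; target unreachable for this geometry"
                )
            density_at_last_check = d
        gap = target - d
        n_steps = 120 if gap > 0.02 else (40 if gap > 0.008 else 12)
        pts, width = _capillary_strand(spec, rng, faz_buffer, n_steps)
        _stamp(cap, pts, width)
    else:
        raise RuntimeError(
            f"could not reach capillary density {target} within "
            f"{max_strands} strands (reached {annulus_density():.3f})"
        )
    density = annulus_density()
    if abs(density - target) > tol:
        raise RuntimeError(
            f"capillary density {density:.4f} overshot target {target} "
            f"beyond +/-{tol}"
        )

    truth_capillary = cap & ~large & ~faz
    vessels = truth_capillary | large

    clean = np.full((n, n), spec.background_intensity, dtype=np.float64)
    clean[vessels] = spec.vessel_intensity
    if spec.render_blur_px > 0:  # soften rasterized rims
        clean = ndi.gaussian_filter(clean, sigma=spec.render_blur_px)
    if spec.noise_sd > 0:
        shape = 1.0 / spec.noise_sd**2
        speckle = rng.gamma(shape, scale=1.0 / shape, size=clean.shape)
        clean = clean * speckle
    pixels = np.clip(clean, 0.0, 255.0)

    image = EnFaceImage(
        pixels=pixels,
        extent_mm=spec.extent_mm,
        layer="unknown",
        source_id=f"phantom-seed{spec.seed}",
    )
    return Phantom(
        image=image,
        truth_large=large,
        truth_capillary=truth_capillary,
        truth_faz=faz,
        true_zone_density=density,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

GROUPS = ("Control", "NDR", "MDR")
LAYER_COLUMNS = {"SRCL": "rcd_srcl", "DRCL": "rcd_drcl"}


@dataclass(frozen=True)
class GroupStat:
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")


def _gs(mean: float, sd: float) -> GroupStat:
    return GroupStat(mean, sd)


@dataclass(frozen=True)
class CohortSpec:
    """Parameter home for the synthetic cohort.

    ``continuous`` maps column -> group -> :class:`GroupStat` (missing
    groups yield NaN for that column). ``binary`` maps column -> group ->
    probability of the positive label. ``rcd`` maps layer -> group ->
    :class:`GroupStat` of the marginal RCD distribution; ``age_rcd_slope``
    (per layer, RCD points per year) is injected via the age draw with the
    residual SD shrunk so the marginal SD still matches.
    """

    sizes: dict = field(
        default_factory=lambda: {"Control": 86, "NDR": 90, "MDR": 36}
    )
    continuous: dict = field(default_factory=dict)
    binary: dict = field(default_factory=dict)
    rcd: dict = field(default_factory=dict)
    age_rcd_slope: dict = field(
        default_factory=lambda: {"SRCL": -0.05, "DRCL": -0.20}
    )
    bounds: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.sizes.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n <= 0:
                raise ValueError("group sizes must be positive")
        for var, per_group in self.binary.items():
            for g, p in per_group.items():
                if p is not None and not 0 <= p <= 1:
                    raise ValueError(f"proportion for {var}/{g} outside [0,1]")

    @classmethod
    def default(cls, seed: int = 0) -> "CohortSpec":
        """Three-group cohort parameterized at the study's summary tables."""
        continuous = {
            "age": {"Control": _gs(52.5, 9.11), "NDR": _gs(52.7, 11.91), "MDR": _gs(56.61, 12.25)},
            "bmi": {"Control": _gs(23.37, 2.84), "NDR": _gs(23.86, 2.95), "MDR": _gs(23.9, 3.04)},
            "sbp": {"Control": _gs(123.48, 13.77), "NDR": _gs(128.4, 16.22), "MDR": _gs(132.31, 18.23)},
            "dbp": {"Control": _gs(76.88, 9.44), "NDR": _gs(79.26, 10.44), "MDR": _gs(78.36, 9.35)},
            "duration": {"Control": None, "NDR": _gs(5.47, 5.34), "MDR": _gs(7.02, 5.65)},
            "bg": {"Control": None, "NDR": _gs(7.85, 3.93), "MDR": _gs(8.09, 2.38)},
            "hba1c": {"Control": None, "NDR": _gs(7.55, 1.78), "MDR": _gs(8.17, 1.98)},
            "bun": {"Control": None, "NDR": _gs(6.24, 5.15), "MDR": _gs(6.04, 4.27)},
            "creatinine": {"Control": None, "NDR": _gs(60.62, 16.88), "MDR": _gs(73.17, 91.96)},
            "tg": {"Control": None, "NDR": _gs(1.99, 1.73), "MDR": _gs(1.59, 1.0)},
            "tc": {"Control": None, "NDR": _gs(4.54, 1.0), "MDR": _gs(4.58, 0.96)},
            "hdl_c": {"Control": None, "NDR": _gs(1.3, 0.37), "MDR": _gs(1.2, 0.28)},
            "ldl_c": {"Control": None, "NDR": _gs(2.48, 0.77), "MDR": _gs(2.45, 0.98)},
        }
        binary = {
            "male": {"Control": 31 / 86, "NDR": 46 / 90, "MDR": 16 / 36},
            "od": {"Control": 47 / 86, "NDR": 52 / 90, "MDR": 21 / 36},
            "smoke": {"Control": None, "NDR": 75 / 90, "MDR": 25 / 36},
            "alcohol": {"Control": None, "NDR": 74 / 90, "MDR": 28 / 36},
            "insulin": {"Control": None, "NDR": 74 / 90, "MDR": 24 / 36},
        }
        rcd = {
            "SRCL": {"Control": _gs(43.9, 1.8), "NDR": _gs(42.4, 3.0), "MDR": _gs(41.0, 2.7)},
            "DRCL": {"Control": _gs(52.6, 3.0), "NDR": _gs(49.9, 5.8), "MDR": _gs(46.6, 6.1)},
        }
        bounds = {
            "age": (18.0, 95.0),
            "bmi": (14.0, 45.0),
            "sbp": (80.0, 220.0),
            "dbp": (40.0, 130.0),
            "duration": (0.0, 40.0),
            "bg": (2.5, 30.0),
            "hba1c": (4.0, 18.0),
            "bun": (1.0, 40.0),
            "creatinine": (20.0, 800.0),
            "tg": (0.2, 15.0),
            "tc": (1.5, 12.0),
            "hdl_c": (0.3, 4.0),
            "ldl_c": (0.3, 8.0),
        }
        return cls(
            continuous=continuous, binary=binary, rcd=rcd, bounds=bounds, seed=seed
        )


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Draw a tidy per-eye cohort table (one row per eye).

    Continuous covariates are independent truncated normals per group;
    binary covariates are Bernoulli. Per-layer RCD is drawn as
    ``mean + slope * (age - group mean age) + residual`` with the residual
    SD shrunk so the *marginal* group mean/SD match the spec.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    rows = []
    eye_id = 0
    for group in GROUPS:
        n = spec.sizes.get(group, 0)
        if n == 0:
            continue
        draws: dict[str, np.ndarray] = {}
        for var, per_group in spec.continuous.items():
            gs = per_group.get(group)
            if gs is None:
                draws[var] = np.full(n, np.nan)
            else:
                x = rng.normal(gs.mean, gs.sd, size=n)
                lo, hi = spec.bounds.get(var, (-np.inf, np.inf))
                draws[var] = np.clip(x, lo, hi)
        for var, per_group in spec.binary.items():
            p = per_group.get(group)
            if p is None:
                draws[var] = np.full(n, np.nan)
            else:
                draws[var] = rng.random(n) < p

        age = draws.get("age")
        age_gs = spec.continuous.get("age", {}).get(group)
        for layer, col in LAYER_COLUMNS.items():
            gs = spec.rcd.get(layer, {}).get(group)
            if gs is None:
                draws[col] = np.full(n, np.nan)
                continue
            slope = float(spec.age_rcd_slope.get(layer, 0.0))
            if age is not None and age_gs is not None and slope != 0.0:
                resid_var = gs.sd**2 - slope**2 * age_gs.sd**2
                resid_sd = math.sqrt(max(resid_var, 1e-4))
                draws[col] = (
                    gs.mean
                    + slope * (age - age_gs.mean)
                    + rng.normal(0.0, resid_sd, size=n)
                )
            else:
                draws[col] = rng.normal(gs.mean, gs.sd, size=n)

        for i in range(n):
            row = {"eye_id": f"E{eye_id:04d}", "group": group}
            for var, vals in draws.items():
                v = vals[i]
                if var in spec.binary:
                    if isinstance(v, (bool, np.bool_)):
                        if var == "male":
                            row["sex"] = "male" if v else "female"
                        elif var == "od":
                            row["eye"] = "OD" if v else "OS"
                        else:
                            row[var] = "Y" if v else "N"
                    else:
                        if var == "male":
                            row["sex"] = None
                        elif var == "od":
                            row["eye"] = None
                        else:
                            row[var] = None
                else:
                    row[var] = float(v) if np.isfinite(v) else np.nan
            rows.append(row)
            eye_id += 1
    df = pd.DataFrame(rows)
    df.attrs["seed"] = spec.seed if seed is None else seed
    return df
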