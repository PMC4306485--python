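"""Gland identification on en-face projections of flattened volumes.

Labial minor salivary glands appear as hypointense foci against the highly
reflective muscular layer in a C-scan taken ~750 um below the mucosal surface.
A focus counts as a gland when an excretory duct — a narrow hypointense
channel running from the surface down to the gland — can be matched to it;
foci at the border of the useful imaging surface are exempt from the duct
requirement, since their duct may fall outside the field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from .geometry import ConfigurationError, ScanGeometry, solve_useful_mask
from .preprocess import FlattenedVolume

__all__ = [
    "AnalysisParams",
    "CScan",
    "UsefulSurfaceMask",
    "GlandCandidate",
    "extract_cscan",
    "make_useful_mask",
    "detect_gland_candidates",
    "detect_duct",
    "count_glands",
]


@dataclass(frozen=True)
class AnalysisParams:
    """Tunable parameters of the gland-counting analysis.

    ``cscan_depth_um``
        centre depth of the en-face slab below the flattened surface.
    ``slab_thickness_um``
        axial extent averaged into the C-scan.
    ``min/max_gland_area_mm2``
        footprint gate for connected components (typical labial gland
        footprints are a fraction of a mm^2 to a few mm^2).
    ``opening_radius_px``
        binary opening radius that suppresses speckle fragments.
    ``presmooth_sigma_um``
        Gaussian pre-smoothing scale applied to the C-scan before
        thresholding; chosen well below the minimum gland radius so it
        suppresses residual speckle without distorting gland footprints.
    ``duct_search_radius_um`` / ``duct_intensity_ratio``
        a duct is declared when some A-scan column within the search radius of
        the focus centroid is darker than ``ratio`` x the local background
        over the span from the surface to the gland top.
    ``min_log_separation``
        required Otsu class separation (in log-intensity) for the hypointense
        class to be considered real; guards against splitting pure speckle
        when no gland is present.
    ``useful_area_cm2``
        area of the useful imaging surface; also the fixed denominator of
        every reported density.
    ``border_margin_px``
        a component within this many pixels of the mask edge is a border
        focus (duct requirement waived).
    """

    cscan_depth_um: float = 750.0
    slab_thickness_um: float = 100.0
    min_gland_area_mm2: float = 0.1
    max_gland_area_mm2: float = 5.0
    opening_radius_px: int = 1
    presmooth_sigma_um: float = 150.0
    duct_search_radius_um: float = 150.0
    duct_intensity_ratio: float = 0.6
    min_log_separation: float = 0.7
    useful_area_cm2: float = 2.43
    border_margin_px: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.duct_intensity_ratio < 1.0:
            raise ConfigurationError("duct_intensity_ratio must lie in (0, 1)")
        if self.useful_area_cm2 <= 0:
            raise ConfigurationError("useful_area_cm2 must be > 0")
        if self.slab_thickness_um <= 0 or self.cscan_depth_um < 0:
            raise ConfigurationError("slab depth/thickness must be positive")
        if self.min_gland_area_mm2 >= self.max_gland_area_mm2:
            raise ConfigurationError("min gland area must be below max gland area")


@dataclass
class CScan:
    """En-face mean-intensity projection over one depth slab."""

    values: np.ndarray  # (slow, fast), finite, >= 0
    depth_um: float
    thickness_um: float
    spacing_um: tuple[float, float]  # (dy, dx)

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or not np.all(np.isfinite(self.values)):
            raise ValueError("C-scan must be a finite 2-D raster")


@dataclass
class UsefulSurfaceMask:
    """Binary useful-surface raster and its achieved physical area."""

    mask: np.ndarray
    area_cm2: float
    pixel_area_cm2: float


@dataclass
class GlandCandidate:
    """One connected hypointense focus inside the useful surface."""

    id: int
    centroid_px: tuple[float, float]  # (row/slow, col/fast)
    centroid_cm: tuple[float, float]  # (x, y)
    area_mm2: float
    mean_intensity: float
    on_border: bool
    has_duct: Optional[bool] = None
    accepted: Optional[bool] = None


def extract_cscan(flat: FlattenedVolume, params: AnalysisParams) -> CScan:
    """Mean-intensity en-face projection over the configured slab.

    The slab spans ``cscan_depth_um +/- slab_thickness_um/2`` below the
    flattened surface.
    """
    dy, dx, dz = flat.spacing_um
    n_depth = flat.intensity.shape[2]
    z_lo = params.cscan_depth_um - params.slab_thickness_um / 2.0
    z_hi = params.cscan_depth_um + params.slab_thickness_um / 2.0
    if z_lo < 0 or z_hi > n_depth * dz:
        raise ValueError(
            f"slab [{z_lo:.0f}, {z_hi:.0f}] um exceeds the depth range "
            f"(0, {n_depth * dz:.0f}) um"
        )
    k_lo = int(np.floor(z_lo / dz))
    k_hi = max(k_lo + 1, int(np.ceil(z_hi / dz)))
    img = flat.intensity[:, :, k_lo:k_hi].mean(axis=2)
    return CScan(
        values=img,
        depth_um=params.cscan_depth_um,
        thickness_um=params.slab_thickness_um,
        spacing_um=(dy, dx),
    )


def make_useful_mask(geometry: ScanGeometry, params: AnalysisParams) -> UsefulSurfaceMask:
    """Centred-disc useful surface whose pixel-counted area matches
    ``params.useful_area_cm2`` to within one pixel area."""
    mask, area = solve_useful_mask(geometry, params.useful_area_cm2)
    return UsefulSurfaceMask(mask=mask, area_cm2=area, pixel_area_cm2=geometry.pixel_area_cm2)


def detect_gland_candidates(
    cscan: CScan, mask: UsefulSurfaceMask, params: AnalysisParams
) -> list[GlandCandidate]:
    """Segment hypointense foci inside the useful surface.

    The C-scan is pre-smoothed at ``presmooth_sigma_um`` to suppress residual
    speckle, intensities are normalised to the in-mask median (the split must
    not depend on the arbitrary intensity units), and the log-transformed
    image within the mask is split by Otsu's threshold.  The dark class is
    cleaned by binary opening, labelled with 8-connectivity, and components
    are gated to the plausible gland footprint range.  If the Otsu split does
    not separate two genuinely distinct classes (``min_log_separation``, in
    log units), the projection is considered gland-free.
    """
    if cscan.values.shape != mask.mask.shape:
        raise ValueError("C-scan and mask shapes disagree")
    if not mask.mask.any():
        raise ValueError("useful-surface mask is empty")

    values = cscan.values.astype(np.float64)
    med = float(np.median(values[mask.mask]))
    if med <= 0 or float(np.ptp(values[mask.mask])) < 1e-12 * max(med, 1.0):
        return []
    dy, dx = cscan.spacing_um
    if params.presmooth_sigma_um > 0:
        values = ndi.gaussian_filter(
            values, sigma=(params.presmooth_sigma_um / dy, params.presmooth_sigma_um / dx)
        )
    # log(1 + I / (0.01 median)): effectively a log transform on normalised
    # intensity, finite at zero-filled pixels
    log_img = np.log1p(values / (0.01 * med))
    inside = log_img[mask.mask]
    if float(np.ptp(inside)) < 1e-9:
        return []
    thr = threshold_otsu(inside)
    dark = inside[inside < thr]
    bright = inside[inside >= thr]
    if dark.size == 0 or bright.size == 0:
        return []
    if float(bright.mean() - dark.mean()) < params.min_log_separation:
        return []

    binary = (log_img < thr) & mask.mask
    if params.opening_radius_px > 0:
        binary = morphology.opening(binary, morphology.disk(params.opening_radius_px))
        binary &= mask.mask

    edge_zone = mask.mask & ~morphology.erosion(
        mask.mask, morphology.disk(params.border_margin_px)
    )

    labels = measure.label(binary, connectivity=2)
    dy, dx = cscan.spacing_um
    px_area_mm2 = (dy / 1e3) * (dx / 1e3)

    out: list[GlandCandidate] = []
    for region in measure.regionprops(labels, intensity_image=cscan.values):
        area_mm2 = region.area * px_area_mm2
        if not params.min_gland_area_mm2 <= area_mm2 <= params.max_gland_area_mm2:
            continue
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        on_border = bool(edge_zone[rr, cc].any())
        cy, cx = region.centroid
        out.append(
            GlandCandidate(
                id=len(out),
                centroid_px=(float(cy), float(cx)),
                centroid_cm=((cx + 0.5) * dx / 1e4, (cy + 0.5) * dy / 1e4),
                area_mm2=float(area_mm2),
                mean_intensity=float(region.intensity_mean),
                on_border=on_border,
            )
        )
    return out


def detect_duct(
    flat: FlattenedVolume, candidate: GlandCandidate, params: AnalysisParams
) -> bool:
    """Decide whether an excretory duct connects ``candidate`` to the surface.

    The gland-top depth is estimated from the candidate's own footprint
    profile (first depth at which the footprint mean falls below half the
    background ring); a duct is declared when any A-scan column within the
    lateral search radius is darker than ``duct_intensity_ratio`` x the ring
    background over the span between the surface and the gland top.
    """
    inten = flat.intensity
    n_slow, n_fast, n_depth = inten.shape
    dy, dx, dz = flat.spacing_um
    py, px = candidate.centroid_px
    if not (0 <= py < n_slow and 0 <= px < n_fast):
        raise ValueError(f"candidate centroid {candidate.centroid_px} outside the volume")

    # lateral radii (um): search disc, candidate footprint, background ring
    r_search = max(params.duct_search_radius_um, 2.0 * max(dx, dy))
    r_fp = max(np.sqrt(candidate.area_mm2 / np.pi) * 1e3, dx)
    ring_in = max(2.0 * r_search, r_fp + 2.0 * max(dx, dy))
    ring_out = ring_in + 2.0 * r_search

    half_px = int(np.ceil(ring_out / min(dx, dy))) + 1
    y0, y1 = max(0, int(py) - half_px), min(n_slow, int(py) + half_px + 1)
    x0, x1 = max(0, int(px) - half_px), min(n_fast, int(px) + half_px + 1)
    yy = (np.arange(y0, y1) - py) * dy
    xx = (np.arange(x0, x1) - px) * dx
    dist = np.sqrt(yy[:, None] ** 2 + xx[None, :] ** 2)
    sub = inten[y0:y1, x0:x1, :]

    search = dist <= r_search
    footprint = dist <= r_fp
    ring = (dist >= ring_in) & (dist <= ring_out)
    if not ring.any() or not search.any():
        return False

    bg_profile = sub[ring, :].mean(axis=0)
    fp_profile = sub[footprint, :].mean(axis=0)

    k0 = max(1, int(round(50.0 / dz)))  # skip the immediate surface voxels
    k_slab_top = int((params.cscan_depth_um - params.slab_thickness_um / 2.0) / dz)
    k_top = k_slab_top
    for k in range(k0, min(k_slab_top, n_depth)):
        if bg_profile[k] > 0 and fp_profile[k] < 0.5 * bg_profile[k]:
            k_top = k
            break
    k_top = max(k_top, k0 + 2)

    bg = float(bg_profile[k0:k_top].mean())
    if bg <= 0:
        return False
    col_means = sub[search, k0:k_top].mean(axis=1)
    return bool(col_means.min() < params.duct_intensity_ratio * bg)


def count_glands(candidates: Sequence[GlandCandidate]) -> int:
    """Apply the counting rule and return the number of accepted glands.

    A focus is accepted when a duct was matched to it, or when it lies at the
    border of the useful surface (where the duct requirement is waived).
    Mutates each candidate's ``accepted`` flag.
    """
    for c in candidates:
        if c.has_duct is None or c.on_border is None:
            raise ValueError(f"candidate {c.id}: duct/border flags must be set first")
    n = 0
    for c in candidates:
        c.accepted = bool(c.has_duct or c.on_border)
        n += c.accepted
    return n
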