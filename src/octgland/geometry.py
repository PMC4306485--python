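"""Scan geometry and the useful-imaging-surface mask.

The raster geometry of a swept-source OCT acquisition: a square field of
``n_fast`` x ``n_slow`` A-scans over ``fov_lateral_cm`` per side, each A-scan
holding ``n_depth`` samples over ``depth_range_mm`` of tissue depth.  The
counting analysis is restricted to a central *useful imaging surface* (a disc
clipped by the scan square, limited by the lens aperture) whose physical area
is a configured constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ScanGeometry", "ConfigurationError", "solve_useful_mask"]


class ConfigurationError(ValueError):
    """A configuration value is inconsistent or physically impossible."""


@dataclass(frozen=True)
class ScanGeometry:
    """Raster-scan geometry of one volumetric acquisition.

    Defaults describe a 400 x 400 A-scan raster over 1.73 x 1.73 cm^2 with a
    3.4 mm depth range, acquired at 50,000 A-scans/s by a 1310 nm source with
    ~100 nm tuning range.
    """

    n_fast: int = 400
    n_slow: int = 400
    n_depth: int = 512
    fov_lateral_cm: float = 1.73
    depth_range_mm: float = 3.4
    sweep_rate_hz: float = 50_000.0
    center_wavelength_nm: float = 1310.0
    tuning_range_nm: float = 100.0

    def __post_init__(self) -> None:
        for name in ("n_fast", "n_slow", "n_depth"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 8:
                raise ConfigurationError(f"{name} must be an integer >= 8, got {v!r}")
        for name in (
            "fov_lateral_cm",
            "depth_range_mm",
            "sweep_rate_hz",
            "center_wavelength_nm",
            "tuning_range_nm",
        ):
            v = getattr(self, name)
            if not v > 0:
                raise ConfigurationError(f"{name} must be > 0, got {v!r}")

    # lateral pitch: field side divided by A-scans per side
    @property
    def dx_um(self) -> float:
        return self.fov_lateral_cm * 1e4 / self.n_fast

    @property
    def dy_um(self) -> float:
        return self.fov_lateral_cm * 1e4 / self.n_slow

    @property
    def dz_um(self) -> float:
        return self.depth_range_mm * 1e3 / self.n_depth

    @property
    def spacing_um(self) -> tuple[float, float, float]:
        """(dy, dx, dz) voxel pitch in micrometres for a (slow, fast, depth) raster."""
        return (self.dy_um, self.dx_um, self.dz_um)

    @property
    def acquisition_time_s(self) -> float:
        """Time to raster the full volume: A-scan count over sweep rate."""
        return self.n_fast * self.n_slow / self.sweep_rate_hz

    @property
    def field_area_cm2(self) -> float:
        return self.fov_lateral_cm**2

    @property
    def pixel_area_cm2(self) -> float:
        return (self.fov_lateral_cm / self.n_fast) * (self.fov_lateral_cm / self.n_slow)


def solve_useful_mask(
    geometry: ScanGeometry, useful_area_cm2: float
) -> tuple[np.ndarray, float]:
    """Binary mask of the useful imaging surface with the requested area.

    The mask is a disc centred on the field, intersected with the scan square.
    The disc radius is solved on the monotone pixel-count-versus-radius curve
    so that the pixel-counted physical area matches ``useful_area_cm2`` to
    within one pixel area; pixels at exactly the boundary radius are included
    in raster order, which breaks the 4/8-fold symmetry ties a pure radius
    threshold cannot.

    Returns ``(mask, area_cm2)`` where ``area_cm2`` is the achieved pixel
    -counted area.
    """
    if useful_area_cm2 <= 0:
        raise ConfigurationError("useful_area_cm2 must be > 0")
    pix = geometry.pixel_area_cm2
    n_px = geometry.n_slow * geometry.n_fast
    if useful_area_cm2 > geometry.field_area_cm2 + 0.5 * pix:
        raise ConfigurationError(
            f"useful area {useful_area_cm2} cm^2 exceeds the scanned field "
            f"({geometry.field_area_cm2:.4f} cm^2)"
        )
    k = int(round(useful_area_cm2 / pix))
    k = min(max(k, 0), n_px)

    half = geometry.fov_lateral_cm / 2.0
    x = (np.arange(geometry.n_fast) + 0.5) * geometry.fov_lateral_cm / geometry.n_fast
    y = (np.arange(geometry.n_slow) + 0.5) * geometry.fov_lateral_cm / geometry.n_slow
    r2 = (y[:, None] - half) ** 2 + (x[None, :] - half) ** 2

    mask = np.zeros(n_px, dtype=bool)
    if k > 0:
        order = np.argsort(r2.ravel(), kind="stable")
        mask[order[:k]] = True
    return mask.reshape(geometry.n_slow, geometry.n_fast), k * pix
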