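"""Mucosal surface segmentation and volume flattening.

The lower-lip mucosa is imaged pressed against a glass plate, so the
tissue/glass interface sits at a slowly varying depth across the field.  To
measure everything in depth *below the tissue surface*, each A-scan's first
significant intensity rise is located (surface segmentation) and the volume is
shifted A-scan by A-scan so the detected surface lands at depth index zero
(flattening).  En-face projections taken after flattening therefore sample a
constant anatomical depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import ScanGeometry

__all__ = [
    "OctVolume",
    "SurfaceMap",
    "FlattenedVolume",
    "NoSurfaceFoundError",
    "segment_surface",
    "flatten_volume",
]

#: fraction of the shallowest depth samples used to estimate the noise floor
NOISE_ESTIMATION_FRACTION = 0.05


class NoSurfaceFoundError(RuntimeError):
    """Raised when too few A-scans contain a detectable tissue interface."""


@dataclass
class OctVolume:
    """A volumetric OCT intensity raster with physical voxel spacing.

    ``intensity`` is indexed ``(slow, fast, depth)`` and must be finite and
    non-negative.  ``spacing_um`` is ``(dy, dx, dz)`` and must agree with the
    scan geometry.
    """

    intensity: np.ndarray
    spacing_um: tuple[float, float, float]
    geometry: ScanGeometry

    def __post_init__(self) -> None:
        a = np.asarray(self.intensity)
        if a.ndim != 3:
            raise ValueError(f"intensity must be 3-D (slow, fast, depth), got ndim={a.ndim}")
        expected = (self.geometry.n_slow, self.geometry.n_fast, self.geometry.n_depth)
        if a.shape != expected:
            raise ValueError(f"intensity shape {a.shape} != geometry shape {expected}")
        if not np.all(np.isfinite(a)) or a.min() < 0:
            raise ValueError("intensity must be finite and >= 0")
        for got, want, name in zip(self.spacing_um, self.geometry.spacing_um, "yxz"):
            if not np.isclose(got, want, rtol=1e-6):
                raise ValueError(
                    f"spacing d{name}={got} inconsistent with geometry ({want})"
                )
        self.intensity = a

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity.shape


@dataclass
class SurfaceMap:
    """Depth index of the tissue/glass interface at every lateral position.

    ``valid`` marks positions where a threshold crossing was actually found;
    invalid positions carry an in-filled index from the nearest valid
    neighbour so the map is total.
    """

    depth_index: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        if self.depth_index.shape != self.valid.shape:
            raise ValueError("depth_index and valid must have the same shape")


@dataclass
class FlattenedVolume:
    """A volume re-aligned so the detected surface sits at depth index 0.

    Intensities are only relocated, never altered; voxels shifted in from
    beyond the acquisition window take ``fill_value``.
    """

    intensity: np.ndarray
    spacing_um: tuple[float, float, float]
    geometry: ScanGeometry
    surface: SurfaceMap
    fill_value: float = 0.0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity.shape


def segment_surface(
    volume: OctVolume, k_sigma: float = 4.0, smooth_window: int = 5
) -> SurfaceMap:
    """Locate the glass/tissue interface in every A-scan.

    The noise floor is estimated from the shallowest 5% of depth samples of
    the whole volume (above the interface the beam traverses only the glass
    plate).  The surface at each lateral position is the first depth sample
    exceeding ``noise_mean + k_sigma * noise_sd``.  Positions without a
    crossing are in-filled from the nearest valid neighbour, and the map is
    smoothed against a ``smooth_window`` x ``smooth_window`` median filter:
    positions deviating from their window median by more than two voxels are
    replaced by it, which repairs isolated speckle-induced outliers without
    perturbing already-exact maps.

    Raises
    ------
    NoSurfaceFoundError
        If more than half of the A-scans have no crossing (empty or corrupt
        volume).
    """
    inten = volume.intensity
    n_depth = inten.shape[2]
    shape = inten.shape[:2]
    n_noise = max(1, int(NOISE_ESTIMATION_FRACTION * n_depth))
    noise = inten[:, :, :n_noise]
    # The shallow region is only a valid noise estimate while the interface
    # lies below it.  When the shallow samples are bright relative to the
    # whole volume the tissue already starts at depth 0 (e.g. an already-
    # flattened volume): the interface is at/above the first sample, so the
    # surface map is identically zero.
    overall_median = float(np.median(inten))
    if overall_median > 0 and float((noise <= overall_median).mean()) < 0.5:
        return SurfaceMap(
            depth_index=np.zeros(shape, dtype=np.int32),
            valid=np.ones(shape, dtype=bool),
        )
    thr = float(noise.mean()) + k_sigma * float(noise.std())

    above = inten > thr
    valid = above.any(axis=2)
    if valid.mean() <= 0.5:
        raise NoSurfaceFoundError(
            f"only {valid.mean():.0%} of A-scans cross the surface threshold"
        )
    raw = above.argmax(axis=2).astype(np.int32)

    if not valid.all():
        # nearest-valid in-fill keeps the map total for flattening
        _, (iy, ix) = ndimage.distance_transform_edt(~valid, return_indices=True)
        raw = raw[iy, ix]

    if smooth_window > 1:
        # outlier repair: replace a position by its window median only when it
        # deviates by > 2 voxels, so exact maps pass through unchanged while
        # isolated speckle-induced misses are corrected
        med = ndimage.median_filter(raw, size=smooth_window, mode="nearest")
        raw = np.where(np.abs(raw - med) > 2, med, raw)
    raw = np.clip(raw, 0, n_depth - 1)
    return SurfaceMap(depth_index=raw, valid=valid)


def flatten_volume(volume: OctVolume, surface: SurfaceMap) -> FlattenedVolume:
    """Shift each A-scan by an integer so its surface lands at depth 0.

    Axial pitch is on the order of the axial resolution, so integer shifts
    lose nothing; vacated deep samples are filled with ``fill_value`` (0).
    """
    inten = volume.intensity
    if surface.depth_index.shape != inten.shape[:2]:
        raise ValueError(
            f"surface shape {surface.depth_index.shape} does not match "
            f"volume lateral shape {inten.shape[:2]}"
        )
    n_depth = inten.shape[2]
    shifts = surface.depth_index.astype(np.int32)
    idx = shifts[:, :, None] + np.arange(n_depth, dtype=np.int32)[None, None, :]
    out = np.take_along_axis(inten, np.minimum(idx, n_depth - 1), axis=2)
    out = np.where(idx < n_depth, out, np.float32(0.0))
    return FlattenedVolume(
        intensity=out.astype(inten.dtype, copy=False),
        spacing_um=volume.spacing_um,
        geometry=volume.geometry,
        surface=surface,
        fill_value=0.0,
    )
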