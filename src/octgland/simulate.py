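"""Synthetic SS-OCT phantoms of lower-lip mucosa with ground truth.

The generator emulates the appearance a swept-source OCT instrument records
from labial mucosa pressed against a glass plate: a tilted, gently bulged
tissue surface; a layered mucosa (epithelium, connective tissue, muscle) whose
backscatter decays exponentially with depth; hypointense ellipsoidal minor
salivary glands connected to the surface by narrow hypointense excretory
ducts; fully developed multiplicative speckle; and an additive detector noise
floor.  Every volume ships with a ground-truth table (gland positions, sizes,
duct presence, border status) so detection can be scored exactly.

Intensity model, per voxel at depth ``d`` micrometres below the local surface::

    I = R(layer(d)) * exp(-mu * d) * C(gland) * S + N,   clipped at 0

where ``R`` is the layer reflectivity, ``mu`` the attenuation per mm,
``C`` equals ``gland_contrast`` inside glands/ducts and 1 elsewhere,
``S`` is unit-mean exponential speckle and ``N`` zero-mean Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import ConfigurationError, ScanGeometry, solve_useful_mask
from .preprocess import OctVolume

__all__ = [
    "GlandSpec",
    "PhantomConfig",
    "PhantomTruth",
    "CohortPreset",
    "PlacementError",
    "simulate_volume",
    "simulate_cohort",
    "iter_cohort",
    "cf_like_preset",
    "hs_like_preset",
    "CF_LIKE_COUNTS",
    "HS_LIKE_COUNTS",
]


class PlacementError(RuntimeError):
    """Requested gland count could not be placed at the required spacing."""


# ----------------------------------------------------------------- configs --

#: layer boundaries below the surface: epithelium / connective tissue, then muscle
DEFAULT_LAYER_DEPTHS_UM = (300.0, 600.0)
#: mean backscatter of epithelium, connective tissue, muscle (arbitrary units)
DEFAULT_LAYER_REFLECTIVITIES = (0.4, 0.7, 1.0)

#: gland size range for ad-hoc phantoms (uniform semi-axes, micrometres)
DEFAULT_GLAND_SEMI_AXES_UM = (500.0, 900.0)

#: cohort-preset gland dimensions: lateral/axial semi-axis ranges and centre
#: depth.  Lateral sizes are kept below the ad-hoc default so that the densest
#: preset (23 glands) still packs into the useful surface at non-overlap
#: spacing.
COHORT_LATERAL_SEMI_AXIS_UM = (400.0, 700.0)
COHORT_AXIAL_SEMI_AXIS_UM = (300.0, 450.0)
COHORT_GLAND_DEPTH_UM = 750.0
COHORT_MIN_SPACING_UM = 1900.0

#: per-subject gland counts for the two cohort presets (18 subjects each);
#: the group medians, divided by the 2.43 cm^2 useful surface, equal the
#: density medians the pipeline is meant to reproduce.
CF_LIKE_COUNTS = (5, 6, 7, 7, 8, 9, 10, 10, 10, 11, 12, 13, 14, 15, 15, 16, 17, 18)
HS_LIKE_COUNTS = (10, 11, 12, 13, 14, 14, 15, 16, 16, 16, 17, 18, 19, 20, 20, 21, 22, 23)

GROUP_SIZE = 18


@dataclass(frozen=True)
class GlandSpec:
    """One gland: lateral centre (cm), centre depth below the surface (um),
    ellipsoid semi-axes (x, y, z; um) and whether an excretory duct connects
    it to the surface."""

    center_xy_cm: tuple[float, float]
    center_depth_um: float
    semi_axes_um: tuple[float, float, float]
    has_duct: bool = True


@dataclass(frozen=True)
class PhantomConfig:
    """Full description of one synthetic volume; equal configs (same seed)
    produce bit-identical volumes."""

    geometry: ScanGeometry = field(default_factory=ScanGeometry)
    layer_depths_um: tuple[float, float] = DEFAULT_LAYER_DEPTHS_UM
    layer_reflectivities: tuple[float, float, float] = DEFAULT_LAYER_REFLECTIVITIES
    gland_specs: tuple[GlandSpec, ...] = ()
    duct_radius_um: float = 30.0
    gland_contrast: float = 0.25
    attenuation_per_mm: float = 0.8
    surface_tilt: tuple[float, float, float] = (400.0, 60.0, 40.0)  # z0, dz/dx, dz/dy (um, um/cm)
    bulge_amp_um: float = 150.0
    speckle: bool = True
    noise_floor_sd: float = 0.01
    seed: int = 0
    useful_area_cm2: float = 2.43  # only consulted for truth border flags

    def __post_init__(self) -> None:
        if not 0.0 < self.gland_contrast < 1.0:
            raise ConfigurationError("gland_contrast must lie in (0, 1): glands are hypointense")
        if self.duct_radius_um <= 0 or self.attenuation_per_mm < 0:
            raise ConfigurationError("duct radius must be > 0 and attenuation >= 0")
        if not (0 < self.layer_depths_um[0] < self.layer_depths_um[1]):
            raise ConfigurationError("layer depths must be increasing and positive")
        g = self.geometry
        depth_um = g.depth_range_mm * 1e3
        for i, spec in enumerate(self.gland_specs):
            cx, cy = spec.center_xy_cm
            ax, ay, az = spec.semi_axes_um
            if min(ax, ay, az) <= 0:
                raise ConfigurationError(f"gland {i}: semi-axes must be > 0")
            if not (0 <= cx * 1e4 - ax and cx * 1e4 + ax <= g.fov_lateral_cm * 1e4):
                raise ConfigurationError(f"gland {i} exceeds the field laterally (x)")
            if not (0 <= cy * 1e4 - ay and cy * 1e4 + ay <= g.fov_lateral_cm * 1e4):
                raise ConfigurationError(f"gland {i} exceeds the field laterally (y)")
            if spec.center_depth_um - az < 0:
                raise ConfigurationError(f"gland {i} breaches the tissue surface")
            z_top = _surface_um(self, np.asarray([cx]), np.asarray([cy]))[0]
            if z_top + spec.center_depth_um + az > depth_um:
                raise ConfigurationError(f"gland {i} exceeds the imaging depth range")


@dataclass
class PhantomTruth:
    """Generator-side ground truth for one volume.

    ``glands`` has one row per gland: id, centre (cm and um depth), semi-axes,
    ``has_duct`` and ``touches_useful_border``.  ``expected_accepted`` applies
    the counting rule (duct required unless the focus sits at the useful-surface
    border) to the glands visible inside the useful surface.
    """

    glands: pd.DataFrame
    surface_tilt: tuple[float, float, float]
    bulge_amp_um: float
    expected_accepted: int


@dataclass(frozen=True)
class CohortPreset:
    """Per-subject gland counts and seeds for one 18-subject group."""

    label: str
    counts: tuple[int, ...]
    seeds: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.counts) != GROUP_SIZE:
            raise ConfigurationError(f"a cohort preset needs exactly {GROUP_SIZE} subjects")
        if len(self.seeds) != len(self.counts):
            raise ConfigurationError("one seed per subject required")
        if any(c < 0 for c in self.counts):
            raise ConfigurationError("gland counts must be non-negative")


def cf_like_preset(base_seed: int = 0) -> CohortPreset:
    """Lower-density group; subject seeds are ``base_seed + index``."""
    return CohortPreset(
        label="CF-like",
        counts=CF_LIKE_COUNTS,
        seeds=tuple(base_seed + i for i in range(GROUP_SIZE)),
    )


def hs_like_preset(base_seed: int = 100) -> CohortPreset:
    """Higher-density group; subject seeds are ``base_seed + index``."""
    return CohortPreset(
        label="HS-like",
        counts=HS_LIKE_COUNTS,
        seeds=tuple(base_seed + i for i in range(GROUP_SIZE)),
    )


# ------------------------------------------------------------------ surface --


def _surface_um(config: PhantomConfig, x_cm: np.ndarray, y_cm: np.ndarray) -> np.ndarray:
    """Interface depth (um from the top of the window) at lateral positions."""
    z0, gx, gy = config.surface_tilt
    half = config.geometry.fov_lateral_cm / 2.0
    r2 = ((x_cm - half) ** 2 + (y_cm - half) ** 2) / (2.0 * half**2)  # 1 at the corners
    return z0 + gx * (x_cm - half) + gy * (y_cm - half) + config.bulge_amp_um * r2


# ------------------------------------------------------------------- volume --


def simulate_volume(config: PhantomConfig) -> tuple[OctVolume, PhantomTruth]:
    """Render one phantom volume and its ground truth.

    Deterministic in ``config`` (including ``seed``): running the same config
    twice yields byte-identical volumes.
    """
    g = config.geometry
    rng = np.random.default_rng(config.seed)
    dy, dx, dz = g.spacing_um

    x_cm = (np.arange(g.n_fast) + 0.5) * g.fov_lateral_cm / g.n_fast
    y_cm = (np.arange(g.n_slow) + 0.5) * g.fov_lateral_cm / g.n_slow
    zs = _surface_um(config, x_cm[None, :], y_cm[:, None]).astype(np.float32)
    z_um = ((np.arange(g.n_depth) + 0.5) * dz).astype(np.float32)

    # depth below the local surface, negative above it
    d = z_um[None, None, :] - zs[:, :, None]

    l0, l1 = config.layer_depths_um
    r0, r1, r2_ = config.layer_reflectivities
    refl = np.where(d < l0, np.float32(r0), np.where(d < l1, np.float32(r1), np.float32(r2_)))
    base = refl * np.exp(np.float32(-config.attenuation_per_mm / 1e3) * np.maximum(d, 0))
    base[d < 0] = 0.0
    del refl

    contrast = np.float32(config.gland_contrast)
    for spec in config.gland_specs:
        _stamp_gland(base, d, config, spec, x_cm, y_cm, contrast)

    if config.speckle:
        # unit-mean exponential speckle, drawn in float32 to bound memory
        u = rng.random(base.shape, dtype=np.float32)
        base *= -np.log1p(-u)
        del u
    if config.noise_floor_sd > 0:
        base += np.float32(config.noise_floor_sd) * rng.standard_normal(
            base.shape, dtype=np.float32
        )
        np.clip(base, 0.0, None, out=base)

    volume = OctVolume(intensity=base, spacing_um=g.spacing_um, geometry=g)
    truth = _build_truth(config)
    return volume, truth


def _stamp_gland(
    base: np.ndarray,
    d: np.ndarray,
    config: PhantomConfig,
    spec: GlandSpec,
    x_cm: np.ndarray,
    y_cm: np.ndarray,
    contrast: np.float32,
) -> None:
    """Scale the gland ellipsoid (and its duct channel) by the contrast factor.

    Coordinates are depth-below-surface, so glands drape with the interface.
    A duct narrower than the lateral pitch is still rendered through the
    single A-scan column nearest its axis: a beam passing through a sub-pitch
    duct sees the full intensity drop, which is what makes ducts recognisable
    at the instrument's sampling density.
    """
    cx_um, cy_um = spec.center_xy_cm[0] * 1e4, spec.center_xy_cm[1] * 1e4
    ax, ay, az = spec.semi_axes_um
    x_um = x_cm * 1e4
    y_um = y_cm * 1e4

    ix = np.flatnonzero(np.abs(x_um - cx_um) <= max(ax, config.duct_radius_um) + x_um[1] - x_um[0])
    iy = np.flatnonzero(np.abs(y_um - cy_um) <= max(ay, config.duct_radius_um) + y_um[1] - y_um[0])
    if ix.size == 0 or iy.size == 0:
        return
    sx, sy = slice(ix[0], ix[-1] + 1), slice(iy[0], iy[-1] + 1)

    xx = (x_um[sx] - cx_um) / ax
    yy = (y_um[sy] - cy_um) / ay
    dd = d[sy, sx, :]
    ell = (
        xx[None, :, None] ** 2
        + yy[:, None, None] ** 2
        + ((dd - spec.center_depth_um) / az) ** 2
    ) <= 1.0
    sub = base[sy, sx, :]
    sub[ell] *= contrast

    if spec.has_duct:
        r2_lat = (x_um[sx] - cx_um)[None, :] ** 2 + (y_um[sy] - cy_um)[:, None] ** 2
        lat = r2_lat <= config.duct_radius_um**2
        # guarantee at least the nearest column carries the duct shadow
        lat.flat[int(np.argmin(r2_lat))] = True
        top = spec.center_depth_um - az
        duct = lat[:, :, None] & (dd >= 0) & (dd < top) & ~ell
        sub[duct] *= contrast
    base[sy, sx, :] = sub


def _build_truth(config: PhantomConfig) -> PhantomTruth:
    g = config.geometry
    rows = []
    if config.gland_specs:
        mask, _ = solve_useful_mask(g, config.useful_area_cm2)
        edge_zone = mask & ~ndimage.binary_erosion(mask)
        x_cm = (np.arange(g.n_fast) + 0.5) * g.fov_lateral_cm / g.n_fast
        y_cm = (np.arange(g.n_slow) + 0.5) * g.fov_lateral_cm / g.n_slow
        for i, spec in enumerate(config.gland_specs):
            fx = ((x_cm - spec.center_xy_cm[0]) * 1e4 / spec.semi_axes_um[0]) ** 2
            fy = ((y_cm - spec.center_xy_cm[1]) * 1e4 / spec.semi_axes_um[1]) ** 2
            footprint = fx[None, :] + fy[:, None] <= 1.0
            visible = bool((footprint & mask).any())
            touches = visible and bool(
                (footprint & ~mask).any() or (footprint & edge_zone).any()
            )
            rows.append(
                {
                    "gland_id": i,
                    "x_cm": spec.center_xy_cm[0],
                    "y_cm": spec.center_xy_cm[1],
                    "depth_um": spec.center_depth_um,
                    "semi_x_um": spec.semi_axes_um[0],
                    "semi_y_um": spec.semi_axes_um[1],
                    "semi_z_um": spec.semi_axes_um[2],
                    "has_duct": spec.has_duct,
                    "visible": visible,
                    "touches_useful_border": touches,
                }
            )
    glands = pd.DataFrame(
        rows,
        columns=[
            "gland_id",
            "x_cm",
            "y_cm",
            "depth_um",
            "semi_x_um",
            "semi_y_um",
            "semi_z_um",
            "has_duct",
            "visible",
            "touches_useful_border",
        ],
    )
    if len(glands):
        accepted = glands["visible"] & (glands["has_duct"] | glands["touches_useful_border"])
        expected = int(accepted.sum())
    else:
        expected = 0
    return PhantomTruth(
        glands=glands,
        surface_tilt=config.surface_tilt,
        bulge_amp_um=config.bulge_amp_um,
        expected_accepted=expected,
    )


# ------------------------------------------------------------------- cohort --


def _place_glands(
    count: int,
    rng: np.random.Generator,
    config: PhantomConfig,
    min_spacing_um: float = COHORT_MIN_SPACING_UM,
    max_draws: int = 20_000,
    max_restarts: int = 20,
) -> tuple[GlandSpec, ...]:
    """Rejection-sample non-overlapping duct-bearing glands inside the useful
    surface, clear of its border."""
    if count == 0:
        return ()
    g = config.geometry
    mask, _ = solve_useful_mask(g, config.useful_area_cm2)
    # distance (um) from each pixel to the mask edge; the array border counts
    # as outside so glands stay clear of the clipped field sides too
    inner = mask.copy()
    inner[0, :] = inner[-1, :] = inner[:, 0] = inner[:, -1] = False
    edt = ndimage.distance_transform_edt(inner, sampling=(g.dy_um, g.dx_um))
    fov_um = g.fov_lateral_cm * 1e4

    for _ in range(max_restarts):
        centers: list[tuple[float, float]] = []
        specs: list[GlandSpec] = []
        draws = 0
        while len(specs) < count and draws < max_draws:
            draws += 1
            ax = rng.uniform(*COHORT_LATERAL_SEMI_AXIS_UM)
            ay = rng.uniform(*COHORT_LATERAL_SEMI_AXIS_UM)
            az = rng.uniform(*COHORT_AXIAL_SEMI_AXIS_UM)
            cx = rng.uniform(0, fov_um)
            cy = rng.uniform(0, fov_um)
            px = min(int(cx / g.dx_um), g.n_fast - 1)
            py = min(int(cy / g.dy_um), g.n_slow - 1)
            # footprint fully interior: stay clear of the mask edge by two pixels
            if edt[py, px] < max(ax, ay) + 2.0 * max(g.dx_um, g.dy_um):
                continue
            if any((cx - ox) ** 2 + (cy - oy) ** 2 < min_spacing_um**2 for ox, oy in centers):
                continue
            centers.append((cx, cy))
            specs.append(
                GlandSpec(
                    center_xy_cm=(cx / 1e4, cy / 1e4),
                    center_depth_um=COHORT_GLAND_DEPTH_UM,
                    semi_axes_um=(ax, ay, az),
                    has_duct=True,
                )
            )
        if len(specs) == count:
            return tuple(specs)
    raise PlacementError(
        f"could not place {count} glands at {min_spacing_um:.0f} um spacing "
        f"within {max_restarts} restarts of {max_draws} draws"
    )


def iter_cohort(
    preset: CohortPreset, base_config: PhantomConfig
) -> Iterator[tuple[OctVolume, PhantomTruth]]:
    """Lazily generate one volume per subject of ``preset``.

    Subject ``i`` contains exactly ``preset.counts[i]`` duct-bearing glands,
    rejection-placed without overlap inside the useful surface; the subject's
    volume seed is ``preset.seeds[i]``.
    """
    for count, seed in zip(preset.counts, preset.seeds):
        placement_rng = np.random.default_rng(seed)
        specs = _place_glands(count, placement_rng, base_config)
        cfg = replace(base_config, gland_specs=specs, seed=seed)
        yield simulate_volume(cfg)


def simulate_cohort(
    preset: CohortPreset, base_config: PhantomConfig
) -> list[tuple[OctVolume, PhantomTruth]]:
    """Materialise the whole cohort as a list.

    At the full 400x400x512 geometry each volume is ~330 MB; prefer
    :func:`iter_cohort` when volumes are processed one at a time.
    """
    return list(iter_cohort(preset, base_config))
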