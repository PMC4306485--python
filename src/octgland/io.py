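"""Volume, table and report I/O.

Volumes travel as multi-page TIFF (one page per B-scan, i.e. per slow-axis
position) with a JSON sidecar carrying the voxel spacing and scan geometry;
gland truth and candidate tables as CSV; summaries and manifests as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .geometry import ScanGeometry
from .glands import CScan, GlandCandidate
from .preprocess import OctVolume
from .simulate import PhantomTruth

__all__ = [
    "write_volume",
    "read_volume",
    "sidecar_path",
    "write_cscan",
    "write_truth",
    "write_candidates",
    "write_json",
]


def sidecar_path(volume_path: Path | str) -> Path:
    return Path(volume_path).with_suffix(".json")


def write_volume(path: Path | str, volume: OctVolume) -> Path:
    """Write a volume as multi-page TIFF plus a JSON geometry sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, volume.intensity, photometric="minisblack")
    g = volume.geometry
    meta = {
        "spacing_um": list(volume.spacing_um),
        "geometry": {
            "n_fast": g.n_fast,
            "n_slow": g.n_slow,
            "n_depth": g.n_depth,
            "fov_lateral_cm": g.fov_lateral_cm,
            "depth_range_mm": g.depth_range_mm,
            "sweep_rate_hz": g.sweep_rate_hz,
            "center_wavelength_nm": g.center_wavelength_nm,
            "tuning_range_nm": g.tuning_range_nm,
        },
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_volume(path: Path | str) -> OctVolume:
    """Read a multi-page TIFF volume and its JSON sidecar."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    side = sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(f"volume sidecar not found: {side}")
    meta = json.loads(side.read_text())
    geometry = ScanGeometry(**meta["geometry"])
    data = tifffile.imread(path)
    return OctVolume(
        intensity=np.asarray(data, dtype=np.float32),
        spacing_um=tuple(meta["spacing_um"]),
        geometry=geometry,
    )


def write_cscan(path: Path | str, cscan: CScan) -> Path:
    """En-face projection as a single-page TIFF with the slab recorded in the
    image description."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    desc = json.dumps(
        {
            "depth_um": cscan.depth_um,
            "thickness_um": cscan.thickness_um,
            "spacing_um": list(cscan.spacing_um),
        }
    )
    tifffile.imwrite(
        path, cscan.values.astype(np.float32), photometric="minisblack", description=desc
    )
    return path


def write_truth(path: Path | str, truth: PhantomTruth) -> Path:
    """Ground-truth gland table as CSV, with a JSON companion holding the
    surface coefficients and the expected accepted count."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    truth.glands.to_csv(path, index=False)
    meta = {
        "surface_tilt": list(truth.surface_tilt),
        "bulge_amp_um": truth.bulge_amp_um,
        "expected_accepted": truth.expected_accepted,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def candidates_frame(candidates: Sequence[GlandCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": c.id,
                "x_cm": c.centroid_cm[0],
                "y_cm": c.centroid_cm[1],
                "area_mm2": c.area_mm2,
                "mean_intensity": c.mean_intensity,
                "has_duct": c.has_duct,
                "on_border": c.on_border,
                "accepted": c.accepted,
            }
            for c in candidates
        ],
        columns=[
            "id",
            "x_cm",
            "y_cm",
            "area_mm2",
            "mean_intensity",
            "has_duct",
            "on_border",
            "accepted",
        ],
    )


def write_candidates(path: Path | str, candidates: Sequence[GlandCandidate]) -> Path:
    """Candidate table as CSV and JSON (same stem)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = candidates_frame(candidates)
    df.to_csv(path, index=False)
    path.with_suffix(".json").write_text(df.to_json(orient="records", indent=2))
    return path


def write_json(path: Path | str, payload: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path
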