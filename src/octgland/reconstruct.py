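"""Spectral-fringe synthesis and A-scan reconstruction.

In swept-source OCT the interference fringe recorded over one wavelength sweep
encodes each reflector's depth in its oscillation frequency: a reflector at
depth ``d`` contributes a cosine whose frequency, in cycles per sweep, is
proportional to ``d``.  The depth profile (A-scan) is the magnitude of the
Fourier transform of the fringe over positive frequencies.  A linear-in-
wavenumber sweep and real-valued detection are assumed, so the unambiguous
depth range maps onto the ``n_k/2`` positive-frequency bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["FringeRecord", "synthesize_fringe", "reconstruct_ascan", "depth_per_bin_um"]

DEFAULT_N_K = 1024
DEFAULT_DEPTH_RANGE_MM = 3.4


@dataclass(frozen=True)
class FringeRecord:
    """Real-valued spectral interferogram over one sweep."""

    samples: np.ndarray
    depth_range_mm: float = DEFAULT_DEPTH_RANGE_MM

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=np.float64)
        if s.ndim != 1:
            raise ValueError("fringe must be a 1-D record")
        object.__setattr__(self, "samples", s)

    @property
    def n_k(self) -> int:
        return self.samples.size


def depth_per_bin_um(n_k: int, depth_range_mm: float = DEFAULT_DEPTH_RANGE_MM) -> float:
    """Depth increment of one positive-frequency bin (um)."""
    return depth_range_mm * 1e3 / (n_k // 2)


def synthesize_fringe(
    reflectors: Sequence[tuple[float, float]],
    n_k: int = DEFAULT_N_K,
    depth_range_mm: float = DEFAULT_DEPTH_RANGE_MM,
) -> FringeRecord:
    """Sum-of-cosines fringe for point reflectors ``(depth_um, amplitude)``.

    Each reflector at depth ``d`` contributes ``a * cos(2*pi * f * j / n_k)``
    with ``f = d / depth_per_bin``; the Nyquist bin ``n_k/2`` corresponds to
    the full depth range.
    """
    if n_k < 8 or (n_k & (n_k - 1)) != 0:
        raise ValueError(f"n_k must be a power of two >= 8, got {n_k}")
    depth_range_um = depth_range_mm * 1e3
    j = np.arange(n_k)
    samples = np.zeros(n_k, dtype=np.float64)
    dpb = depth_per_bin_um(n_k, depth_range_mm)
    for depth_um, amplitude in reflectors:
        if not 0 <= depth_um < depth_range_um:
            raise ValueError(
                f"reflector depth {depth_um} um outside the unambiguous range "
                f"[0, {depth_range_um}) um"
            )
        samples += amplitude * np.cos(2.0 * np.pi * (depth_um / dpb) * j / n_k)
    return FringeRecord(samples=samples, depth_range_mm=depth_range_mm)


def reconstruct_ascan(fringe: FringeRecord) -> np.ndarray:
    """Depth profile: transform magnitude over the positive-frequency half.

    Normalised so a unit-amplitude cosine at bin ``b`` yields a profile value
    of ~1 at index ``b``; index ``k`` corresponds to depth
    ``k * depth_per_bin_um(n_k, depth_range_mm)``.
    """
    if fringe.n_k < 8:
        raise ValueError("fringe record too short (need >= 8 samples)")
    spectrum = np.fft.rfft(fringe.samples)
    profile = np.abs(spectrum[: fringe.n_k // 2]) / (fringe.n_k / 2.0)
    return profile
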