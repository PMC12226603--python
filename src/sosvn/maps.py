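"""Slowness and speed-of-sound maps and their conversions.

The reconstructed quantity is the slowness *deviation* ``x`` (s/mm) from the
beamforming slowness ``x0 = 1 / c0`` (with ``c0`` in mm/s internally); the
speed-of-sound map follows as ``c = 1 / (x + x0)``.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .geometry import ImagingGrid

MM_PER_M = 1000.0


def slowness_of(c_m_per_s: float) -> float:
    """Slowness (s/mm) of a speed of sound given in m/s."""
    if c_m_per_s <= 0:
        raise ValueError("speed of sound must be positive")
    return 1.0 / (c_m_per_s * MM_PER_M)


@dataclasses.dataclass
class SoSMap:
    """Speed-of-sound map in m/s on an imaging grid."""

    values: np.ndarray
    grid: ImagingGrid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"SoS map shape {self.values.shape} does not match grid {self.grid.shape}"
            )


@dataclasses.dataclass
class SlownessMap:
    """Slowness-deviation map ``x`` (s/mm) plus the beamforming slowness ``x0``."""

    values: np.ndarray
    x0: float
    grid: ImagingGrid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"slowness map shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if self.x0 <= 0:
            raise ValueError("beamforming slowness must be positive")


def slowness_to_sos(x: SlownessMap) -> SoSMap:
    """Elementwise conversion ``c = 1 / (x + x0)``, returned in m/s."""
    total = x.values + x.x0
    bad = int(np.count_nonzero(total <= 0))
    if bad:
        raise ValueError(
            f"nonpositive total slowness at {bad} pixel(s); cannot convert to SoS"
        )
    return SoSMap(values=1.0 / (total * MM_PER_M), grid=x.grid)


def sos_to_slowness(c: SoSMap, c0: float) -> SlownessMap:
    """Inverse of :func:`slowness_to_sos` for a beamforming SoS ``c0`` (m/s)."""
    if np.any(c.values <= 0):
        raise ValueError("speed of sound must be positive everywhere")
    x0 = slowness_of(c0)
    return SlownessMap(values=1.0 / (c.values * MM_PER_M) - x0, x0=x0, grid=c.grid)
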