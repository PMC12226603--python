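"""Trust attribution: uncertainty-based selection among repeated acquisitions.

For each acquired frame, the per-pixel uncertainty map is reduced to an
inclusion mean and a background mean over the 5 mm ring surrounding the
inclusion; the *relative* uncertainty is their absolute difference.  Frame
selection picks the frame minimizing relative uncertainty (policy SI_rel) or
inclusion uncertainty (SI_inc); uninformed baselines take the first frame
(S1), the third (S3), or a uniformly random one (SR).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.ndimage

from .geometry import ImagingGrid
from .uncertainty import PosteriorSummary

POLICIES = ("SI_rel", "SI_inc", "S1", "S3", "SR")


@dataclasses.dataclass
class FrameScore:
    """Per-frame uncertainty statistics (m/s)."""

    frame_index: int
    inc_unc: float
    bkg_unc: float

    @property
    def rel_unc(self) -> float:
        return abs(self.inc_unc - self.bkg_unc)


@dataclasses.dataclass(frozen=True)
class SelectionPolicy:
    policy: str = "SI_rel"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.policy not in POLICIES:
            raise ValueError(f"unknown policy {self.policy!r}; one of {POLICIES}")


def ring_background_mask(
    inclusion: np.ndarray, grid: ImagingGrid, ring_mm: float = 5.0
) -> np.ndarray:
    """Ring of width ``ring_mm`` around the inclusion (morphological dilation).

    The dilation uses an axis-aligned rectangular structuring element whose
    half-widths are ``ceil(ring_mm / pitch)`` pixels per axis (anisotropic
    pitches honored); the inclusion itself is subtracted, so the ring is
    disjoint from it by construction and clipped at the image bounds.
    """
    inclusion = np.asarray(inclusion, dtype=bool)
    if inclusion.shape != grid.shape:
        raise ValueError("inclusion mask shape does not match grid")
    if not inclusion.any():
        raise ValueError("inclusion mask is empty")
    r_ax = int(np.ceil(ring_mm / grid.pitch_ax))
    r_lat = int(np.ceil(ring_mm / grid.pitch_lat))
    if r_ax < 1 or r_lat < 1:
        return np.zeros_like(inclusion)
    structure = np.ones((2 * r_ax + 1, 2 * r_lat + 1), dtype=bool)
    dilated = scipy.ndimage.binary_dilation(inclusion, structure=structure)
    return dilated & ~inclusion


def score_frame(
    summary: PosteriorSummary,
    inclusion: np.ndarray,
    grid: ImagingGrid,
    ring_mm: float = 5.0,
    frame_index: int = 0,
    reducer: str = "mean",
) -> FrameScore:
    """Inclusion / ring-background uncertainty means for one frame."""
    inclusion = np.asarray(inclusion, dtype=bool)
    if summary.std_map.shape != grid.shape or inclusion.shape != grid.shape:
        raise ValueError("masks and uncertainty map must live on the same grid")
    ring = ring_background_mask(inclusion, grid, ring_mm)
    if not ring.any():
        raise ValueError("ring background mask is empty")
    red = np.median if reducer == "median" else np.mean
    return FrameScore(
        frame_index=frame_index,
        inc_unc=float(red(summary.std_map[inclusion])),
        bkg_unc=float(red(summary.std_map[ring])),
    )


def select_frame(
    scores: list[FrameScore],
    policy: SelectionPolicy,
    rng: np.random.Generator | None = None,
) -> int:
    """Select one frame index; ties broken by lowest index, SR is random."""
    if not scores:
        raise ValueError("no frames to select from")
    n = len(scores)
    if policy.policy == "S1":
        return 0
    if policy.policy == "S3":
        if n < 3:
            raise ValueError("policy S3 requires at least 3 frames")
        return 2
    if policy.policy == "SR":
        if rng is None:
            rng = np.random.default_rng(policy.seed)
        return int(rng.integers(n))
    key = (lambda sc: sc.rel_unc) if policy.policy == "SI_rel" else (lambda sc: sc.inc_unc)
    values = [key(sc) for sc in scores]
    return int(np.argmin(values))  # argmin takes the first of tied minima
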