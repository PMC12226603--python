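"""Imaging geometry and the straight-ray differential forward model.

Pulse-echo speed-of-sound imaging measures apparent echo shifts (time delays)
between frames beamformed from different virtual-source (VS) transmits.  A
local deviation of the slowness (inverse speed of sound) from the beamforming
slowness delays the echo of a scatterer by the path integral of the deviation
along the round-trip propagation path.  Tracking displacements between a
*pair* of transmits therefore senses the *difference* of the two round-trip
path integrals, which this module encodes as a sparse matrix ``L`` acting on
the vectorized slowness-deviation map.

Conventions
-----------
* Axial axis (``ax``) points away from the transducer, lateral axis (``lat``)
  along the aperture; the aperture sits at the top edge of the grid, centered
  laterally at 0.
* Pixel centers are at ``(i + 0.5) * pitch`` from the grid edge; indices are
  zero based, arrays are ``(n_ax, n_lat)`` row-major.
* ``L`` entries are path lengths in mm, so applying ``L`` to a slowness
  deviation in s/mm yields time delays in seconds.

The rays are straight (refraction-free); this is the single largest modeling
simplification and is shared by the simulator and all reconstructors (the
simulator avoids the inverse crime by using a finer discretization, not a
different physics).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg


@dataclasses.dataclass(frozen=True)
class ImagingGrid:
    """Regular reconstruction/measurement grid.

    Parameters
    ----------
    n_ax, n_lat : int
        Pixel counts along the axial (depth) and lateral directions.
    pitch_ax, pitch_lat : float
        Pixel pitches in mm.
    depth_offset : float
        Axial position (mm) of the top grid edge relative to the aperture.
    """

    n_ax: int
    n_lat: int
    pitch_ax: float
    pitch_lat: float
    depth_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.n_ax < 2 or self.n_lat < 2:
            raise ValueError("grid needs at least 2 pixels per axis")
        if self.pitch_ax <= 0 or self.pitch_lat <= 0:
            raise ValueError("pixel pitches must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_ax, self.n_lat)

    @property
    def n_pixels(self) -> int:
        return self.n_ax * self.n_lat

    @property
    def width(self) -> float:
        """Lateral extent in mm."""
        return self.n_lat * self.pitch_lat

    @property
    def depth(self) -> float:
        """Axial extent in mm."""
        return self.n_ax * self.pitch_ax

    @property
    def lateral_edges(self) -> np.ndarray:
        return -0.5 * self.width + np.arange(self.n_lat + 1) * self.pitch_lat

    @property
    def axial_edges(self) -> np.ndarray:
        return self.depth_offset + np.arange(self.n_ax + 1) * self.pitch_ax

    @property
    def lateral_centers(self) -> np.ndarray:
        return self.lateral_edges[:-1] + 0.5 * self.pitch_lat

    @property
    def axial_centers(self) -> np.ndarray:
        return self.axial_edges[:-1] + 0.5 * self.pitch_ax

    def upsample(self, factor: int) -> "ImagingGrid":
        """Grid covering the same field of view at ``factor``-times finer pitch."""
        if factor < 1:
            raise ValueError("upsampling factor must be >= 1")
        return ImagingGrid(
            self.n_ax * factor,
            self.n_lat * factor,
            self.pitch_ax / factor,
            self.pitch_lat / factor,
            self.depth_offset,
        )

    def same_fov(self, other: "ImagingGrid", tol: float = 1e-9) -> bool:
        return (
            abs(self.width - other.width) <= tol
            and abs(self.depth - other.depth) <= tol
            and abs(self.depth_offset - other.depth_offset) <= tol
        )


def _default_angles(n_transmits: int, span_deg: float = 20.0) -> tuple[float, ...]:
    return tuple(np.linspace(-span_deg, span_deg, n_transmits))


@dataclasses.dataclass(frozen=True)
class AcquisitionSpec:
    """Virtual-source transmit sequence.

    ``n_transmits`` steered transmits are fired; displacements are tracked
    between transmits a fixed index gap ``pair_offset`` apart, giving
    ``n_transmits - pair_offset`` measurement pairs (17 transmits with offset
    2 give the standard 15 displacement maps).  Each virtual source sits
    ``vs_focal_mm`` behind the aperture, laterally placed so its central ray
    crosses the aperture center at the given steering angle.
    """

    n_transmits: int = 17
    pair_offset: int = 2
    vs_angles_deg: tuple[float, ...] | None = None
    c0: float = 1500.0
    aperture_width: float | None = None
    vs_focal_mm: float = 25.0

    def __post_init__(self) -> None:
        if self.n_transmits < 2:
            raise ValueError("need at least 2 transmits")
        if self.c0 <= 0:
            raise ValueError("beamforming speed of sound must be positive")
        if self.vs_angles_deg is not None:
            angles = np.asarray(self.vs_angles_deg, dtype=float)
            if len(angles) != self.n_transmits:
                raise ValueError("vs_angles_deg length must equal n_transmits")
            if np.any(np.diff(angles) <= 0):
                raise ValueError("vs_angles_deg must be strictly increasing")

    @property
    def angles_deg(self) -> np.ndarray:
        if self.vs_angles_deg is None:
            return np.asarray(_default_angles(self.n_transmits))
        return np.asarray(self.vs_angles_deg, dtype=float)

    @property
    def n_pairs(self) -> int:
        return self.n_transmits - self.pair_offset

    def vs_positions(self) -> np.ndarray:
        """(n_transmits, 2) virtual-source positions (lat, ax) in mm, ax < 0."""
        theta = np.deg2rad(self.angles_deg)
        z = -self.vs_focal_mm * np.ones_like(theta)
        x = -(-z) * np.tan(theta)  # central ray passes through the aperture center
        return np.stack([x, z], axis=1)


def build_transmit_pairs(spec: AcquisitionSpec) -> list[tuple[int, int]]:
    """Ordered zero-based transmit index pairs ``(i, i + pair_offset)``."""
    if spec.pair_offset < 1 or spec.pair_offset >= spec.n_transmits:
        raise ValueError(
            f"pair_offset must be in [1, n_transmits); got {spec.pair_offset} "
            f"with {spec.n_transmits} transmits"
        )
    return [(i, i + spec.pair_offset) for i in range(spec.n_transmits - spec.pair_offset)]


def _trace_segment(
    grid: ImagingGrid, p0: np.ndarray, p1: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel traversal lengths of the segment p0 -> p1 (points are (lat, ax)).

    Siddon-style exact tracing: the segment is clipped to the grid bounding
    box; crossings with pixel edge planes split it into intervals, each lying
    in a single pixel.  Returns flat pixel indices (row-major over (ax, lat))
    and lengths in mm.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    delta = p1 - p0
    seg_len = float(np.hypot(*delta))
    empty = (np.empty(0, dtype=np.int64), np.empty(0, dtype=float))
    if seg_len == 0.0:
        return empty

    xe = grid.lateral_edges
    ze = grid.axial_edges
    # Clip parameter range to the bounding box (slab method).
    t_lo, t_hi = 0.0, 1.0
    for axis, (lo, hi) in enumerate(((xe[0], xe[-1]), (ze[0], ze[-1]))):
        d = delta[axis]
        p = p0[axis]
        if d == 0.0:
            if p <= lo or p >= hi:
                return empty
        else:
            ta, tb = (lo - p) / d, (hi - p) / d
            if ta > tb:
                ta, tb = tb, ta
            t_lo = max(t_lo, ta)
            t_hi = min(t_hi, tb)
    if t_hi <= t_lo:
        return empty

    ts = [np.array([t_lo, t_hi])]
    for axis, edges in ((0, xe), (1, ze)):
        d = delta[axis]
        if d != 0.0:
            tc = (edges - p0[axis]) / d
            ts.append(tc[(tc > t_lo) & (tc < t_hi)])
    t = np.unique(np.concatenate(ts))
    t = t[(t >= t_lo - 1e-12) & (t <= t_hi + 1e-12)]
    if len(t) < 2:
        return empty

    tm = 0.5 * (t[:-1] + t[1:])
    mid = p0[None, :] + tm[:, None] * delta[None, :]
    ix = np.floor((mid[:, 0] - xe[0]) / grid.pitch_lat).astype(np.int64)
    iz = np.floor((mid[:, 1] - ze[0]) / grid.pitch_ax).astype(np.int64)
    ok = (ix >= 0) & (ix < grid.n_lat) & (iz >= 0) & (iz < grid.n_ax)
    lengths = np.diff(t) * seg_len
    ok &= lengths > 1e-12
    return (iz[ok] * grid.n_lat + ix[ok], lengths[ok])


def _transmit_path_matrix(
    vs: np.ndarray, recon_grid: ImagingGrid, meas_grid: ImagingGrid
) -> sp.csr_matrix:
    """Round-trip path matrix of one transmit.

    Row m (a measurement pixel) holds per-recon-pixel traversal lengths of the
    ray from the virtual source to that pixel plus the straight receive path
    from the pixel back up to the aperture.
    """
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    z_top = recon_grid.axial_edges[0]
    lat = meas_grid.lateral_centers
    axc = meas_grid.axial_centers
    for m_ax in range(meas_grid.n_ax):
        for m_lat in range(meas_grid.n_lat):
            target = np.array([lat[m_lat], axc[m_ax]])
            row = m_ax * meas_grid.n_lat + m_lat
            for a, b in ((vs, target), (target, np.array([target[0], z_top]))):
                idx, lng = _trace_segment(recon_grid, a, b)
                if len(idx):
                    rows.append(np.full(len(idx), row, dtype=np.int64))
                    cols.append(idx)
                    vals.append(lng)
    if rows:
        coo = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(meas_grid.n_pixels, recon_grid.n_pixels),
        )
    else:  # pragma: no cover - degenerate geometry
        coo = sp.coo_matrix((meas_grid.n_pixels, recon_grid.n_pixels))
    return coo.tocsr()


@dataclasses.dataclass
class ForwardModel:
    """Sparse differential path-integral operator.

    ``L`` maps a vectorized slowness deviation (s/mm, on ``recon_grid``) to
    stacked time-delay measurements (s), pair-major: rows
    ``[p * n_meas, (p+1) * n_meas)`` belong to transmit pair ``pairs[p]``.
    """

    L: sp.csr_matrix
    recon_grid: ImagingGrid
    meas_grid: ImagingGrid
    pairs: tuple[tuple[int, int], ...]
    spec: AcquisitionSpec
    _spectral_norm: float | None = dataclasses.field(default=None, repr=False)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def meas_shape(self) -> tuple[int, int, int]:
        return (self.n_pairs, self.meas_grid.n_ax, self.meas_grid.n_lat)

    def spectral_norm(self) -> float:
        """Largest singular value of L (cached; used for normalization)."""
        if self._spectral_norm is None:
            k = min(self.L.shape) - 1
            if k >= 1:
                try:
                    n = min(self.L.shape)
                    v0 = np.linspace(1.0, 2.0, n)  # fixed start: deterministic result
                    s = scipy.sparse.linalg.svds(
                        self.L.astype(float), k=1, return_singular_vectors=False,
                        maxiter=5000, v0=v0,
                    )
                    self._spectral_norm = float(s[0])
                except Exception:  # pragma: no cover - svds convergence corner
                    self._spectral_norm = float(
                        np.linalg.norm(self.L.toarray(), 2)
                    )
            else:  # pragma: no cover
                self._spectral_norm = float(np.linalg.norm(self.L.toarray(), 2))
        return self._spectral_norm


@dataclasses.dataclass
class DisplacementMeasurements:
    """Tracked time delays, shape (n_pairs, n_ax', n_lat'), seconds."""

    values: np.ndarray
    grid: ImagingGrid
    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.pairs), self.grid.n_ax, self.grid.n_lat):
            raise ValueError(
                f"displacement shape {self.values.shape} inconsistent with "
                f"{len(self.pairs)} pairs on grid {self.grid.shape}"
            )

    def ravel(self) -> np.ndarray:
        return self.values.ravel()


def build_forward_model(
    spec: AcquisitionSpec,
    recon_grid: ImagingGrid,
    meas_grid: ImagingGrid | None = None,
) -> ForwardModel:
    """Stack per-pair differential path matrices into the forward operator.

    For each pair (i, j) the block is ``P_i - P_j`` where ``P_t`` is the
    round-trip path matrix of transmit ``t``; the common receive leg cancels,
    leaving the differential transmit paths (rows can carry both signs).
    Rays leaving the field of view are truncated at the boundary.
    """
    if meas_grid is None:
        meas_grid = recon_grid
    if not recon_grid.same_fov(meas_grid):
        raise ValueError("reconstruction and measurement grids must share the field of view")
    pairs = tuple(build_transmit_pairs(spec))
    vs = spec.vs_positions()
    per_tx = {}
    needed = sorted({t for pr in pairs for t in pr})
    for t in needed:
        per_tx[t] = _transmit_path_matrix(vs[t], recon_grid, meas_grid)
    blocks = [per_tx[i] - per_tx[j] for (i, j) in pairs]
    L = sp.vstack(blocks, format="csr")
    L.eliminate_zeros()
    return ForwardModel(L=L, recon_grid=recon_grid, meas_grid=meas_grid, pairs=pairs, spec=spec)


def apply_forward(model: ForwardModel, x) -> DisplacementMeasurements:
    """Noise-free predicted measurements ``d = L x`` for a slowness deviation."""
    values = np.asarray(getattr(x, "values", x), dtype=float)
    if values.shape != model.recon_grid.shape:
        raise ValueError(
            f"slowness map shape {values.shape} does not match recon grid "
            f"{model.recon_grid.shape}"
        )
    d = model.L @ values.ravel()
    return DisplacementMeasurements(
        values=d.reshape(model.meas_shape), grid=model.meas_grid, pairs=model.pairs
    )
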