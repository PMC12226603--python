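"""Independent brute-force oracles used across the test suite.

These deliberately avoid the package's own numerical paths: dense matrices,
fine-step ray marching, direct summation, and exhaustive enumeration.
"""

from __future__ import annotations

import itertools

import numpy as np

from sosvn.geometry import AcquisitionSpec, ImagingGrid


def ray_march_path_row(
    grid: ImagingGrid, p0: np.ndarray, p1: np.ndarray, step: float
) -> np.ndarray:
    """Per-pixel traversal lengths of segment p0->p1 by midpoint marching."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    length = float(np.hypot(*(p1 - p0)))
    row = np.zeros(grid.n_pixels)
    if length == 0:
        return row
    n = max(2, int(np.ceil(length / step)))
    ds = length / n
    t = (np.arange(n) + 0.5) / n
    pts = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    xe, ze = grid.lateral_edges, grid.axial_edges
    ix = np.floor((pts[:, 0] - xe[0]) / grid.pitch_lat).astype(int)
    iz = np.floor((pts[:, 1] - ze[0]) / grid.pitch_ax).astype(int)
    ok = (ix >= 0) & (ix < grid.n_lat) & (iz >= 0) & (iz < grid.n_ax)
    np.add.at(row, iz[ok] * grid.n_lat + ix[ok], ds)
    return row


def ray_march_forward_matrix(
    spec: AcquisitionSpec, grid: ImagingGrid, step: float
) -> np.ndarray:
    """Dense differential path matrix via fine-step marching (pair-major)."""
    from sosvn.geometry import build_transmit_pairs

    vs = spec.vs_positions()
    z_top = grid.axial_edges[0]
    n_meas = grid.n_pixels
    per_tx = {}
    pairs = build_transmit_pairs(spec)
    needed = sorted({t for p in pairs for t in p})
    lat, axc = grid.lateral_centers, grid.axial_centers
    for t in needed:
        P = np.zeros((n_meas, grid.n_pixels))
        for m_ax in range(grid.n_ax):
            for m_lat in range(grid.n_lat):
                target = np.array([lat[m_lat], axc[m_ax]])
                row = ray_march_path_row(grid, vs[t], target, step)
                row += ray_march_path_row(
                    grid, target, np.array([target[0], z_top]), step
                )
                P[m_ax * grid.n_lat + m_lat] = row
        per_tx[t] = P
    return np.vstack([per_tx[i] - per_tx[j] for i, j in pairs])


def auc_by_pair_counting(scores, labels) -> float:
    """AUC as the concordant-pair fraction with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def ranksum_p_by_enumeration(a, b) -> float:
    """Two-sided rank-sum p by enumerating every label assignment of the
    pooled values (recomputing midranks from the values each time)."""
    import scipy.stats

    pooled = np.concatenate([np.asarray(a, float), np.asarray(b, float)])
    n1 = len(a)
    ranks = scipy.stats.rankdata(pooled)
    obs = ranks[:n1].sum()
    sums = [
        ranks[list(c)].sum() for c in itertools.combinations(range(len(pooled)), n1)
    ]
    sums = np.asarray(sums)
    lo = np.mean(sums <= obs + 1e-12)
    hi = np.mean(sums >= obs - 1e-12)
    return float(min(1.0, 2.0 * min(lo, hi)))


def dense_conv_same(x: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Direct-summation zero-padded convolution cropped to input size."""
    n1, n2 = x.shape
    o1, o2 = k.shape
    s1, s2 = (o1 - 1) // 2, (o2 - 1) // 2
    out = np.zeros((n1 + o1 - 1, n2 + o2 - 1))
    for a in range(n1):
        for b in range(n2):
            out[a : a + o1, b : b + o2] += x[a, b] * k
    return out[s1 : s1 + n1, s2 : s2 + n2]
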