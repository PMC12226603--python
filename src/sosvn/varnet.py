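"""Unrolled variational network for speed-of-sound reconstruction.

The network unrolls K gradient-descent steps on the inverse problem, with a
learnable data term and a field-of-experts regularizer:

    x_k = x_{k-1} - [ (s_k L)^T psi_k( s_k (L x_{k-1} - d) )
                      + sum_j rbar_k^j * ( w_k^j . phi_k^j( r_k^j * x_{k-1} ) ) ]

where ``r`` are convolution kernels, ``rbar`` the transposed (flipped)
kernels, ``w`` per-pixel weights, ``phi``/``psi`` piecewise-linear functions
parameterized by control points in a normalized response interval, and ``s``
per-pair measurement weights.  The standalone regularization weight of the
plain gradient-descent view is absorbed into the learnable ``w``.

All computations run in a nondimensionalized space: the operator is scaled
to unit spectral norm and slowness/measurements by dataset-derived units, so
parameters, responses and ADAM steps are O(1) regardless of the physical
scales (slowness deviations are ~1e-8 s/mm).

Forward pass, training loss, and full reverse-mode gradients are implemented
by hand in NumPy/SciPy; gradient correctness is checked against central
finite differences in the test suite.  The convolution machinery is batched
(one einsum over sliding windows covers a whole mini-batch, or a whole stack
of posterior samples with per-sample kernels), which is what keeps CPU
training and many-sample inference fast.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.signal import convolve2d, correlate2d

from .geometry import DisplacementMeasurements, ForwardModel
from .maps import SlownessMap, slowness_of
from .phantoms import SimDataset

# ---------------------------------------------------------------------------
# Piecewise-linear control-point functions
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ControlPointFunction:
    """Continuous piecewise-linear function on fixed knots, clamped outside.

    The identity function is represented exactly by ``y = knots``.
    """

    knots: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.knots.ndim != 1 or len(self.knots) < 2:
            raise ValueError("need at least 2 control points")
        if self.y.shape != self.knots.shape:
            raise ValueError("ordinates must match knots")
        d = np.diff(self.knots)
        if np.any(d <= 0):
            raise ValueError("knots must be strictly increasing")
        self._h = float(d[0]) if np.allclose(d, d[0], rtol=1e-12, atol=0.0) else None

    @classmethod
    def identity(cls, n_knots: int = 31, limit: float = 1.0) -> "ControlPointFunction":
        k = np.linspace(-limit, limit, n_knots)
        return cls(knots=k, y=k.copy())

    @classmethod
    def zeros(cls, n_knots: int = 31, limit: float = 1.0) -> "ControlPointFunction":
        k = np.linspace(-limit, limit, n_knots)
        return cls(knots=k, y=np.zeros(n_knots))

    def _state(self, v: np.ndarray):
        k = self.knots
        n = len(k)
        h = self._h  # cached uniform knot spacing (None if non-uniform)
        if h is not None:
            # arithmetic indexing: much faster than searchsorted
            idx = np.clip(((v - k[0]) // h).astype(np.intp) + 1, 1, n - 1)
        else:
            idx = np.clip(np.searchsorted(k, v, side="right"), 1, n - 1)
        k0, k1 = k[idx - 1], k[idx]
        t = (v - k0) / (k1 - k0)
        below = v < k[0]
        above = v > k[-1]
        np.clip(t, 0.0, 1.0, out=t)
        return idx, t, below, above

    def __call__(self, v):
        v = np.asarray(v, dtype=float)
        idx, t, below, above = self._state(v)
        f = (1.0 - t) * self.y[idx - 1] + t * self.y[idx]
        return np.where(below, self.y[0], np.where(above, self.y[-1], f))

    def eval_with_grad(self, v: np.ndarray):
        """Value, derivative w.r.t. input, and a closure for ordinate grads."""
        v = np.asarray(v, dtype=float)
        idx, t, below, above = self._state(v)
        y0, y1 = self.y[idx - 1], self.y[idx]
        f = (1.0 - t) * y0 + t * y1
        f = np.where(below, self.y[0], np.where(above, self.y[-1], f))
        clamped = below | above
        slope = (y1 - y0) / (self.knots[idx] - self.knots[idx - 1])
        slope[clamped] = 0.0
        n = len(self.y)
        # precompute flattened contribution indices/weights for ordinate grads
        idx_f = idx.ravel()
        t_f = t.ravel()
        clamped_f = clamped.ravel()
        below_f = below.ravel()
        above_f = above.ravel()

        def grad_y(g_out: np.ndarray) -> np.ndarray:
            g_f = np.asarray(g_out, dtype=float).ravel()
            w0 = np.where(clamped_f, 0.0, 1.0 - t_f) * g_f
            w1 = np.where(clamped_f, 0.0, t_f) * g_f
            g = np.bincount(idx_f - 1, weights=w0, minlength=n)
            g += np.bincount(idx_f, weights=w1, minlength=n)
            if below_f.any():
                g[0] += float(g_f[below_f].sum())
            if above_f.any():
                g[-1] += float(g_f[above_f].sum())
            return g

        return f, slope, grad_y


def eval_cpf(f: ControlPointFunction, v) -> np.ndarray:
    """Piecewise-linear interpolation of ``v`` through the control points."""
    return f(v)


def _eval_cpf_bank(phis: list[ControlPointFunction], vv: np.ndarray, with_grad: bool):
    """Evaluate one control-point function per prior on (B, J, n1, n2) input.

    All functions share the knot vector by construction, so a single gather
    covers the whole bank; falls back to a per-prior loop otherwise.
    """
    k = phis[0].knots
    if any(p.knots.shape != k.shape or not np.array_equal(p.knots, k) for p in phis[1:]):
        f = np.empty_like(vv)
        slope = np.empty_like(vv) if with_grad else None
        grad_fns = [] if with_grad else None
        for j, p in enumerate(phis):
            if with_grad:
                f[:, j], slope[:, j], g = p.eval_with_grad(vv[:, j])
                grad_fns.append(g)
            else:
                f[:, j] = p(vv[:, j])
        if not with_grad:
            return f
        return f, slope, (lambda g: [grad_fns[j](g[:, j]) for j in range(len(phis))])

    n = len(k)
    J = len(phis)
    Y = np.stack([p.y for p in phis])  # (J, n)
    h = phis[0]._h
    if h is not None:
        idx = np.clip(((vv - k[0]) // h).astype(np.intp) + 1, 1, n - 1)
    else:  # pragma: no cover - non-uniform knots
        idx = np.clip(np.searchsorted(k, vv, side="right"), 1, n - 1)
    t = (vv - k[idx - 1]) / (k[idx] - k[idx - 1])
    below = vv < k[0]
    above = vv > k[-1]
    np.clip(t, 0.0, 1.0, out=t)
    joff = (np.arange(J) * n)[None, :, None, None]
    flat = Y.ravel()
    y0 = flat[joff + idx - 1]
    y1 = flat[joff + idx]
    f = (1.0 - t) * y0 + t * y1
    f = np.where(below, flat[joff + 0], np.where(above, flat[joff + n - 1], f))
    if not with_grad:
        return f
    clamped = below | above
    slope = (y1 - y0) / (k[idx] - k[idx - 1])
    slope[clamped] = 0.0
    jidx = (joff + idx).ravel()
    t_f, cl_f = t.ravel(), clamped.ravel()
    bel_f, abo_f = below.ravel(), above.ravel()
    j_of = np.broadcast_to(joff, vv.shape).ravel()

    def grad_bank(g_out: np.ndarray) -> np.ndarray:
        g_f = g_out.ravel()
        w0 = np.where(cl_f, 0.0, 1.0 - t_f) * g_f
        w1 = np.where(cl_f, 0.0, t_f) * g_f
        g = np.bincount(jidx - 1, weights=w0, minlength=J * n)
        g += np.bincount(jidx, weights=w1, minlength=J * n)
        if bel_f.any():
            g += np.bincount(j_of[bel_f], weights=g_f[bel_f], minlength=J * n)
        if abo_f.any():
            g += np.bincount(j_of[abo_f] + (n - 1), weights=g_f[abo_f], minlength=J * n)
        return g.reshape(J, n)

    return f, slope, grad_bank


# ---------------------------------------------------------------------------
# "same"-size convolution with explicit adjoint
# ---------------------------------------------------------------------------


def _offsets(o1: int, o2: int) -> tuple[int, int]:
    return (o1 - 1) // 2, (o2 - 1) // 2


def _embed(y: np.ndarray, o1: int, o2: int) -> np.ndarray:
    s1, s2 = _offsets(o1, o2)
    full = np.zeros((y.shape[0] + o1 - 1, y.shape[1] + o2 - 1))
    full[s1 : s1 + y.shape[0], s2 : s2 + y.shape[1]] = y
    return full


def conv_same(x: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Zero-padded convolution cropped to the input size."""
    s1, s2 = _offsets(*k.shape)
    full = convolve2d(x, k, mode="full")
    return full[s1 : s1 + x.shape[0], s2 : s2 + x.shape[1]]


def conv_same_T(y: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`conv_same` in its first argument (transposed kernel)."""
    return correlate2d(_embed(y, *k.shape), k, mode="valid")


def conv_same_grad_k(x: np.ndarray, gy: np.ndarray, kshape: tuple[int, int]) -> np.ndarray:
    """Gradient w.r.t. the kernel of ``<gy, conv_same(x, k)>``."""
    return correlate2d(_embed(gy, *kshape), x, mode="valid")


# Batched counterparts: images carry a leading batch axis, kernels either a
# shared (J, o, o) stack or a per-sample (B, J, o, o) stack (the latter is
# what dropout masks and Bayesian filter draws produce).  All four operations
# reduce to one einsum over sliding windows.


def _win(xpad: np.ndarray, o1: int, o2: int) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(xpad, (o1, o2), axis=(-2, -1))


def _pad_conv(x: np.ndarray, o1: int, o2: int) -> np.ndarray:
    s1, s2 = _offsets(o1, o2)
    pad = [(0, 0)] * (x.ndim - 2) + [(o1 - 1 - s1, s1), (o2 - 1 - s2, s2)]
    return np.pad(x, pad)


def _pad_corr(x: np.ndarray, o1: int, o2: int) -> np.ndarray:
    s1, s2 = _offsets(o1, o2)
    pad = [(0, 0)] * (x.ndim - 2) + [(s1, o1 - 1 - s1), (s2, o2 - 1 - s2)]
    return np.pad(x, pad)


def _conv_windows(x: np.ndarray, o1: int, o2: int) -> np.ndarray:
    """Contiguous (B, n1, n2, o1, o2) windows for the convolution side."""
    return np.ascontiguousarray(_win(_pad_conv(x, o1, o2), o1, o2))


def _corr_windows(m: np.ndarray, o1: int, o2: int) -> np.ndarray:
    """Contiguous (B, n1, n2, J, o1, o2) windows for the transposed side.

    The per-prior axis is moved inside so the contraction over (J, o1, o2)
    is a single plain matmul with no internal transposition.
    """
    w = _win(_pad_corr(m, o1, o2), o1, o2)  # (B, J, n1, n2, o1, o2)
    return np.ascontiguousarray(w.transpose(0, 2, 3, 1, 4, 5))


def _conv_from_windows(w: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    B, n1, n2, o1, o2 = w.shape
    W2 = w.reshape(B, n1 * n2, o1 * o2)
    kf = kernels[..., ::-1, ::-1]
    if kernels.ndim == 3:
        out = W2 @ kf.reshape(kf.shape[0], -1).T  # (B, n, J)
    else:
        out = np.matmul(W2, kf.reshape(B, kf.shape[1], -1).transpose(0, 2, 1))
    return np.ascontiguousarray(out.transpose(0, 2, 1)).reshape(B, -1, n1, n2)


def _convT_from_windows(w: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    B, n1, n2, J, o1, o2 = w.shape
    W2 = w.reshape(B, n1 * n2, J * o1 * o2)
    if kernels.ndim == 3:
        out = W2 @ kernels.ravel()
    else:
        out = np.matmul(W2, kernels.reshape(B, -1, 1))[:, :, 0]
    return out.reshape(B, n1, n2)


def conv_same_batch(x: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    """(B, n1, n2) convolved with (J, o, o) or (B, J, o, o) -> (B, J, n1, n2)."""
    o1, o2 = kernels.shape[-2:]
    return _conv_from_windows(_conv_windows(x, o1, o2), kernels)


def conv_same_T_batch(m: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    """Adjoint accumulation over priors: (B, J, n1, n2) -> (B, n1, n2)."""
    o1, o2 = kernels.shape[-2:]
    return _convT_from_windows(_corr_windows(m, o1, o2), kernels)


def _gradk_from_conv_windows(w, gy, per_sample: bool) -> np.ndarray:
    B, n1, n2, o1, o2 = w.shape
    W2 = w.reshape(B, n1 * n2, o1 * o2)
    G = gy.reshape(B, -1, n1 * n2)  # (B, J, n)
    if per_sample:
        g = np.matmul(G, W2)  # (B, J, o^2)
        return g.reshape(B, -1, o1, o2)[..., ::-1, ::-1]
    g = np.tensordot(G, W2, axes=([0, 2], [0, 1]))  # (J, o^2)
    return g.reshape(-1, o1, o2)[..., ::-1, ::-1]


def _gradk_from_corr_windows(w, h, per_sample: bool) -> np.ndarray:
    B, n1, n2, J, o1, o2 = w.shape
    if per_sample:
        g = np.matmul(
            w.reshape(B, n1 * n2, -1).transpose(0, 2, 1), h.reshape(B, -1, 1)
        )[:, :, 0]
        return g.reshape(B, J, o1, o2)
    g = h.ravel() @ w.reshape(B * n1 * n2, -1)
    return g.reshape(J, o1, o2)


def conv_grad_kernels(x, gy, kshape, per_sample: bool) -> np.ndarray:
    """Gradient w.r.t. kernels of ``<gy, conv_same_batch(x, k)>``."""
    o1, o2 = kshape
    return _gradk_from_conv_windows(_conv_windows(x, o1, o2), gy, per_sample)


def convT_grad_kernels(m, h, kshape, per_sample: bool) -> np.ndarray:
    """Gradient w.r.t. kernels of ``<h, conv_same_T_batch(m, k)>``."""
    o1, o2 = kshape
    return _gradk_from_corr_windows(_corr_windows(m, o1, o2), h, per_sample)


class _FFTConv:
    """Frequency-domain engine for the layer convolutions.

    All four operations (convolution, its adjoint, and both kernel-gradient
    contractions) are evaluated on the common zero-padded full-convolution
    grid (N1, N2) = (n + o - 1); offsets reproduce the "same"-crop
    conventions of the direct implementations exactly, for even and odd
    kernel sizes.  Batched FFTs over (B[, J]) axes replace the large
    sliding-window gathers of the direct path.
    """

    def __init__(self, n1: int, n2: int, o1: int, o2: int):
        import scipy.fft

        self.fft = scipy.fft
        self.n1, self.n2, self.o1, self.o2 = n1, n2, o1, o2
        self.N1, self.N2 = n1 + o1 - 1, n2 + o2 - 1
        self.s1, self.s2 = _offsets(o1, o2)

    def rfft(self, a: np.ndarray) -> np.ndarray:
        return self.fft.rfft2(a, s=(self.N1, self.N2))

    def embed_fft(self, a: np.ndarray, off1: int, off2: int) -> np.ndarray:
        full = np.zeros(a.shape[:-2] + (self.N1, self.N2))
        full[..., off1 : off1 + a.shape[-2], off2 : off2 + a.shape[-1]] = a
        return self.fft.rfft2(full)

    def conv_crop(self, F: np.ndarray) -> np.ndarray:
        full = self.fft.irfft2(F, s=(self.N1, self.N2))
        return full[..., self.s1 : self.s1 + self.n1, self.s2 : self.s2 + self.n2]

    def corr_crop(self, F: np.ndarray) -> np.ndarray:
        full = self.fft.irfft2(F, s=(self.N1, self.N2))
        a1, a2 = self.o1 - 1 - self.s1, self.o2 - 1 - self.s2
        return full[..., a1 : a1 + self.n1, a2 : a2 + self.n2]

    def kernel_crop(self, F: np.ndarray) -> np.ndarray:
        full = self.fft.irfft2(F, s=(self.N1, self.N2))
        return full[..., : self.o1, : self.o2]


_FFT_CACHE: dict = {}


def _fft_for(n1: int, n2: int, o1: int, o2: int) -> _FFTConv:
    key = (n1, n2, o1, o2)
    fc = _FFT_CACHE.get(key)
    if fc is None:
        fc = _FFTConv(n1, n2, o1, o2)
        _FFT_CACHE[key] = fc
    return fc


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class VNArchitecture:
    """Free structural hyperparameters of the unrolled network."""

    K: int = 10
    n_priors: int = 16
    kernel_size: int = 8
    n_knots: int = 31
    response_limit: float = 1.0

    def __post_init__(self) -> None:
        if self.K < 1 or self.n_priors < 1:
            raise ValueError("K and n_priors must be >= 1")


def scaled_down_architecture() -> VNArchitecture:
    """Desk-scale preset used for CPU training runs."""
    return VNArchitecture(K=8, n_priors=6, kernel_size=5, n_knots=13)


@dataclasses.dataclass(frozen=True)
class TrainingConfig:
    """Loss and optimizer settings.

    ``tau`` is the exponential decay of per-layer loss weights, ``lambda_r``
    the control-point second-difference smoothness weight, ``eps`` its
    smoothing constant; ``alpha`` (prior precision) and ``beta`` (KL weight)
    only matter for the Bayesian variant.
    """

    tau: float = 0.5
    lambda_r: float = 1e-3
    eps: float = 1e-6
    alpha: float = 0.1
    beta: float = 10.0
    dropout_p: float = 0.0  # per-filter training dropout (0 = deterministic)
    iterations: int = 3000
    batch_size: int = 8
    lr: float = 1e-2
    lr_schedule: str = "cosine"  # or "constant"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tau", "lambda_r", "eps", "alpha", "beta", "lr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.lr_schedule not in ("cosine", "constant"):
            raise ValueError("lr_schedule must be 'cosine' or 'constant'")

    def lr_at(self, iteration: int) -> float:
        """Learning rate for one iteration (cosine-annealed by default)."""
        if self.lr_schedule == "constant" or self.iterations <= 1:
            return self.lr
        frac = iteration / max(1, self.iterations - 1)
        return self.lr * 0.5 * (1.0 + float(np.cos(np.pi * frac)))


@dataclasses.dataclass
class VNLayerParams:
    """Learnable parameters of one unrolled layer."""

    filters: np.ndarray  # (N_k, o, o)
    w: np.ndarray  # (N_k, n_ax, n_lat) spatial prior weights
    phi: list[ControlPointFunction]  # one per prior
    psi: ControlPointFunction  # data-residual penalty transform
    s: np.ndarray  # (n_pairs,) per-pair data weights
    phi_scale: np.ndarray  # (N_k,) response normalization
    psi_scale: float = 1.0


@dataclasses.dataclass
class VNParams:
    """Full network: K layers plus the normalization frame.

    ``x_unit`` (s/mm) and ``d_unit`` (s) map physical slowness deviations and
    measurements into the O(1) space the network operates in; they satisfy
    ``d_unit = sigma_max(L) * x_unit``.
    """

    layers: list[VNLayerParams]
    recon_shape: tuple[int, int]
    n_pairs: int
    x_unit: float
    d_unit: float
    c0: float

    @property
    def K(self) -> int:
        return len(self.layers)

    def copy(self) -> "VNParams":
        layers = [
            VNLayerParams(
                filters=l.filters.copy(),
                w=l.w.copy(),
                phi=[ControlPointFunction(p.knots.copy(), p.y.copy()) for p in l.phi],
                psi=ControlPointFunction(l.psi.knots.copy(), l.psi.y.copy()),
                s=l.s.copy(),
                phi_scale=l.phi_scale.copy(),
                psi_scale=l.psi_scale,
            )
            for l in self.layers
        ]
        return VNParams(
            layers=layers,
            recon_shape=self.recon_shape,
            n_pairs=self.n_pairs,
            x_unit=self.x_unit,
            d_unit=self.d_unit,
            c0=self.c0,
        )


@dataclasses.dataclass
class NormalizedOperator:
    """Unit-spectral-norm version of the forward operator (and its adjoint)."""

    Ln: sp.csr_matrix
    LnT: sp.csr_matrix
    meas_shape: tuple[int, int, int]
    recon_shape: tuple[int, int]

    @classmethod
    def from_model(cls, model: ForwardModel) -> "NormalizedOperator":
        Ln = (model.L / model.spectral_norm()).tocsr()
        return cls(
            Ln=Ln,
            LnT=Ln.T.tocsr(),
            meas_shape=model.meas_shape,
            recon_shape=model.recon_grid.shape,
        )

    def apply(self, x: np.ndarray) -> np.ndarray:
        return (self.Ln @ x.ravel()).reshape(self.meas_shape)

    def applyT(self, y: np.ndarray) -> np.ndarray:
        return (self.LnT @ y.ravel()).reshape(self.recon_shape)

    def apply_batch(self, x: np.ndarray) -> np.ndarray:
        B = x.shape[0]
        out = self.Ln @ x.reshape(B, -1).T
        return np.ascontiguousarray(out.T).reshape((B,) + self.meas_shape)

    def applyT_batch(self, y: np.ndarray) -> np.ndarray:
        B = y.shape[0]
        out = self.LnT @ y.reshape(B, -1).T
        return np.ascontiguousarray(out.T).reshape((B,) + self.recon_shape)


# ---------------------------------------------------------------------------
# Forward pass (batched core; public single-sample wrappers)
# ---------------------------------------------------------------------------


def _effective_kernels(layer: VNLayerParams, masks, override):
    """(synthesis, analysis) kernel stacks after masks / posterior draws.

    Returns arrays of shape (J, o, o) or, with per-sample masks/overrides,
    (B, J, o, o).
    """
    filt = layer.filters if override is None else override
    if masks is None:
        return filt, filt
    m1, m2 = masks
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if m1.ndim in (1, 2):  # per-filter scalars: (J,) or (B, J)
        m1 = m1[..., None, None]
        m2 = m2[..., None, None]
    return m1 * filt, m2 * filt


def _layer_forward_batch(layer, x, dprime, op, syn, ana, cache=None):
    """One unrolled update on a batch: x, dprime carry a leading batch axis."""
    resid = op.apply_batch(x) - dprime
    s4 = layer.s[None, :, None, None]
    u = s4 * resid
    v = u / layer.psi_scale
    if cache is not None:
        psi_v, psi_slope, psi_grad_y = layer.psi.eval_with_grad(v)
    else:
        psi_v = layer.psi(v)
        psi_slope = psi_grad_y = None
    psi_out = layer.psi_scale * psi_v
    z = s4 * psi_out
    g_data = op.applyT_batch(z)

    o1, o2 = layer.filters.shape[-2:]
    fc = _fft_for(x.shape[-2], x.shape[-1], o1, o2)
    Fx = fc.rfft(x)
    Fana = fc.rfft(ana)
    c = fc.conv_crop(Fx[:, None] * Fana)  # (B, J, na, nl)
    ps4 = layer.phi_scale[None, :, None, None]
    vv = c / ps4
    if cache is not None:
        phi_v, phi_slopes, phi_grad_bank = _eval_cpf_bank(layer.phi, vv, True)
    else:
        phi_v = _eval_cpf_bank(layer.phi, vv, False)
        phi_slopes = phi_grad_bank = None
    phi_out = ps4 * phi_v
    m = layer.w[None] * phi_out
    Fm = fc.rfft(m)
    Fsynflip = fc.rfft(syn[..., ::-1, ::-1])
    g_reg = fc.corr_crop((Fm * Fsynflip).sum(axis=-3))
    x_new = x - (g_data + g_reg)
    if cache is not None:
        cache.update(
            resid=resid,
            psi_out=psi_out,
            psi_slope=psi_slope,
            psi_grad_y=psi_grad_y,
            syn=syn,
            ana=ana,
            phi_out=phi_out,
            phi_slopes=phi_slopes,
            phi_grad_bank=phi_grad_bank,
            fc=fc,
            Fx=Fx,
            Fm=Fm,
        )
    return x_new


def _forward_batch(params, dprime, op, kernels_per_layer=None, caches=None):
    """Run all K layers on a batch; kernels_per_layer[k] is a (syn, ana) pair
    (defaults to the point-estimate filters)."""
    x = np.zeros((dprime.shape[0],) + params.recon_shape)
    trajectory = []
    for k, layer in enumerate(params.layers):
        if kernels_per_layer is None:
            syn = ana = layer.filters
        else:
            syn, ana = kernels_per_layer[k]
        c = None if caches is None else caches[k]
        x = _layer_forward_batch(layer, x, dprime, op, syn, ana, cache=c)
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(f"non-finite reconstruction at unrolled layer {k + 1}")
        trajectory.append(x)
    return trajectory


def _kernels_from(params, masks_per_layer, overrides):
    if masks_per_layer is None and overrides is None:
        return None
    out = []
    for k, layer in enumerate(params.layers):
        masks = None if masks_per_layer is None else masks_per_layer[k]
        ov = None if overrides is None else overrides[k]
        out.append(_effective_kernels(layer, masks, ov))
    return out


def _forward_normalized(params, dprime, op, masks_per_layer=None, overrides=None):
    """Single-sample trajectory (normalized units); thin batch-of-1 wrapper."""
    kernels = _kernels_from(params, masks_per_layer, overrides)
    traj = _forward_batch(params, dprime[None], op, kernels_per_layer=kernels)
    return [t[0] for t in traj]


def regularizer_gradient(
    layer: VNLayerParams, x: np.ndarray, masks=None, filter_override=None
) -> np.ndarray:
    """Field-of-experts regularization gradient of one layer.

    ``sum_j rbar_j * ( w_j . phi_j( r_j * x ) )`` with zero-padded "same"
    convolutions; ``rbar`` is the transposed (flipped) kernel so the adjoint
    identity ``<r*a, b> = <a, rbar*b>`` holds exactly.
    """
    x = np.asarray(x, dtype=float)
    syn, ana = _effective_kernels(layer, masks, filter_override)
    c = conv_same_batch(x[None], ana)[0]
    phi_out = np.stack(
        [
            layer.phi_scale[j] * layer.phi[j](c[j] / layer.phi_scale[j])
            for j in range(layer.filters.shape[0])
        ]
    )
    return conv_same_T_batch((layer.w * phi_out)[None], syn)[0]


@dataclasses.dataclass
class VNReconstruction:
    """Output of an unrolled forward pass."""

    slowness: SlownessMap
    trajectory: list[np.ndarray]  # normalized x_1..x_K

    @property
    def sos(self):
        from .maps import slowness_to_sos

        return slowness_to_sos(self.slowness)


def vn_forward(
    params: VNParams,
    d: DisplacementMeasurements,
    model: ForwardModel,
    masks_per_layer=None,
    filter_overrides=None,
    op: NormalizedOperator | None = None,
) -> VNReconstruction:
    """Run the unrolled network on measurements; deterministic given inputs."""
    if d.values.shape != model.meas_shape:
        raise ValueError("measurement shape does not match forward model")
    if op is None:
        op = NormalizedOperator.from_model(model)
    dprime = d.values / params.d_unit
    trajectory = _forward_normalized(
        params, dprime, op, masks_per_layer=masks_per_layer, overrides=filter_overrides
    )
    x = SlownessMap(
        values=trajectory[-1] * params.x_unit,
        x0=slowness_of(params.c0),
        grid=model.recon_grid,
    )
    return VNReconstruction(slowness=x, trajectory=trajectory)


def vn_forward_stack(
    params: VNParams,
    d: DisplacementMeasurements,
    model: ForwardModel,
    kernels_per_layer,
    op: NormalizedOperator | None = None,
) -> np.ndarray:
    """Many posterior draws at once: per-layer (syn, ana) kernel stacks with a
    leading sample axis produce a (S, n_ax, n_lat) stack of slowness maps."""
    if op is None:
        op = NormalizedOperator.from_model(model)
    S = kernels_per_layer[0][0].shape[0]
    dprime = np.broadcast_to(d.values / params.d_unit, (S,) + d.values.shape)
    traj = _forward_batch(params, dprime, op, kernels_per_layer=kernels_per_layer)
    return traj[-1] * params.x_unit


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------


def _layer_weights(K: int, tau: float) -> np.ndarray:
    return np.exp(-tau * (K - np.arange(1, K + 1)))


def _smoothness_penalty(y: np.ndarray, eps: float) -> float:
    d2 = y[:-2] - 2 * y[1:-1] + y[2:]
    return float(np.sum(np.sqrt(d2 * d2 + eps)))


def vn_loss(
    trajectory: Sequence[np.ndarray],
    x_star: np.ndarray,
    params: VNParams,
    cfg: TrainingConfig,
) -> float:
    """Exponentially layer-weighted L1 loss plus control-point smoothness.

    This is the deterministic part of the training objective (the Bayesian
    variant adds the weighted KL term on top).  Operates on normalized maps.
    """
    K = len(trajectory)
    wk = _layer_weights(K, cfg.tau)
    loss = sum(float(wk[k] * np.abs(trajectory[k] - x_star).sum()) for k in range(K))
    if cfg.lambda_r > 0:
        for layer in params.layers:
            for p in layer.phi:
                loss += cfg.lambda_r * _smoothness_penalty(p.y, cfg.eps)
    return loss


# ---------------------------------------------------------------------------
# Backward pass
# ---------------------------------------------------------------------------


def _zero_grads(params: VNParams) -> list[dict]:
    return [
        {
            "filters": np.zeros_like(l.filters),
            "w": np.zeros_like(l.w),
            "phi_y": [np.zeros_like(p.y) for p in l.phi],
            "psi_y": np.zeros_like(l.psi.y),
            "s": np.zeros_like(l.s),
        }
        for l in params.layers
    ]


def _layer_backward_batch(layer, cache, op, g_out, grads, per_sample_kernels):
    """Accumulate parameter grads (summed over the batch); return the
    gradient w.r.t. the layer input.  With per-sample kernels the effective
    kernel gradient is returned per sample instead of summed."""
    h = g_out
    s4 = layer.s[None, :, None, None]
    # ----- data path -----
    gz = op.apply_batch(h)
    g_psi_out = s4 * gz
    grads["s"] -= np.einsum("bpxy,bpxy->p", cache["psi_out"], gz)
    g_psi_v = layer.psi_scale * g_psi_out
    grads["psi_y"] -= cache["psi_grad_y"](g_psi_v)
    g_u = (cache["psi_slope"] * g_psi_v) / layer.psi_scale
    grads["s"] -= np.einsum("bpxy,bpxy->p", cache["resid"], g_u)
    g_x = op.applyT_batch(s4 * g_u)
    # ----- regularizer path -----
    syn, ana = cache["syn"], cache["ana"]
    fc, Fx, Fm = cache["fc"], cache["Fx"], cache["Fm"]
    Fh = fc.rfft(h)
    g_m = fc.conv_crop(Fh[:, None] * fc.rfft(syn))  # (B, J, na, nl)
    FH2 = fc.embed_fft(h, fc.o1 - 1 - fc.s1, fc.o2 - 1 - fc.s2)
    prod = np.conj(Fm) * FH2[:, None]
    g_syn = fc.kernel_crop(prod if per_sample_kernels else prod.sum(axis=0))[
        ..., ::-1, ::-1
    ]
    grads["w"] -= np.einsum("bjxy->jxy", cache["phi_out"] * g_m)
    g_phi_out = layer.w[None] * g_m
    ps4 = layer.phi_scale[None, :, None, None]
    g_phi_v = ps4 * g_phi_out
    bank = cache["phi_grad_bank"](g_phi_v)
    for j in range(len(layer.phi)):
        grads["phi_y"][j] -= bank[j]
    g_c = (cache["phi_slopes"] * g_phi_v) / ps4
    g_x += fc.corr_crop((fc.rfft(g_c) * fc.rfft(ana[..., ::-1, ::-1])).sum(axis=-3))
    FG2 = fc.embed_fft(g_c, fc.s1, fc.s2)
    prod2 = np.conj(Fx)[:, None] * FG2
    g_ana = fc.kernel_crop(prod2 if per_sample_kernels else prod2.sum(axis=0))
    kernel_grad = -(g_syn + g_ana)  # dL/d(effective kernels)
    if per_sample_kernels:
        cache["kernel_grad"] = kernel_grad
        masks = cache.get("masks")
        if masks is not None:
            # chain through the dropout masks to the underlying filters
            m1, m2 = masks  # (B, J) per-filter keep-masks
            grads["filters"] -= np.einsum("bjuv,bj->juv", g_syn, m1) + np.einsum(
                "bjuv,bj->juv", g_ana, m2
            )
        else:
            grads["filters"] += kernel_grad.sum(axis=0)
    else:
        grads["filters"] += kernel_grad
    return g_out - g_x


def vn_value_and_grad_batch(
    params: VNParams,
    dprime: np.ndarray,
    x_star: np.ndarray,
    op: NormalizedOperator,
    cfg: TrainingConfig,
    overrides=None,
    masks_per_layer=None,
):
    """Total loss over a batch and gradients for every parameter family.

    ``overrides`` (per layer, shape (B, N_k, o, o)) replaces the
    point-estimate filters by per-sample draws; in that case the returned
    ``kernel_grads[k]`` keeps the per-sample axis (for the Bayesian
    reparameterization chain), otherwise it is ``None``.
    ``masks_per_layer`` (per layer, a pair of (B, N_k) keep-masks) trains
    with per-filter dropout; gradients chain through the masks to the
    underlying filters.  Parameter gradients are summed over the batch.
    """
    per_sample = overrides is not None or masks_per_layer is not None
    kernels = None
    caches = [dict() for _ in params.layers]
    if overrides is not None:
        kernels = [(ov, ov) for ov in overrides]
    elif masks_per_layer is not None:
        kernels = []
        for k, layer in enumerate(params.layers):
            m1, m2 = masks_per_layer[k]  # (B, J) keep-masks
            syn = m1[:, :, None, None] * layer.filters[None]
            ana = m2[:, :, None, None] * layer.filters[None]
            kernels.append((syn, ana))
            caches[k]["masks"] = (m1, m2)
    trajectory = _forward_batch(params, dprime, op, kernels_per_layer=kernels, caches=caches)
    K = params.K
    wk = _layer_weights(K, cfg.tau)
    loss = sum(float(wk[k] * np.abs(trajectory[k] - x_star).sum()) for k in range(K))
    grads = _zero_grads(params)
    g = np.zeros_like(x_star)
    for k in range(K - 1, -1, -1):
        g = g + wk[k] * np.sign(trajectory[k] - x_star)
        g = _layer_backward_batch(params.layers[k], caches[k], op, g, grads[k], per_sample)
    B = dprime.shape[0]
    if cfg.lambda_r > 0:
        # smoothness penalty on phi ordinates (per batch element, as the data
        # term is also summed over the batch)
        for k, layer in enumerate(params.layers):
            for j, p in enumerate(layer.phi):
                y = p.y
                d2 = y[:-2] - 2 * y[1:-1] + y[2:]
                sroot = np.sqrt(d2 * d2 + cfg.eps)
                loss += B * cfg.lambda_r * float(sroot.sum())
                gd2 = B * cfg.lambda_r * d2 / sroot
                gy = np.zeros_like(y)
                gy[:-2] += gd2
                gy[1:-1] -= 2 * gd2
                gy[2:] += gd2
                grads[k]["phi_y"][j] += gy
    kernel_grads = [c.get("kernel_grad") for c in caches] if per_sample else None
    return loss, grads, kernel_grads


def vn_value_and_grad(
    params: VNParams,
    dprime: np.ndarray,
    x_star: np.ndarray,
    op: NormalizedOperator,
    cfg: TrainingConfig,
    overrides=None,
):
    """Single-sample loss and gradients (batch-of-1 wrapper)."""
    ov = None if overrides is None else [o[None] for o in overrides]
    loss, grads, kernel_grads = vn_value_and_grad_batch(
        params, dprime[None], x_star[None], op, cfg, overrides=ov
    )
    filter_grads = (
        [g[0] for g in kernel_grads] if kernel_grads is not None
        else [grads[k]["filters"] for k in range(params.K)]
    )
    return loss, grads, filter_grads


# ---------------------------------------------------------------------------
# Initialization and scale calibration
# ---------------------------------------------------------------------------


def _tv_kernel(o: int, axis: int) -> np.ndarray:
    k = np.zeros((o, o))
    c = (o - 1) // 2
    if axis == 0:
        k[c, c], k[c + 1, c] = 1.0, -1.0
    else:
        k[c, c], k[c, c + 1] = 1.0, -1.0
    return k


def init_vn_params(
    arch: VNArchitecture,
    model: ForwardModel,
    x_unit: float,
    rng: np.random.Generator,
    w0: float = 0.1,
    s0: float = 0.7,
) -> VNParams:
    """Initialize near a plain TV-regularized gradient-descent scheme.

    The first two priors start as axial/lateral difference kernels, the rest
    as small zero-mean random kernels; ``phi``/``psi`` start as identities,
    so the untrained network is already a sensible (if generic) solver.
    """
    o = arch.kernel_size
    shape = model.recon_grid.shape
    layers = []
    for _ in range(arch.K):
        filters = 0.25 / o * rng.standard_normal((arch.n_priors, o, o))
        filters -= filters.mean(axis=(1, 2), keepdims=True)
        filters[0] = _tv_kernel(o, 0)
        if arch.n_priors > 1:
            filters[1] = _tv_kernel(o, 1)
        layers.append(
            VNLayerParams(
                filters=filters,
                w=np.full((arch.n_priors,) + shape, w0 / arch.n_priors),
                phi=[
                    ControlPointFunction.identity(arch.n_knots, arch.response_limit)
                    for _ in range(arch.n_priors)
                ],
                psi=ControlPointFunction.identity(arch.n_knots, arch.response_limit),
                s=np.full(model.n_pairs, s0),
                phi_scale=np.ones(arch.n_priors),
                psi_scale=1.0,
            )
        )
    return VNParams(
        layers=layers,
        recon_shape=shape,
        n_pairs=model.n_pairs,
        x_unit=x_unit,
        d_unit=x_unit * model.spectral_norm(),
        c0=model.spec.c0,
    )


def calibrate_scales(
    params: VNParams,
    dprimes: Sequence[np.ndarray],
    op: NormalizedOperator,
    xstars: Sequence[np.ndarray] | None = None,
    margin: float = 1.5,
) -> None:
    """Set phi/psi response normalization scales from a first batch.

    The data-residual scale (psi) is largest at the zero initialization, so
    it is taken from the running max of ``s (L x - d)`` along the initial
    forward trajectory.  Filter responses grow toward the responses of the
    converged map, so phi scales are taken from convolutions of the
    ground-truth maps (falling back to the initial trajectory when no
    targets are supplied), times a safety margin, keeping the normalized
    responses inside the control-point interval throughout training.
    """
    for layer in params.layers:
        layer.phi_scale[:] = 1e-12
        layer.psi_scale = 1e-12
    for i, dprime in enumerate(dprimes):
        x = np.zeros((1,) + params.recon_shape)
        dp = dprime[None]
        for layer in params.layers:
            u = layer.s[None, :, None, None] * (op.apply_batch(x) - dp)
            layer.psi_scale = max(layer.psi_scale, margin * float(np.abs(u).max()) + 1e-12)
            ref = x if xstars is None else xstars[i][None]
            c = conv_same_batch(ref, layer.filters)
            peaks = np.abs(c).max(axis=(0, 2, 3))
            np.maximum(layer.phi_scale, margin * peaks + 1e-12, out=layer.phi_scale)
            x = _layer_forward_batch(layer, x, dp, op, layer.filters, layer.filters)


# ---------------------------------------------------------------------------
# ADAM on the nested parameter structure
# ---------------------------------------------------------------------------


class AdamState:
    """Standard ADAM moments for a list-of-dicts gradient tree."""

    def __init__(self, grads_template: list[dict]):
        self.m = _tree_map(np.zeros_like, grads_template)
        self.v = _tree_map(np.zeros_like, grads_template)
        self.t = 0

    def step(self, params_tree, grads, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.t += 1
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t

        def upd(p, g, m, v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= lr * (m / bc1) / (np.sqrt(v / bc2) + eps)

        _tree_apply(upd, params_tree, grads, self.m, self.v)


def _tree_map(f, tree):
    if isinstance(tree, list):
        return [_tree_map(f, t) for t in tree]
    if isinstance(tree, dict):
        return {k: _tree_map(f, v) for k, v in tree.items()}
    return f(tree)


def _tree_apply(f, *trees):
    t0 = trees[0]
    if isinstance(t0, list):
        for items in zip(*trees):
            _tree_apply(f, *items)
    elif isinstance(t0, dict):
        for k in t0:
            _tree_apply(f, *[t[k] for t in trees])
    else:
        f(*trees)


def _params_tree(params: VNParams) -> list[dict]:
    """Views of the trainable arrays, matching the gradient structure."""
    return [
        {
            "filters": l.filters,
            "w": l.w,
            "phi_y": [p.y for p in l.phi],
            "psi_y": l.psi.y,
            "s": l.s,
        }
        for l in params.layers
    ]


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite; carries the last checkpoint."""

    def __init__(self, message: str, params: VNParams):
        super().__init__(message)
        self.params = params


@dataclasses.dataclass
class VNTrainResult:
    params: VNParams
    loss_history: np.ndarray
    cfg: TrainingConfig
    arch: VNArchitecture


def dataset_x_unit(dataset: SimDataset, c0: float) -> float:
    """Slowness normalization unit: spread of the ground-truth deviations."""
    from .maps import MM_PER_M

    x = 1.0 / (dataset.sos_gt * MM_PER_M) - 1.0 / (c0 * MM_PER_M)
    unit = float(np.std(x))
    return unit if unit > 0 else 1e-8


def _normalized_training_arrays(dataset: SimDataset, params: VNParams):
    from .maps import MM_PER_M

    dprime = dataset.d / params.d_unit
    xstar = (
        1.0 / (dataset.sos_gt * MM_PER_M) - slowness_of(params.c0)
    ) / params.x_unit
    return dprime, xstar


def train_vn(
    dataset: SimDataset,
    model: ForwardModel,
    cfg: TrainingConfig | None = None,
    arch: VNArchitecture | None = None,
    init_params: VNParams | None = None,
) -> VNTrainResult:
    """Train the deterministic VN with mini-batch ADAM.

    Deterministic given ``cfg.seed``.  A non-finite loss aborts with a
    :class:`TrainingDiverged` carrying the last finite checkpoint.
    """
    if cfg is None:
        cfg = TrainingConfig()
    if arch is None:
        arch = scaled_down_architecture()
    rng = np.random.default_rng(cfg.seed)
    op = NormalizedOperator.from_model(model)
    if init_params is None:
        x_unit = dataset_x_unit(dataset, model.spec.c0)
        params = init_vn_params(arch, model, x_unit, rng)
        dprime_all, xstar_all = _normalized_training_arrays(dataset, params)
        nb = min(cfg.batch_size, dataset.n)
        calibrate_scales(params, dprime_all[:nb], op, xstars=xstar_all[:nb])
    else:
        params = init_params.copy()
        dprime_all, xstar_all = _normalized_training_arrays(dataset, params)

    tree = _params_tree(params)
    adam = AdamState(_zero_grads(params))
    history = np.zeros(cfg.iterations)
    for it in range(cfg.iterations):
        idx = rng.choice(dataset.n, size=min(cfg.batch_size, dataset.n), replace=False)
        masks = None
        if cfg.dropout_p > 0:
            B = len(idx)
            masks = [
                (
                    (rng.random((B, l.filters.shape[0])) >= cfg.dropout_p).astype(float),
                    (rng.random((B, l.filters.shape[0])) >= cfg.dropout_p).astype(float),
                )
                for l in params.layers
            ]
        loss, grads, _ = vn_value_and_grad_batch(
            params, dprime_all[idx], xstar_all[idx], op, cfg, masks_per_layer=masks
        )
        nb = float(len(idx))
        _tree_apply(lambda a: a.__imul__(1.0 / nb), grads)
        loss /= nb
        if not np.isfinite(loss):
            raise TrainingDiverged(
                f"non-finite training loss at iteration {it}", params.copy()
            )
        history[it] = loss
        adam.step(tree, grads, cfg.lr_at(it))
    return VNTrainResult(params=params, loss_history=history, cfg=cfg, arch=arch)
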