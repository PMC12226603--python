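"""Posterior sampling for VN reconstructions: MC Dropout and Bayesian VI.

Monte Carlo Dropout (MCD) draws independent Bernoulli(1 - p) masks over the
regularizer filters at inference time (per-filter by default: a dropped
filter removes its whole prior component on that side; analysis and
synthesis masks are independent, and no 1/(1-p) rescaling is applied).

Bayesian Variational Inference (BVI) learns a Gaussian posterior over the
concatenated filter coefficients, N(mu, Sigma) with Sigma = D D^T factored
through a block-diagonal lower-triangular D (one o^2 x o^2 block per filter,
filters mutually uncorrelated).  Samples are mu + D y with y ~ N(0, I); the
KL toward the isotropic prior N(mu, alpha^{-1} I) reduces (up to constants)
to ``alpha tr(D D^T) - 2 tr(log D)``, evaluated without forming Sigma or any
determinant.

Either scheme is sampled S times; the per-pixel sample mean is the
reconstruction and the sample standard deviation the uncertainty map.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .geometry import DisplacementMeasurements, ForwardModel
from .maps import SlownessMap, SoSMap, slowness_to_sos
from .phantoms import SimDataset
from .varnet import (
    AdamState,
    NormalizedOperator,
    TrainingConfig,
    TrainingDiverged,
    VNParams,
    VNReconstruction,
    _effective_kernels,
    _normalized_training_arrays,
    _params_tree,
    _tree_apply,
    _zero_grads,
    vn_forward,
    vn_forward_stack,
    vn_value_and_grad_batch,
)

# ---------------------------------------------------------------------------
# Monte Carlo Dropout
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class MCDConfig:
    """Dropout probability, mask granularity and sample count."""

    p: float = 0.25
    granularity: str = "per-filter"  # or "per-element"
    n_samples: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p < 1.0:
            raise ValueError("dropout probability must lie in [0, 1)")
        if self.n_samples < 2:
            raise ValueError("need at least 2 posterior samples")
        if self.granularity not in ("per-filter", "per-element"):
            raise ValueError("granularity must be 'per-filter' or 'per-element'")


def draw_masks(
    params: VNParams, cfg: MCDConfig, rng: np.random.Generator
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Independent Bernoulli(1 - p) keep-masks (synthesis, analysis) per layer."""
    masks = []
    for layer in params.layers:
        if cfg.granularity == "per-filter":
            shape = (layer.filters.shape[0],)
        else:
            shape = layer.filters.shape
        m1 = (rng.random(shape) >= cfg.p).astype(float)
        m2 = (rng.random(shape) >= cfg.p).astype(float)
        masks.append((m1, m2))
    return masks


def mcd_sample(
    params: VNParams,
    d: DisplacementMeasurements,
    model: ForwardModel,
    cfg: MCDConfig,
    rng: np.random.Generator,
    op: NormalizedOperator | None = None,
) -> SlownessMap:
    """One dropout-masked forward pass."""
    masks = draw_masks(params, cfg, rng)
    return vn_forward(params, d, model, masks_per_layer=masks, op=op).slowness


# ---------------------------------------------------------------------------
# BVI posterior
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class BVIPosterior:
    """Gaussian filter posterior (mu, D) with block-diagonal Cholesky factor.

    ``mu`` has length t = K * N_k * o^2; ``blocks`` is (n_blocks, o^2, o^2),
    lower-triangular with strictly positive diagonals, ordered layer-major.
    """

    mu: np.ndarray
    blocks: np.ndarray
    K: int
    n_priors: int
    kernel_size: int
    alpha: float = 0.1

    def __post_init__(self) -> None:
        d = self.kernel_size**2
        n_blocks = self.K * self.n_priors
        self.mu = np.asarray(self.mu, dtype=float)
        self.blocks = np.asarray(self.blocks, dtype=float)
        if self.mu.shape != (n_blocks * d,):
            raise ValueError(f"mu must have length {n_blocks * d}")
        if self.blocks.shape != (n_blocks, d, d):
            raise ValueError(f"blocks must be ({n_blocks}, {d}, {d})")

    @property
    def t(self) -> int:
        return self.mu.size

    def filters_per_layer(self, flat: np.ndarray) -> list[np.ndarray]:
        o = self.kernel_size
        return [
            flat.reshape(self.K, self.n_priors, o, o)[k] for k in range(self.K)
        ]


def bvi_sample_filters(
    post: BVIPosterior, rng: np.random.Generator, return_y: bool = False
):
    """Draw filters ``mu + D y`` with fresh standard-normal y, per block."""
    d = post.kernel_size**2
    diag = np.diagonal(post.blocks, axis1=1, axis2=2)
    if np.any(diag <= 0):
        raise ValueError("Cholesky factor diagonal must be strictly positive")
    y = rng.standard_normal((post.blocks.shape[0], d))
    flat = post.mu.reshape(-1, d) + np.einsum("bij,bj->bi", post.blocks, y)
    flat = flat.ravel()
    if return_y:
        return post.filters_per_layer(flat), y
    return post.filters_per_layer(flat)


def kl_term(post: BVIPosterior, alpha: float | None = None) -> float:
    """``alpha * tr(D D^T) - 2 * sum_i log(D_ii)`` without forming Sigma."""
    if alpha is None:
        alpha = post.alpha
    diag = np.diagonal(post.blocks, axis1=1, axis2=2)
    if np.any(diag <= 0):
        raise ValueError("Cholesky factor diagonal must be strictly positive")
    trace = float(np.sum(post.blocks * post.blocks))
    return alpha * trace - 2.0 * float(np.sum(np.log(diag)))


# ---------------------------------------------------------------------------
# Posterior summaries
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PosteriorSummary:
    """Per-pixel sample mean (reconstruction) and std (uncertainty, m/s)."""

    mean_sos: SoSMap
    std_map: np.ndarray
    n_samples: int


def posterior_summarize(samples: list[SoSMap]) -> PosteriorSummary:
    """Sample mean and ddof=1 standard deviation over S >= 2 SoS maps."""
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to summarize a posterior")
    grid = samples[0].grid
    for s in samples[1:]:
        if s.grid.shape != grid.shape:
            raise ValueError("samples must share a common grid")
    stack = np.stack([s.values for s in samples])
    return PosteriorSummary(
        mean_sos=SoSMap(values=stack.mean(axis=0), grid=grid),
        std_map=stack.std(axis=0, ddof=1),
        n_samples=len(samples),
    )


def _summarize_slowness_stack(stack: np.ndarray, params: VNParams, grid):
    """SoS-convert a (S, n_ax, n_lat) slowness stack and summarize it."""
    from .maps import MM_PER_M, slowness_of as _slowness_of

    total = stack + _slowness_of(params.c0)
    if np.any(total <= 0):
        raise ValueError("nonpositive total slowness in posterior samples")
    sos = 1.0 / (total * MM_PER_M)
    return PosteriorSummary(
        mean_sos=SoSMap(values=sos.mean(axis=0), grid=grid),
        std_map=sos.std(axis=0, ddof=1),
        n_samples=stack.shape[0],
    ), sos


def mcd_posterior(
    params: VNParams,
    d: DisplacementMeasurements,
    model: ForwardModel,
    cfg: MCDConfig,
    rng: np.random.Generator,
    op: NormalizedOperator | None = None,
    return_samples: bool = False,
):
    """S dropout samples summarized into mean/uncertainty maps.

    All S masked forward passes run as one batched computation (the masks
    become per-sample kernel stacks).
    """
    if op is None:
        op = NormalizedOperator.from_model(model)
    S = cfg.n_samples
    kernels_per_layer = []
    for layer in params.layers:
        J = layer.filters.shape[0]
        shape = (S, J) if cfg.granularity == "per-filter" else (S,) + layer.filters.shape
        m1 = (rng.random(shape) >= cfg.p).astype(float)
        m2 = (rng.random(shape) >= cfg.p).astype(float)
        if m1.ndim == 2:
            m1 = m1[:, :, None, None]
            m2 = m2[:, :, None, None]
        kernels_per_layer.append((m1 * layer.filters[None], m2 * layer.filters[None]))
    stack = vn_forward_stack(params, d, model, kernels_per_layer, op=op)
    summary, sos = _summarize_slowness_stack(stack, params, model.recon_grid)
    if return_samples:
        maps = [SoSMap(values=sos[s], grid=model.recon_grid) for s in range(S)]
        return summary, maps
    return summary


def bvi_posterior(
    post: BVIPosterior,
    params: VNParams,
    d: DisplacementMeasurements,
    model: ForwardModel,
    n_samples: int,
    rng: np.random.Generator,
    op: NormalizedOperator | None = None,
    return_samples: bool = False,
):
    """S reparameterized filter draws pushed through the network at once."""
    if op is None:
        op = NormalizedOperator.from_model(model)
    draws = [bvi_sample_filters(post, rng) for _ in range(n_samples)]
    kernels_per_layer = []
    for k in range(params.K):
        stack_k = np.stack([draws[s][k] for s in range(n_samples)])
        kernels_per_layer.append((stack_k, stack_k))
    stack = vn_forward_stack(params, d, model, kernels_per_layer, op=op)
    summary, sos = _summarize_slowness_stack(stack, params, model.recon_grid)
    if return_samples:
        maps = [SoSMap(values=sos[s], grid=model.recon_grid) for s in range(n_samples)]
        return summary, maps
    return summary


# ---------------------------------------------------------------------------
# BVI training
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class BVITrainResult:
    posterior: BVIPosterior
    params: VNParams  # non-filter parameters (filters hold the posterior mean)
    loss_history: np.ndarray
    cfg: TrainingConfig


def _lower_tri_mask(d: int) -> np.ndarray:
    return np.tril(np.ones((d, d)))


def train_bvi(
    dataset: SimDataset,
    init: VNParams,
    cfg: TrainingConfig,
    model: ForwardModel,
    mu_init: np.ndarray | None = None,
    freeze_cov: bool = False,
    diag_init: float | None = None,
    diag_floor: float = 1e-8,
) -> BVITrainResult:
    """Optimize the BVI loss (layer-weighted L1 + smoothness + beta * KL).

    Non-filter parameters start from (and continue training on) ``init``;
    the posterior mean is initialized N(0, 1e-2^2) and the factor diagonal
    Uniform(0.9, 1.1) unless ``mu_init`` overrides the means.  Diagonal
    positivity is enforced by optimizing its logarithm.  One reparameterized
    filter sample is drawn per forward pass.  Batch order is driven by a
    generator seeded with ``cfg.seed`` (independent of the sampling stream),
    so the beta=0, frozen-covariance limit reduces to deterministic training.
    """
    params = init.copy()
    o = params.layers[0].filters.shape[-1]
    n_priors = params.layers[0].filters.shape[0]
    K = params.K
    dblk = o * o
    n_blocks = K * n_priors

    batch_rng = np.random.default_rng(cfg.seed)
    sample_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))

    if mu_init is None:
        mu = 1e-2 * sample_rng.standard_normal(n_blocks * dblk)
    else:
        mu = np.asarray(mu_init, dtype=float).copy()
    if diag_init is None:
        rho = np.log(sample_rng.uniform(0.9, 1.1, size=(n_blocks, dblk)))  # log diag
    else:
        rho = np.full((n_blocks, dblk), np.log(diag_init))
    off = np.zeros((n_blocks, dblk, dblk))  # strict lower triangle
    tril = _lower_tri_mask(dblk) - np.eye(dblk)

    op = NormalizedOperator.from_model(model)
    dprime_all, xstar_all = _normalized_training_arrays(dataset, params)

    tree = _params_tree(params)
    adam = AdamState(_zero_grads(params))
    mu_adam = AdamState([{"mu": np.zeros_like(mu)}])
    cov_adam = AdamState([{"rho": np.zeros_like(rho), "off": np.zeros_like(off)}])

    def blocks_of():
        D = off * tril
        idx = np.arange(dblk)
        D[:, idx, idx] = np.exp(rho) + diag_floor
        return D

    history = np.zeros(cfg.iterations)
    post = None
    for it in range(cfg.iterations):
        idx = batch_rng.choice(dataset.n, size=min(cfg.batch_size, dataset.n), replace=False)
        nb = float(len(idx))
        D = blocks_of()
        post = BVIPosterior(
            mu=mu.copy(), blocks=D, K=K, n_priors=n_priors, kernel_size=o, alpha=cfg.alpha
        )
        # one reparameterized filter draw per sample in the batch
        draws = [bvi_sample_filters(post, sample_rng, return_y=True) for _ in idx]
        overrides = [
            np.stack([draws[b][0][k] for b in range(len(idx))]) for k in range(K)
        ]
        ys = np.stack([draws[b][1] for b in range(len(idx))])  # (B, n_blocks, dblk)
        loss_acc, total, kernel_grads = vn_value_and_grad_batch(
            params, dprime_all[idx], xstar_all[idx], op, cfg, overrides=overrides
        )
        # per-sample filter gradients, layer-major blocks: (B, n_blocks, dblk)
        gf = np.concatenate(
            [kg.reshape(len(idx), n_priors, dblk) for kg in kernel_grads], axis=1
        )
        g_mu = gf.sum(axis=0).ravel()
        g_rho = np.zeros_like(rho)
        g_off = np.zeros_like(off)
        if not freeze_cov:
            gD = np.einsum("sbi,sbj->bij", gf, ys)
            g_off = gD * tril
            diag = np.exp(rho) + diag_floor
            g_rho = np.einsum("bii->bi", gD) * diag
        _tree_apply(lambda a: a.__imul__(1.0 / nb), total)
        for layer_grads in total:
            # filters are not point-estimate trainables here; mu/D carry them
            layer_grads["filters"][:] = 0.0
        g_mu /= nb
        g_rho /= nb
        g_off /= nb
        loss_acc = loss_acc / nb
        if cfg.beta > 0:
            loss_acc += cfg.beta * kl_term(post)
            if not freeze_cov:
                D = post.blocks
                gD_kl = cfg.beta * 2.0 * cfg.alpha * D
                diag = np.exp(rho) + diag_floor
                g_off += gD_kl * tril
                g_rho += (np.einsum("bii->bi", gD_kl) - 2.0 * cfg.beta / diag) * diag
        if not np.isfinite(loss_acc):
            raise TrainingDiverged(f"non-finite BVI loss at iteration {it}", params.copy())
        history[it] = loss_acc
        lr = cfg.lr_at(it)
        adam.step(tree, total, lr)
        mu_adam.step([{"mu": mu}], [{"mu": g_mu}], lr)
        if not freeze_cov:
            cov_adam.step(
                [{"rho": rho, "off": off}], [{"rho": g_rho, "off": g_off}], lr
            )

    final_post = BVIPosterior(
        mu=mu.copy(), blocks=blocks_of(), K=K, n_priors=n_priors, kernel_size=o,
        alpha=cfg.alpha,
    )
    # store the posterior mean in the point-estimate filter slots for convenience
    for k, f in enumerate(final_post.filters_per_layer(final_post.mu)):
        params.layers[k].filters = f.copy()
    return BVITrainResult(
        posterior=final_post, params=params, loss_history=history, cfg=cfg
    )
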