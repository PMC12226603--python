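"""Dropout masks, Gaussian filter posterior, KL reformulation, summaries."""

import dataclasses

import numpy as np
import pytest

from sosvn.geometry import (
    AcquisitionSpec,
    DisplacementMeasurements,
    ImagingGrid,
    build_forward_model,
)
from sosvn.maps import SoSMap
from sosvn.phantoms import SimulationConfig, make_dataset
from sosvn.uncertainty import (
    BVIPosterior,
    MCDConfig,
    bvi_sample_filters,
    draw_masks,
    kl_term,
    mcd_posterior,
    mcd_sample,
    posterior_summarize,
    train_bvi,
)
from sosvn.varnet import (
    TrainingConfig,
    VNArchitecture,
    calibrate_scales,
    init_vn_params,
    train_vn,
    vn_forward,
)
from sosvn.varnet import NormalizedOperator, _normalized_training_arrays


def _random_valid_blocks(n_blocks, d, rng, scale=0.3):
    blocks = np.zeros((n_blocks, d, d))
    for b in range(n_blocks):
        blocks[b] = np.tril(scale * rng.standard_normal((d, d)))
        blocks[b][np.arange(d), np.arange(d)] = rng.uniform(0.2, 1.5, d)
    return blocks


@pytest.fixture(scope="module")
def trained_tiny():
    """A lightly trained tiny VN used for dropout/posterior behavior tests."""
    grid = ImagingGrid(8, 8, 2.0, 2.0)
    spec = AcquisitionSpec(n_transmits=5, pair_offset=2)
    cfg = SimulationConfig(grid=grid, spec=spec, n_train=16, n_test=4, seed=2)
    train_set, test_set = make_dataset(cfg)
    model = build_forward_model(spec, grid)
    tc = TrainingConfig(iterations=40, batch_size=8, lr=5e-3, seed=0)
    arch = VNArchitecture(K=3, n_priors=4, kernel_size=3, n_knots=9)
    result = train_vn(train_set, model, tc, arch)
    d, _, _ = test_set.record(0)
    meas = DisplacementMeasurements(values=d, grid=grid, pairs=model.pairs)
    return result.params, meas, model, train_set


# ---------------------------------------------------------------------------
# MCD
# ---------------------------------------------------------------------------


def test_mcd_config_validation():
    with pytest.raises(ValueError):
        MCDConfig(p=1.0)
    with pytest.raises(ValueError):
        MCDConfig(n_samples=1)
    with pytest.raises(ValueError):
        MCDConfig(granularity="per-layer")


def test_mcd_without_dropout_equals_deterministic_network(trained_tiny):
    params, meas, model, _ = trained_tiny
    cfg = MCDConfig(p=0.0, n_samples=2)
    sample = mcd_sample(params, meas, model, cfg, np.random.default_rng(0))
    ref = vn_forward(params, meas, model).slowness
    assert np.array_equal(sample.values, ref.values)


def test_forced_full_dropout_reduces_to_data_term_only(trained_tiny):
    """All-dropped masks equal a network whose prior weights are zeroed."""
    params, meas, model, _ = trained_tiny
    masks = [
        (np.zeros(l.filters.shape[0]), np.zeros(l.filters.shape[0]))
        for l in params.layers
    ]
    dropped = vn_forward(params, meas, model, masks_per_layer=masks).slowness
    wipe = params.copy()
    for l in wipe.layers:
        l.w[:] = 0.0
    ref = vn_forward(wipe, meas, model).slowness
    np.testing.assert_allclose(dropped.values, ref.values, rtol=1e-12, atol=1e-18)


def test_mask_drop_fraction_matches_bernoulli(trained_tiny):
    """Empirical drop fraction at p=0.25 within the 99% binomial band."""
    params, _, _, _ = trained_tiny
    cfg = MCDConfig(p=0.25, n_samples=2)
    rng = np.random.default_rng(1)
    dropped = total = 0
    for _ in range(2000):
        for m1, m2 in draw_masks(params, cfg, rng):
            dropped += np.sum(m1 == 0.0) + np.sum(m2 == 0.0)
            total += m1.size + m2.size
    frac = dropped / total
    assert abs(frac - 0.25) < 2.576 * np.sqrt(0.25 * 0.75 / total)


def test_mcd_uncertainty_shrinks_with_dropout_rate(trained_tiny):
    """Mean posterior std decreases monotonically over p in {0.25, 0.1, 0.01}."""
    params, meas, model, _ = trained_tiny
    stds = []
    for p in (0.25, 0.1, 0.01):
        cfg = MCDConfig(p=p, n_samples=40)
        summ = mcd_posterior(params, meas, model, cfg, np.random.default_rng(5))
        assert np.all(summ.std_map >= 0.0)
        stds.append(summ.std_map.mean())
    assert stds[0] > stds[1] > stds[2]


# ---------------------------------------------------------------------------
# BVI posterior sampling and KL
# ---------------------------------------------------------------------------


def test_bvi_samples_concentrate_on_mean_for_tiny_factor():
    rng = np.random.default_rng(0)
    post = BVIPosterior(
        mu=rng.standard_normal(2 * 2 * 9),
        blocks=1e-12 * np.stack([np.eye(9)] * 4),
        K=2,
        n_priors=2,
        kernel_size=3,
    )
    filters = bvi_sample_filters(post, np.random.default_rng(1))
    flat = np.concatenate([f.ravel() for f in filters])
    assert np.max(np.abs(flat - post.mu)) < 1e-10


def test_bvi_sample_covariance_matches_factor():
    """Sample covariance of 50,000 draws matches D D^T within 5% Frobenius
    and cross-filter covariances vanish (block-diagonal structure)."""
    rng = np.random.default_rng(3)
    d = 16
    n_blocks = 4  # t = 64 coefficients
    blocks = _random_valid_blocks(n_blocks, d, rng)
    post = BVIPosterior(
        mu=np.zeros(n_blocks * d), blocks=blocks, K=2, n_priors=2, kernel_size=4
    )
    draw_rng = np.random.default_rng(4)
    n = 50_000
    y = draw_rng.standard_normal((n, n_blocks, d))
    flats = post.mu.reshape(n_blocks, d)[None] + np.einsum("bij,nbj->nbi", blocks, y)
    flats = flats.reshape(n, n_blocks * d)
    emp = np.cov(flats.T)
    sigma = np.zeros((n_blocks * d, n_blocks * d))
    for b in range(n_blocks):
        sigma[b * d : (b + 1) * d, b * d : (b + 1) * d] = blocks[b] @ blocks[b].T
    rel = np.linalg.norm(emp - sigma) / np.linalg.norm(sigma)
    assert rel < 0.05
    # off-block entries are statistically indistinguishable from zero
    off = emp.copy()
    for b in range(n_blocks):
        off[b * d : (b + 1) * d, b * d : (b + 1) * d] = 0.0
    assert np.abs(off).max() < 6.0 / np.sqrt(n) * np.abs(np.diag(sigma)).max()


def test_bvi_sampler_rejects_nonpositive_diagonal():
    blocks = np.stack([np.eye(4)])
    blocks[0, 2, 2] = -0.1
    post = BVIPosterior(mu=np.zeros(4), blocks=blocks, K=1, n_priors=1, kernel_size=2)
    with pytest.raises(ValueError):
        bvi_sample_filters(post, np.random.default_rng(0))
    with pytest.raises(ValueError):
        kl_term(post)


def test_kl_identity_factor():
    post = BVIPosterior(
        mu=np.zeros(2 * 9), blocks=np.stack([np.eye(9)] * 2), K=1, n_priors=2,
        kernel_size=3, alpha=1.0,
    )
    # alpha tr(I) - 2 tr(log I) = t
    assert kl_term(post) == pytest.approx(post.t)


def test_kl_matches_dense_log_det_oracle():
    """The 2 tr(log D) reformulation equals log det(D D^T) computed densely."""
    rng = np.random.default_rng(7)
    for _ in range(100):
        d = int(rng.integers(2, 12))
        n_blocks = int(rng.integers(1, 5))
        blocks = _random_valid_blocks(n_blocks, d, rng)
        D = np.zeros((n_blocks * d, n_blocks * d))
        for b in range(n_blocks):
            D[b * d : (b + 1) * d, b * d : (b + 1) * d] = blocks[b]
        alpha = 0.1
        ours = alpha * float(np.sum(blocks * blocks)) - 2.0 * float(
            np.sum(np.log(np.diagonal(blocks, axis1=1, axis2=2)))
        )
        sign, logdet = np.linalg.slogdet(D @ D.T)
        oracle = alpha * np.trace(D @ D.T) - logdet
        assert sign > 0
        assert abs(ours - oracle) <= 1e-8 * max(1.0, abs(oracle))


def test_kl_scaling_law():
    """Scaling D by c multiplies the trace term by c^2 and shifts the log
    term by -2 t log c."""
    rng = np.random.default_rng(9)
    blocks = _random_valid_blocks(2, 9, rng)
    post = BVIPosterior(mu=np.zeros(18), blocks=blocks, K=1, n_priors=2, kernel_size=3,
                        alpha=0.7)
    c = 1.7
    scaled = BVIPosterior(mu=np.zeros(18), blocks=c * blocks, K=1, n_priors=2,
                          kernel_size=3, alpha=0.7)
    trace = float(np.sum(blocks * blocks))
    expected = 0.7 * (c**2) * trace - (
        2.0 * float(np.sum(np.log(np.diagonal(blocks, axis1=1, axis2=2))))
        + 2.0 * post.t * np.log(c)
    )
    assert kl_term(scaled) == pytest.approx(expected, rel=1e-12)


# ---------------------------------------------------------------------------
# posterior summary
# ---------------------------------------------------------------------------


def test_summary_of_identical_maps_has_zero_std():
    grid = ImagingGrid(3, 3, 1.0, 1.0)
    m = SoSMap(values=np.full(grid.shape, 1520.0), grid=grid)
    s = posterior_summarize([m, dataclasses.replace(m)])
    assert np.all(s.std_map == 0.0)
    assert np.allclose(s.mean_sos.values, 1520.0)
    assert s.n_samples == 2


def test_summary_two_point_closed_form():
    grid = ImagingGrid(2, 2, 1.0, 1.0)
    a = SoSMap(values=np.full(grid.shape, 1500.0), grid=grid)
    b = SoSMap(values=np.full(grid.shape, 1502.0), grid=grid)
    s = posterior_summarize([a, b])
    assert np.allclose(s.mean_sos.values, 1501.0)
    assert np.allclose(s.std_map, np.sqrt(2.0))


def test_summary_requires_two_samples():
    grid = ImagingGrid(2, 2, 1.0, 1.0)
    with pytest.raises(ValueError):
        posterior_summarize([SoSMap(values=np.zeros(grid.shape) + 1500, grid=grid)])


def test_default_sample_count_is_hundred():
    assert MCDConfig().n_samples == 100


# ---------------------------------------------------------------------------
# BVI training
# ---------------------------------------------------------------------------


def test_bvi_degenerate_limit_reduces_to_deterministic_training(trained_tiny):
    """beta=0 with a frozen, tiny covariance reproduces the deterministic
    VN loss trajectory."""
    _, _, model, train_set = trained_tiny
    arch = VNArchitecture(K=2, n_priors=2, kernel_size=3, n_knots=7)
    rng = np.random.default_rng(0)
    from sosvn.varnet import dataset_x_unit

    init = init_vn_params(arch, model, dataset_x_unit(train_set, model.spec.c0), rng)
    op = NormalizedOperator.from_model(model)
    dprime, _ = _normalized_training_arrays(train_set, init)
    calibrate_scales(init, dprime[:8], op)

    tc = TrainingConfig(iterations=25, batch_size=4, lr=5e-3, seed=3, beta=0.0)
    det = train_vn(train_set, model, tc, arch, init_params=init)
    bvi = train_bvi(
        train_set,
        init,
        tc,
        model,
        mu_init=np.concatenate([l.filters.ravel() for l in init.layers]),
        freeze_cov=True,
        diag_init=1e-12,
        diag_floor=1e-13,
    )
    np.testing.assert_allclose(det.loss_history, bvi.loss_history, rtol=1e-6)


def test_bvi_training_decreases_loss(trained_tiny):
    params, _, model, train_set = trained_tiny
    tc = TrainingConfig(iterations=50, batch_size=4, lr=5e-3, seed=1, beta=0.1)
    res = train_bvi(train_set, params, tc, model)
    assert np.mean(res.loss_history[-10:]) < np.mean(res.loss_history[:10])
    diag = np.diagonal(res.posterior.blocks, axis1=1, axis2=2)
    assert np.all(diag > 0)
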