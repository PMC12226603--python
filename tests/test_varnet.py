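"""Unrolled network: control-point functions, convolution adjoints,
regularizer gradients, forward pass, loss, autodiff, and training."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import dense_conv_same

from sosvn.geometry import (
    AcquisitionSpec,
    DisplacementMeasurements,
    ImagingGrid,
    build_forward_model,
)
from sosvn.phantoms import SimulationConfig, make_dataset
from sosvn.varnet import (
    ControlPointFunction,
    NormalizedOperator,
    TrainingConfig,
    VNArchitecture,
    VNLayerParams,
    VNParams,
    conv_same,
    conv_same_T,
    eval_cpf,
    init_vn_params,
    regularizer_gradient,
    train_vn,
    vn_forward,
    vn_loss,
    vn_value_and_grad,
)
from sosvn.varnet import _forward_normalized  # noqa: PLC2701 - trajectory access


# ---------------------------------------------------------------------------
# control-point functions
# ---------------------------------------------------------------------------


def test_cpf_identity_and_annihilator():
    f = ControlPointFunction.identity(11)
    v = np.linspace(-0.99, 0.99, 37)
    np.testing.assert_allclose(eval_cpf(f, v), v, rtol=0, atol=1e-14)
    z = ControlPointFunction.zeros(11)
    assert np.all(eval_cpf(z, v) == 0.0)


def test_cpf_clamps_outside_knot_range():
    f = ControlPointFunction(knots=np.array([-1.0, 0.0, 1.0]), y=np.array([2.0, 0.0, -3.0]))
    assert eval_cpf(f, np.array([-5.0]))[0] == 2.0
    assert eval_cpf(f, np.array([7.0]))[0] == -3.0


def test_cpf_requires_two_knots():
    with pytest.raises(ValueError):
        ControlPointFunction(knots=np.array([0.0]), y=np.array([1.0]))


@given(st.integers(min_value=0, max_value=10_000))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_cpf_matches_two_point_interpolation_oracle(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(2, 12)
    knots = np.sort(rng.uniform(-2, 2, n))
    knots += np.arange(n) * 1e-3  # enforce strict increase
    y = rng.uniform(-3, 3, n)
    f = ControlPointFunction(knots=knots, y=y)
    v = rng.uniform(knots[0] - 1, knots[-1] + 1, 25)
    got = eval_cpf(f, v)
    for vi, gi in zip(v, got):
        if vi <= knots[0]:
            expect = y[0]
        elif vi >= knots[-1]:
            expect = y[-1]
        else:
            j = np.searchsorted(knots, vi, side="right")
            t = (vi - knots[j - 1]) / (knots[j] - knots[j - 1])
            expect = (1 - t) * y[j - 1] + t * y[j]
        assert abs(gi - expect) < 1e-12


# ---------------------------------------------------------------------------
# convolution machinery
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("o", [2, 3, 5, 8])
def test_conv_adjoint_identity(o):
    """<r*a, b> == <a, rbar*b> for even and odd kernel sizes."""
    rng = np.random.default_rng(o)
    a = rng.standard_normal((9, 7))
    b = rng.standard_normal((9, 7))
    r = rng.standard_normal((o, o))
    lhs = np.sum(conv_same(a, r) * b)
    rhs = np.sum(a * conv_same_T(b, r))
    assert abs(lhs - rhs) < 1e-10


def test_conv_same_matches_direct_summation():
    rng = np.random.default_rng(0)
    x = rng.standard_normal((6, 5))
    k = rng.standard_normal((3, 4))
    np.testing.assert_allclose(conv_same(x, k), dense_conv_same(x, k), atol=1e-12)


# ---------------------------------------------------------------------------
# regularizer gradient
# ---------------------------------------------------------------------------


def _single_prior_layer(r, shape, w_value=1.0, n_knots=9):
    n_k = 1
    return VNLayerParams(
        filters=r[None],
        w=np.full((n_k,) + shape, w_value),
        phi=[ControlPointFunction.identity(n_knots, 1.0)],
        psi=ControlPointFunction.identity(n_knots, 1.0),
        s=np.ones(1),
        phi_scale=np.full(n_k, 50.0),
        psi_scale=50.0,
    )


def test_regularizer_gradient_zero_weights():
    rng = np.random.default_rng(0)
    layer = _single_prior_layer(rng.standard_normal((3, 3)), (6, 6), w_value=0.0)
    g = regularizer_gradient(layer, rng.standard_normal((6, 6)))
    assert np.all(g == 0.0)


def test_regularizer_gradient_is_quadratic_energy_gradient():
    """With identity phi and unit weights, the layer gradient equals the
    analytic gradient of 1/2 ||r * x||^2 (checked by finite differences)."""
    r = np.zeros((3, 3))
    r[1, 1], r[1, 2] = 1.0, -1.0  # lateral finite difference
    layer = _single_prior_layer(r, (6, 6))
    rng = np.random.default_rng(1)
    x = rng.standard_normal((6, 6))
    g = regularizer_gradient(layer, x)

    def energy(x):
        return 0.5 * np.sum(conv_same(x, r) ** 2)

    h = 1e-6
    for idx in rng.choice(36, size=10, replace=False):
        xp, xm = x.copy().ravel(), x.copy().ravel()
        xp[idx] += h
        xm[idx] -= h
        fd = (energy(xp.reshape(6, 6)) - energy(xm.reshape(6, 6))) / (2 * h)
        assert abs(fd - g.ravel()[idx]) <= 1e-5 * max(1.0, abs(fd))


def test_regularizer_gradient_additive_over_priors():
    rng = np.random.default_rng(2)
    shape = (5, 5)
    r1, r2 = rng.standard_normal((3, 3)), rng.standard_normal((3, 3))
    w1, w2 = rng.standard_normal(shape), rng.standard_normal(shape)
    two = VNLayerParams(
        filters=np.stack([r1, r2]),
        w=np.stack([w1, w2]),
        phi=[ControlPointFunction.identity(9) for _ in range(2)],
        psi=ControlPointFunction.identity(9),
        s=np.ones(1),
        phi_scale=np.full(2, 50.0),
        psi_scale=50.0,
    )
    x = rng.standard_normal(shape)
    g_two = regularizer_gradient(two, x)
    singles = []
    for r, w in ((r1, w1), (r2, w2)):
        layer = _single_prior_layer(r, shape)
        layer.w = w[None]
        singles.append(regularizer_gradient(layer, x))
    np.testing.assert_allclose(g_two, singles[0] + singles[1], atol=1e-12)


# ---------------------------------------------------------------------------
# forward pass
# ---------------------------------------------------------------------------


def _manual_params(model, K=1, n_priors=1, o=3, s=1.0, w=0.0, x_unit=1.0, d_unit=1.0):
    shape = model.recon_grid.shape
    layers = []
    for _ in range(K):
        layers.append(
            VNLayerParams(
                filters=np.zeros((n_priors, o, o)),
                w=np.full((n_priors,) + shape, w),
                phi=[ControlPointFunction.identity(9) for _ in range(n_priors)],
                psi=ControlPointFunction.identity(9),
                s=np.full(model.n_pairs, s),
                phi_scale=np.full(n_priors, 1e3),
                psi_scale=1e3,
            )
        )
    return VNParams(
        layers=layers,
        recon_shape=shape,
        n_pairs=model.n_pairs,
        x_unit=x_unit,
        d_unit=d_unit,
        c0=model.spec.c0,
    )


def test_null_update_returns_zero(tiny_model):
    params = _manual_params(tiny_model, K=3)
    for layer in params.layers:
        layer.psi.y[:] = 0.0  # psi == 0 and w == 0: nothing moves
    d = DisplacementMeasurements(
        values=np.random.default_rng(0).standard_normal(tiny_model.meas_shape),
        grid=tiny_model.meas_grid,
        pairs=tiny_model.pairs,
    )
    rec = vn_forward(params, d, tiny_model)
    assert np.all(rec.slowness.values == 0.0)


def test_single_layer_matches_adjoint_oracle(tiny_model):
    """K=1, identity psi, s=1, no regularizer: x_1 = L^T d."""
    params = _manual_params(tiny_model, K=1)
    rng = np.random.default_rng(1)
    raw = NormalizedOperator(
        Ln=tiny_model.L.tocsr(),
        LnT=tiny_model.L.T.tocsr(),
        meas_shape=tiny_model.meas_shape,
        recon_shape=tiny_model.recon_grid.shape,
    )
    d = DisplacementMeasurements(
        values=0.01 * rng.standard_normal(tiny_model.meas_shape),
        grid=tiny_model.meas_grid,
        pairs=tiny_model.pairs,
    )
    rec = vn_forward(params, d, tiny_model, op=raw)
    oracle = (tiny_model.L.toarray().T @ d.ravel()).reshape(rec.slowness.values.shape)
    np.testing.assert_allclose(rec.slowness.values, oracle, rtol=1e-10, atol=1e-12)


def test_default_sequence_feeds_fifteen_maps():
    spec = AcquisitionSpec()
    assert spec.n_pairs == 15  # 17 transmits -> 15 displacement maps into the VN


def test_vn_limit_equals_hand_rolled_gradient_descent(tiny_model):
    """TV filters, identity transforms, constant weights reproduce plain
    gradient descent on the quadratic-plus-TV objective over K=10 steps."""
    K, lam, step = 10, 0.3, 0.6
    o = 3
    rx = np.zeros((o, o))
    rx[1, 1], rx[1, 2] = 1.0, -1.0
    rz = np.zeros((o, o))
    rz[1, 1], rz[2, 1] = 1.0, -1.0
    params = _manual_params(tiny_model, K=K, n_priors=2, o=o, s=np.sqrt(step), w=lam)
    for layer in params.layers:
        layer.filters = np.stack([rx, rz])
    op = NormalizedOperator.from_model(tiny_model)
    rng = np.random.default_rng(3)
    dprime = rng.standard_normal(tiny_model.meas_shape)
    traj = _forward_normalized(params, dprime, op)

    # independent dense loop
    A = tiny_model.L.toarray() / tiny_model.spectral_norm()
    x = np.zeros(tiny_model.recon_grid.n_pixels)
    shape = tiny_model.recon_grid.shape
    for _ in range(K):
        grad_data = step * (A.T @ (A @ x - dprime.ravel()))
        xm = x.reshape(shape)
        reg = lam * (
            dense_conv_same(dense_conv_same(xm, rx), rx[::-1, ::-1])
            + dense_conv_same(dense_conv_same(xm, rz), rz[::-1, ::-1])
        )
        x = x - (grad_data + reg.ravel())
    assert np.max(np.abs(traj[-1].ravel() - x)) <= 1e-8


def test_forward_rejects_shape_mismatch(tiny_model):
    params = _manual_params(tiny_model)
    bad = DisplacementMeasurements(
        values=np.zeros((tiny_model.n_pairs, 3, 3)),
        grid=ImagingGrid(3, 3, 2.0, 2.0),
        pairs=tiny_model.pairs,
    )
    with pytest.raises(ValueError):
        vn_forward(params, bad, tiny_model)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------


def test_loss_vanishes_on_perfect_trajectory_with_linear_controls(tiny_model):
    params = _manual_params(tiny_model, K=2)
    cfg = TrainingConfig(tau=0.5, lambda_r=0.1, eps=1e-8)
    x_star = np.random.default_rng(0).standard_normal(tiny_model.recon_grid.shape)
    traj = [x_star.copy(), x_star.copy()]
    # identity control points are a linear sequence: second differences vanish
    n_terms = sum(len(p.y) - 2 for l in params.layers for p in l.phi)
    expected = cfg.lambda_r * n_terms * np.sqrt(cfg.eps)
    assert vn_loss(traj, x_star, params, cfg) == pytest.approx(expected, rel=1e-12)


def test_loss_weights_equal_when_tau_zero(tiny_model):
    params = _manual_params(tiny_model, K=2)
    cfg = TrainingConfig(tau=0.0, lambda_r=0.0)
    x_star = np.zeros(tiny_model.recon_grid.shape)
    a = np.ones_like(x_star)
    assert vn_loss([a, 0 * a], x_star, params, cfg) == pytest.approx(
        vn_loss([0 * a, a], x_star, params, cfg)
    )


def test_loss_matches_direct_summation_oracle(tiny_model):
    rng = np.random.default_rng(5)
    params = _manual_params(tiny_model, K=3, n_priors=2)
    for l in params.layers:
        for p in l.phi:
            p.y = rng.standard_normal(p.y.shape)
    cfg = TrainingConfig(tau=0.37, lambda_r=0.21, eps=1e-5)
    x_star = rng.standard_normal(tiny_model.recon_grid.shape)
    traj = [rng.standard_normal(x_star.shape) for _ in range(3)]
    # independent summation
    expected = 0.0
    for k in range(3):
        expected += np.exp(-cfg.tau * (3 - (k + 1))) * np.abs(traj[k] - x_star).sum()
    for l in params.layers:
        for p in l.phi:
            for j in range(1, len(p.y) - 1):
                d2 = p.y[j - 1] - 2 * p.y[j] + p.y[j + 1]
                expected += cfg.lambda_r * np.sqrt(d2**2 + cfg.eps)
    assert vn_loss(traj, x_star, params, cfg) == pytest.approx(expected, rel=1e-10)


# ---------------------------------------------------------------------------
# gradients of the full unrolled computation
# ---------------------------------------------------------------------------


def test_unrolled_gradients_match_finite_differences(tiny_model):
    """Central finite differences vs reverse-mode for every parameter family."""
    rng = np.random.default_rng(0)
    arch = VNArchitecture(K=2, n_priors=2, kernel_size=3, n_knots=7)
    params = init_vn_params(arch, tiny_model, x_unit=1.0, rng=rng)
    for l in params.layers:
        l.filters += 0.1 * rng.standard_normal(l.filters.shape)
        l.w += 0.05 * rng.standard_normal(l.w.shape)
        for p in l.phi:
            p.y += 0.1 * rng.standard_normal(p.y.shape)
        l.psi.y += 0.1 * rng.standard_normal(l.psi.y.shape)
        l.s += 0.1 * rng.standard_normal(l.s.shape)
        l.phi_scale[:] = 2.0
        l.psi_scale = 2.0
    op = NormalizedOperator.from_model(tiny_model)
    dprime = 0.5 * rng.standard_normal(tiny_model.meas_shape)
    x_star = 0.5 * rng.standard_normal(tiny_model.recon_grid.shape)
    cfg = TrainingConfig(tau=0.3, lambda_r=1e-2, eps=1e-4)
    _, grads, _ = vn_value_and_grad(params, dprime, x_star, op, cfg)

    def loss_now():
        traj = _forward_normalized(params, dprime, op)
        return vn_loss(traj, x_star, params, cfg)

    h = 1e-6
    checked = 0
    for k, l in enumerate(params.layers):
        families = [
            (l.filters.ravel(), np.asarray(grads[k]["filters"]).ravel()),
            (l.w.ravel(), np.asarray(grads[k]["w"]).ravel()),
            (l.s, np.asarray(grads[k]["s"])),
            (l.psi.y, np.asarray(grads[k]["psi_y"])),
        ] + [(p.y, np.asarray(grads[k]["phi_y"][j])) for j, p in enumerate(l.phi)]
        for arr, garr in families:
            for idx in rng.choice(arr.size, size=min(4, arr.size), replace=False):
                old = arr[idx]
                arr[idx] = old + h
                fp = loss_now()
                arr[idx] = old - h
                fm = loss_now()
                arr[idx] = old
                fd = (fp - fm) / (2 * h)
                assert abs(fd - garr[idx]) <= 1e-4 * max(1.0, abs(fd), abs(garr[idx]))
                checked += 1
    assert checked >= 40


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def toy_training_setup():
    grid = ImagingGrid(8, 8, 2.0, 2.0)
    spec = AcquisitionSpec(n_transmits=5, pair_offset=2)
    cfg = SimulationConfig(grid=grid, spec=spec, n_train=16, n_test=4, seed=1)
    train_set, test_set = make_dataset(cfg)
    model = build_forward_model(spec, grid)
    return train_set, test_set, model


def test_training_reduces_running_loss(toy_training_setup):
    train_set, _, model = toy_training_setup
    tc = TrainingConfig(iterations=60, batch_size=8, lr=5e-3, seed=0)
    arch = VNArchitecture(K=3, n_priors=3, kernel_size=3, n_knots=9)
    res = train_vn(train_set, model, tc, arch)
    assert np.mean(res.loss_history[-10:]) < np.mean(res.loss_history[:10])


def test_training_is_deterministic(toy_training_setup):
    train_set, _, model = toy_training_setup
    tc = TrainingConfig(iterations=10, batch_size=4, lr=5e-3, seed=3)
    arch = VNArchitecture(K=2, n_priors=2, kernel_size=3, n_knots=7)
    a = train_vn(train_set, model, tc, arch)
    b = train_vn(train_set, model, tc, arch)
    assert np.array_equal(a.loss_history, b.loss_history)
    for la, lb in zip(a.params.layers, b.params.layers):
        assert np.array_equal(la.filters, lb.filters)
        assert np.array_equal(la.w, lb.w)
        assert np.array_equal(la.s, lb.s)
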