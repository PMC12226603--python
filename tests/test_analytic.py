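"""LBFGS baseline reconstruction and slowness/SoS conversions."""

import numpy as np
import pytest

from sosvn.analytic import (
    AnalyticalConfig,
    objective_and_grad,
    solve_inverse_lbfgs,
)
from sosvn.geometry import (
    AcquisitionSpec,
    DisplacementMeasurements,
    ImagingGrid,
    apply_forward,
    build_forward_model,
)
from sosvn.maps import (
    SlownessMap,
    SoSMap,
    slowness_of,
    slowness_to_sos,
    sos_to_slowness,
)


@pytest.fixture(scope="module")
def toy_model():
    """4x4 grid with enough transmits for a full-column-rank operator."""
    grid = ImagingGrid(4, 4, 1.0, 1.0)
    spec = AcquisitionSpec(
        n_transmits=8,
        pair_offset=1,
        vs_angles_deg=tuple(np.linspace(-24, 24, 8)),
    )
    model = build_forward_model(spec, grid)
    assert np.linalg.matrix_rank(model.L.toarray()) == grid.n_pixels
    return model


def _zero_measurements(model):
    return DisplacementMeasurements(
        values=np.zeros(model.meas_shape), grid=model.meas_grid, pairs=model.pairs
    )


def test_zero_data_yields_zero_map(toy_model):
    res = solve_inverse_lbfgs(
        _zero_measurements(toy_model), toy_model, AnalyticalConfig(lambda_reg=0.1)
    )
    assert np.allclose(res.slowness.values, 0.0)
    assert np.allclose(res.sos.values, toy_model.spec.c0)


def test_unregularized_l2_matches_pseudoinverse(toy_model):
    """p=2, lambda=0 solution equals the dense least-squares oracle."""
    rng = np.random.default_rng(3)
    x_true = 1e-8 * rng.standard_normal(toy_model.recon_grid.shape)
    d = apply_forward(toy_model, x_true)
    cfg = AnalyticalConfig(norm_p=2, lambda_reg=0.0, max_iter=2000, grad_tol=1e-12)
    res = solve_inverse_lbfgs(d, toy_model, cfg)
    oracle = np.linalg.pinv(toy_model.L.toarray()) @ d.ravel()
    err = np.linalg.norm(res.slowness.values.ravel() - oracle) / np.linalg.norm(oracle)
    assert err <= 1e-6


@pytest.mark.parametrize("norm_p", [1, 2])
def test_objective_gradient_matches_finite_differences(toy_model, norm_p):
    rng = np.random.default_rng(0)
    cfg = AnalyticalConfig(norm_p=norm_p, lambda_reg=0.05, smoothing_eps=1e-4)
    Ln = toy_model.L / toy_model.spectral_norm()
    d = rng.standard_normal(toy_model.L.shape[0])
    u = rng.standard_normal(toy_model.recon_grid.n_pixels)
    f, g = objective_and_grad(u, Ln, d, cfg, toy_model.recon_grid.shape)
    h = 1e-6
    for idx in rng.choice(u.size, size=8, replace=False):
        up, um = u.copy(), u.copy()
        up[idx] += h
        um[idx] -= h
        fd = (
            objective_and_grad(up, Ln, d, cfg, toy_model.recon_grid.shape)[0]
            - objective_and_grad(um, Ln, d, cfg, toy_model.recon_grid.shape)[0]
        ) / (2 * h)
        assert abs(fd - g[idx]) <= 1e-5 * max(1.0, abs(fd))


def test_solution_gradient_norm_below_tolerance(toy_model):
    """Returned solution is a stationary point of the smoothed objective."""
    rng = np.random.default_rng(1)
    d = DisplacementMeasurements(
        values=1e-8 * rng.standard_normal(toy_model.meas_shape),
        grid=toy_model.meas_grid,
        pairs=toy_model.pairs,
    )
    cfg = AnalyticalConfig(lambda_reg=0.01, max_iter=3000, grad_tol=1e-10)
    res = solve_inverse_lbfgs(d, toy_model, cfg)
    assert res.converged
    assert res.grad_norm <= 1e-6  # normalized-objective gradient
    # cross-check stationarity with a finite-difference gradient
    Ln = toy_model.L / toy_model.spectral_norm()
    d_unit = np.abs(d.ravel()).max()
    x_unit = d_unit / toy_model.spectral_norm()
    u = res.slowness.values.ravel() / x_unit
    dprime = d.ravel() / d_unit
    h = 1e-7
    fd = np.zeros_like(u)
    for i in range(u.size):
        up, um = u.copy(), u.copy()
        up[i] += h
        um[i] -= h
        fd[i] = (
            objective_and_grad(up, Ln, dprime, cfg, toy_model.recon_grid.shape)[0]
            - objective_and_grad(um, Ln, dprime, cfg, toy_model.recon_grid.shape)[0]
        ) / (2 * h)
    assert np.linalg.norm(fd) <= 1e-5


def test_tv_of_solution_decreases_with_lambda(toy_model):
    rng = np.random.default_rng(2)
    d = DisplacementMeasurements(
        values=1e-8 * rng.standard_normal(toy_model.meas_shape),
        grid=toy_model.meas_grid,
        pairs=toy_model.pairs,
    )

    def tv(x):
        return np.abs(np.diff(x, axis=0)).sum() + np.abs(np.diff(x, axis=1)).sum()

    tvs = []
    for lam in [0.0, 0.01, 0.05, 0.2, 1.0]:
        res = solve_inverse_lbfgs(
            d, toy_model, AnalyticalConfig(lambda_reg=lam, max_iter=2000, grad_tol=1e-12)
        )
        tvs.append(tv(res.slowness.values))
    assert all(b <= a + 1e-14 for a, b in zip(tvs, tvs[1:]))


def test_noise_free_recovery_on_full_rank_system():
    """With full-rank stacked paths and lambda -> 0, the phantom is recovered."""
    grid = ImagingGrid(8, 8, 1.0, 1.0)
    spec = AcquisitionSpec(
        n_transmits=12, pair_offset=1, vs_angles_deg=tuple(np.linspace(-25, 25, 12))
    )
    model = build_forward_model(spec, grid)
    assert np.linalg.matrix_rank(model.L.toarray()) == grid.n_pixels
    rng = np.random.default_rng(4)
    c_gt = 1500.0 + 8.0 * rng.standard_normal(grid.shape)
    x_true = sos_to_slowness(SoSMap(values=c_gt, grid=grid), spec.c0)
    d = apply_forward(model, x_true)
    res = solve_inverse_lbfgs(
        d, model, AnalyticalConfig(lambda_reg=0.0, max_iter=4000, grad_tol=1e-13)
    )
    err = np.sqrt(np.mean((res.sos.values - c_gt) ** 2))
    assert err <= 0.5


def test_slowness_sos_round_trip():
    grid = ImagingGrid(5, 4, 1.0, 1.0)
    rng = np.random.default_rng(0)
    x = SlownessMap(
        values=1e-8 * rng.standard_normal(grid.shape), x0=slowness_of(1500.0), grid=grid
    )
    back = sos_to_slowness(slowness_to_sos(x), 1500.0)
    np.testing.assert_allclose(back.values, x.values, rtol=1e-12, atol=1e-20)


def test_conversion_examples_and_errors():
    grid = ImagingGrid(2, 2, 1.0, 1.0)
    zero = SlownessMap(values=np.zeros(grid.shape), x0=slowness_of(1500.0), grid=grid)
    assert np.allclose(slowness_to_sos(zero).values, 1500.0)
    x = SlownessMap(
        values=np.full(grid.shape, slowness_of(1540.0)) - slowness_of(1500.0),
        x0=slowness_of(1500.0),
        grid=grid,
    )
    assert np.allclose(slowness_to_sos(x).values, 1540.0)
    bad = SlownessMap(values=np.full(grid.shape, -1.0), x0=slowness_of(1500.0), grid=grid)
    with pytest.raises(ValueError, match="4 pixel"):
        slowness_to_sos(bad)
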