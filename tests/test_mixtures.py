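"""Form factors, polydispersity, bilayers, structure factors, mixture fits."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from saskit import mixtures as mx
from saskit.exceptions import DataError
from saskit.sas_io import Curve

S = np.linspace(0.0, 3.0, 400)


def _sphere(R=5.0, **kw):
    return mx.ComponentModel("sphere", {"R": R}, **kw)


def test_sphere_forward_limit():
    comp = _sphere(R=5.0)
    V = 4.0 / 3.0 * math.pi * 125.0
    I = mx.form_factor(comp, np.array([0.0]))
    np.testing.assert_allclose(I[0], V ** 2, rtol=1e-10)


def test_sphere_first_minimum_at_classical_root():
    """First zero of the sphere form factor at s R = x0, tan x0 = x0 (~4.4934)."""
    comp = _sphere(R=5.0)
    x0 = brentq(lambda x: math.tan(x) - x, math.pi + 1e-6, 1.5 * math.pi - 1e-6)
    f = lambda s: mx.form_factor(comp, np.array([s]))[0]
    s_grid = np.linspace(0.5, 1.2, 2000)
    vals = mx.form_factor(comp, s_grid)
    s_min = s_grid[np.argmin(vals)]
    assert abs(s_min * 5.0 - x0) < 0.01
    assert abs(x0 - 4.4934) < 1e-3


def test_core_shell_equal_contrast_reduces_to_sphere():
    cs = mx.ComponentModel("core_shell_sphere",
                           {"R_core": 3.0, "R_total": 5.0,
                            "drho_core": 2.0, "drho_shell": 2.0})
    sphere = _sphere(R=5.0, contrast=2.0)
    np.testing.assert_allclose(mx.form_factor(cs, S), mx.form_factor(sphere, S),
                               rtol=1e-12, atol=1e-12)


def test_ellipsoid_unit_ratio_reduces_to_sphere():
    ell = mx.ComponentModel("ellipsoid_of_revolution", {"a": 4.0, "epsilon": 1.0})
    sphere = _sphere(R=4.0)
    np.testing.assert_allclose(mx.form_factor(ell, S), mx.form_factor(sphere, S),
                               rtol=1e-8)


def test_cylinder_forward_limit_and_positivity():
    cyl = mx.ComponentModel("cylinder", {"R": 2.0, "L": 10.0})
    I = mx.form_factor(cyl, S)
    V = math.pi * 4.0 * 10.0
    np.testing.assert_allclose(I[0], V ** 2, rtol=1e-6)
    assert np.all(I >= 0)


def test_form_factors_continuous_at_origin():
    """I(s->0) approaches the analytic limit for every kind (series check)."""
    comps = [_sphere(R=5.0),
             mx.ComponentModel("ellipsoid_of_revolution", {"a": 3.0, "epsilon": 2.0}),
             mx.ComponentModel("cylinder", {"R": 2.0, "L": 8.0}),
             mx.ComponentModel("core_shell_sphere",
                               {"R_core": 2.0, "R_total": 4.0,
                                "drho_core": 1.0, "drho_shell": -0.5})]
    tiny = np.array([0.0, 1e-6, 1e-5])
    for comp in comps:
        I = mx.form_factor(comp, tiny)
        np.testing.assert_allclose(I[1:], I[0], rtol=1e-6)


def test_polydisperse_zero_width_is_monodisperse():
    comp = _sphere(R=5.0, polydispersity=0.0)
    np.testing.assert_array_equal(mx.polydisperse(comp, S), mx.form_factor(comp, S))


@pytest.mark.parametrize("distribution", ["gaussian", "schulz"])
def test_polydispersity_fills_the_minimum(distribution):
    mono = _sphere(R=5.0)
    poly = _sphere(R=5.0, polydispersity=0.10, distribution=distribution)
    s_grid = np.linspace(0.5, 1.2, 2000)
    s_min = s_grid[np.argmin(mx.form_factor(mono, s_grid))]
    at_min = np.array([s_min])
    assert mx.polydisperse(poly, at_min)[0] > mx.form_factor(mono, at_min)[0]


@pytest.mark.parametrize("distribution", ["gaussian", "schulz"])
def test_quadrature_self_convergence(distribution):
    """51 vs 201 size-quadrature nodes agree to 1e-4 relative."""
    comp = _sphere(R=5.0, polydispersity=0.15, distribution=distribution)
    s_grid = np.linspace(0.05, 2.0, 100)
    coarse = mx.polydisperse(comp, s_grid)
    orig = mx.N_SIZE_NODES
    try:
        mx.N_SIZE_NODES = 201
        fine = mx.polydisperse(comp, s_grid)
    finally:
        mx.N_SIZE_NODES = orig
    assert np.max(np.abs(coarse / fine - 1.0)) < 1e-4


def _bilayer(**kw):
    args = dict(z_H=2.0, sigma_H=0.35, rho_H=1.0, sigma_C=0.6, rho_C=-1.2,
                N_lam=1, d_lam=6.0, sigma_d=0.0, f_diffuse=1.0)
    args.update(kw)
    return mx.BilayerModel(**args)


def test_bilayer_forward_amplitude_closed_form():
    m = _bilayer()
    F0 = math.sqrt(2 * math.pi) * (2 * m.sigma_H * m.rho_H + m.sigma_C * m.rho_C)
    got = mx._bilayer_amplitude(m, np.array([0.0]))[0]
    np.testing.assert_allclose(got, F0, rtol=1e-12)


def test_paracrystal_bragg_value_is_N_squared():
    for N in (1, 2, 5, 9):
        s_bragg = np.array([2.0 * math.pi / 6.0])
        assert mx.paracrystal_sf(s_bragg, N, 6.0, 0.0)[0] == pytest.approx(N ** 2)


def test_unilamellar_equals_diffuse():
    m_uni = _bilayer(N_lam=1, f_diffuse=0.0)
    m_diff = _bilayer(N_lam=1, f_diffuse=1.0)
    s_grid = np.linspace(0.0, 3.0, 200)
    np.testing.assert_allclose(mx.bilayer_intensity(m_uni, s_grid),
                               mx.bilayer_intensity(m_diff, s_grid), rtol=1e-12)


def test_multilamellar_bragg_peak_appears():
    m = _bilayer(N_lam=6, f_diffuse=0.0, sigma_d=0.1)
    s_grid = np.linspace(0.5, 1.6, 500)
    I = mx.bilayer_intensity(m, s_grid)
    s_peak = s_grid[np.argmax(I)]
    assert abs(s_peak - 2 * math.pi / 6.0) < 0.05


def test_percus_yevick_limits():
    s_grid = np.linspace(0.0, 3.0, 100)
    np.testing.assert_array_equal(mx.percus_yevick_sf(s_grid, 3.0, 0.0), 1.0)
    eta = 0.2
    S0 = mx.percus_yevick_sf(np.array([0.0]), 3.0, eta)[0]
    np.testing.assert_allclose(S0, (1 - eta) ** 4 / (1 + 2 * eta) ** 2, rtol=1e-6)
    S_num = mx.percus_yevick_sf(np.array([1e-5, 0.1, 1.0]), 3.0, eta)
    assert np.all(S_num > 0) and S_num[0] == pytest.approx(S0, rel=1e-4)


def test_mixture_single_component_identity():
    comp = _sphere(R=5.0)
    model = mx.MixtureModel([comp], [1.0])
    np.testing.assert_allclose(mx.mixture_intensity(model, S),
                               mx.polydisperse(comp, S) / comp.volume())


def test_mixture_two_identical_halves_equal_one():
    comp = _sphere(R=5.0)
    one = mx.MixtureModel([comp], [1.0])
    two = mx.MixtureModel([_sphere(R=5.0), _sphere(R=5.0)], [0.5, 0.5])
    np.testing.assert_allclose(mx.mixture_intensity(two, S),
                               mx.mixture_intensity(one, S), rtol=1e-12)


def test_mixture_linear_in_volume_fractions():
    a, b = _sphere(R=3.0), _sphere(R=6.0)
    s_grid = np.linspace(0.01, 3.0, 100)
    Ia = mx.mixture_intensity(mx.MixtureModel([a], [1.0]), s_grid)
    Ib = mx.mixture_intensity(mx.MixtureModel([b], [1.0]), s_grid)
    Iab = mx.mixture_intensity(mx.MixtureModel([_sphere(R=3.0), _sphere(R=6.0)],
                                               [0.3, 0.7]), s_grid)
    np.testing.assert_allclose(Iab, 0.3 * Ia + 0.7 * Ib, rtol=1e-10)


def _two_sphere_curve(v=(0.3, 0.7), noise=0.0, seed=0):
    model = mx.MixtureModel([_sphere(R=3.0), _sphere(R=6.0)], list(v))
    s_grid = np.linspace(0.02, 3.0, 200)
    I = mx.mixture_intensity(model, s_grid)
    if noise > 0:
        rng = np.random.default_rng(seed)
        sigma = noise * I
        I = I + rng.standard_normal(len(s_grid)) * sigma
        return Curve(s_grid, I, sigma), model
    return Curve(s_grid, I, np.full_like(s_grid, np.nan)), model


def test_fit_mixture_noiseless_round_trip():
    curve, truth = _two_sphere_curve()
    fitted, scale, chi2 = mx.fit_mixture(
        curve, truth, {"volume_fractions": True, 0: ["R"], 1: ["R"]})
    np.testing.assert_allclose(fitted.volume_fractions, [0.3, 0.7], atol=1e-4)
    assert scale == pytest.approx(1.0, rel=1e-6)


def test_fit_mixture_frozen_mask_returns_input_and_analytic_scale():
    curve, truth = _two_sphere_curve()
    scaled = Curve(curve.s, 2.5 * curve.I, curve.sigma)
    fitted, scale, _ = mx.fit_mixture(scaled, truth, {})
    assert fitted is truth
    assert scale == pytest.approx(2.5, rel=1e-12)


def test_fit_mixture_noisy_recovery_over_seeds():
    """1% noise, initials +/-20%: median radii within 2%, fractions within 0.05."""
    r_errs, v_errs = [], []
    for seed in range(20):
        curve, _ = _two_sphere_curve(noise=0.01, seed=seed)
        rng = np.random.default_rng(5000 + seed)
        f = 1.0 + rng.uniform(-0.2, 0.2, 2)
        start = mx.MixtureModel([_sphere(R=3.0 * f[0]), _sphere(R=6.0 * f[1])],
                                [0.5, 0.5])
        fitted, _, _ = mx.fit_mixture(
            curve, start, {"volume_fractions": True, 0: ["R"], 1: ["R"]})
        r_errs.append(max(abs(fitted.components[0].params["R"] / 3.0 - 1.0),
                          abs(fitted.components[1].params["R"] / 6.0 - 1.0)))
        v_errs.append(abs(fitted.volume_fractions[0] - 0.3))
    assert np.median(r_errs) < 0.02
    assert np.median(v_errs) < 0.05


def test_batch_fit_identical_curves_identical_results():
    curve, truth = _two_sphere_curve()
    res = mx.batch_fit([curve, curve.copy()], truth,
                       {"volume_fractions": True}, chain=False)
    v0 = res[0][0].volume_fractions
    v1 = res[1][0].volume_fractions
    np.testing.assert_array_equal(v0, v1)


def test_batch_fit_collects_per_curve_errors():
    curve, truth = _two_sphere_curve()
    bad = Curve(curve.s[:3], curve.I[:3], curve.sigma[:3])  # too few points
    res = mx.batch_fit([curve, bad, curve.copy()], truth,
                       {"volume_fractions": True, 0: ["R"], 1: ["R"]})
    assert isinstance(res[1], Exception)
    assert not isinstance(res[0], Exception) and not isinstance(res[2], Exception)


def test_batch_fit_chain_tracks_slow_series():
    """Chained fits follow a slowly drifting radius without diverging."""
    s_grid = np.linspace(0.02, 3.0, 200)
    rng = np.random.default_rng(1)
    curves = []
    for step in range(5):
        R = 5.0 + 0.1 * step
        I = mx.mixture_intensity(mx.MixtureModel([_sphere(R=R)], [1.0]), s_grid)
        sigma = 0.01 * I
        curves.append(Curve(s_grid, I + rng.standard_normal(len(s_grid)) * sigma,
                            sigma))
    start = mx.MixtureModel([_sphere(R=5.0)], [1.0])
    res = mx.batch_fit(curves, start, {0: ["R"]}, chain=True)
    for out in res:
        assert not isinstance(out, Exception)
        _, _, chi2 = out
        assert chi2 < 2.0


def test_component_validation():
    with pytest.raises(DataError):
        _sphere(R=-1.0).validate()
    with pytest.raises(DataError):
        mx.ComponentModel("cube", {"R": 1.0}).validate()
    with pytest.raises(DataError):
        _sphere(R=1.0, polydispersity=0.8).validate()
    with pytest.raises(DataError):
        mx.ComponentModel("core_shell_sphere",
                          {"R_core": 5.0, "R_total": 3.0,
                           "drho_core": 1.0, "drho_shell": 1.0}).validate()


def test_volume_fractions_renormalised():
    model = mx.MixtureModel([_sphere(R=3.0), _sphere(R=6.0)], [2.0, 6.0])
    np.testing.assert_allclose(model.volume_fractions, [0.25, 0.75])
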