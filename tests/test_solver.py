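"""Solver checks: boundaries, conservation, fixed point, linear growth."""

import numpy as np
import pytest

from turingbuds.kinetics import (
    KineticParameters,
    growth_rate,
    homogeneous_steady_state,
    jacobian_at_steady_state,
)
from turingbuds.masks import full_mask
from turingbuds.solver import (
    Grid,
    ScalarField,
    SolverSettings,
    Stepper,
    laplacian,
    make_initial_condition,
    run_to_stationarity,
    step,
)

P = KineticParameters()


class TestInitialCondition:
    def test_zero_amplitude_is_exact_steady_state(self):
        g = Grid(n_x=16, n_y=16)
        u, v = make_initial_condition(g, P, amplitude=0.0, seed=5)
        u_star, v_star = homogeneous_steady_state(P)
        assert np.all(u.values == u_star)
        assert np.all(v.values == v_star)

    def test_seeded_reproducibility(self):
        g = Grid(n_x=16, n_y=16)
        u1, v1 = make_initial_condition(g, P, amplitude=0.01, seed=7)
        u2, v2 = make_initial_condition(g, P, amplitude=0.01, seed=7)
        assert np.array_equal(u1.values, u2.values)
        assert np.array_equal(v1.values, v2.values)
        u3, _ = make_initial_condition(g, P, amplitude=0.01, seed=8)
        assert not np.array_equal(u1.values, u3.values)

    def test_perturbation_bounded_by_amplitude(self):
        g = Grid(n_x=32, n_y=32)
        u, _ = make_initial_condition(g, P, amplitude=0.01, seed=3)
        u_star, _ = homogeneous_steady_state(P)
        assert u.values.min() >= 0.99 * u_star
        assert u.values.max() <= 1.01 * u_star

    def test_noise_grid_refinement_shares_realization(self):
        coarse = Grid(n_x=16, n_y=20)
        fine = Grid(n_x=32, n_y=40)
        uc, _ = make_initial_condition(coarse, P, 0.01, seed=2)
        uf, _ = make_initial_condition(fine, P, 0.01, seed=2, noise_grid=coarse)
        assert np.array_equal(uf.values[::2, ::2], uc.values)


class TestLaplacian:
    def test_constant_field_maps_to_zero(self):
        g = Grid(n_x=16, n_y=16)
        lap = laplacian(ScalarField(g, np.full(g.shape, 3.7)))
        np.testing.assert_allclose(lap.values, 0.0, atol=1e-12)

    def test_periodic_eigenfunction_in_y(self):
        g = Grid(n_x=16, n_y=400)
        vals = np.broadcast_to(
            np.cos(2 * np.pi * g.y_centers / g.width_y)[:, None], g.shape
        ).copy()
        lap = laplacian(ScalarField(g, vals))
        k2 = (2 * np.pi / g.width_y) ** 2
        np.testing.assert_allclose(lap.values, -k2 * vals, atol=k2 * 2e-3)

    def test_neumann_eigenfunction_in_x(self):
        g = Grid(n_x=400, n_y=16)
        vals = np.broadcast_to(
            np.cos(np.pi * g.x_centers / g.width_x)[None, :], g.shape
        ).copy()
        lap = laplacian(ScalarField(g, vals))
        k2 = (np.pi / g.width_x) ** 2
        np.testing.assert_allclose(lap.values, -k2 * vals, atol=k2 * 2e-3)


@pytest.mark.parametrize("scheme,dt", [("imex", 0.05), ("explicit", 3e-4)])
def test_masked_off_dynamics_conserve_mass(scheme, dt):
    """With reactions off everywhere, both boundaries conserve total mass."""
    g = Grid(n_x=30, n_y=50)
    vals = np.full(g.shape, 0.1)
    vals[25, 15] = 5.0  # point pulse
    u = ScalarField(g, vals)
    v = ScalarField(g, np.full(g.shape, 0.2))
    mask = ScalarField(g, np.zeros(g.shape))
    settings = SolverSettings(dt=dt, duration=1000 * dt, scheme=scheme)
    res = run_to_stationarity(u, v, mask.values, P, settings)
    for before, after in ((u, res.u), (v, res.v)):
        total0 = before.values.sum()
        assert abs(after.values.sum() - total0) / total0 < 1e-8


def test_homogeneous_steady_state_is_fixed_point():
    g = Grid(n_x=30, n_y=50)
    u, v = make_initial_condition(g, P, amplitude=0.0, seed=0)
    settings = SolverSettings(dt=0.1, duration=50.0)
    res = run_to_stationarity(u, v, full_mask(g), P, settings)
    u_star, v_star = homogeneous_steady_state(P)
    assert np.abs(res.u.values - u_star).max() < 1e-12
    assert np.abs(res.v.values - v_star).max() < 1e-12
    assert res.converged


def seeded_mode_fields(grid, p, mode_y, eps=1e-4):
    """Perturb (u*, v*) along the unstable eigenvector of one y-eigenmode."""
    u_star, v_star = homogeneous_steady_state(p)
    k = 2 * np.pi * mode_y / grid.width_y
    M = jacobian_at_steady_state(p) - k * k * np.diag([p.D_u, p.D_v])
    w, vecs = np.linalg.eig(M)
    phi = np.real(vecs[:, np.argmax(w.real)])
    mode = np.cos(k * grid.y_centers)[:, None] * np.ones(grid.shape)
    u = ScalarField(grid, u_star + eps * phi[0] * mode)
    v = ScalarField(grid, v_star + eps * phi[1] * mode, "inhibitor")
    return u, v, mode, k


def measured_growth_rate(grid, p, mode_y, duration=30.0, dt=0.01):
    u, v, mode, k = seeded_mode_fields(grid, p, mode_y)
    u_star, _ = homogeneous_steady_state(p)
    norm = (mode * mode).sum()

    def amp(field):
        return ((field.values - u_star) * mode).sum() / norm

    a0 = amp(u)
    settings = SolverSettings(dt=dt, duration=duration)
    res = run_to_stationarity(u, v, full_mask(grid), p, settings)
    a1 = amp(res.u)
    return np.log(abs(a1) / abs(a0)) / duration, k


def test_single_mode_grows_at_dispersion_rate():
    """Early-time growth of a seeded eigenmode matches the closed form."""
    g = Grid(n_x=24, n_y=100)
    rate, k = measured_growth_rate(g, P, mode_y=2)
    expected = growth_rate(P, k)
    assert expected > 0
    assert rate == pytest.approx(expected, rel=0.05)


def test_zero_duration_returns_inputs():
    g = Grid(n_x=16, n_y=16)
    u, v = make_initial_condition(g, P, amplitude=0.01, seed=4)
    res = run_to_stationarity(u, v, full_mask(g), P, SolverSettings(dt=0.1, duration=0.0))
    assert np.array_equal(res.u.values, u.values)
    assert np.array_equal(res.v.values, v.values)
    assert not res.converged  # a perturbed state still has a finite change rate


def test_stable_parameters_relax_to_homogeneity():
    p = KineticParameters(D_u=1.0, D_v=1.0)
    g = Grid(n_x=30, n_y=50)
    u, v = make_initial_condition(g, p, amplitude=0.01, seed=9)
    res = run_to_stationarity(u, v, full_mask(g), p, SolverSettings(dt=0.1, duration=200.0))
    u_star, v_star = homogeneous_steady_state(p)
    assert res.converged
    assert np.abs(res.u.values - u_star).max() < 1e-4
    assert np.abs(res.v.values - v_star).max() < 1e-4


def test_periodic_shift_equivariance():
    """Cyclic y-shift of the initial state cyclically shifts the outcome."""
    g = Grid(n_x=24, n_y=40)
    u, v = make_initial_condition(g, P, amplitude=0.01, seed=11)
    shift = 13
    us = ScalarField(g, np.roll(u.values, shift, axis=0))
    vs = ScalarField(g, np.roll(v.values, shift, axis=0), "inhibitor")
    settings = SolverSettings(dt=0.1, duration=100.0)
    res = run_to_stationarity(u, v, full_mask(g), P, settings)
    res_s = run_to_stationarity(us, vs, full_mask(g), P, settings)
    np.testing.assert_allclose(
        res_s.u.values, np.roll(res.u.values, shift, axis=0), atol=1e-8
    )


def test_x_mirror_symmetry_preserved():
    """A left-right symmetric state stays symmetric: the discrete zero-flux
    boundary is exactly the mirror symmetry."""
    g = Grid(n_x=24, n_y=40)
    u, v = make_initial_condition(g, P, amplitude=0.01, seed=12)
    u.values = 0.5 * (u.values + u.values[:, ::-1])
    v.values = 0.5 * (v.values + v.values[:, ::-1])
    res = run_to_stationarity(u, v, full_mask(g), P, SolverSettings(dt=0.1, duration=100.0))
    np.testing.assert_allclose(res.u.values, res.u.values[:, ::-1], atol=1e-8)


def test_halving_dt_preserves_the_pattern():
    """Halving dt leaves the stationary spot pattern unchanged: same spot
    count, centroids within half a wavelength cell, and both endpoints solve
    the dt-independent discrete stationarity equation D lap(u) + f S = 0."""
    from turingbuds.kinetics import evaluate_kinetics
    from turingbuds.masks import extract_condensations
    from turingbuds.solver import laplacian_values

    g = Grid(n_x=48, n_y=80)
    u, v = make_initial_condition(g, P, amplitude=0.01, seed=21)
    r1 = run_to_stationarity(u, v, full_mask(g), P, SolverSettings(dt=0.1, duration=600.0))
    r2 = run_to_stationarity(u, v, full_mask(g), P, SolverSettings(dt=0.05, duration=600.0))
    scale = r1.u.values.max() - r1.u.values.min()
    assert scale > 0.5  # a genuine pattern formed
    c1 = extract_condensations(r1.u, P)
    c2 = extract_condensations(r2.u, P)
    assert len(c1) == len(c2) > 0
    for a, b in zip(
        sorted(c1, key=lambda r: r.centroid), sorted(c2, key=lambda r: r.centroid)
    ):
        assert np.hypot(
            a.centroid[0] - b.centroid[0], a.centroid[1] - b.centroid[1]
        ) < 0.5
    for r in (r1, r2):
        f, _ = evaluate_kinetics(P, r.u.values, r.v.values)
        residual = P.D_u * laplacian_values(r.u.values, g) + f
        assert np.abs(residual).max() < 1e-8


def test_explicit_scheme_agrees_with_imex_short_time():
    g = Grid(n_x=30, n_y=50)
    u, v = make_initial_condition(g, P, amplitude=0.01, seed=6)
    dt = 3e-4
    kw = dict(dt=dt, duration=2.0)
    r_exp = run_to_stationarity(u, v, full_mask(g), P, SolverSettings(scheme="explicit", **kw))
    r_imx = run_to_stationarity(u, v, full_mask(g), P, SolverSettings(scheme="imex", **kw))
    np.testing.assert_allclose(r_exp.u.values, r_imx.u.values, atol=1e-5)


def test_explicit_scheme_rejects_unstable_dt():
    g = Grid(n_x=60, n_y=100)
    with pytest.raises(ValueError, match="explicit scheme needs dt"):
        Stepper(g, P, SolverSettings(dt=0.1, scheme="explicit"))


def test_step_requires_shared_grid():
    g1, g2 = Grid(n_x=16, n_y=16), Grid(n_x=16, n_y=20)
    u, _ = make_initial_condition(g1, P, 0.0, 0)
    _, v = make_initial_condition(g2, P, 0.0, 0)
    with pytest.raises(ValueError, match="share one grid"):
        step(u, v, None, P, SolverSettings(dt=0.1))


def test_grid_validation():
    with pytest.raises(ValueError, match="at least 8x8"):
        Grid(n_x=4, n_y=100)
    with pytest.raises(ValueError, match="extents"):
        Grid(width_x=-1.0)
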