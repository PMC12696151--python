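"""Time integration, decay-rate measurement, and center reconstruction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm

from kswave import (
    CFLError, Field, Grid, ModelParams, Trajectory, apply_FC, decay_rate,
    h1_norm, l2_norm, numeric_TW, perturbation_fixture, project, psi,
    reconstruct_center, refine_equilibrium, simulate, solve_P0, step,
    synthesize,
)
from kswave.stationary_spectral import apply_SC, sc_matrix


def test_stationary_state_is_fixed_point(grid, params):
    m = Field(grid, np.ones(grid.n), bc="neumann")
    out = step(m, 1e-3, params)
    assert np.max(np.abs(out.values - 1.0)) < 1e-13


@pytest.mark.parametrize("scheme", ["imex", "exponential"])
def test_mass_conserved_every_step(grid, params, scheme):
    u = perturbation_fixture("random_trig", 0.02, seed=1, n_modes=6)
    m0 = Field(grid, 1 + u.values, bc="neumann", deriv=u.deriv, deriv2=u.deriv2)
    traj = simulate(m0, params, T=0.05, dt=1e-3, scheme=scheme)
    assert np.max(np.abs(traj.mass - 1.0)) < 1e-12


def test_cfl_violation_suggests_dt(grid):
    pars = ModelParams(50.0, 0.5)
    u = perturbation_fixture("single_mode", 0.5, mode=2)
    m = Field(grid, 1 + u.values, bc="neumann")
    with pytest.raises(CFLError) as err:
        step(m, 1.0, pars)
    assert err.value.suggested_dt < 1.0


def test_step_preserves_traveling_wave():
    """One step from the exact wave moves it only by discretization error."""
    g = Grid.uniform(513)
    tw = numeric_TW(0.05, 1.0, grid=g)
    pars = ModelParams(tw.P, 1.0)
    dt = 1e-3
    out = step(Field(g, tw.m.values, bc="neumann"), dt, pars)
    move = np.sqrt(np.sum(g.weights * (out.values - tw.m.values) ** 2))
    assert move < 1e-6 * dt


def test_single_mode_decay_monotone_and_rate(grid, params):
    """cos(2 pi x) perturbation decays at the printed closed-form rate."""
    u = perturbation_fixture("single_mode", 0.01, mode=2)
    m0 = Field(grid, 1 + u.values, bc="neumann", deriv=u.deriv, deriv2=u.deriv2)
    traj = simulate(m0, params, T=0.4, dt=4e-4)
    assert np.all(np.diff(np.log(traj.l2)) < 0)
    fit = decay_rate(traj)
    lam = -4 * np.pi ** 2 + 1 / (1 + 1 / (4 * np.pi ** 2))
    assert fit.rate == pytest.approx(-lam, rel=0.02)
    assert fit.monotone


def test_decay_rate_exact_on_synthetic_series(grid, params):
    t = np.linspace(0, 2, 201)
    traj = Trajectory(times=t, l2=np.exp(-3 * t), h1=np.exp(-3 * t),
                      mass=np.ones_like(t), phip_half=None, snap_times=None,
                      snapshots=None, params=params, dt=0.01, scheme="imex",
                      grid=grid, reference=np.ones(grid.n))
    fit = decay_rate(traj, window=(0.0, 2.0))
    assert fit.rate == pytest.approx(3.0, abs=1e-10)
    assert fit.residual < 1e-10


def test_growth_above_threshold(grid):
    """Slightly supercritical activity turns the fitted rate negative."""
    Z = 1.0
    th = solve_P0(Z)
    u = perturbation_fixture("null_mode", 1e-3, Z=Z)
    m0 = Field(grid, 1 + u.values, bc="neumann", deriv=u.deriv, deriv2=u.deriv2)
    rates = {}
    for fac in (1 - 5e-3, 1 + 5e-3):
        pars = ModelParams(th.P0 * fac, Z)
        traj = simulate(m0, pars, T=60.0, dt=0.05, scheme="exponential",
                        store_fields=False)
        rates[fac] = decay_rate(traj).rate
    assert rates[1 - 5e-3] > 0 > rates[1 + 5e-3]


# ---------------------------------------------------------------------------
# the quadratic part
# ---------------------------------------------------------------------------

def test_psi_zero_at_origin(grid, params):
    z = synthesize(np.zeros(4), grid)
    assert np.max(np.abs(psi(z, params).values)) == 0.0


@settings(deadline=None, derandomize=True, max_examples=20)
@given(st.floats(0.5, 4.0))
def test_psi_quadratic_homogeneity(alpha):
    g = Grid.uniform(129)
    pars = ModelParams(1.0, 1.0)
    u = synthesize(np.array([0.02, -0.01, 0.03]), g)
    au = synthesize(alpha * np.array([0.02, -0.01, 0.03]), g)
    assert np.max(np.abs(psi(au, pars).values
                         - alpha ** 2 * psi(u, pars).values)) < 1e-10


def test_psi_bilinear_bound(grid):
    """||Psi(u)|| <= C (P/Z) ||u||_L2 ||u||_H1 with a uniform empirical C."""
    rng = np.random.default_rng(42)
    worst = 0.0
    for P, Z in [(1.0, 1.0), (5.0, 0.5), (2.0, 4.0)]:
        pars = ModelParams(P, Z)
        for _ in range(30):
            u = synthesize(0.1 * rng.standard_normal(10), grid)
            ratio = l2_norm(psi(u, pars)) / (
                (P / Z) * l2_norm(u) * h1_norm(u))
            worst = max(worst, ratio)
    assert np.isfinite(worst) and worst < 10.0


# ---------------------------------------------------------------------------
# semigroup and H1 control
# ---------------------------------------------------------------------------

def test_linear_regime_matches_semigroup(grid):
    """A tiny perturbation follows exp(t A_N) on the projected coefficients."""
    Z = 1.0
    th = solve_P0(Z)
    pars = ModelParams(0.9 * th.P0, Z)
    u = perturbation_fixture("random_trig", 1e-8, seed=3, n_modes=6)
    m0 = Field(grid, 1 + u.values, bc="neumann", deriv=u.deriv, deriv2=u.deriv2)
    T = 1.0
    traj = simulate(m0, pars, T, dt=0.01, scheme="exponential", n_modes=64)
    K = 64
    cT = expm(sc_matrix(pars.P, pars.Z, K) * T) @ project(u, K)
    uT = synthesize(cT, grid)
    err = np.sqrt(np.sum(grid.weights * (traj.snapshots[-1] - 1 - uT.values) ** 2))
    assert err < 1e-6 * np.linalg.norm(cT)


def test_h1_no_growth_in_stable_regime(grid, params):
    u = perturbation_fixture("random_trig", 1e-3, seed=9, n_modes=6)
    m0 = Field(grid, 1 + u.values, bc="neumann", deriv=u.deriv, deriv2=u.deriv2)
    traj = simulate(m0, params, T=0.3, dt=5e-4)
    assert np.max(traj.h1) <= traj.h1[0] * (1 + 1e-6)


# ---------------------------------------------------------------------------
# center reconstruction
# ---------------------------------------------------------------------------

def test_center_stationary_run_stays_put(grid, params):
    m0 = Field(grid, np.ones(grid.n), bc="neumann")
    traj = simulate(m0, params, T=0.2, dt=1e-3)
    ct = reconstruct_center(traj)
    assert np.max(np.abs(ct.c)) < 1e-8
    assert ct.c[0] == 0.0


def test_center_tracks_wave_velocity(grid):
    Z, V = 1.0, 0.05
    tw = numeric_TW(V, Z, grid=grid)
    pars = ModelParams(tw.P, Z)
    m0 = Field(grid, tw.m.values, bc="neumann")
    traj = simulate(m0, pars, T=20.0, dt=5e-3, reference=tw)
    ct = reconstruct_center(traj)
    assert abs(ct.c[-1] / ct.times[-1] - V) <= 0.01 * V
    # reflected initial data moves the other way
    m0r = Field(grid, tw.m.values[::-1], bc="neumann")
    trajr = simulate(m0r, pars, T=5.0, dt=5e-3)
    ctr = reconstruct_center(trajr)
    assert ctr.c[-1] == pytest.approx(-V * 5.0, rel=0.02)


def test_center_requires_snapshots(grid, params):
    m0 = Field(grid, np.ones(grid.n), bc="neumann")
    traj = simulate(m0, params, T=0.05, dt=1e-3, store_fields=False)
    with pytest.raises(Exception):
        reconstruct_center(traj)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def test_fixture_single_mode_normalization(grid):
    u = perturbation_fixture("single_mode", 0.01, mode=2)
    assert np.max(np.abs(u.values - 0.01 * np.sqrt(2)
                         * np.cos(2 * np.pi * grid.nodes))) < 1e-10
    assert l2_norm(u) == pytest.approx(0.01, abs=1e-10)


def test_fixture_determinism_and_band_limit(grid):
    a = perturbation_fixture("random_trig", 0.05, seed=77, n_modes=8)
    b = perturbation_fixture("random_trig", 0.05, seed=77, n_modes=8)
    assert np.array_equal(a.values, b.values)
    c = project(a, 20)
    assert np.max(np.abs(c[8:])) < 1e-12
    assert abs(a.mass()) < 1e-12
    assert l2_norm(a) == pytest.approx(0.05, abs=1e-10)


def test_fixture_null_mode(grid):
    u = perturbation_fixture("null_mode", 0.02, Z=1.0)
    assert l2_norm(u) == pytest.approx(0.02, abs=1e-10)
    assert np.max(np.abs(u.values + u.values[::-1])) < 1e-9   # odd
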