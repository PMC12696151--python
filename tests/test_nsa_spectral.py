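"""Non-self-adjoint diagnostics about traveling waves."""

import numpy as np
import pytest

from kswave import (
    GERSHGORIN_RHO, Field, Grid, ModelParams, adjoint_commutator, apply_SC,
    apply_TC, assemble_SC, assemble_TC, asymptotic_TW, commutator_V_slope,
    gershgorin_report, inner_product, leading_eigenvalue, mu1,
    mu1_solvability, null_eigenvector, numeric_TW, project, resolvent_scan,
    solve_P0, spectrum_report, synthesize,
)
from kswave.stationary_spectral import eigs_SC, sc_matrix
from kswave.traveling_waves import P2_closed_form


def test_reduces_to_resting_operator_at_zero_velocity(grid):
    Z = 50.0
    tw = asymptotic_TW(0.0, Z, grid)
    pars = tw.params
    u = synthesize(np.array([0.4, -0.3, 0.2]), grid)
    t = apply_TC(u, tw)
    s = apply_SC(u, pars)
    assert np.max(np.abs(t.values - s.values)) < 1e-10
    A = assemble_TC(tw, None, 24).entries
    S = sc_matrix(pars.P, Z, 24)
    assert np.max(np.abs(A - S)) < 1e-10


def test_output_has_zero_mean(quad_grid):
    tw = asymptotic_TW(0.05, 50.0, quad_grid)
    u = synthesize(np.array([0.5, 0.1, -0.2, 0.3]), quad_grid)
    assert abs(apply_TC(u, tw).mass()) < 1e-9


def test_matrix_matches_quadrature(quad_grid):
    Z, V, N = 50.0, 0.05, 16
    tw = asymptotic_TW(V, Z, quad_grid)
    A = assemble_TC(tw, None, N, quad_grid).entries
    E = [synthesize(np.eye(N)[j], quad_grid) for j in range(N)]
    Q = np.array([[inner_product(E[m], apply_TC(E[n], tw)) for n in range(N)]
                  for m in range(N)])
    assert np.max(np.abs(A - Q)) < 1e-7


def test_wave_correction_linear_in_velocity(quad_grid):
    """Row sums of the d-part halve (within 20%) when V halves."""
    Z = 50.0

    def rowmax(V):
        tw = asymptotic_TW(V, Z, quad_grid)
        D = assemble_TC(tw, None, 32, quad_grid).entries - \
            sc_matrix(tw.P, Z, 32)
        return np.abs(D).sum(axis=1).max()

    r1, r2 = rowmax(0.05), rowmax(0.025)
    assert r1 / r2 == pytest.approx(2.0, rel=0.2)


def test_symmetry_defect_onset(quad_grid):
    """Zero at V = 0, growing linearly in V: the operator turns non-self-adjoint."""
    Z = 200.0
    d0 = assemble_TC(asymptotic_TW(0.0, Z, quad_grid), None, 32, quad_grid)
    assert d0.symmetry_defect < 1e-12
    d1 = assemble_TC(asymptotic_TW(0.02, Z, quad_grid), None, 32, quad_grid)
    d2 = assemble_TC(asymptotic_TW(0.04, Z, quad_grid), None, 32, quad_grid)
    assert d2.symmetry_defect / d1.symmetry_defect == pytest.approx(2.0, rel=0.2)
    assert d1.symmetry_defect > 1e-4


def test_commutator_antisymmetry(quad_grid):
    tw = asymptotic_TW(0.05, 50.0, quad_grid)
    op = lambda u: apply_TC(u, tw)
    u1 = synthesize(np.array([1.0, 0.2]), quad_grid)
    u2 = synthesize(np.array([0.0, 1.0, -0.5]), quad_grid)
    assert adjoint_commutator(op, u1, u2) == pytest.approx(
        -adjoint_commutator(op, u2, u1), abs=1e-12)
    assert adjoint_commutator(op, u1, u1) == pytest.approx(0.0, abs=1e-12)


def test_commutator_matrix_consistency(quad_grid):
    """H by quadrature equals the projected antisymmetric part of the matrix."""
    Z, V, N = 50.0, 0.05, 24
    tw = asymptotic_TW(V, Z, quad_grid)
    A = assemble_TC(tw, None, N, quad_grid).entries
    op = lambda u: apply_TC(u, tw)
    rng = np.random.default_rng(5)
    for _ in range(3):
        c1 = np.zeros(N); c1[:8] = rng.standard_normal(8)
        c2 = np.zeros(N); c2[:8] = rng.standard_normal(8)
        u1, u2 = synthesize(c1, quad_grid), synthesize(c2, quad_grid)
        H = adjoint_commutator(op, u1, u2)
        assert H == pytest.approx(c2 @ (A - A.T) @ c1, abs=1e-7)


def test_commutator_slope_large_viscosity_limit():
    """The onset slope of non-self-adjointness approaches 9 pi^2/16.

    Frozen oracle: term-by-term closed-form evaluation of the slope's five
    integrals (boundary term 0, frame term -2/3, drift term -10/3, transport
    terms 4 - 9 pi^2/16 in the reversed ordering), cross-checked against an
    independent dense finite-difference discretization.
    """
    s3 = commutator_V_slope(1e3)
    s4 = commutator_V_slope(1e4)
    limit = 9 * np.pi ** 2 / 16
    assert s4 == pytest.approx(limit, rel=1e-4)
    assert abs(s4 - limit) < abs(s3 - limit)


# ---------------------------------------------------------------------------
# the critical-eigenvalue slope
# ---------------------------------------------------------------------------

def test_mu1_large_viscosity():
    assert 1e3 * mu1(1e3) == pytest.approx(1.0, abs=1e-4)
    assert 1e4 * mu1(1e4) == pytest.approx(1.0, abs=1e-5)


def test_mu1_matches_eigenvalue_slope():
    Z = 1.0
    th = solve_P0(Z)
    dp = 1e-4
    up = eigs_SC(ModelParams(th.P0 + dp, Z), 96, converge=False)[0]
    dn = eigs_SC(ModelParams(th.P0 - dp, Z), 96, converge=False)[0]
    assert (up - dn) / (2 * dp) == pytest.approx(mu1(Z), abs=1e-4)


def test_mu1_matches_solvability_integral():
    for Z in (0.05, 1.0, 50.0):
        assert mu1_solvability(Z) == pytest.approx(mu1(Z), abs=1e-8)


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def test_leading_eigenvalue_zero_at_zero_velocity(grid):
    lam = leading_eigenvalue(0.0, 200.0)
    assert abs(lam) < 1e-6
    # its eigenvector is the neutral threshold mode
    tw = asymptotic_TW(0.0, 200.0)
    A = assemble_TC(tw, None, 64).entries
    w, Q = np.linalg.eig(A)
    vec = np.real(Q[:, np.argmax(w.real)])
    c = project(null_eigenvector(200.0, grid), 64)
    assert abs(vec @ c) / np.linalg.norm(c) > 1 - 1e-6


def test_eigenvalue_curvature_large_viscosity():
    for V in (0.02, 0.04):
        lam = leading_eigenvalue(V, 200.0)
        assert lam.imag == pytest.approx(0.0, abs=1e-10)
        assert lam.real / V ** 2 == pytest.approx(-np.pi ** 2 / 24,
                                                  rel=0.1)


@pytest.mark.parametrize("Z", [50.0, 200.0])
def test_eigenvalue_exchange_identity(Z):
    """lambda''(0) = -2 P_TW''(0) mu'(P0) with P_TW''(0) = 2 P2."""
    V1, V2 = 0.02, 0.04
    l1 = leading_eigenvalue(V1, Z).real
    l2 = leading_eigenvalue(V2, Z).real
    # quadratic fit through 0, +-V1, +-V2 (even function)
    lpp = 2 * np.polyfit([V1 ** 2, V2 ** 2], [l1, l2], 1)[0]
    expected = -4 * P2_closed_form(Z) * mu1(Z)
    assert lpp == pytest.approx(expected, rel=0.05)


def test_spectrum_conjugate_symmetry_and_convergence():
    rep = spectrum_report(0.05, 200.0, N=48)
    lam = rep.eigenvalues
    for v in lam:
        if abs(v.imag) > 1e-10:
            assert np.min(np.abs(lam - np.conj(v))) < 1e-8
    assert rep.converged
    assert rep.abscissa < 0


# ---------------------------------------------------------------------------
# Gershgorin report
# ---------------------------------------------------------------------------

def test_gershgorin_constant():
    expected = (2 + 5 * np.pi ** 2 + 4 * np.pi ** 4) / \
               (2 + 6 * np.pi ** 2 + 4 * np.pi ** 4)
    assert GERSHGORIN_RHO == pytest.approx(expected, abs=1e-15)
    assert GERSHGORIN_RHO == pytest.approx(0.97811, abs=5e-6)


def test_gershgorin_conditions_high_viscosity(grid):
    tw = asymptotic_TW(0.01, 100.0, grid)
    rep = gershgorin_report(tw, None, 64)
    assert rep.cond_diag_negative
    assert rep.cond_ratio
    assert rep.cond_separation
    assert rep.cond_bounded
    # every row but the first confines its eigenvalue below -1
    assert rep.rows_below_minus_one[1:].all()
    frame = rep.as_frame()
    assert (frame["Q_n"] >= 0).all()


# ---------------------------------------------------------------------------
# resolvent scans
# ---------------------------------------------------------------------------

def test_resolvent_far_field_decay(grid):
    tw = asymptotic_TW(0.05, 200.0, grid)
    scan = resolvent_scan(tw, None, 32, omegas=np.array([1e6]))
    assert scan.norms[0] == pytest.approx(1e-6, rel=1e-3)


def test_resolvent_diverges_on_axis_at_zero_velocity(grid):
    tw = asymptotic_TW(0.0, 200.0, grid)
    for N in (32, 64):
        scan = resolvent_scan(tw, None, N, omegas=np.array([0.0]))
        assert scan.norms[0] > 1e10 or scan.singular[0]


def test_resolvent_supremum_stable_under_truncation(grid):
    tw = asymptotic_TW(0.05, 200.0, grid)
    s32 = resolvent_scan(tw, None, 32).supremum
    s64 = resolvent_scan(tw, None, 64).supremum
    assert np.isfinite(s32) and np.isfinite(s64)
    assert s64 == pytest.approx(s32, rel=0.1)
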