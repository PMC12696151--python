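"""Non-self-adjoint stability diagnostics for traveling waves.

Linearizing the co-moving model about a traveling wave gives

    T_C u = u'' + phi'(1/2) m_TW' + V u' - (m_TW phi')' - (u phi_TW')',

with phi the periodic elliptic response to ``P_TW(V) u``.  At V = 0 this is
the self-adjoint resting-state operator at threshold, but for V != 0 it is
non-self-adjoint: eigenvectors need not span the space, so this module
complements eigenvalue computations with adjoint-commutator measurements,
Gershgorin-type row bounds on the trig-basis matrix, and resolvent-norm
scans along the imaginary axis (finite resolvent supremum + negative
spectral abscissa is the practical signature of exponential linear decay).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .core_model import (
    Field, Grid, ModelParams, ParameterError, SingularityError, ZERO_MEAN_TOL,
    default_grid, inner_product, solve_elliptic, synthesize, _derivs_of,
    DEFAULT_QUAD_SIZE,
)
from .stationary_spectral import OperatorMatrix, sc_matrix, solve_P0
from .traveling_waves import TravelingWave, asymptotic_TW, numeric_TW

__all__ = [
    "SpectrumReport", "GershgorinReport", "ResolventScan", "GERSHGORIN_RHO",
    "apply_TC", "assemble_TC", "adjoint_commutator", "commutator_V_slope",
    "mu1", "mu1_solvability", "leading_eigenvalue", "spectrum_report",
    "gershgorin_report", "resolvent_scan",
]

# the contraction constant of the Gershgorin row-ratio bound
GERSHGORIN_RHO = (2 + 5 * np.pi ** 2 + 4 * np.pi ** 4) / \
                 (2 + 6 * np.pi ** 2 + 4 * np.pi ** 4)


def _sort_eigs(lam: np.ndarray) -> np.ndarray:
    """Descending real part; ties by ascending imaginary part."""
    order = np.lexsort((lam.imag, -lam.real))
    return lam[order]


@dataclass
class SpectrumReport:
    operator: OperatorMatrix
    eigenvalues: np.ndarray
    abscissa: float
    symmetry_defect: float
    converged: bool


@dataclass
class GershgorinReport:
    """Row diagnostics of B = A - I, A the halved (Gram) operator matrix."""

    diag: np.ndarray            # b_nn
    radii: np.ndarray           # Q_n = sum_{m != n} |b_mn|
    ratios: np.ndarray          # Q_n / |b_nn|
    rho: float
    cond_diag_negative: bool    # all b_nn < 0 (and nonzero)
    cond_ratio: bool            # max ratio < rho
    cond_separation: bool       # |b_nn - b_mm| >= Q_n + Q_m for odd n != m
    cond_bounded: bool          # sup |b_mn| finite
    rows_below_minus_one: np.ndarray  # b_nn + Q_n < -1 per row

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "n": np.arange(1, self.diag.size + 1),
            "b_nn": self.diag, "Q_n": self.radii, "ratio": self.ratios,
            "below_minus_one": self.rows_below_minus_one,
        })


@dataclass
class ResolventScan:
    omegas: np.ndarray
    norms: np.ndarray
    supremum: float
    argmax: float
    N: int
    singular: np.ndarray        # flags: i*omega collided with an eigenvalue


# ---------------------------------------------------------------------------
# operator action
# ---------------------------------------------------------------------------

def apply_TC(u: Field, tw: TravelingWave,
             params: Optional[ModelParams] = None) -> Field:
    """T_C u about the wave ``tw``; reduces to S_C(P0) at V = 0."""
    if abs(u.mass()) > ZERO_MEAN_TOL * max(1.0, float(np.max(np.abs(u.values)))):
        raise ParameterError("T_C acts on zero-mean perturbations")
    pars = params or tw.params
    x = u.grid.nodes
    f = tw.evaluate(x)
    phi = solve_elliptic(u, pars)
    du, d2u = _derivs_of(u)
    out = (d2u + phi.deriv[-1] * f["dm"] + tw.V * du
           - (f["dm"] * phi.deriv + f["m"] * phi.deriv2)
           - (du * f["dphi"] + u.values * f["d2phi"]))
    return Field(u.grid, out, bc="none")


# ---------------------------------------------------------------------------
# matrix assembly: a_mn = c_mn + d_mn
# ---------------------------------------------------------------------------

def assemble_TC(tw: TravelingWave, params: Optional[ModelParams] = None,
                N: int = 64, quad_grid: Optional[Grid] = None) -> OperatorMatrix:
    """Trig-basis matrix of T_C (orthonormalized basis).

    The V = 0 part is the closed-form resting-state matrix at P = P_TW(V);
    the wave-dependent correction d_mn is assembled by Clenshaw-Curtis
    quadrature against the traveling-wave profile fields (using the exact
    single-mode elliptic responses phi_n).  Row/column absolute sums of the
    correction scale like O(|V|).
    """
    if N < 2:
        raise ParameterError("basis size must be >= 2")
    pars = params or tw.params
    P, Z = pars.P, pars.Z
    quad_grid = quad_grid or Grid.collocation(DEFAULT_QUAD_SIZE)
    x = quad_grid.nodes
    w = quad_grid.weights
    f = tw.evaluate(x)
    mt = f["m"] - 1.0                           # m~_TW
    V, dV, _ = quad_grid.basis(N)
    s = np.sqrt(2.0)
    n = np.arange(1, N + 1)

    # exact elliptic response of each basis mode at P (orthonormalized)
    amp = P / (1.0 + n ** 2 * np.pi ** 2 * Z)
    dphi_n = s * amp[:, None] * dV
    phi_n_vals = s * amp[:, None] * V
    dphi_half = np.zeros(N)
    odd = n % 2 == 1
    if np.any(odd):
        b = 1.0 / np.sqrt(Z)
        Bc = -s * amp[odd] * np.sin(n[odd] * np.pi / 2) / np.sinh(b / 2)
        phi_n_vals[odd] += Bc[:, None] * np.sinh(b * x)[None, :]
        dphi_n[odd] += Bc[:, None] * (b * np.cosh(b * x))[None, :]
        dphi_half[odd] = Bc * b * np.cosh(b / 2)
    d2phi_n = (phi_n_vals - P * s * V) / Z

    # operand rows: the wave-dependent part of T_C applied to each mode
    op = (dphi_half[:, None] * f["dm"][None, :]
          + tw.V * s * dV
          - mt[None, :] * d2phi_n
          - f["dm"][None, :] * dphi_n
          - s * dV * f["dphi"][None, :]
          - s * V * f["d2phi"][None, :])
    D = (s * V * w) @ op.T                      # D[m, n] = <e_m, op_n>
    entries = sc_matrix(P, Z, N) + D
    return OperatorMatrix(entries, N, pars, V=tw.V, kind="TC")


# ---------------------------------------------------------------------------
# adjoint commutator
# ---------------------------------------------------------------------------

def adjoint_commutator(op: Callable[[Field], Field], u1: Field, u2: Field) -> float:
    """H(u1, u2) = <A u1, u2> - <u1, A u2>; zero iff A is self-adjoint.

    Antisymmetric in its arguments.  Note that the printed expansion of this
    quantity in the source analysis orders the slots the other way round, so
    its sign convention is the negative of this one.
    """
    return inner_product(op(u1), u2) - inner_product(u1, op(u2))


def commutator_V_slope(Z: float, dv: float = 1e-3,
                       quad_grid: Optional[Grid] = None,
                       source: str = "asymptotic") -> float:
    """d/dV at V = 0 of H(sin pi x, cos 2pi x) for T_C, by central difference.

    The onset rate of non-self-adjointness along the wave branch.  Definition
    ordering (operator acting on the first slot); the large-Z limit of this
    slope is +9 pi^2/16 (its negative in the reversed, printed ordering).
    """
    quad_grid = quad_grid or Grid.collocation(DEFAULT_QUAD_SIZE)
    u1 = synthesize(np.array([1.0]), quad_grid)            # sqrt2 sin(pi x) scale
    u2 = synthesize(np.array([0.0, 1.0]), quad_grid)
    # undo orthonormal scaling: the classical test fields are sin/cos themselves
    for u in (u1, u2):
        u.values /= np.sqrt(2.0)
        u.deriv /= np.sqrt(2.0)
        u.deriv2 /= np.sqrt(2.0)

    def H(Vv: float) -> float:
        if source == "numeric":
            tw = numeric_TW(Vv, Z)
        else:
            tw = asymptotic_TW(Vv, Z, quad_grid)
        op = lambda u: apply_TC(u, tw)
        return adjoint_commutator(op, u1, u2)

    return (H(dv) - H(-dv)) / (2 * dv)


# ---------------------------------------------------------------------------
# the critical-eigenvalue slope mu'(P0)
# ---------------------------------------------------------------------------

def mu1(Z: float) -> float:
    """Slope in P at P0 of the critical eigenvalue of the resting operator.

    Closed form mu1 = 3 (P0-1)(P0^2 - 12 Z) / (P0 Z (3 P0^2 - 60 Z + 2));
    behaves like 1/Z for large Z.
    """
    P0 = solve_P0(Z).P0
    den = P0 * Z * (3 * P0 ** 2 - 60 * Z + 2)
    if abs(den) < 1e-14 * max(1.0, P0 ** 3):
        raise SingularityError("mu1 denominator vanishes at this Z")
    return 3 * (P0 - 1) * (P0 ** 2 - 12 * Z) / den


def mu1_solvability(Z: float, n_quad: int = 4097) -> float:
    """mu1 recomputed from the first-order solvability integral.

    int (mu1 u0 - u0/Z + phi0/(P0 Z)) u0 dx = 0 with phi0 = u0 + x, so
    mu1 = int (u0/Z - phi0/(P0 Z)) u0 / int u0^2.
    """
    from scipy.integrate import simpson
    from .stationary_spectral import null_eigenvector
    g = Grid.uniform(n_quad)
    th = solve_P0(Z)
    u0 = null_eigenvector(Z, g)
    phi0 = u0.values + g.nodes
    num = simpson((u0.values / Z - phi0 / (th.P0 * Z)) * u0.values, x=g.nodes)
    den = simpson(u0.values ** 2, x=g.nodes)
    return float(num / den)


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def _wave_for(V: float, Z: float, source: str,
              branch_index: int = 1) -> TravelingWave:
    if source == "numeric":
        return numeric_TW(V, Z, branch_index=branch_index)
    if source == "asymptotic":
        return asymptotic_TW(V, Z, branch_index=branch_index)
    raise ParameterError("wave_source must be 'asymptotic' or 'numeric'")


def leading_eigenvalue(V: float, Z: float, N: int = 64,
                       wave_source: str = "asymptotic") -> complex:
    """Eigenvalue of the truncated T_C with the largest real part.

    Vanishes at V = 0 (the translation mode of the bifurcating family) and
    moves into the left half-plane like -(pi^2/24) V^2 at large viscosity.
    """
    tw = _wave_for(V, Z, wave_source)
    A = assemble_TC(tw, None, N).entries
    lam = _sort_eigs(np.linalg.eigvals(A))
    return complex(lam[0])


def spectrum_report(V: float, Z: float, N: int = 64,
                    wave_source: str = "asymptotic",
                    conv_tol: float = 1e-6) -> SpectrumReport:
    tw = _wave_for(V, Z, wave_source)
    op = assemble_TC(tw, None, N)
    lam = _sort_eigs(np.linalg.eigvals(op.entries))
    op2 = assemble_TC(tw, None, 2 * N)
    lam2 = _sort_eigs(np.linalg.eigvals(op2.entries))
    converged = bool(abs(lam2[0].real - lam[0].real) < conv_tol)
    return SpectrumReport(operator=op, eigenvalues=lam,
                          abscissa=float(lam[0].real),
                          symmetry_defect=op.symmetry_defect,
                          converged=converged)


# ---------------------------------------------------------------------------
# Gershgorin-type localization
# ---------------------------------------------------------------------------

def gershgorin_report(tw: TravelingWave, params: Optional[ModelParams] = None,
                      N: int = 64) -> GershgorinReport:
    """Row bounds of the shifted Gram matrix B = A - I.

    A is the un-normalized (halved) matrix <v_m, T_C v_n>/||v||^2-free Gram
    bookkeeping of the localization argument: entries are half the
    orthonormalized matrix.  The report evaluates each printed condition:
    negative unbounded diagonal, the row ratio bound Q_n/|b_nn| < rho with
    rho = (2 + 5 pi^2 + 4 pi^4)/(2 + 6 pi^2 + 4 pi^4), odd-row separation,
    boundedness, and the per-row certificate b_nn + Q_n < -1 that confines
    every eigenvalue but the first.
    """
    A = 0.5 * assemble_TC(tw, params, N).entries
    B = A - np.eye(N)
    diag = np.diag(B).copy()
    absB = np.abs(B)
    radii = absB.sum(axis=0) - np.abs(diag)
    ratios = radii / np.abs(diag)
    nn = np.arange(1, N + 1)
    odd = np.where(nn % 2 == 1)[0]
    sep = True
    for i in odd:
        for j in odd:
            if i < j and abs(diag[i] - diag[j]) < radii[i] + radii[j]:
                sep = False
    return GershgorinReport(
        diag=diag, radii=radii, ratios=ratios, rho=float(GERSHGORIN_RHO),
        cond_diag_negative=bool(np.all(diag < 0)),
        cond_ratio=bool(np.max(ratios) < GERSHGORIN_RHO),
        cond_separation=bool(sep),
        cond_bounded=bool(np.isfinite(absB).all()),
        rows_below_minus_one=(diag + radii < -1.0),
    )


# ---------------------------------------------------------------------------
# resolvent scan
# ---------------------------------------------------------------------------

def default_omega_grid(n_log: int = 30, n_lin: int = 41,
                       omega_max: float = 1e3,
                       omega_patch: float = 1.0) -> np.ndarray:
    """Symmetric logarithmic grid plus a fine linear patch near 0."""
    logs = np.geomspace(omega_patch, omega_max, n_log)
    lin = np.linspace(-omega_patch, omega_patch, n_lin)
    return np.unique(np.concatenate([-logs, lin, logs]))


def resolvent_scan(tw: TravelingWave, params: Optional[ModelParams] = None,
                   N: int = 64, omegas: Optional[np.ndarray] = None) -> ResolventScan:
    """||(i omega I - A_N)^{-1}||_2 = 1/sigma_min(i omega I - A_N) along i R.

    A uniformly bounded supremum (stable under doubling N) is the numerical
    shadow of the resolvent bound behind exponential semigroup decay; at
    V = 0 the zero translation eigenvalue sits on the axis and the norm at
    omega = 0 diverges with N instead.
    """
    omegas = default_omega_grid() if omegas is None else np.asarray(omegas, float)
    A = assemble_TC(tw, params, N).entries
    eye = np.eye(N)
    norms = np.empty(omegas.size)
    singular = np.zeros(omegas.size, dtype=bool)
    for i, om in enumerate(omegas):
        sv = np.linalg.svd(1j * om * eye - A, compute_uv=False)
        smin = sv[-1]
        if smin < 1e-14 * max(1.0, sv[0]):
            singular[i] = True
            norms[i] = np.inf
        else:
            norms[i] = 1.0 / smin
    finite = norms[np.isfinite(norms)]
    sup = float(np.max(finite)) if finite.size else float("inf")
    arg = float(omegas[int(np.nanargmax(np.where(np.isfinite(norms), norms, -1)))])
    return ResolventScan(omegas=omegas, norms=norms, supremum=sup,
                         argmax=arg, N=N, singular=singular)
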