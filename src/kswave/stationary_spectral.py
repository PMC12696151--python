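"""Linear stability of the resting cell: S_C, its matrix, and the threshold P0(Z).

The linearization of the model about the homogeneous state ``m = 1`` is

    S_C u = u'' - phi'',      -Z phi'' + phi = P u  (periodic),

a self-adjoint operator on zero-mean Neumann perturbations.  All of its
eigenvalues are negative for ``P`` below a threshold activity ``P0(Z)``,
the smallest positive nontrivial root of

    tanh(s) = P0 s,  s = sqrt(1 - P0)/(2 sqrt(Z))     (P0 < 1, Z < 1/12)
    tan(w)  = P0 w,  w = sqrt(P0 - 1)/(2 sqrt(Z))     (P0 > 1, Z > 1/12),

at which a branch of traveling waves bifurcates.  At Z = 1/12 the root
P0 = 1 is degenerate and no bifurcation occurs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core_model import (
    DegenerateThresholdError, Field, Grid, ModelParams, ParameterError,
    ZERO_MEAN_TOL, default_grid, solve_elliptic, _derivs_of,
)

__all__ = [
    "OperatorMatrix", "ThresholdResult", "apply_SC", "sc_matrix",
    "assemble_SC", "eigs_SC", "k1", "k2", "solve_P0", "null_eigenvector",
    "threshold_table",
]

DEGENERACY_GUARD = 1e-6       # refuse solve_P0 within this of Z = 1/12


@dataclass
class OperatorMatrix:
    """Truncated operator matrix in the orthonormalized basis sqrt(2) v_n.

    With this normalization matrix eigenvalues equal operator eigenvalues
    directly (the un-normalized Gram matrix of the v_n carries a factor 1/2).
    """

    entries: np.ndarray
    basis_size: int
    params: ModelParams
    V: float = 0.0
    kind: str = "SC"

    @property
    def symmetry_defect(self) -> float:
        return float(np.max(np.abs(self.entries - self.entries.T)))


@dataclass
class ThresholdResult:
    Z: float
    P0: float
    branch: str          # "tanh" | "tan"
    root: float          # v (tanh branch) or w (tan branch)
    residual: float      # bounded-form residual of the threshold equation
    branch_index: int = 1


# ---------------------------------------------------------------------------
# operator action and matrix
# ---------------------------------------------------------------------------

def apply_SC(u: Field, params: ModelParams) -> Field:
    """S_C u = u'' - phi'' for a zero-mean Neumann-compatible perturbation."""
    if abs(u.mass()) > ZERO_MEAN_TOL * max(1.0, float(np.max(np.abs(u.values)))):
        raise ParameterError("S_C acts on zero-mean perturbations")
    phi = solve_elliptic(u, params)
    _, d2u = _derivs_of(u)
    return Field(u.grid, d2u - phi.deriv2, bc="none")


def sc_matrix(P: float, Z: float, N: int) -> np.ndarray:
    """Closed-form matrix of S_C in the orthonormalized trig basis.

    Diagonal: -n^2 pi^2 + (P/Z)/(1 + 1/(n^2 pi^2 Z)); odd modes pick up the
    coupling generated by the periodicity correction of the elliptic solve,
    +- 4 P coth(1/(2 sqrt Z)) / (sqrt(Z)(1 + m^2 pi^2 Z)(1 + n^2 pi^2 Z)),
    positive on the diagonal (the sign that puts the leading eigenvalue at
    exactly zero when P = P0).  Even/odd cross terms vanish.
    """
    n = np.arange(1, N + 1)
    A = np.zeros((N, N))
    A[np.diag_indices(N)] = (-n ** 2 * np.pi ** 2
                             + (P / Z) / (1.0 + 1.0 / (np.pi ** 2 * n ** 2 * Z)))
    odd = n[n % 2 == 1]
    coth = 1.0 / np.tanh(0.5 / np.sqrt(Z))
    t = (-1.0) ** ((odd - 1) // 2) / (1.0 + odd ** 2 * np.pi ** 2 * Z)
    block = (4.0 * P * coth / np.sqrt(Z)) * np.outer(t, t)
    ii = odd - 1
    A[np.ix_(ii, ii)] += block
    return A


def assemble_SC(params: ModelParams, N: int = 64) -> OperatorMatrix:
    if N < 2:
        raise ParameterError("basis size must be >= 2")
    return OperatorMatrix(sc_matrix(params.P, params.Z, N), N, params, 0.0, "SC")


def eigs_SC(params: ModelParams, N: int = 64, converge: bool = True,
            tol: float = 1e-8, max_N: int = 512) -> np.ndarray:
    """Real eigenvalues of the truncated S_C, in descending order.

    With ``converge`` the truncation is doubled until the leading eigenvalue
    moves by less than ``tol``.
    """
    lam = np.linalg.eigvalsh(sc_matrix(params.P, params.Z, N))[::-1]
    while converge and 2 * N <= max_N:
        lam2 = np.linalg.eigvalsh(sc_matrix(params.P, params.Z, 2 * N))[::-1]
        if abs(lam2[0] - lam[0]) < tol:
            return lam2
        N *= 2
        lam = lam2
    return lam


# ---------------------------------------------------------------------------
# threshold equation
# ---------------------------------------------------------------------------

def k1(v):
    """(v - tanh v)/(4 v^3): monotone decreasing, 1/12 at 0+, -> 0 at infinity.

    Solving k1(v) = Z gives the tanh-branch threshold for Z < 1/12.  A Taylor
    branch avoids catastrophic cancellation for small arguments.
    """
    v = np.asarray(v, dtype=float)
    out = np.empty_like(v)
    small = np.abs(v) < 0.05
    vs = v[small]
    out[small] = (1.0 / 12 - vs ** 2 / 30 + 17 * vs ** 4 / 1260
                  - 62 * vs ** 6 / 11340)
    vb = v[~small]
    out[~small] = (vb - np.tanh(vb)) / (4 * vb ** 3)
    return out if out.ndim else float(out)


def k2(w):
    """(tan w - w)/(4 w^3): monotone increasing on (0, pi/2), 1/12 at 0+."""
    w = np.asarray(w, dtype=float)
    out = np.empty_like(w)
    small = np.abs(w) < 0.05
    ws = w[small]
    out[small] = (1.0 / 12 + ws ** 2 / 30 + 17 * ws ** 4 / 1260
                  + 62 * ws ** 6 / 11340)
    wb = w[~small]
    out[~small] = (np.tan(wb) - wb) / (4 * wb ** 3)
    return out if out.ndim else float(out)


def solve_P0(Z: float, branch_index: int = 1) -> ThresholdResult:
    """Threshold activity P0(Z): root of the transcendental equation.

    ``branch_index`` is odd: 1 selects the principal root (the bifurcation
    point of the stable wave family); 3, 5, ... select the higher roots
    (w in ((b-2) pi/2, b pi/2)), the bifurcation points of the higher,
    conjecturally unstable, traveling-wave families.

    The root is found on the monotone k1/k2 formulation, never on the raw
    equation near the double root P0 = 1.  The reported residual is that of
    the bounded form sin(w) - P0 w cos(w) (resp. tanh(v) - P0 v).
    """
    if Z <= 0:
        raise ParameterError("Z must be positive")
    if branch_index < 1 or branch_index % 2 == 0:
        raise ParameterError("branch_index must be an odd positive integer")
    if branch_index == 1:
        if abs(Z - 1.0 / 12) < DEGENERACY_GUARD:
            raise DegenerateThresholdError(
                "Z = 1/12: P0 = 1 is a degenerate root (no transversality); "
                "the principal branch is undefined here")
        if Z < 1.0 / 12:
            v = brentq(lambda t: k1(t) - Z, 1e-12, 60.0,
                       xtol=1e-15, rtol=8.9e-16)
            P0 = np.tanh(v) / v
            resid = np.tanh(v) - P0 * v
            return ThresholdResult(Z, float(P0), "tanh", float(v),
                                   float(abs(resid)), 1)
        lo, hi = 1e-12, np.pi / 2 * (1 - 1e-14)
    else:
        lo = (branch_index - 2) * np.pi / 2 * (1 + 1e-12) + 1e-9
        hi = branch_index * np.pi / 2 * (1 - 1e-12) - 1e-9
    w = brentq(lambda t: k2(t) - Z, lo, hi, xtol=1e-14, rtol=8.9e-16)
    P0 = 1.0 + 4.0 * Z * w ** 2
    resid = np.sin(w) - P0 * w * np.cos(w)
    return ThresholdResult(Z, float(P0), "tan", float(w), float(abs(resid)),
                           branch_index)


def threshold_residual(P0: float, Z: float) -> float:
    """Bounded-form residual of the threshold equation at arbitrary (P0, Z)."""
    if P0 > 1:
        w = np.sqrt(P0 - 1) / (2 * np.sqrt(Z))
        return float(np.sin(w) - P0 * w * np.cos(w))
    v = np.sqrt(1 - P0) / (2 * np.sqrt(Z))
    return float(np.tanh(v) - P0 * v)


# ---------------------------------------------------------------------------
# the neutral mode at threshold
# ---------------------------------------------------------------------------

def _ratio_sin(omega2: complex, x: np.ndarray, half: bool = True):
    """sin(omega x)/sin(omega/2) with omega = sqrt(omega2), real for both signs.

    For omega2 < 0 this continues to sinh(|omega| x)/sinh(|omega|/2).
    """
    om = complex(np.emath.sqrt(omega2))
    denom = np.sin(om / 2) if half else np.sin(om)
    return (np.sin(om * np.asarray(x, dtype=complex)) / denom).real


def null_eigenvector(Z: float, grid: Grid | None = None,
                     branch_index: int = 1) -> Field:
    """The odd, zero-mean neutral mode u0 of S_C at P = P0(Z).

    u0(x) = x/(P0-1) - (P0/(2(P0-1))) sin(omega x)/sin(omega/2), with
    omega = sqrt((P0-1)/Z); for P0 < 1 the trig form continues to the
    hyperbolic one.  Its endpoint derivative vanishes exactly because P0
    solves the threshold equation.
    """
    grid = grid or default_grid()
    th = solve_P0(Z, branch_index)
    P0 = th.P0
    om2 = (P0 - 1.0) / Z
    om = complex(np.emath.sqrt(om2))
    x = grid.nodes
    p1 = P0 - 1.0
    u = x / p1 - 0.5 * P0 / p1 * _ratio_sin(om2, x)
    csc = 1.0 / np.sin(om / 2)
    du = (1.0 / p1 - 0.5 * P0 / p1 * (csc * om * np.cos(om * np.asarray(x, complex))).real)
    d2u = (0.5 * P0 / p1 * (csc * om ** 2 * np.sin(om * np.asarray(x, complex))).real)
    return Field(grid, u, bc="neumann", deriv=du, deriv2=d2u)


# ---------------------------------------------------------------------------
# CLI table
# ---------------------------------------------------------------------------

def threshold_table(zmin: float, zmax: float, steps: int,
                    branch_index: int = 1) -> pd.DataFrame:
    zs = np.geomspace(zmin, zmax, steps)
    rows = []
    for Z in zs:
        th = solve_P0(float(Z), branch_index)
        rows.append({"Z": th.Z, "P0": th.P0, "branch": th.branch,
                     "residual": th.residual})
    return pd.DataFrame(rows)
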