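"""Grids, fields and the building blocks of the stiff-limit cell-motility model.

The model lives on the fixed, dimensionless cell body ``[-1/2, 1/2]``: a
myosin density ``m`` (zero-flux/Neumann ends, unit mass) drives a pressure
``phi`` through the screened-Poisson problem ``-Z phi'' + phi = P m`` with
periodic boundary conditions, and is advected in turn by the pressure
gradient in the frame co-moving with the cell center,

    dm/dt = F_C(m) = m'' + phi'(1/2) m' - (m phi')'.

``P`` measures motor activity, ``Z`` bulk viscosity.  Everything spectral in
this package is expressed in the mixed trigonometric basis

    v_n(x) = sin(n pi x)  (n odd),    cos(n pi x)  (n even),

which is exactly the zero-mean Neumann eigenbasis of d^2/dx^2 on the cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ModelParams", "Grid", "Field", "KswaveError", "ParameterError",
    "GridMismatchError", "ConvergenceError", "SingularityError",
    "DegenerateThresholdError", "MassContractWarning",
    "trig_mode", "trig_mode_deriv", "project", "synthesize",
    "inner_product", "l2_norm", "h1_norm", "mass",
    "solve_elliptic", "apply_FC", "endpoint_derivatives",
    "read_field_csv", "write_field_csv",
]

# ---------------------------------------------------------------------------
# configuration constants (package-wide defaults)
# ---------------------------------------------------------------------------

DEFAULT_GRID_SIZE = 257          # uniform grid nodes
DEFAULT_QUAD_SIZE = 513          # Chebyshev-Lobatto quadrature nodes
BC_TOL = 1e-6                    # boundary-condition validation tolerance
MASS_TOL = 1e-6                  # unit-mass contract tolerance for F_C input
ZERO_MEAN_TOL = 1e-8             # zero-mean contract for linearized operators


class KswaveError(Exception):
    """Base class for package errors."""


class ParameterError(KswaveError, ValueError):
    """Invalid model or numerical parameter."""


class GridMismatchError(KswaveError, ValueError):
    """Two fields do not share a grid."""


class ConvergenceError(KswaveError, RuntimeError):
    """An iterative solve failed; carries the last residual when known."""

    def __init__(self, msg, residual=None):
        super().__init__(msg)
        self.residual = residual


class SingularityError(KswaveError, ZeroDivisionError):
    """A printed closed form is evaluated at a vanishing denominator."""


class DegenerateThresholdError(ParameterError):
    """Z = 1/12: the threshold root P0 = 1 is degenerate (no transversality)."""


class MassContractWarning(UserWarning):
    """Input to F_C does not carry unit mass."""


@dataclass(frozen=True)
class ModelParams:
    """Dimensionless activity ``P`` and viscosity ``Z`` (both positive)."""

    P: float
    Z: float

    def __post_init__(self):
        if not (self.P > 0):
            raise ParameterError(f"activity P must be positive, got {self.P}")
        if not (self.Z > 0):
            raise ParameterError(f"viscosity Z must be positive, got {self.Z}")


# ---------------------------------------------------------------------------
# grids and quadrature
# ---------------------------------------------------------------------------

def _clenshaw_curtis_weights(n: int) -> np.ndarray:
    """Clenshaw-Curtis weights on [-1, 1] for n Chebyshev-Lobatto nodes."""
    if n < 3:
        raise ParameterError("need at least three quadrature nodes")
    N = n - 1                                   # number of intervals
    theta = np.pi * np.arange(n) / N
    w = np.zeros(n)
    ii = np.arange(1, N)
    v = np.ones(N - 1)
    if N % 2 == 0:
        w[0] = w[N] = 1.0 / (N ** 2 - 1)
        for k in range(1, N // 2):
            v -= 2.0 * np.cos(2 * k * theta[ii]) / (4 * k ** 2 - 1)
        v -= np.cos(N * theta[ii]) / (N ** 2 - 1)
    else:
        w[0] = w[N] = 1.0 / N ** 2
        for k in range(1, (N - 1) // 2 + 1):
            v -= 2.0 * np.cos(2 * k * theta[ii]) / (4 * k ** 2 - 1)
    w[ii] = 2.0 * v / N
    return w


@dataclass
class Grid:
    """Nodes spanning [-1/2, 1/2] with positive quadrature weights (sum 1)."""

    nodes: np.ndarray
    weights: np.ndarray
    kind: str = "uniform"

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.nodes.size < 4:
            raise ParameterError("grid needs at least 4 nodes")
        if not (np.all(np.diff(self.nodes) > 0)):
            raise ParameterError("grid nodes must be strictly increasing")
        if abs(self.nodes[0] + 0.5) > 1e-12 or abs(self.nodes[-1] - 0.5) > 1e-12:
            raise ParameterError("grid must span [-1/2, 1/2]")
        if np.any(self.weights <= 0) or abs(self.weights.sum() - 1.0) > 1e-12:
            raise ParameterError("quadrature weights must be positive and sum to 1")
        self._basis_cache: dict = {}

    @property
    def n(self) -> int:
        return self.nodes.size

    @classmethod
    def uniform(cls, n: int = DEFAULT_GRID_SIZE) -> "Grid":
        """Uniform grid with trapezoid weights.

        Trapezoid weights realize the DCT-I discrete orthogonality, so inner
        products of basis modes with indices below ``n - 1`` are exact.
        """
        x = np.linspace(-0.5, 0.5, n)
        h = 1.0 / (n - 1)
        w = np.full(n, h)
        w[0] = w[-1] = h / 2
        return cls(x, w, kind="uniform")

    @classmethod
    def collocation(cls, n: int = DEFAULT_QUAD_SIZE) -> "Grid":
        """Chebyshev-Lobatto nodes with Clenshaw-Curtis weights (spectral)."""
        m = n - 1
        x = -0.5 * np.cos(np.pi * np.arange(n) / m)
        x[0], x[-1] = -0.5, 0.5
        w = 0.5 * _clenshaw_curtis_weights(n)
        return cls(x, w, kind="collocation")

    # number of basis modes this grid can project reliably
    def max_modes(self) -> int:
        if self.kind == "uniform":
            return self.n - 2
        return (self.n - 1) // 2

    def basis(self, nmodes: int):
        """Cached (values, derivatives, 2nd derivatives) of v_1..v_nmodes."""
        key = int(nmodes)
        if key not in self._basis_cache:
            n = np.arange(1, nmodes + 1)
            V = np.empty((nmodes, self.n))
            dV = np.empty_like(V)
            for i, ni in enumerate(n):
                V[i] = trig_mode(ni, self.nodes)
                dV[i] = trig_mode_deriv(ni, self.nodes)
            d2V = -((n * np.pi) ** 2)[:, None] * V
            self._basis_cache[key] = (V, dV, d2V)
        return self._basis_cache[key]


_DEFAULT_GRID: Optional[Grid] = None


def default_grid() -> Grid:
    global _DEFAULT_GRID
    if _DEFAULT_GRID is None:
        _DEFAULT_GRID = Grid.uniform(DEFAULT_GRID_SIZE)
    return _DEFAULT_GRID


# ---------------------------------------------------------------------------
# trig basis
# ---------------------------------------------------------------------------

def trig_mode(n: int, x: np.ndarray) -> np.ndarray:
    """v_n(x): sin(n pi x) for odd n, cos(n pi x) for even n.

    Each v_n has zero mean and zero endpoint derivative; ||v_n||_{L2}^2 = 1/2.
    """
    if n < 1:
        raise ParameterError("mode index must be a positive integer")
    x = np.asarray(x, dtype=float)
    return np.sin(n * np.pi * x) if n % 2 else np.cos(n * np.pi * x)


def trig_mode_deriv(n: int, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if n % 2:
        return n * np.pi * np.cos(n * np.pi * x)
    return -n * np.pi * np.sin(n * np.pi * x)


# ---------------------------------------------------------------------------
# fields
# ---------------------------------------------------------------------------

def endpoint_derivatives(values: np.ndarray, nodes: np.ndarray):
    """One-sided 3-point endpoint derivative estimates (left, right)."""
    hl0 = nodes[1] - nodes[0]
    hl1 = nodes[2] - nodes[1]
    # non-uniform 3-point one-sided stencil
    left = (-(2 * hl0 + hl1) / (hl0 * (hl0 + hl1)) * values[0]
            + (hl0 + hl1) / (hl0 * hl1) * values[1]
            - hl0 / (hl1 * (hl0 + hl1)) * values[2])
    hr0 = nodes[-1] - nodes[-2]
    hr1 = nodes[-2] - nodes[-3]
    right = ((2 * hr0 + hr1) / (hr0 * (hr0 + hr1)) * values[-1]
             - (hr0 + hr1) / (hr0 * hr1) * values[-2]
             + hr0 / (hr1 * (hr0 + hr1)) * values[-3])
    return left, right


@dataclass
class Field:
    """Samples of a scalar field on a grid, with a boundary-condition tag.

    ``bc`` is one of ``"neumann"`` (zero endpoint derivative, e.g. myosin),
    ``"periodic"`` (matching value and derivative at +-1/2, e.g. pressure) or
    ``"none"``.  When analytic derivatives are known (synthesized fields,
    elliptic solves, traveling waves) they ride along in ``deriv``/``deriv2``
    so that downstream operators do not pay numerical-differentiation error.
    """

    grid: Grid
    values: np.ndarray
    bc: str = "none"
    deriv: Optional[np.ndarray] = None
    deriv2: Optional[np.ndarray] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.nodes.shape:
            raise GridMismatchError("values shape does not match grid")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("field values must be finite")
        if self.bc not in ("neumann", "periodic", "none"):
            raise ParameterError(f"unknown bc tag {self.bc!r}")

    # -- contracts ---------------------------------------------------------
    def validate_bc(self, tol: float = BC_TOL) -> bool:
        if self.bc == "none":
            return True
        if self.deriv is not None:
            dl, dr = self.deriv[0], self.deriv[-1]
        else:
            dl, dr = endpoint_derivatives(self.values, self.grid.nodes)
        scale = max(1.0, float(np.max(np.abs(self.values))))
        if self.bc == "neumann":
            return abs(dl) <= tol * scale and abs(dr) <= tol * scale
        return (abs(self.values[0] - self.values[-1]) <= tol * scale
                and abs(dl - dr) <= tol * scale)

    # -- convenience -------------------------------------------------------
    def mass(self) -> float:
        return float(self.grid.weights @ self.values)

    def copy(self) -> "Field":
        return Field(self.grid, self.values.copy(), self.bc,
                     None if self.deriv is None else self.deriv.copy(),
                     None if self.deriv2 is None else self.deriv2.copy())


def _check_same_grid(u: Field, v: Field):
    if u.grid is not v.grid and not (
            u.grid.n == v.grid.n and np.array_equal(u.grid.nodes, v.grid.nodes)):
        raise GridMismatchError("fields live on different grids")


def inner_product(u: Field, v: Field) -> float:
    """Quadrature L2 inner product on the shared grid."""
    _check_same_grid(u, v)
    return float(np.sum(u.grid.weights * u.values * v.values))


def l2_norm(u: Field) -> float:
    return float(np.sqrt(np.sum(u.grid.weights * u.values ** 2)))


def mass(u: Field) -> float:
    return u.mass()


def h1_norm(u: Field) -> float:
    """sqrt(||u||^2 + ||u'||^2); uses analytic derivative when available."""
    du = u.deriv if u.deriv is not None else field_derivative(u)[0]
    return float(np.sqrt(np.sum(u.grid.weights * (u.values ** 2 + du ** 2))))


# ---------------------------------------------------------------------------
# projection / synthesis
# ---------------------------------------------------------------------------

def project(u: Field, nmodes: int) -> np.ndarray:
    """Coefficients of ``u`` in the orthonormalized basis sqrt(2) v_n.

    The round trip ``synthesize(project(u, N))`` converges in L2 for smooth
    zero-mean Neumann fields as N grows.
    """
    if nmodes < 1:
        raise ParameterError("nmodes must be >= 1")
    V, _, _ = u.grid.basis(nmodes)
    return np.sqrt(2.0) * (V * u.grid.weights) @ u.values


def synthesize(coeffs: np.ndarray, grid: Optional[Grid] = None,
               mean: float = 0.0, bc: str = "neumann") -> Field:
    """Field ``mean + sum_n c_n sqrt(2) v_n`` with exact derivative arrays."""
    grid = grid or default_grid()
    coeffs = np.asarray(coeffs, dtype=float)
    V, dV, d2V = grid.basis(coeffs.size)
    s = np.sqrt(2.0)
    vals = mean + s * coeffs @ V
    return Field(grid, vals, bc=bc, deriv=s * coeffs @ dV, deriv2=s * coeffs @ d2V)


def field_derivative(u: Field, nmodes: Optional[int] = None):
    """(u', u'') by differentiating the truncated basis expansion of u - mean.

    Appropriate for Neumann-compatible fields; fields carrying analytic
    ``deriv``/``deriv2`` attributes should be preferred when present.
    """
    nmodes = nmodes or u.grid.max_modes()
    c = project(u, nmodes)
    _, dV, d2V = u.grid.basis(nmodes)
    s = np.sqrt(2.0)
    return s * c @ dV, s * c @ d2V


def _derivs_of(u: Field, nmodes: Optional[int] = None):
    if u.deriv is not None and u.deriv2 is not None:
        return u.deriv, u.deriv2
    return field_derivative(u, nmodes)


# ---------------------------------------------------------------------------
# elliptic pressure solve
# ---------------------------------------------------------------------------

def elliptic_mode_response(n: int, params: ModelParams, x: np.ndarray):
    """Exact periodic solve of -Z phi'' + phi = P v_n for a single mode.

    Even modes are eigenfunctions: phi = P v_n / (1 + n^2 pi^2 Z).  Odd modes
    additionally need a sinh-type homogeneous correction to restore value
    periodicity (their particular solution jumps across +-1/2); this
    correction is the origin of the odd-odd coupling in the operator matrix.

    Returns (phi, phi', phi'(1/2)).
    """
    P, Z = params.P, params.Z
    amp = P / (1.0 + n ** 2 * np.pi ** 2 * Z)
    v = trig_mode(n, x)
    dv = trig_mode_deriv(n, x)
    phi = amp * v
    dphi = amp * dv
    dphi_half = 0.0
    if n % 2:
        b = 1.0 / np.sqrt(Z)
        s = np.sin(n * np.pi / 2)            # +-1
        B = -amp * s / np.sinh(b / 2)
        phi = phi + B * np.sinh(b * x)
        dphi = dphi + B * b * np.cosh(b * x)
        dphi_half = B * b * np.cosh(b / 2)
    return phi, dphi, dphi_half


def solve_elliptic(m: Field, params: ModelParams, nmodes: Optional[int] = None) -> Field:
    """Pressure phi solving -Z phi'' + phi = P m with periodic conditions.

    The zero-mean part of ``m`` is expanded in the trig basis (each mode is
    damped by 1/(1 + n^2 pi^2 Z)); a sinh-type homogeneous correction enforces
    value periodicity, and mean(phi) = P mean(m).  The returned field carries
    analytic first and second derivatives (the latter from the ODE itself).
    """
    P, Z = params.P, params.Z
    grid = m.grid
    nmodes = nmodes or grid.max_modes()
    c = project(m, nmodes)                  # orthonormal-basis coefficients
    mbar = m.mass()
    n = np.arange(1, nmodes + 1)
    amp = P * c / (1.0 + n ** 2 * np.pi ** 2 * Z)
    V, dV, _ = grid.basis(nmodes)
    s = np.sqrt(2.0)
    phi = P * mbar + s * amp @ V
    dphi = s * amp @ dV
    # periodicity correction: particular parts of odd modes jump across +-1/2
    odd = n % 2 == 1
    if np.any(odd):
        b = 1.0 / np.sqrt(Z)
        jump = np.sum(amp[odd] * np.sin(n[odd] * np.pi / 2))
        B = -s * jump / np.sinh(b / 2)
        phi = phi + B * np.sinh(b * grid.nodes)
        dphi = dphi + B * b * np.cosh(b * grid.nodes)
    d2phi = (phi - P * m.values) / Z
    return Field(grid, phi, bc="periodic", deriv=dphi, deriv2=d2phi)


# ---------------------------------------------------------------------------
# the nonlinear evolution operator
# ---------------------------------------------------------------------------

def apply_FC(m: Field, params: ModelParams, check_mass: bool = True) -> Field:
    """Right-hand side F_C(m) = m'' + phi'(1/2) m' - (m phi')'.

    The integral of F_C vanishes identically (the frame term's boundary flux
    cancels against the Keller-Segel flux because phi' is periodic and
    m'(+-1/2) = 0); discretely this holds to quadrature accuracy.
    """
    if check_mass and abs(m.mass() - 1.0) > MASS_TOL:
        warnings.warn(
            f"F_C input has mass {m.mass():.8f} != 1", MassContractWarning)
    phi = solve_elliptic(m, params)
    dm, d2m = _derivs_of(m)
    out = d2m + phi.deriv[-1] * dm - (dm * phi.deriv + m.values * phi.deriv2)
    return Field(m.grid, out, bc="none")


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def write_field_csv(u: Field, path) -> None:
    pd.DataFrame({"x": u.grid.nodes, "value": u.values}).to_csv(path, index=False)


def read_field_csv(path, bc: str = "none") -> Field:
    df = pd.read_csv(path)
    if not {"x", "value"} <= set(df.columns):
        raise ParameterError("field CSV needs columns 'x,value'")
    x = df["x"].to_numpy(float)
    n = x.size
    if np.allclose(np.diff(x), x[1] - x[0], rtol=1e-8):
        grid = Grid.uniform(n)
    else:
        grid = Grid.collocation(n)
    if not np.allclose(grid.nodes, x, atol=1e-9):
        raise ParameterError("field CSV nodes are neither uniform nor "
                             "Chebyshev-Lobatto on [-1/2, 1/2]")
    return Field(grid, df["value"].to_numpy(float), bc=bc)
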