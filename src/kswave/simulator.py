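"""Time integration of the co-moving model and stability measurement.

Two complementary schemes integrate ``dm/dt = F_C(m)``:

* ``"imex"`` (default): finite-volume fluxes on the uniform grid with
  Crank-Nicolson for the stiff diffusion and an explicit, centrally averaged
  conservative advective flux.  The frame term ``phi'(1/2) m'`` enters the
  same interface flux as the Keller-Segel term, and the boundary fluxes
  vanish identically (``m' = 0`` and periodicity of ``phi'``), so the
  discrete mass is conserved to solver round-off each step.
* ``"exponential"``: a trig-basis Galerkin truncation whose linear part
  (the resting-state operator) is advanced exactly through its
  eigendecomposition, with the quadratic part handled by exponential Euler.
  The constant mode is excluded from the basis, so mass conservation is
  structural.  This scheme reproduces the linear semigroup to round-off and
  is the cheap choice for slow near-threshold dynamics.

Fitting ``log ||m(t) - reference||`` over the late window of a run recovers
the decay (or growth) rate, which is compared against spectral predictions;
integrating ``phi'(1/2, t)`` reconstructs the cell-center track of the
stiff-limit model before the co-moving change of frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.linalg import solve_banded

from .core_model import (
    Field, Grid, ModelParams, ParameterError, default_grid, project,
    synthesize, solve_elliptic, _derivs_of,
)
from .stationary_spectral import null_eigenvector, sc_matrix
from .traveling_waves import TravelingWave

__all__ = [
    "Trajectory", "CenterTrack", "DecayFit", "CFLError", "step", "simulate",
    "psi", "decay_rate", "reconstruct_center", "perturbation_fixture",
    "refine_equilibrium",
]

DEFAULT_SEED = 12345
BLOWUP_FACTOR = 1e3
ELLIPTIC_MODES = 128          # modal resolution of the in-step pressure solve


class CFLError(ParameterError):
    """Advective CFL violated; carries a suggested time step."""

    def __init__(self, dt, dt_max):
        super().__init__(
            f"dt = {dt:g} violates the advective CFL limit; use dt <= {dt_max:g}")
        self.suggested_dt = dt_max


@dataclass
class Trajectory:
    times: np.ndarray
    l2: np.ndarray                  # ||m(t) - reference||_L2
    h1: np.ndarray                  # ||m(t) - reference||_H1
    mass: np.ndarray
    phip_half: Optional[np.ndarray]
    snap_times: Optional[np.ndarray]
    snapshots: Optional[np.ndarray]     # (n_snap, n_nodes)
    params: ModelParams
    dt: float
    scheme: str
    grid: Grid
    reference: np.ndarray
    blew_up: bool = False


@dataclass
class CenterTrack:
    times: np.ndarray
    c: np.ndarray


@dataclass
class DecayFit:
    rate: float          # positive = decay, negative = growth
    residual: float      # rms residual of the log-linear fit
    monotone: bool       # log-norm monotone over the window


# ---------------------------------------------------------------------------
# IMEX finite-volume stepper
# ---------------------------------------------------------------------------

class _ImexStepper:
    """Caches grid geometry, basis synthesis at interfaces, and CN bands."""

    def __init__(self, grid: Grid, params: ModelParams, dt: float,
                 nmodes: int = ELLIPTIC_MODES):
        if grid.kind != "uniform":
            raise ParameterError("the IMEX scheme runs on a uniform grid")
        self.grid = grid
        self.params = params
        self.dt = dt
        n = grid.n
        self.h = grid.nodes[1] - grid.nodes[0]
        self.w = grid.weights
        self.nmodes = min(nmodes, grid.max_modes())
        self.mid = 0.5 * (grid.nodes[:-1] + grid.nodes[1:])
        k = np.arange(1, self.nmodes + 1)
        from .core_model import trig_mode_deriv
        self.dV_mid = np.vstack([trig_mode_deriv(int(ki), self.mid) for ki in k])
        self.mode_gain = params.P / (1.0 + k ** 2 * np.pi ** 2 * params.Z)
        self.odd = k % 2 == 1
        self.sin_half = np.sin(k[self.odd] * np.pi / 2)
        b = 1.0 / np.sqrt(params.Z)
        self.b = b
        self.cosh_mid = b * np.cosh(b * self.mid)
        self.cosh_half = b * np.cosh(b / 2)
        self.sinh_half = np.sinh(b / 2)
        # Crank-Nicolson bands for the diffusion operator in flux form
        L = np.zeros((3, n))
        hh = self.h
        # interior rows: (m_{j+1} - 2 m_j + m_{j-1})/h^2 ; boundary: half cells
        main = np.full(n, -2.0 / hh ** 2)
        off = np.full(n - 1, 1.0 / hh ** 2)
        main[0] = main[-1] = -2.0 / hh ** 2
        # flux form with zero boundary flux: row 0: (m_1 - m_0)/h / (h/2)
        main[0] = -2.0 / hh ** 2
        self._L_main, self._L_off = main, off
        # w-weighted: row j divides by w_j; build explicit dense action lazily
        self.A_main = main.copy()
        self.A_off_up = off.copy()
        self.A_off_lo = off.copy()
        # boundary rows use half weights: L m|_0 = ((m1-m0)/h - 0)/ (h/2)
        self.A_main[0] = -2.0 / hh ** 2
        self.A_off_up[0] = 2.0 / hh ** 2
        self.A_main[-1] = -2.0 / hh ** 2
        self.A_off_lo[-1] = 2.0 / hh ** 2
        ab = np.zeros((3, n))
        ab[0, 1:] = -0.5 * dt * self.A_off_up
        ab[1, :] = 1.0 - 0.5 * dt * self.A_main
        ab[2, :-1] = -0.5 * dt * self.A_off_lo
        self._cn_band = ab

    def laplacian(self, m: np.ndarray) -> np.ndarray:
        out = np.empty_like(m)
        out[1:-1] = (m[2:] - 2 * m[1:-1] + m[:-2]) / self.h ** 2
        out[0] = 2.0 * (m[1] - m[0]) / self.h ** 2
        out[-1] = 2.0 * (m[-2] - m[-1]) / self.h ** 2
        return out

    def dphi(self, m: np.ndarray):
        """phi' at interfaces and at x = 1/2, from the modal elliptic solve."""
        c = np.sqrt(2.0) * (self.grid.basis(self.nmodes)[0] * self.w) @ m
        a = self.mode_gain * c
        dmid = np.sqrt(2.0) * a @ self.dV_mid
        dhalf = 0.0
        if np.any(self.odd):
            jump = np.sum(a[self.odd] * self.sin_half)
            B = -np.sqrt(2.0) * jump / self.sinh_half
            dmid = dmid + B * self.cosh_mid
            dhalf = B * self.cosh_half
        return dmid, dhalf

    def advection(self, m: np.ndarray):
        dmid, dhalf = self.dphi(m)
        a_if = dhalf - dmid
        flux = a_if * 0.5 * (m[:-1] + m[1:])
        out = np.empty_like(m)
        out[0] = flux[0] / self.w[0]
        out[1:-1] = (flux[1:] - flux[:-1]) / self.w[1:-1]
        out[-1] = -flux[-1] / self.w[-1]
        return out, float(np.max(np.abs(a_if))), dhalf

    def cfl_dt(self, amax: float) -> float:
        return 0.5 * self.h / max(amax, 1e-300)

    def step(self, m: np.ndarray, enforce_cfl: bool = True):
        adv, amax, dhalf = self.advection(m)
        if enforce_cfl and self.dt > self.cfl_dt(amax):
            raise CFLError(self.dt, self.cfl_dt(amax))
        rhs = m + 0.5 * self.dt * self.laplacian(m) + self.dt * adv
        return solve_banded((1, 1), self._cn_band, rhs), dhalf


def step(m: Field, dt: float, params: ModelParams) -> Field:
    """A single IMEX step; ``m = 1`` is an exact fixed point."""
    if dt <= 0:
        raise ParameterError("dt must be positive")
    st = _ImexStepper(m.grid, params, dt)
    vals, _ = st.step(m.values)
    return Field(m.grid, vals, bc="neumann")


# ---------------------------------------------------------------------------
# the quadratic part
# ---------------------------------------------------------------------------

def psi(u: Field, params: ModelParams) -> Field:
    """Psi(u) = phi'(1/2) u' - (u phi')': the quadratic remainder of F_C.

    Satisfies F_C(1 + u) = S_C u + Psi(u) exactly, is quadratically
    homogeneous, and is bounded by C (P/Z) ||u||_L2 ||u||_H1.
    """
    phi = solve_elliptic(u, params)
    du, _ = _derivs_of(u)
    out = phi.deriv[-1] * du - (du * phi.deriv + u.values * phi.deriv2)
    return Field(u.grid, out, bc="none")


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def _reference_values(reference, grid: Grid) -> np.ndarray:
    if reference is None or (isinstance(reference, str) and reference == "stationary"):
        return np.ones(grid.n)
    if isinstance(reference, TravelingWave):
        if reference.m.grid.n != grid.n:
            return reference.evaluate(grid.nodes)["m"]
        return reference.m.values
    if isinstance(reference, Field):
        return reference.values
    raise ParameterError("reference must be None, 'stationary', a Field or a "
                         "TravelingWave")


def _u_norms(u: np.ndarray, grid: Grid, nmodes: int):
    c = np.sqrt(2.0) * (grid.basis(nmodes)[0] * grid.weights) @ (u - u.mean())
    l2 = float(np.sqrt(np.sum(grid.weights * u ** 2)))
    k = np.arange(1, nmodes + 1)
    du_sq = float(np.sum((k * np.pi * c) ** 2))
    return l2, float(np.sqrt(l2 ** 2 + du_sq))


def simulate(m0: Field, params: ModelParams, T: float, dt: float,
             reference=None, scheme: str = "imex", n_modes: int = 64,
             store_fields: bool = True, snap_count: int = 200) -> Trajectory:
    """Integrate the model from ``m0`` and record norms against a reference.

    Norms are stored every step, snapshots (and the pressure-gradient series
    used for center reconstruction) are thinned to about ``snap_count``.
    Stops early when the perturbation norm exceeds 1000x its initial value.
    """
    if abs(m0.mass() - 1.0) > 1e-6:
        raise ParameterError("initial condition must have unit mass")
    grid = m0.grid
    nsteps = int(round(T / dt))
    ref = _reference_values(reference, grid)
    stride = max(1, nsteps // snap_count)

    times = np.empty(nsteps + 1)
    l2 = np.empty(nsteps + 1)
    h1 = np.empty(nsteps + 1)
    ms = np.empty(nsteps + 1)
    phip = np.empty(nsteps + 1) if store_fields else None
    snaps, snap_t = ([], []) if store_fields else (None, None)

    norm_modes = min(n_modes, grid.max_modes())

    if scheme == "imex":
        st = _ImexStepper(grid, params, dt)
        m = m0.values.copy()

        def current_phip(mv):
            _, _, dhalf = st.advection(mv)
            return dhalf

        advance = st.step
    elif scheme == "exponential":
        K = min(n_modes, grid.max_modes())
        M = sc_matrix(params.P, params.Z, K)
        lam, Q = np.linalg.eigh(M)
        E = np.exp(lam * dt)
        phi1 = np.where(np.abs(lam * dt) > 1e-12,
                        (E - 1.0) / np.where(lam == 0, 1.0, lam),
                        dt * (1.0 + lam * dt / 2))
        m = m0.values.copy()

        def advance(mv, enforce_cfl=True):
            u = Field(grid, mv - 1.0)
            c = project(u, K)
            nl = project(psi(Field(grid, mv - 1.0), params), K)
            c_new = Q @ (E * (Q.T @ c) + phi1 * (Q.T @ nl))
            f = synthesize(c_new, grid)
            return 1.0 + f.values, solve_elliptic(Field(grid, mv), params).deriv[-1]

        def current_phip(mv):
            return solve_elliptic(Field(grid, mv), params).deriv[-1]
    else:
        raise ParameterError(f"unknown scheme {scheme!r}")

    u = m - ref
    l2[0], h1[0] = _u_norms(u, grid, norm_modes)
    times[0] = 0.0
    ms[0] = float(grid.weights @ m)
    if store_fields:
        phip[0] = current_phip(m)
        snaps.append(m.copy())
        snap_t.append(0.0)
    blew_up = False
    k = 0
    for k in range(1, nsteps + 1):
        m, dhalf = advance(m)
        times[k] = k * dt
        ms[k] = float(grid.weights @ m)
        u = m - ref
        l2[k], h1[k] = _u_norms(u, grid, norm_modes)
        if store_fields:
            phip[k] = dhalf
            if k % stride == 0 or k == nsteps:
                snaps.append(m.copy())
                snap_t.append(k * dt)
        if l2[k] > max(BLOWUP_FACTOR * l2[0], 1.0):
            blew_up = True
            break
    end = k + 1
    return Trajectory(
        times=times[:end], l2=l2[:end], h1=h1[:end], mass=ms[:end],
        phip_half=None if phip is None else phip[:end],
        snap_times=None if snap_t is None else np.asarray(snap_t),
        snapshots=None if snaps is None else np.asarray(snaps),
        params=params, dt=dt, scheme=scheme, grid=grid, reference=ref,
        blew_up=blew_up)


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------

def decay_rate(traj: Trajectory, window: Optional[tuple] = None) -> DecayFit:
    """Least-squares slope of log ||u(t)||_L2; positive rate means decay.

    The window defaults to the last half of the run, past the nonlinear
    (Duhamel) transient.
    """
    t, y = traj.times, traj.l2
    if window is None:
        window = (traj.times[-1] / 2.0, traj.times[-1])
    lo, hi = window
    sel = (t >= lo) & (t <= hi) & (y > 0)
    if sel.sum() < 2:
        raise ParameterError("decay window contains fewer than two samples")
    ts, ls = t[sel], np.log(y[sel])
    coef = np.polyfit(ts, ls, 1)
    resid = float(np.sqrt(np.mean((np.polyval(coef, ts) - ls) ** 2)))
    monotone = bool(np.all(np.diff(ls) <= 1e-12) or np.all(np.diff(ls) >= -1e-12))
    return DecayFit(rate=float(-coef[0]), residual=resid, monotone=monotone)


def reconstruct_center(traj: Trajectory) -> CenterTrack:
    """Cell-center track c(t) = int_0^t phi'(1/2, s) ds (trapezoid).

    Undoes the co-moving change of frame: for a traveling-wave initial state
    c(t) tracks V t; for the resting state it stays at 0.
    """
    if traj.phip_half is None:
        raise ParameterError("norm-only trajectory: center reconstruction "
                             "needs a run with store_fields=True")
    t, p = traj.times, traj.phip_half
    c = np.concatenate([[0.0], np.cumsum(0.5 * (p[1:] + p[:-1]) * np.diff(t))])
    return CenterTrack(times=t, c=c)


# ---------------------------------------------------------------------------
# seeded perturbation fixtures
# ---------------------------------------------------------------------------

def perturbation_fixture(kind: str, amplitude: float, seed: int = DEFAULT_SEED,
                         grid: Optional[Grid] = None, mode: int = 2,
                         n_modes: int = 8, Z: Optional[float] = None) -> Field:
    """Deterministic zero-mean Neumann perturbations of prescribed L2 norm.

    kinds: ``single_mode`` (one trig mode), ``random_trig`` (seeded random
    weights over the first ``n_modes`` modes), ``null_mode`` (the neutral
    threshold mode u0 at viscosity Z, projected onto the basis).
    """
    if amplitude <= 0:
        raise ParameterError("amplitude must be positive")
    grid = grid or default_grid()
    if kind == "single_mode":
        c = np.zeros(mode)
        c[mode - 1] = 1.0
    elif kind == "random_trig":
        rng = np.random.default_rng(seed)
        c = rng.standard_normal(n_modes)
    elif kind == "null_mode":
        if Z is None:
            raise ParameterError("null_mode fixture needs the viscosity Z")
        u0 = null_eigenvector(Z, grid)
        c = project(u0, min(64, grid.max_modes()))
    else:
        raise ParameterError(f"unknown fixture kind {kind!r}")
    c = amplitude * c / np.linalg.norm(c)
    return synthesize(c, grid)


# ---------------------------------------------------------------------------
# discrete equilibria (for decay-rate comparisons against spectra)
# ---------------------------------------------------------------------------

def refine_equilibrium(m_guess: Field, params: ModelParams,
                       n_modes: int = 48, tol: float = 1e-11,
                       max_iter: int = 30) -> Field:
    """Newton-polish a steady state of the modal Galerkin system.

    Solves M c + N(c) = 0 (M the resting-state matrix, N the projected
    quadratic part) starting from the projection of ``m_guess``; used to
    remove the O(truncation) drift of an interpolated traveling wave before
    measuring decay rates against the spectral abscissa.
    """
    grid = m_guess.grid
    K = min(n_modes, grid.max_modes())
    M = sc_matrix(params.P, params.Z, K)

    def G(c):
        f = synthesize(c, grid)
        return M @ c + project(psi(f, params), K)

    c = project(Field(grid, m_guess.values - 1.0), K)
    for _ in range(max_iter):
        g = G(c)
        if np.linalg.norm(g) < tol:
            break
        # finite-difference Jacobian of the quadratic part
        J = M.copy()
        h = 1e-7 * max(1.0, np.linalg.norm(c))
        for j in range(K):
            e = np.zeros(K)
            e[j] = h
            J[:, j] += (G(c + e) - G(c - e)) / (2 * h) - M[:, j]
        c = c - np.linalg.solve(J, g)
    else:
        from .core_model import ConvergenceError
        raise ConvergenceError("equilibrium refinement did not converge",
                               residual=float(np.linalg.norm(G(c))))
    f = synthesize(c, grid)
    return Field(grid, 1.0 + f.values, bc="neumann",
                 deriv=f.deriv, deriv2=f.deriv2)
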