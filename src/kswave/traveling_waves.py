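"""Traveling-wave solutions: small-velocity closed forms and an exact BVP solver.

A cell translating steadily with velocity ``V`` corresponds to a stationary
profile of the co-moving model satisfying

    m_TW = Lambda e^{phi_TW - V x},
    -Z phi_TW'' + phi_TW = P(V) Lambda e^{phi_TW - V x},
    phi_TW(-1/2) = phi_TW(1/2),   phi_TW'(+-1/2) = V,   int m_TW = 1.

The activity ``P = P_TW(V)`` is selected by the third boundary condition and
the waves bifurcate from the resting state at ``P_TW(0) = P0(Z)`` in a
pitchfork: ``P_TW(V) = P0 + V^2 P2 + O(V^4)``, ``m_TW = 1 + V m1 + V^2 m2 +
O(V^3)``, with every coefficient available in closed form.  All closed forms
are written with the complex-safe frequency ``omega = sqrt((P0-1)/Z)`` so the
``P0 < 1`` (small-viscosity) branch continues automatically to hyperbolic
functions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.integrate import simpson, solve_bvp

from .core_model import (
    ConvergenceError, Field, Grid, ModelParams, ParameterError,
    SingularityError, default_grid, l2_norm, apply_FC,
)
from .stationary_spectral import solve_P0

__all__ = [
    "TravelingWave", "AsymptoticCoefficients", "asymptotic_coefficients",
    "asymptotic_TW", "P2_closed_form", "P2_solvability", "lambda2_scaled",
    "lambda2_scaled_mass_route", "numeric_TW", "tw_family",
]

V_SOFT_LIMIT = 0.2        # warn above this velocity (asymptotics degrade)
V_HARD_LIMIT = 0.5        # refuse asymptotic construction above this


# ---------------------------------------------------------------------------
# closed-form expansion coefficients
# ---------------------------------------------------------------------------

@dataclass
class AsymptoticCoefficients:
    """All printed small-V expansion coefficients at a given viscosity Z.

    Scalars named after the expansion: P0, P2, the m2 shape constants A..F,
    the phi2 shape constants a0..d0, and ``lam2_scaled`` = e^{P0} Lambda2
    (kept in scaled form because e^{-P0} underflows at large Z).  Field
    callables are vectorized in x and real-valued on both threshold branches.
    """

    Z: float
    P0: float
    P2: float
    A: complex; B: complex; C: complex; D: complex; E: complex; F: complex
    a0: complex; a2: complex; b0: complex; b2: complex; c1: complex; d0: complex
    lam2_scaled: float
    _om: complex = 0.0
    _csc: complex = 0.0

    # -- order V fields ----------------------------------------------------
    def phi1(self, x):
        x = np.asarray(x, dtype=complex)
        p1 = self.P0 - 1.0
        return (self.P0 * x / p1
                - 0.5 * self.P0 / p1 * self._csc * np.sin(self._om * x)).real

    def dphi1(self, x):
        x = np.asarray(x, dtype=complex)
        p1 = self.P0 - 1.0
        return (self.P0 / p1
                - 0.5 * self.P0 / p1 * self._csc * self._om * np.cos(self._om * x)).real

    def d2phi1(self, x):
        x = np.asarray(x, dtype=float)
        return ((1.0 - self.P0) * self.phi1(x) + self.P0 * x) / self.Z

    def m1(self, x):
        return self.phi1(x) - np.asarray(x, dtype=float)

    def dm1(self, x):
        return self.dphi1(x) - 1.0

    def d2m1(self, x):
        return self.d2phi1(x)

    # -- order V^2 fields --------------------------------------------------
    def m2(self, x):
        x = np.asarray(x, dtype=complex)
        om = self._om
        return (self.A + self.B * x ** 2 + (self.C + self.D * x ** 2) * np.cos(om * x)
                + self.E * x * np.sin(om * x) + self.F * np.cos(2 * om * x)).real

    def phi2t(self, x):
        """phi2 - P2 (the P2-independent shape of the second-order pressure)."""
        x = np.asarray(x, dtype=complex)
        om = self._om
        return (self.a0 + self.a2 * x ** 2
                + (self.b0 + self.b2 * x ** 2) * np.cos(om * x)
                + self.c1 * x * np.sin(om * x) + self.d0 * np.cos(2 * om * x)).real

    def phi2(self, x):
        return self.P2 + self.phi2t(x)

    def dphi2(self, x):
        x = np.asarray(x, dtype=complex)
        om = self._om
        return (2 * self.a2 * x + 2 * self.b2 * x * np.cos(om * x)
                - om * (self.b0 + self.b2 * x ** 2) * np.sin(om * x)
                + self.c1 * np.sin(om * x) + self.c1 * om * x * np.cos(om * x)
                - 2 * om * self.d0 * np.sin(2 * om * x)).real

    def d2phi2(self, x):
        # from the second-order equation -Z phi2'' + (1-P0) phi2 = R2
        x = np.asarray(x, dtype=float)
        R2 = (self.P2 + self.P0 * self.lam2_scaled
              + 0.5 * self.P0 * self.m1(x) ** 2)
        return ((1.0 - self.P0) * self.phi2(x) - R2) / self.Z

    def dm2(self, x):
        x = np.asarray(x, dtype=float)
        f1, df1 = self.phi1(x), self.dphi1(x)
        return x - f1 - x * df1 + f1 * df1 + self.dphi2(x)

    def d2m2(self, x):
        x = np.asarray(x, dtype=float)
        f1, df1, d2f1 = self.phi1(x), self.dphi1(x), self.d2phi1(x)
        return 1.0 - 2 * df1 - x * d2f1 + df1 ** 2 + f1 * d2f1 + self.d2phi2(x)


def asymptotic_coefficients(Z: float, branch_index: int = 1) -> AsymptoticCoefficients:
    th = solve_P0(Z, branch_index)
    P0 = th.P0
    if abs(P0 ** 2 - 12 * Z) < 1e-10 * max(P0 ** 2, 12 * Z):
        raise SingularityError(
            "P0^2 = 12 Z: the printed P2 denominator vanishes at this Z")
    p1 = P0 - 1.0
    om = complex(np.emath.sqrt((P0 - 1.0) / Z))
    csc = 1.0 / np.sin(om / 2)
    sq = complex(np.emath.sqrt((P0 ** 3 - P0 ** 2 + 4 * Z) / Z))
    sqz = complex(np.emath.sqrt(P0 ** 3 - P0 ** 2 + 4 * Z))
    p1_35 = complex(np.emath.power(p1, 3.5))
    P2 = P0 * (6 * P0 ** 6 - 15 * P0 ** 5 - 3 * P0 ** 4 * (56 * Z - 5)
               + P0 ** 3 * (514 * Z - 6) - 1044 * P0 ** 2 * Z
               + 72 * P0 * Z * (55 * Z - 1) + 5280 * Z ** 2) / (
                   288 * p1 ** 4 * (P0 ** 2 - 12 * Z))
    q = (3 * P0 ** 2 - 60 * Z + 2) / (48 * p1 ** 2)
    coeff = AsymptoticCoefficients(
        Z=Z, P0=P0, P2=float(P2),
        A=(-6 * P0 * Z + P0 + 24 * Z - 1) / (24 * p1 ** 4),
        B=(12 - 12 * P0) / (24 * p1 ** 4),
        C=(P0 * (28 * Z - 3) + 3 * P0 ** 2 - 60 * Z) * sq / (96 * p1 ** 4),
        D=-P0 * sq / (8 * p1 ** 3),
        E=(4 - 3 * P0) * np.sqrt(Z) * sq / (8 * p1_35),
        F=(3 - 4 * P0) * (P0 ** 3 - P0 ** 2 + 4 * Z) / (48 * p1 ** 4),
        a0=(P0 ** 2 * (1 - 30 * Z) + P0 * (48 * Z - 1)) / (24 * p1 ** 4),
        a2=-P0 / (2 * p1 ** 3),
        b0=(P0 * (28 * Z - 3) + 3 * P0 ** 2 - 60 * Z) * sqz / (96 * p1 ** 4 * np.sqrt(Z)),
        b2=-P0 * sqz / (8 * p1 ** 3 * np.sqrt(Z)),
        c1=P0 * sqz / (8 * p1_35),
        d0=(-4 * P0 * Z - P0 ** 4 + P0 ** 3) / (48 * p1 ** 4),
        lam2_scaled=float(-(P2 + q)),
    )
    coeff._om = om
    coeff._csc = csc
    return coeff


def P2_closed_form(Z: float, branch_index: int = 1) -> float:
    """Quadratic pitchfork coefficient of P_TW(V) from the printed rational form."""
    return asymptotic_coefficients(Z, branch_index).P2


def P2_solvability(Z: float, branch_index: int = 1, n_quad: int = 4097) -> float:
    """P2 from the third-order solvability condition, by quadrature.

    Integrates f = phi1 - x and g = P0 (phi1 - x)(e^{P0} Lambda2~ + phi2~)
    + P0 (phi1 - x)^3 / 6 against the homogeneous solution
    U(x) = sin(x sqrt(P0-1)/sqrt(Z)); P2 = -int(g U)/int(f U).  Serves as a
    mutual oracle for the closed form.
    """
    a = asymptotic_coefficients(Z, branch_index)
    x = np.linspace(-0.5, 0.5, n_quad)
    f = a.m1(x)
    lam2t_scaled = -(3 * a.P0 ** 2 - 60 * Z + 2) / (48 * (a.P0 - 1) ** 2)
    g = a.P0 * f * (lam2t_scaled + a.phi2t(x)) + a.P0 * f ** 3 / 6
    U = np.sin(a._om * np.asarray(x, dtype=complex))
    num = simpson(g * U, x=x)
    den = simpson(f * U, x=x)
    return float((-num / den).real)


def lambda2_scaled(Z: float) -> float:
    """e^{P0} Lambda2 from the printed closed form."""
    return asymptotic_coefficients(Z).lam2_scaled


def lambda2_scaled_mass_route(Z: float, n_quad: int = 4097) -> float:
    """e^{P0} Lambda2 recomputed from the order-V^2 unit-mass condition."""
    a = asymptotic_coefficients(Z)
    x = np.linspace(-0.5, 0.5, n_quad)
    f1 = a.phi1(x)
    integrand = x ** 2 - 2 * x * f1 + f1 ** 2 + 2 * a.phi2(x)
    return float(-0.5 * simpson(integrand, x=x))


# ---------------------------------------------------------------------------
# the wave object
# ---------------------------------------------------------------------------

@dataclass
class TravelingWave:
    """A traveling wave (V, P, Lambda) with its profile fields and residuals.

    ``m`` and ``phi`` carry analytic derivative arrays; ``evaluate(x)``
    reconstructs all profile fields on an arbitrary abscissa (used by the
    spectral quadratures).  ``log_Lambda`` is stored because Lambda = e^{-P0}
    underflows already for moderate viscosities.
    """

    V: float
    P: float
    Z: float
    log_Lambda: float
    m: Field
    phi: Field
    residuals: dict
    source: str = "asymptotic"
    branch_index: int = 1
    _eval: Optional[Callable] = None

    @property
    def Lambda(self) -> float:
        return float(np.exp(self.log_Lambda))

    @property
    def params(self) -> ModelParams:
        return ModelParams(self.P, self.Z)

    def evaluate(self, x: np.ndarray) -> dict:
        """Profile fields {m, dm, phi, dphi, d2phi} at arbitrary points."""
        if self._eval is None:
            raise ParameterError("wave does not carry an evaluation backend")
        return self._eval(np.asarray(x, dtype=float))


def _wave_residuals(tw: TravelingWave) -> dict:
    pars = tw.params
    F = apply_FC(tw.m, pars, check_mass=False)
    ansatz = np.exp(tw.log_Lambda + tw.phi.values - tw.V * tw.m.grid.nodes)
    return {
        "ode": l2_norm(F),
        "velocity": abs(tw.phi.deriv[-1] - tw.V),
        "mass": abs(tw.m.mass() - 1.0),
        "ansatz": float(np.max(np.abs(tw.m.values - ansatz))),
    }


# ---------------------------------------------------------------------------
# asymptotic construction
# ---------------------------------------------------------------------------

def asymptotic_TW(V: float, Z: float, grid: Optional[Grid] = None,
                  branch_index: int = 1) -> TravelingWave:
    """Traveling wave from the closed-form expansion, fields to O(V^2).

    At V = 0 this is exactly the resting state (m = 1, phi = P0).  The
    consistency residuals of the returned wave are O(V^3) by construction.
    """
    if abs(V) > V_HARD_LIMIT:
        raise ParameterError(f"|V| = {abs(V)} beyond the asymptotic range "
                             f"({V_HARD_LIMIT})")
    if abs(V) > V_SOFT_LIMIT:
        warnings.warn(f"|V| = {abs(V)} > {V_SOFT_LIMIT}: the O(V^3) remainder "
                      "of the expansion may be significant")
    grid = grid or default_grid()
    a = asymptotic_coefficients(Z, branch_index)
    P = a.P0 + V ** 2 * a.P2
    log_Lam = -a.P0 + np.log1p(V ** 2 * a.lam2_scaled)

    def ev(x):
        return {
            "m": 1.0 + V * a.m1(x) + V ** 2 * a.m2(x),
            "dm": V * a.dm1(x) + V ** 2 * a.dm2(x),
            "d2m": V * a.d2m1(x) + V ** 2 * a.d2m2(x),
            "phi": a.P0 + V * a.phi1(x) + V ** 2 * a.phi2(x),
            "dphi": V * a.dphi1(x) + V ** 2 * a.dphi2(x),
            "d2phi": V * a.d2phi1(x) + V ** 2 * a.d2phi2(x),
        }

    f = ev(grid.nodes)
    m = Field(grid, f["m"], bc="neumann", deriv=f["dm"], deriv2=f["d2m"])
    phi = Field(grid, f["phi"], bc="periodic", deriv=f["dphi"], deriv2=f["d2phi"])
    tw = TravelingWave(V=V, P=float(P), Z=Z, log_Lambda=float(log_Lam),
                       m=m, phi=phi, residuals={}, source="asymptotic",
                       branch_index=branch_index, _eval=ev)
    tw.residuals = _wave_residuals(tw)
    return tw


# ---------------------------------------------------------------------------
# exact solve (collocation BVP with P, log Lambda as unknown parameters)
# ---------------------------------------------------------------------------

def numeric_TW(V: float, Z: float, guess: Optional[TravelingWave] = None,
               grid: Optional[Grid] = None, tol: float = 1e-10,
               branch_index: int = 1) -> TravelingWave:
    """Solve the traveling-wave boundary-value problem exactly.

    States are (phi, phi', cumulative mass); unknown parameters (P, log
    Lambda).  Five boundary conditions: phi'(+-1/2) = V, value periodicity,
    and the cumulative mass running from 0 to 1.  The default initial iterate
    is the asymptotic wave.
    """
    grid = grid or default_grid()
    if guess is None:
        guess = asymptotic_TW(min(max(V, -V_HARD_LIMIT), V_HARD_LIMIT), Z,
                              grid, branch_index)

    def fun(x, y, p):
        P, lL = p
        mv = np.exp(lL + y[0] - V * x)
        return np.vstack([y[1], (y[0] - P * mv) / Z, mv])

    def bc(ya, yb, p):
        return np.array([ya[1] - V, yb[1] - V, ya[0] - yb[0],
                         ya[2], yb[2] - 1.0])

    xg = guess.m.grid.nodes if guess.m.grid.n <= 401 else np.linspace(-0.5, 0.5, 201)
    gvals = guess.evaluate(xg)
    y0 = np.vstack([gvals["phi"], gvals["dphi"],
                    np.concatenate([[0.0], np.cumsum(
                        0.5 * (gvals["m"][1:] + gvals["m"][:-1]) * np.diff(xg))])])
    # solve_bvp's tolerance is relative; at large Z the pressure is O(pi^2 Z)
    # and demanding 1e-10 relative runs into round-off-driven mesh refinement
    tol_eff = max(tol, 5e-12 * max(1.0, abs(guess.P)))
    sol = solve_bvp(fun, bc, xg, y0, p=[guess.P, guess.log_Lambda],
                    tol=tol_eff, max_nodes=200000)
    if sol.status != 0:
        raise ConvergenceError(
            f"traveling-wave solve failed at V={V}: {sol.message}",
            residual=float(np.max(sol.rms_residuals)) if sol.rms_residuals.size else None)
    P, lL = float(sol.p[0]), float(sol.p[1])
    pars = ModelParams(P, Z)

    def ev(x):
        y = sol.sol(x)
        mv = np.exp(lL + y[0] - V * x)
        d2phi = (y[0] - P * mv) / Z
        return {"m": mv, "dm": mv * (y[1] - V),
                "d2m": mv * ((y[1] - V) ** 2 + d2phi),
                "phi": y[0], "dphi": y[1], "d2phi": d2phi}

    f = ev(grid.nodes)
    m = Field(grid, f["m"], bc="neumann", deriv=f["dm"], deriv2=f["d2m"])
    phi = Field(grid, f["phi"], bc="periodic", deriv=f["dphi"], deriv2=f["d2phi"])
    tw = TravelingWave(V=V, P=P, Z=Z, log_Lambda=lL, m=m, phi=phi,
                       residuals={}, source="numeric",
                       branch_index=branch_index, _eval=ev)
    tw.residuals = _wave_residuals(tw)
    return tw


def tw_family(Z: float, v_max: float, steps: int, numeric: bool = True,
              grid: Optional[Grid] = None, branch_index: int = 1) -> pd.DataFrame:
    """Continuation table (V, P_TW(V), ||m_TW - 1||_L2) from V = 0.

    Natural continuation with warm starts and step halving on failure; the
    pitchfork shape shows as P even in V and the amplitude linear in |V|.
    """
    if steps < 2:
        raise ParameterError("steps must be >= 2")
    grid = grid or default_grid()
    vs = np.linspace(0.0, v_max, steps)
    rows = []
    prev = None
    one = np.ones(grid.n)
    for V in vs:
        try:
            if numeric:
                tw = numeric_TW(float(V), Z, guess=prev, grid=grid,
                                branch_index=branch_index)
            else:
                tw = asymptotic_TW(float(V), Z, grid, branch_index)
        except ConvergenceError:
            if prev is None:
                raise
            # one round of step halving before giving up
            vmid = 0.5 * (prev.V + V)
            try:
                mid = numeric_TW(float(vmid), Z, guess=prev, grid=grid,
                                 branch_index=branch_index)
                tw = numeric_TW(float(V), Z, guess=mid, grid=grid,
                                branch_index=branch_index)
            except ConvergenceError as exc:
                raise ConvergenceError(
                    f"continuation lost the branch at V={V}") from exc
        amp = float(np.sqrt(np.sum(grid.weights * (tw.m.values - one) ** 2)))
        rows.append({"V": tw.V, "P": tw.P, "ampL2": amp})
        prev = tw
    return pd.DataFrame(rows)
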