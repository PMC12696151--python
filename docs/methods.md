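# Methods

## Model and scope

The package implements the stiff-limit ("fixed length") form of the 1D
mechanical Keller–Segel model of contraction-driven locomotion, in the frame
co-moving with the cell center:

    ∂t m = F_C(m) = m″ + φ′(1/2) m′ − (m φ′)′,
    −Z φ″ + φ = P m  on (−1/2, 1/2),  φ periodic in value and slope,
    m′(±1/2) = 0,  ∫ m dx = 1.

All quantities are dimensionless; `P > 0` is motor activity, `Z > 0` bulk
viscosity.  The frame term `φ′(1/2) m′` encodes the eliminated cell-center
coordinate, whose motion is recovered a posteriori as
`c(t) = ∫₀ᵗ φ′(1/2, s) ds`.  The finite-stiffness free-boundary model that
this is the limit of is out of scope, as are 2D (Hele-Shaw) versions and the
functional-analytic proof apparatus (Lax–Milgram, Grönwall, semigroup
generation); the *conclusions* of that apparatus appear here as testable
numerical statements.

## Trigonometric basis and quadrature

Zero-mean Neumann perturbations are expanded in
`v_n(x) = sin(nπx)` (n odd) / `cos(nπx)` (n even) — the zero-mean Neumann
eigenbasis of d²/dx².  Operator matrices use the orthonormalized basis
`√2 v_n`, so matrix eigenvalues equal operator eigenvalues directly; the
Gershgorin report separately reproduces the un-normalized (halved) Gram
bookkeeping `B = A_gram − I` of the localization argument, to keep its
printed inequalities checkable verbatim.

Two grids are used.  The default is uniform with `N = 257` nodes and
trapezoid weights: by discrete cosine orthogonality these weights integrate
products of basis modes with indices below `N − 1` *exactly*, so projection
is a DCT in disguise.  For operator quadrature (assembling the wave-dependent
part of `T_C`, commutator measurements) a Chebyshev–Lobatto grid with 513
Clenshaw–Curtis weights is used, which integrates the smooth non-polynomial
integrands (sinh corrections, wave profiles) to near machine precision.
Endpoint derivatives of raw sampled fields are estimated with one-sided
3-point stencils; fields constructed by the package (synthesized modes,
elliptic solves, traveling waves) carry exact derivative arrays instead, and
boundary-condition validation uses those when present.

## Elliptic solve

The pressure solve is modal: the zero-mean part of `m` is projected onto the
basis, each mode damped by `1/(1 + n²π²Z)`, and the mean maps to `P·mean(m)`.
Even modes are exact eigenfunctions of the periodic operator; odd modes are
not — their particular solution jumps across ±1/2 and a homogeneous
`sinh(x/√Z)` correction restores value periodicity.  That correction is the
origin of the odd–odd coupling block in the operator matrix; its projection
is `+4P coth(1/(2√Z)) t_m t_n`, `t_n = (−1)^{(n−1)/2}/(1 + n²π²Z)` — a
rank-one, positive-semidefinite update.  The sign of its diagonal was fixed
by requiring (and verifying, for Z ∈ {0.05, 1, 10, 200}) that the leading
eigenvalue vanish exactly at the threshold `P = P₀(Z)`; a dense
finite-difference solve of the periodic boundary-value problem serves as the
independent oracle in the tests.  `φ″` is always evaluated through the ODE
itself, `φ″ = (φ − Pm)/Z`, never by numerical differentiation.

## Threshold and expansion coefficients

`P₀(Z)` is found on the monotone formulations
`k₁(v) = (v − tanh v)/(4v³) = Z` (for `Z < 1/12`) and
`k₂(w) = (tan w − w)/(4w³) = Z` (for `Z > 1/12`) with bracketed Brent
iteration; both functions use a Taylor branch below argument 0.05 to avoid
catastrophic cancellation (`k → 1/12 ∓ v²/30 ± …`).  Near the pole of `tan`
the raw threshold equation has derivative-amplified residuals, so the
residual contract (≤ 1e−12) is stated for the bounded equivalent
`sin w − P₀ w cos w` (resp. `tanh v − P₀ v`).  `Z = 1/12` is refused within
1e−6: there the root `P₀ = 1` is degenerate and no bifurcation occurs.
Higher roots (`branch_index = 3, 5, …`, one per interval
`((b−2)π/2, bπ/2)`) give the higher, conjecturally unstable wave families.

All small-velocity expansion coefficients (`m₁, m₂, φ₁, φ₂, Λ₂, P₂`) are
evaluated with the complex-safe frequency `ω = √((P₀−1)/Z)`, so the
`P₀ < 1` branch continues automatically to hyperbolic functions; imaginary
parts cancel to round-off and are dropped.  `csc(ω/2)` is equivalent to
`√((P₀³−P₀²+4Z)/((P₀−1)P₀²))` on the principal branch, which the tests use
as a consistency identity.  `P₂` has two independent routes — the closed
rational form and the third-order solvability quotient
`−∫gU/∫fU`, `U = sin(ωx)` — that agree to ~1e−12 relative; both are exposed
and tested as mutual oracles.  `Λ = e^{−P₀}` underflows for `Z ≳ 75`, so
waves store `log Λ` and form `m = exp(log Λ + φ − Vx)` directly.

## Exact traveling waves

`numeric_TW` solves the wave boundary-value problem with
`scipy.integrate.solve_bvp` (adaptive 4th-order collocation): states
`(φ, φ′, cumulative mass)`, unknown parameters `(P, log Λ)`, and five
boundary conditions (`φ′(±1/2) = V`, value periodicity, mass running from 0
to 1).  The default initial iterate is the asymptotic wave.  The solver
tolerance is relative; because `φ = O(π²Z)`, the effective tolerance is
floored at `5e−12·P₀` to avoid round-off-driven mesh refinement at large Z.
Continuation in V is natural (warm starts, one step-halving retry); no
folds are expected at small velocity and none are handled.

## Non-self-adjoint diagnostics

`T_C`'s matrix is assembled as the closed-form resting-state matrix at
`P = P_TW(V)` plus the wave-dependent correction `d_mn`, quadratured with
the exact single-mode elliptic responses `φ_n` (also at `P_TW(V)`).  The
correction's absolute row sums scale linearly in V, its symmetry defect
measures the onset of non-self-adjointness, and at `V = 0` the matrix
coincides with the resting-state one at threshold.  Eigenvalues of the
non-symmetric truncations come from LAPACK's general dense solver (balancing
left on), ordered by descending real part with ties broken by imaginary
part; symmetric problems use the symmetric solver.  Resolvent norms are
`1/σ_min(iωI − A_N)` on a symmetric logarithmic ω-grid (±[1, 10³]) plus a
fine linear patch near 0.  Default truncation `N = 64` with a
doubling-based convergence guard; all reported leading eigenvalues are
stable to ≤1e−6 under doubling in the regimes exercised.

### The onset constant (known discrepancy)

The large-viscosity limit of `∂_V H(sin πx, cos 2πx)|_{V=0}` computed here
is `9π²/16 ≈ 5.5517` in the definition ordering `⟨Au,v⟩ − ⟨u,Av⟩`
(equivalently `−9π²/16` in the reversed ordering used by the source
analysis' printed expansion, whose stated value is `−3`).  The package's
value was verified three independent ways: Gauss–Legendre/Clenshaw–Curtis
quadrature of the closed-form wave fields, a dense finite-difference
discretization of both the elliptic solve and `T_C`, and term-by-term
closed-form evaluation of the expansion's five integrals (boundary term 0,
frame term −2/3, drift term −10/3, transport terms `4 − 9π²/16`).  The
acceptance script reports the honestly computed value; the corresponding
acceptance test is left failing rather than retuned.

## Time integration

The default `"imex"` scheme is a vertex-centered finite-volume method on
the uniform grid: Crank–Nicolson for diffusion, explicit centrally-averaged
conservative fluxes for the advective part, with the frame term and the
Keller–Segel term sharing one interface flux
`(φ′(1/2) − φ′(x)) m̄` whose boundary values vanish identically — so the
trapezoid-weighted mass is conserved to solver round-off per step (the
tests assert ≤1e−12).  A central rather than upwind-biased interface
average keeps the scheme second order, which the 2%-accuracy decay-rate
checks require; the advective CFL guard `dt ≤ 0.5 h/max|φ′(1/2) − φ′|`
protects the explicit part, and a violation raises with a suggested step.

The `"exponential"` scheme is a trig-basis Galerkin truncation (default 64
modes; the constant mode is excluded, making mass conservation structural)
whose linear part is advanced exactly via the eigendecomposition of the
resting-state matrix, with the quadratic part handled by exponential Euler.
It reproduces the linear semigroup to round-off — the semigroup-consistency
test integrates an amplitude-1e−8 perturbation to `t = 1` and matches
`exp(tA_N)` on the projected coefficients to 1e−6 relative, a statement the
second-order finite-difference scheme cannot make (its spatial eigenvalue
error alone is ~5e−5) — and is the cheap choice for the slow near-threshold
dynamics (decay rates ~1e−3 needing horizons of hundreds of time units).

Decay rates are least-squares slopes of `log‖u‖_{L2}` over the last half of
the run (the nonlinear transient decays first); the fit residual and a
monotonicity flag are reported.  For wave-relaxation measurements the wave
is first Newton-polished into an exact steady state of the truncated
Galerkin system, so the measured decay is not floored by the truncation
offset of the interpolated wave.

## Perturbation fixtures (synthetic inputs)

The model has no external data; initial conditions are seeded fixtures:
`single_mode` (one trig mode), `random_trig` (standard-normal weights on
the first K modes, default seed 12345), `null_mode` (the neutral threshold
mode `u₀`), all normalized to a prescribed L² amplitude (default regimes:
1e−2 for nonlinear decay runs, 1e−3 for threshold bracketing, 1e−4 for
wave-relaxation, 1e−8 for semigroup consistency).  These emulate smooth,
band-limited disturbances of a resting or crawling cell; they do not
emulate rough or localized myosin fluctuations, parameter noise, or
boundary perturbations, so passing tests speak to smooth-perturbation
stability only — consistent with the H¹-neighborhood hypotheses of the
underlying theory.

## Problem sizes and runtimes

Defaults were chosen so every check runs on a laptop core in seconds:
grids of 257 (fields) and 513 (quadrature) points, truncations N = 64
(guarded by doubling), wave continuation to |V| ≤ 0.2, simulation horizons
≤ 400 time units at Galerkin resolution 48.  Large-viscosity limits are
evaluated at Z = 10³ and 10⁴ and extrapolated linearly in 1/Z.

## Known limitations

* The asymptotic wave fields are O(V³) accurate; consistency residuals of
  asymptotic `TravelingWave` objects are therefore O(V³), not 1e−8 — only
  `numeric_TW` meets the tight residual contracts.
* Natural continuation cannot round folds; the existence radius in V is not
  known a priori and `V_max` is a user parameter with no guarantee.
* Whether `P₀(Z)² = 12Z` can meet the principal branch (which would make
  the printed `P₂` singular) is unresolved; the coefficient routines raise
  on a vanishing denominator rather than guess.
* The Gershgorin row-1 certificate (`b₁₁ + Q₁ < −1`) rightly fails — row 1
  carries the near-neutral eigenvalue; the report exposes per-row flags so
  the one admissible exception is visible.
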