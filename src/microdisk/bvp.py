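"""Reference finite-difference solution of the biosensor boundary-value problem.

The substrate equation S'' + (2/R)S' = gamma_E*S/(1+alpha*S) is discretized
with second-order central differences on a uniform grid and solved by damped
Newton iteration with an analytic banded Jacobian; a geometric continuation
in gamma_E is the fallback for strongly reaction-limited films.  The peroxide
equation is linear given S and is solved directly; independently, the
harmonic combination W = gamma_S*S + gamma_E*H satisfies the radial Laplace
equation (the rate terms cancel), so H can also be reconstructed in closed
form from S alone — the two routes cross-check each other.

The alpha = 0 (first-order-kinetics) limit has the exact solution
S = (C/R)[cosh(m(R-1)) + sinh(m(R-1))/m], m = sqrt(gamma_E), used as the
analytic oracle for convergence studies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import solve_banded

from .params import (
    ConcentrationProfile,
    ModelParams,
    RadialGrid,
    mm_rate,
    mm_rate_derivative,
)

__all__ = [
    "SolverOptions",
    "ConvergenceError",
    "solve_substrate",
    "solve_peroxide_linear",
    "reconstruct_peroxide_harmonic",
    "solve_coupled",
    "first_order_exact",
    "harmonic_invariant_residual",
]


@dataclass(frozen=True)
class SolverOptions:
    """Newton/continuation controls for the substrate solve."""

    n: int = 4001
    newton_tol: float = 1e-12
    max_newton_iters: int = 50
    damping: float = 0.5
    continuation_steps: int = 8

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("n must be >= 3")
        if self.newton_tol <= 0:
            raise ValueError("newton_tol must be positive")
        if not 0 < self.damping < 1:
            raise ValueError("damping must lie in (0, 1)")


class ConvergenceError(RuntimeError):
    """Newton iteration failed to reach the requested residual tolerance."""

    def __init__(self, message: str, last_residual: float):
        super().__init__(f"{message} (last residual max-norm {last_residual:.3e})")
        self.last_residual = last_residual


def _substrate_system(S: np.ndarray, R: np.ndarray, h: float, params: ModelParams):
    """Residual vector and banded Jacobian (l=1, u=2) of the discrete system."""
    n = R.size
    F = np.empty(n)
    # second-order one-sided Neumann at R=1
    F[0] = (-3.0 * S[0] + 4.0 * S[1] - S[2]) / (2.0 * h)
    Rm = R[1:-1]
    F[1:-1] = (
        (S[:-2] - 2.0 * S[1:-1] + S[2:]) / h**2
        + (2.0 / Rm) * (S[2:] - S[:-2]) / (2.0 * h)
        - mm_rate(np.clip(S[1:-1], 0.0, None), params.gamma_E, params.alpha)
    )
    F[-1] = S[-1] - 1.0

    # banded storage for scipy.linalg.solve_banded with (l, u) = (1, 2)
    ab = np.zeros((4, n))
    ab[0, 2] = -1.0 / (2.0 * h)              # row 0, col 2
    ab[1, 1] = 4.0 / (2.0 * h)               # row 0, col 1
    ab[2, 0] = -3.0 / (2.0 * h)              # row 0, col 0
    drate = mm_rate_derivative(
        np.clip(S[1:-1], 0.0, None), params.gamma_E, params.alpha
    )
    ab[1, 2:] = 1.0 / h**2 + 1.0 / (h * Rm)       # superdiag, rows 1..n-2
    ab[2, 1:-1] = -2.0 / h**2 - drate             # diagonal
    ab[3, :-2] = 1.0 / h**2 - 1.0 / (h * Rm)      # subdiag
    ab[2, -1] = 1.0                               # Dirichlet row
    ab[3, -2] = 0.0
    return F, ab


def _newton(S0: np.ndarray, R: np.ndarray, h: float, params: ModelParams,
            opts: SolverOptions):
    # Convergence: residual max-norm <= tol, or a full Newton step smaller
    # than tol (the residual floor is ~eps/h^2, unreachable on fine grids).
    S = S0.copy()
    F, ab = _substrate_system(S, R, h, params)
    norm = np.max(np.abs(F))
    for _ in range(opts.max_newton_iters):
        if norm <= opts.newton_tol:
            return S, norm, True
        delta = solve_banded((1, 2), ab, -F)
        step = np.max(np.abs(delta))
        lam = 1.0
        while True:
            trial = S + lam * delta
            Ft, abt = _substrate_system(trial, R, h, params)
            tnorm = np.max(np.abs(Ft))
            if tnorm < norm or lam < 1e-8:
                S, F, ab, norm = trial, Ft, abt, tnorm
                break
            lam *= opts.damping
        if step <= opts.newton_tol * max(1.0, np.max(np.abs(S))):
            return S, norm, True
    floor = 64.0 * np.finfo(float).eps / h**2
    return S, norm, norm <= max(opts.newton_tol, floor)


def solve_substrate(params: ModelParams, opts: SolverOptions = SolverOptions()
                    ) -> ConcentrationProfile:
    """Solve the nonlinear substrate BVP; returns an S-only profile.

    Starts Newton from S = 1; if that stalls, ramps gamma_E geometrically
    over ``opts.continuation_steps`` from a 100-fold smaller value.
    """
    grid = RadialGrid.uniform(params.q, opts.n)
    R = grid.R
    h = R[1] - R[0]
    if params.gamma_E == 0.0:
        S = np.ones_like(R)
        return ConcentrationProfile(grid=grid, params=params, S=S,
                                    provenance="numerical",
                                    meta={"residual": 0.0, "newton_iters": 0})

    S, norm, ok = _newton(np.ones_like(R), R, h, params, opts)
    if not ok:
        S = np.ones_like(R)
        gammas = np.geomspace(params.gamma_E / 100.0, params.gamma_E,
                              opts.continuation_steps)
        for g in gammas:
            p_g = replace(params, gamma_E=g)
            S, norm, ok = _newton(S, R, h, p_g, opts)
        if not ok:
            raise ConvergenceError("substrate Newton iteration did not converge",
                                   norm)
    return ConcentrationProfile(grid=grid, params=params, S=S,
                                provenance="numerical",
                                meta={"residual": float(norm)})


def solve_peroxide_linear(params: ModelParams,
                          s_profile: ConcentrationProfile) -> ConcentrationProfile:
    """Solve the linear peroxide BVP with source +gamma_S*S/(1+alpha*S).

    H(1) = H(q) = 0 Dirichlet rows; tridiagonal central-difference system.
    Returns a copy of the profile with H attached.
    """
    if s_profile.S is None:
        raise ValueError("substrate profile required first")
    R = s_profile.grid.R
    n = R.size
    h = R[1] - R[0]
    source = -mm_rate(np.clip(s_profile.S, 0.0, None), params.gamma_S, params.alpha)

    # interior-only tridiagonal solve; H(1) = H(q) = 0 imposed exactly
    m = n - 2
    Rm = R[1:-1]
    upper = 1.0 / h**2 + 1.0 / (h * Rm)
    lower = 1.0 / h**2 - 1.0 / (h * Rm)
    ab = np.zeros((3, m))
    ab[0, 1:] = upper[:-1]
    ab[1, :] = -2.0 / h**2
    ab[2, :-1] = lower[1:]
    rhs = source[1:-1].copy()
    H = np.zeros(n)
    H[1:-1] = solve_banded((1, 1), ab, rhs)
    return ConcentrationProfile(grid=s_profile.grid, params=params,
                                S=s_profile.S, H=H,
                                provenance=s_profile.provenance,
                                meta=dict(s_profile.meta))


def reconstruct_peroxide_harmonic(params: ModelParams,
                                  s_profile: ConcentrationProfile
                                  ) -> ConcentrationProfile:
    """Closed-form H from S via the harmonic combination.

    W = gamma_S*S + gamma_E*H obeys W'' + (2/R)W' = 0, so W = a + b/R with
    the constants fixed by H(1) = H(q) = 0 and S(q) = 1:
    b = gamma_S*q*(S(1)-1)/(q-1), a = gamma_S*S(1) - b.
    """
    if s_profile.S is None:
        raise ValueError("substrate profile required first")
    if params.gamma_E == 0.0:
        raise ValueError("gamma_E = 0: use solve_peroxide_linear instead")
    R = s_profile.grid.R
    S = s_profile.S
    q = s_profile.grid.q
    S1 = S[0]
    b = params.gamma_S * q * (S1 - 1.0) / (q - 1.0)
    a = params.gamma_S * S1 - b
    H = (a + b / R - params.gamma_S * S) / params.gamma_E
    return ConcentrationProfile(grid=s_profile.grid, params=params,
                                S=S, H=H, provenance=s_profile.provenance,
                                meta={**s_profile.meta, "harmonic_a": float(a),
                                      "harmonic_b": float(b)})


def solve_coupled(params: ModelParams, opts: SolverOptions = SolverOptions(),
                  cross_check_tol: float | None = 1e-6) -> ConcentrationProfile:
    """Solve S then H; cross-check the two H routes when gamma_E > 0.

    The exported H is from the linear solve.  A disagreement beyond
    ``cross_check_tol`` raises (set ``cross_check_tol=None`` to skip).
    """
    sp = solve_substrate(params, opts)
    prof = solve_peroxide_linear(params, sp)
    if params.gamma_E > 0 and cross_check_tol is not None:
        rec = reconstruct_peroxide_harmonic(params, sp)
        dev = float(np.max(np.abs(prof.H - rec.H)))
        prof.meta["h_cross_check"] = dev
        if dev > cross_check_tol:
            raise ConvergenceError("H cross-check failed", dev)
    return prof


def first_order_exact(gamma_E: float, q: float,
                      grid: RadialGrid | None = None,
                      n: int = 4001) -> ConcentrationProfile:
    """Exact alpha = 0 substrate solution (analytic oracle).

    With m = sqrt(gamma_E) and u = R*S, u'' = gamma_E*u gives
    S(R) = (C/R)[cosh(m(R-1)) + sinh(m(R-1))/m],
    C = q/[cosh(m(q-1)) + sinh(m(q-1))/m]; S'(1) = 0 and S(q) = 1 hold
    exactly by construction.
    """
    if gamma_E <= 0:
        raise ValueError("gamma_E must be positive")
    if grid is None:
        grid = RadialGrid.uniform(q, n)
    R = grid.R
    m = np.sqrt(gamma_E)
    shape = np.cosh(m * (R - 1.0)) + np.sinh(m * (R - 1.0)) / m
    C = q / (np.cosh(m * (q - 1.0)) + np.sinh(m * (q - 1.0)) / m)
    S = C * shape / R
    params = ModelParams(gamma_E=gamma_E, gamma_S=gamma_E, alpha=0.0, q=q)
    return ConcentrationProfile(grid=grid, params=params, S=S,
                                provenance="exact-limit")


def harmonic_invariant_residual(profile: ConcentrationProfile,
                                params: ModelParams) -> float:
    """Max deviation of W = gamma_S*S + gamma_E*H from its best a + b/R fit.

    Scaled by gamma_S so the number is comparable across parameter sets.
    A converged numerical profile makes this small; a corrupted one does not.
    """
    if profile.S is None or profile.H is None:
        raise ValueError("profile must carry both S and H")
    R = profile.grid.R
    W = params.gamma_S * profile.S + params.gamma_E * profile.H
    A = np.column_stack([np.ones_like(R), 1.0 / R])
    coef, *_ = np.linalg.lstsq(A, W, rcond=None)
    return float(np.max(np.abs(W - A @ coef)) / params.gamma_S)
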