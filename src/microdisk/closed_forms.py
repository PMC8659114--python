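"""Printed analytical approximations to the biosensor profiles.

Three published series approximations are evaluated exactly as printed —
the modified Adomian decomposition method (MADM), the homotopy analysis
method (HAM, with its convergence-control parameter h), and the homotopy
perturbation method (HPM, in its own scaled variables) — together with the
saturated (zero-order, alpha -> infinity) limit.  All are algebraic
closed forms: no solving happens here.  They are deliberately NOT corrected
where they leave the physical range; a validity flag is reported instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ConcentrationProfile, ModelParams, RadialGrid

__all__ = [
    "HamConfig",
    "ScaledHPMProfile",
    "madm_profiles",
    "ham_profiles",
    "hpm_profiles",
    "saturated_limit_profile",
]


@dataclass(frozen=True)
class HamConfig:
    """HAM convergence-control parameter; h = -1 is the common default."""

    h: float = -1.0

    def __post_init__(self) -> None:
        if self.h == 0:
            raise ValueError("HAM parameter h must be nonzero")


@dataclass(frozen=True)
class ScaledHPMProfile:
    """HPM result in its own scaled variables CSP/CHP on the r/r0 grid.

    The HPM scaling definition is typographically ambiguous in its source,
    so these values are kept in their native scale rather than silently
    converted to S/H.
    """

    r_over_r0: np.ndarray
    CSP: np.ndarray
    CHP: np.ndarray


def madm_profiles(params: ModelParams, grid: RadialGrid) -> ConcentrationProfile:
    """MADM quadratic closed forms for S and H.

    S(R) = 1 + (a/3)q - (a/6)q^2 - (a/3)R + (a/6)R^2 with a = gamma_E/(1+alpha);
    H(R) = -(b/6)q + (b/6)(1+q)R - (b/6)R^2 with b = gamma_S/(1+alpha).
    Both satisfy all four boundary conditions identically.
    """
    R = grid.R
    q = grid.q
    a = params.gamma_E / (1.0 + params.alpha)
    b = params.gamma_S / (1.0 + params.alpha)
    S = 1.0 + a / 3.0 * q - a / 6.0 * q**2 - a / 3.0 * R + a / 6.0 * R**2
    H = -b / 6.0 * q + b / 6.0 * (1.0 + q) * R - b / 6.0 * R**2
    return ConcentrationProfile(grid=grid, params=params, S=S, H=H,
                                provenance="madm")


def ham_profiles(params: ModelParams, ham: HamConfig,
                 grid: RadialGrid) -> ConcentrationProfile:
    """HAM quadratic closed forms for S and H at control parameter h.

    S(R) = 1 + (h*a/2)q^2 - h*a*q + h*a*R - (h*a/2)R^2, a = gamma_E/(1+alpha);
    H(R) = (h*b/2)q - (h*b/2)(q+1)R + (h*b/2)R^2, b = gamma_S/(1+alpha).
    For large a these leave [0, 1]; they are returned as printed regardless.
    """
    R = grid.R
    q = grid.q
    a = params.gamma_E / (1.0 + params.alpha)
    b = params.gamma_S / (1.0 + params.alpha)
    h = ham.h
    S = 1.0 + h * a / 2.0 * q**2 - h * a * q + h * a * R - h * a / 2.0 * R**2
    H = h * b / 2.0 * q - h * b / 2.0 * (q + 1.0) * R + h * b / 2.0 * R**2
    return ConcentrationProfile(grid=grid, params=params, S=S, H=H,
                                provenance="ham",
                                meta={"h": h})


def hpm_profiles(q: float, r_over_r0: np.ndarray) -> ScaledHPMProfile:
    """HPM closed forms in the scaled variables CSP and CHP.

    With rho = r/r0 in [1, q]:
    CSP = rho - rho^2/2 + q^2/2 - q  (vanishes at rho = q);
    CHP = (q*rho - rho^2 - q + rho)/2 = (q - rho)(rho - 1)/2 (vanishes at
    both film boundaries, matching the peroxide boundary conditions).
    """
    rho = np.asarray(r_over_r0, dtype=float)
    if np.any(rho < 1.0 - 1e-12) or np.any(rho > q + 1e-12):
        raise ValueError("r/r0 must lie within [1, q]")
    CSP = rho - 0.5 * rho**2 + 0.5 * q**2 - q
    CHP = 0.5 * (q * rho - rho**2 - q + rho)
    return ScaledHPMProfile(r_over_r0=rho, CSP=CSP, CHP=CHP)


def saturated_limit_profile(params: ModelParams, grid: RadialGrid
                            ) -> tuple[ConcentrationProfile, bool]:
    """Zero-order (saturated) limit S and its validity flag.

    When alpha*S >> 1 the rate saturates at k = gamma_E/alpha and the
    substrate equation becomes S'' + (2/R)S' = k with the exact solution
    S(R) = 1 + k(R^2 - q^2)/6 + (k/3)(1/R - 1/q).  The limit breaks down
    (flag False) when it predicts S <= 0 anywhere.
    """
    if params.alpha <= 0:
        raise ValueError("saturated limit needs alpha > 0")
    R = grid.R
    q = grid.q
    k = params.gamma_E / params.alpha
    S = 1.0 + k * (R**2 - q**2) / 6.0 + (k / 3.0) * (1.0 / R - 1.0 / q)
    valid = bool(np.min(S) > 0.0)
    prof = ConcentrationProfile(grid=grid, params=params, S=S,
                                provenance="exact-limit",
                                meta={"k": k, "valid": valid})
    return prof, valid
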