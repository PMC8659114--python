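"""Model parameterization for the micro-disk enzyme biosensor.

An enzyme film occupies the spherical shell between the electrode surface
(radius ``r0``) and the film boundary (radius ``r1``).  At steady state the
dimensionless substrate ``S`` and hydrogen-peroxide ``H`` concentrations obey

    S'' + (2/R) S' - gamma_E * S / (1 + alpha * S) = 0,
    H'' + (2/R) H' + gamma_S * S / (1 + alpha * S) = 0,

on R in [1, q], q = r1/r0, with S'(1) = 0, S(q) = 1, H(1) = H(q) = 0.
``gamma_E`` and ``gamma_S`` are Thiele-modulus-like reaction-diffusion
groups, ``alpha = CS*/KM`` the saturation parameter of the Michaelis-Menten
rate law.

This module holds the parameter containers, the nondimensionalization map,
the rate term, discrete residual evaluation and profile CSV I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "DimensionalParams",
    "ModelParams",
    "RadialGrid",
    "ConcentrationProfile",
    "mm_rate",
    "mm_rate_derivative",
    "to_dimensionless",
    "residuals",
    "read_profile_csv",
    "write_profile_csv",
]

_REL_TOL = 1e-12


@dataclass(frozen=True)
class DimensionalParams:
    """Physical (dimensional) biosensor parameters.

    Units: diffusivities in cm^2/s, rate constants in 1/s (k1 in
    cm^3/(mol s)), concentrations in mol/cm^3, radii in cm.  The peroxide
    concentration scale ``CH_star`` must equal ``CS_star``: it is the unique
    scaling under which the peroxide balance keeps the printed dimensionless
    form.
    """

    DS: float
    DH: float
    kcat: float
    CE: float
    KM: float
    r0: float
    r1: float
    CS_star: float
    CH_star: Optional[float] = None
    k1: Optional[float] = None
    k_rev: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("DS", "DH", "kcat", "CE", "KM", "r0", "r1", "CS_star"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        if self.r1 <= self.r0:
            raise ValueError(f"r1 ({self.r1}) must exceed r0 ({self.r0})")
        if self.CH_star is None:
            object.__setattr__(self, "CH_star", self.CS_star)
        elif not np.isclose(self.CH_star, self.CS_star, rtol=_REL_TOL, atol=0.0):
            raise ValueError("CH_star must equal CS_star (peroxide scale)")
        if self.k1 is not None and self.k_rev is not None:
            km = (self.k_rev + self.kcat) / self.k1
            if abs(km - self.KM) > _REL_TOL * abs(self.KM):
                raise ValueError(
                    f"KM={self.KM} inconsistent with (k_rev+kcat)/k1={km}"
                )


@dataclass(frozen=True)
class ModelParams:
    """Dimensionless parameters driving the coupled reaction-diffusion BVP."""

    gamma_E: float
    gamma_S: float
    alpha: float
    q: float

    def __post_init__(self) -> None:
        if self.gamma_E < 0 or self.gamma_S < 0:
            raise ValueError("reaction-diffusion parameters must be >= 0")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.q <= 1:
            raise ValueError(f"q = r1/r0 must exceed 1, got {self.q}")


@dataclass(frozen=True)
class RadialGrid:
    """Strictly increasing dimensionless radii spanning [1, q]."""

    R: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float)
        object.__setattr__(self, "R", R)
        if R.ndim != 1 or R.size < 3:
            raise ValueError("grid needs at least 3 one-dimensional points")
        if not np.all(np.diff(R) > 0):
            raise ValueError("grid must be strictly increasing")
        if abs(R[0] - 1.0) > 1e-12:
            raise ValueError("grid must start at R = 1")

    @property
    def n(self) -> int:
        return self.R.size

    @property
    def q(self) -> float:
        return float(self.R[-1])

    @classmethod
    def uniform(cls, q: float, n: int) -> "RadialGrid":
        if q <= 1:
            raise ValueError("q must exceed 1")
        return cls(np.linspace(1.0, q, n))


@dataclass
class ConcentrationProfile:
    """Radial concentration profile(s) plus solver provenance.

    ``S`` and/or ``H`` may be absent (None).  ``provenance`` is one of
    numerical | madm | ham | hpm-rescaled | surrogate | exact-limit.
    """

    grid: RadialGrid
    params: ModelParams
    S: Optional[np.ndarray] = None
    H: Optional[np.ndarray] = None
    provenance: str = "numerical"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("S", "H"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.grid.R.shape:
                    raise ValueError(f"{name} shape {v.shape} != grid {self.grid.R.shape}")
                setattr(self, name, v)


def mm_rate(s, gamma: float, alpha: float):
    """Michaelis-Menten consumption term gamma*s/(1 + alpha*s).

    Monotone nondecreasing in ``s``; saturates at gamma/alpha for alpha > 0.
    """
    s = np.asarray(s, dtype=float)
    if gamma < 0 or alpha < 0:
        raise ValueError("gamma and alpha must be >= 0")
    if np.any(s < 0):
        raise ValueError("substrate concentration must be >= 0")
    out = gamma * s / (1.0 + alpha * s)
    return float(out) if out.ndim == 0 else out


def mm_rate_derivative(s, gamma: float, alpha: float):
    """d/ds of mm_rate: gamma/(1 + alpha*s)^2 (used by the Newton Jacobian)."""
    s = np.asarray(s, dtype=float)
    out = gamma / (1.0 + alpha * s) ** 2
    return float(out) if out.ndim == 0 else out


def to_dimensionless(p: DimensionalParams) -> ModelParams:
    """Map dimensional parameters to the dimensionless group (gamma_E, gamma_S, alpha, q).

    gamma_E = kcat*CE*r0^2/(DS*KM), gamma_S = kcat*CE*r0^2/(DH*KM),
    alpha = CS*/KM, q = r1/r0; hence gamma_E/gamma_S = DH/DS.
    """
    gamma_E = p.kcat * p.CE * p.r0**2 / (p.DS * p.KM)
    gamma_S = p.kcat * p.CE * p.r0**2 / (p.DH * p.KM)
    return ModelParams(
        gamma_E=gamma_E,
        gamma_S=gamma_S,
        alpha=p.CS_star / p.KM,
        q=p.r1 / p.r0,
    )


def _second_derivative(y: np.ndarray, h: float) -> np.ndarray:
    return (y[:-2] - 2.0 * y[1:-1] + y[2:]) / h**2


def _first_derivative_central(y: np.ndarray, h: float) -> np.ndarray:
    return (y[2:] - y[:-2]) / (2.0 * h)


def residuals(profile: ConcentrationProfile, params: ModelParams):
    """Discrete residuals of both balance equations on a uniform grid.

    Returns ``(resS, resH, bc_res)`` with interior residuals evaluated via
    second-order central differences (expanded form S'' + (2/R)S') and the
    four boundary residuals [S'(1), S(q)-1, H(1), H(q)].  The one-sided
    S'(1) uses the second-order 3-point stencil.
    """
    if profile.S is None or profile.H is None:
        raise ValueError("profile must carry both S and H")
    R = profile.grid.R
    S, H = profile.S, profile.H
    if S.shape != H.shape or S.shape != R.shape:
        raise ValueError("S, H and grid must share one shape")
    h = R[1] - R[0]
    if not np.allclose(np.diff(R), h, rtol=1e-10):
        raise ValueError("residuals require a uniform grid")
    Rm = R[1:-1]
    rate = mm_rate(np.clip(S[1:-1], 0.0, None), params.gamma_E, params.alpha)
    rate_H = mm_rate(np.clip(S[1:-1], 0.0, None), params.gamma_S, params.alpha)
    resS = (
        _second_derivative(S, h)
        + (2.0 / Rm) * _first_derivative_central(S, h)
        - rate
    )
    resH = (
        _second_derivative(H, h)
        + (2.0 / Rm) * _first_derivative_central(H, h)
        + rate_H
    )
    sprime1 = (-3.0 * S[0] + 4.0 * S[1] - S[2]) / (2.0 * h)
    bc_res = np.array([sprime1, S[-1] - 1.0, H[0], H[-1]])
    return resS, resH, bc_res


_CSV_FLOAT = "%.17g"


def write_profile_csv(profile: ConcentrationProfile, path) -> None:
    """Write a profile as CSV with header ``R,S,H``; absent components are empty."""
    n = profile.grid.n

    def col(v):
        if v is None:
            return [""] * n
        return [(_CSV_FLOAT % x) for x in v]

    df = pd.DataFrame(
        {
            "R": [(_CSV_FLOAT % x) for x in profile.grid.R],
            "S": col(profile.S),
            "H": col(profile.H),
        }
    )
    df.to_csv(path, index=False)


def read_profile_csv(path, params: Optional[ModelParams] = None,
                     provenance: str = "numerical") -> ConcentrationProfile:
    df = pd.read_csv(path)
    grid = RadialGrid(df["R"].to_numpy(dtype=float))
    if params is None:
        params = ModelParams(gamma_E=0.0, gamma_S=0.0, alpha=0.0, q=grid.q)

    def col(name):
        if name not in df or df[name].isna().all():
            return None
        return df[name].to_numpy(dtype=float)

    return ConcentrationProfile(
        grid=grid, params=params, S=col("S"), H=col("H"), provenance=provenance
    )
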