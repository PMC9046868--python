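"""Right-hand sides of the five 2D environment fields.

The extracellular nutritional environment (ECNE) ``v`` is an immobile
matrix/substrate with logistic self-restoration, degraded by the acid
field and by slow natural decay.  Three diffusible species live on the
same spatial grid: the nutrient ``n`` (sourced by the ECNE, consumed by
cells — also the chemoattractant), the acid ``a`` (produced by cells,
degrading the ECNE), and the two drug concentrations ``w_B`` (BRAF/MEK
inhibitors) and ``w_H`` (HCT), which are administered uniformly in space
while dosing is on and are cleared naturally and by cell uptake.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ContractViolationError
from .geometry import GridSpec


@dataclass(frozen=True)
class EnvironmentParams:
    """Environment kinetics (rates per day; fields dimensionless)."""

    r_v: float = 0.2          # ECNE logistic restoration
    v_max: float = 1.0         # ECNE capacity
    lam_av: float = 0.1        # acid-induced ECNE degradation
    lam_v: float = 0.01        # natural ECNE decay
    D_n: float = 1.0e-3        # nutrient diffusivity
    D_a: float = 1.0e-3        # acid diffusivity
    D_w: float = 2.0e-3        # drug diffusivity
    alpha_n: float = 0.9       # nutrient production per unit ECNE
    beta_n: float = 0.02       # nutrient consumption per unit cell density
    lam_n: float = 0.4         # nutrient decay
    alpha_a: float = 0.01      # acid production per unit cell density
    lam_a: float = 0.5         # acid decay
    lam_w: float = 0.5         # drug natural clearance
    eps_w: float = 0.1        # drug uptake per unit cell density

    def __post_init__(self):
        for key in self.__dataclass_fields__:
            if getattr(self, key) < 0:
                raise ConfigurationError(f"environment.{key} must be >= 0")
        if not self.v_max > 0:
            raise ConfigurationError("environment.v_max must be > 0")


def neumann_laplacian(f: np.ndarray, h: float) -> np.ndarray:
    """5-point Laplacian with zero-flux (mirror) boundaries."""
    out = np.zeros_like(f)
    inv_h2 = 1.0 / (h * h)
    d = np.diff(f, axis=0) * inv_h2
    out[:-1, :] += d
    out[1:, :] -= d
    d = np.diff(f, axis=1) * inv_h2
    out[:, :-1] += d
    out[:, 1:] -= d
    return out


def environment_rhs(
    v: np.ndarray,
    n: np.ndarray,
    a: np.ndarray,
    w_B: np.ndarray,
    w_H: np.ndarray,
    rho: np.ndarray,
    dose: tuple[float, float],
    grid: GridSpec,
    params: EnvironmentParams,
):
    """Time derivatives (dv, dn, da, dw_B, dw_H) of the environment fields."""
    p = params
    fields = {"v": v, "n": n, "a": a, "w_B": w_B, "w_H": w_H, "rho": rho}
    for name, f in fields.items():
        if np.any(np.asarray(f) < 0):
            raise ContractViolationError(f"environment field {name} contains negative values")
    dose_B, dose_H = dose
    if dose_B < 0 or dose_H < 0:
        raise ContractViolationError("dose rates must be nonnegative")
    h = grid.dx
    dv = p.r_v * v * (1.0 - v / p.v_max) - p.lam_av * a * v - p.lam_v * v
    dn = p.D_n * neumann_laplacian(n, h) + p.alpha_n * v - (p.beta_n * rho + p.lam_n) * n
    da = p.D_a * neumann_laplacian(a, h) + p.alpha_a * rho - p.lam_a * a
    dwB = p.D_w * neumann_laplacian(w_B, h) + dose_B - (p.lam_w + p.eps_w * rho) * w_B
    dwH = p.D_w * neumann_laplacian(w_H, h) + dose_H - (p.lam_w + p.eps_w * rho) * w_H
    return dv, dn, da, dwB, dwH


def nutrient_equilibrium(v: np.ndarray, rho: np.ndarray, params: EnvironmentParams) -> np.ndarray:
    """Pointwise nutrient fixed point n* = alpha_n v / (beta_n rho + lam_n)."""
    denom = params.beta_n * rho + params.lam_n
    return np.where(denom > 0, params.alpha_n * v / np.where(denom > 0, denom, 1.0), 0.0)
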