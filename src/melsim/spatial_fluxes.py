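"""Spatial transport of the cell density: diffusion, chemotaxis, haptotaxis.

Cells random-walk through the tissue (undirected diffusion, throttled by a
volume-filling factor as the local total density approaches the crowding
capacity) and migrate up gradients of the diffusible nutrient (chemotaxis)
and of the immobile extracellular nutritional environment, ECNE
(haptotaxis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ContractViolationError
from .geometry import GridSpec


@dataclass(frozen=True)
class SpatialFluxParams:
    """Motility parameters (space^2/day for D_x; space^2/day per unit field
    for the taxis sensitivities; cells/space^2 for the crowding capacity)."""

    D_x: float = 5.0e-5
    chi_n: float = 5.0e-4
    chi_v: float = 5.0e-4
    rho_max: float = 100.0
    volume_filling: str = "diffusion"  # where the (1 - rho/rho_max)+ factor acts

    def __post_init__(self):
        for key in ("D_x", "chi_n", "chi_v"):
            if getattr(self, key) < 0:
                raise ConfigurationError(f"spatial_fluxes.{key} must be >= 0")
        if not self.rho_max > 0:
            raise ConfigurationError("spatial_fluxes.rho_max must be > 0")
        if self.volume_filling not in ("diffusion", "taxis", "both"):
            raise ConfigurationError(
                "spatial_fluxes.volume_filling must be one of diffusion|taxis|both"
            )


class SpatialOperator:
    """Spatial transport divergence on arrays whose two *leading* axes are
    the spatial grid; trailing structural axes broadcast."""

    def __init__(self, grid: GridSpec, params: SpatialFluxParams):
        self.grid = grid
        self.params = params
        self.inv_dx = 1.0 / grid.dx

    def face_fields(self, n: np.ndarray, v: np.ndarray, rho: np.ndarray):
        """Per-face mobility factors and taxis velocities from the current
        2D environment fields; recomputed once per right-hand-side call."""
        p = self.params
        dx = self.inv_dx
        phi = np.maximum(1.0 - rho / p.rho_max, 0.0)
        phi1 = 0.5 * (phi[:-1, :] + phi[1:, :])  # faces along axis 0
        phi2 = 0.5 * (phi[:, :-1] + phi[:, 1:])  # faces along axis 1
        u1 = p.chi_n * (n[1:, :] - n[:-1, :]) * dx + p.chi_v * (v[1:, :] - v[:-1, :]) * dx
        u2 = p.chi_n * (n[:, 1:] - n[:, :-1]) * dx + p.chi_v * (v[:, 1:] - v[:, :-1]) * dx
        if p.volume_filling in ("taxis", "both"):
            u1 = u1 * phi1
            u2 = u2 * phi2
        if p.volume_filling == "taxis":
            phi1 = np.ones_like(phi1)
            phi2 = np.ones_like(phi2)
        return phi1, phi2, u1, u2

    def divergence(self, c, phi1, phi2, u1, u2) -> np.ndarray:
        """-d/dx . F_x with F_x = -D_x phi grad c + c u, zero-flux walls."""
        p = self.params
        dx = self.inv_dx
        extra = c.ndim - 2  # trailing structural axes
        idx = (...,) + (None,) * extra

        out = np.zeros_like(c)
        # axis 0 faces
        cl = c[:-1, ...]
        cr = c[1:, ...]
        flux = (
            np.maximum(u1, 0.0)[idx] * cl
            + np.minimum(u1, 0.0)[idx] * cr
            - (p.D_x * phi1)[idx] * (cr - cl) * dx
        )
        out[:-1, ...] -= flux * dx
        out[1:, ...] += flux * dx
        # axis 1 faces
        cl = c[:, :-1, ...]
        cr = c[:, 1:, ...]
        idx1 = (slice(None), slice(None)) + (None,) * extra
        flux = (
            np.maximum(u2, 0.0)[idx1] * cl
            + np.minimum(u2, 0.0)[idx1] * cr
            - (p.D_x * phi2)[idx1] * (cr - cl) * dx
        )
        out[:, :-1, ...] -= flux * dx
        out[:, 1:, ...] += flux * dx
        return out


def spatial_transport_divergence(
    c_slice: np.ndarray,
    n: np.ndarray,
    v: np.ndarray,
    rho: np.ndarray,
    grid: GridSpec,
    params: SpatialFluxParams,
) -> np.ndarray:
    """Conservative spatial transport divergence for one structural slice.

    Upwind taxis, central diffusion with the volume-filling factor averaged
    onto faces, zero-flux boundaries; output sums to zero.
    """
    c_slice = np.asarray(c_slice, dtype=float)
    shape = (grid.n_spatial, grid.n_spatial)
    for name, f in (("n", n), ("v", v), ("rho", rho)):
        if np.asarray(f).shape != shape:
            raise ContractViolationError(f"field {name} has shape {np.asarray(f).shape}, expected {shape}")
    if c_slice.shape[:2] != shape:
        raise ContractViolationError(f"c slice leading shape {c_slice.shape[:2]} != {shape}")
    if np.any(c_slice < 0):
        raise ContractViolationError("spatial slice contains negative density")
    op = SpatialOperator(grid, params)
    return op.divergence(c_slice, *op.face_fields(np.asarray(n, float), np.asarray(v, float), np.asarray(rho, float)))
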