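"""Cell-state (structural) advection and diffusion fluxes.

Deterministic state changes are modelled as a horizontal advection field
that relaxes the first structural coordinate onto an attractor line
interpolating between the proliferative and SMC anchors: naive cells are
held at the proliferative state in the south, while cells driven north
are funnelled onto the minimally mitotic SMC state.  Random state changes
are modelled as anisotropic Fickian diffusion whose horizontal component
grows linearly from south to north (rare proliferative<->URC transitions,
frequent exchanges among northern states) and whose vertical component is
parabolic in the horizontal coordinate, maximal at the west/east edges
(proliferative<->pigmented and invasive/URC<->NCSC routes) and minimal in
the center (slow SMC<->south exchange).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ContractViolationError
from .geometry import GridSpec, SubpopulationAtlas, _check_inside


@dataclass(frozen=True)
class StructuralFluxParams:
    """Rates of the structural advection/diffusion fields (per day)."""

    k_adv: float = 1.5e-3
    d_h_min: float = 1.0e-5
    d_h_max: float = 5.0e-4
    d_v_min: float = 1.0e-5
    d_v_max: float = 7.0e-4

    def __post_init__(self):
        for key in ("k_adv", "d_h_min", "d_h_max", "d_v_min", "d_v_max"):
            if getattr(self, key) < 0:
                raise ConfigurationError(f"structural_fluxes.{key} must be >= 0")
        if self.d_h_max < self.d_h_min:
            raise ConfigurationError("structural_fluxes: d_h_max < d_h_min")
        if self.d_v_max < self.d_v_min:
            raise ConfigurationError("structural_fluxes: d_v_max < d_v_min")


def attractor_abscissa(y2, atlas: SubpopulationAtlas):
    """Horizontal position a(y2) the advection relaxes to.

    Linear interpolation between the proliferative abscissa at the south
    edge (y2=0) and the SMC abscissa at the north edge (y2=1), scaled to
    the structural extent.
    """
    y2 = np.asarray(y2, dtype=float)
    s = y2 / atlas.extent
    y1_p = atlas.position("proliferative")[0]
    y1_smc = atlas.position("SMC")[0]
    return (1.0 - s) * y1_p + s * y1_smc


def advection_field(y, atlas: SubpopulationAtlas, params: StructuralFluxParams) -> np.ndarray:
    """Structural drift Phi(y) = (-k_adv * (y1 - a(y2)), 0)."""
    y = _check_inside(y, atlas.extent)
    a = attractor_abscissa(y[..., 1], atlas)
    u1 = -params.k_adv * (y[..., 0] - a)
    return np.stack([u1, np.zeros_like(u1)], axis=-1)


def horizontal_diffusivity(y2, params: StructuralFluxParams, extent: float = 1.0):
    """D_h(y2): linear increase from d_h_min (south) to d_h_max (north)."""
    s = np.asarray(y2, dtype=float) / extent
    return params.d_h_min + (params.d_h_max - params.d_h_min) * s


def vertical_diffusivity(y1, params: StructuralFluxParams, extent: float = 1.0):
    """D_v(y1): parabola, maximal at the west/east edges, minimal centrally."""
    s = np.asarray(y1, dtype=float) / extent
    return params.d_v_min + (params.d_v_max - params.d_v_min) * (2.0 * s - 1.0) ** 2


def structural_diffusivity(y, params: StructuralFluxParams, extent: float = 1.0) -> np.ndarray:
    """Diagonal diffusion tensor diag(D_h(y2), D_v(y1)) at a structural point."""
    y = _check_inside(y, extent)
    dh = horizontal_diffusivity(y[..., 1], params, extent)
    dv = vertical_diffusivity(y[..., 0], params, extent)
    return np.stack([dh, dv], axis=-1)


class StructuralOperator:
    """Precomputed face coefficients for the structural transport divergence.

    Operates on arrays whose two *trailing* axes are the structural grid,
    so the same operator serves a single slice ``(ny, ny)`` or the full 4D
    density ``(nx, nx, ny, ny)`` by broadcasting.
    """

    def __init__(self, grid: GridSpec, atlas: SubpopulationAtlas, params: StructuralFluxParams):
        self.grid = grid
        self.params = params
        dy = grid.dy
        yc = grid.y_centers
        yf = grid.y_faces
        # Advection: horizontal only; upwind velocities at y1-faces, (ny-1, ny).
        a = attractor_abscissa(yc, atlas)  # (ny,) over y2
        u = -params.k_adv * (yf[:, None] - a[None, :])
        self.u_plus = np.maximum(u, 0.0)
        self.u_minus = np.minimum(u, 0.0)
        # Diffusion: D_h on y1-faces depends only on y2 -> (1, ny);
        # D_v on y2-faces depends only on y1 -> (ny, 1).
        self.dh_face = horizontal_diffusivity(yc, params, grid.structural_extent)[None, :]
        self.dv_face = vertical_diffusivity(yc, params, grid.structural_extent)[:, None]
        self.inv_dy = 1.0 / dy

    def divergence(self, c: np.ndarray) -> np.ndarray:
        """-d/dy . (c Phi - D_y grad c), zero-flux boundaries."""
        dy = self.inv_dy
        out = np.zeros_like(c)
        # --- y1 (axis -2): upwind advection + central diffusion ---
        cl = c[..., :-1, :]
        cr = c[..., 1:, :]
        flux = self.u_plus * cl + self.u_minus * cr - self.dh_face * (cr - cl) * dy
        out[..., :-1, :] -= flux * dy
        out[..., 1:, :] += flux * dy
        # --- y2 (axis -1): diffusion only ---
        dflux = -self.dv_face * (c[..., 1:] - c[..., :-1]) * dy
        out[..., :-1] -= dflux * dy
        out[..., 1:] += dflux * dy
        return out


def structural_transport_divergence(
    c_xy: np.ndarray,
    grid: GridSpec,
    atlas: SubpopulationAtlas,
    params: StructuralFluxParams,
) -> np.ndarray:
    """Conservative divergence of the structural fluxes for one slice.

    First-order upwind advection, central diffusion with face-averaged
    diffusivity, zero-flux boundaries; the output integrates to zero over
    the slice up to round-off.
    """
    c_xy = np.asarray(c_xy, dtype=float)
    if np.any(c_xy < 0):
        raise ContractViolationError("structural slice contains negative density")
    return StructuralOperator(grid, atlas, params).divergence(c_xy)
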