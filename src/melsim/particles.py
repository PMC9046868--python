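"""Monte Carlo particle counterpart of the PDE, used as a verification oracle.

Each particle carries a spatial position, a structural state and a weight.
States follow the Ito SDE

    dY = [Phi(Y) + div_y D_y(Y)] dt + sqrt(2 D_y(Y)) dW,

whose law solves the divergence-form (Fickian) diffusion-advection
equation used by the grid solver; the div D drift correction is computed
by central finite differences of the diffusivity profiles, so the oracle
stays correct for any configured profile.  Spatial motion is analogous,
with taxis velocities interpolated from frozen environment fields
(one-way coupling: the oracle never feeds back onto the environment).
Boundaries reflect, mirroring the solver's zero-flux condition.  Optional
birth/death multiplies weights by exp(rate * dt).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .errors import ConfigurationError, ContractViolationError, MetricUndefinedError
from .geometry import GridSpec
from .solver import SolverOperators, initial_state, stable_dt
from .structural_fluxes import (
    StructuralFluxParams,
    attractor_abscissa,
    horizontal_diffusivity,
    vertical_diffusivity,
)


@dataclass
class ParticleEnsemble:
    """Weighted particle cloud at one instant."""

    positions: np.ndarray  # (n, 2) spatial
    states: np.ndarray     # (n, 2) structural
    weights: np.ndarray    # (n,)
    seed: int
    t: float

    def __post_init__(self):
        if np.any(self.weights < 0):
            raise ContractViolationError("particle weights must be nonnegative")


def _reflect(x: np.ndarray, extent: float) -> np.ndarray:
    """Reflect coordinates into [0, extent] (handles multiple bounces)."""
    period = 2.0 * extent
    x = np.mod(x, period)
    return np.where(x > extent, period - x, x)


def _div_d_correction(y: np.ndarray, params: StructuralFluxParams, extent: float, eps: float = 1e-6):
    """(d/dy1 D_h, d/dy2 D_v) by central differences (zero for the default
    profiles, where each diagonal entry depends on the *other* coordinate)."""
    y1 = y[:, 0]
    y2 = y[:, 1]
    lo1 = np.clip(y1 - eps, 0, extent)
    hi1 = np.clip(y1 + eps, 0, extent)
    lo2 = np.clip(y2 - eps, 0, extent)
    hi2 = np.clip(y2 + eps, 0, extent)
    dh = (_dh_at(hi1, y2, params, extent) - _dh_at(lo1, y2, params, extent)) / (hi1 - lo1)
    dv = (_dv_at(y1, hi2, params, extent) - _dv_at(y1, lo2, params, extent)) / (hi2 - lo2)
    return np.stack([dh, dv], axis=-1)


def _dh_at(y1, y2, params, extent):
    return horizontal_diffusivity(y2, params, extent)


def _dv_at(y1, y2, params, extent):
    return vertical_diffusivity(y1, params, extent)


def simulate_particles(
    config,
    n_particles: int,
    seed: int,
    t_end: float = 5.0,
    dt: float | None = None,
    with_spatial: bool = True,
    with_sources: bool = False,
    record_every: int | None = None,
):
    """Euler-Maruyama particle run under a scenario configuration.

    Environment fields are frozen at their initial values.  Returns the
    final :class:`ParticleEnsemble` (or a list of ensembles if
    ``record_every`` is set).
    """
    from .config import as_scenario

    if n_particles < 1:
        raise ConfigurationError("n_particles must be >= 1")
    scn = as_scenario(config)
    grid = scn.grid()
    atlas = scn.atlas()
    params = scn.model_params()
    sp = params.structural
    ext_y = grid.structural_extent
    ext_x = grid.spatial_extent

    max_stable = stable_dt(params, grid, safety=1.0)
    if dt is None:
        dt = 0.5 * max_stable
    if dt > max_stable:
        raise ConfigurationError(
            f"particle step {dt} exceeds the stability bound {max_stable:.3g}"
        )

    rng = np.random.default_rng(seed)
    ic = scn.section("initial_condition")
    center = np.asarray(ic["spatial_center"], dtype=float)
    _yc = ic.get("structural_center")
    yp = atlas.position("proliferative") if _yc is None else np.asarray(_yc, dtype=float)
    X = rng.normal(center, ic["spatial_sigma"], size=(n_particles, 2))
    Y = rng.normal(yp, ic["structural_sigma"], size=(n_particles, 2))
    X = _reflect(X, ext_x)
    Y = _reflect(Y, ext_y)
    W = np.full(n_particles, float(ic["mass"]) / n_particles)

    # frozen environment (initial condition of the PDE run)
    state0 = initial_state(grid, atlas, params, ic)
    xc = grid.x_centers
    taxis = None
    if with_spatial and (params.spatial.chi_n > 0 or params.spatial.chi_v > 0):
        field = params.spatial.chi_n * state0.n + params.spatial.chi_v * state0.v
        g1, g2 = np.gradient(field, xc, xc)
        taxis = (
            RegularGridInterpolator((xc, xc), g1, bounds_error=False, fill_value=None),
            RegularGridInterpolator((xc, xc), g2, bounds_error=False, fill_value=None),
        )
    source_rate = None
    if with_sources:
        ops = SolverOperators(grid, atlas, params)
        gn = state0.n / (params.growth.n_half + state0.n)
        rate_xy = RegularGridInterpolator((xc, xc), gn, bounds_error=False, fill_value=None)
        yc = grid.y_centers
        rate_y = RegularGridInterpolator((yc, yc), ops.P, bounds_error=False, fill_value=None)
        source_rate = (rate_xy, rate_y)

    out = []
    t = 0.0
    nsteps = int(round(t_end / dt))
    for istep in range(nsteps):
        # structural drift + diffusion
        a = attractor_abscissa(Y[:, 1], atlas)
        drift = np.zeros_like(Y)
        drift[:, 0] = -sp.k_adv * (Y[:, 0] - a)
        drift += _div_d_correction(Y, sp, ext_y)
        dh = horizontal_diffusivity(Y[:, 1], sp, ext_y)
        dv = vertical_diffusivity(Y[:, 0], sp, ext_y)
        noise = rng.standard_normal(Y.shape)
        Y = Y + drift * dt + np.sqrt(2 * dt) * np.stack(
            [np.sqrt(dh), np.sqrt(dv)], axis=-1
        ) * noise
        Y = _reflect(Y, ext_y)
        # spatial diffusion + frozen taxis
        if with_spatial:
            xdrift = np.zeros_like(X)
            if taxis is not None:
                xdrift[:, 0] = taxis[0](X)
                xdrift[:, 1] = taxis[1](X)
            xnoise = rng.standard_normal(X.shape)
            X = X + xdrift * dt + np.sqrt(2 * params.spatial.D_x * dt) * xnoise
            X = _reflect(X, ext_x)
        if source_rate is not None:
            rate = source_rate[0](X) * source_rate[1](Y)
            W = W * np.exp(rate * dt)
        t += dt
        if record_every and (istep + 1) % record_every == 0:
            out.append(ParticleEnsemble(X.copy(), Y.copy(), W.copy(), seed, t))

    final = ParticleEnsemble(X, Y, W, seed, t)
    if record_every:
        if not out or out[-1].t != t:
            out.append(final)
        return out
    return final


def histogram_density(ensemble: ParticleEnsemble, grid: GridSpec, structural_only: bool = False):
    """Bin the weighted ensemble onto the grid as a density."""
    if structural_only:
        edges = np.linspace(0, grid.structural_extent, grid.n_structural + 1)
        h, _, _ = np.histogram2d(
            ensemble.states[:, 0], ensemble.states[:, 1], bins=(edges, edges),
            weights=ensemble.weights,
        )
        return h / grid.structural_cell_area
    ex = np.linspace(0, grid.spatial_extent, grid.n_spatial + 1)
    ey = np.linspace(0, grid.structural_extent, grid.n_structural + 1)
    sample = np.hstack([ensemble.positions, ensemble.states])
    h, _ = np.histogramdd(sample, bins=(ex, ex, ey, ey), weights=ensemble.weights)
    return h / grid.cell_volume_4d


def density_distance(
    ensemble: ParticleEnsemble,
    pde_density: np.ndarray,
    grid: GridSpec,
) -> float:
    """Total-variation distance between the normalized particle histogram
    and the normalized PDE density (0 identical, 1 disjoint)."""
    pde = np.asarray(pde_density, dtype=float)
    structural_only = pde.ndim == 2
    hist = histogram_density(ensemble, grid, structural_only=structural_only)
    if hist.shape != pde.shape:
        raise ContractViolationError(f"histogram shape {hist.shape} != density shape {pde.shape}")
    wsum = hist.sum()
    psum = pde.sum()
    if wsum <= 0 or psum <= 0:
        raise MetricUndefinedError("total-variation distance undefined for zero mass")
    return float(0.5 * np.abs(hist / wsum - pde / psum).sum())
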