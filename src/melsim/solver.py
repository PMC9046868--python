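"""Time integration of the coupled cell-density / environment system.

The cell density ``c(t, x, y)`` obeys a 4D continuity equation

    dc/dt = -div_x F_x - div_y F_y + S,

with spatial fluxes (diffusion + chemo/haptotaxis), structural fluxes
(state advection + anisotropic state diffusion) and a source term
combining nutrient-limited, crowding-limited proliferation with
drug-induced death.  Five 2D environment fields (ECNE, nutrient, acid,
two drugs) evolve alongside.  Integration is explicit second-order Heun
with a global stability-limited step; negative values produced by the
scheme are clipped to zero and the clipped mass is logged, keeping the
run auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .environment import EnvironmentParams, environment_rhs, nutrient_equilibrium
from .errors import ConfigurationError, ContractViolationError, IntegrationError
from .geometry import GridSpec, SubpopulationAtlas
from .spatial_fluxes import SpatialFluxParams, SpatialOperator
from .structural_fluxes import StructuralFluxParams, StructuralOperator
from .treatment import (
    TreatmentSchedule,
    adaptive_decision,
    default_response_params,
    dose_schedule,
    drug_response,
)


@dataclass(frozen=True)
class GrowthParams:
    """Proliferation profile over the cell-state plane.

    Growth peaks at the proliferative anchor (Gaussian bump of width
    sigma_P), is suppressed near the starved-like SMC state (depth
    smc_suppression, width sigma_S) and saturates in nutrient with
    half-saturation n_half.  Treatment is the only cause of active death.
    """

    p_max: float = 0.12
    sigma_P: float = 0.75
    smc_suppression: float = 0.9
    sigma_S: float = 0.5
    n_half: float = 0.35

    def __post_init__(self):
        for key in self.__dataclass_fields__:
            if getattr(self, key) < 0:
                raise ConfigurationError(f"source.{key} must be >= 0")
        if self.smc_suppression > 1:
            raise ConfigurationError("source.smc_suppression must be <= 1")
        if not (self.sigma_P > 0 and self.sigma_S > 0):
            raise ConfigurationError("source widths must be > 0")


@dataclass(frozen=True)
class ModelParams:
    """All rate constants of the model, grouped by mechanism."""

    structural: StructuralFluxParams = field(default_factory=StructuralFluxParams)
    spatial: SpatialFluxParams = field(default_factory=SpatialFluxParams)
    environment: EnvironmentParams = field(default_factory=EnvironmentParams)
    growth: GrowthParams = field(default_factory=GrowthParams)
    response: dict = field(default_factory=default_response_params)


@dataclass
class FieldState:
    """Full simulation state at one instant."""

    t: float
    c: np.ndarray      # (nx, nx, ny, ny)
    v: np.ndarray      # ECNE
    n: np.ndarray      # nutrient
    a: np.ndarray      # acid
    w_B: np.ndarray    # BRAF/MEKi concentration
    w_H: np.ndarray    # HCT concentration
    treatment_on: bool = False

    def validate(self, grid: GridSpec):
        shapes = {
            "c": (grid.n_spatial, grid.n_spatial, grid.n_structural, grid.n_structural),
            "v": (grid.n_spatial, grid.n_spatial),
            "n": (grid.n_spatial, grid.n_spatial),
            "a": (grid.n_spatial, grid.n_spatial),
            "w_B": (grid.n_spatial, grid.n_spatial),
            "w_H": (grid.n_spatial, grid.n_spatial),
        }
        for name, shape in shapes.items():
            f = getattr(self, name)
            if f.shape != shape:
                raise ContractViolationError(f"field {name} shape {f.shape} != {shape}")
            if not np.all(np.isfinite(f)):
                raise IntegrationError(f"field {name} contains non-finite values at t={self.t}")
            if np.any(f < 0):
                raise ContractViolationError(f"field {name} negative at t={self.t}")

    def copy(self) -> "FieldState":
        return FieldState(
            t=self.t,
            c=self.c.copy(), v=self.v.copy(), n=self.n.copy(), a=self.a.copy(),
            w_B=self.w_B.copy(), w_H=self.w_H.copy(), treatment_on=self.treatment_on,
        )


@dataclass
class Trajectory:
    """Recorded output of one simulation run."""

    times: np.ndarray
    mass: np.ndarray
    dose_B: np.ndarray
    dose_H: np.ndarray
    treatment_on: np.ndarray       # bool per recorded time
    clipped_mass: np.ndarray       # mass removed by positivity clipping, per step
    snapshot_times: np.ndarray
    snapshots: list
    config: dict = field(default_factory=dict)
    config_hash: str = ""

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise ContractViolationError("trajectory times must be strictly increasing")
        if np.any(self.mass < 0):
            raise ContractViolationError("trajectory mass must be nonnegative")


def growth_profile(grid: GridSpec, atlas: SubpopulationAtlas, growth: GrowthParams) -> np.ndarray:
    """P(y) on the structural grid: proliferative bump x SMC suppression."""
    y1, y2 = grid.structural_mesh()
    yp = atlas.position("proliferative")
    ys = atlas.position("SMC")
    d2p = (y1 - yp[0]) ** 2 + (y2 - yp[1]) ** 2
    d2s = (y1 - ys[0]) ** 2 + (y2 - ys[1]) ** 2
    bump = np.exp(-d2p / (2.0 * growth.sigma_P**2))
    supp = 1.0 - growth.smc_suppression * np.exp(-d2s / (2.0 * growth.sigma_S**2))
    return growth.p_max * bump * supp


def total_density(c: np.ndarray, grid: GridSpec) -> np.ndarray:
    """rho(x): cell density integrated over the structural plane."""
    return c.sum(axis=(2, 3)) * grid.structural_cell_area


class SolverOperators:
    """Static precomputed arrays shared by every right-hand-side call.

    The cell-density right-hand side runs through a fused compiled kernel
    when numba is available (``use_fused=True``, the default) and through
    the composable numpy operators otherwise; both paths are assembled
    from identical face coefficients and agree to round-off.
    """

    def __init__(
        self,
        grid: GridSpec,
        atlas: SubpopulationAtlas,
        params: ModelParams,
        use_fused: bool = True,
    ):
        from ._kernels import HAVE_NUMBA

        self.grid = grid
        self.atlas = atlas
        self.params = params
        self.use_fused = use_fused and HAVE_NUMBA
        self.structural = StructuralOperator(grid, atlas, params.structural)
        self.spatial = SpatialOperator(grid, params.spatial)
        self.P = growth_profile(grid, atlas, params.growth)  # (ny, ny)
        y1, y2 = grid.structural_mesh()
        pts = np.stack([y1, y2], axis=-1)
        self.psi_B = drug_response(pts, "BRAF_MEKi", atlas, params.response)
        self.psi_H = drug_response(pts, "HCT", atlas, params.response)
        self.delta_B = params.response["BRAF_MEKi"].delta
        self.delta_H = params.response["HCT"].delta
        # 1D face diffusivities for the fused kernel
        yc = grid.y_centers
        from .structural_fluxes import horizontal_diffusivity, vertical_diffusivity

        self._dh_1d = np.ascontiguousarray(
            horizontal_diffusivity(yc, params.structural, grid.structural_extent)
        )
        self._dv_1d = np.ascontiguousarray(
            vertical_diffusivity(yc, params.structural, grid.structural_extent)
        )
        self._dc_buf = np.empty(
            (grid.n_spatial, grid.n_spatial, grid.n_structural, grid.n_structural)
        )

    def _dc_dt(self, state: FieldState, rho: np.ndarray) -> np.ndarray:
        p = self.params
        gn = state.n / (p.growth.n_half + state.n)
        room = np.maximum(1.0 - rho / p.spatial.rho_max, 0.0)
        grow = gn * room
        phi1, phi2, u1, u2 = self.spatial.face_fields(state.n, state.v, rho)
        if self.use_fused:
            from ._kernels import rhs_cell_density

            return rhs_cell_density(
                state.c,
                self._dc_buf,
                self.structural.u_plus,
                self.structural.u_minus,
                self._dh_1d,
                self._dv_1d,
                self.structural.inv_dy,
                np.maximum(u1, 0.0),
                np.minimum(u1, 0.0),
                p.spatial.D_x * phi1,
                np.maximum(u2, 0.0),
                np.minimum(u2, 0.0),
                p.spatial.D_x * phi2,
                self.spatial.inv_dx,
                grow,
                self.delta_B * state.w_B,
                self.delta_H * state.w_H,
                self.P,
                self.psi_B,
                self.psi_H,
            ).copy()
        c = state.c
        dc = self.structural.divergence(c)
        dc += self.spatial.divergence(c, phi1, phi2, u1, u2)
        dc += grow[:, :, None, None] * self.P[None, None, :, :] * c
        kill = (self.delta_B * state.w_B)[:, :, None, None] * self.psi_B[None, None, :, :]
        kill += (self.delta_H * state.w_H)[:, :, None, None] * self.psi_H[None, None, :, :]
        dc -= kill * c
        return dc

    def rhs(self, state: FieldState, dose: tuple[float, float]):
        """Time derivatives of all six fields."""
        rho = total_density(state.c, self.grid)
        dc = self._dc_dt(state, rho)
        denv = environment_rhs(
            state.v, state.n, state.a, state.w_B, state.w_H, rho, dose,
            self.grid, self.params.environment,
        )
        return (dc,) + denv


def reaction_source(
    c: np.ndarray,
    n: np.ndarray,
    w_B: np.ndarray,
    w_H: np.ndarray,
    grid: GridSpec,
    atlas: SubpopulationAtlas,
    params: ModelParams,
) -> np.ndarray:
    """Source term S = proliferation - drug-induced death (4D array)."""
    for name, f in (("c", c), ("n", n), ("w_B", w_B), ("w_H", w_H)):
        if np.any(np.asarray(f) < 0):
            raise ContractViolationError(f"reaction_source input {name} is negative")
    ops = SolverOperators(grid, atlas, params)
    rho = total_density(c, grid)
    gn = n / (params.growth.n_half + n)
    room = np.maximum(1.0 - rho / params.spatial.rho_max, 0.0)
    src = (gn * room)[:, :, None, None] * ops.P[None, None, :, :] * c
    kill = (ops.delta_B * w_B)[:, :, None, None] * ops.psi_B[None, None, :, :]
    kill += (ops.delta_H * w_H)[:, :, None, None] * ops.psi_H[None, None, :, :]
    return src - kill * c


def stable_dt(
    params: ModelParams,
    grid: GridSpec,
    safety: float = 0.8,
    schedule: TreatmentSchedule | None = None,
    max_dt: float = 0.25,
) -> float:
    """Stability-limited explicit step (days).

    Mechanism bounds (spatial/structural diffusion, advection CFL, fastest
    linear rate) are combined harmonically — the combined step is never
    larger than the smallest individual bound, which keeps the sum of the
    operators stable rather than each one separately.
    """
    if not (0 < safety <= 1):
        raise ConfigurationError(f"safety factor must lie in (0, 1], got {safety}")
    p = params
    inv = 0.0
    # spatial diffusion (cells + fastest environment species)
    d_sp = max(p.spatial.D_x, p.environment.D_n, p.environment.D_a, p.environment.D_w)
    if d_sp > 0:
        inv += 4.0 * d_sp / grid.dx**2
    # structural diffusion
    d_st = p.structural.d_h_max + p.structural.d_v_max
    if d_st > 0:
        inv += 2.0 * d_st / grid.dy**2
    # structural advection CFL: |u1| = k_adv |y1 - a(y2)| <= k_adv * extent
    vmax_y = p.structural.k_adv * grid.structural_extent
    if vmax_y > 0:
        inv += vmax_y / grid.dy
    # spatial taxis CFL (gradient scale ~4/extent of the field amplitudes)
    n_ref = p.environment.alpha_n * p.environment.v_max / max(p.environment.lam_n, 1e-12)
    v_tax = 4.0 * (p.spatial.chi_n * n_ref + p.spatial.chi_v * p.environment.v_max)
    v_tax /= grid.spatial_extent
    if v_tax > 0:
        inv += v_tax / grid.dx
    # fastest linear reaction/decay rate
    env = p.environment
    w_ref = 0.0
    if schedule is not None and schedule.mode != "none":
        dmax = max(schedule.dose_rate.values(), default=0.0)
        w_ref = dmax / max(env.lam_w, 1e-12)
    kill_max = w_ref * max(p.response["BRAF_MEKi"].delta, p.response["HCT"].delta)
    rate_max = max(
        p.growth.p_max,
        env.lam_n + env.beta_n * p.spatial.rho_max,
        env.lam_a,
        env.lam_w + env.eps_w * p.spatial.rho_max,
        env.r_v + env.lam_v + env.lam_av * env.alpha_a * p.spatial.rho_max / max(env.lam_a, 1e-12),
        kill_max,
    )
    inv += rate_max
    if inv == 0.0:
        return max_dt
    return min(safety / inv, max_dt)


def heun_step(
    state: FieldState,
    dt: float,
    ops: SolverOperators,
    dose: tuple[float, float],
):
    """One explicit Heun step; returns (new_state, clipped_mass)."""
    fields = ("c", "v", "n", "a", "w_B", "w_H")
    u = [getattr(state, f) for f in fields]
    k1 = ops.rhs(state, dose)
    pred = FieldState(
        state.t + dt,
        *[np.maximum(ui + dt * ki, 0.0) for ui, ki in zip(u, k1)],
        treatment_on=state.treatment_on,
    )
    k2 = ops.rhs(pred, dose)
    new = [ui + 0.5 * dt * (k1i + k2i) for ui, k1i, k2i in zip(u, k1, k2)]
    # positivity clipping with mass audit on the 4D density
    neg = np.minimum(new[0], 0.0)
    clipped = -neg.sum() * ops.grid.cell_volume_4d
    out = FieldState(
        state.t + dt,
        *[np.maximum(f, 0.0) for f in new],
        treatment_on=dose[0] + dose[1] > 0,
    )
    for name, f in zip(fields, (out.c, out.v, out.n, out.a, out.w_B, out.w_H)):
        if not np.all(np.isfinite(f)):
            bad = np.argwhere(~np.isfinite(f))[0]
            raise IntegrationError(
                f"non-finite value in field {name} at index {tuple(bad)}, t={out.t:.4f}"
            )
    return out, float(clipped)


def step(
    state: FieldState,
    dt: float,
    grid: GridSpec,
    atlas: SubpopulationAtlas,
    schedule: TreatmentSchedule,
    params: ModelParams,
    ops: SolverOperators | None = None,
    adaptive_state: bool = True,
) -> FieldState:
    """Advance the full state by one step (dose held constant over the step)."""
    if ops is None:
        ops = SolverOperators(grid, atlas, params)
    dose = dose_schedule(state.t, schedule, adaptive_state)
    new, _ = heun_step(state, dt, ops, dose)
    return new


def initial_state(
    grid: GridSpec,
    atlas: SubpopulationAtlas,
    params: ModelParams,
    ic: dict | None = None,
) -> FieldState:
    """Naive tumor: spatial Gaussian at the domain center, structural
    Gaussian at the proliferative anchor; ECNE dented under the tumor,
    nutrient at its local equilibrium, no acid, no drug."""
    ic = dict(ic or {})
    mass = float(ic.get("mass", 1.0))
    center = tuple(ic.get("spatial_center", (0.5 * grid.spatial_extent,) * 2))
    sx = float(ic.get("spatial_sigma", 0.1))
    sy = float(ic.get("structural_sigma", 0.06))
    dip = float(ic.get("ecne_dip", 0.5))
    if mass <= 0 or sx <= 0 or sy <= 0 or not (0 <= dip <= 1):
        raise ConfigurationError("invalid initial_condition settings")
    _yc = ic.get("structural_center")
    yp = atlas.position("proliferative") if _yc is None else np.asarray(_yc, dtype=float)

    def cell_avg_gauss(n_cells, h, mu, sigma):
        # exact Gaussian mass per cell (finite-volume average, not a
        # center-point sample) via the error function
        faces = np.arange(n_cells + 1) * h
        cdf = 0.5 * (1.0 + erf((faces - mu) / (sigma * np.sqrt(2.0))))
        return np.diff(cdf) / h

    gx1 = cell_avg_gauss(grid.n_spatial, grid.dx, center[0], sx)
    gx2 = cell_avg_gauss(grid.n_spatial, grid.dx, center[1], sx)
    gy1 = cell_avg_gauss(grid.n_structural, grid.dy, yp[0], sy)
    gy2 = cell_avg_gauss(grid.n_structural, grid.dy, yp[1], sy)
    gx = np.outer(gx1, gx2)
    gy = np.outer(gy1, gy2)
    c = gx[:, :, None, None] * gy[None, None, :, :]
    total = c.sum() * grid.cell_volume_4d
    c *= mass / total
    env = params.environment
    v = env.v_max * (1.0 - dip * gx / gx.max())
    rho = total_density(c, grid)
    n = nutrient_equilibrium(v, rho, env)
    zeros = np.zeros_like(v)
    return FieldState(t=0.0, c=c, v=v, n=n, a=zeros.copy(), w_B=zeros.copy(), w_H=zeros.copy())


def simulate(config) -> Trajectory:
    """Run a scenario from t=0 to the horizon and record its trajectory.

    ``config`` is a ScenarioConfig or a plain config dict (see
    :mod:`melsim.config`); the run is fully deterministic.
    """
    from .config import as_scenario

    scn = as_scenario(config)
    grid = scn.grid()
    atlas = scn.atlas()
    params = scn.model_params()
    schedule = scn.schedule()
    run = scn.section("run")
    ops = SolverOperators(grid, atlas, params)

    dt = stable_dt(params, grid, safety=run["safety"], schedule=schedule, max_dt=run["max_dt"])
    if dt < run["min_dt"]:
        raise ConfigurationError(
            f"stable step {dt:.3g} d below the minimum allowed {run['min_dt']:.3g} d; "
            "reduce rates or refine the configuration"
        )
    horizon = float(run["horizon"])
    snap_every = float(run["snapshot_interval"])

    state = initial_state(grid, atlas, params, scn.section("initial_condition"))
    state.validate(grid)
    m0 = float(state.c.sum() * grid.cell_volume_4d)
    # burden at treatment start; the adaptive thresholds are fractions of it
    baseline = m0 if schedule.start_time <= 0 else None

    adaptive_on = True
    times = [0.0]
    dose0 = dose_schedule(0.0, schedule, adaptive_on)
    mass = [m0]
    dose_B = [dose0[0]]
    dose_H = [dose0[1]]
    on = [dose0[0] + dose0[1] > 0]
    clipped = [0.0]
    snapshots = [state.copy()]
    snapshot_times = [0.0]
    next_snap = snap_every
    next_decision = schedule.start_time + schedule.decision_interval

    t = 0.0
    eps = 1e-9
    while t < horizon - eps:
        dt_step = min(dt, horizon - t)
        dose = dose_schedule(t, schedule, adaptive_on)
        state, clip_mass = heun_step(state, dt_step, ops, dose)
        t = state.t
        m = float(state.c.sum() * grid.cell_volume_4d)
        times.append(t)
        mass.append(m)
        dose_B.append(dose[0])
        dose_H.append(dose[1])
        on.append(dose[0] + dose[1] > 0)
        clipped.append(clip_mass)
        if baseline is None and t + eps >= schedule.start_time:
            baseline = m
        if schedule.mode == "adaptive" and t + eps >= next_decision and baseline is not None:
            adaptive_on = adaptive_decision(m, baseline, adaptive_on, schedule)
            while next_decision <= t + eps:
                next_decision += schedule.decision_interval
        if t + eps >= next_snap or t >= horizon - eps:
            snapshots.append(state.copy())
            snapshot_times.append(t)
            while next_snap <= t + eps:
                next_snap += snap_every

    return Trajectory(
        times=np.asarray(times),
        mass=np.asarray(mass),
        dose_B=np.asarray(dose_B),
        dose_H=np.asarray(dose_H),
        treatment_on=np.asarray(on, dtype=bool),
        clipped_mass=np.asarray(clipped),
        snapshot_times=np.asarray(snapshot_times),
        snapshots=snapshots,
        config=scn.as_dict(),
        config_hash=scn.hash(),
    )
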