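import numpy as np
import pytest

import melsim
from melsim.config import load_config
from melsim.errors import ConfigurationError, ContractViolationError
from melsim.geometry import GridSpec, default_atlas
from melsim.solver import (
    FieldState,
    GrowthParams,
    ModelParams,
    SolverOperators,
    growth_profile,
    heun_step,
    initial_state,
    reaction_source,
    simulate,
    stable_dt,
    step,
)
from melsim.spatial_fluxes import SpatialFluxParams
from melsim.structural_fluxes import StructuralFluxParams
from melsim.environment import EnvironmentParams
from melsim.treatment import DrugProfile, TreatmentSchedule

from conftest import small_overrides


def transport_only_params():
    """All sources and environment kinetics off: pure transport."""
    response = {
        "BRAF_MEKi": DrugProfile(delta=0.0),
        "HCT": DrugProfile(components=(("invasive", 1.0),), delta=0.0),
    }
    return ModelParams(
        structural=StructuralFluxParams(k_adv=0.05, d_h_max=1e-3, d_v_max=1e-3),
        spatial=SpatialFluxParams(D_x=1e-4, chi_n=0.0, chi_v=0.0, rho_max=1e12),
        environment=EnvironmentParams(
            r_v=0, lam_av=0, lam_v=0, alpha_n=0, beta_n=0, lam_n=0,
            alpha_a=0, lam_a=0, lam_w=0, eps_w=0, D_n=0, D_a=0, D_w=0,
        ),
        growth=GrowthParams(p_max=0.0),
        response=response,
    )


class TestReactionSource:
    def test_zero_nutrient_means_zero_growth(self, grid8, atlas):
        params = ModelParams()
        c = np.ones((8, 8, 8, 8))
        zero = np.zeros((8, 8))
        src = reaction_source(c, zero, zero, zero, grid8, atlas, params)
        np.testing.assert_allclose(src, 0.0, atol=1e-15)

    def test_no_death_without_drug(self, grid8, atlas):
        params = ModelParams()
        c = np.random.default_rng(0).uniform(0, 1, (8, 8, 8, 8))
        n = np.full((8, 8), 0.8)
        zero = np.zeros((8, 8))
        src = reaction_source(c, n, zero, zero, grid8, atlas, params)
        assert np.all(src >= 0)

    def test_full_suppression_at_smc_anchor(self, atlas):
        grid = GridSpec(n_spatial=4, n_structural=40)
        growth = GrowthParams(smc_suppression=1.0)
        P = growth_profile(grid, atlas, growth)
        smc = atlas.position("SMC")
        iy = tuple(int(np.argmin(np.abs(grid.y_centers - smc[a]))) for a in range(2))
        assert P[iy] < 1e-3 * growth.p_max

    def test_negative_input_rejected(self, grid8, atlas):
        c = -np.ones((8, 8, 8, 8))
        zero = np.zeros((8, 8))
        with pytest.raises(ContractViolationError):
            reaction_source(c, zero, zero, zero, grid8, atlas, ModelParams())


class TestStableDt:
    def diffusion_only(self, D):
        return ModelParams(
            structural=StructuralFluxParams(k_adv=0, d_h_min=0, d_h_max=0, d_v_min=0, d_v_max=0),
            spatial=SpatialFluxParams(D_x=D, chi_n=0, chi_v=0),
            environment=EnvironmentParams(
                r_v=0, lam_av=0, lam_v=0, alpha_n=0, beta_n=0, lam_n=0,
                alpha_a=0, lam_a=0, lam_w=0, eps_w=0, D_n=0, D_a=0, D_w=0,
            ),
            growth=GrowthParams(p_max=0.0),
            response={"BRAF_MEKi": DrugProfile(delta=0.0),
                      "HCT": DrugProfile(components=(("invasive", 1.0),), delta=0.0)},
        )

    def test_parabolic_scaling_under_refinement(self):
        params = self.diffusion_only(1e-3)
        dt_coarse = stable_dt(params, GridSpec(n_spatial=8, n_structural=8), safety=1.0, max_dt=100.0)
        dt_fine = stable_dt(params, GridSpec(n_spatial=16, n_structural=16), safety=1.0, max_dt=100.0)
        assert dt_coarse == pytest.approx(4 * dt_fine)

    def test_diffusion_bound_alone(self):
        params = self.diffusion_only(2e-3)
        grid = GridSpec(n_spatial=8, n_structural=8)
        assert stable_dt(params, grid, safety=1.0, max_dt=100.0) == pytest.approx(grid.dx**2 / (4 * 2e-3))

    def test_safety_scales_linearly(self):
        params = self.diffusion_only(2e-3)
        grid = GridSpec(n_spatial=8, n_structural=8)
        full = stable_dt(params, grid, safety=1.0, max_dt=100.0)
        assert stable_dt(params, grid, safety=0.5, max_dt=100.0) == pytest.approx(0.5 * full)

    def test_all_rates_zero_returns_max_dt(self):
        params = self.diffusion_only(0.0)
        grid = GridSpec(n_spatial=8, n_structural=8)
        assert stable_dt(params, grid, max_dt=0.25) == 0.25


class TestStep:
    def test_transport_only_conserves_mass(self, atlas):
        grid = GridSpec(n_spatial=8, n_structural=8)
        params = transport_only_params()
        ops = SolverOperators(grid, atlas, params)
        state = initial_state(grid, atlas, params, {"spatial_sigma": 0.15, "structural_sigma": 0.12})
        m0 = state.c.sum() * grid.cell_volume_4d
        dt = stable_dt(params, grid)
        for _ in range(100):
            state, clipped = heun_step(state, dt, ops, (0.0, 0.0))
            assert clipped <= 1e-12 * m0
        m1 = state.c.sum() * grid.cell_volume_4d
        assert abs(m1 - m0) <= 1e-10 * m0

    def test_step_is_deterministic(self, atlas):
        grid = GridSpec(n_spatial=8, n_structural=8)
        params = ModelParams()
        schedule = TreatmentSchedule(mode="continuous", start_time=0.0)
        state = initial_state(grid, atlas, params)
        a = step(state.copy(), 0.01, grid, atlas, schedule, params)
        b = step(state.copy(), 0.01, grid, atlas, schedule, params)
        assert np.array_equal(a.c, b.c)
        assert np.array_equal(a.w_B, b.w_B)

    def test_drug_decays_with_correct_half_life(self, atlas):
        grid = GridSpec(n_spatial=8, n_structural=8)
        params = transport_only_params()
        lam = 0.5
        params = ModelParams(
            structural=params.structural, spatial=params.spatial,
            environment=EnvironmentParams(
                r_v=0, lam_av=0, lam_v=0, alpha_n=0, beta_n=0, lam_n=0,
                alpha_a=0, lam_a=0, lam_w=lam, eps_w=0, D_n=0, D_a=0, D_w=0,
            ),
            growth=params.growth, response=params.response,
        )
        ops = SolverOperators(grid, atlas, params)
        state = initial_state(grid, atlas, params)
        state.w_B[:] = 1.0
        t_half = np.log(2) / lam
        nsteps = 200
        dt = t_half / nsteps
        for _ in range(nsteps):
            state, _ = heun_step(state, dt, ops, (0.0, 0.0))
        np.testing.assert_allclose(state.w_B, 0.5, rtol=5 * dt**2)

    def test_fused_kernel_matches_numpy_path(self, atlas):
        grid = GridSpec(n_spatial=8, n_structural=8)
        params = ModelParams()
        fused = SolverOperators(grid, atlas, params, use_fused=True)
        plain = SolverOperators(grid, atlas, params, use_fused=False)
        state = initial_state(grid, atlas, params)
        state.w_B[:] = 0.4
        d1 = fused.rhs(state, (0.5, 0.2))
        d2 = plain.rhs(state, (0.5, 0.2))
        for a, b in zip(d1, d2):
            np.testing.assert_allclose(a, b, atol=1e-12, rtol=1e-10)


class TestSimulate:
    def test_untreated_mass_is_nondecreasing(self):
        traj = simulate(small_overrides(mode="none"))
        diffs = np.diff(traj.mass)
        assert np.all(diffs >= -1e-9 * traj.mass[:-1].max())

    def test_repeat_runs_identical(self):
        over = small_overrides(mode="continuous", drug_order=["BRAF_MEKi"], start_time=5.0)
        t1 = simulate(over)
        t2 = simulate(over)
        assert np.array_equal(t1.mass, t2.mass)
        assert t1.config_hash == t2.config_hash

    def test_snapshots_align_with_cadence(self):
        traj = simulate(small_overrides(mode="none"))
        assert traj.snapshot_times[0] == 0.0
        assert traj.snapshot_times[-1] == pytest.approx(traj.times[-1])
        assert len(traj.snapshots) == len(traj.snapshot_times)
        assert np.all(np.diff(traj.times) > 0)

    def test_adaptive_state_recorded(self):
        over = small_overrides(
            mode="adaptive", drug_order=["BRAF_MEKi"], start_time=2.0,
            lower_threshold=0.3, upper_threshold=0.5,
        )
        traj = simulate(over)
        assert traj.treatment_on.dtype == bool
        # dosing only after the start day
        assert not traj.treatment_on[traj.times < 2.0].any()

    def test_refuses_unresolvable_step(self):
        over = small_overrides(mode="none")
        over["run"]["min_dt"] = 10.0
        with pytest.raises(ConfigurationError):
            simulate(over)
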