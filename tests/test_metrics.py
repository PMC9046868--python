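import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from melsim.errors import ContractViolationError, MetricUndefinedError
from melsim.geometry import GridSpec, classify_grid, default_atlas
from melsim.metrics import (
    count_modes,
    count_onoff_cycles,
    heterogeneity_variance,
    segment_phases,
    structural_marginal,
    subpop_fractions,
    time_to_resistance,
    total_mass,
    zoning_overlap,
)


def c4(grid, fill=1.0):
    n, m = grid.n_spatial, grid.n_structural
    return np.full((n, n, m, m), float(fill))


class TestMassAndMarginal:
    def test_unit_density_on_unit_domain(self, grid8):
        assert total_mass(c4(grid8, 1.0), grid8) == pytest.approx(1.0)
        assert total_mass(c4(grid8, 0.0), grid8) == 0.0

    def test_mass_is_linear(self, grid8, rng):
        c = rng.uniform(0, 1, (8, 8, 8, 8))
        assert total_mass(2 * c, grid8) == pytest.approx(2 * total_mass(c, grid8))

    def test_marginal_of_separable_density(self, grid8, rng):
        f = rng.uniform(0.1, 1, (8, 8))
        g = rng.uniform(0.1, 1, (8, 8))
        c = f[:, :, None, None] * g[None, None, :, :]
        marg = structural_marginal(c, grid8)
        ratio = marg / g
        np.testing.assert_allclose(ratio, ratio[0, 0])

    def test_fubini(self, grid8, rng):
        c = rng.uniform(0, 1, (8, 8, 8, 8))
        m = structural_marginal(c, grid8).sum() * grid8.structural_cell_area
        assert m == pytest.approx(total_mass(c, grid8), rel=1e-12)

    def test_shape_mismatch(self, grid8):
        with pytest.raises(ContractViolationError):
            total_mass(np.ones((4, 4, 8, 8)), grid8)


class TestSubpopFractions:
    def test_concentrated_at_anchor(self, atlas):
        grid = GridSpec(n_spatial=4, n_structural=24)
        c = np.zeros((4, 4, 24, 24))
        pro = atlas.position("proliferative")
        iy = tuple(int(np.argmin(np.abs(grid.y_centers - pro[a]))) for a in range(2))
        c[:, :, iy[0], iy[1]] = 1.0
        fr = subpop_fractions(c, atlas, grid)
        assert fr["proliferative"] == pytest.approx(1.0)

    def test_uniform_density_matches_disc_cell_counts(self, atlas):
        # oracle: exhaustive classification of grid centers
        grid = GridSpec(n_spatial=4, n_structural=24)
        labels = classify_grid(grid, atlas)
        fr = subpop_fractions(c4(grid), atlas, grid)
        for i, name in enumerate(atlas.names):
            expected = np.sum(labels == i) / labels.size
            assert fr[name] == pytest.approx(expected, rel=1e-12)

    def test_partition_sums_to_one(self, atlas, grid8, rng):
        c = rng.uniform(0, 1, (8, 8, 8, 8))
        fr = subpop_fractions(c, atlas, grid8)
        total = sum(fr[name] for name in atlas.names) + fr["unassigned"]
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_zero_mass_flagged(self, atlas, grid8):
        fr = subpop_fractions(c4(grid8, 0.0), atlas, grid8)
        assert fr["undefined"] is True
        assert all(fr[name] == 0.0 for name in atlas.names)


class TestHeterogeneityVariance:
    def test_point_mass_is_nearly_zero(self, grid8):
        c = np.zeros((8, 8, 8, 8))
        c[:, :, 3, 3] = 1.0
        assert heterogeneity_variance(c, grid8) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_density_analytic_value(self):
        # Var(U[0,1]) = 1/12 per axis -> trace = 1/6; the midpoint-grid
        # variance is (1 - 1/n^2)/12 per axis
        grid = GridSpec(n_spatial=4, n_structural=40)
        expected = 2 * (1 - 1 / 40**2) / 12
        assert heterogeneity_variance(c4(grid), grid) == pytest.approx(expected, rel=1e-12)

    def test_two_equal_masses_at_opposite_corners(self):
        grid = GridSpec(n_spatial=4, n_structural=16)
        c = np.zeros((4, 4, 16, 16))
        c[:, :, 0, 0] = 1.0
        c[:, :, -1, -1] = 1.0
        # corners at cell centers (h/2) and (1 - h/2): each at squared
        # distance 0.5*(1-h)^2 from the mean
        h = grid.dy
        expected = (1 - h) ** 2 / 2
        assert heterogeneity_variance(c, grid) == pytest.approx(expected, rel=1e-12)

    def test_translation_invariance_and_quadratic_scaling(self, rng):
        grid = GridSpec(n_spatial=4, n_structural=16)
        big = GridSpec(n_spatial=4, n_structural=16, structural_extent=2.0)
        marg = rng.uniform(0, 1, (16, 16))
        c = np.broadcast_to(marg, (4, 4, 16, 16)).copy()
        v1 = heterogeneity_variance(c, grid)
        # scaling the structural extent by L scales the variance by L^2
        v2 = heterogeneity_variance(c / 4.0, big)
        assert v2 == pytest.approx(4 * v1, rel=1e-12)

    def test_zero_mass_undefined(self, grid8):
        with pytest.raises(MetricUndefinedError):
            heterogeneity_variance(c4(grid8, 0.0), grid8)


class TestCountModes:
    def grid_gauss(self, centers, n=40, sig=0.06):
        # snap centers onto cell centers so peaks are strict maxima, not
        # two-cell plateaus
        y = (np.arange(n) + 0.5) / n
        centers = [(y[np.argmin(np.abs(y - cx))], y[np.argmin(np.abs(y - cy))])
                   for cx, cy in centers]
        y1, y2 = np.meshgrid(y, y, indexing="ij")
        out = np.zeros((n, n))
        for cx, cy in centers:
            out += np.exp(-((y1 - cx) ** 2 + (y2 - cy) ** 2) / (2 * sig**2))
        return out

    def test_single_bump(self):
        assert count_modes(self.grid_gauss([(0.5, 0.5)])) == 1

    def test_two_well_separated_bumps(self):
        assert count_modes(self.grid_gauss([(0.25, 0.25), (0.75, 0.75)])) == 2

    def test_three_bumps(self):
        m = self.grid_gauss([(0.2, 0.2), (0.8, 0.2), (0.5, 0.8)])
        assert count_modes(m) == 3

    def test_uniform_field_has_no_strict_maxima(self):
        assert count_modes(np.ones((24, 24))) == 0

    def test_all_zero_marginal(self):
        assert count_modes(np.zeros((24, 24))) == 0

    def test_faint_bump_below_threshold_ignored(self):
        m = self.grid_gauss([(0.25, 0.25)]) + 0.01 * self.grid_gauss([(0.75, 0.75)])
        assert count_modes(m, rel_threshold=0.05) == 1


class TestTimeToResistance:
    def test_interpolated_crossing(self):
        times = np.array([0.0, 50.0, 100.0, 110.0])
        mass = np.array([1.0, 0.2, 0.9, 1.1])
        assert time_to_resistance(mass, times, 1.0) == pytest.approx(105.0)

    def test_never_recovers(self):
        times = np.linspace(0, 100, 11)
        mass = np.linspace(1.0, 0.1, 11)
        assert time_to_resistance(mass, times, 1.0) is None

    def test_always_below(self):
        times = np.linspace(0, 100, 11)
        mass = np.full(11, 0.5)
        assert time_to_resistance(mass, times, 1.0) is None

    def test_no_response_means_immediate(self):
        times = np.linspace(0, 100, 11)
        mass = np.linspace(1.0, 2.0, 11)
        assert time_to_resistance(mass, times, 1.0) == pytest.approx(times[1])

    def test_rescaling_invariance(self):
        times = np.array([0.0, 50.0, 100.0, 110.0])
        mass = np.array([1.0, 0.2, 0.9, 1.1])
        a = time_to_resistance(mass, times, 1.0)
        b = time_to_resistance(7.3 * mass, times, 7.3)
        assert a == pytest.approx(b)


class TestSegmentPhases:
    def synthetic_series(self):
        t = np.arange(0, 251.0, 0.5)
        mass = np.piecewise(
            t,
            [t <= 50, (t > 50) & (t <= 150), t > 150],
            [lambda t: 1 - 0.018 * t, lambda t: 0.1, lambda t: 0.1 + 0.011 * (t - 150)],
        )
        return mass, t

    def test_three_phase_boundaries(self):
        mass, t = self.synthetic_series()
        phases = segment_phases(mass, t)
        labels = [p[0] for p in phases]
        assert labels == ["shrink", "MRD", "regrow"]
        assert phases[0][2] == pytest.approx(50, abs=10)
        assert phases[2][1] == pytest.approx(150, abs=10)
        # intervals partition the span
        assert phases[0][1] == t[0] and phases[-1][2] == t[-1]

    def test_monotone_growth_is_one_regrow_phase(self):
        t = np.arange(0, 100.0, 0.5)
        phases = segment_phases(np.exp(0.02 * t), t)
        assert [p[0] for p in phases] == ["regrow"]

    def test_constant_series_is_mrd(self):
        t = np.arange(0, 100.0, 0.5)
        phases = segment_phases(np.ones_like(t), t)
        assert [p[0] for p in phases] == ["MRD"]

    def test_rescaling_invariance(self):
        mass, t = self.synthetic_series()
        assert segment_phases(mass, t) == segment_phases(123.0 * mass, t)

    def test_too_short_series_rejected(self):
        with pytest.raises(ContractViolationError):
            segment_phases(np.array([1.0, 2.0]), np.array([0.0, 1.0]))


class TestZoning:
    def test_hand_computed_cosine(self, atlas):
        # m_s = (1,0,...) vs m_s' = (1,1,0,...): cosine = 1/sqrt(2)
        a = np.zeros(16)
        b = np.zeros(16)
        a[0] = 1.0
        b[:2] = 1.0
        cos = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
        assert cos == pytest.approx(1 / np.sqrt(2))

    def build_density(self, grid, atlas, spatial_by_name):
        labels = classify_grid(grid, atlas)
        c = np.zeros((grid.n_spatial,) * 2 + (grid.n_structural,) * 2)
        for name, field in spatial_by_name.items():
            mask = labels == atlas.names.index(name)
            c[:, :, mask] = field[:, :, None]
        return c

    def test_identical_fields_full_overlap(self, atlas):
        grid = GridSpec(n_spatial=8, n_structural=24)
        f = np.random.default_rng(3).uniform(0.1, 1, (8, 8))
        c = self.build_density(grid, atlas, {"proliferative": f, "URC": f})
        ov, zi, _ = zoning_overlap(c, atlas, grid)
        i, j = atlas.names.index("proliferative"), atlas.names.index("URC")
        assert ov[i, j] == pytest.approx(1.0)
        assert zi == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_zero_overlap(self, atlas):
        grid = GridSpec(n_spatial=8, n_structural=24)
        left = np.zeros((8, 8))
        left[:4, :] = 1.0
        right = np.zeros((8, 8))
        right[4:, :] = 1.0
        c = self.build_density(grid, atlas, {"proliferative": left, "URC": right})
        ov, zi, _ = zoning_overlap(c, atlas, grid)
        i, j = atlas.names.index("proliferative"), atlas.names.index("URC")
        assert ov[i, j] == 0.0
        assert zi == pytest.approx(1.0)

    def test_matrix_symmetric_unit_diagonal(self, atlas, grid8, rng):
        grid = GridSpec(n_spatial=8, n_structural=24)
        c = rng.uniform(0, 1, (8, 8, 24, 24))
        ov, _, _ = zoning_overlap(c, atlas, grid)
        np.testing.assert_allclose(ov, ov.T)
        np.testing.assert_allclose(np.diag(ov), 1.0)

    def test_zero_mass_undefined(self, atlas):
        grid = GridSpec(n_spatial=8, n_structural=24)
        with pytest.raises(MetricUndefinedError):
            zoning_overlap(np.zeros((8, 8, 24, 24)), atlas, grid)


class TestCycles:
    def test_counts_complete_on_off_on_cycles(self):
        on = np.array([1, 1, 0, 0, 1, 1, 0, 1, 1], dtype=bool)
        assert count_onoff_cycles(on) == 2

    def test_trailing_off_not_counted(self):
        on = np.array([1, 1, 0, 0, 0], dtype=bool)
        assert count_onoff_cycles(on) == 0
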