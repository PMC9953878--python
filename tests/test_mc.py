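"""Monte Carlo photon transport: interaction physics and full-run invariants."""

import math

import numpy as np
import pytest

import optrodesim as osim
from optrodesim.grid import EMISSION_525, EXCITATION_465, InvalidParameterError, OpticalProperties
from optrodesim.mc import (
    FiberSpec,
    FluorophoreMap,
    PhotonPacket,
    absorb,
    emit_fluorescence,
    fluence_from_absorption,
    launch_from_fiber,
    run_excitation_emission,
    sample_step,
    scatter_direction,
)


class TestStepSampling:
    def test_xi_one_gives_zero_step(self):
        assert sample_step(1.0, EXCITATION_465) == 0.0

    def test_step_at_inverse_e_equals_mean_free_path(self):
        # -ln(e^-1)/(mu_a + mu_s) = 1/262.273 cm ~ 38.13 um
        ds = sample_step(math.exp(-1.0), EXCITATION_465)
        assert ds == pytest.approx(1.0 / 262.273, rel=1e-9)
        assert ds * 1e4 == pytest.approx(38.128, rel=1e-3)

    @pytest.mark.parametrize("xi", [0.0, -0.2, 1.2])
    def test_invalid_variate_rejected(self, xi):
        with pytest.raises(InvalidParameterError):
            sample_step(xi, EXCITATION_465)

    def test_empirical_mean_matches_mean_free_path(self, rng):
        xi = rng.random(100_000)
        xi = xi[xi > 0]
        steps = np.array([sample_step(v, EXCITATION_465) for v in xi[:50_000]])
        assert steps.mean() == pytest.approx(1.0 / 262.273, rel=0.02)


class TestAbsorption:
    def _packet(self, w=1.0):
        return PhotonPacket(position_um=np.zeros(3), direction=np.array([0.0, 0.0, 1.0]),
                            weight=w)

    def test_fraction_at_excitation_wavelength(self):
        dw, updated = absorb(self._packet(), EXCITATION_465)
        assert dw == pytest.approx(4.642 / 262.273, rel=1e-9)
        assert dw == pytest.approx(0.017699, abs=5e-7)
        assert updated.weight == pytest.approx(0.982301, abs=5e-7)

    def test_fraction_at_emission_wavelength(self):
        dw, _ = absorb(self._packet(), EMISSION_525)
        assert dw == pytest.approx(4.873 / 228.947, rel=1e-9)
        assert dw == pytest.approx(0.021284, abs=5e-7)

    def test_conservative_scattering_deposits_nothing(self):
        props = OpticalProperties(mu_a_per_cm=0.0, mu_s_per_cm=100.0)
        dw, updated = absorb(self._packet(0.7), props)
        assert dw == 0.0
        assert updated.weight == 0.7


class TestScattering:
    def test_isotropic_mean_deflection_cosine_is_zero(self, rng):
        d = np.array([0.0, 0.0, 1.0])
        cosines = [scatter_direction(d, 0.0, rng) @ d for _ in range(20_000)]
        assert abs(np.mean(cosines)) < 0.02

    def test_henyey_greenstein_first_moment_equals_g(self, rng):
        d = np.array([0.0, 0.0, 1.0])
        g = 0.9
        cosines = [scatter_direction(d, g, rng) @ d for _ in range(100_000)]
        assert np.mean(cosines) == pytest.approx(g, rel=0.01)

    def test_output_stays_unit_norm(self, rng):
        d = np.array([3.0, -4.0, 12.0]) / 13.0
        for g in (-0.5, 0.0, 0.9):
            for _ in range(200):
                d = scatter_direction(d, g, rng)
                assert np.linalg.norm(d) == pytest.approx(1.0, abs=1e-12)


class TestFiberLaunch:
    def test_cone_and_disc_bounds(self, rng):
        fiber = FiberSpec(tip_position_um=(0.0, 0.0, 0.0))
        axis = np.asarray(fiber.axis)
        max_cos = math.cos(math.radians(20.5))
        offsets, cosines = [], []
        for _ in range(20_000):
            p = launch_from_fiber(fiber, rng)
            offsets.append(np.linalg.norm(p.position_um[:2]))
            cosines.append(p.direction @ axis)
            assert p.weight == 1.0 and p.wavelength_tag == "excitation"
        assert max(offsets) <= 100.0 + 1e-9
        assert min(cosines) >= max_cos - 1e-12

    def test_degenerate_cone_launches_along_axis(self, rng):
        fiber = FiberSpec(tip_position_um=(0.0, 0.0, 0.0), half_angle_deg=0.0)
        for _ in range(100):
            p = launch_from_fiber(fiber, rng)
            assert p.direction @ np.asarray(fiber.axis) == pytest.approx(1.0, abs=1e-12)

    def test_mean_start_position_is_disc_centre(self, rng):
        fiber = FiberSpec(tip_position_um=(50.0, -20.0, 0.0))
        pos = np.array([launch_from_fiber(fiber, rng).position_um for _ in range(20_000)])
        se = 100.0 / math.sqrt(len(pos))  # core radius sets the scale
        assert np.allclose(pos.mean(axis=0), (50.0, -20.0, 0.0), atol=5 * se)

    def test_half_angle_from_na_matches_printed_value(self):
        fiber = FiberSpec.from_na((0, 0, 0))
        assert fiber.half_angle_deg == pytest.approx(20.5, abs=0.05)


class TestFluorescenceAndFluence:
    def test_emission_weight_is_dw_times_qy(self):
        assert emit_fluorescence(0.02, 0.0) == 0.0
        assert emit_fluorescence(0.02, 1.0) == 0.02
        assert emit_fluorescence(0.02, 0.5) == pytest.approx(0.01)
        with pytest.raises(InvalidParameterError):
            emit_fluorescence(0.02, 1.5)

    def test_phi_unit_example(self, small_grid):
        absorbed = np.zeros(small_grid.shape)
        absorbed[10, 10, 10] = 4.873e-9
        fmap = osim.FluenceMap(grid=small_grid, absorbed_weight=absorbed,
                               wavelength_tag="emission", launched_weight=1.0,
                               escaped_weight=0.0, roulette_net=0.0)
        fluence_from_absorption(fmap, EMISSION_525)
        # phi = absorbed / (mu_a * V) with V = 1e-9 cm^3 at 10 um voxels
        assert fmap.phi[10, 10, 10] == pytest.approx(1.0, rel=1e-12)
        assert fmap.total_phi == pytest.approx(1.0, rel=1e-12)

    def test_phi_linear_in_absorbed_weight(self, small_grid, rng):
        absorbed = rng.random(small_grid.shape)
        kwargs = dict(grid=small_grid, wavelength_tag="emission",
                      launched_weight=1.0, escaped_weight=0.0, roulette_net=0.0)
        f1 = fluence_from_absorption(
            osim.FluenceMap(absorbed_weight=absorbed, **kwargs), EMISSION_525)
        f2 = fluence_from_absorption(
            osim.FluenceMap(absorbed_weight=2 * absorbed, **kwargs), EMISSION_525)
        assert np.allclose(f2.phi, 2 * f1.phi)

    def test_zero_mu_a_has_no_fluence(self, small_grid):
        props = OpticalProperties(mu_a_per_cm=0.0, mu_s_per_cm=10.0)
        fmap = osim.FluenceMap(grid=small_grid, absorbed_weight=np.zeros(small_grid.shape),
                               wavelength_tag="excitation", launched_weight=1.0,
                               escaped_weight=1.0, roulette_net=0.0)
        with pytest.raises(InvalidParameterError):
            fluence_from_absorption(fmap, props)


class TestFullRuns:
    def _tissue_run(self, qy_value, n_photons=20_000, seed=7, edge=20.0):
        grid = osim.make_grid((1.0, 1.0, 1.0), edge)
        fiber = FiberSpec(tip_position_um=(500.0, 500.0, 100.0))
        qy = FluorophoreMap(grid=grid, qy=np.full(grid.shape, qy_value))
        return run_excitation_emission(grid, EXCITATION_465, EMISSION_525, fiber, qy,
                                       n_photons=n_photons, seed=seed)

    def test_zero_qy_no_emission_and_energy_conserved(self):
        fl_ex, fl_em, phi = self._tissue_run(0.0)
        assert phi == 0.0
        assert fl_em.launched_weight == 0.0
        assert np.all(fl_em.absorbed_weight == 0.0)
        # exact ledger including the roulette term
        assert fl_ex.conservation_error() < 1e-10
        # roulette bias bound: launched ~ absorbed + escaped within 0.1%
        assert abs(fl_ex.roulette_net) / fl_ex.launched_weight < 1e-3

    def test_fixed_seed_bit_identical(self):
        a = self._tissue_run(1.0, n_photons=5_000)
        b = self._tissue_run(1.0, n_photons=5_000)
        assert np.array_equal(a[0].absorbed_weight, b[0].absorbed_weight)
        assert np.array_equal(a[1].absorbed_weight, b[1].absorbed_weight)
        assert a[2] == b[2]

    def test_total_phi_linear_in_uniform_qy(self):
        _, _, phi_full = self._tissue_run(1.0)
        _, _, phi_half = self._tissue_run(0.5)
        assert phi_half == pytest.approx(0.5 * phi_full, rel=1e-9)

    def test_nested_qy_supports_order_total_phi(self):
        """More fluorescing voxels cannot decrease spawned emission."""
        grid = osim.make_grid((1.0, 1.0, 1.0), 20.0)
        fiber = FiberSpec(tip_position_um=(500.0, 500.0, 100.0))
        x, y, z = grid.meshgrid_um()
        r = np.sqrt((x - 500) ** 2 + (y - 500) ** 2 + (z - 300) ** 2)
        phis = []
        for radius in (150.0, 300.0):
            qy = FluorophoreMap(grid=grid, qy=(r < radius).astype(float))
            phis.append(run_excitation_emission(grid, EXCITATION_465, EMISSION_525,
                                                fiber, qy, n_photons=20_000, seed=11)[2])
        assert 0.0 < phis[0] <= phis[1]

    def test_beer_lambert_depth_profile_without_scattering(self):
        """Pencil beam in a purely absorbing slab: deposited weight per depth
        bin follows exp(-mu_a z) within 3 Monte Carlo standard errors."""
        grid = osim.make_grid((1.0, 1.0, 2.0), 20.0)
        mu_a = 10.0
        props = OpticalProperties(mu_a_per_cm=mu_a, mu_s_per_cm=0.0, g=0.0)
        fiber = FiberSpec(tip_position_um=(500.0, 500.0, 1.0), axis=(0, 0, 1),
                          core_diameter_um=1e-6, half_angle_deg=0.0)
        qy = FluorophoreMap(grid=grid, qy=np.zeros(grid.shape))
        n = 100_000
        fl_ex, _, _ = run_excitation_emission(grid, props, EMISSION_525, fiber, qy,
                                              n_photons=n, seed=42)
        profile = fl_ex.absorbed_weight.sum(axis=(0, 1))
        edge_cm = grid.voxel_edge_um * 1e-4
        z0 = np.arange(grid.shape[2]) * edge_cm
        expected = n * (np.exp(-mu_a * z0) - np.exp(-mu_a * (z0 + edge_cm)))
        se = np.sqrt(np.maximum(expected * (1 - expected / n), 1.0))
        assert np.all(np.abs(profile - expected) <= 3.0 * se)

    def test_point_source_fluence_matches_diffusion_approximation(self):
        """Isotropic point source in a scattering medium: shell-averaged
        fluence matches the diffusion Green's function within 15% at
        >= 10 transport mean free paths."""
        grid = osim.make_grid((6.0, 6.0, 6.0), 60.0)
        # excitation deposits everything at the tip voxel; each absorption
        # spawns one isotropic unit-weight emission packet -> point source
        instant = OpticalProperties(mu_a_per_cm=1e4, mu_s_per_cm=0.0, g=0.0)
        mu_a, mu_s = 0.1, 100.0
        medium = OpticalProperties(mu_a_per_cm=mu_a, mu_s_per_cm=mu_s, g=0.0,
                                   wavelength_tag="emission")
        fiber = FiberSpec(tip_position_um=(3000.0, 3000.0, 3000.0),
                          core_diameter_um=1e-6, half_angle_deg=0.0)
        qy = FluorophoreMap(grid=grid, qy=np.ones(grid.shape))
        _, fl_em, _ = run_excitation_emission(grid, instant, medium, fiber, qy,
                                              n_photons=60_000, seed=5)
        x, y, z = grid.meshgrid_um()
        r_cm = np.sqrt((x - 3000) ** 2 + (y - 3000) ** 2 + (z - 3000) ** 2) * 1e-4
        diff_coeff = 1.0 / (3.0 * (mu_a + mu_s))
        mu_eff = math.sqrt(mu_a / diff_coeff)
        phi_per_weight = fl_em.phi / fl_em.launched_weight
        for r_lo, r_hi in ((0.10, 0.12), (0.12, 0.14)):  # 10-14 transport mfp
            shell = (r_cm >= r_lo) & (r_cm < r_hi)
            r_mean = r_cm[shell].mean()
            theory = math.exp(-mu_eff * r_mean) / (4 * math.pi * diff_coeff * r_mean)
            assert phi_per_weight[shell].mean() == pytest.approx(theory, rel=0.15)

    def test_fiber_outside_grid_rejected(self):
        grid = osim.make_grid((1.0, 1.0, 1.0), 20.0)
        fiber = FiberSpec(tip_position_um=(5000.0, 500.0, 100.0))
        qy = FluorophoreMap(grid=grid, qy=np.zeros(grid.shape))
        with pytest.raises(InvalidParameterError):
            run_excitation_emission(grid, EXCITATION_465, EMISSION_525, fiber, qy,
                                    n_photons=10, seed=0)
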