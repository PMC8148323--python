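import numpy as np
import pytest

from vapordose.airway_tissue import (
    TissueLayer,
    TissueStack,
    equilibrium_capacity,
    interface_values,
    series_resistance_flux,
    solve_tissue_diffusion,
)
from vapordose.errors import ConfigurationError, InvalidArgumentError


def const_series(value, t_end):
    return (np.array([0.0, t_end]), np.array([value, value]))


@pytest.fixture(scope="module")
def multilayer():
    return TissueStack(
        layers=[
            TissueLayer("mucus", 10e-6, 3e-10, 1e3),
            TissueLayer("epithelium", 50e-6, 1e-10, 0.5),
            TissueLayer("subepithelium", 100e-6, 1.2e-10, 2.0),
        ],
        grid_points_per_layer=40,
    )


class TestInterfaceValues:
    def test_zero_bulk_gives_zero_everything(self):
        cw, cs, flux = interface_values(0.0, 1e-3, 1e-3, 100.0)
        assert cw == cs == flux == 0.0

    def test_gas_resistance_vanishes_at_large_kg(self):
        cw, cs, _ = interface_values(1.0, 1e6, 1e-3, 50.0)
        assert cw == pytest.approx(1.0, rel=1e-3)
        assert cs == pytest.approx(50.0 * cw)

    def test_equal_films_unit_partition_halves_wall_concentration(self):
        # two equal resistances in series: wall sits at the midpoint
        cw, cs, flux = interface_values(1.0, 2e-3, 2e-3, 1.0)
        assert cw == pytest.approx(0.5)
        assert cs == pytest.approx(0.5)
        assert flux == pytest.approx(2e-3 * 0.5)

    def test_flux_conservation(self):
        k_g, k_l, K = 3e-3, 7e-4, 42.0
        cw, cs, flux = interface_values(2.5, k_g, k_l, K)
        gas_side = k_g * (2.5 - cw)
        liquid_side = k_l * (cs - 0.0) / K * K  # liquid film from surface to zero bulk
        assert gas_side == pytest.approx(flux, rel=1e-10)
        assert cs == pytest.approx(K * cw, rel=1e-12)

    def test_insoluble_limit_not_an_error(self):
        cw, cs, flux = interface_values(1.0, 1e-3, 1e-3, 0.0)
        assert flux == 0.0 and cw == 1.0 and cs == 0.0


class TestSolveTissueDiffusion:
    def test_zero_exposure_zero_flux(self, thc, multilayer):
        res = solve_tissue_diffusion(multilayer, thc, const_series(0.0, 5.0), dt=0.05)
        assert np.all(res.flux == 0.0)
        assert res.cumulative_uptake[-1] == 0.0

    def test_semi_infinite_early_time_flux(self, thc):
        # single thick layer, constant exposure, no gas-side film:
        # flux(t) = K C sqrt(D / (pi t))
        D, K, L = 1e-10, 1000.0, 2e-4
        stack = TissueStack(
            [TissueLayer("mucus", L, D, K)], grid_points_per_layer=200
        )
        res = solve_tissue_diffusion(stack, thc, const_series(1.0, 10.0), dt=0.005)
        for t in (2.0, 5.0, 10.0):
            i = int(np.argmin(np.abs(res.times - t)))
            exact = K * np.sqrt(D / (np.pi * t))
            assert res.flux[i] == pytest.approx(exact, rel=0.02)

    def test_steady_state_matches_series_resistance(self, thc, multilayer):
        k_g = 0.01
        res = solve_tissue_diffusion(
            multilayer, thc, const_series(1.0, 2000.0), dt=2.0, gas_film_coeff=k_g
        )
        exact = series_resistance_flux(multilayer, thc, 1.0, gas_film_coeff=k_g)
        assert res.flux[-1] == pytest.approx(exact, rel=0.005)

    def test_mass_conservation(self, thc, multilayer):
        res = solve_tissue_diffusion(
            multilayer, thc, const_series(1.0, 50.0), dt=0.05, gas_film_coeff=2e-3
        )
        # uptake equals flux time-integral by construction of the ledger;
        # check it against trapezoid independently, then against inventory+sink
        trapz = np.trapezoid(res.flux, res.times)
        assert res.cumulative_uptake[-1] == pytest.approx(trapz, rel=1e-2)
        assert res.cumulative_uptake[-1] == pytest.approx(
            res.tissue_inventory + res.sink_outflow, rel=1e-6
        )

    def test_convergence_under_refinement(self, thc):
        def run(dt, n):
            stack = TissueStack(
                [
                    TissueLayer("mucus", 10e-6, 3e-10, 1e3),
                    TissueLayer("epithelium", 50e-6, 1e-10, 1.0),
                ],
                grid_points_per_layer=n,
            )
            res = solve_tissue_diffusion(
                stack, thc, const_series(1.0, 10.0), dt=dt, gas_film_coeff=2e-3
            )
            return res.cumulative_uptake[-1]

        coarse = run(0.02, 20)
        fine = run(0.01, 40)
        assert fine == pytest.approx(coarse, rel=0.01)

    def test_uptake_monotone_in_partition_and_diffusivity(self, thc):
        def uptake(K, D):
            stack = TissueStack(
                [TissueLayer("mucus", 20e-6, D, K)], grid_points_per_layer=20
            )
            res = solve_tissue_diffusion(
                stack, thc, const_series(1.0, 5.0), dt=0.05, gas_film_coeff=2e-3
            )
            return res.cumulative_uptake[-1]

        for D in (1e-10, 3e-10):
            vals = [uptake(K, D) for K in (10.0, 100.0, 1e3, 1e4)]
            assert np.all(np.diff(vals) >= 0)
        for K in (100.0, 1e4):
            vals = [uptake(K, D) for D in (3e-11, 1e-10, 3e-10)]
            assert np.all(np.diff(vals) >= 0)

    def test_flux_continuity_across_interfaces(self, thc, multilayer):
        # at near-steady state the flux through each internal interface must
        # match the surface flux
        res = solve_tissue_diffusion(
            multilayer, thc, const_series(1.0, 3000.0), dt=5.0, gas_film_coeff=0.01
        )
        profile = res.layer_profiles[-1]
        x = res.x
        n = multilayer.grid_points_per_layer
        surface_flux = res.flux[-1]
        bounds = [n, 2 * n]  # cell indices at the two internal interfaces
        layers = multilayer.layers
        k_cum = np.cumprod([l.partition_vs_previous for l in layers])
        for b, (lay_a, lay_b, ka, kb) in zip(
            bounds,
            [
                (layers[0], layers[1], k_cum[0], k_cum[1]),
                (layers[1], layers[2], k_cum[1], k_cum[2]),
            ],
        ):
            # gas-equivalent gradient across the interface (harmonic form)
            psi_a = profile[b - 1] / ka
            psi_b = profile[b] / kb
            dx_a = lay_a.thickness / n
            dx_b = lay_b.thickness / n
            g = 1.0 / (
                dx_a / (2 * lay_a.diffusivity * ka) + dx_b / (2 * lay_b.diffusivity * kb)
            )
            assert g * (psi_a - psi_b) == pytest.approx(surface_flux, rel=1e-4)

    def test_no_sink_uptake_bounded_by_capacity(self, thc):
        stack = TissueStack(
            [TissueLayer("mucus", 20e-6, 3e-10, 500.0)],
            base_condition="no_flux",
            grid_points_per_layer=20,
        )
        res = solve_tissue_diffusion(
            stack, thc, const_series(1.0, 500.0), dt=0.5, gas_film_coeff=2e-3
        )
        cap = equilibrium_capacity(stack, thc, 1.0)
        assert np.all(res.cumulative_uptake <= cap * (1 + 1e-9))
        # and approaches it at long time
        assert res.cumulative_uptake[-1] == pytest.approx(cap, rel=0.05)

    def test_grid_too_coarse_rejected(self):
        with pytest.raises(ConfigurationError):
            TissueStack([TissueLayer("mucus", 1e-5, 1e-10, 1.0)], grid_points_per_layer=2)


class TestEquilibriumCapacity:
    def test_zero_air_zero_capacity(self, thc, multilayer):
        assert equilibrium_capacity(multilayer, thc, 0.0) == 0.0

    def test_single_layer_direct_product(self, thc):
        stack = TissueStack([TissueLayer("mucus", 1e-5, 1e-10, 2.0)])
        assert equilibrium_capacity(stack, thc, 1.0) == pytest.approx(2e-5)

    def test_linear_in_partition(self, thc):
        s1 = TissueStack([TissueLayer("mucus", 1e-5, 1e-10, 2.0)])
        s2 = TissueStack([TissueLayer("mucus", 1e-5, 1e-10, 4.0)])
        assert equilibrium_capacity(s2, thc, 1.0) == pytest.approx(
            2 * equilibrium_capacity(s1, thc, 1.0)
        )
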