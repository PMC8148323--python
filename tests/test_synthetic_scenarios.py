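import numpy as np
import pytest

from vapordose.airway_tissue import TissueLayer, TissueStack, solve_tissue_diffusion
from vapordose.airway_transport import build_airway_tree, budget, simulate_puff
from vapordose.chem_props import ChemicalSpecies
from vapordose.errors import InvalidArgumentError
from vapordose.puff_profiles import build_exhalation, build_puff
from vapordose.synthetic_scenarios import (
    DEFAULT_RANGES,
    generate_ensemble,
    random_scenario,
    random_species,
    recover_partition_coefficient,
)


class TestRandomSpecies:
    def test_deterministic_under_seed(self):
        assert random_species(42) == random_species(42)

    def test_samples_within_bounds(self):
        for seed in range(200):
            sp = random_species(seed)
            lo, hi = DEFAULT_RANGES["K_mucus_air"]
            assert lo <= sp.K_mucus_air <= hi
            lo, hi = DEFAULT_RANGES["D_mucus"]
            assert lo <= sp.D_layer["mucus"] <= hi
            lo, hi = DEFAULT_RANGES["molar_mass"]
            assert lo <= sp.molar_mass <= hi

    def test_degenerate_range_is_exact(self):
        ranges = {"K_mucus_air": (1234.0, 1234.0)}
        assert random_species(7, ranges).K_mucus_air == 1234.0

    def test_inverted_bounds_rejected(self):
        with pytest.raises(InvalidArgumentError):
            random_species(0, {"K_mucus_air": (10.0, 1.0)})


class TestEnsembles:
    def test_regeneration_bit_exact(self):
        a = generate_ensemble(3, 5)
        b = generate_ensemble(3, 5)
        assert a.scenarios == b.scenarios

    def test_scenarios_satisfy_type_invariants(self):
        ens = generate_ensemble(11, 20)
        for scen in ens.scenarios:
            sp = ChemicalSpecies.from_dict(scen["species"])
            assert sp.D_air > max(sp.D_layer.values())
            assert scen["puff"]["duration_s"] > 0
            assert scen["room"]["volume_m3"] > 0

    def test_scenarios_run_end_to_end(self):
        # a small seeded batch must simulate without error and close its budget
        tree = build_airway_tree(None)
        for scen in generate_ensemble(5, 8).scenarios:
            sp = ChemicalSpecies.from_dict(scen["species"])
            puff = build_puff(
                "custom", scen["puff"]["duration_s"], scen["puff"]["volume_m3"],
                shape=scen["puff"]["shape"],
            )
            exh = build_exhalation(scen["puff"]["volume_m3"], scen["exhalation"]["duration_s"])
            res = simulate_puff(
                tree, sp, puff, exh, C_inlet=1.0,
                dt=scen["airway"]["dt_s"],
                grid_points_per_layer=scen["airway"]["grid_points_per_layer"],
                dx_target=0.02,
            )
            total = (
                res.absorbed_mass + res.exhaled_mass + res.resident_mass + res.distal_outflow_mass
            )
            assert total == pytest.approx(res.inhaled_mass, rel=5e-3)
            b = budget(res)
            assert (
                b.absorbed_frac + b.exhaled_frac + b.remaining_frac + b.to_lung_frac
                == pytest.approx(100.0, abs=0.1)
            )


@pytest.fixture(scope="module")
def recovery_problem(thc):
    K_true = 1000.0
    stack = TissueStack(
        [
            TissueLayer("mucus", 10e-6, 3e-10, K_true),
            TissueLayer("epithelium", 50e-6, 1e-10, 1.0),
        ],
        grid_points_per_layer=10,
    )
    series = (np.array([0.0, 5.0]), np.array([1.0, 1.0]))
    dt, k_g = 0.05, 2e-3
    res = solve_tissue_diffusion(stack, thc, series, dt, gas_film_coeff=k_g)
    return K_true, stack, series, dt, k_g, res


class TestPartitionRecovery:
    def test_noise_free_recovery_within_2pct(self, thc, recovery_problem):
        K_true, stack, series, dt, k_g, res = recovery_problem
        out = recover_partition_coefficient(
            (res.times, res.flux), stack, thc, series, dt,
            gas_film_coeff=k_g, bounds=(10.0, 1e6),
        )
        assert out.identifiable
        assert out.K == pytest.approx(K_true, rel=0.02)

    def test_doubled_truth_doubles_estimate(self, thc, recovery_problem):
        K_true, stack, series, dt, k_g, _ = recovery_problem
        stack2 = TissueStack(
            [
                TissueLayer("mucus", 10e-6, 3e-10, 2 * K_true),
                TissueLayer("epithelium", 50e-6, 1e-10, 1.0),
            ],
            grid_points_per_layer=10,
        )
        res2 = solve_tissue_diffusion(stack2, thc, series, dt, gas_film_coeff=k_g)
        out = recover_partition_coefficient(
            (res2.times, res2.flux), stack2, thc, series, dt,
            gas_film_coeff=k_g, bounds=(10.0, 1e6),
        )
        assert out.K == pytest.approx(2 * K_true, rel=0.02)

    def test_noisy_recovery_median_within_10pct(self, thc, recovery_problem):
        K_true, stack, series, dt, k_g, res = recovery_problem
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noisy = np.maximum(res.flux * (1 + 0.05 * rng.standard_normal(res.flux.shape)), 0.0)
            out = recover_partition_coefficient(
                (res.times, noisy), stack, thc, series, dt,
                gas_film_coeff=k_g, bounds=(10.0, 1e6),
            )
            errs.append(abs(out.K / K_true - 1.0))
        assert np.median(errs) < 0.10

    def test_deposition_limited_flagged_non_identifiable(self, thc):
        # gas film controls: flux carries no information about K
        stack = TissueStack(
            [
                TissueLayer("mucus", 10e-6, 3e-10, 1e7),
                TissueLayer("epithelium", 50e-6, 1e-10, 1.0),
            ],
            grid_points_per_layer=10,
        )
        series = (np.array([0.0, 5.0]), np.array([1.0, 1.0]))
        res = solve_tissue_diffusion(stack, thc, series, 0.05, gas_film_coeff=2e-3)
        out = recover_partition_coefficient(
            (res.times, res.flux), stack, thc, series, 0.05,
            gas_film_coeff=2e-3, bounds=(1e5, 1e9),
        )
        assert not out.identifiable
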