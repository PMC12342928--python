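"""Water-mass mixing inversion: scaling, exact recovery, oracle dominance."""

import numpy as np
import pandas as pd
import pytest

from conftest import mix_sample
from oceanch4 import synthetic as syn
from oceanch4.omp import (
    EndmemberSet,
    OMPError,
    PROPERTIES,
    classify_dominant_mass,
    grid_search_omp,
    normalize_system,
    omp_section,
    solve_omp,
)


class TestEndmemberSet:
    def test_rejects_single_endmember(self):
        with pytest.raises(OMPError, match="at least 2"):
            EndmemberSet(("a",), np.ones((1, 6)))

    def test_rejects_more_than_seven(self):
        props = np.arange(48, dtype=float).reshape(8, 6)
        with pytest.raises(OMPError, match="at most 7"):
            EndmemberSet(tuple("abcdefgh"), props)

    def test_rejects_duplicate_endmembers(self):
        props = np.vstack([np.arange(6.0), np.arange(6.0)])
        with pytest.raises(OMPError, match="identical"):
            EndmemberSet(("a", "b"), props)

    def test_accepts_two_to_seven(self, three_endmembers):
        ems, _ = three_endmembers
        assert ems.n_endmembers == 3


class TestNormalizeSystem:
    def test_temperature_row_scaled_by_population_sd(self):
        # endmember T of 5 and 25: population sd is 10, so the scaled
        # coefficients are 0.5 and 2.5 -> 2 * weight apart
        props = np.array(
            [[5.0, 33.0, 200.0, 0.5, 5.0, 10.0], [25.0, 35.0, 300.0, 1.5, 15.0, 40.0]]
        )
        ems = EndmemberSet(("cold", "warm"), props)
        system = normalize_system(ems)
        t_row = system.matrix[system.row_properties.index("T")]
        assert t_row[1] - t_row[0] == pytest.approx(2.0)

    def test_prestandardized_properties_unchanged(self):
        # endmember values of -1 and +1 have population sd 1: with unit
        # weights the scaled matrix equals the raw property matrix
        ems = EndmemberSet(("a", "b"), np.vstack([-np.ones(6), np.ones(6)]))
        system = normalize_system(ems)
        np.testing.assert_allclose(system.matrix[:-1], ems.properties.T)

    def test_constant_property_excluded(self):
        props = np.array(
            [[5.0, 34.0, 200.0, 0.5, 5.0, 10.0], [25.0, 34.0, 300.0, 1.5, 15.0, 40.0]]
        )
        ems = EndmemberSet(("a", "b"), props)
        system = normalize_system(ems)
        assert "S" in system.excluded
        assert "S" not in system.row_properties


class TestSolveOMP:
    def test_pure_endmember_recovered(self, two_endmembers):
        ems, _ = two_endmembers
        sol = solve_omp(mix_sample(ems, [0.0, 1.0]), ems)
        np.testing.assert_allclose(sol.fractions, [0.0, 1.0], atol=1e-12)
        assert all(abs(r) < 1e-9 for r in sol.residuals.values())

    def test_fifty_fifty_mixture(self, two_endmembers):
        ems, _ = two_endmembers
        sol = solve_omp(mix_sample(ems, [0.5, 0.5]), ems)
        np.testing.assert_allclose(sol.fractions, [0.5, 0.5], atol=1e-9)
        assert sol.objective < 1e-18

    def test_nan_observation_rejected(self, two_endmembers):
        ems, _ = two_endmembers
        bad = mix_sample(ems, [0.5, 0.5])
        bad["O"] = np.nan
        with pytest.raises(OMPError, match="non-finite"):
            solve_omp(bad, ems)

    def test_nonnegativity_outside_mixing_triangle(self, two_endmembers):
        # a sample colder/fresher than either endmember must not go negative
        ems, _ = two_endmembers
        sample = mix_sample(ems, [0.0, 1.0])
        sample["T"] -= 3.0
        sample["S"] -= 0.5
        sol = solve_omp(sample, ems)
        assert np.all(sol.fractions >= 0)

    def test_grid_search_oracle_dominance(self, three_endmembers, rng):
        """NNLS objective never exceeds the best 0.01-step simplex grid point."""
        ems, _ = three_endmembers
        for _ in range(20):
            x_true = rng.dirichlet(np.ones(3))
            sample = mix_sample(ems, x_true)
            noisy = {p: sample[p] + rng.normal(0, 0.3) for p in PROPERTIES}
            sol = solve_omp(noisy, ems)
            x_grid, obj_grid = grid_search_omp(noisy, ems, step=0.01)
            assert sol.objective <= obj_grid + 1e-9
            # loose sanity bound: flat objective directions can separate the
            # two argmins, but never by much on a 0.01 grid
            assert np.abs(sol.fractions - x_grid).max() < 0.05

    def test_mass_weight_monotonically_tightens_mass_residual(self, two_endmembers):
        ems, _ = two_endmembers
        sample = mix_sample(ems, [0.6, 0.4])
        sample["T"] += 1.5  # inconsistent observation forces residuals
        last = np.inf
        for mw in (1.0, 10.0, 100.0, 1000.0):
            ems_w = EndmemberSet(ems.names, ems.properties, mass_weight=mw)
            sol = solve_omp(sample, ems_w)
            assert abs(sol.mass_residual) <= last + 1e-12
            last = abs(sol.mass_residual)


class TestOMPSection:
    def test_noiseless_section_recovered_exactly(self):
        cfg = syn.default_scenario(seed=7, n_stations=5, noise_sd={}, ch4_noise_sd=0.0)
        samples, truth = syn.generate_section(cfg)
        sec = omp_section(samples, cfg.endmembers)
        frac_cols = [f"frac_{n}" for n in cfg.endmembers.names]
        err = np.abs(sec[frac_cols].to_numpy() - truth[frac_cols].to_numpy()).max()
        assert err < 1e-9

    def test_empty_input_returns_empty_table(self, two_endmembers):
        ems, _ = two_endmembers
        out = omp_section(pd.DataFrame(), ems)
        assert out.empty

    def test_bad_sample_flagged_not_fatal(self, two_endmembers):
        ems, _ = two_endmembers
        rows = [
            {"station": "A", "depth_m": 5.0, **mix_sample(ems, [1.0, 0.0])},
            {"station": "B", "depth_m": 5.0, **mix_sample(ems, [0.5, 0.5])},
        ]
        rows[0]["Si"] = np.nan
        out = omp_section(pd.DataFrame(rows), ems)
        assert out["failed"].tolist() == [True, False]


class TestClassifyDominant:
    @pytest.mark.parametrize(
        "fractions, expected, tie",
        [([0.7, 0.2, 0.1], "a", False), ([0.5, 0.5, 0.0], "a", True), ([0.0, 1.0, 0.0], "b", False)],
    )
    def test_argmax_and_tie_rule(self, fractions, expected, tie):
        from oceanch4.omp import OMPSolution

        sol = OMPSolution(
            names=("a", "b", "c"),
            fractions=np.array(fractions),
            residuals={},
            residuals_scaled={},
            mass_residual=0.0,
            objective=0.0,
        )
        label, frac, tied = classify_dominant_mass(sol)
        assert label == expected
        assert tied is tie
        assert frac == max(fractions)
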