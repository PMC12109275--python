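"""Factorial design generation, effect estimation, optimum selection."""

import numpy as np
import pandas as pd
import pytest

from fundusfusion.doe import (
    DEFAULT_FACTORS,
    Factor,
    estimate_effects,
    full_factorial,
    rank_combinations,
    run_design,
    select_optimum,
)


def _factors(k):
    return [Factor(f"F{i}", 0, 1) for i in range(k)]


class TestFullFactorial:
    def test_2pow4_has_16_runs(self):
        design = full_factorial(DEFAULT_FACTORS)
        assert design.runs.shape == (16, 4)
        assert len(np.unique(design.runs, axis=0)) == 16

    def test_one_factor_two_runs(self):
        design = full_factorial(_factors(1))
        np.testing.assert_array_equal(design.runs, [[-1], [1]])

    def test_standard_order_first_factor_fastest(self):
        design = full_factorial(_factors(3))
        np.testing.assert_array_equal(design.runs[:4, 0], [-1, 1, -1, 1])
        np.testing.assert_array_equal(design.runs[:4, 1], [-1, -1, 1, 1])

    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5, 6])
    def test_balance_and_orthogonality(self, k):
        runs = full_factorial(_factors(k)).runs
        assert np.all(runs.sum(axis=0) == 0)  # balanced columns
        gram = runs.T @ runs
        assert np.all(gram[~np.eye(k, dtype=bool)] == 0)  # orthogonal pairs

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            full_factorial([Factor("A", 0, 1), Factor("A", 2, 3)])

    def test_equal_levels_rejected(self):
        with pytest.raises(ValueError):
            Factor("A", 1, 1)


class TestRunDesign:
    def test_16_runs_x_2_replicates(self):
        design = full_factorial(DEFAULT_FACTORS, replicates=2)
        calls = []

        def experiment(settings, seed):
            calls.append((tuple(settings.values()), seed))
            return np.array([0.5, 0.6])

        results = run_design(design, experiment)
        assert len(calls) == 32
        assert len(results) == 32

    def test_stored_mean_matches_accuracies(self):
        design = full_factorial(_factors(2), replicates=1)
        results = run_design(design, lambda s, seed: np.array([0.2, 0.4, 0.9]))
        for r in results:
            assert r.mean == pytest.approx(np.mean(r.accuracies))

    def test_deterministic_callback_reproducible(self):
        design = full_factorial(_factors(2), replicates=2)

        def experiment(settings, seed):
            rng = np.random.default_rng(seed)
            return rng.random(3)

        a = run_design(design, experiment)
        b = run_design(design, experiment)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.accuracies, rb.accuracies)

    def test_callback_failure_recorded_not_fatal(self):
        design = full_factorial(_factors(1), replicates=1)

        def experiment(settings, seed):
            if settings["F0"] == 1:
                raise RuntimeError("diverged")
            return np.array([0.7])

        results = run_design(design, experiment)
        assert results[0].error is None
        assert results[1].error == "diverged"
        assert results[1].accuracies is None


class TestEstimateEffects:
    def test_noiseless_linear_response_recovered(self):
        design = full_factorial(_factors(3), replicates=2)
        coded = design.runs

        def experiment(settings, seed):
            j = experiment.counter // design.replicates
            experiment.counter += 1
            a = coded[j]
            return np.array([3.0 + 2.0 * a[0]])  # y = 3 + 2*F0

        experiment.counter = 0
        results = run_design(design, experiment)
        table = estimate_effects(design, results)
        by_term = table.set_index("Term")
        assert by_term.loc["F0", "Effect"] == pytest.approx(4.0, abs=1e-10)
        assert by_term.loc["F0", "Coef"] == pytest.approx(2.0, abs=1e-10)
        assert by_term.loc["F1", "Effect"] == pytest.approx(0.0, abs=1e-10)
        assert by_term.loc["F2", "Effect"] == pytest.approx(0.0, abs=1e-10)

    def test_constant_response_all_effects_zero(self):
        design = full_factorial(_factors(2), replicates=2)
        results = run_design(design, lambda s, seed: np.array([0.8, 0.8]))
        table = estimate_effects(design, results)
        assert np.allclose(table["Effect"], 0.0)

    def test_effect_is_twice_coefficient(self):
        design = full_factorial(_factors(4), replicates=2)

        def experiment(settings, seed):
            return np.random.default_rng(seed).uniform(0.5, 1.0, 5)

        table = estimate_effects(design, run_design(design, experiment))
        np.testing.assert_allclose(table["Effect"], 2.0 * table["Coef"])

    def test_coefficient_se_matches_theory_with_noise(self):
        """Empirical SD of coefficients ~ sigma/sqrt(N) over 200 reps."""
        sigma = 0.05
        design = full_factorial(_factors(4), replicates=2)
        n_total = len(design.runs) * design.replicates  # one response per run
        coefs = []
        master = np.random.default_rng(2024)
        for _ in range(200):
            def experiment(settings, seed, rng=master):
                return np.array([0.7 + sigma * rng.standard_normal()])

            table = estimate_effects(design, run_design(design, experiment))
            coefs.append(table["Coef"].to_numpy())
        emp_sd = np.std(np.array(coefs), axis=0, ddof=1)
        theory = sigma / np.sqrt(n_total)
        assert np.all(np.abs(emp_sd - theory) / theory < 0.20)

    def test_interaction_terms_estimable(self):
        design = full_factorial(_factors(2), replicates=2)
        coded = design.runs

        def experiment(settings, seed):
            j = experiment.counter // design.replicates
            experiment.counter += 1
            a = coded[j]
            return np.array([1.0 + 0.5 * a[0] * a[1]])

        experiment.counter = 0
        results = run_design(design, experiment)
        table = estimate_effects(design, results, terms=["F0", "F1", "F0:F1"])
        by_term = table.set_index("Term")
        assert by_term.loc["F0:F1", "Coef"] == pytest.approx(0.5, abs=1e-10)


class TestSelectOptimum:
    def test_sign_pattern_plus_plus_minus_plus(self):
        """Coefficients (+,+,-,+) pick (4 layers, 16 nodes, 2 layers, 16 nodes)."""
        table = pd.DataFrame({
            "Term": ["A3", "B3", "C3", "D3"],
            "Effect": [0.006, 0.009, -0.002, 0.021],
            "Coef": [0.003, 0.004, -0.001, 0.011],
            "T-Value": [2.09, 2.92, -0.75, 7.04],
            "p-Value": [0.041, 0.005, 0.456, 0.0],
        })
        opt = select_optimum(table, factors=DEFAULT_FACTORS)
        assert opt["A3"]["setting"] == 4
        assert opt["B3"]["setting"] == 16
        assert opt["C3"]["setting"] == 2
        assert opt["D3"]["setting"] == 16

    def test_all_negative_gives_all_low(self):
        table = pd.DataFrame({"Term": ["A", "B"], "Effect": [-1, -2],
                              "Coef": [-0.5, -1.0], "T-Value": [0, 0],
                              "p-Value": [1, 1]})
        opt = select_optimum(table)
        assert all(v["level"] == -1 for v in opt.values())

    def test_zero_coefficient_breaks_to_low(self):
        table = pd.DataFrame({"Term": ["A"], "Effect": [0.0], "Coef": [0.0],
                              "T-Value": [0.0], "p-Value": [1.0]})
        assert select_optimum(table)["A"]["level"] == -1


class TestRankCombinations:
    def _results(self, design, means):
        def experiment(settings, seed):
            j = experiment.counter // design.replicates
            experiment.counter += 1
            return np.array([means[j], means[j]])

        experiment.counter = 0
        return run_design(design, experiment)

    def test_highest_mean_first(self):
        design = full_factorial(_factors(2), replicates=1)
        means = [0.6, 0.9, 0.7, 0.5]
        table = rank_combinations(design, self._results(design, means))
        assert table.iloc[0]["combination"] == 2
        assert table.iloc[0]["mean_accuracy"] == pytest.approx(0.9)

    def test_rows_carry_decoded_settings(self):
        design = full_factorial(DEFAULT_FACTORS, replicates=1)
        means = list(np.linspace(0.5, 0.9, 16))
        table = rank_combinations(design, self._results(design, means))
        assert {"A3", "B3", "C3", "D3"} <= set(table.columns)
        assert set(table["A3"]) <= {2, 4}
        assert set(table["D3"]) <= {4, 16}

    def test_ranking_invariant_to_input_order(self):
        design = full_factorial(_factors(2), replicates=1)
        results = self._results(design, [0.6, 0.9, 0.7, 0.5])
        a = rank_combinations(design, results)
        b = rank_combinations(design, list(reversed(results)))
        pd.testing.assert_frame_equal(a, b)
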