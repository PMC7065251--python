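import numpy as np
import pandas as pd
import pytest

from surromix.mcmc import MCMCConfig
from surromix.simulate import (
    ScenarioResults,
    ScenarioSpec,
    generate_replication,
    get_scenario,
    performance_metrics,
    run_scenario,
    scenario_presets,
    solve_psi1,
)


class TestSolvePsi1:
    def test_table_inputs_give_known_value(self):
        # design-1 class-1 inputs; the value also satisfies the Monte Carlo
        # correlation check below
        assert solve_psi1(0.08, 0.40, 0.89) == pytest.approx(0.3904, abs=2e-4)

    def test_symmetric_case(self):
        assert solve_psi1(0.3, 1.0, 1 / np.sqrt(2)) == pytest.approx(0.3)

    def test_monotone_in_rho_b(self):
        vals = [solve_psi1(0.08, 0.5, r) for r in (0.5, 0.9, 0.99)]
        assert vals[0] < vals[1] < vals[2]

    def test_sign_of_slope_irrelevant(self):
        assert solve_psi1(0.1, -0.4, 0.9) == solve_psi1(0.1, 0.4, 0.9)

    @pytest.mark.parametrize("kwargs", [
        {"psi2": 0.1, "lambda1": 0.0, "rho_b": 0.9},
        {"psi2": 0.1, "lambda1": 0.5, "rho_b": 1.0},
        {"psi2": -0.1, "lambda1": 0.5, "rho_b": 0.9},
    ])
    def test_domain_errors(self, kwargs):
        with pytest.raises(ValueError):
            solve_psi1(**kwargs)

    def test_monte_carlo_correlation_oracle(self):
        """psi1 from the inversion must reproduce the target between-study
        correlation when simulating the true effects directly."""
        rng = np.random.default_rng(0)
        psi2, lam1, rho_b = 0.08, 0.40, 0.89
        psi1 = solve_psi1(psi2, lam1, rho_b)
        mu1 = rng.normal(0.3, psi1, 1_000_000)
        mu2 = lam1 * mu1 + rng.normal(0.0, psi2, 1_000_000)
        assert np.corrcoef(mu1, mu2)[0, 1] == pytest.approx(rho_b, abs=0.005)


class TestGeneration:
    def test_design1_n16_shape(self):
        ds, truth = generate_replication(get_scenario("design1_n16"), 1)
        assert ds.n_studies == 80
        assert ds.n_classes == 5
        assert list(ds.n_per_class) == [16] * 5
        assert truth.mu1.shape == (80,)

    def test_unbalanced_sizes(self):
        ds, _ = generate_replication(get_scenario("design3_unbalanced"), 1)
        assert list(ds.n_per_class) == [4, 8, 6, 10, 7]

    def test_noiseless_limit_recovers_truth(self):
        spec = get_scenario("design1_n16")
        tiny = ScenarioSpec(
            name="tiny-noise",
            lambda1=spec.lambda1, rho_b=spec.rho_b, psi2=spec.psi2,
            n_j=spec.n_j, sigma=1e-9,
        )
        ds, truth = generate_replication(tiny, 3)
        np.testing.assert_allclose(ds.y1, truth.mu1, atol=1e-6)
        np.testing.assert_allclose(ds.y2, truth.mu2, atol=1e-6)

    def test_moment_oracle(self):
        """Empirical moments of the generated true effects match the
        closed-form algebra of the product-normal generator."""
        one_class = ScenarioSpec(
            name="one", lambda1=(0.45,), rho_b=(0.90,), psi2=(0.08,), n_j=(100_000,)
        )
        ds, truth = generate_replication(one_class, 5)
        psi1 = one_class.psi1[0]
        sd_mu2 = np.sqrt(0.45**2 * psi1**2 + 0.08**2)
        assert np.corrcoef(truth.mu1, truth.mu2)[0, 1] == pytest.approx(0.90, abs=0.005)
        assert truth.mu2.std() == pytest.approx(sd_mu2, rel=0.005)
        assert truth.mu1.mean() == pytest.approx(0.3, abs=0.005)

    def test_seed_determinism(self):
        a, _ = generate_replication(get_scenario("design2_n8"), 42)
        b, _ = generate_replication(get_scenario("design2_n8"), 42)
        assert a.to_frame().equals(b.to_frame())
        c, _ = generate_replication(get_scenario("design2_n8"), 43)
        assert not a.to_frame().equals(c.to_frame())


def test_nine_presets_resolve():
    presets = scenario_presets()
    assert len(presets) == 9
    for d in (1, 2, 3):
        for size in ("n16", "n8", "unbalanced"):
            assert f"design{d}_{size}" in presets
    with pytest.raises(KeyError, match="valid presets"):
        get_scenario("design4_n2")


class TestPerformanceMetrics:
    @staticmethod
    def _results(rows):
        spec = get_scenario("design1_n16")
        return ScenarioResults(scenario=spec, records=pd.DataFrame(rows))

    @staticmethod
    def _row(rep, model, cid, truth, est, half=0.2, strong=False):
        return {
            "rep": rep, "model": model, "class_id": cid,
            "lam1_true": truth, "lam1_hat": est,
            "lo": est - half, "hi": est + half, "width": 2 * half,
            "mc_error": 0.001, "bf_psi": 1.0, "intercept_ok": True,
            "slope_ok": True, "variance_ok": strong, "strong": strong,
            "p_weight": np.nan, "flagged": False,
        }

    def test_perfect_estimates(self):
        rows = [self._row(r, "standard", "c1", 0.5, 0.5, strong=True) for r in range(4)]
        table = self._results(rows).aggregate()
        row = table.by_model.iloc[0]
        assert row["coverage"] == 1.0
        assert row["abs_bias"] == 0.0
        assert row["rmse"] == 0.0
        assert row["p_strong"] == 1.0

    def test_symmetric_errors_hand_computed(self):
        # estimates truth +/- d: bias of the mean is 0, |error| and RMSE are d
        d = 0.1
        rows = [
            self._row(0, "standard", "c1", 0.5, 0.5 + d),
            self._row(1, "standard", "c1", 0.5, 0.5 - d),
        ]
        row = self._results(rows).aggregate().by_model.iloc[0]
        assert row["abs_bias_of_mean"] == pytest.approx(0.0, abs=1e-12)
        assert row["abs_bias"] == pytest.approx(d)
        assert row["rmse"] == pytest.approx(d)

    def test_width_ratio_against_itself_is_one(self):
        rows = []
        for r in range(3):
            rows.append(self._row(r, "standard", "c1", 0.5, 0.5, half=0.3))
            rows.append(self._row(r, "fex", "c1", 0.5, 0.5, half=0.3))
        table = self._results(rows).aggregate()
        by = table.by_model.set_index("model")
        assert by.loc["fex", "width_ratio"] == pytest.approx(1.0)
        assert np.isnan(by.loc["standard", "width_ratio"])

    def test_mismatched_replications_raise(self):
        rows = [
            self._row(0, "standard", "c1", 0.5, 0.5),
            self._row(0, "fex", "c1", 0.5, 0.5),
            self._row(1, "fex", "c1", 0.5, 0.5),
        ]
        with pytest.raises(ValueError, match="mismatched"):
            self._results(rows).aggregate()


def test_single_replication_run_is_well_formed(fast_mcmc):
    res = run_scenario(
        "design1_n8", models=("standard",), n_reps=1, mcmc=fast_mcmc, seed=3
    )
    assert res.records["rep"].nunique() == 1
    table = res.aggregate()
    assert set(table.per_class["coverage"]).issubset({0.0, 1.0})


def test_run_scenario_seed_determinism(fast_mcmc):
    a = run_scenario("design1_n8", models=("standard",), n_reps=2, mcmc=fast_mcmc, seed=5)
    b = run_scenario("design1_n8", models=("standard",), n_reps=2, mcmc=fast_mcmc, seed=5)
    pd.testing.assert_frame_equal(a.records, b.records)
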