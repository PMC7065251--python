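import json

import numpy as np
import pytest

from surromix import SurrogacyDataset, TrialRecord
from surromix.mcmc import MCMCConfig, mc_error
from surromix.models import (
    DEFAULT_PRIORS,
    PriorConfig,
    _fit,
    fit_fex,
    fit_model,
    fit_pex,
    fit_standard,
    summarize_fit,
)


def _combined_tol(fit_a, fit_b, name, cid, k=4.0):
    ea = fit_a.class_summary(name, cid).mc_error
    eb = fit_b.class_summary(name, cid).mc_error
    return k * np.hypot(ea, eb)


def test_noiseless_linear_limit(fast_mcmc):
    """Data lying exactly on y2 = 0.5*y1 with tiny SEs pin the slope."""
    y1 = np.linspace(-1, 1, 10)
    records = [
        TrialRecord(f"s{i}", "c", float(y1[i]), float(0.5 * y1[i]), 1e-3, 1e-3, 0.0)
        for i in range(10)
    ]
    fit = fit_standard(SurrogacyDataset(records), mcmc=fast_mcmc)
    s = fit.class_summary("lam1", "c")
    assert s.mean == pytest.approx(0.5, abs=0.01)
    assert np.median(fit.chain("psi", "c")) < 0.02


def test_linear_gaussian_oracle_with_fixed_latents(medium_mcmc):
    """With mu1 and psi pinned the posterior of (lambda0, lambda1) is exactly
    Gaussian; the sampler must match the closed form from precision algebra."""
    rng = np.random.default_rng(5)
    n, psi = 12, 0.15
    mu1 = rng.normal(0.3, 0.5, n)
    records = [
        TrialRecord(
            f"s{i}", "c",
            float(mu1[i] + 0.1 * rng.standard_normal()),
            float(0.1 + 0.6 * mu1[i] + 0.2 * rng.standard_normal()),
            0.1, 0.12, 0.4,
        )
        for i in range(n)
    ]
    ds = SurrogacyDataset(records)
    fit = _fit(
        ds, "standard", DEFAULT_PRIORS, medium_mcmc,
        fix={"mu1": mu1, "psi": psi},
    )
    # oracle: z = y2 - k*(y1 - mu1) ~ N(l0 + l1*mu1, c + psi^2), flat-ish prior
    k = ds.rho_w * ds.se2 / ds.se1
    z = ds.y2 - k * (ds.y1 - mu1)
    v = ds.se2**2 * (1 - ds.rho_w**2) + psi**2
    X = np.column_stack([np.ones(n), mu1])
    a2 = DEFAULT_PRIORS.loc_sd**2
    prec = X.T @ (X / v[:, None]) + np.eye(2) / a2
    cov = np.linalg.inv(prec)
    mean = cov @ (X.T @ (z / v))
    for idx, name in enumerate(("lam0", "lam1")):
        s = fit.class_summary(name, "c")
        assert s.mean == pytest.approx(mean[idx], abs=4 * s.mc_error)
        assert s.sd == pytest.approx(np.sqrt(cov[idx, idx]), rel=0.06)


class TestHierarchicalLimits:
    def test_no_pooling_limit_equals_subgroup_fits(self, three_class_dataset, medium_mcmc):
        fex = _fit(
            three_class_dataset, "fex", DEFAULT_PRIORS, medium_mcmc,
            fix={"xi0": 1e6, "xi1": 1e6},
        )
        std = fit_standard(three_class_dataset, mcmc=medium_mcmc)
        for cid in three_class_dataset.class_ids:
            diff = abs(
                fex.class_summary("lam1", cid).mean - std.class_summary("lam1", cid).mean
            )
            assert diff < _combined_tol(fex, std, "lam1", cid)

    def test_complete_pooling_limit_collapses_slopes(self, three_class_dataset, fast_mcmc):
        fex = _fit(
            three_class_dataset, "fex", DEFAULT_PRIORS, fast_mcmc,
            fix={"xi0": 1e-6, "xi1": 1e-6},
        )
        means = [fex.class_summary("lam1", c).mean for c in fex.class_ids]
        assert np.ptp(means) < 1e-3

    def test_pex_with_pi_one_matches_fex(self, three_class_dataset, medium_mcmc):
        pex = fit_pex(three_class_dataset, pi=1.0, mcmc=medium_mcmc)
        fex = fit_fex(three_class_dataset, mcmc=medium_mcmc)
        assert np.all(pex.run.pooled("p") == 1.0)
        for cid in three_class_dataset.class_ids:
            for name in ("lam0", "lam1", "psi"):
                diff = abs(
                    pex.class_summary(name, cid).mean
                    - fex.class_summary(name, cid).mean
                )
                assert diff < _combined_tol(pex, fex, name, cid)

    def test_pex_with_pi_zero_matches_subgroup_slopes(self, three_class_dataset, medium_mcmc):
        # with pi = 0 every slope uses the vague component; the remaining
        # difference from the subgroup fit is the intercept hierarchy, so
        # that borrowing is disabled too for an exact limit
        pex = _fit(
            three_class_dataset, "pex", DEFAULT_PRIORS, medium_mcmc,
            pi=0.0, fix={"xi0": 1e6},
        )
        std = fit_standard(three_class_dataset, mcmc=medium_mcmc)
        assert np.all(pex.run.pooled("p") == 0.0)
        for cid in three_class_dataset.class_ids:
            for name in ("lam0", "lam1"):
                diff = abs(
                    pex.class_summary(name, cid).mean
                    - std.class_summary(name, cid).mean
                )
                assert diff < _combined_tol(pex, std, name, cid)

    def test_shrinkage_direction(self, three_class_dataset, medium_mcmc):
        """Exchangeable slope estimates lie weakly between the subgroup
        estimate and the common mean beta1."""
        fex = fit_fex(three_class_dataset, mcmc=medium_mcmc)
        std = fit_standard(three_class_dataset, mcmc=medium_mcmc)
        b1 = fex.scalar_summary("beta1")
        for cid in three_class_dataset.class_ids:
            sub = std.class_summary("lam1", cid).mean
            ex = fex.class_summary("lam1", cid).mean
            slack = 2 * np.sqrt(
                fex.class_summary("lam1", cid).mc_error ** 2
                + std.class_summary("lam1", cid).mc_error ** 2
                + b1.mc_error**2
            )
            lo, hi = min(sub, b1.mean) - slack, max(sub, b1.mean) + slack
            assert lo <= ex <= hi


def test_single_study_class_posterior_is_prior(fast_mcmc):
    """One study cannot identify a slope: its posterior width must match the
    vague prior's 95% width."""
    records = [
        TrialRecord("only", "solo", 0.05, 0.1, 0.1, 0.1, 0.4),
    ]
    ds = SurrogacyDataset(records)
    cfg = MCMCConfig(n_iter=30000, burn_in=3000, n_chains=1, seed=1, adapt_iter=3000)
    with pytest.warns(UserWarning, match="slope unidentified"):
        fit = fit_standard(ds, mcmc=cfg)
    s = fit.class_summary("lam1", "solo")
    prior_width = 2 * 1.959964 * DEFAULT_PRIORS.loc_sd
    assert (s.q97_5 - s.q2_5) == pytest.approx(prior_width, rel=0.10)


def test_label_invariance_under_class_permutation(three_class_dataset, medium_mcmc):
    recs = list(three_class_dataset.records)
    permuted = SurrogacyDataset(
        [r for r in recs if r.class_id == "antiVEGF"]
        + [r for r in recs if r.class_id != "antiVEGF"]
    )
    a = fit_fex(three_class_dataset, mcmc=medium_mcmc)
    b = fit_fex(permuted, mcmc=medium_mcmc)
    assert b.class_ids[0] == "antiVEGF"
    for cid in three_class_dataset.class_ids:
        diff = abs(a.class_summary("lam1", cid).mean - b.class_summary("lam1", cid).mean)
        assert diff < _combined_tol(a, b, "lam1", cid)
    hyper_diff = abs(a.scalar_summary("beta1").mean - b.scalar_summary("beta1").mean)
    tol = 4 * np.hypot(a.scalar_summary("beta1").mc_error, b.scalar_summary("beta1").mc_error)
    assert hyper_diff < tol


class TestSummaries:
    def test_psi2_uses_median_of_squares(self, three_class_dataset, fast_mcmc):
        fit = fit_standard(three_class_dataset, mcmc=fast_mcmc)
        table = fit.summary().set_index("parameter")
        for cid in fit.class_ids:
            chain = fit.chain("psi", cid)
            assert table.loc[f"psi2[{cid}]", "median"] == pytest.approx(
                np.median(chain**2)
            )

    def test_symmetric_chain_mean_close_to_median(self, three_class_dataset, fast_mcmc):
        fit = fit_fex(three_class_dataset, mcmc=fast_mcmc)
        s = fit.scalar_summary("beta1")
        assert s.mean == pytest.approx(s.median, abs=4 * s.mc_error)

    def test_dumped_chains_reproduce_summaries(self, three_class_dataset, fast_mcmc, tmp_path):
        fit = fit_fex(three_class_dataset, mcmc=fast_mcmc)
        path = tmp_path / "chains.csv"
        fit.dump_chains(path)
        import pandas as pd

        chains = pd.read_csv(path)
        for cid in fit.class_ids:
            col = chains[f"lam1[{cid}]"].to_numpy()
            assert col.mean() == pytest.approx(
                fit.class_summary("lam1", cid).mean, rel=1e-12
            )

    def test_json_export(self, three_class_dataset, fast_mcmc, tmp_path):
        fit = fit_pex(three_class_dataset, pi=0.5, mcmc=fast_mcmc)
        path = tmp_path / "fit.json"
        fit.to_json(path)
        payload = json.loads(path.read_text())
        assert payload["model"] == "pex"
        assert set(payload["mixture_weights"]) == set(three_class_dataset.class_ids)
        assert all(0.0 <= w <= 1.0 for w in payload["mixture_weights"].values())


def test_unknown_model_kind_rejected(three_class_dataset):
    with pytest.raises(ValueError, match="unknown model kind"):
        fit_model("netma", three_class_dataset)


def test_prior_validation():
    with pytest.raises(ValueError):
        PriorConfig(loc_sd=-1.0)
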