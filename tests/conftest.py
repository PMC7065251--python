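import numpy as np
import pytest

from surromix import SurrogacyDataset, TrialRecord
from surromix.mcmc import MCMCConfig


@pytest.fixture(scope="session")
def fast_mcmc():
    """Short chains for unit tests; burn-in covers adaptation."""
    return MCMCConfig(n_iter=4000, burn_in=1500, n_chains=1, seed=42, adapt_iter=1500)


@pytest.fixture(scope="session")
def medium_mcmc():
    """Longer single chain where equivalence checks need small MC error."""
    return MCMCConfig(n_iter=20000, burn_in=4000, n_chains=2, seed=7, adapt_iter=4000)


def _linear_class(rng, class_id, n, slope, intercept=0.0, psi=0.05, se=0.1, rho=0.4):
    mu1 = rng.normal(0.3, 0.4, size=n)
    mu2 = intercept + slope * mu1 + rng.normal(0.0, psi, size=n)
    z = rng.standard_normal((n, 2))
    y1 = mu1 + se * z[:, 0]
    y2 = mu2 + se * (rho * z[:, 0] + np.sqrt(1 - rho**2) * z[:, 1])
    return [
        TrialRecord(f"{class_id}_s{i}", class_id, float(y1[i]), float(y2[i]), se, se, rho)
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def three_class_dataset():
    """Small synthetic dataset: three classes with similar slopes."""
    rng = np.random.default_rng(2024)
    records = (
        _linear_class(rng, "chemo", 8, 0.45)
        + _linear_class(rng, "antiEGFR", 6, 0.55)
        + _linear_class(rng, "antiVEGF", 7, 0.50)
    )
    return SurrogacyDataset(records)


@pytest.fixture()
def tiny_csv(tmp_path):
    path = tmp_path / "trials.csv"
    path.write_text(
        "study_id,class_id,y1,y2,se1,se2,rho_w\n"
        "s1,chemo,-0.2,-0.1,0.1,0.12,0.4\n"
        "s2,chemo,0.3,0.2,0.15,0.1,0.4\n"
        "s3,egfr,-0.5,-0.3,0.2,0.2,0.3\n"
    )
    return path
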