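"""Simulation study: class-structured data generation and operating characteristics.

Data are generated from the product-normal formulation of bivariate
random-effects meta-analysis: within class ``j`` the true surrogate
effects are ``mu1_ij ~ N(eta1_j, psi1_j^2)``, the true final-outcome
effects follow the linear relationship
``mu2_ij ~ N(lambda0_j + lambda1_j * mu1_ij, psi2_j^2)``, and the observed
effects are bivariate normal around the truth with within-study sd
``sigma`` and correlation ``rho_w``.  The marginal sd of the true
surrogate effects is not free: given the slope, the conditional sd and the
between-study correlation ``rho_b = corr(mu1, mu2)``, it must equal

    psi1 = psi2 / (|lambda1| * sqrt(1/rho_b^2 - 1)),

the unique positive solution of the correlation identity (``solve_psi1``).

Nine preset scenarios combine three designs (similar strong classes; one
outlying slope; a mix of strong and weak classes) with three study-count
patterns (16 per class, 8 per class, unbalanced 4/8/6/10/7) over five
treatment classes.  ``run_scenario`` generates replications, fits the
requested models, applies the surrogacy criteria, optionally runs
leave-one-out cross-validation against the simulated truth, and
aggregates coverage, absolute bias, RMSE, credible-interval width ratios
versus subgroup analysis, the largest Monte Carlo error and the
probability of declaring a strong association.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .criteria import assess_all
from .crossval import run_cv
from .data import SurrogacyDataset, TrialRecord
from .mcmc import MCMCConfig
from .models import DEFAULT_PRIORS, PriorConfig, fit_model

logger = logging.getLogger(__name__)

N_CLASSES = 5
UNBALANCED = (4, 8, 6, 10, 7)


def solve_psi1(psi2: float, lambda1: float, rho_b: float) -> float:
    """Sd of the true surrogate effects implied by the correlation identity.

    Inverts ``rho_b = lambda1*psi1 / sqrt(lambda1^2 psi1^2 + psi2^2)``;
    strictly increasing in ``rho_b`` and divergent as ``rho_b -> 1``.
    """
    if lambda1 == 0:
        raise ValueError("lambda1 must be nonzero")
    if not 0.0 < rho_b < 1.0:
        raise ValueError("rho_b must lie strictly in (0, 1)")
    if psi2 <= 0:
        raise ValueError("psi2 must be > 0")
    return psi2 / (abs(lambda1) * np.sqrt(1.0 / rho_b**2 - 1.0))


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation design: per-class truth plus shared noise settings."""

    name: str
    lambda1: tuple[float, ...]
    rho_b: tuple[float, ...]
    psi2: tuple[float, ...]
    n_j: tuple[int, ...]
    lambda0: tuple[float, ...] | None = None
    eta1: float = 0.3
    sigma: float = 0.1
    rho_w: float = 0.4

    def __post_init__(self) -> None:
        J = len(self.lambda1)
        if self.lambda0 is None:
            object.__setattr__(self, "lambda0", tuple(0.0 for _ in range(J)))
        for name in ("rho_b", "psi2", "n_j", "lambda0"):
            if len(getattr(self, name)) != J:
                raise ValueError(f"{name} must have one entry per class")
        if any(l == 0 for l in self.lambda1):
            raise ValueError("lambda1 entries must be nonzero")
        if any(not 0 < r < 1 for r in self.rho_b):
            raise ValueError("rho_b entries must lie in (0, 1)")
        if any(p <= 0 for p in self.psi2):
            raise ValueError("psi2 entries must be > 0")
        if any(n < 2 for n in self.n_j):
            raise ValueError("each class needs >= 2 studies")

    @property
    def n_classes(self) -> int:
        return len(self.lambda1)

    @property
    def psi1(self) -> tuple[float, ...]:
        return tuple(
            solve_psi1(p2, l1, rb)
            for p2, l1, rb in zip(self.psi2, self.lambda1, self.rho_b)
        )


def _designs() -> dict[int, dict]:
    return {
        1: dict(
            lambda1=(0.40, 0.45, 0.50, 0.55, 0.60),
            rho_b=(0.89, 0.90, 0.91, 0.92, 0.93),
            psi2=(0.08,) * 5,
        ),
        2: dict(
            lambda1=(0.60, 1.55, 1.60, 1.65, 1.70),
            rho_b=(0.93, 0.99, 0.99, 0.99, 0.99),
            psi2=(0.08,) * 5,
        ),
        3: dict(
            lambda1=(0.40, 0.50, 0.60, 0.70, 0.80),
            rho_b=(0.90, 0.70, 0.93, 0.75, 0.95),
            psi2=(0.08, 0.30, 0.08, 0.30, 0.08),
        ),
    }


def scenario_presets() -> dict[str, ScenarioSpec]:
    """The nine named scenarios (3 designs x 3 study-count patterns)."""
    sizes = {"n16": (16,) * 5, "n8": (8,) * 5, "unbalanced": UNBALANCED}
    presets = {}
    for d, params in _designs().items():
        for size_name, n_j in sizes.items():
            name = f"design{d}_{size_name}"
            presets[name] = ScenarioSpec(name=name, n_j=n_j, **params)
    return presets


def get_scenario(name: str) -> ScenarioSpec:
    presets = scenario_presets()
    if name not in presets:
        raise KeyError(
            f"unknown scenario {name!r}; valid presets: {sorted(presets)}"
        )
    return presets[name]


@dataclass(frozen=True)
class ReplicationTruth:
    """Simulated true effects behind one generated dataset."""

    scenario: ScenarioSpec
    mu1: np.ndarray
    mu2: np.ndarray
    class_codes: np.ndarray

    def lambda1_true(self) -> np.ndarray:
        return np.asarray(self.scenario.lambda1)


def generate_replication(
    scenario: ScenarioSpec, seed: int | np.random.Generator
) -> tuple[SurrogacyDataset, ReplicationTruth]:
    """Draw one dataset from the product-normal generator.

    Returns the aggregate dataset (observed effects, their sds and the
    within-study correlation) together with the hidden truth used for
    scoring.  Deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    records = []
    mu1_all, mu2_all, codes = [], [], []
    psi1 = scenario.psi1
    sig, rw = scenario.sigma, scenario.rho_w
    chol_off = sig * rw
    chol_res = sig * np.sqrt(1.0 - rw**2)
    for j in range(scenario.n_classes):
        nj = scenario.n_j[j]
        mu1 = rng.normal(scenario.eta1, psi1[j], size=nj)
        mu2 = rng.normal(
            scenario.lambda0[j] + scenario.lambda1[j] * mu1, scenario.psi2[j]
        )
        z = rng.standard_normal((nj, 2))
        y1 = mu1 + sig * z[:, 0]
        y2 = mu2 + chol_off * z[:, 0] + chol_res * z[:, 1]
        cid = f"class{j + 1}"
        for i in range(nj):
            records.append(
                TrialRecord(
                    study_id=f"{cid}_s{i + 1:02d}",
                    class_id=cid,
                    y1=float(y1[i]),
                    y2=float(y2[i]),
                    se1=sig,
                    se2=sig,
                    rho_w=rw,
                )
            )
        mu1_all.append(mu1)
        mu2_all.append(mu2)
        codes.append(np.full(nj, j))
    truth = ReplicationTruth(
        scenario=scenario,
        mu1=np.concatenate(mu1_all),
        mu2=np.concatenate(mu2_all),
        class_codes=np.concatenate(codes),
    )
    return SurrogacyDataset(records), truth


# ---------------------------------------------------------------------------
# scenario runs and performance aggregation
# ---------------------------------------------------------------------------

@dataclass
class ScenarioResults:
    """Per-replication, per-class results of one scenario run."""

    scenario: ScenarioSpec
    records: pd.DataFrame
    cv_records: pd.DataFrame | None = None
    n_failed: int = 0
    n_flagged: int = 0

    def aggregate(self, baseline: str = "standard") -> "PerformanceTable":
        return performance_metrics(self, baseline=baseline)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


@dataclass
class PerformanceTable:
    """Operating characteristics per model (and per class where relevant)."""

    scenario: str
    by_model: pd.DataFrame
    per_class: pd.DataFrame
    cv_by_model: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        out = {
            "scenario": self.scenario,
            "by_model": self.by_model.to_dict(orient="records"),
            "per_class": self.per_class.to_dict(orient="records"),
        }
        if self.cv_by_model is not None:
            out["cv_by_model"] = self.cv_by_model.to_dict(orient="records")
        return out


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def run_scenario(
    scenario: ScenarioSpec | str,
    models: tuple[str, ...] = ("standard", "fex", "pex"),
    n_reps: int = 200,
    mcmc: MCMCConfig = MCMCConfig(n_chains=1),
    seed: int = 0,
    priors: PriorConfig = DEFAULT_PRIORS,
    pi: float = 0.5,
    cv: bool = False,
    cv_reps: int | None = None,
    progress: bool = False,
) -> ScenarioResults:
    """Generate ``n_reps`` datasets, fit the requested models, score them.

    Replication ``r`` derives all of its seeds (generation, one per model
    fit, cross-validation) from child ``r`` of the root seed, so runs are
    reproducible and replications could be distributed across workers.
    A fit that raises or returns non-finite estimates is excluded and
    counted in ``n_failed``; a finite fit whose split-Rhat exceeds 1.05 is
    kept but counted in ``n_flagged``.
    """
    if isinstance(scenario, str):
        scenario = get_scenario(scenario)
    rows, cv_rows = [], []
    n_failed = n_flagged = 0
    rep_seeds = np.random.SeedSequence(seed).spawn(n_reps)
    cv_reps = n_reps if cv_reps is None else min(cv_reps, n_reps)
    for r in range(n_reps):
        children = rep_seeds[r].spawn(len(models) * 2 + 1)
        dataset, truth = generate_replication(
            scenario, np.random.default_rng(children[0])
        )
        for m, kind in enumerate(models):
            cfg = replace(mcmc, seed=_child_seed(children[1 + m]))
            try:
                fit = fit_model(kind, dataset, priors=priors, mcmc=cfg, **(
                    {"pi": pi} if kind == "pex" else {}
                ))
                verdicts = assess_all(fit)
            except Exception:  # noqa: BLE001 - scored runs must not abort
                logger.exception("replication %d: %s fit failed", r, kind)
                n_failed += 1
                continue
            weights = fit.mixture_weights() if kind == "pex" else None
            flagged = not fit.converged
            n_flagged += flagged
            bad = False
            rep_rows = []
            for j, cid in enumerate(fit.class_ids):
                s = fit.class_summary("lam1", cid)
                v = verdicts[j]
                if not np.isfinite(s.mean):
                    bad = True
                rep_rows.append(
                    {
                        "rep": r,
                        "model": kind,
                        "class_id": cid,
                        "lam1_true": scenario.lambda1[j],
                        "lam1_hat": s.mean,
                        "lo": s.q2_5,
                        "hi": s.q97_5,
                        "width": s.q97_5 - s.q2_5,
                        "mc_error": s.mc_error,
                        "bf_psi": v.bf_psi,
                        "intercept_ok": v.intercept_ok,
                        "slope_ok": v.slope_ok,
                        "variance_ok": v.variance_ok,
                        "strong": v.strong,
                        "p_weight": np.nan if weights is None else weights[cid],
                        "flagged": flagged,
                    }
                )
            if bad:
                n_failed += 1
            else:
                rows.extend(rep_rows)
        if cv and r < cv_reps:
            for m, kind in enumerate(models):
                cfg = replace(
                    mcmc, seed=_child_seed(children[1 + len(models) + m])
                )
                cv_res = run_cv(
                    dataset, kind, priors=priors, mcmc=cfg, pi=pi,
                    reference=truth.mu2,
                )
                for res in cv_res.results:
                    cv_rows.append(
                        {
                            "rep": r,
                            "model": kind,
                            "class_id": res.class_id,
                            "study_id": res.study_id,
                            "predicted_mean": res.predicted_mean,
                            "reference": res.reference_value,
                            "lo": res.lo,
                            "hi": res.hi,
                            "width": res.width,
                            "covered": res.covered,
                            "abs_error": res.absolute_error,
                            "mc_error": res.mc_error,
                        }
                    )
        if progress:
            logger.info("scenario %s: replication %d/%d done", scenario.name, r + 1, n_reps)
    if n_failed:
        logger.warning("scenario %s: %d failed fits excluded", scenario.name, n_failed)
    if n_flagged:
        logger.info("scenario %s: %d fits flagged by split-Rhat > 1.05", scenario.name, n_flagged)
    return ScenarioResults(
        scenario=scenario,
        records=pd.DataFrame(rows),
        cv_records=pd.DataFrame(cv_rows) if cv_rows else None,
        n_failed=n_failed,
        n_flagged=n_flagged,
    )


def _width_ratio(records: pd.DataFrame, model: str, baseline: str, keys: list[str]) -> float:
    if model == baseline:
        return np.nan
    left = records[records["model"] == model].set_index(keys)["width"]
    right = records[records["model"] == baseline].set_index(keys)["width"]
    common = left.index.intersection(right.index)
    if len(common) == 0:
        return np.nan
    if len(common) != len(left):
        raise ValueError("mismatched replication sets between models")
    return float((left.loc[common] / right.loc[common]).mean())


def performance_metrics(
    results: ScenarioResults, baseline: str = "standard"
) -> PerformanceTable:
    """Aggregate per-replication results into the operating characteristics.

    Coverage is the fraction of replications whose 95% credible interval
    contains the true slope, averaged over classes.  Absolute bias is the
    per-replication ``|error|`` averaged over replications and classes
    (``|mean(estimate) - truth|`` per class is also emitted, as
    ``abs_bias_of_mean``); RMSE is the per-class root mean squared error
    averaged over classes.  Width ratios divide a model's per-replication
    interval width by the subgroup model's on the same replication.
    ``p_strong`` is the fraction of class-replications declaring a strong
    association.
    """
    rec = results.records
    model_rows, class_rows = [], []
    for model, df in rec.groupby("model", sort=False):
        per_class = df.groupby("class_id", sort=False)
        cover = per_class.apply(
            lambda g: ((g["lo"] <= g["lam1_true"]) & (g["lam1_true"] <= g["hi"])).mean(),
            include_groups=False,
        )
        # headline absolute bias: mean over replications of |error|, then over
        # classes; |mean error| per class is emitted alongside
        bias = per_class.apply(
            lambda g: (g["lam1_hat"] - g["lam1_true"]).abs().mean(),
            include_groups=False,
        )
        bias_of_mean = per_class.apply(
            lambda g: abs(g["lam1_hat"].mean() - g["lam1_true"].iloc[0]),
            include_groups=False,
        )
        rmse = per_class.apply(
            lambda g: np.sqrt(((g["lam1_hat"] - g["lam1_true"]) ** 2).mean()),
            include_groups=False,
        )
        p_strong = per_class["strong"].mean()
        model_rows.append(
            {
                "model": model,
                "n_reps": int(df["rep"].nunique()),
                "coverage": float(cover.mean()),
                "abs_bias": float(bias.mean()),
                "abs_bias_of_mean": float(bias_of_mean.mean()),
                "rmse": float(rmse.mean()),
                "width_ratio": _width_ratio(rec, model, baseline, ["rep", "class_id"]),
                "max_mce": float(df["mc_error"].max()),
                "p_strong": float(p_strong.mean()),
            }
        )
        for cid in cover.index:
            class_rows.append(
                {
                    "model": model,
                    "class_id": cid,
                    "coverage": float(cover[cid]),
                    "abs_bias": float(bias[cid]),
                    "rmse": float(rmse[cid]),
                    "p_strong": float(p_strong[cid]),
                    "mean_p_weight": float(
                        df[df["class_id"] == cid]["p_weight"].mean()
                    ),
                }
            )
    cv_table = None
    if results.cv_records is not None:
        cv_rows = []
        cvr = results.cv_records
        for model, df in cvr.groupby("model", sort=False):
            cv_rows.append(
                {
                    "model": model,
                    "n_predictions": int(len(df)),
                    "coverage": float(df["covered"].mean()),
                    "abs_bias": float(df["abs_error"].mean()),
                    "rmse": float(np.sqrt((df["abs_error"] ** 2).mean())),
                    "width_ratio": _width_ratio(
                        cvr, model, baseline, ["rep", "study_id"]
                    ),
                    "max_mce": float(df["mc_error"].max()),
                }
            )
        cv_table = pd.DataFrame(cv_rows)
    return PerformanceTable(
        scenario=results.scenario.name,
        by_model=pd.DataFrame(model_rows),
        per_class=pd.DataFrame(class_rows),
        cv_by_model=cv_table,
    )
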