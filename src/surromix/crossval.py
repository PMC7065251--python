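"""Leave-one-out prediction of the final-outcome effect from the surrogate.

For each study in turn, the observed effect on the final outcome ``y2`` is
hidden and the model is refit: the held-out study contributes only the
marginal likelihood of its surrogate effect ``y1``, and its true
final-outcome effect ``mu2`` is supplied by the between-study regression.
The predictive mean is the posterior mean of ``mu2``; the predictive
variance decomposes as the known within-study sampling variance plus the
posterior variance of the true effect,

    var_pred = se2^2 + var(mu2 | y1, data without y2),

and the 95% predictive interval is ``mean +/- 1.96 * sd`` (normal form).
In simulation studies the interval is checked against the simulated true
effect; on real data, against the observed ``y2``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import SurrogacyDataset
from .mcmc import MCMCConfig, mc_error_chains
from .models import DEFAULT_PRIORS, ModelFit, PriorConfig, _fit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PredictionResult:
    """One leave-one-out prediction."""

    study_id: str
    class_id: str
    predicted_mean: float
    predictive_variance: float
    lo: float
    hi: float
    reference_value: float
    covered: bool
    absolute_error: float
    mc_error: float

    @property
    def width(self) -> float:
        return self.hi - self.lo


def _resolve_index(dataset: SurrogacyDataset, held_out: int | str) -> int:
    if isinstance(held_out, str):
        try:
            return dataset.study_ids.index(held_out)
        except ValueError as exc:
            raise KeyError(f"study {held_out!r} not in dataset") from exc
    if not 0 <= held_out < dataset.n_studies:
        raise KeyError(f"held-out index {held_out} out of range")
    return int(held_out)


def loo_predict(
    dataset: SurrogacyDataset,
    model_kind: str,
    held_out: int | str,
    priors: PriorConfig = DEFAULT_PRIORS,
    mcmc: MCMCConfig = MCMCConfig(),
    pi: float | np.ndarray = 0.5,
    reference: float | None = None,
    level: float = 0.95,
) -> tuple[PredictionResult, ModelFit]:
    """Refit with one study's ``y2`` treated as missing and predict it.

    For the standard (subgroup) model only the held-out study's class is
    used; the hierarchical models refit the full multi-class dataset.
    ``reference`` defaults to the observed ``y2`` of the held-out study;
    in simulation mode pass the simulated true effect instead.  The stored
    ``y2`` value of the held-out study does not influence the fit.
    """
    idx = _resolve_index(dataset, held_out)
    record = dataset.records[idx]
    if model_kind == "standard":
        sub = dataset.restrict(record.class_id)
        fit_data = sub
        fit_idx = sub.study_ids.index(record.study_id)
    else:
        fit_data = dataset
        fit_idx = idx
    missing = np.zeros(fit_data.n_studies, dtype=bool)
    missing[fit_idx] = True
    pi_arr = None
    if model_kind == "pex":
        if np.ndim(pi) > 0 and len(np.atleast_1d(pi)) == dataset.n_classes:
            # re-map per-class weights onto the (possibly restricted) data
            pi_arr = np.asarray(pi, dtype=float)
        else:
            pi_arr = np.broadcast_to(float(np.atleast_1d(pi)[0]), (fit_data.n_classes,))
    fit = _fit(
        fit_data,
        model_kind,
        priors,
        mcmc,
        pi=pi_arr if model_kind == "pex" else None,
        missing_y2=missing,
        monitor_mu=True,
    )
    mu2_chains = fit.run.chains["mu2"][:, :, fit_idx]
    draws = mu2_chains.ravel()
    predicted_mean = float(draws.mean())
    predictive_variance = float(record.se2**2 + draws.var(ddof=1))
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(predictive_variance)
    lo, hi = predicted_mean - half, predicted_mean + half
    ref = record.y2 if reference is None else float(reference)
    result = PredictionResult(
        study_id=record.study_id,
        class_id=record.class_id,
        predicted_mean=predicted_mean,
        predictive_variance=predictive_variance,
        lo=lo,
        hi=hi,
        reference_value=ref,
        covered=bool(lo <= ref <= hi),
        absolute_error=abs(predicted_mean - ref),
        mc_error=mc_error_chains(mu2_chains),
    )
    return result, fit


@dataclass
class CVResult:
    """Per-study leave-one-out predictions and their aggregates."""

    model_kind: str
    results: list[PredictionResult]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            d = vars(r).copy()
            d["width"] = r.width
            rows.append(d)
        return pd.DataFrame(rows)

    def summary(self, baseline: "CVResult | None" = None) -> dict:
        """Coverage, error and (against a baseline CV) interval-width ratios,
        overall and per class."""
        frame = self.to_frame()

        def block(df: pd.DataFrame) -> dict:
            return {
                "n": int(len(df)),
                "coverage": float(df["covered"].mean()),
                "median_abs_error": float(df["absolute_error"].median()),
                "mean_abs_error": float(df["absolute_error"].mean()),
            }

        out = {"model": self.model_kind, "overall": block(frame), "per_class": {}}
        if baseline is not None:
            base = baseline.to_frame().set_index("study_id")["width"]
            ratio = frame["width"].values / base.loc[frame["study_id"]].values
            frame = frame.assign(width_ratio=ratio)
            out["overall"]["median_width_ratio"] = float(np.median(ratio))
            out["overall"]["mean_width_ratio"] = float(np.mean(ratio))
        for cid, df in frame.groupby("class_id", sort=False):
            cb = block(df)
            if baseline is not None:
                cb["median_width_ratio"] = float(df["width_ratio"].median())
                cb["mean_width_ratio"] = float(df["width_ratio"].mean())
            out["per_class"][cid] = cb
        return out


def run_cv(
    dataset: SurrogacyDataset,
    model_kind: str,
    priors: PriorConfig = DEFAULT_PRIORS,
    mcmc: MCMCConfig = MCMCConfig(),
    pi: float | np.ndarray = 0.5,
    reference: np.ndarray | None = None,
    level: float = 0.95,
) -> CVResult:
    """Leave-one-out over every study; one refit per study.

    Each refit uses an independent seed derived from ``mcmc.seed``.
    ``reference`` (optional) is an array of truth values aligned with the
    dataset's record order (simulation mode).
    """
    if reference is not None and len(reference) != dataset.n_studies:
        raise ValueError("reference must align with dataset records")
    seeds = [
        int(s.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
        for s in np.random.SeedSequence(mcmc.seed).spawn(dataset.n_studies)
    ]
    results = []
    for i in range(dataset.n_studies):
        cfg = MCMCConfig(
            n_iter=mcmc.n_iter,
            burn_in=mcmc.burn_in,
            n_chains=mcmc.n_chains,
            seed=seeds[i],
            thin=mcmc.thin,
            adapt_iter=mcmc.adapt_iter,
        )
        ref = None if reference is None else float(reference[i])
        result, _ = loo_predict(
            dataset, model_kind, i, priors=priors, mcmc=cfg, pi=pi,
            reference=ref, level=level,
        )
        results.append(result)
    return CVResult(model_kind=model_kind, results=results)
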