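"""Bayesian models for trial-level surrogacy within and across treatment classes.

Three model fits share one likelihood: within each study the observed
effects ``(y1, y2)`` are bivariate normal around the true effects
``(mu1, mu2)`` with known standard errors and within-study correlation, and
between studies the true effects follow the Daniels–Hughes regression

    mu2 | mu1 ~ N(lambda0_j + lambda1_j * mu1, psi_j^2),

with the true surrogate effects ``mu1`` modeled as fixed effects under
vague normal priors.  The fits differ in the prior on the class-specific
regression parameters:

* ``fit_standard`` — independent vague priors per class (subgroup
  analysis; no borrowing of information),
* ``fit_fex`` — full exchangeability: ``lambda0_j ~ N(beta0, xi0^2)`` and
  ``lambda1_j ~ N(beta1, xi1^2)`` (borrowing across classes, shrinkage
  toward the common means),
* ``fit_pex`` — partial exchangeability: each slope is exchangeable with
  probability ``pi_j`` (Bernoulli indicator ``p_j``) and otherwise follows
  its own vague prior; the posterior mean of ``p_j`` is the class's
  mixture weight.

Location parameters have normal full conditionals and are updated by exact
Gibbs draws; the scale parameters (``psi_j``, ``xi0``, ``xi1``) use
adaptive random-walk Metropolis on the log scale.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import SurrogacyDataset
from .mcmc import (
    ChainSummary,
    ConjugateBlock,
    GibbsModel,
    MCMCConfig,
    RandomWalkBlock,
    SamplerRun,
    run_sampler,
    summarize_chain,
)

logger = logging.getLogger(__name__)

RHAT_FLAG = 1.05
_SCALE_FLOOR = 1e-3


@dataclass(frozen=True)
class PriorConfig:
    """Standard deviations of the vague priors.

    ``loc_sd`` (a) — sd of the normal priors on all location parameters
    (true surrogate effects, intercepts, slopes, hyper-means, and the
    non-exchangeable slope component in the partial-exchangeability
    model).  The default is the BUGS-conventional vague normal
    ``dnorm(0, 0.001)``, i.e. variance 1000.
    ``scale_sd`` (b) — sd of the half-normal priors on the between-class
    sds ``xi0``, ``xi1`` and, when no Bayes factor is required, on the
    conditional sds ``psi_j``; also the sd of the non-exchangeable slope
    prior in the partial-exchangeability model.
    ``psi_bf_sd`` — sd of the moderately informative half-normal prior on
    ``psi_j`` used whenever Savage–Dickey Bayes factors are wanted (the
    density ratio needs a proper, moderately concentrated prior).
    """

    loc_sd: float = 1000.0**0.5
    scale_sd: float = 10.0
    psi_bf_sd: float = 2.0

    def __post_init__(self) -> None:
        if min(self.loc_sd, self.scale_sd, self.psi_bf_sd) <= 0:
            raise ValueError("all prior sds must be > 0")


DEFAULT_PRIORS = PriorConfig()


def _json_scalar(obj):
    if isinstance(obj, np.generic):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")

_HIER_KINDS = ("fex", "pex")
MODEL_KINDS = ("standard",) + _HIER_KINDS


@dataclass
class ModelFit:
    """Posterior samples and summaries of one fitted surrogacy model."""

    kind: str
    class_ids: tuple[str, ...]
    study_ids: tuple[str, ...]
    class_codes: np.ndarray
    run: SamplerRun
    priors: PriorConfig
    mcmc: MCMCConfig
    psi_prior_sd: float
    pi: np.ndarray | None = None
    data_arrays: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _summary: pd.DataFrame | None = field(default=None, repr=False)

    # -- chain access ---------------------------------------------------
    def chain(self, name: str, class_id: str | None = None) -> np.ndarray:
        """Pooled retained draws; 1-D for scalars or a selected class."""
        arr = self.run.pooled(name)
        if class_id is not None:
            j = self.class_ids.index(class_id)
            return arr[:, j]
        return arr[:, 0] if arr.shape[1] == 1 else arr

    def class_chains(self, name: str) -> np.ndarray:
        """Per-chain draws of a class-indexed parameter, (C, K, J)."""
        return self.run.chains[name]

    @property
    def n_per_class(self) -> np.ndarray:
        return np.bincount(self.class_codes, minlength=len(self.class_ids))

    def class_summary(self, name: str, class_id: str) -> ChainSummary:
        j = self.class_ids.index(class_id)
        return summarize_chain(self.run.chains[name][:, :, j])

    def scalar_summary(self, name: str) -> ChainSummary:
        return summarize_chain(self.run.chains[name][:, :, 0])

    def mixture_weights(self) -> pd.Series:
        """Posterior mean of the exchangeability indicator per class."""
        if self.kind != "pex":
            raise ValueError("mixture weights exist only for the P-EX model")
        w = self.run.pooled("p").mean(axis=0)
        return pd.Series(w, index=list(self.class_ids), name="mixture_weight")

    @property
    def max_rhat(self) -> float:
        vals = []
        for name, arr in self.run.chains.items():
            if name in ("mu1", "mu2", "p"):
                continue
            for j in range(arr.shape[2]):
                vals.append(np.nan_to_num(self._rhat(arr[:, :, j]), nan=1.0))
        return float(max(vals)) if vals else np.nan

    @staticmethod
    def _rhat(chains_2d: np.ndarray) -> float:
        from .mcmc import split_rhat

        return split_rhat(chains_2d)

    @property
    def converged(self) -> bool:
        return self.max_rhat <= RHAT_FLAG

    # -- summaries ------------------------------------------------------
    def summary(self) -> pd.DataFrame:
        if self._summary is None:
            self._summary = summarize_fit(self)
        return self._summary

    def to_dict(self) -> dict:
        summary = self.summary().to_dict(orient="records")
        payload = {
            "model": self.kind,
            "class_ids": list(self.class_ids),
            "n_per_class": self.n_per_class.tolist(),
            "priors": vars(self.priors).copy(),
            "psi_prior_sd": self.psi_prior_sd,
            "mcmc": {k: getattr(self.mcmc, k) for k in
                     ("n_iter", "burn_in", "n_chains", "seed", "thin", "adapt_iter")},
            "summary": summary,
        }
        if self.kind == "pex":
            payload["pi"] = np.asarray(self.pi).tolist()
            payload["mixture_weights"] = self.mixture_weights().to_dict()
        return payload

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True, default=_json_scalar)
        )

    def dump_chains(self, path: str | Path) -> None:
        """CSV dump of all monitored scalars (one column per scalar)."""
        cols = {}
        for name, arr in self.run.chains.items():
            flat = arr.reshape(-1, arr.shape[-1])
            labels = self._labels(name, arr.shape[-1])
            for k, lab in enumerate(labels):
                cols[lab] = flat[:, k]
        pd.DataFrame(cols).to_csv(path, index=False)

    def _labels(self, name: str, dim: int) -> list[str]:
        if dim == 1:
            return [name]
        if dim == len(self.class_ids):
            return [f"{name}[{c}]" for c in self.class_ids]
        return [f"{name}[{s}]" for s in self.study_ids]


def summarize_fit(fit: ModelFit) -> pd.DataFrame:
    """Tabular posterior summary: one row per monitored scalar.

    Means with 95% credible intervals throughout; the conditional variances
    ``psi_j^2`` get extra rows summarized by the posterior median (their
    posteriors are strongly right-skewed, so the median is the reported
    point estimate).
    """
    rows = []

    def add_row(label: str, class_id: str, chains_2d: np.ndarray) -> None:
        s = summarize_chain(chains_2d)
        rows.append(
            {
                "parameter": label,
                "class_id": class_id,
                "mean": s.mean,
                "sd": s.sd,
                "median": s.median,
                "q2.5": s.q2_5,
                "q97.5": s.q97_5,
                "mc_error": s.mc_error,
                "rhat": s.rhat,
                "n": s.n,
            }
        )

    class_names = {c: j for j, c in enumerate(fit.class_ids)}
    for name, arr in fit.run.chains.items():
        if name in ("mu1", "mu2"):
            for i, sid in enumerate(fit.study_ids):
                cid = fit.class_ids[fit.class_codes[i]]
                add_row(f"{name}[{sid}]", cid, arr[:, :, i])
        elif name in ("beta0", "beta1", "xi0", "xi1"):
            add_row(name, "", arr[:, :, 0])
        else:
            for cid, j in class_names.items():
                add_row(f"{name}[{cid}]", cid, arr[:, :, j])
                if name == "psi":
                    add_row(f"psi2[{cid}]", cid, arr[:, :, j] ** 2)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

def _initial_values(
    y1: np.ndarray,
    y2: np.ndarray,
    se2: np.ndarray,
    cls: np.ndarray,
    n_classes: int,
    y2_obs: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class weighted least squares of y2 on y1 (moment starts)."""
    lam0 = np.zeros(n_classes)
    lam1 = np.zeros(n_classes)
    for j in range(n_classes):
        mask = (cls == j) & y2_obs
        xj, yj, wj = y1[mask], y2[mask], 1.0 / se2[mask] ** 2
        if mask.sum() >= 2 and np.ptp(xj) > 0:
            wsum = wj.sum()
            xbar, ybar = (wj * xj).sum() / wsum, (wj * yj).sum() / wsum
            sxx = (wj * (xj - xbar) ** 2).sum()
            if sxx > 0:
                lam1[j] = (wj * (xj - xbar) * (yj - ybar)).sum() / sxx
            lam0[j] = ybar - lam1[j] * xbar
        elif mask.sum() == 1:
            lam0[j] = yj[0]
    return lam0, lam1


def build_surrogacy_model(
    dataset: SurrogacyDataset,
    kind: str,
    priors: PriorConfig,
    psi_prior_sd: float,
    pi: np.ndarray | None = None,
    fix: dict[str, np.ndarray | float] | None = None,
    missing_y2: np.ndarray | None = None,
    monitor_mu: bool = False,
) -> GibbsModel:
    """Assemble the Gibbs/Metropolis update schedule for one model fit.

    ``fix`` pins named state entries at given values (no update block);
    ``missing_y2`` is a boolean mask of studies whose final-outcome
    estimate is treated as unobserved (their within-study likelihood
    reduces to the marginal of ``y1``), used by cross-validation.
    """
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")
    fix = dict(fix or {})
    hier = kind in _HIER_KINDS

    y1, y2 = dataset.y1, dataset.y2
    se1, se2, rho = dataset.se1, dataset.se2, dataset.rho_w
    cls = dataset.class_codes
    n, J = dataset.n_studies, dataset.n_classes
    n_j = dataset.n_per_class.astype(float)

    y2_obs = np.ones(n, dtype=bool)
    if missing_y2 is not None:
        y2_obs = ~np.asarray(missing_y2, dtype=bool)
    obs = y2_obs.astype(float)

    # The latent final-outcome effects mu2 are integrated out analytically:
    # given mu1 and the regression parameters, y2 | y1 is normal with mean
    # lambda0 + lambda1*mu1 + k*(y1 - mu1), k = rho*se2/se1, and variance
    # c + psi^2 with c = se2^2*(1 - rho^2).  This keeps the sampler out of
    # the psi -> 0 funnel (the collapsed likelihood is positive at psi = 0),
    # which matters for the Savage-Dickey density estimate at the boundary.
    # mu2 itself is drawn per iteration as a generated quantity when needed.
    one_m_r2 = 1.0 - rho**2
    k_slope = rho * se2 / se1
    c_var = se2**2 * one_m_r2
    z0 = np.where(y2_obs, y2 - k_slope * y1, 0.0)  # z = z0 + k*mu1
    # within-study precision elements for the generated mu2 draw
    w22 = np.where(y2_obs, 1.0 / (se2**2 * one_m_r2), 0.0)
    w12 = np.where(y2_obs, -rho / (se1 * se2 * one_m_r2), 0.0)
    y2s = np.where(y2_obs, y2, 0.0)  # value never used where weight is zero

    a2 = priors.loc_sd**2
    b = priors.scale_sd
    psi_sd = float(psi_prior_sd)
    if pi is not None:
        pi = np.broadcast_to(np.asarray(pi, dtype=float), (J,)).copy()
        if np.any((pi < 0) | (pi > 1)):
            raise ValueError("pi_j must lie in [0, 1]")

    def init(rng: np.random.Generator) -> dict:
        lam0_init, lam1_init = _initial_values(y1, y2, se2, cls, J, y2_obs)
        state = {
            "mu1": y1.copy(),
            "mu2": np.where(y2_obs, y2, lam0_init[cls] + lam1_init[cls] * y1),
            "lam0": lam0_init,
            "lam1": lam1_init,
            "psi": np.full(J, max(0.5 * psi_sd, _SCALE_FLOOR)),
        }
        if hier:
            state["beta0"] = np.array([lam0_init.mean()])
            state["beta1"] = np.array([lam1_init.mean()])
            state["xi0"] = np.array([max(0.5 * b, _SCALE_FLOOR)])
            state["xi1"] = np.array([max(0.5 * b, _SCALE_FLOOR)])
        if kind == "pex":
            state["p"] = np.ones(J)
        for name, value in fix.items():
            state[name] = np.broadcast_to(
                np.asarray(value, dtype=float), np.shape(state[name])
            ).copy()
        return state

    # -- location updates (exact Gibbs; normal-normal algebra) ----------
    def draw_mu1(state, rng):
        lam0c, lam1c = state["lam0"][cls], state["lam1"][cls]
        v = c_var + state["psi"][cls] ** 2
        coef = lam1c - k_slope
        prec = 1.0 / se1**2 + obs * coef**2 / v + 1.0 / a2
        lin = y1 / se1**2 + obs * coef * (z0 - lam0c) / v
        return lin / prec + rng.standard_normal(n) / np.sqrt(prec)

    def draw_mu2(state, rng):
        # generated quantity: exact conditional given mu1 and the regression
        mu1 = state["mu1"]
        lam0c, lam1c = state["lam0"][cls], state["lam1"][cls]
        psic2 = state["psi"][cls] ** 2
        prec = w22 + 1.0 / psic2
        lin = w22 * y2s + w12 * (y1 - mu1) + (lam0c + lam1c * mu1) / psic2
        return lin / prec + rng.standard_normal(n) / np.sqrt(prec)

    def lam0_prior(state):
        if hier:
            return state["beta0"][0], state["xi0"][0] ** 2
        return 0.0, a2

    def draw_lam0(state, rng):
        m0, v0 = lam0_prior(state)
        v = c_var + (state["psi"] ** 2)[cls]
        z = z0 + k_slope * state["mu1"]
        resid = z - state["lam1"][cls] * state["mu1"]
        s = np.bincount(cls, weights=obs * resid / v, minlength=J)
        prec = np.bincount(cls, weights=obs / v, minlength=J) + 1.0 / v0
        lin = s + m0 / v0
        return lin / prec + rng.standard_normal(J) / np.sqrt(prec)

    def lam1_prior(state):
        if kind == "fex":
            return (
                np.full(J, state["beta1"][0]),
                np.full(J, state["xi1"][0] ** 2),
            )
        if kind == "pex":
            # non-exchangeable component: same vague prior as the
            # subgroup model's slope
            ex = state["p"] > 0.5
            m1 = np.where(ex, state["beta1"][0], 0.0)
            v1 = np.where(ex, state["xi1"][0] ** 2, a2)
            return m1, v1
        return np.zeros(J), np.full(J, a2)

    def draw_lam1(state, rng):
        m1, v1 = lam1_prior(state)
        v = c_var + (state["psi"] ** 2)[cls]
        mu1 = state["mu1"]
        z = z0 + k_slope * mu1 - state["lam0"][cls]
        sxz = np.bincount(cls, weights=obs * mu1 * z / v, minlength=J)
        sxx = np.bincount(cls, weights=obs * mu1**2 / v, minlength=J)
        prec = sxx + 1.0 / v1
        lin = sxz + m1 / v1
        return lin / prec + rng.standard_normal(J) / np.sqrt(prec)

    # -- scale updates (random walk on the log scale) -------------------
    def logpdf_psi(psi, state):
        mu1 = state["mu1"]
        resid = z0 + k_slope * mu1 - state["lam0"][cls] - state["lam1"][cls] * mu1
        v = c_var + (psi**2)[cls]
        terms = obs * (-0.5 * np.log(v) - resid**2 / (2.0 * v))
        return (
            np.bincount(cls, weights=terms, minlength=J)
            - psi**2 / (2.0 * psi_sd**2)
        )

    def draw_p(state, rng):
        lam1, xi1 = state["lam1"], state["xi1"][0]
        beta1 = state["beta1"][0]
        with np.errstate(divide="ignore"):
            log_w1 = (
                np.log(pi)
                - np.log(xi1)
                - (lam1 - beta1) ** 2 / (2.0 * xi1**2)
            )
            log_w0 = (
                np.log1p(-pi)
                - np.log(priors.loc_sd)
                - lam1**2 / (2.0 * a2)
            )
        prob = expit(log_w1 - log_w0)
        return (rng.random(J) < prob).astype(float)

    def draw_beta0(state, rng):
        xi02 = state["xi0"][0] ** 2
        prec = J / xi02 + 1.0 / a2
        lin = state["lam0"].sum() / xi02
        return np.array([lin / prec + rng.standard_normal() / np.sqrt(prec)])

    def draw_beta1(state, rng):
        mask = state["p"] > 0.5 if kind == "pex" else np.ones(J, dtype=bool)
        xi12 = state["xi1"][0] ** 2
        prec = mask.sum() / xi12 + 1.0 / a2
        lin = state["lam1"][mask].sum() / xi12
        return np.array([lin / prec + rng.standard_normal() / np.sqrt(prec)])

    def logpdf_xi0(xi, state):
        dev2 = ((state["lam0"] - state["beta0"][0]) ** 2).sum()
        return -J * np.log(xi) - dev2 / (2.0 * xi**2) - xi**2 / (2.0 * b**2)

    def logpdf_xi1(xi, state):
        mask = state["p"] > 0.5 if kind == "pex" else np.ones(J, dtype=bool)
        dev2 = ((state["lam1"][mask] - state["beta1"][0]) ** 2).sum()
        return -mask.sum() * np.log(xi) - dev2 / (2.0 * xi**2) - xi**2 / (2.0 * b**2)

    blocks: list = []

    def add(block):
        if block.name not in fix:
            blocks.append(block)

    add(ConjugateBlock("mu1", draw_mu1))
    add(ConjugateBlock("lam0", draw_lam0))
    add(ConjugateBlock("lam1", draw_lam1))
    add(RandomWalkBlock("psi", logpdf_psi, init_scale=0.5, multiplicative=True))
    if kind == "pex":
        add(ConjugateBlock("p", draw_p))
    if hier:
        add(ConjugateBlock("beta0", draw_beta0))
        add(ConjugateBlock("beta1", draw_beta1))
        add(RandomWalkBlock("xi0", logpdf_xi0, init_scale=0.5, multiplicative=True))
        add(RandomWalkBlock("xi1", logpdf_xi1, init_scale=0.5, multiplicative=True))
    if monitor_mu:
        add(ConjugateBlock("mu2", draw_mu2))

    monitors = ["lam0", "lam1", "psi", "mu1"]
    if hier:
        monitors += ["beta0", "beta1", "xi0", "xi1"]
    if kind == "pex":
        monitors.append("p")
    if monitor_mu:
        monitors.append("mu2")
    return GibbsModel(init=init, blocks=blocks, monitors=monitors)


def _fit(
    dataset: SurrogacyDataset,
    kind: str,
    priors: PriorConfig,
    mcmc: MCMCConfig,
    *,
    pi: np.ndarray | float | None = None,
    bf_ready: bool = True,
    fix: dict | None = None,
    missing_y2: np.ndarray | None = None,
    monitor_mu: bool = False,
) -> ModelFit:
    psi_sd = priors.psi_bf_sd if bf_ready else priors.scale_sd
    if pi is not None:
        pi = np.broadcast_to(np.asarray(pi, dtype=float), (dataset.n_classes,)).copy()
    model = build_surrogacy_model(
        dataset,
        kind,
        priors,
        psi_sd,
        pi=pi,
        fix=fix,
        missing_y2=missing_y2,
        monitor_mu=monitor_mu,
    )
    run = run_sampler(model, mcmc)
    obs = np.ones(dataset.n_studies, dtype=bool)
    if missing_y2 is not None:
        obs = ~np.asarray(missing_y2, dtype=bool)
    return ModelFit(
        kind=kind,
        class_ids=dataset.class_ids,
        study_ids=dataset.study_ids,
        class_codes=dataset.class_codes,
        run=run,
        priors=priors,
        mcmc=mcmc,
        psi_prior_sd=psi_sd,
        pi=pi,
        data_arrays={
            "y1": dataset.y1,
            "y2": dataset.y2,
            "se1": dataset.se1,
            "se2": dataset.se2,
            "rho_w": dataset.rho_w,
            "y2_observed": obs,
        },
    )


def fit_standard(
    dataset: SurrogacyDataset,
    priors: PriorConfig = DEFAULT_PRIORS,
    mcmc: MCMCConfig = MCMCConfig(),
    **kwargs,
) -> ModelFit:
    """Subgroup analysis: independent Daniels–Hughes fit per treatment class.

    Classes share no parameters, so fitting a multi-class dataset in one
    run is identical to fitting each class separately.  A class with fewer
    than three studies triggers a warning; with a single study the slope is
    unidentified and its posterior is essentially the prior.
    """
    for cid, nj in zip(dataset.class_ids, dataset.n_per_class):
        if nj == 1:
            warnings.warn(
                f"class {cid!r} has a single study: slope unidentified; "
                "posterior approximately equals the prior",
                UserWarning,
                stacklevel=2,
            )
        elif nj < 3:
            warnings.warn(
                f"class {cid!r} has only {nj} studies; subgroup estimates "
                "will be very uncertain",
                UserWarning,
                stacklevel=2,
            )
    return _fit(dataset, "standard", priors, mcmc, **kwargs)


def fit_fex(
    dataset: SurrogacyDataset,
    priors: PriorConfig = DEFAULT_PRIORS,
    mcmc: MCMCConfig = MCMCConfig(),
    **kwargs,
) -> ModelFit:
    """Full-exchangeability hierarchical fit (borrowing across classes)."""
    if dataset.n_classes < 2:
        warnings.warn(
            "only one treatment class: hierarchical structure is redundant",
            UserWarning,
            stacklevel=2,
        )
    return _fit(dataset, "fex", priors, mcmc, **kwargs)


def fit_pex(
    dataset: SurrogacyDataset,
    pi: np.ndarray | float = 0.5,
    priors: PriorConfig = DEFAULT_PRIORS,
    mcmc: MCMCConfig = MCMCConfig(),
    **kwargs,
) -> ModelFit:
    """Partial-exchangeability fit: slopes mixed between an exchangeable
    component and a class-specific vague prior, with fixed prior weights
    ``pi_j`` (0.5 by default: exchangeability and non-exchangeability a
    priori equally likely)."""
    return _fit(dataset, "pex", priors, mcmc, pi=pi, **kwargs)


def fit_model(kind: str, dataset: SurrogacyDataset, **kwargs) -> ModelFit:
    """Dispatch on model kind."""
    if kind == "standard":
        return fit_standard(dataset, **kwargs)
    if kind == "fex":
        return fit_fex(dataset, **kwargs)
    if kind == "pex":
        return fit_pex(dataset, **kwargs)
    raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")


def scaled_config(config: MCMCConfig, factor: float) -> MCMCConfig:
    """A config with iteration counts multiplied by ``factor`` (>=1 keeps
    burn-in proportional); convenience for sensitivity checks."""
    return replace(
        config,
        n_iter=int(config.n_iter * factor),
        burn_in=int(config.burn_in * factor),
        adapt_iter=min(int(config.adapt_iter * factor), int(config.burn_in * factor)),
    )
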