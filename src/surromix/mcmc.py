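"""Component-wise MCMC engine: deterministic-scan Metropolis-within-Gibbs.

A model is a :class:`GibbsModel`: an initializer for the state dict plus an
ordered list of parameter blocks.  Each block is either

* a :class:`ConjugateBlock` — draws a new value directly from its full
  conditional, or
* a :class:`RandomWalkBlock` — a component-wise random-walk Metropolis
  update with per-component step sizes adapted during burn-in toward an
  acceptance rate of 0.44 and frozen afterwards (so the retained chain
  satisfies detailed balance).

Positive scale parameters use multiplicative (log-scale) proposals.  The
engine stores retained draws for the monitored state entries, derives one
random stream per chain from a single root seed, and reports acceptance
rates, split-chain potential-scale-reduction diagnostics, batch-means Monte
Carlo errors and equal-tailed credible intervals.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Callable, Sequence
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

TARGET_ACCEPTANCE = 0.44
ADAPT_BATCH = 50


class InsufficientSamplesError(ValueError):
    """Too few retained samples for the requested estimate."""


class InitializationError(RuntimeError):
    """A block's log-density is non-finite at the initial state."""


@dataclass
class MCMCConfig:
    """Chain-length and seeding settings.

    Defaults follow common practice for these models: 50 000 iterations with
    the first 20 000 discarded as burn-in, two chains.  ``adapt_iter`` is the
    window (within burn-in) during which random-walk step sizes adapt.
    """

    n_iter: int = 50_000
    burn_in: int = 20_000
    n_chains: int = 2
    seed: int = 0
    thin: int = 1
    adapt_iter: int = 5_000

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("require 0 <= burn_in < n_iter")
        if self.adapt_iter > self.burn_in:
            raise ValueError("adapt_iter must not exceed burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in + self.thin - 1) // self.thin


@dataclass
class ChainSummary:
    """Posterior summary of one monitored scalar."""

    mean: float
    sd: float
    median: float
    q2_5: float
    q97_5: float
    mc_error: float
    rhat: float
    n: int


class ConjugateBlock:
    """Exact draw from a full conditional: ``draw(state, rng) -> value``."""

    def __init__(self, name: str, draw: Callable[[dict, np.random.Generator], np.ndarray]):
        self.name = name
        self.draw = draw


class RandomWalkBlock:
    """Component-wise random-walk Metropolis update.

    ``logpdf(value, state)`` must return the per-component log full
    conditional (an array matching ``value``; components must be
    conditionally independent given the rest of the state).  With
    ``multiplicative=True`` proposals are ``x * exp(eps)`` and the log
    Jacobian ``log x' - log x`` is added to the acceptance ratio, keeping
    positive parameters positive.
    """

    def __init__(
        self,
        name: str,
        logpdf: Callable[[np.ndarray, dict], np.ndarray],
        init_scale: float = 0.5,
        multiplicative: bool = False,
    ):
        self.name = name
        self.logpdf = logpdf
        self.init_scale = init_scale
        self.multiplicative = multiplicative


@dataclass
class GibbsModel:
    """A full conditional-update schedule."""

    init: Callable[[np.random.Generator], dict]
    blocks: Sequence[ConjugateBlock | RandomWalkBlock]
    monitors: Sequence[str]


@dataclass
class SamplerRun:
    """Retained chains plus sampler diagnostics.

    ``chains[name]`` has shape ``(n_chains, n_retained, dim)``.
    """

    chains: dict[str, np.ndarray]
    acceptance: dict[str, np.ndarray]
    scales: dict[str, np.ndarray]
    config: MCMCConfig
    monitors: tuple[str, ...] = field(default_factory=tuple)

    def pooled(self, name: str) -> np.ndarray:
        """All retained draws of ``name`` pooled across chains, (C*K, dim)."""
        arr = self.chains[name]
        return arr.reshape(-1, arr.shape[-1])


def _chain_rngs(seed: int, n_chains: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n_chains)]


def run_sampler(model: GibbsModel, config: MCMCConfig) -> SamplerRun:
    """Run the deterministic-scan sampler; reproducible given ``config.seed``."""
    rw_blocks = [b for b in model.blocks if isinstance(b, RandomWalkBlock)]
    chains: dict[str, list[np.ndarray]] = {m: [] for m in model.monitors}
    acc_out: dict[str, list[np.ndarray]] = {b.name: [] for b in rw_blocks}
    scale_out: dict[str, list[np.ndarray]] = {b.name: [] for b in rw_blocks}

    for rng in _chain_rngs(config.seed, config.n_chains):
        state = model.init(rng)
        for block in rw_blocks:
            lp = np.asarray(block.logpdf(np.atleast_1d(state[block.name]), state))
            if not np.all(np.isfinite(lp)):
                raise InitializationError(
                    f"non-finite log-density for block {block.name!r} at initialization"
                )
        log_scale = {
            b.name: np.full(np.atleast_1d(state[b.name]).shape, np.log(b.init_scale))
            for b in rw_blocks
        }
        batch_acc = {b.name: np.zeros_like(log_scale[b.name]) for b in rw_blocks}
        post_acc = {b.name: np.zeros_like(log_scale[b.name]) for b in rw_blocks}
        post_count = 0
        batch_no = 0

        store = {
            m: np.empty((config.n_retained, np.atleast_1d(state[m]).size))
            for m in model.monitors
        }
        kept = 0
        for t in range(config.n_iter):
            for block in model.blocks:
                if isinstance(block, ConjugateBlock):
                    state[block.name] = block.draw(state, rng)
                    continue
                name = block.name
                x = np.atleast_1d(np.asarray(state[name], dtype=float))
                step = np.exp(log_scale[name])
                eps = rng.standard_normal(x.shape) * step
                if block.multiplicative:
                    xp = x * np.exp(eps)
                    log_ratio = (
                        block.logpdf(xp, state)
                        - block.logpdf(x, state)
                        + np.log(xp)
                        - np.log(x)
                    )
                else:
                    xp = x + eps
                    log_ratio = block.logpdf(xp, state) - block.logpdf(x, state)
                accept = np.log(rng.random(x.shape)) < log_ratio
                x = np.where(accept, xp, x)
                state[name] = x
                batch_acc[name] += accept
                if t >= config.burn_in:
                    post_acc[name] += accept
            if t >= config.burn_in:
                post_count += 1
            # step-size adaptation, burn-in only
            if t < config.adapt_iter and (t + 1) % ADAPT_BATCH == 0:
                batch_no += 1
                delta = min(0.25, 1.0 / np.sqrt(batch_no))
                for name in batch_acc:
                    rate = batch_acc[name] / ADAPT_BATCH
                    log_scale[name] += delta * (rate - TARGET_ACCEPTANCE)
                    batch_acc[name][:] = 0.0
            if t >= config.burn_in and (t - config.burn_in) % config.thin == 0:
                for m in model.monitors:
                    store[m][kept] = np.atleast_1d(state[m])
                kept += 1

        for m in model.monitors:
            chains[m].append(store[m][:kept])
        for b in rw_blocks:
            rate = post_acc[b.name] / max(post_count, 1)
            acc_out[b.name].append(rate)
            scale_out[b.name].append(np.exp(log_scale[b.name]))
            if np.any(rate < 0.05) or np.any(rate > 0.95):
                warnings.warn(
                    f"random-walk block {b.name!r}: post-adaptation acceptance "
                    f"rate outside [0.05, 0.95] (rates={np.round(rate, 3)})",
                    RuntimeWarning,
                    stacklevel=2,
                )

    return SamplerRun(
        chains={m: np.stack(v) for m, v in chains.items()},
        acceptance={k: np.stack(v) for k, v in acc_out.items()},
        scales={k: np.stack(v) for k, v in scale_out.items()},
        config=config,
        monitors=tuple(model.monitors),
    )


# ---------------------------------------------------------------------------
# chain statistics
# ---------------------------------------------------------------------------

def mc_error(samples: np.ndarray) -> float:
    """Batch-means Monte Carlo standard error of the chain mean.

    The chain is split into ``B = floor(sqrt(n))`` consecutive batches and
    the standard deviation of the batch means divided by ``sqrt(B)`` is
    returned; this accounts for autocorrelation at the batch scale.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    n = samples.size
    if n < 100:
        raise InsufficientSamplesError(f"need >= 100 samples, got {n}")
    n_batches = int(np.floor(np.sqrt(n)))
    batch_len = n // n_batches
    trimmed = samples[: n_batches * batch_len]
    means = trimmed.reshape(n_batches, batch_len).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))


def mc_error_chains(chains: np.ndarray) -> float:
    """Monte Carlo error of the pooled mean across chains, (C, K) input."""
    chains = np.asarray(chains, dtype=float)
    if chains.ndim == 1:
        return mc_error(chains)
    per_chain = np.array([mc_error(c) for c in chains])
    return float(np.sqrt(np.sum(per_chain**2)) / len(per_chain))


def credible_interval(samples: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed credible interval from posterior draws."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size == 0:
        raise ValueError("empty chain")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(samples, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor, (C, K) input."""
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    k = chains.shape[1] // 2
    if k < 2:
        return np.nan
    halves = np.concatenate([chains[:, :k], chains[:, k : 2 * k]], axis=0)
    m, n = halves.shape
    means = halves.mean(axis=1)
    within = halves.var(axis=1, ddof=1).mean()
    between = n * means.var(ddof=1)
    if within == 0:
        return 1.0 if between == 0 else np.inf
    var_hat = (n - 1) / n * within + between / n
    return float(np.sqrt(var_hat / within))


def summarize_chain(chains: np.ndarray) -> ChainSummary:
    """Posterior summary of one scalar from its (C, K) retained chains."""
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    pooled = chains.ravel()
    lo, hi = credible_interval(pooled)
    return ChainSummary(
        mean=float(pooled.mean()),
        sd=float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0,
        median=float(np.median(pooled)),
        q2_5=lo,
        q97_5=hi,
        mc_error=mc_error_chains(chains),
        rhat=split_rhat(chains),
        n=int(pooled.size),
    )
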