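"""Backend-neutral MCMC engine for the item response models.

The default kernel is componentwise adaptive random-walk Metropolis.  It
exploits the conditional independence structure of the IRT posterior: given
the item parameters, the taker abilities theta_j are mutually independent,
and vice versa, so each sweep proposes and accepts a whole block (all theta,
then all beta, then all log-alpha) in vectorized form.  Per-coordinate step
sizes are adapted during warmup by Robbins-Monro toward a target acceptance
probability and frozen afterwards, so the retained draws come from a fixed
Markov kernel.

Sampling happens on the unconstrained vector (theta, beta, a = log alpha);
the prior on a is Normal(0.5, var 1) directly, so no Jacobian term is needed.

``sample_logpdf`` runs the identical kernel against an arbitrary black-box
log-density, which is how the engine is validated on closed-form targets.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .model_core import (
    ModelSpec,
    ModelType,
    ParameterSet,
    ResponseData,
    bernoulli_loglik,
)

__all__ = [
    "InitStrategy",
    "SamplerConfig",
    "ChainSet",
    "run_chains",
    "sample_logpdf",
    "unconstrain",
    "constrain",
    "parameter_names",
]

_MAX_INIT_RETRIES = 100


class InitStrategy(enum.Enum):
    PRIOR_DRAW = "prior_draw"
    ZEROS = "zeros"


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC run settings.

    ``num_samples`` counts retained draws per chain; warmup draws are
    discarded.  Chains receive independent, reproducible substreams spawned
    from ``seed`` and always produce identical draws for identical inputs.
    """

    num_chains: int = 6
    num_samples: int = 8000
    num_warmup: int = 2000
    seed: int = 0
    target_acceptance: float = 0.44
    init_strategy: InitStrategy = InitStrategy.PRIOR_DRAW
    initial_step: float = 0.5

    def __post_init__(self) -> None:
        if self.num_chains < 1:
            raise ValueError("num_chains must be >= 1")
        if self.num_samples < 1:
            raise ValueError("num_samples must be >= 1")
        if self.num_warmup < 0:
            raise ValueError("num_warmup must be >= 0")
        if not 0.0 < self.target_acceptance < 1.0:
            raise ValueError("target_acceptance must lie in (0, 1)")
        if isinstance(self.init_strategy, str):
            object.__setattr__(self, "init_strategy", InitStrategy(self.init_strategy))

    def to_dict(self) -> dict:
        return {
            "num_chains": self.num_chains,
            "num_samples": self.num_samples,
            "num_warmup": self.num_warmup,
            "seed": self.seed,
            "target_acceptance": self.target_acceptance,
            "init_strategy": self.init_strategy.value,
            "initial_step": self.initial_step,
        }


def parameter_names(spec: ModelSpec, n_items: int, n_takers: int) -> List[str]:
    """Constrained parameter labels in storage order: theta, beta, (alpha)."""
    names = [f"theta[{j}]" for j in range(n_takers)]
    names += [f"beta[{i}]" for i in range(n_items)]
    if spec.is_two_pl:
        names += [f"alpha[{i}]" for i in range(n_items)]
    return names


def unconstrain(params: ParameterSet, spec: ModelSpec) -> np.ndarray:
    """Map a ParameterSet to the unconstrained vector (theta, beta, log alpha)."""
    params._check_spec(spec)
    parts = [params.theta, params.beta]
    if spec.is_two_pl:
        if (params.alpha <= 0).any():
            raise ValueError("alpha must be strictly positive")
        parts.append(np.log(params.alpha))
    return np.concatenate(parts)


def constrain(vector: np.ndarray, spec: ModelSpec, n_items: int, n_takers: int) -> ParameterSet:
    """Inverse of :func:`unconstrain`."""
    vector = np.asarray(vector, dtype=float)
    expected = n_takers + n_items * (2 if spec.is_two_pl else 1)
    if vector.size != expected:
        raise ValueError(f"expected vector of length {expected}, got {vector.size}")
    theta = vector[:n_takers]
    beta = vector[n_takers:n_takers + n_items]
    alpha = np.exp(vector[n_takers + n_items:]) if spec.is_two_pl else None
    return ParameterSet(theta=theta, beta=beta, alpha=alpha)


@dataclass
class ChainSet:
    """Post-warmup draws, shape (num_chains, num_samples, P), unconstrained scale.

    ``parameter_names`` are the constrained labels; ``constrained_draws``
    exponentiates the alpha coordinates.
    """

    draws: np.ndarray
    parameter_names: List[str]
    acceptance_rate: np.ndarray          # (num_chains,) mean post-warmup acceptance
    acceptance_per_coord: np.ndarray     # (num_chains, P)
    spec: Optional[ModelSpec]
    config: SamplerConfig
    n_items: int = 0
    n_takers: int = 0

    @property
    def num_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def num_samples(self) -> int:
        return self.draws.shape[1]

    @property
    def constrained_draws(self) -> np.ndarray:
        out = self.draws.copy()
        for k, name in enumerate(self.parameter_names):
            if name.startswith("alpha["):
                out[:, :, k] = np.exp(out[:, :, k])
        return out

    def parameter_set(self, chain: int, iteration: int) -> ParameterSet:
        if self.spec is None:
            raise ValueError("ChainSet was not produced from an IRT model")
        return constrain(self.draws[chain, iteration], self.spec, self.n_items, self.n_takers)

    def export(self, directory) -> None:
        """One CSV per chain (chain,iteration,<params...>) plus a JSON sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        con = self.constrained_draws
        for c in range(self.num_chains):
            df = pd.DataFrame(con[c], columns=self.parameter_names)
            df.insert(0, "iteration", np.arange(self.num_samples))
            df.insert(0, "chain", c)
            df.to_csv(directory / f"chain_{c}.csv", index=False)
        sidecar = {
            "config": self.config.to_dict(),
            "model_type": self.spec.model_type.value if self.spec else None,
            "n_items": self.n_items,
            "n_takers": self.n_takers,
            "parameter_names": self.parameter_names,
            "acceptance_rate": [float(a) for a in self.acceptance_rate],
        }
        (directory / "draws_meta.json").write_text(json.dumps(sidecar, indent=2))


# --------------------------------------------------------------------------
# conditional-update targets
# --------------------------------------------------------------------------

class _IRTConditionals:
    """Blocked conditional updates for the IRT posterior with cached state.

    Caches d_r = theta_{j(r)} - beta_{i(r)} and the per-record log-likelihood;
    z_r = m_r * d_r where m_r = alpha_{i(r)} (1 for 1PL).
    """

    def __init__(self, data: ResponseData, spec: ModelSpec):
        self.spec = spec
        self.data = data
        self.I = data.n_items
        self.J = data.n_takers
        self.items = data.item_ids
        self.takers = data.taker_ids
        self.r = data.responses.astype(float)
        self.two_pl = spec.is_two_pl
        self.n_params = self.J + self.I * (2 if self.two_pl else 1)
        # blocks: (slice into x, group index array per record, group count)
        self.blocks = [("theta", slice(0, self.J), self.takers, self.J),
                       ("beta", slice(self.J, self.J + self.I), self.items, self.I)]
        if self.two_pl:
            self.blocks.append(("a", slice(self.J + self.I, self.n_params), self.items, self.I))
        s = spec
        self._prior_mean = np.concatenate([
            np.full(self.J, s.theta_prior_mean),
            np.full(self.I, s.beta_prior_mean),
        ] + ([np.full(self.I, s.logalpha_prior_mean)] if self.two_pl else []))
        self._prior_var = np.concatenate([
            np.full(self.J, s.theta_prior_var),
            np.full(self.I, s.beta_prior_var),
        ] + ([np.full(self.I, s.logalpha_prior_var)] if self.two_pl else []))

    def init_vector(self, rng: np.random.Generator, strategy: InitStrategy) -> np.ndarray:
        if strategy is InitStrategy.ZEROS:
            return np.zeros(self.n_params)
        return self._prior_mean + np.sqrt(self._prior_var) * rng.standard_normal(self.n_params)

    def set_state(self, x: np.ndarray) -> None:
        self.x = np.asarray(x, dtype=float).copy()
        theta = self.x[:self.J]
        beta = self.x[self.J:self.J + self.I]
        self.d = theta[self.takers] - beta[self.items]
        self.m = np.exp(self.x[self.J + self.I:])[self.items] if self.two_pl else 1.0
        self.ll = bernoulli_loglik(self.m * self.d, self.r)

    def log_posterior(self) -> float:
        lp = float(np.sum(self.ll))
        lp += float(np.sum(-0.5 * (np.log(2 * np.pi * self._prior_var)
                                   + (self.x - self._prior_mean) ** 2 / self._prior_var)))
        return lp

    def sweep(self, rng: np.random.Generator, log_step: np.ndarray,
              accept_prob_out: np.ndarray) -> None:
        """One full sweep over all blocks; mutates state and records per-coordinate
        acceptance probabilities into accept_prob_out."""
        for name, sl, groups, size in self.blocks:
            cur = self.x[sl]
            step = np.exp(log_step[sl])
            prop = cur + step * rng.standard_normal(size)
            if name == "a":
                m_new = np.exp(prop)[self.items]
                z_new = m_new * self.d
            else:
                delta = prop - cur
                if name == "beta":
                    delta = -delta
                d_new = self.d + delta[groups]
                z_new = self.m * d_new
            ll_new = bernoulli_loglik(z_new, self.r)
            dll = np.bincount(groups, weights=ll_new - self.ll, minlength=size)
            pm = self._prior_mean[sl]
            pv = self._prior_var[sl]
            dlp = dll + (-0.5 * (prop - pm) ** 2 + 0.5 * (cur - pm) ** 2) / pv
            accept_prob_out[sl] = np.exp(np.minimum(0.0, dlp))
            accept = np.log(rng.random(size)) < dlp
            if accept.any():
                rec = accept[groups]
                self.x[sl] = np.where(accept, prop, cur)
                if name == "a":
                    self.m = np.where(rec, m_new, self.m)
                else:
                    self.d[rec] = d_new[rec]
                self.ll[rec] = ll_new[rec]


class _DenseConditionals:
    """Componentwise updates against a black-box log-density (small dims only)."""

    def __init__(self, logpdf: Callable[[np.ndarray], float], dim: int,
                 init_scale: float = 1.0):
        self.logpdf = logpdf
        self.n_params = dim
        self.init_scale = init_scale

    def init_vector(self, rng: np.random.Generator, strategy: InitStrategy) -> np.ndarray:
        if strategy is InitStrategy.ZEROS:
            return np.zeros(self.n_params)
        return self.init_scale * rng.standard_normal(self.n_params)

    def set_state(self, x: np.ndarray) -> None:
        self.x = np.asarray(x, dtype=float).copy()
        self.lp = float(self.logpdf(self.x))

    def log_posterior(self) -> float:
        return self.lp

    def sweep(self, rng: np.random.Generator, log_step: np.ndarray,
              accept_prob_out: np.ndarray) -> None:
        for k in range(self.n_params):
            prop = self.x.copy()
            prop[k] += np.exp(log_step[k]) * rng.standard_normal()
            lp_new = float(self.logpdf(prop))
            dlp = lp_new - self.lp
            accept_prob_out[k] = np.exp(min(0.0, dlp))
            if np.log(rng.random()) < dlp:
                self.x = prop
                self.lp = lp_new


# --------------------------------------------------------------------------
# engine
# --------------------------------------------------------------------------

def _run_one_chain(target, rng: np.random.Generator, config: SamplerConfig):
    P = target.n_params
    for attempt in range(_MAX_INIT_RETRIES):
        x0 = target.init_vector(rng, config.init_strategy)
        target.set_state(x0)
        if np.isfinite(target.log_posterior()):
            break
        if config.init_strategy is InitStrategy.ZEROS:
            raise RuntimeError("log-posterior not finite at zero initialization")
    else:
        raise RuntimeError("could not find a finite-density initialization")

    log_step = np.full(P, np.log(config.initial_step))
    accept_prob = np.empty(P)
    # warmup: Robbins-Monro adaptation of per-coordinate log step sizes
    for t in range(config.num_warmup):
        target.sweep(rng, log_step, accept_prob)
        gamma = (t + 1.0) ** -0.6
        log_step += gamma * (accept_prob - config.target_acceptance)
    # sampling with frozen steps
    draws = np.empty((config.num_samples, P))
    acc_sum = np.zeros(P)
    for t in range(config.num_samples):
        target.sweep(rng, log_step, accept_prob)
        acc_sum += accept_prob
        draws[t] = target.x
    return draws, acc_sum / config.num_samples


def run_chains(data: ResponseData, spec: ModelSpec, config: SamplerConfig) -> ChainSet:
    """Draw from the IRT posterior; deterministic for fixed (data, spec, config)."""
    data.validate(for_fitting=True)
    streams = np.random.SeedSequence(config.seed).spawn(config.num_chains)
    all_draws = []
    all_acc = []
    for ss in streams:
        target = _IRTConditionals(data, spec)
        draws, acc = _run_one_chain(target, np.random.default_rng(ss), config)
        all_draws.append(draws)
        all_acc.append(acc)
    acc_per_coord = np.stack(all_acc)
    return ChainSet(
        draws=np.stack(all_draws),
        parameter_names=parameter_names(spec, data.n_items, data.n_takers),
        acceptance_rate=acc_per_coord.mean(axis=1),
        acceptance_per_coord=acc_per_coord,
        spec=spec,
        config=config,
        n_items=data.n_items,
        n_takers=data.n_takers,
    )


def sample_logpdf(logpdf: Callable[[np.ndarray], float], dim: int,
                  config: SamplerConfig,
                  parameter_labels: Optional[Sequence[str]] = None,
                  init_scale: float = 1.0) -> ChainSet:
    """Run the same adaptive kernel against an arbitrary log-density.

    Intended for validating the engine on closed-form targets; dimensions
    should stay small because every coordinate proposal re-evaluates
    ``logpdf`` on the full vector.
    """
    streams = np.random.SeedSequence(config.seed).spawn(config.num_chains)
    all_draws, all_acc = [], []
    for ss in streams:
        target = _DenseConditionals(logpdf, dim, init_scale=init_scale)
        draws, acc = _run_one_chain(target, np.random.default_rng(ss), config)
        all_draws.append(draws)
        all_acc.append(acc)
    acc_per_coord = np.stack(all_acc)
    labels = list(parameter_labels) if parameter_labels else [f"x[{k}]" for k in range(dim)]
    return ChainSet(
        draws=np.stack(all_draws),
        parameter_names=labels,
        acceptance_rate=acc_per_coord.mean(axis=1),
        acceptance_per_coord=acc_per_coord,
        spec=None,
        config=config,
    )
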