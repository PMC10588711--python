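"""Synthetic binary-response generators emulating the BONE / BRAIN study data.

The real rating data (7 radiologists x 60 patients for BONE, 14 x 42 for
BRAIN) are not redistributable, so this module reproduces their statistical
structure by a two-step scheme: latent parameters are drawn either from the
model priors or from normal approximations to published per-taker posterior
summaries (packaged as a fixture table), then binary responses are generated
from the IRT equations.  A scaling ladder multiplies the number of test
takers by 1x-1000x while keeping the item roster fixed, reproducing the
benchmark totals 420 ... 420,000 (BONE-like) and 588 ... 588,000
(BRAIN-like).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .model_core import (
    ModelSpec,
    ModelType,
    ParameterSet,
    ResponseData,
    linear_predictors,
    response_probability,
)

__all__ = [
    "Dataset",
    "RosterPlan",
    "PosteriorRoster",
    "SCALE_FACTORS",
    "load_reference_summaries",
    "load_posterior_roster",
    "draw_parameters_from_priors",
    "draw_parameters_from_posterior",
    "generate_responses",
    "build_simulation_ladder",
]

SCALE_FACTORS = (1, 2, 5, 10, 20, 50, 100, 200, 500, 1000)


class Dataset(enum.Enum):
    """Roster shapes of the two emulated rating studies."""

    BONE_LIKE = ("BONE", 60, 7)
    BRAIN_LIKE = ("BRAIN", 42, 14)

    def __init__(self, label: str, n_items: int, n_takers: int):
        self.label = label
        self.base_items = n_items
        self.base_takers = n_takers

    @classmethod
    def parse(cls, value) -> "Dataset":
        if isinstance(value, cls):
            return value
        v = str(value).strip().upper()
        for member in cls:
            if v in {member.name, member.label}:
                return member
        raise ValueError(f"unknown dataset: {value!r}")


@dataclass(frozen=True)
class RosterPlan:
    """Scaled roster: items fixed, takers multiplied by the scale factor."""

    base_items: int
    base_takers: int
    scale_factor: int = 1

    def __post_init__(self) -> None:
        if self.scale_factor not in SCALE_FACTORS:
            raise ValueError(f"scale_factor must be one of {SCALE_FACTORS}")
        if self.base_items < 1 or self.base_takers < 1:
            raise ValueError("roster dimensions must be >= 1")

    @property
    def scaled_takers(self) -> int:
        return self.scale_factor * self.base_takers

    @property
    def total_responses(self) -> int:
        return self.base_items * self.scaled_takers

    @classmethod
    def for_dataset(cls, dataset, scale_factor: int = 1) -> "RosterPlan":
        d = Dataset.parse(dataset)
        return cls(base_items=d.base_items, base_takers=d.base_takers,
                   scale_factor=scale_factor)


@dataclass(frozen=True)
class PosteriorRoster:
    """Normal approximations N(mean, sd^2) to per-taker ability posteriors."""

    names: tuple
    means: np.ndarray
    sds: np.ndarray
    source_table: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "means", np.asarray(self.means, dtype=float))
        object.__setattr__(self, "sds", np.asarray(self.sds, dtype=float))
        if not (self.sds > 0).all():
            raise ValueError("every posterior sd must be strictly positive")
        if not len(self.names) == self.means.size == self.sds.size:
            raise ValueError("names, means and sds must align")

    @property
    def n_takers(self) -> int:
        return self.means.size


def load_reference_summaries(dataset=None, model=None, block: Optional[str] = None) -> pd.DataFrame:
    """Packaged per-taker ability summaries from the published comparison.

    Columns: source_table, dataset, model, block, name, mean, sd, hdi_3%,
    hdi_97%.  Blocks are the three estimation runs being compared (pystan,
    numpyro_cpu, numpyro_gpu).  Filters are optional.
    """
    with resources.files("birt.data").joinpath("reference_summaries.csv").open() as fh:
        df = pd.read_csv(fh)
    if dataset is not None:
        df = df[df["dataset"] == Dataset.parse(dataset).label]
    if model is not None:
        df = df[df["model"] == ModelType.parse(model).value]
    if block is not None:
        df = df[df["block"] == block]
    return df.reset_index(drop=True)


def load_posterior_roster(dataset, model, block: str = "pystan") -> PosteriorRoster:
    """Ability roster for posterior-based generation, from one table block."""
    df = load_reference_summaries(dataset, model, block)
    if df.empty:
        raise ValueError(f"no fixture rows for dataset={dataset}, model={model}, block={block}")
    d = Dataset.parse(dataset)
    expected = [f"theta[{j}]" for j in range(d.base_takers)]
    missing = sorted(set(expected) - set(df["name"]))
    if missing:
        raise ValueError(f"fixture is missing ability rows: {missing}")
    df = df.set_index("name").loc[expected]
    return PosteriorRoster(names=tuple(expected), means=df["mean"].to_numpy(),
                           sds=df["sd"].to_numpy(),
                           source_table=str(df["source_table"].iloc[0]))


def draw_parameters_from_priors(n_items: int, n_takers: int, spec: ModelSpec,
                                seed: int) -> ParameterSet:
    """Sample a full ParameterSet from the model priors."""
    if n_items < 1 or n_takers < 1:
        raise ValueError("roster dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    theta = spec.theta_prior_mean + np.sqrt(spec.theta_prior_var) * rng.standard_normal(n_takers)
    beta = spec.beta_prior_mean + np.sqrt(spec.beta_prior_var) * rng.standard_normal(n_items)
    alpha = None
    if spec.is_two_pl:
        alpha = np.exp(spec.logalpha_prior_mean
                       + np.sqrt(spec.logalpha_prior_var) * rng.standard_normal(n_items))
    return ParameterSet(theta=theta, beta=beta, alpha=alpha)


def draw_parameters_from_posterior(roster: PosteriorRoster, plan: RosterPlan,
                                   spec: ModelSpec, seed: int) -> ParameterSet:
    """Abilities from the posterior normal approximations, items from priors.

    Replicate k of base taker j draws theta ~ N(mean_j, sd_j^2)
    independently, giving ``plan.scaled_takers`` ability values ordered
    replicate-major (all base takers, then the next replicate block).  Item
    parameters fall back to prior draws because the published summaries omit
    item rows.
    """
    if roster.n_takers != plan.base_takers:
        raise ValueError(f"roster covers {roster.n_takers} takers, plan expects "
                         f"{plan.base_takers}")
    ss = np.random.SeedSequence(seed).spawn(2)
    rng = np.random.default_rng(ss[0])
    f = plan.scale_factor
    means = np.tile(roster.means, f)
    sds = np.tile(roster.sds, f)
    theta = means + sds * rng.standard_normal(plan.scaled_takers)
    items = draw_parameters_from_priors(plan.base_items, 1, spec,
                                        seed=ss[1].generate_state(1)[0] % (2 ** 31))
    return ParameterSet(theta=theta, beta=items.beta, alpha=items.alpha)


def generate_responses(params: ParameterSet, spec: ModelSpec, seed: int) -> ResponseData:
    """One Bernoulli(p_ij) record per (item, taker) cell of the full grid."""
    params._check_spec(spec)
    I, J = params.n_items, params.n_takers
    item_ids = np.repeat(np.arange(I), J)
    taker_ids = np.tile(np.arange(J), I)
    data_stub = ResponseData(item_ids, taker_ids, np.zeros(I * J, dtype=np.int8),
                             n_items=I, n_takers=J)
    p = response_probability(linear_predictors(params, data_stub, spec))
    rng = np.random.default_rng(seed)
    responses = (rng.random(I * J) < p).astype(np.int8)
    return ResponseData(item_ids, taker_ids, responses, n_items=I, n_takers=J)


def build_simulation_ladder(dataset, model_type, seed: int,
                            scale_factors: Sequence[int] = SCALE_FACTORS,
                            block: str = "pystan") -> List[ResponseData]:
    """The benchmark ladder: one dataset per scale factor, ascending totals.

    Latent abilities come from the packaged posterior summaries of the chosen
    dataset/model, item parameters from the priors; each rung gets its own
    reproducible substream of ``seed``.
    """
    d = Dataset.parse(dataset)
    spec = ModelSpec(model_type=ModelType.parse(model_type))
    roster = load_posterior_roster(d, spec.model_type, block=block)
    streams = np.random.SeedSequence(seed).spawn(2 * len(scale_factors))
    out = []
    for k, f in enumerate(scale_factors):
        plan = RosterPlan.for_dataset(d, f)
        params = draw_parameters_from_posterior(
            roster, plan, spec, seed=streams[2 * k].generate_state(1)[0] % (2 ** 31))
        data = generate_responses(
            params, spec, seed=streams[2 * k + 1].generate_state(1)[0] % (2 ** 31))
        out.append(data)
    return out
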