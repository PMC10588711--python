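"""Core 1PL/2PL logistic item response model: data container, priors, log-posterior.

The model treats each binary record r_ij (taker j answering item i) as
Bernoulli with success probability ``logistic(z_ij)`` where

* 1PL:  ``z_ij = theta_j - beta_i``
* 2PL:  ``z_ij = alpha_i * (theta_j - beta_i)``

theta is taker ability, beta item difficulty, alpha (2PL only) item
discrimination, constrained positive via a log-normal prior.  Priors are
normal with *variance* (not sd) hyperparameters: theta, beta ~ N(0, var 2)
and log(alpha) ~ N(0.5, var 1).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "ModelType",
    "ModelSpec",
    "ResponseData",
    "ParameterSet",
    "linear_predictor",
    "response_probability",
    "log_likelihood",
    "log_prior",
    "log_posterior",
]

_LOG_2PI = np.log(2.0 * np.pi)


class ModelType(enum.Enum):
    """Which logistic item response model is being fitted."""

    ONE_PL = "1PL"
    TWO_PL = "2PL"

    @classmethod
    def parse(cls, value: "ModelType | str") -> "ModelType":
        if isinstance(value, cls):
            return value
        v = str(value).strip().upper().replace("-", "").replace("_", "")
        if v in {"1PL", "ONEPL", "1PLIRT"}:
            return cls.ONE_PL
        if v in {"2PL", "TWOPL", "2PLIRT"}:
            return cls.TWO_PL
        raise ValueError(f"unknown model type: {value!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Model type plus prior hyperparameters (second argument is a variance)."""

    model_type: ModelType = ModelType.ONE_PL
    theta_prior_mean: float = 0.0
    theta_prior_var: float = 2.0
    beta_prior_mean: float = 0.0
    beta_prior_var: float = 2.0
    logalpha_prior_mean: float = 0.5
    logalpha_prior_var: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "model_type", ModelType.parse(self.model_type))
        for field in ("theta_prior_var", "beta_prior_var", "logalpha_prior_var"):
            if not getattr(self, field) > 0:
                raise ValueError(f"{field} must be strictly positive")

    @property
    def is_two_pl(self) -> bool:
        return self.model_type is ModelType.TWO_PL


class ResponseData:
    """Long-format binary responses: one record per (item, taker) pair.

    Parameters
    ----------
    item_ids, taker_ids : integer arrays of equal length
        0-based indices into the item / taker rosters.
    responses : array of 0/1
    n_items, n_takers : optional roster sizes; inferred as ``max id + 1``
        when omitted.
    """

    def __init__(self, item_ids, taker_ids, responses,
                 n_items: Optional[int] = None, n_takers: Optional[int] = None):
        self.item_ids = np.asarray(item_ids, dtype=np.int64)
        self.taker_ids = np.asarray(taker_ids, dtype=np.int64)
        self.responses = np.asarray(responses, dtype=np.int8)
        if not (self.item_ids.shape == self.taker_ids.shape == self.responses.shape):
            raise ValueError("item_ids, taker_ids and responses must have equal length")
        if self.item_ids.ndim != 1:
            raise ValueError("records must form 1-d arrays")
        self.n_items = int(n_items) if n_items is not None else int(self.item_ids.max(initial=-1)) + 1
        self.n_takers = int(n_takers) if n_takers is not None else int(self.taker_ids.max(initial=-1)) + 1
        self.validate()

    def validate(self, for_fitting: bool = False) -> None:
        if self.n_records == 0:
            if for_fitting:
                raise ValueError("empty response data: nothing to fit")
            return
        if not np.isin(self.responses, (0, 1)).all():
            raise ValueError("responses must all be 0 or 1")
        if self.item_ids.min() < 0 or self.item_ids.max() >= self.n_items:
            raise ValueError("item_id out of range [0, n_items)")
        if self.taker_ids.min() < 0 or self.taker_ids.max() >= self.n_takers:
            raise ValueError("taker_id out of range [0, n_takers)")
        keys = self.item_ids * self.n_takers + self.taker_ids
        if np.unique(keys).size != keys.size:
            raise ValueError("duplicate (item_id, taker_id) record")
        if for_fitting:
            if np.unique(self.item_ids).size != self.n_items:
                raise ValueError("every item must appear in at least one record for fitting")
            if np.unique(self.taker_ids).size != self.n_takers:
                raise ValueError("every taker must appear in at least one record for fitting")

    @property
    def n_records(self) -> int:
        return self.item_ids.size

    @classmethod
    def from_records(cls, records, n_items=None, n_takers=None) -> "ResponseData":
        """Build from an iterable of (item_id, taker_id, response) triples."""
        arr = np.asarray(list(records), dtype=np.int64)
        if arr.size == 0:
            arr = arr.reshape(0, 3)
        return cls(arr[:, 0], arr[:, 1], arr[:, 2], n_items=n_items, n_takers=n_takers)

    @classmethod
    def from_csv(cls, path, n_items=None, n_takers=None) -> "ResponseData":
        df = pd.read_csv(path)
        required = {"item_id", "taker_id", "response"}
        if not required.issubset(df.columns):
            raise ValueError(f"CSV must have columns {sorted(required)}")
        return cls(df["item_id"].to_numpy(), df["taker_id"].to_numpy(),
                   df["response"].to_numpy(), n_items=n_items, n_takers=n_takers)

    def to_csv(self, path) -> None:
        pd.DataFrame({"item_id": self.item_ids, "taker_id": self.taker_ids,
                      "response": self.responses}).to_csv(path, index=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"item_id": self.item_ids, "taker_id": self.taker_ids,
                             "response": self.responses.astype(np.int64)})

    def __eq__(self, other) -> bool:
        return (isinstance(other, ResponseData)
                and self.n_items == other.n_items and self.n_takers == other.n_takers
                and np.array_equal(self.item_ids, other.item_ids)
                and np.array_equal(self.taker_ids, other.taker_ids)
                and np.array_equal(self.responses, other.responses))

    def __repr__(self) -> str:
        return (f"ResponseData(n_items={self.n_items}, n_takers={self.n_takers}, "
                f"n_records={self.n_records})")


@dataclass(frozen=True)
class ParameterSet:
    """Latent parameter vectors: theta (J,), beta (I,), alpha (I,) for 2PL."""

    theta: np.ndarray
    beta: np.ndarray
    alpha: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta", np.atleast_1d(np.asarray(self.theta, dtype=float)))
        object.__setattr__(self, "beta", np.atleast_1d(np.asarray(self.beta, dtype=float)))
        if self.alpha is not None:
            alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
            if alpha.shape != self.beta.shape:
                raise ValueError("alpha must have one entry per item")
            if not (alpha > 0).all():
                raise ValueError("discrimination alpha must be strictly positive")
            object.__setattr__(self, "alpha", alpha)

    @property
    def n_takers(self) -> int:
        return self.theta.size

    @property
    def n_items(self) -> int:
        return self.beta.size

    def _check_spec(self, spec: ModelSpec) -> None:
        if spec.is_two_pl and self.alpha is None:
            raise ValueError("2PL model requires discrimination parameters alpha")


def linear_predictor(params: ParameterSet, i: int, j: int, spec: ModelSpec) -> float:
    """z_ij for a single cell: theta_j - beta_i, scaled by alpha_i under 2PL."""
    params._check_spec(spec)
    if not (0 <= i < params.n_items and 0 <= j < params.n_takers):
        raise IndexError("item or taker index out of range")
    z = params.theta[j] - params.beta[i]
    if spec.is_two_pl:
        z = params.alpha[i] * z
    return float(z)


def linear_predictors(params: ParameterSet, data: ResponseData, spec: ModelSpec) -> np.ndarray:
    """Vector of z_ij over the records of ``data``, in record order."""
    params._check_spec(spec)
    if params.n_items < data.n_items or params.n_takers < data.n_takers:
        raise ValueError("parameter vectors shorter than the data roster")
    z = params.theta[data.taker_ids] - params.beta[data.item_ids]
    if spec.is_two_pl:
        z = params.alpha[data.item_ids] * z
    return z


def response_probability(z):
    """Pr(r=1) = 1 / (1 + exp(-z)); overflow-safe for any finite z."""
    z = np.asarray(z, dtype=float)
    if not np.isfinite(z).all():
        raise ValueError("linear predictor must be finite")
    p = expit(z)
    return float(p) if p.ndim == 0 else p


def bernoulli_loglik(z, r):
    """Per-record log-likelihood r*log(p) + (1-r)*log(1-p) = r*z - log(1+e^z)."""
    z = np.asarray(z, dtype=float)
    r = np.asarray(r, dtype=float)
    return r * z - np.logaddexp(0.0, z)


def log_likelihood(params: ParameterSet, data: ResponseData, spec: ModelSpec) -> float:
    """Bernoulli log-likelihood of the responses, summed in canonical (i, j) order.

    Canonical ordering makes the value independent of how the records were
    stored, bit for bit.
    """
    if data.n_records == 0:
        raise ValueError("empty response data: log-likelihood undefined")
    z = linear_predictors(params, data, spec)
    ll = bernoulli_loglik(z, data.responses)
    order = np.lexsort((data.taker_ids, data.item_ids))
    return float(np.sum(ll[order]))


def _normal_logpdf_sum(x: np.ndarray, mean: float, var: float) -> float:
    x = np.asarray(x, dtype=float)
    return float(-0.5 * x.size * (_LOG_2PI + np.log(var))
                 - 0.5 * np.sum((x - mean) ** 2) / var)


def log_prior(params: ParameterSet, spec: ModelSpec) -> float:
    """Log prior density; the 2PL alpha term is the normal density of log(alpha).

    No Jacobian is added here: the sampler works on the unconstrained
    coordinate a = log(alpha) whose prior *is* N(0.5, var 1).
    """
    params._check_spec(spec)
    lp = _normal_logpdf_sum(params.theta, spec.theta_prior_mean, spec.theta_prior_var)
    lp += _normal_logpdf_sum(params.beta, spec.beta_prior_mean, spec.beta_prior_var)
    if spec.is_two_pl:
        if not (params.alpha > 0).all():
            raise ValueError("alpha must be strictly positive")
        lp += _normal_logpdf_sum(np.log(params.alpha),
                                 spec.logalpha_prior_mean, spec.logalpha_prior_var)
    return lp


def log_posterior(params: ParameterSet, data: ResponseData, spec: ModelSpec) -> float:
    """Unnormalised log posterior: log-likelihood plus log prior."""
    return log_likelihood(params, data, spec) + log_prior(params, spec)
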