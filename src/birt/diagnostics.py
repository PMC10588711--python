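"""Posterior summaries and convergence diagnostics.

Implements the rank-normalized split R-hat and bulk/tail effective sample
size of Vehtari, Gelman, Simpson, Carpenter & Burkner (2021) — the
estimators behind the standard ``mean sd hdi_3% hdi_97% ess_bulk ess_tail
r_hat`` summary-table schema — plus the shortest-interval HDI.

Conventions for degenerate input: constant draws give r_hat = 1.0 (nothing
to diagnose) and ESS = 0 (no information).
"""

from __future__ import annotations

import logging
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from .sampler import ChainSet

__all__ = ["hdi", "split_rhat", "ess_bulk", "ess_tail", "summarize", "write_summary_csv"]

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = ["name", "mean", "sd", "hdi_3%", "hdi_97%", "ess_bulk", "ess_tail", "r_hat"]


def hdi(sample: Sequence[float], mass: float = 0.94) -> Tuple[float, float]:
    """Highest-density interval: shortest contiguous window of the sorted
    sample containing ``ceil(mass * n)`` points; leftmost window on ties."""
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("hdi requires at least 2 sample points")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie in (0, 1)")
    m = int(np.ceil(mass * n))
    m = min(max(m, 1), n)
    widths = x[m - 1:] - x[:n - m + 1]
    lo = int(np.argmin(widths))  # argmin takes the first minimum: leftmost tie
    return float(x[lo]), float(x[lo + m - 1])


def _as_chains(draws) -> np.ndarray:
    a = np.asarray(draws, dtype=float)
    if a.ndim == 1:
        a = a[None, :]
    if a.ndim != 2:
        raise ValueError("draws must be (chains, iterations) or 1-d")
    return a


def _split_chains(a: np.ndarray) -> np.ndarray:
    """Split each chain into halves of equal length (middle draw dropped if odd)."""
    n = a.shape[1]
    half = n // 2
    return np.concatenate([a[:, :half], a[:, n - half:]], axis=0)


def _rank_normalize(a: np.ndarray) -> np.ndarray:
    """Pooled fractional ranks mapped through the standard-normal quantile."""
    r = rankdata(a, method="average").reshape(a.shape)
    return ndtri((r - 0.375) / (a.size + 0.25))


def _rhat_classic(a: np.ndarray) -> float:
    m, n = a.shape
    chain_var = a.var(axis=1, ddof=1)
    w = chain_var.mean()
    if w == 0.0:
        return 1.0
    var_plus = (n - 1) / n * w
    if m > 1:
        var_plus += a.mean(axis=1).var(ddof=1)
    return float(np.sqrt(var_plus / w))


def split_rhat(draws) -> float:
    """Rank-normalized split R-hat for one parameter (chains x iterations)."""
    a = _as_chains(draws)
    if a.shape[1] < 4:
        raise ValueError("split_rhat needs at least 4 iterations per chain")
    if np.ptp(a) == 0.0:
        return 1.0
    z = _rank_normalize(_split_chains(a))
    return _rhat_classic(z)


def _autocov(a: np.ndarray) -> np.ndarray:
    """Biased (1/n) autocovariance of each row via FFT."""
    m, n = a.shape
    centered = a - a.mean(axis=1, keepdims=True)
    size = 2 ** int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(centered, n=size, axis=1)
    acov = np.fft.irfft(f * np.conj(f), n=size, axis=1)[:, :n].real
    return acov / n


def _ess(a: np.ndarray) -> float:
    """Multi-chain ESS via Geyer's initial monotone positive sequence."""
    m, n = a.shape
    if np.ptp(a) == 0.0:
        return 0.0
    if n < 4:
        raise ValueError("ess needs at least 4 iterations per chain")
    acov = _autocov(a)
    mean_var = acov[:, 0].mean() * n / (n - 1.0)
    var_plus = mean_var * (n - 1.0) / n
    if m > 1:
        var_plus += a.mean(axis=1).var(ddof=1)
    if var_plus == 0.0:
        return 0.0

    rho = np.zeros(n)
    rho[0] = 1.0
    rho_even = 1.0
    rho_odd = 1.0 - (mean_var - acov[:, 1].mean()) / var_plus
    rho[1] = rho_odd
    # initial positive sequence: keep pair sums while they stay positive
    t = 1
    while t < n - 3 and (rho_even + rho_odd) > 0.0:
        rho_even = 1.0 - (mean_var - acov[:, t + 1].mean()) / var_plus
        rho_odd = 1.0 - (mean_var - acov[:, t + 2].mean()) / var_plus
        if (rho_even + rho_odd) >= 0.0:
            rho[t + 1] = rho_even
            rho[t + 2] = rho_odd
        t += 2
    max_t = t - 2
    if rho_even > 0.0:  # improve estimate on odd truncation
        rho[max_t + 1] = rho_even
    # Geyer initial monotone sequence: pair sums forced non-increasing
    t = 1
    while t <= max_t - 2:
        pair = rho[t + 1] + rho[t + 2]
        prev = rho[t - 1] + rho[t]
        if pair > prev:
            rho[t + 1] = prev / 2.0
            rho[t + 2] = prev / 2.0
        t += 2
    tau = -1.0 + 2.0 * np.sum(rho[:max_t + 1]) + rho[max_t + 1]
    tau = max(tau, 1.0 / np.log10(m * n)) if m * n > 10 else max(tau, 1e-8)
    ess = m * n / tau
    return float(min(ess, m * n * np.log10(m * n)))


def ess_bulk(draws) -> float:
    """Bulk ESS: ESS of the rank-normalized split chains."""
    a = _as_chains(draws)
    if np.ptp(a) == 0.0:
        logger.warning("ess_bulk: constant draws carry no information; returning 0")
        return 0.0
    return _ess(_rank_normalize(_split_chains(a)))


def ess_tail(draws) -> float:
    """Tail ESS: minimum ESS of the 5% and 95% quantile indicator sequences."""
    a = _as_chains(draws)
    if np.ptp(a) == 0.0:
        logger.warning("ess_tail: constant draws carry no information; returning 0")
        return 0.0
    out = []
    for q in (0.05, 0.95):
        indicator = (a <= np.quantile(a, q)).astype(float)
        split = _split_chains(indicator)
        out.append(_ess(_rank_normalize(split)) if np.ptp(split) else 0.0)
    return float(min(out))


def summarize(chains: ChainSet, hdi_mass: float = 0.94) -> pd.DataFrame:
    """Per-parameter posterior summary on the constrained scale.

    Pools all chains for mean / sd (n-1 denominator) / HDI; r_hat and the
    two ESS columns use the chain structure.  Returns full-precision values;
    :func:`write_summary_csv` applies the table rounding on export.
    """
    if chains.num_samples == 0:
        raise ValueError("empty ChainSet")
    con = chains.constrained_draws
    rows = []
    for k, name in enumerate(chains.parameter_names):
        d = con[:, :, k]
        pooled = d.reshape(-1)
        lo, hi = hdi(pooled, mass=hdi_mass) if pooled.size >= 2 else (pooled[0], pooled[0])
        rows.append({
            "name": name,
            "mean": float(pooled.mean()),
            "sd": float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0,
            "hdi_3%": lo,
            "hdi_97%": hi,
            "ess_bulk": ess_bulk(d) if d.shape[1] >= 4 else 0.0,
            "ess_tail": ess_tail(d) if d.shape[1] >= 4 else 0.0,
            "r_hat": split_rhat(d) if d.shape[1] >= 4 else 1.0,
        })
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def write_summary_csv(summary: pd.DataFrame, path) -> None:
    """Export with the printed-table rounding: 3 decimals, ESS to integers."""
    out = summary.copy()
    for col in ["mean", "sd", "hdi_3%", "hdi_97%", "r_hat"]:
        out[col] = out[col].round(3)
    for col in ["ess_bulk", "ess_tail"]:
        out[col] = out[col].round(0).astype(np.int64)
    out.to_csv(path, index=False)
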