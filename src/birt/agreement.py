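"""Agreement between two estimation runs via Lin's concordance correlation.

Lin's CCC measures how well paired measurements fall on the identity line:

    ccc = 2 * s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2)

with population (1/n) moments, following Lin (1989).  Values are classified
after rounding to 3 decimals: < 0.900 poor, 0.900-0.950 moderate,
0.951-0.990 substantial, > 0.990 almost perfect.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["AgreementLabel", "AgreementResult", "lin_ccc", "classify_ccc",
           "compare_summaries", "write_agreement_csv"]

AgreementLabel = str  # one of: poor, moderate, substantial, almost_perfect

POOR = "poor"
MODERATE = "moderate"
SUBSTANTIAL = "substantial"
ALMOST_PERFECT = "almost_perfect"


@dataclass(frozen=True)
class AgreementResult:
    ccc: float
    n: int
    label: AgreementLabel

    def __post_init__(self) -> None:
        if abs(self.ccc) > 1.0 + 1e-12:
            raise ValueError("|ccc| must be <= 1")


def lin_ccc(x: Sequence[float], y: Sequence[float]) -> float:
    """Lin's concordance correlation coefficient with 1/n moments.

    Elementwise-identical inputs return exactly 1.0.  Two constant sequences
    return 1.0 when equal and 0.0 otherwise (no variance to concord).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d sequences of equal length")
    if x.size < 2:
        raise ValueError("lin_ccc requires at least 2 pairs")
    if np.array_equal(x, y):
        return 1.0
    sx2 = x.var()   # population (1/n) moments
    sy2 = y.var()
    if sx2 == 0.0 and sy2 == 0.0:
        return 0.0  # both constant but unequal
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    return float(2.0 * sxy / (sx2 + sy2 + (x.mean() - y.mean()) ** 2))


def classify_ccc(ccc: float) -> AgreementLabel:
    """Agreement class of a CCC value, applied after rounding to 3 decimals."""
    if abs(ccc) > 1.0 + 1e-12:
        raise ValueError("|ccc| must be <= 1")
    r = round(ccc, 3)
    if r < 0.900:
        return POOR
    if r <= 0.950:
        return MODERATE
    if r <= 0.990:
        return SUBSTANTIAL
    return ALMOST_PERFECT


def compare_summaries(a: pd.DataFrame, b: pd.DataFrame, statistic: str = "mean",
                      parameter_filter: Optional[str] = None) -> AgreementResult:
    """CCC between one summary statistic of two summary tables.

    Parameters
    ----------
    a, b : summary tables with ``name`` and statistic columns
    statistic : which column to compare ("mean" or "sd")
    parameter_filter : optional regex on parameter names, e.g. ``theta``
        to restrict to ability parameters (matched with ``re.search``).
    """
    if statistic not in ("mean", "sd"):
        raise ValueError("statistic must be 'mean' or 'sd'")
    names_a = list(a["name"])
    names_b = list(b["name"])
    if parameter_filter is not None:
        pat = re.compile(parameter_filter)
        names_a = [n for n in names_a if pat.search(n)]
        names_b = [n for n in names_b if pat.search(n)]
    if set(names_a) != set(names_b):
        only_a = sorted(set(names_a) - set(names_b))
        only_b = sorted(set(names_b) - set(names_a))
        raise ValueError(f"parameter names differ: only in a={only_a}, only in b={only_b}")
    if not names_a:
        raise ValueError("parameter filter matched no parameters")
    sa = a.set_index("name").loc[names_a, statistic].to_numpy(dtype=float)
    sb = b.set_index("name").loc[names_a, statistic].to_numpy(dtype=float)
    ccc = lin_ccc(sa, sb)
    return AgreementResult(ccc=ccc, n=len(names_a), label=classify_ccc(ccc))


def write_agreement_csv(rows, path) -> None:
    """Agreement report CSV: data,model,comparison,ccc,label (ccc to 3 decimals)."""
    df = pd.DataFrame(rows, columns=["data", "model", "comparison", "ccc", "label"])
    df["ccc"] = df["ccc"].astype(float).round(3)
    df.to_csv(path, index=False)
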