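"""Shared statistical primitives.

Small, brute-force-verifiable pieces used across the pipeline: the
chi-square survival function (for the G test's p-value), linear-interpolation
quantiles (for the input-blacklist IQR rule) and a result container that
serialises into the TSV reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special

__all__ = ["TestResult", "chisq_sf", "quantile", "iqr"]


@dataclass(frozen=True)
class TestResult:
    statistic_name: str
    statistic: float
    p_value: float
    df: int | None = None
    exact: bool = False
    n: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")

    def as_dict(self) -> dict:
        return {
            "statistic": self.statistic_name,
            "value": self.statistic,
            "p_value": self.p_value,
            "df": self.df,
            "exact": self.exact,
            "n": self.n,
        }


def chisq_sf(x: float, df: int) -> float:
    """Upper-tail probability of the chi-square distribution.

    Computed as the regularized upper incomplete gamma function
    Q(df/2, x/2); relative accuracy is at the level of machine precision.
    """
    if x < 0:
        raise ValueError("x must be non-negative")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(special.gammaincc(df / 2.0, x / 2.0))


def quantile(values: Sequence[float], q: float) -> float:
    """Linear-interpolation (type-7) order statistic."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty values")
    if not (0.0 <= q <= 1.0):
        raise ValueError("q must be in [0, 1]")
    return float(np.quantile(values, q, method="linear"))


def iqr(values: Sequence[float]) -> float:
    return quantile(values, 0.75) - quantile(values, 0.25)
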