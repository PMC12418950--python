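"""Small statistics for embryological endpoints.

Rates from counts (cleavage rate = cleaved / oocytes; blastocyst rate =
blastocysts / cleaved), mean +- SEM summaries, and the pooled two-sample
t-test used to compare groups.  Rates are rounded half-up to match printed
one-decimal percentages.  Normality (Kolmogorov-Smirnov) and Levene
homogeneity checks are reported as diagnostics only.
"""

from __future__ import annotations

import decimal
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

#: sentinel p-value for a degenerate (zero-variance, unequal-means) comparison
P_DEGENERATE = 1e-13


@dataclass(frozen=True)
class EmbryoOutcome:
    group: str
    n_oocytes: int
    n_cleaved: int
    n_blastocysts: int
    cells_per_blastocyst: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.n_blastocysts <= self.n_cleaved <= self.n_oocytes:
            raise ValueError(
                f"require 0 <= blastocysts ({self.n_blastocysts}) <= cleaved "
                f"({self.n_cleaved}) <= oocytes ({self.n_oocytes})"
            )

    @property
    def cleavage_rate(self) -> float:
        return rate_percent(self.n_cleaved, self.n_oocytes)

    @property
    def blastocyst_rate(self) -> float:
        return rate_percent(self.n_blastocysts, self.n_cleaved)


def rate_percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """100 x numerator / denominator, half-up rounded to ``decimals``."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    q = decimal.Decimal(1).scaleb(-decimals)
    pct = decimal.Decimal(100) * decimal.Decimal(numerator) / decimal.Decimal(denominator)
    return float(pct.quantize(q, rounding=decimal.ROUND_HALF_UP))


def mean_sem(values: Sequence[float]) -> tuple[float, float]:
    """Mean and standard error of the mean (n-1 denominator sd)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 values")
    return float(x.mean()), float(x.std(ddof=1) / math.sqrt(x.size))


def two_sample_t(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float]:
    """Pooled-variance two-sided Student t-test.

    Zero variance in both samples returns t=0, p=1 for equal means and a
    guarded (+-inf, P_DEGENERATE) for distinct means.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per sample")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), P_DEGENERATE
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def normality_check(values: Sequence[float]) -> tuple[float, float]:
    """Kolmogorov-Smirnov test against a normal with the sample's moments.

    Diagnostic only; the comparison path does not branch on it.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 values")
    sd = x.std(ddof=1)
    if sd == 0:
        return float("nan"), 0.0
    res = stats.kstest(x, "norm", args=(x.mean(), sd))
    return float(res.statistic), float(res.pvalue)


def levene_check(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float]:
    """Levene homogeneity-of-variance diagnostic."""
    res = stats.levene(np.asarray(values_a, float), np.asarray(values_b, float))
    return float(res.statistic), float(res.pvalue)


def outcome_table(outcomes: Sequence[EmbryoOutcome]) -> "pd.DataFrame":
    import pandas as pd

    rows = []
    for o in outcomes:
        row = {
            "group": o.group,
            "n_oocytes": o.n_oocytes,
            "n_cleaved": o.n_cleaved,
            "n_blastocysts": o.n_blastocysts,
            "cleavage_rate_pct": o.cleavage_rate,
            "blastocyst_rate_pct": o.blastocyst_rate,
        }
        if o.cells_per_blastocyst:
            m, s = mean_sem(o.cells_per_blastocyst)
            row["cells_per_blastocyst_mean"] = m
            row["cells_per_blastocyst_sem"] = s
        rows.append(row)
    return pd.DataFrame(rows)
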