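"""Diagnostic-performance arithmetic: Wilson score intervals for
sensitivity/specificity and prevalence-indexed predictive values."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "TestPerformance",
    "PredictiveValues",
    "wilson_ci",
    "ppv_npv",
    "performance_table",
    "DEFAULT_PREVALENCE_GRIDS",
]


@dataclass
class TestPerformance:
    sensitivity: float
    specificity: float
    n_cases: int
    n_controls: int
    ci_level: float = 0.95


@dataclass
class PredictiveValues:
    prevalence: float
    ppv: float
    npv: float


def wilson_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for ``k`` successes of ``n`` trials.

    The normal quantile is used at full precision (1.959964... at 95%),
    not rounded to 1.96.  For k = n the lower bound reduces to
    n / (n + z^2).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    z = norm.ppf((1 + level) / 2)
    p = k / n
    denom = 1 + z * z / n
    centre = p + z * z / (2 * n)
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n))
    return float((centre - half) / denom), float((centre + half) / denom)


def ppv_npv(sensitivity: float, specificity: float,
            prevalence: float) -> PredictiveValues:
    """Bayes' rule predictive values at a population prevalence pi:

        PPV = se*pi / (se*pi + (1-sp)(1-pi))
        NPV = sp(1-pi) / (sp(1-pi) + (1-se)pi)

    Degenerate denominators resolve by the limits pi=0 -> (0, 1) and
    pi=1 -> (1, 0).
    """
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity),
                    ("prevalence", prevalence)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    pi = prevalence
    ppv_num = sensitivity * pi
    ppv_den = ppv_num + (1 - specificity) * (1 - pi)
    npv_num = specificity * (1 - pi)
    npv_den = npv_num + (1 - sensitivity) * pi
    ppv = 0.0 if ppv_den == 0 else ppv_num / ppv_den
    npv = 1.0 if npv_den == 0 else npv_num / npv_den
    if pi == 0:
        ppv, npv = 0.0, 1.0
    elif pi == 1:
        ppv, npv = 1.0, 0.0
    return PredictiveValues(pi, float(ppv), float(npv))


#: prevalence grids (fractions) typically reported per trisomy; population
#: prevalences per 10,000 births are about 22 (T21), 5 (T18) and 2 (T13).
DEFAULT_PREVALENCE_GRIDS: dict[str, tuple[float, ...]] = {
    "chr21": (0.0005, 0.0010, 0.0020, 0.0050, 0.0100, 0.0150, 0.0200),
    "chr18": (0.0003, 0.0005, 0.0010, 0.0020, 0.0030, 0.0040, 0.0050),
    "chr13": (0.0001, 0.0002, 0.0005, 0.0010, 0.0020),
}


def performance_table(performance: dict[str, TestPerformance],
                      prevalence_grids: dict[str, tuple[float, ...]] | None = None
                      ) -> pd.DataFrame:
    """Evaluate PPV/NPV over a prevalence grid per chromosome."""
    grids = prevalence_grids or DEFAULT_PREVALENCE_GRIDS
    rows = []
    for chrom, perf in performance.items():
        for pi in grids.get(chrom, ()):
            pv = ppv_npv(perf.sensitivity, perf.specificity, pi)
            rows.append({"chrom": chrom, "prevalence": pi,
                         "ppv": pv.ppv, "npv": pv.npv})
    return pd.DataFrame(rows)
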