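"""Cohort validation statistics: relative risk, hypergeometric enrichment, rates.

These operate on explicit counts so that in-text arithmetic from published
cohort analyses can be reproduced exactly from the printed numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
from scipy import stats as sps

from .errors import UndefinedStatisticError

__all__ = [
    "TwoByTwo",
    "RelativeRiskResult",
    "relative_risk",
    "hypergeom_enrichment",
    "rate_report",
]


@dataclass(frozen=True)
class TwoByTwo:
    """A 2×2 exposure/outcome table.

    ``a`` exposed with outcome, ``b`` exposed without, ``c`` unexposed with
    outcome, ``d`` unexposed without.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise UndefinedStatisticError("2x2 cells must be nonnegative")


class RelativeRiskResult(NamedTuple):
    rr: float
    ci_low: float
    ci_high: float
    p_value: float


def relative_risk(
    table: TwoByTwo,
    ci_level: float = 0.95,
    continuity_correction: bool = False,
) -> RelativeRiskResult:
    """Risk ratio with Wald (log-scale) confidence interval and p-value.

    RR = [a/(a+b)] / [c/(c+d)]. The CI is
    exp(ln RR ± z·SE) with SE = sqrt(1/a − 1/(a+b) + 1/c − 1/(c+d)), and the
    p-value is the two-sided normal test of ln RR = 0. With
    ``continuity_correction`` 0.5 is added to every cell, allowing zero
    cells; otherwise a zero in ``a`` or ``c`` (or an empty margin) raises.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if continuity_correction:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if a + b == 0 or c + d == 0 or a == 0 or c == 0:
        raise UndefinedStatisticError(
            "relative risk undefined with a zero cell/margin; "
            "consider continuity_correction=True"
        )
    rr = (a / (a + b)) / (c / (c + d))
    se = np.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    z = sps.norm.ppf(1 - (1 - ci_level) / 2)
    log_rr = np.log(rr)
    ci_low = float(np.exp(log_rr - z * se))
    ci_high = float(np.exp(log_rr + z * se))
    if se == 0:
        p = 1.0 if log_rr == 0 else 0.0
    else:
        p = float(2 * sps.norm.sf(abs(log_rr) / se))
    return RelativeRiskResult(float(rr), ci_low, ci_high, p)


def hypergeom_enrichment(
    population: int, successes_in_pop: int, sample: int, observed: int
) -> float:
    """Upper-tail hypergeometric enrichment p-value P(X >= observed).

    Drawing ``sample`` without replacement from ``population`` containing
    ``successes_in_pop`` successes.
    """
    N, K, n, k = population, successes_in_pop, sample, observed
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise UndefinedStatisticError(
            f"inconsistent hypergeometric counts N={N}, K={K}, n={n}, k={k}"
        )
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def rate_report(
    numerator: int,
    denominator: int,
    reference_rate: Optional[float] = None,
    decimals: int = 1,
) -> tuple[float, Optional[float]]:
    """Percentage rate (rounded to ``decimals``) and fold over a reference rate.

    Returns ``(100 * numerator / denominator, fold)`` where ``fold`` is the
    unrounded ratio of the raw rate to ``reference_rate`` (None if no
    reference given).
    """
    if denominator <= 0:
        raise UndefinedStatisticError("rate denominator must be positive")
    rate = numerator / denominator
    fold: Optional[float] = None
    if reference_rate is not None:
        if reference_rate <= 0:
            raise UndefinedStatisticError("reference rate must be positive")
        fold = rate / reference_rate
    return round(100.0 * rate, decimals), fold
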