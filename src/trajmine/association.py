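"""Relative association (RA) of disease pairs, binomial significance, BH-FDR.

For diseases *i*, *j* with patient-level incidences ``I_i``, ``I_j`` among
``N`` patients, the expected number of patients carrying both under
independence is ``C* = I_i * I_j / N``. The relative association of the
observed within-window co-diagnosis count ``C_ij`` is

    RA = C_ij / C*  =  C_ij * N / (I_i * I_j)

RA > 1 means the pair co-occurs more often than chance. Significance is a
one-sided upper-tail binomial test of ``C_ij`` against
``p0 = (I_i/N)(I_j/N)`` — only "more than expected" is ever of interest
because the downstream filter requires RA > 1 — followed by
Benjamini–Hochberg adjustment over all tested pairs in one family.

Note an asymmetry inherited from the source method: the observed count
``C_ij`` requires both first diagnoses within the one-year window, while
the expectation ``C*`` ignores the window. The window can therefore only
reduce RA, making the test conservative for pairs whose diagnoses are far
apart.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import UndefinedStatisticError
from .records import PatientTimeline

__all__ = [
    "PairStatistic",
    "count_incidences",
    "count_cooccurrence",
    "relative_association",
    "binomial_pvalue",
    "bh_adjust",
    "compute_pair_statistics",
    "significant_pairs",
    "pair_table",
]

#: Default co-diagnosis window: first diagnoses within one year.
DEFAULT_WINDOW_DAYS = 365


@dataclass(frozen=True)
class PairStatistic:
    """Association statistics for one unordered disease pair (i < j lexically)."""

    disease_i: str
    disease_j: str
    I_i: int
    I_j: int
    N: int
    C_ij: int
    C_star: float
    RA: float
    p_value: float
    q_value: float = float("nan")


def count_incidences(
    timelines: Sequence[PatientTimeline],
) -> tuple[dict[str, int], int]:
    """Patient-level incidence per code and the total patient count N."""
    I: dict[str, int] = {}
    for tl in timelines:
        for code in tl.first_dx_day:
            I[code] = I.get(code, 0) + 1
    return I, len(timelines)


def _timeline_matrix(
    timelines: Sequence[PatientTimeline], codes: Sequence[str]
) -> np.ndarray:
    """(n_patients, n_codes) first-diagnosis days; NaN where absent."""
    col = {c: k for k, c in enumerate(codes)}
    D = np.full((len(timelines), len(codes)), np.nan)
    for p, tl in enumerate(timelines):
        for code, day in tl.first_dx_day.items():
            if code in col:
                D[p, col[code]] = day
    return D


def count_cooccurrence(
    timelines: Sequence[PatientTimeline],
    window_days: int = DEFAULT_WINDOW_DAYS,
) -> dict[tuple[str, str], int]:
    """Patients with both first diagnoses at most ``window_days`` apart.

    Keys are unordered pairs stored lexically (i < j); the window boundary
    is inclusive. Pairs never co-observed are absent from the map.
    """
    codes = sorted({c for tl in timelines for c in tl.first_dx_day})
    D = _timeline_matrix(timelines, codes)
    present = ~np.isnan(D)
    C: dict[tuple[str, str], int] = {}
    for a, b in combinations(range(len(codes)), 2):
        both = present[:, a] & present[:, b]
        if not both.any():
            continue
        gaps = np.abs(D[both, a] - D[both, b])
        n = int(np.count_nonzero(gaps <= window_days))
        if n:
            C[(codes[a], codes[b])] = n
    return C


def relative_association(C_ij: int, I_i: int, I_j: int, N: int) -> float:
    """RA = C_ij * N / (I_i * I_j); undefined when either incidence is zero."""
    if N <= 0 or I_i <= 0 or I_j <= 0:
        raise UndefinedStatisticError(
            f"RA undefined for I_i={I_i}, I_j={I_j}, N={N}"
        )
    return C_ij * N / (I_i * I_j)


def binomial_pvalue(C_ij: int, N: int, p0: float) -> float:
    """Upper-tail binomial probability P(X >= C_ij), X ~ Binomial(N, p0)."""
    if not 0.0 <= p0 <= 1.0:
        raise UndefinedStatisticError(f"null probability {p0} outside [0, 1]")
    if not 0 <= C_ij <= N:
        raise UndefinedStatisticError(f"count {C_ij} outside [0, {N}]")
    # sf(k-1) is the survival tail including k; scipy computes it stably.
    return float(sps.binom.sf(C_ij - 1, N, p0))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, returned in input order.

    q(i) = min_{j >= i} m * p_(j) / j over the ascending order, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise UndefinedStatisticError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def compute_pair_statistics(
    timelines: Sequence[PatientTimeline],
    window_days: int = DEFAULT_WINDOW_DAYS,
) -> list[PairStatistic]:
    """RA, binomial p and BH q for every pair with both incidences > 0.

    All tested pairs form one BH family; pairs with a zero incidence are
    never tested and so carry no multiple-testing penalty.
    """
    I, N = count_incidences(timelines)
    if N == 0:
        return []
    C = count_cooccurrence(timelines, window_days)
    stats: list[PairStatistic] = []
    for i, j in combinations(sorted(I), 2):
        c = C.get((i, j), 0)
        ra = relative_association(c, I[i], I[j], N)
        p0 = (I[i] / N) * (I[j] / N)
        p = binomial_pvalue(c, N, p0)
        stats.append(
            PairStatistic(
                disease_i=i,
                disease_j=j,
                I_i=I[i],
                I_j=I[j],
                N=N,
                C_ij=c,
                C_star=I[i] * I[j] / N,
                RA=ra,
                p_value=p,
            )
        )
    q = bh_adjust([s.p_value for s in stats])
    return [replace(s, q_value=float(qv)) for s, qv in zip(stats, q)]


def significant_pairs(
    stats: Iterable[PairStatistic],
    ra_min: float = 1.0,
    fdr: float = 0.1,
) -> list[PairStatistic]:
    """Pairs with RA > ``ra_min`` and BH q-value < ``fdr``."""
    return [s for s in stats if s.RA > ra_min and s.q_value < fdr]


def pair_table(stats: Sequence[PairStatistic]) -> pd.DataFrame:
    """Pair statistics as a DataFrame for delimited-text export."""
    return pd.DataFrame(
        [
            {
                "disease_i": s.disease_i,
                "disease_j": s.disease_j,
                "I_i": s.I_i,
                "I_j": s.I_j,
                "N": s.N,
                "C_ij": s.C_ij,
                "RA": s.RA,
                "p": s.p_value,
                "q": s.q_value,
            }
            for s in stats
        ],
        columns=["disease_i", "disease_j", "I_i", "I_j", "N", "C_ij", "RA", "p", "q"],
    )
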