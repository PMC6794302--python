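"""Temporal directionality of correlated disease pairs.

For a patient *p* diagnosed with both diseases *i* and *j* no more than a
year apart, the order indicator ``d_p`` is +1 if *i* came first and −1 if
*j* came first; same-day diagnoses are excluded, as in the standard sign
test. The directionality score

    delta(i→j) = mean of d_p over contributing patients

lies in [−1, 1]; delta > 0 means *i* tends to precede *j*. Its
significance is a two-sided exact sign test (binomial against 1/2), with
Benjamini–Hochberg adjustment applied across all pairs tested at this
stage — a family separate from the association-stage family, since each
criterion is screened at its own false-discovery rate.

Retained pairs are emitted oriented so that delta > 0, with the mean and
sample standard deviation of the source→target interval over
forward-ordered patients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .association import DEFAULT_WINDOW_DAYS, PairStatistic, bh_adjust, _timeline_matrix
from .errors import UndefinedStatisticError
from .records import PatientTimeline

__all__ = [
    "DirectedPair",
    "order_indicator",
    "delta_score",
    "sign_test",
    "directed_pairs",
    "directed_pair_table",
]

#: Sentinel for patients excluded from delta (tie or gap beyond the window).
EXCLUDED = 0


@dataclass(frozen=True)
class DirectedPair:
    """An oriented disease pair: source tends to be diagnosed first."""

    source: str
    target: str
    n_ordered_patients: int  # patients contributing a ±1 indicator
    n_forward: int  # indicators equal to +1 (source first)
    delta: float
    p_value: float
    q_value: float
    interval_mean_days: float  # over forward-ordered patients
    interval_sd_days: float  # sample SD (n-1); NaN if fewer than 2
    patient_count: int  # patients with source strictly before target in window


def order_indicator(
    timeline: PatientTimeline,
    i: str,
    j: str,
    window_days: int = DEFAULT_WINDOW_DAYS,
) -> int:
    """+1 if *i* precedes *j* within the window, −1 if *j* precedes *i*,
    :data:`EXCLUDED` (0) on a tie or a gap beyond the window."""
    try:
        di = timeline.first_dx_day[i]
        dj = timeline.first_dx_day[j]
    except KeyError as exc:
        raise UndefinedStatisticError(
            f"code {exc.args[0]!r} absent from timeline of {timeline.patient_id!r}"
        ) from exc
    if abs(di - dj) > window_days or di == dj:
        return EXCLUDED
    return 1 if di < dj else -1


def delta_score(indicators: Sequence[int]) -> float:
    """Mean of ±1 order indicators; undefined on an empty sequence."""
    arr = np.asarray(indicators, dtype=float)
    if arr.size == 0:
        raise UndefinedStatisticError("no patients contribute an order indicator")
    return float(arr.mean())


def sign_test(n_forward: int, n_total: int) -> float:
    """Two-sided exact sign test: X ~ Binomial(n_total, 1/2).

    The doubled smaller tail, capped at 1.
    """
    if n_total <= 0 or not 0 <= n_forward <= n_total:
        raise UndefinedStatisticError(
            f"invalid sign-test counts: {n_forward} of {n_total}"
        )
    lower = sps.binom.cdf(n_forward, n_total, 0.5)
    upper = sps.binom.sf(n_forward - 1, n_total, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


def directed_pairs(
    timelines: Sequence[PatientTimeline],
    pairs: Iterable[PairStatistic],
    window_days: int = DEFAULT_WINDOW_DAYS,
    fdr: float = 0.1,
) -> list[DirectedPair]:
    """Orient significantly associated pairs by temporal direction.

    For every input pair, delta and its sign-test p are computed from the
    timelines; q-values are BH-adjusted across all pairs tested here; pairs
    with q >= ``fdr`` or delta == 0 are dropped, the rest oriented so that
    delta > 0.
    """
    pair_list = list(pairs)
    codes = sorted({c for s in pair_list for c in (s.disease_i, s.disease_j)})
    col = {c: k for k, c in enumerate(codes)}
    D = _timeline_matrix(timelines, codes)

    tested: list[tuple[str, str, int, int]] = []  # (i, j, n_forward, n_total)
    p_values: list[float] = []
    for s in pair_list:
        di = D[:, col[s.disease_i]]
        dj = D[:, col[s.disease_j]]
        both = ~np.isnan(di) & ~np.isnan(dj)
        gap = di[both] - dj[both]
        contributing = (np.abs(gap) <= window_days) & (gap != 0)
        n_total = int(np.count_nonzero(contributing))
        if n_total == 0:
            continue
        n_forward = int(np.count_nonzero(gap[contributing] < 0))  # i first
        tested.append((s.disease_i, s.disease_j, n_forward, n_total))
        p_values.append(sign_test(n_forward, n_total))

    q_values = bh_adjust(p_values)
    out: list[DirectedPair] = []
    for (i, j, n_forward, n_total), p, q in zip(tested, p_values, q_values):
        delta = (2 * n_forward - n_total) / n_total
        if q >= fdr or delta == 0:
            continue
        if delta > 0:
            src, tgt = i, j
            nf = n_forward
        else:
            src, tgt = j, i
            nf = n_total - n_forward
            delta = -delta
        ds = D[:, col[src]]
        dt = D[:, col[tgt]]
        both = ~np.isnan(ds) & ~np.isnan(dt)
        gap = dt[both] - ds[both]
        forward_gaps = gap[(gap > 0) & (gap <= window_days)]
        out.append(
            DirectedPair(
                source=src,
                target=tgt,
                n_ordered_patients=n_total,
                n_forward=nf,
                delta=delta,
                p_value=float(p),
                q_value=float(q),
                interval_mean_days=float(forward_gaps.mean()),
                interval_sd_days=float(forward_gaps.std(ddof=1))
                if forward_gaps.size > 1
                else float("nan"),
                patient_count=int(forward_gaps.size),
            )
        )
    return out


def directed_pair_table(pairs: Sequence[DirectedPair]) -> pd.DataFrame:
    """Directed pairs as a DataFrame for delimited-text export."""
    return pd.DataFrame(
        [
            {
                "source": d.source,
                "target": d.target,
                "n_total": d.n_ordered_patients,
                "n_forward": d.n_forward,
                "delta": d.delta,
                "p": d.p_value,
                "q": d.q_value,
                "interval_mean": d.interval_mean_days,
                "interval_sd": d.interval_sd_days,
                "patient_count": d.patient_count,
            }
            for d in pairs
        ],
        columns=[
            "source",
            "target",
            "n_total",
            "n_forward",
            "delta",
            "p",
            "q",
            "interval_mean",
            "interval_sd",
            "patient_count",
        ],
    )
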