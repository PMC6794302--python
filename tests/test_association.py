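"""RA statistic, binomial tail, BH adjustment and pair selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trajmine.association import (
    PairStatistic,
    bh_adjust,
    binomial_pvalue,
    compute_pair_statistics,
    count_cooccurrence,
    count_incidences,
    relative_association,
    significant_pairs,
)
from trajmine.errors import UndefinedStatisticError

from conftest import make_timeline


def exact_binom_upper_tail(c, n, p):
    """Enumeration oracle: sum of the exact pmf over k >= c."""
    return sum(math.comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(c, n + 1))


def bh_bruteforce(p_values):
    """Step-up definition applied literally."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    for rank, i in enumerate(order, start=1):
        q[i] = min(
            min(m * p_values[j] / (r + 1) for r, j in enumerate(order) if r + 1 >= rank),
            1.0,
        )
    return q


class TestCounting:
    def test_incidences(self):
        tls = [
            make_timeline("p1", {"A": 0}),
            make_timeline("p2", {"A": 0, "B": 10}),
            make_timeline("p3", {"B": 5}),
        ]
        I, N = count_incidences(tls)
        assert I == {"A": 2, "B": 2} and N == 3

    def test_incidences_empty(self):
        assert count_incidences([]) == ({}, 0)

    def test_cooccurrence_window_inclusive(self):
        tls = [make_timeline("p", {"A": 0, "B": 365})]
        assert count_cooccurrence(tls, 365) == {("A", "B"): 1}

    def test_cooccurrence_outside_window(self):
        tls = [make_timeline("p", {"A": 0, "B": 400})]
        assert count_cooccurrence(tls, 365) == {}

    def test_cooccurrence_counts_patients(self):
        tls = [
            make_timeline("p1", {"A": 0, "B": 100}),
            make_timeline("p2", {"B": 50, "A": 20}),
        ]
        assert count_cooccurrence(tls, 365) == {("A", "B"): 2}


class TestRelativeAssociation:
    def test_hand_arithmetic(self):
        assert relative_association(4, 10, 20, 100) == pytest.approx(2.0)

    def test_ra_one_at_expectation(self):
        # C equals I_i * I_j / N exactly
        assert relative_association(2, 10, 20, 100) == pytest.approx(1.0)

    def test_zero_count(self):
        assert relative_association(0, 10, 20, 100) == 0.0

    def test_zero_incidence_raises(self):
        with pytest.raises(UndefinedStatisticError):
            relative_association(0, 0, 20, 100)

    def test_symmetry(self):
        assert relative_association(7, 13, 29, 500) == relative_association(7, 29, 13, 500)


class TestBinomialPvalue:
    @pytest.mark.parametrize(
        "c,n,p0,expected",
        [
            (10, 10, 0.5, 2**-10),
            (0, 10, 0.3, 1.0),
            (1, 2, 0.5, 0.75),
        ],
    )
    def test_examples(self, c, n, p0, expected):
        assert binomial_pvalue(c, n, p0) == pytest.approx(expected, abs=1e-12)

    def test_matches_enumeration_oracle(self):
        for n in range(1, 31):
            for p0 in (0.01, 0.2, 0.5, 0.9):
                for c in range(n + 1):
                    assert binomial_pvalue(c, n, p0) == pytest.approx(
                        exact_binom_upper_tail(c, n, p0), abs=1e-12
                    )

    def test_invalid_p0(self):
        with pytest.raises(UndefinedStatisticError):
            binomial_pvalue(1, 10, 1.5)


class TestBHAdjust:
    def test_stepup_by_hand(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert bh_adjust([0.37]) == pytest.approx([0.37])

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_returned_in_input_order(self):
        p = [0.5, 0.001, 0.2]
        q = bh_adjust(p)
        assert q[1] == min(q)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=25))
    def test_matches_bruteforce_definition(self, p_values):
        assert np.allclose(bh_adjust(p_values), bh_bruteforce(p_values), atol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=25))
    def test_q_at_least_p(self, p_values):
        assert np.all(bh_adjust(p_values) >= np.asarray(p_values) - 1e-15)

    def test_matches_statsmodels(self):
        # independent library cross-check on a fixed vector
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(11)
        p = rng.random(200)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(bh_adjust(p), q_sm, atol=1e-12)


class TestSelection:
    @pytest.mark.parametrize(
        "ra,q,kept",
        [(1.5, 0.05, True), (0.8, 0.001, False), (3.0, 0.2, False)],
    )
    def test_filter(self, ra, q, kept):
        s = PairStatistic("A", "B", 10, 10, 100, 5, 1.0, ra, 0.01, q)
        assert (significant_pairs([s]) == [s]) is kept

    def test_pairs_with_zero_incidence_never_tested(self):
        tls = [make_timeline("p1", {"A": 0, "B": 10}), make_timeline("p2", {"A": 5})]
        stats = compute_pair_statistics(tls)
        assert {(s.disease_i, s.disease_j) for s in stats} == {("A", "B")}
        assert all(s.q_value >= s.p_value for s in stats)
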