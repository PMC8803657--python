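"""Diversity indices against independent brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repdiv import diversity as dv
from repdiv.errors import DomainError, UndefinedStatisticError
from tests.conftest import random_counts, rep_from_counts

# ---------------------------------------------------------------- oracles


def oracle_shannon(counts):
    total = sum(counts)
    return -sum((c / total) * math.log(c / total) for c in counts)


def oracle_simpson_dominance(counts):
    total = sum(counts)
    return sum((c / total) ** 2 for c in counts)


def oracle_d50(counts):
    ranked = sorted(counts, reverse=True)
    total = sum(ranked)
    cum = 0
    for k, c in enumerate(ranked, start=1):
        cum += c
        if cum / total >= 0.5:
            return 100.0 * k / len(ranked)
    raise AssertionError("unreachable")


def oracle_chao1(counts):
    s = len(counts)
    f1 = sum(1 for c in counts if c == 1)
    f2 = sum(1 for c in counts if c == 2)
    if f2 == 0:
        return s + f1 * (f1 - 1) / 2.0
    return s + f1 * f1 / (2.0 * f2)


def oracle_top100(counts):
    ranked = sorted(counts, reverse=True)
    return 100.0 * sum(ranked[:100]) / sum(ranked)


def oracle_hill(counts, q):
    total = sum(counts)
    p = [c / total for c in counts]
    if q == 0:
        return float(len(p))
    if q == 1:
        return math.exp(-sum(pi * math.log(pi) for pi in p))
    return sum(pi**q for pi in p) ** (1.0 / (1.0 - q))


# ---------------------------------------------------------------- fixed examples


class TestShannon:
    def test_uniform4(self, uniform4):
        assert dv.shannon(uniform4) == pytest.approx(math.log(4), abs=1e-12)

    def test_skewed(self, skewed):
        assert dv.shannon(skewed) == pytest.approx(1.0397207708399179, abs=1e-9)
        assert dv.shannon(skewed) == pytest.approx(oracle_shannon([2, 1, 1]), abs=1e-12)

    def test_single_clone(self):
        assert dv.shannon(rep_from_counts([10])) == 0.0

    def test_empty_raises(self):
        with pytest.raises(UndefinedStatisticError):
            dv.shannon(rep_from_counts([]))


class TestSimpson:
    def test_uniform4(self, uniform4):
        dom, div = dv.simpson(uniform4)
        assert dom == pytest.approx(0.25, abs=1e-12)
        assert div == pytest.approx(0.75, abs=1e-12)

    def test_skewed(self, skewed):
        dom, _ = dv.simpson(skewed)
        assert dom == pytest.approx(0.375, abs=1e-12)

    def test_single_clone(self):
        dom, div = dv.simpson(rep_from_counts([7]))
        assert dom == 1.0 and div == 0.0

    def test_forms_complementary(self, rng):
        for _ in range(50):
            counts = random_counts(rng)
            dom, div = dv.simpson(rep_from_counts(counts))
            assert abs(dom + div - 1.0) < 1e-12


class TestD50:
    def test_uniform100(self):
        assert dv.d50(rep_from_counts([1] * 100)) == pytest.approx(50.0)

    def test_dominant_clone(self):
        assert dv.d50(rep_from_counts([6, 1, 1, 1, 1])) == pytest.approx(20.0)

    def test_single_clone(self):
        assert dv.d50(rep_from_counts([5])) == pytest.approx(100.0)

    def test_matches_oracle(self, rng):
        for _ in range(200):
            counts = random_counts(rng)
            assert dv.d50(rep_from_counts(counts)) == pytest.approx(
                oracle_d50(counts), abs=1e-9
            )


class TestChao1:
    def test_no_singletons(self):
        counts = [3, 4, 5]
        assert dv.chao1(rep_from_counts(counts)) == pytest.approx(3.0)

    def test_classic_branch(self):
        # S_obs = 5, f1 = 2, f2 = 1 -> 5 + 4/2 = 7
        assert dv.chao1(rep_from_counts([1, 1, 2, 3, 4])) == pytest.approx(7.0)

    def test_bias_corrected_branch(self):
        # f1 = 3, f2 = 0, S_obs = 4 -> 4 + 3*2/2 = 7
        assert dv.chao1(rep_from_counts([1, 1, 1, 5])) == pytest.approx(7.0)

    def test_at_least_richness(self, rng):
        for _ in range(100):
            counts = random_counts(rng)
            assert dv.chao1(rep_from_counts(counts)) >= len(counts)


class TestTop100:
    def test_fewer_than_100(self):
        assert dv.top100(rep_from_counts([1] * 50)) == 100.0

    def test_uniform200(self):
        assert dv.top100(rep_from_counts([1] * 200)) == pytest.approx(50.0)

    def test_dominant(self):
        counts = [100] + [1] * 100
        assert dv.top100(rep_from_counts(counts)) == pytest.approx(99.5)
        assert dv.top100(rep_from_counts(counts)) == pytest.approx(
            oracle_top100(counts), abs=1e-12
        )


class TestHill:
    def test_uniform_invariance(self):
        rep = rep_from_counts([3] * 7)
        for _, qd in dv.hill_curve(rep):
            assert qd == pytest.approx(7.0, abs=1e-9)

    def test_q2_skewed(self, skewed):
        assert dv.hill_number(skewed, 2.0) == pytest.approx(1 / 0.375, abs=1e-9)

    def test_q1_limit(self, rng):
        for _ in range(20):
            rep = rep_from_counts(random_counts(rng))
            assert dv.hill_number(rep, 1.0) == pytest.approx(
                math.exp(dv.shannon(rep)), abs=1e-9
            )

    def test_negative_q_rejected(self, skewed):
        with pytest.raises(DomainError):
            dv.hill_number(skewed, -0.5)

    def test_monotone_non_increasing(self, rng):
        for _ in range(30):
            curve = dv.hill_curve(rep_from_counts(random_counts(rng)))
            vals = [qd for _, qd in curve]
            assert all(a >= b - 1e-9 for a, b in zip(vals, vals[1:]))


class TestCurves:
    def test_rank_abundance_flat(self):
        ra = dv.rank_abundance(rep_from_counts([2] * 5))
        assert ra == [(i, pytest.approx(0.2)) for i in range(1, 6)]

    def test_rank_abundance_sorted(self):
        assert dv.rank_abundance(rep_from_counts([1, 3])) == [
            (1, pytest.approx(0.75)),
            (2, pytest.approx(0.25)),
        ]

    def test_rank_abundance_length(self, rng):
        counts = random_counts(rng)
        assert len(dv.rank_abundance(rep_from_counts(counts))) == len(counts)

    def test_cumulative_curve_diagonal(self):
        curve = dv.cumulative_clonotype_curve(rep_from_counts([1] * 4))
        for (x, y), k in zip(curve, range(1, 5)):
            assert x == pytest.approx(k / 4) and y == pytest.approx(k / 4)

    def test_cumulative_curve_single(self):
        assert dv.cumulative_clonotype_curve(rep_from_counts([9])) == [(1.0, 1.0)]

    def test_cumulative_curve_dominant(self):
        curve = dv.cumulative_clonotype_curve(rep_from_counts([6, 1, 1, 1, 1]))
        assert curve[0] == (pytest.approx(0.2), pytest.approx(0.6))
        assert curve[-1] == (pytest.approx(1.0), pytest.approx(1.0))


# ---------------------------------------------------------------- properties


@settings(max_examples=60, deadline=None)
@given(
    counts=st.lists(st.integers(1, 100), min_size=1, max_size=30),
    factor=st.integers(2, 9),
)
def test_scale_invariance(counts, factor):
    """Multiplying counts by a constant changes no index except Chao1."""
    a = rep_from_counts(counts)
    b = rep_from_counts([c * factor for c in counts])
    assert dv.shannon(a) == pytest.approx(dv.shannon(b), abs=1e-9)
    assert dv.simpson(a)[0] == pytest.approx(dv.simpson(b)[0], abs=1e-9)
    assert dv.d50(a) == pytest.approx(dv.d50(b), abs=1e-9)
    assert dv.top100(a) == pytest.approx(dv.top100(b), abs=1e-9)
    assert dv.hill_number(a, 2.5) == pytest.approx(dv.hill_number(b, 2.5), abs=1e-9)


@settings(max_examples=60, deadline=None)
@given(counts=st.lists(st.integers(1, 100), min_size=2, max_size=30))
def test_coarsening_inequality(counts):
    """Merging two clonotypes never increases Shannon or Simpson 1-D."""
    merged = [counts[0] + counts[1]] + counts[2:]
    a, b = rep_from_counts(counts), rep_from_counts(merged)
    assert dv.shannon(b) <= dv.shannon(a) + 1e-12
    assert dv.simpson(b)[1] <= dv.simpson(a)[1] + 1e-12


def test_brute_force_agreement_bulk(rng):
    """All indices agree with the oracles on 1,000 random repertoires."""
    for _ in range(1000):
        counts = random_counts(rng, max_clones=25, max_count=40)
        rep = rep_from_counts(counts)
        assert dv.shannon(rep) == pytest.approx(oracle_shannon(counts), abs=1e-9)
        assert dv.simpson(rep)[0] == pytest.approx(
            oracle_simpson_dominance(counts), abs=1e-9
        )
        assert dv.d50(rep) == pytest.approx(oracle_d50(counts), abs=1e-9)
        assert dv.chao1(rep) == pytest.approx(oracle_chao1(counts), abs=1e-9)
        assert dv.top100(rep) == pytest.approx(oracle_top100(counts), abs=1e-9)
        q = float(rng.uniform(0, 5))
        assert dv.hill_number(rep, q) == pytest.approx(
            oracle_hill(counts, q), rel=1e-9
        )
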