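"""Needleman-Wunsch and Gotoh inside/outside engines and match posteriors."""


from functools import lru_cache

import numpy as np
import pytest

from conftest import random_dna
from gadp.alignment import (
    GOTOH_OUTSIDE_RULES_IMPLEMENTED,
    ScoringScheme,
    alignment_weight,
    enumerate_alignments,
    gotoh_inside,
    gotoh_outside,
    match_posterior,
    nw_inside_outside,
    nw_match_posterior,
    split_probability,
)
from gadp.grammar import derive_outside
from gadp.grammars import gotoh_grammar


@lru_cache(maxsize=None)
def delannoy(n: int, m: int) -> int:
    """Independent recurrence D(n,m) = D(n-1,m) + D(n,m-1) + D(n-1,m-1)."""
    if n == 0 or m == 0:
        return 1
    return delannoy(n - 1, m) + delannoy(n, m - 1) + delannoy(n - 1, m - 1)


def edit_distance(x: str, y: str) -> int:
    """Textbook unit-cost edit distance (independent oracle)."""
    prev = list(range(len(y) + 1))
    for i, cx in enumerate(x, 1):
        cur = [i]
        for j, cy in enumerate(y, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1,
                           prev[j - 1] + (cx != cy)))
        prev = cur
    return prev[-1]


def ensemble_oracle(x, y, scheme):
    """Z and match frequencies from exhaustive alignment enumeration."""
    Z = 0.0
    freq = np.zeros((len(x), len(y)))
    for cols in enumerate_alignments(x, y):
        w = alignment_weight(x, y, cols, scheme)
        Z += w
        for kind, i, j in cols:
            if kind == "M":
                freq[i - 1, j - 1] += w
    return Z, freq / Z


class TestCountAlgebra:
    @pytest.mark.parametrize("n", range(7))
    @pytest.mark.parametrize("m", range(7))
    def test_totals_are_delannoy_numbers(self, n, m):
        s = ScoringScheme(mode="count")
        x, y = "A" * n, "C" * m
        assert nw_inside_outside(x, y, s).Z == delannoy(n, m)
        # affine classification does not change the number of alignments
        assert gotoh_inside(x, y, s).Z == delannoy(n, m)

    def test_empty_inputs(self):
        s = ScoringScheme(mode="count")
        t = nw_inside_outside("", "", s)
        assert t.A[0, 0] == 1 and t.Z == 1
        assert gotoh_inside("", "", s).Z == 1

    def test_outside_count_total_matches(self):
        s = ScoringScheme(mode="count")
        inside = gotoh_inside("ACG", "AG", s)
        outside = gotoh_outside("ACG", "AG", s, inside)
        # M holds the empty alignment, so M*(0,0) sees every alignment once
        assert outside.M_star[0, 0] == inside.Z


class TestOptimizeAlgebra:
    @pytest.mark.parametrize("seed", range(5))
    def test_unit_costs_reproduce_edit_distance(self, seed):
        rng = np.random.default_rng(seed)
        x = random_dna(rng, int(rng.integers(0, 7)))
        y = random_dna(rng, int(rng.integers(0, 7)))
        s = ScoringScheme(match=0, mismatch=1, gap_open=1, mode="optimize",
                          objective="min")
        assert nw_inside_outside(x, y, s).Z == edit_distance(x, y)

    @pytest.mark.parametrize("seed", range(5))
    def test_gotoh_collapses_to_nw_when_gaps_equal(self, seed):
        rng = np.random.default_rng(100 + seed)
        x, y = random_dna(rng, 6), random_dna(rng, 5)
        s = ScoringScheme(gap_open=-1.3, gap_extend=-1.3, mode="optimize")
        assert gotoh_inside(x, y, s).Z == pytest.approx(
            nw_inside_outside(x, y, s).Z
        )

    def test_gotoh_optimum_matches_enumeration(self, rng):
        x, y = "GATTAC", "GCAT"
        s = ScoringScheme(gap_open=-2.0, gap_extend=-0.5, mode="optimize")
        best = max(alignment_weight(x, y, c, s)
                   for c in enumerate_alignments(x, y))
        assert gotoh_inside(x, y, s).Z == pytest.approx(best)


class TestPartitionAlgebra:
    def test_single_character_closed_form(self):
        """Three alignments of "A"/"A": match or two opposite gap runs."""
        s = ScoringScheme(match=0.7, gap_open=-1.1, mode="partition")
        w_m, w_g = np.exp(0.7), np.exp(-1.1)
        inside = gotoh_inside("A", "A", s)
        assert inside.Z == pytest.approx(w_m + 2 * w_g**2, rel=1e-12)
        outside = gotoh_outside("A", "A", s, inside)
        P = match_posterior(inside, outside)
        assert P[0, 0] == pytest.approx(w_m / (w_m + 2 * w_g**2), rel=1e-12)

    def test_outside_corner_receives_start_weight(self):
        s = ScoringScheme(mode="partition")
        inside = gotoh_inside("AC", "AG", s)
        outside = gotoh_outside("AC", "AG", s, inside)
        assert outside.M_star[-1, -1] == 1.0
        assert outside.D_star[-1, -1] == 1.0
        assert outside.I_star[-1, -1] == 1.0

    def test_outside_total_reproduces_z(self, rng):
        x, y = random_dna(rng, 5), random_dna(rng, 4)
        s = ScoringScheme(gap_open=-1.8, gap_extend=-0.6, mode="partition")
        inside = gotoh_inside(x, y, s)
        outside = gotoh_outside(x, y, s, inside)
        assert outside.M_star[0, 0] == pytest.approx(inside.Z, rel=1e-12)
        sp = split_probability(inside, outside)
        assert sp[0, 0] == pytest.approx(1.0)
        assert sp[-1, -1] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_match_posteriors_equal_boltzmann_frequencies(self, seed):
        rng = np.random.default_rng(200 + seed)
        x = random_dna(rng, int(rng.integers(1, 6)))
        y = random_dna(rng, int(rng.integers(1, 6)))
        s = ScoringScheme(gap_open=float(rng.uniform(-3, -1)),
                          gap_extend=float(rng.uniform(-1, 0)),
                          mode="partition")
        inside = gotoh_inside(x, y, s)
        outside = gotoh_outside(x, y, s, inside)
        P = match_posterior(inside, outside)
        Z, freq = ensemble_oracle(x, y, s)
        assert inside.Z == pytest.approx(Z, rel=1e-12)
        np.testing.assert_allclose(P, freq, atol=1e-10)
        assert (P.sum(axis=0) <= 1 + 1e-9).all()
        assert (P.sum(axis=1) <= 1 + 1e-9).all()

    def test_nw_match_posterior_against_oracle(self):
        x, y = "GAT", "GT"
        s = ScoringScheme(mode="partition")  # linear: only gap_open used
        t = nw_inside_outside(x, y, s)
        P = nw_match_posterior(t)
        Z = 0.0
        freq = np.zeros((len(x), len(y)))
        for cols in enumerate_alignments(x, y):
            w = 1.0
            for kind, i, j in cols:
                w *= np.exp(s.sub_score(x[i - 1], y[j - 1])
                            if kind == "M" else s.gap_open)
            Z += w
            for kind, i, j in cols:
                if kind == "M":
                    freq[i - 1, j - 1] += w
        np.testing.assert_allclose(P, freq / Z, atol=1e-12)

    def test_identical_sequences_strong_match_limit(self):
        """As the match reward dominates, the diagonal posterior -> 1."""
        s = ScoringScheme(match=25.0, mode="partition")
        x = "ACGT"
        inside = gotoh_inside(x, x, s)
        outside = gotoh_outside(x, x, s, inside)
        P = match_posterior(inside, outside)
        assert np.diag(P).min() > 1 - 1e-6

    def test_posterior_reversal_symmetry(self, rng):
        x, y = random_dna(rng, 5), random_dna(rng, 4)
        s = ScoringScheme(gap_open=-2.0, gap_extend=-0.7, mode="partition")
        P = match_posterior(gotoh_inside(x, y, s),
                            gotoh_outside(x, y, s, gotoh_inside(x, y, s)))
        xr, yr = x[::-1], y[::-1]
        Pr = match_posterior(gotoh_inside(xr, yr, s),
                             gotoh_outside(xr, yr, s, gotoh_inside(xr, yr, s)))
        np.testing.assert_allclose(P, Pr[::-1, ::-1], rtol=1e-12)

    def test_non_partition_tables_rejected(self):
        s = ScoringScheme(mode="count")
        inside = gotoh_inside("A", "A", s)
        outside = gotoh_outside("A", "A", s, inside)
        with pytest.raises(ValueError):
            match_posterior(inside, outside)

    def test_shape_mismatch_rejected(self):
        s = ScoringScheme(mode="partition")
        inside = gotoh_inside("A", "A", s)
        with pytest.raises(ValueError):
            gotoh_outside("AC", "A", s, inside)


def test_engine_outside_rules_equal_mechanical_derivation():
    """The hand-written outside loops implement exactly the rule set the
    symbolic transform derives from the engine's inside grammar."""
    og = derive_outside(gotoh_grammar("match"))
    derived = {(p.lhs, p.rhs) for p in og.productions}
    assert derived == set(GOTOH_OUTSIDE_RULES_IMPLEMENTED)


def test_attribute_mapping_follows_signature_isomorphism():
    """The inside rule opening a deletion after an insertion maps to the
    outside rule extending I* by the same gap-opening column."""
    og = derive_outside(gotoh_grammar("match"))
    by_rule = {(p.lhs, p.rhs): p.attribute for p in og.productions}
    assert by_rule[("I*", ("D*", "(u-)"))] == "open_del_after_insert"
    assert by_rule[("M*", ("D*", "(u-)"))] == "open_del_after_match"
    assert by_rule[("D*", ("I*", "(-v)"))] == "open_ins_after_delete"


def test_scoring_scheme_validation():
    with pytest.raises(ValueError):
        ScoringScheme(mode="bogus")
    with pytest.raises(ValueError):
        ScoringScheme(mode="partition", RT=0.0)
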