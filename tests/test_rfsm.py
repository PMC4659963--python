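"""Discretization, DFA compilation, matching, and online reconfiguration."""

import re

import numpy as np
import pytest

from wearecg import (
    AttributeRange,
    ConfigError,
    DomainError,
    Matcher,
    Pattern,
    compile_patterns,
    default_disease_patterns,
    derive_alphabet,
    discretize,
    match,
    reconfigure,
)
from wearecg.rfsm import dfa_from_json, dfa_to_json, patterns_from_json, patterns_to_json


@pytest.fixture(scope="module")
def patterns():
    return default_disease_patterns()


@pytest.fixture(scope="module")
def matcher(patterns):
    return Matcher(patterns)


def brute_force(patterns, values):
    """Reference semantics: direct numeric range check of every pattern."""
    return tuple(p.id for p in patterns if p.matches(values))


def regex_match(patterns, dmap, values):
    """Second independent route: the textbook regex view over symbol strings."""
    string = "".join(discretize(values, dmap))
    out = []
    for p in patterns:
        groups = "".join(
            "(" + "|".join(map(re.escape, dmap.pattern_symbols(p, a))) + ")"
            for a in dmap.attributes
        )
        if re.fullmatch(groups, string):
            out.append(p.id)
    return tuple(out)


class TestAlphabet:
    def test_x_partition_structure(self, matcher):
        # the illustrative decompositions: P1's X range is one symbol,
        # P2's "3 < X < 65535" is five, P4's "4 < X < 65535" is four
        dmap = matcher.dmap
        by_id = {p.id: p for p in matcher.patterns}
        assert len(dmap.pattern_symbols(by_id["P1"], "X")) == 1
        assert len(dmap.pattern_symbols(by_id["P2"], "X")) == 5
        assert len(dmap.pattern_symbols(by_id["P4"], "X")) == 4
        described = [p.describe() for p in dmap.pieces["X"]]
        for expected in ("(0, 3)", "(3, 4]", "(4, 7)", "{7}", "(10, 65535)"):
            assert expected in described

    def test_exact_union_invariant(self, matcher):
        # every pattern range equals the union of its symbols' pieces,
        # membership-tested on all integer points 0..200
        dmap = matcher.dmap
        for p in matcher.patterns:
            for attr in dmap.attributes:
                rng = p.range_for(attr)
                symbols = set(dmap.pattern_symbols(p, attr))
                for v in range(201):
                    piece = dmap.piece_for(attr, float(v))
                    assert rng.contains(float(v)) == (piece.symbol in symbols)

    def test_wildcard_spans_whole_domain(self):
        pats = [
            Pattern(
                "W",
                (
                    AttributeRange("X", low=1.0, high=2.0),
                    AttributeRange("Y", wildcard=True),
                ),
                "Act",
            )
        ]
        dmap = derive_alphabet(pats)
        assert len(dmap.pieces["Y"]) == 1
        assert dmap.pieces["Y"][0].describe() == "[0, 65536]"

    def test_randomized_exact_union(self, rng):
        # 50 random patterns on a small integer grid vs brute membership
        pats = []
        for i in range(50):
            lo = float(rng.integers(0, 190))
            hi = float(rng.integers(int(lo) + 1, 200))
            pats.append(
                Pattern(
                    f"R{i}",
                    (
                        AttributeRange("X", low=lo, high=hi),
                        AttributeRange("Y", wildcard=True),
                    ),
                    "A",
                )
            )
        dmap = derive_alphabet(pats)
        for p in pats:
            symbols = set(dmap.pattern_symbols(p, "X"))
            for v in range(201):
                assert p.range_for("X").contains(float(v)) == (
                    dmap.piece_for("X", float(v)).symbol in symbols
                )

    def test_malformed_range_rejected(self):
        with pytest.raises(ConfigError):
            AttributeRange("X", low=5.0, high=2.0)


class TestDiscretize:
    @pytest.mark.parametrize("x,expected_piece", [(2.0, "(0, 3)"), (7.0, "{7}"), (8.0, "(7, 10]")])
    def test_x_examples(self, matcher, x, expected_piece):
        piece = matcher.dmap.piece_for("X", x)
        assert piece.describe() == expected_piece

    def test_out_of_domain(self, matcher):
        with pytest.raises(DomainError):
            discretize((70000.0, 0.0, 0.0), matcher.dmap)

    def test_fixed_length_output(self, matcher):
        syms = discretize((2.0, 5.0, 100.0), matcher.dmap)
        assert len(syms) == 3
        assert syms[0].startswith("x") and syms[1].startswith("y") and syms[2].startswith("z")


class TestMatch:
    @pytest.mark.parametrize(
        "values,expected_ids,expected_actions",
        [
            ((7.0, 100.0, 100.0), ("P5",), ("Artifact",)),
            ((12.0, 8.0, 1.0), ("P4", "P6"), ("Disease 4", "Alarm")),
            ((2.0, 5.0, 100.0), ("P1",), ("Disease 1",)),
            ((0.0, 0.0, 0.0), (), ()),
        ],
    )
    def test_reference_tuples(self, matcher, values, expected_ids, expected_actions):
        result = matcher.match(values)
        assert result.pattern_ids == expected_ids
        assert result.actions == expected_actions
        assert brute_force(matcher.patterns, values) == expected_ids

    def test_empty_pattern_list_matches_nothing(self, rng):
        m = Matcher([])
        # empty attribute set: DFA accepts nothing for any tuple shape it knows
        assert m.dfa.accepting == {} or all(not v for v in m.dfa.accepting.values())

    def test_wildcard_only_pattern_always_matches(self, rng):
        m = Matcher(
            [
                Pattern(
                    "ALL",
                    (AttributeRange("X", wildcard=True), AttributeRange("Y", wildcard=True)),
                    "Act",
                )
            ]
        )
        for _ in range(50):
            v = tuple(rng.uniform(0, 65536, 2))
            assert m.match(v).pattern_ids == ("ALL",)

    def test_equivalence_vs_brute_force_and_regex(self, matcher, rng):
        for _ in range(2000):
            v = tuple(rng.uniform(0.0, 65536.0, 3))
            got = matcher.match(v).pattern_ids
            assert got == brute_force(matcher.patterns, v)
            assert got == regex_match(matcher.patterns, matcher.dmap, v)

    def test_equivalence_on_integer_grid(self, matcher):
        # small integers hit every singleton/boundary piece
        for x in range(13):
            for y in range(13):
                for z in (0.0, 1.0, 2.0, 2.5, 3.0, 5.0, 6.0):
                    v = (float(x), float(y), z)
                    assert matcher.match(v).pattern_ids == brute_force(matcher.patterns, v)

    def test_dfa_transition_total(self, matcher):
        dfa = matcher.dfa
        for s in dfa.states:
            for sym in dfa.alphabet:
                assert (s, sym) in dfa.transition

    def test_recompilation_deterministic(self, patterns, rng):
        m1, m2 = Matcher(patterns), Matcher(patterns)
        for _ in range(300):
            v = tuple(rng.uniform(0.0, 65536.0, 3))
            assert m1.match(v).pattern_ids == m2.match(v).pattern_ids


class TestReconfigure:
    def test_added_pattern_preserves_old_results(self, patterns, rng):
        base = Matcher(patterns)
        p8 = Pattern(
            "P8",
            (
                AttributeRange("X", equality=3.0),
                AttributeRange("Y", wildcard=True),
                AttributeRange("Z", wildcard=True),
            ),
            "Disease 5",
        )
        new = reconfigure(patterns, add=p8)
        assert new.match((3.0, 5.0, 5.0)).pattern_ids == ("P8",)
        for _ in range(2000):
            v = tuple(rng.uniform(0.0, 65536.0, 3))
            before = base.match(v).pattern_ids
            after = new.match(v).pattern_ids
            assert tuple(i for i in after if i != "P8") == before

    def test_duplicate_pattern_co_fires(self, patterns, rng):
        p5 = next(p for p in patterns if p.id == "P5")
        dup = Pattern("P8", p5.ranges, p5.action)
        m = reconfigure(patterns, add=dup)
        for _ in range(500):
            v = tuple(rng.uniform(0.0, 65536.0, 3))
            ids = m.match(v).pattern_ids
            assert ("P5" in ids) == ("P8" in ids)

    def test_remove_all(self, patterns):
        m = reconfigure(patterns, remove_ids=[p.id for p in patterns])
        assert m.patterns == []


class TestSerialization:
    def test_pattern_table_roundtrip(self, patterns):
        back = patterns_from_json(patterns_to_json(patterns))
        assert back == patterns

    def test_lookup_table_roundtrip(self, matcher, rng):
        dfa2 = dfa_from_json(dfa_to_json(matcher.dfa))
        for _ in range(500):
            v = tuple(rng.uniform(0.0, 65536.0, 3))
            assert match(dfa2, v, matcher.dmap).pattern_ids == matcher.match(v).pattern_ids
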