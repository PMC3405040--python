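"""Motif parsing, derivation, and scanning against a regex oracle."""

import re

import pytest
from hypothesis import given, settings, strategies as st

from paralogon.formats import Alignment, ProteinSequence
from paralogon.motif import (
    Class,
    Literal,
    PatternError,
    Wildcard,
    derive_pattern,
    parse_phi_pattern,
    pattern_summary,
    scan_sequence,
)

from conftest import PARALEMMIN_PATTERN

AA = "ACDEFGHIKLMNPQRSTVWY"


def regex_oracle(pattern_text: str) -> re.Pattern:
    """Independent exact-match oracle built from the pattern TEXT alone.

    Wildcards become the class of any residue or unknown ('X'), matching
    the scanner's contract that a sequence 'X' satisfies only wildcards;
    overlapping matches are found with a lookahead.
    """
    out = []
    i = 0
    while i < len(pattern_text):
        ch = pattern_text[i]
        if ch == "X":
            out.append(f"[{AA}X]")
            i += 1
        elif ch == "[":
            j = pattern_text.index("]", i)
            out.append("[" + pattern_text[i + 1 : j] + "]")
            i = j + 1
        else:
            out.append(ch)
            i += 1
    return re.compile("(?=(" + "".join(out) + "))")


def oracle_exact_offsets(pattern_text: str, sequence: str) -> list:
    return [m.start() for m in regex_oracle(pattern_text).finditer(sequence)]


class TestParse:
    def test_paralemmin_pattern_position_kinds(self):
        pat = parse_phi_pattern(PARALEMMIN_PATTERN)
        kinds = [type(p).__name__ for p in pat.positions]
        assert kinds == [
            "Literal", "Wildcard", "Class", "Wildcard", "Wildcard",
            "Literal", "Class", "Wildcard", "Literal", "Literal", "Class",
        ]
        assert [p.residue for p in pat.positions if isinstance(p, Literal)] == [
            "K", "R", "W", "L",
        ]
        assert [set(p.residues) for p in pat.positions if isinstance(p, Class)] == [
            {"K", "R"}, {"E", "D"}, {"M", "L"},
        ]

    def test_minimal_literal(self):
        pat = parse_phi_pattern("A")
        assert len(pat) == 1 and isinstance(pat.positions[0], Literal)

    @pytest.mark.parametrize(
        "text,msg",
        [
            ("K[]", "empty class"),
            ("K[KR", "unclosed"),
            ("K1R", "illegal character"),
            ("K]R", "unmatched"),
            ("", "empty pattern"),
        ],
    )
    def test_parse_errors(self, text, msg):
        with pytest.raises(PatternError, match=msg):
            parse_phi_pattern(text)

    def test_error_reports_offset(self):
        with pytest.raises(PatternError, match="offset 2"):
            parse_phi_pattern("KX[]")


@st.composite
def phi_patterns(draw):
    units = draw(
        st.lists(
            st.one_of(
                st.sampled_from(list(AA)),
                st.just("X"),
                st.sets(st.sampled_from(list(AA)), min_size=2, max_size=4).map(
                    lambda s: "[" + "".join(sorted(s)) + "]"
                ),
            ),
            min_size=1,
            max_size=12,
        )
    )
    return "".join(units)


class TestSummary:
    def test_paralemmin_counts(self):
        pat = parse_phi_pattern(PARALEMMIN_PATTERN)
        assert pattern_summary(pat) == {
            "length": 11,
            "n_literal": 4,
            "n_class": 3,
            "n_wildcard": 4,
        }

    def test_all_wildcards(self):
        assert pattern_summary(parse_phi_pattern("XXX")) == {
            "length": 3,
            "n_literal": 0,
            "n_class": 0,
            "n_wildcard": 3,
        }

    @settings(max_examples=100, derandomize=True)
    @given(phi_patterns())
    def test_components_sum_to_length(self, text):
        pat = parse_phi_pattern(text)
        s = pattern_summary(pat)
        # independent recount from the parsed structure
        n_lit = sum(1 for p in pat.positions if isinstance(p, Literal))
        n_cls = sum(1 for p in pat.positions if isinstance(p, Class))
        n_wild = sum(1 for p in pat.positions if isinstance(p, Wildcard))
        assert (s["n_literal"], s["n_class"], s["n_wildcard"]) == (
            n_lit, n_cls, n_wild,
        )
        assert s["n_literal"] + s["n_class"] + s["n_wildcard"] == s["length"]


class TestScan:
    def test_exact_hit_at_origin(self):
        pat = parse_phi_pattern(PARALEMMIN_PATTERN)
        hits = scan_sequence(pat, ("s", "KAKAARDAWLM"), 4, 3)
        assert [(h.offset, h.exact) for h in hits] == [(0, True)]
        assert oracle_exact_offsets(PARALEMMIN_PATTERN, "KAKAARDAWLM") == [0]

    def test_broken_literals_no_hit(self):
        pat = parse_phi_pattern(PARALEMMIN_PATTERN)
        assert scan_sequence(pat, ("s", "KAKAARDAWAA"), 4, 3) == []
        assert oracle_exact_offsets(PARALEMMIN_PATTERN, "KAKAARDAWAA") == []

    def test_partial_hit_below_exact(self):
        # lancelet-style: 3 of 4 literals, all 3 classes
        pat = parse_phi_pattern(PARALEMMIN_PATTERN)
        seq = "KAKAARDAWAM"  # L literal broken, [ML] intact
        hits = scan_sequence(pat, ("s", seq), 3, 3)
        assert len(hits) == 1 and not hits[0].exact
        assert hits[0].n_literal_matched == 3 and hits[0].n_class_matched == 3

    def test_empty_and_short_sequences(self):
        pat = parse_phi_pattern(PARALEMMIN_PATTERN)
        assert scan_sequence(pat, ("s", "KAK"), 0, 0) == []

    def test_sequence_x_matches_only_wildcards(self):
        pat = parse_phi_pattern("KXA")
        assert scan_sequence(pat, ("s", "KXA"))[0].exact
        # 'X' at the K-literal position does not count; only A matches
        assert scan_sequence(pat, ("s", "XXA"), 0, 0)[0].n_literal_matched == 1
        # X at a literal position never counts as a match
        assert scan_sequence(pat, ("s", "XKA")) == []

    @settings(max_examples=150, derandomize=True)
    @given(
        phi_patterns(),
        st.text(alphabet=AA + "X", min_size=0, max_size=60),
    )
    def test_exact_hits_match_regex_oracle(self, pattern_text, sequence):
        pat = parse_phi_pattern(pattern_text)
        exact = [h.offset for h in scan_sequence(pat, ("s", sequence)) if h.exact]
        assert exact == oracle_exact_offsets(pattern_text, sequence)

    @settings(max_examples=60, derandomize=True)
    @given(
        phi_patterns(),
        st.text(alphabet=AA, min_size=5, max_size=40),
        st.integers(min_value=0, max_value=3),
        st.integers(min_value=0, max_value=3),
    )
    def test_lowering_thresholds_is_monotone(self, text, seq, d_lit, d_cls):
        pat = parse_phi_pattern(text)
        hi_lit = pat.n_literal
        hi_cls = pat.n_class
        lo_lit = max(0, hi_lit - d_lit)
        lo_cls = max(0, hi_cls - d_cls)
        hi = {h.offset for h in scan_sequence(pat, ("s", seq), hi_lit, hi_cls)}
        lo = {h.offset for h in scan_sequence(pat, ("s", seq), lo_lit, lo_cls)}
        assert hi <= lo


class TestDerive:
    def test_identical_rows_all_literal(self):
        aln = Alignment([ProteinSequence(f"r{i}", "MKVLA") for i in range(5)])
        pat, cls = derive_pattern(aln, 0, 5)
        assert pat.text == "MKVLA"
        assert cls.n_invariant == 5

    def test_invariant_conservative_wildcard_columns(self):
        aln = Alignment(
            [ProteinSequence("r1", "KEA"), ProteinSequence("r2", "KDW")]
        )
        pat, cls = derive_pattern(aln, 0, 3)
        assert isinstance(pat.positions[0], Literal)
        assert isinstance(pat.positions[1], Class)
        assert set(pat.positions[1].residues) == {"E", "D"}
        assert isinstance(pat.positions[2], Wildcard)
        assert [k for k, _ in cls.columns] == ["invariant", "conservative", "wildcard"]

    def test_gap_column_forces_wildcard(self):
        aln = Alignment(
            [ProteinSequence("r1", "K-A"), ProteinSequence("r2", "KKA")]
        )
        pat, _ = derive_pattern(aln, 0, 3)
        assert isinstance(pat.positions[1], Wildcard)

    def test_observed_set_not_whole_group_recorded(self):
        # {E,D} fits NDEQ but only the observed pair is kept in the class
        aln = Alignment(
            [ProteinSequence("r1", "E"), ProteinSequence("r2", "D")]
        )
        pat, cls = derive_pattern(aln, 0, 1)
        assert set(pat.positions[0].residues) == {"E", "D"}
        assert cls.columns[0] == ("conservative", "DENQ")

    def test_window_outside_alignment_rejected(self):
        aln = Alignment(
            [ProteinSequence("r1", "MKV"), ProteinSequence("r2", "MKV")]
        )
        with pytest.raises(ValueError, match="window"):
            derive_pattern(aln, 1, 4)

    def test_derived_pattern_rescans_its_own_rows(self):
        aln = Alignment(
            [
                ProteinSequence("r1", "AAKEKAARDAWLMAA"),
                ProteinSequence("r2", "CCKDRAARDAWLLCC"),
            ]
        )
        pat, _ = derive_pattern(aln, 2, 13)
        for row in aln.rows:
            hits = scan_sequence(pat, (row.id, row.residues), pat.n_literal, pat.n_class)
            assert any(h.offset == 2 and h.exact for h in hits)
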