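"""Motif grammar, scanning semantics, and the unique-match classifier."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import regex_match_starts
from paofam.errors import ConfigurationError, MotifParseError
from paofam.io_core import SequenceRecord
from paofam.motif_engine import (
    Call, ElementKind, classify, parse_motif, scan,
)
from paofam.synthetic import SimConfig, embed_motif, realize_motif, \
    random_residues


def rec(residues, seq_id="s"):
    return SequenceRecord(seq_id, "", residues)


class TestParse:
    def test_set_repeat_literal(self):
        pat = parse_motif("[DE]x(1,2)K", "p")
        kinds = [e.kind for e in pat.elements]
        assert kinds == [ElementKind.SET, ElementKind.ANY, ElementKind.LITERAL]
        assert pat.elements[0].residues == frozenset("DE")
        assert (pat.elements[1].min_repeat, pat.elements[1].max_repeat) == (1, 2)
        assert (pat.min_len, pat.max_len) == (3, 4)

    def test_four_packaged_motifs_parse_and_reserialize(self, packaged_motifs):
        assert [p.pattern_id for p in packaged_motifs] == \
            ["subfamily1", "subfamily2", "subfamily3", "subfamily4"]
        for pat in packaged_motifs:
            assert pat.to_raw() == pat.raw

    def test_subfamily3_variable_slack(self, packaged_motifs):
        # hand parse of the printed string: exactly two x(1,2) repeats are
        # variable (slack 1 each); x(2) and x(3) are fixed
        pat = next(p for p in packaged_motifs if p.pattern_id == "subfamily3")
        assert pat.max_len - pat.min_len == 2

    @pytest.mark.parametrize("bad,offset", [
        ("x(", 1),
        ("K(2)", 1),          # repeat after a literal
        ("[DE", 0),           # unbalanced set
        ("[]K", 0),           # empty set
        ("x(2,1)", 1),        # n > m
        ("aK", 0),            # unknown character
        ("x(a)", 1),
    ])
    def test_parse_errors_carry_offset(self, bad, offset):
        with pytest.raises(MotifParseError) as err:
            parse_motif(bad, "p")
        assert err.value.offset == offset

    def test_empty_pattern_rejected(self):
        with pytest.raises(MotifParseError):
            parse_motif("", "p")


class TestScan:
    def test_literal_single_hit(self):
        (m,) = scan(rec("AKA"), parse_motif("K", "p"))
        assert (m.start, m.end, m.matched_text) == (2, 2, "K")

    def test_fixed_wildcard_matches_all_feasible_starts(self):
        matches = scan(rec("ACD"), parse_motif("x(2)", "p"))
        assert [(m.start, m.end) for m in matches] == [(1, 2), (2, 3)]

    def test_shortest_extent_reported(self):
        (m,) = scan(rec("DAAK"), parse_motif("[DE]x(1,2)K", "p"))
        # only the 4-long extent matches here; on "DAK" the 3-long one
        assert (m.start, m.end) == (1, 4)
        (m,) = scan(rec("DAKK"), parse_motif("[DE]x(1,2)K", "p"))
        assert (m.start, m.end) == (1, 3)

    def test_sequence_x_matches_wildcard_only(self):
        assert scan(rec("X"), parse_motif("K", "p")) == []
        assert scan(rec("X"), parse_motif("[KR]", "p")) == []
        (m,) = scan(rec("X"), parse_motif("x", "p"))
        assert (m.start, m.end) == (1, 1)

    def test_matched_text_rematches_in_isolation(self, packaged_motifs, rng):
        cfg = SimConfig(seed=7, seq_length=200)
        for pat in packaged_motifs:
            record, truth = embed_motif(pat, cfg, rng, position=30)
            for m in scan(record, pat):
                again = scan(rec(m.matched_text), pat)
                assert any(a.start == 1 for a in again)

    @pytest.mark.parametrize("seed", range(4))
    def test_start_sets_equal_regex_oracle_random_patterns(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(250):
            pat = random_pattern(rng)
            seq = random_residues(rng, 60)
            if rng.random() < 0.2:  # sprinkle unknown residues
                chars = list(seq)
                for i in rng.choice(60, size=5, replace=False):
                    chars[i] = "X"
                seq = "".join(chars)
            got = [m.start for m in scan(rec(seq), pat)]
            assert got == regex_match_starts(seq, pat), pat.raw

    def test_start_sets_equal_regex_oracle_real_motifs(
            self, packaged_motifs, rng):
        cfg = SimConfig(seed=11, seq_length=200)
        for k in range(100):
            pat = packaged_motifs[k % 4]
            record, _ = embed_motif(pat, cfg, rng)
            got = [m.start for m in scan(record, pat)]
            assert got == regex_match_starts(record.residues, pat)


def random_pattern(rng) -> "MotifPattern":
    """Small random pattern over the full grammar, built as a raw string."""
    from paofam.motif_engine import STANDARD_RESIDUES
    parts = []
    for _ in range(int(rng.integers(2, 7))):
        kind = rng.random()
        if kind < 0.4:
            parts.append(str(rng.choice(list(STANDARD_RESIDUES))))
        elif kind < 0.7:
            members = rng.choice(list(STANDARD_RESIDUES),
                                 size=int(rng.integers(2, 5)), replace=False)
            parts.append("[" + "".join(sorted(set(members))) + "]")
        else:
            core = "x"
            r = rng.random()
            if r < 0.33:
                parts.append(core)
            elif r < 0.66:
                parts.append(f"{core}({int(rng.integers(1, 4))})")
            else:
                lo = int(rng.integers(0, 3))
                hi = lo + int(rng.integers(1, 3))
                parts.append(f"{core}({lo},{hi})")
    return parse_motif("".join(parts), "rand")


class TestRealizationClosure:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000), st.integers(0, 3))
    def test_every_realization_matches_its_own_motif(self, seed, which):
        from paofam.motif_engine import load_packaged_motifs
        pat = load_packaged_motifs()[which]
        rng = np.random.default_rng(seed)
        realization = realize_motif(pat, rng)
        matches = scan(rec(realization), pat)
        assert any(m.start == 1 for m in matches)

    def test_1000_seeded_realizations_per_motif(self, packaged_motifs):
        rng = np.random.default_rng(42)
        cfg = SimConfig(seed=42, seq_length=150)
        for pat in packaged_motifs:
            for _ in range(250):
                record, truth = embed_motif(pat, cfg, rng)
                starts = [m.start for m in scan(record, pat)]
                assert truth["start"] in starts


class TestClassify:
    def test_short_random_sequence_is_no_hit(self, packaged_motifs, rng):
        call = classify(rec(random_residues(rng, 20)), packaged_motifs)
        assert call.call is Call.NO_HIT and not call.matched_patterns

    def test_planted_motifs_classified_to_their_subfamily(
            self, packaged_motifs, rng):
        cfg = SimConfig(seed=3, seq_length=250)
        expected = {
            "subfamily1": Call.SUBFAMILY_1, "subfamily2": Call.SUBFAMILY_2,
            "subfamily3": Call.SUBFAMILY_3, "subfamily4": Call.SUBFAMILY_4,
        }
        for k in range(80):
            pat = packaged_motifs[k % 4]
            record, _ = embed_motif(pat, cfg, rng)
            call = classify(record, packaged_motifs)
            assert call.call is expected[pat.pattern_id]

    def test_two_planted_motifs_give_ambiguous(self, packaged_motifs, rng):
        r1 = realize_motif(packaged_motifs[0], rng)
        r2 = realize_motif(packaged_motifs[1], rng)
        call = classify(rec(r1 + "AAAA" + r2), packaged_motifs)
        assert call.call is Call.AMBIGUOUS
        assert call.matched_patterns == {"subfamily1", "subfamily2"}

    def test_pattern_order_invariance(self, packaged_motifs, rng):
        cfg = SimConfig(seed=9, seq_length=250)
        record, _ = embed_motif(packaged_motifs[2], cfg, rng)
        forward = classify(record, packaged_motifs)
        backward = classify(record, list(reversed(packaged_motifs)))
        assert forward.call is backward.call
        assert forward.matched_patterns == backward.matched_patterns

    def test_empty_pattern_list_rejected(self):
        with pytest.raises(ConfigurationError):
            classify(rec("ACDE"), [])
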