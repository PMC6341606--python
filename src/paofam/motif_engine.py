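"""PROSITE-style motif parsing, scanning and subfamily classification.

Each of the four plant PAO subfamilies carries a differential conserved
motif written in a deterministic pattern syntax: uppercase literals,
residue sets ``[FY]``, the wildcard ``x``, and repeat counts ``x(3)`` /
``x(1,2)`` suffixing a wildcard or set.  A sequence is assigned to a
subfamily when it matches that subfamily's motif and no other
(``NO_HIT`` when nothing matches, ``AMBIGUOUS`` when several do — the
engine refuses to guess a priority order among motifs).

The four motif strings ship as packaged data
(``data/motifs.tsv``), loaded at runtime, so a transcription fix is a
data fix, never a code change.

Matching semantics: a literal matches only itself; a set matches its
members; ``x`` matches any residue including the unknown residue ``X``;
``X`` in a sequence matches *only* ``x`` (it mismatches every literal
and set element).  At each matching start position the shortest matching
extent is reported — classification only needs presence.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from enum import Enum
from typing import Iterable

from .errors import ConfigurationError, MotifParseError
from .io_core import SequenceRecord

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


class ElementKind(Enum):
    LITERAL = "LITERAL"
    SET = "SET"
    ANY = "ANY"


@dataclass(frozen=True)
class MotifElement:
    """One pattern element with repeat bounds (fixed elements have 1, 1)."""

    kind: ElementKind
    residues: frozenset[str]  # LITERAL: singleton; ANY: empty (matches all)
    min_repeat: int = 1
    max_repeat: int = 1

    def matches(self, ch: str) -> bool:
        if self.kind is ElementKind.ANY:
            return True
        return ch in self.residues  # 'X' is never a member

    def to_raw(self) -> str:
        if self.kind is ElementKind.LITERAL:
            core = next(iter(self.residues))
        elif self.kind is ElementKind.SET:
            core = "[" + "".join(sorted(self.residues)) + "]"
        else:
            core = "x"
        if (self.min_repeat, self.max_repeat) == (1, 1):
            return core
        if self.min_repeat == self.max_repeat:
            return f"{core}({self.min_repeat})"
        return f"{core}({self.min_repeat},{self.max_repeat})"


@dataclass(frozen=True)
class MotifPattern:
    pattern_id: str
    raw: str
    elements: tuple[MotifElement, ...]

    @property
    def min_len(self) -> int:
        return sum(e.min_repeat for e in self.elements)

    @property
    def max_len(self) -> int:
        return sum(e.max_repeat for e in self.elements)

    def to_raw(self) -> str:
        return "".join(e.to_raw() for e in self.elements)


@dataclass(frozen=True)
class MotifMatch:
    seq_id: str
    pattern_id: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    matched_text: str


class Call(Enum):
    SUBFAMILY_1 = "SUBFAMILY_1"
    SUBFAMILY_2 = "SUBFAMILY_2"
    SUBFAMILY_3 = "SUBFAMILY_3"
    SUBFAMILY_4 = "SUBFAMILY_4"
    NO_HIT = "NO_HIT"
    AMBIGUOUS = "AMBIGUOUS"


#: pattern_id in the packaged motif table -> subfamily call
PATTERN_CALLS = {
    "subfamily1": Call.SUBFAMILY_1,
    "subfamily2": Call.SUBFAMILY_2,
    "subfamily3": Call.SUBFAMILY_3,
    "subfamily4": Call.SUBFAMILY_4,
}


@dataclass(frozen=True)
class SubfamilyCall:
    seq_id: str
    call: Call
    matched_patterns: frozenset[str]
    evidence: tuple[MotifMatch, ...]


# ---------------------------------------------------------------------------
# Parsing

def parse_motif(raw: str, pattern_id: str) -> MotifPattern:
    """Parse a pattern string into elements.

    Grammar: LITERAL — one uppercase residue letter; SET — ``[`` one or
    more literals ``]``; ANY — lowercase ``x``; REPEAT — ``(n)`` or
    ``(n,m)`` (n <= m) immediately after an ANY or SET.  Elements are
    concatenated with no separators.  Errors carry the byte offset.
    """
    if not raw:
        raise MotifParseError("empty pattern", 0)
    elements: list[MotifElement] = []
    i = 0
    n = len(raw)
    while i < n:
        ch = raw[i]
        if ch in STANDARD_RESIDUES:
            elements.append(
                MotifElement(ElementKind.LITERAL, frozenset(ch)))
            i += 1
        elif ch == "x":
            elements.append(MotifElement(ElementKind.ANY, frozenset()))
            i += 1
        elif ch == "[":
            j = raw.find("]", i + 1)
            if j < 0:
                raise MotifParseError("unbalanced '['", i)
            members = raw[i + 1:j]
            if not members:
                raise MotifParseError("empty residue set", i)
            bad = [k for k, m in enumerate(members)
                   if m not in STANDARD_RESIDUES]
            if bad:
                raise MotifParseError(
                    f"illegal set member {members[bad[0]]!r}", i + 1 + bad[0])
            elements.append(
                MotifElement(ElementKind.SET, frozenset(members)))
            i = j + 1
        elif ch == "(":
            if not elements or elements[-1].kind is ElementKind.LITERAL \
                    or elements[-1].max_repeat != 1:
                raise MotifParseError(
                    "repeat without a preceding wildcard or set", i)
            j = raw.find(")", i + 1)
            if j < 0:
                raise MotifParseError("unbalanced '('", i)
            body = raw[i + 1:j]
            parts = body.split(",")
            if not (1 <= len(parts) <= 2) or not all(p.isdigit() for p in parts):
                raise MotifParseError(f"malformed repeat {body!r}", i)
            lo = int(parts[0])
            hi = int(parts[-1])
            if lo > hi:
                raise MotifParseError(f"repeat bounds {lo} > {hi}", i)
            prev = elements.pop()
            elements.append(MotifElement(prev.kind, prev.residues, lo, hi))
            i = j + 1
        else:
            raise MotifParseError(f"unknown character {ch!r}", i)
    return MotifPattern(pattern_id=pattern_id, raw=raw,
                        elements=tuple(elements))


def load_packaged_motifs() -> list[MotifPattern]:
    """The four subfamily motifs shipped with the package."""
    text = (importlib.resources.files("paofam") / "data" / "motifs.tsv"
            ).read_text()
    return load_motif_table(text.splitlines())


def load_motif_table(lines: Iterable[str]) -> list[MotifPattern]:
    """Parse a two-column TSV (pattern_id, raw pattern); header required."""
    rows = [ln.rstrip("\n") for ln in lines if ln.strip()]
    if not rows or rows[0].split("\t")[:2] != ["pattern_id", "pattern"]:
        raise ConfigurationError(
            "motif table must start with header 'pattern_id<TAB>pattern'")
    out = []
    for ln in rows[1:]:
        fields = ln.split("\t")
        if len(fields) < 2:
            raise ConfigurationError(f"motif table row lacks a pattern: {ln!r}")
        out.append(parse_motif(fields[1], fields[0]))
    return out


# ---------------------------------------------------------------------------
# Scanning

def scan(record: SequenceRecord, pattern: MotifPattern) -> list[MotifMatch]:
    """All start positions where the pattern matches, ascending.

    At each matching start the shortest matching extent is reported;
    overlapping matches across different starts are allowed.  Uses a
    set-of-offsets propagation: after consuming each element the set of
    reachable sequence offsets is advanced, which handles variable
    repeats without backtracking.
    """
    seq = record.residues
    L = len(seq)
    min_len = pattern.min_len
    out: list[MotifMatch] = []
    for s in range(0, L - min_len + 1):
        offsets = {s}
        for el in pattern.elements:
            nxt: set[int] = set()
            for off in offsets:
                # consume min_repeat..max_repeat copies of el from off
                pos = off
                ok = True
                for _ in range(el.min_repeat):
                    if pos >= L or not el.matches(seq[pos]):
                        ok = False
                        break
                    pos += 1
                if not ok:
                    continue
                nxt.add(pos)
                for _ in range(el.max_repeat - el.min_repeat):
                    if pos >= L or not el.matches(seq[pos]):
                        break
                    pos += 1
                    nxt.add(pos)
            offsets = nxt
            if not offsets:
                break
        if offsets:
            end = min(offsets)  # shortest extent
            out.append(MotifMatch(
                seq_id=record.id, pattern_id=pattern.pattern_id,
                start=s + 1, end=end, matched_text=seq[s:end]))
    return out


def classify(record: SequenceRecord,
             patterns: list[MotifPattern] | None = None) -> SubfamilyCall:
    """Scan against every pattern and apply the unique-match rule."""
    if patterns is None:
        patterns = load_packaged_motifs()
    if not patterns:
        raise ConfigurationError("classify requires at least one pattern")
    evidence: list[MotifMatch] = []
    matched: set[str] = set()
    for pat in sorted(patterns, key=lambda p: p.pattern_id):
        hits = scan(record, pat)
        if hits:
            matched.add(pat.pattern_id)
            evidence.extend(hits)
    if not matched:
        call = Call.NO_HIT
    elif len(matched) >= 2:
        call = Call.AMBIGUOUS
    else:
        pid = next(iter(matched))
        if pid not in PATTERN_CALLS:
            raise ConfigurationError(
                f"pattern id {pid!r} has no subfamily mapping; use ids "
                f"{sorted(PATTERN_CALLS)}")
        call = PATTERN_CALLS[pid]
    return SubfamilyCall(
        seq_id=record.id, call=call,
        matched_patterns=frozenset(matched), evidence=tuple(evidence))
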