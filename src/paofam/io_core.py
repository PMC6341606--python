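"""Readers and writers for every external format the pipeline touches.

Formats: FASTA (protein sequences), aligned FASTA (MSAs, gap ``-``),
a 10-column tab-separated domain-hit table (hmmscan-domtblout-like),
Newick (ultrametric trees) and TSV reports.  All serialized coordinates
are 1-based inclusive, following the HMMER/Pfam convention.

``X`` is accepted everywhere as an unknown residue; downstream it
mismatches every literal and set element in motif matching and counts as
a comparable (mismatching) position in distances.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .errors import (
    AlignmentWidthError,
    AlphabetError,
    DuplicateIdError,
    FormatError,
    ValidationError,
)

#: The 20 standard residues plus X for unknown.
RESIDUE_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
GAP = "-"

DOMAIN_TABLE_COLUMNS = [
    "seq_id",
    "seq_len",
    "domain_acc",
    "domain_name",
    "model_len",
    "hmm_from",
    "hmm_to",
    "env_from",
    "env_to",
    "evalue",
]


@dataclass(frozen=True)
class SequenceRecord:
    """An identified amino-acid sequence — the pipeline's atom."""

    id: str
    description: str
    residues: str

    def __post_init__(self):
        if not self.id:
            raise ValidationError("sequence record with empty id")
        bad = set(self.residues) - RESIDUE_ALPHABET
        if bad:
            raise AlphabetError(
                f"illegal residue character(s) {sorted(bad)!r} in record {self.id!r}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Msa:
    """A multiple sequence alignment with validated equal row widths."""

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self):
        if not self.rows:
            raise ValidationError("empty alignment")
        widths = {len(s) for _, s in self.rows}
        if len(widths) > 1:
            offenders = sorted(
                {i for i, (_, s) in enumerate(self.rows)
                 if len(s) != len(self.rows[0][1])}
            )
            ids = [self.rows[i][0] for i in offenders]
            raise AlignmentWidthError(
                f"ragged alignment rows (ids {ids}); widths seen: {sorted(widths)}"
            )
        ids = [i for i, _ in self.rows]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DuplicateIdError(f"duplicate alignment ids: {dupes}")
        for rid, s in self.rows:
            bad = set(s) - RESIDUE_ALPHABET - {GAP}
            if bad:
                raise AlphabetError(
                    f"illegal character(s) {sorted(bad)!r} in aligned row {rid!r}"
                )

    @property
    def width(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.rows]

    def row(self, seq_id: str) -> str:
        for rid, s in self.rows:
            if rid == seq_id:
                return s
        raise KeyError(seq_id)

    def ungapped(self) -> list[SequenceRecord]:
        return [
            SequenceRecord(rid, "", s.replace(GAP, "")) for rid, s in self.rows
        ]


@dataclass(frozen=True)
class DomainHit:
    """One Pfam-model match, in 1-based inclusive coordinates.

    ``hmm_from``/``hmm_to`` index HMM (model) positions,
    ``env_from``/``env_to`` index sequence positions (envelope).
    """

    seq_id: str
    seq_len: int
    domain_acc: str
    domain_name: str
    model_len: int
    hmm_from: int
    hmm_to: int
    env_from: int
    env_to: int
    evalue: float = 0.0

    def __post_init__(self):
        if not (1 <= self.hmm_from <= self.hmm_to <= self.model_len):
            raise ValidationError(
                f"hit on {self.seq_id!r}: model coordinates "
                f"{self.hmm_from}..{self.hmm_to} violate 1 <= from <= to <= "
                f"model_len={self.model_len}"
            )
        if not (1 <= self.env_from <= self.env_to <= self.seq_len):
            raise ValidationError(
                f"hit on {self.seq_id!r}: sequence coordinates "
                f"{self.env_from}..{self.env_to} violate 1 <= from <= to <= "
                f"seq_len={self.seq_len}"
            )
        if self.evalue < 0:
            raise ValidationError(f"hit on {self.seq_id!r}: negative E-value")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read a protein FASTA file.

    Residues are uppercased and ``*`` stop characters stripped; the id is
    the first whitespace-delimited token of the header, the rest of the
    header is the description.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        # Reject junk before the first header; SimpleFastaParser skips it.
        pos = fh.tell()
        for line in fh:
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise FormatError(
                    f"{path}: non-FASTA content before first header: {line.strip()[:40]!r}"
                )
            break
        fh.seek(pos)
        for header, seq in SimpleFastaParser(fh):
            parts = header.split(None, 1)
            if not parts:
                raise FormatError(f"{path}: empty FASTA header")
            rid = parts[0]
            desc = parts[1] if len(parts) > 1 else ""
            if rid in seen:
                raise DuplicateIdError(f"{path}: duplicate sequence id {rid!r}")
            seen.add(rid)
            residues = seq.upper().replace("*", "")
            records.append(SequenceRecord(rid, desc, residues))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, rec.length, width):
                fh.write(rec.residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Aligned FASTA

def read_msa(path: str | os.PathLike) -> Msa:
    """Read an aligned FASTA file (gap character ``-``)."""
    rows = []
    with open(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            rid = header.split(None, 1)[0]
            rows.append((rid, seq.upper()))
    if not rows:
        raise FormatError(f"{path}: no alignment rows")
    return Msa(tuple(rows))


def write_msa(msa: Msa, path: str | os.PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, s in msa.rows:
            fh.write(f">{rid}\n")
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Domain-hit table

def read_domain_table(path: str | os.PathLike) -> list[DomainHit]:
    """Read the package's 10-column tab-separated domain-hit table.

    Header row required; ``#``-prefixed lines ignored.  This is a cleaned
    stand-in for hmmscan ``--domtblout``; see
    :func:`convert_domtblout` for converting real hmmscan output.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                         skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty domain table (header required)")
    missing = [c for c in DOMAIN_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    hits: list[DomainHit] = []
    for rownum, row in enumerate(df.itertuples(index=False), start=2):
        try:
            hits.append(DomainHit(
                seq_id=row.seq_id,
                seq_len=int(row.seq_len),
                domain_acc=row.domain_acc,
                domain_name=row.domain_name,
                model_len=int(row.model_len),
                hmm_from=int(row.hmm_from),
                hmm_to=int(row.hmm_to),
                env_from=int(row.env_from),
                env_to=int(row.env_to),
                evalue=float(row.evalue),
            ))
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}, row {rownum}: {exc}") from exc
        except ValidationError as exc:
            raise ValidationError(f"{path}, row {rownum}: {exc}") from exc
    return hits


def write_domain_table(hits: Iterable[DomainHit],
                       path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [[h.seq_id, h.seq_len, h.domain_acc, h.domain_name, h.model_len,
          h.hmm_from, h.hmm_to, h.env_from, h.env_to, h.evalue]
         for h in hits],
        columns=DOMAIN_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def convert_domtblout(path: str | os.PathLike) -> list[DomainHit]:
    """Convert real hmmscan ``--domtblout`` output to :class:`DomainHit`.

    Utility, not a core dependency of the pipeline: the pipeline's own
    dialect is the 10-column TSV of :func:`read_domain_table`.
    Uses the standard domtblout column layout (whitespace-separated, 23+
    columns, query name in column 4, hmm/env coordinates in columns
    16-17/20-21, 1-based).
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.split()
            if len(f) < 23:
                raise FormatError(f"{path}: short domtblout line: {line[:60]!r}")
            hits.append(DomainHit(
                seq_id=f[3], seq_len=int(f[5]),
                domain_acc=f[1].split(".")[0], domain_name=f[0],
                model_len=int(f[2]),
                hmm_from=int(f[15]), hmm_to=int(f[16]),
                env_from=int(f[19]), env_to=int(f[20]),
                evalue=float(f[6]),
            ))
    return hits
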