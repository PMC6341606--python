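"""Homology-model quality gate.

Each candidate sequence is modeled (externally, e.g. SWISS-MODEL)
against the three available PAO crystal structures — ZmPAO1 (PDB 3KU9),
FMS1 (1XPQ) and MmAPAO (5MBX) — and the resulting QMEAN Z-score and GMQE
are consumed here.  A model is low quality when |QMEAN Z| > 4.5 or
GMQE < 0.6 (strict inequalities: the boundary values are acceptable).
A clade counts as a PAO subfamily unless *every* model of *every* member
is low quality.

"Best template" is operationalized GMQE-primary, |QMEAN Z|-secondary
(ties broken by the fixed template order 3KU9, 1XPQ, 5MBX); the clade's
best template is the per-sequence majority.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import pandas as pd

from .errors import FormatError, ValidationError

TEMPLATES = ("3KU9", "1XPQ", "5MBX")  # ZmPAO1, FMS1, MmAPAO
QMEAN_ABS_MAX = 4.5
GMQE_MIN = 0.6

QUALITY_TABLE_COLUMNS = ["seq_id", "template_id", "qmean_z", "gmqe"]


@dataclass(frozen=True)
class ModelQuality:
    seq_id: str
    template_id: str
    qmean_z: float
    gmqe: float

    def __post_init__(self):
        if not (0.0 <= self.gmqe <= 1.0):
            raise ValidationError(
                f"{self.seq_id}/{self.template_id}: GMQE {self.gmqe} "
                f"outside [0, 1]")


def is_low_quality(q: ModelQuality, qmean_abs_max: float = QMEAN_ABS_MAX,
                   gmqe_min: float = GMQE_MIN) -> bool:
    """|QMEAN Z| > 4.5 or GMQE < 0.6; boundaries are acceptable."""
    return abs(q.qmean_z) > qmean_abs_max or q.gmqe < gmqe_min


def _template_rank(template_id: str) -> int:
    try:
        return TEMPLATES.index(template_id)
    except ValueError:
        return len(TEMPLATES)


def best_template_for_sequence(records: list[ModelQuality]) -> str | None:
    """Best acceptable template for one sequence, or None.

    Highest GMQE among non-low-quality models; ties by smaller
    |QMEAN Z|, then template order.
    """
    acceptable = [q for q in records if not is_low_quality(q)]
    if not acceptable:
        return None
    best = min(acceptable,
               key=lambda q: (-q.gmqe, abs(q.qmean_z),
                              _template_rank(q.template_id)))
    return best.template_id


def best_template_for_clade(records: list[ModelQuality]) -> str | None:
    """Most frequent per-sequence best template (majority vote).

    Ties go to the fixed template order; None when no sequence has any
    acceptable model.
    """
    by_seq: dict[str, list[ModelQuality]] = {}
    for q in records:
        by_seq.setdefault(q.seq_id, []).append(q)
    votes: dict[str, int] = {}
    for seq_records in by_seq.values():
        best = best_template_for_sequence(seq_records)
        if best is not None:
            votes[best] = votes.get(best, 0) + 1
    if not votes:
        return None
    return min(votes, key=lambda t: (-votes[t], _template_rank(t)))


def clade_is_pao(records: list[ModelQuality]) -> bool:
    """False iff every model of every sequence is low quality.

    An empty clade (no records) is vacuously not a PAO subfamily.
    """
    return any(not is_low_quality(q) for q in records)


def n_acceptable(records: list[ModelQuality]) -> int:
    return sum(not is_low_quality(q) for q in records)


def read_quality_table(path: str | os.PathLike) -> list[ModelQuality]:
    """Read the 4-column TSV (seq_id, template_id, qmean_z, gmqe)."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty quality table (header required)")
    missing = [c for c in QUALITY_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    out = []
    for rownum, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(ModelQuality(
                seq_id=row.seq_id, template_id=row.template_id,
                qmean_z=float(row.qmean_z), gmqe=float(row.gmqe)))
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}, row {rownum}: {exc}") from exc
    return out
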