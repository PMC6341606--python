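"""Domain-architecture rule and sequence-selection criteria.

Candidate PAOs must carry exactly one Amino_oxidase domain (PF01593) and
no other domain — known PAOs are single-domain proteins, while e.g.
plant lysine histone demethylases carry an extra SWIRM domain.  Sequences
passing the architecture rule are then screened on four criteria derived
from the domain hit coordinates:

* ``MISSING_SIDE`` — at most 50 model positions missing on either side
  of the domain (measured in model coordinates);
* ``INTERNAL_INDEL`` — the absolute difference between the sequence span
  and the model span of the hit may not exceed 150 aa, a proxy for "no
  internal insertion/deletion longer than 150 aa" computable from
  domtblout-level coordinates alone;
* ``FLANK`` — at least five residues before the domain start and after
  its end (guards against truncated sequences);
* ``LENGTH`` — at most 700 residues in total (guards against proteins
  with additional, unannotated domains).

Boundary semantics are literal: "less or equal to 50" passes at 50,
"at least five" passes at 5, "no more than 700" passes at 700.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConsistencyError, ValidationError
from .io_core import DomainHit, SequenceRecord

ARCHITECTURE = "ARCHITECTURE"
MISSING_SIDE = "MISSING_SIDE"
INTERNAL_INDEL = "INTERNAL_INDEL"
FLANK = "FLANK"
LENGTH = "LENGTH"

FAILURE_CODES = (ARCHITECTURE, MISSING_SIDE, INTERNAL_INDEL, FLANK, LENGTH)


@dataclass(frozen=True)
class FilterConfig:
    max_missing_per_side: int = 50
    max_internal_indel: int = 150
    min_flank: int = 5
    max_length: int = 700
    target_domain: str = "PF01593"

    def __post_init__(self):
        for name in ("max_missing_per_side", "max_internal_indel",
                     "min_flank", "max_length"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class FilterReport:
    """Audit trail for one sequence: pass/fail plus every measured value."""

    seq_id: str
    passed: bool
    failures: tuple[str, ...]
    missing_left: int | None = None
    missing_right: int | None = None
    indel_excess: int | None = None
    flank_left: int | None = None
    flank_right: int | None = None
    length: int | None = None


def check_architecture(hits: list[DomainHit], cfg: FilterConfig) -> bool:
    """True iff exactly one hit matches the target domain and no other
    domain is present.  An empty hit list is False, not an error."""
    if hits:
        ids = {h.seq_id for h in hits}
        if len(ids) > 1:
            raise ConsistencyError(f"hits from multiple sequences: {sorted(ids)}")
    target = [h for h in hits if h.domain_acc == cfg.target_domain]
    other = [h for h in hits if h.domain_acc != cfg.target_domain]
    return len(target) == 1 and not other


def evaluate_sequence(record: SequenceRecord, hit: DomainHit,
                      cfg: FilterConfig) -> FilterReport:
    """Measure the four criteria for a single-architecture sequence."""
    if hit.seq_id != record.id:
        raise ConsistencyError(
            f"hit seq_id {hit.seq_id!r} != record id {record.id!r}"
        )
    if hit.seq_len != record.length:
        raise ConsistencyError(
            f"{record.id!r}: hit seq_len {hit.seq_len} != record length "
            f"{record.length}"
        )
    missing_left = hit.hmm_from - 1
    missing_right = hit.model_len - hit.hmm_to
    flank_left = hit.env_from - 1
    flank_right = hit.seq_len - hit.env_to
    indel_excess = abs((hit.env_to - hit.env_from) - (hit.hmm_to - hit.hmm_from))
    length = hit.seq_len

    failures = []
    if missing_left > cfg.max_missing_per_side or \
            missing_right > cfg.max_missing_per_side:
        failures.append(MISSING_SIDE)
    if indel_excess > cfg.max_internal_indel:
        failures.append(INTERNAL_INDEL)
    if flank_left < cfg.min_flank or flank_right < cfg.min_flank:
        failures.append(FLANK)
    if length > cfg.max_length:
        failures.append(LENGTH)

    return FilterReport(
        seq_id=record.id,
        passed=not failures,
        failures=tuple(failures),
        missing_left=missing_left,
        missing_right=missing_right,
        indel_excess=indel_excess,
        flank_left=flank_left,
        flank_right=flank_right,
        length=length,
    )


def filter_database(records: list[SequenceRecord], hits: list[DomainHit],
                    cfg: FilterConfig = FilterConfig()
                    ) -> tuple[list[SequenceRecord], list[FilterReport]]:
    """Apply architecture + criteria to a whole database, order preserved.

    Returns (survivors, one report per input record).  A sequence with
    multiple target-domain hits fails ARCHITECTURE and its per-criterion
    values stay unmeasured.
    """
    known = {r.id for r in records}
    by_seq: dict[str, list[DomainHit]] = {}
    for h in hits:
        if h.seq_id not in known:
            raise ConsistencyError(f"hit references unknown seq_id {h.seq_id!r}")
        by_seq.setdefault(h.seq_id, []).append(h)

    survivors: list[SequenceRecord] = []
    reports: list[FilterReport] = []
    for rec in records:
        seq_hits = by_seq.get(rec.id, [])
        if not check_architecture(seq_hits, cfg):
            reports.append(FilterReport(
                seq_id=rec.id, passed=False, failures=(ARCHITECTURE,),
                length=rec.length,
            ))
            continue
        (hit,) = [h for h in seq_hits if h.domain_acc == cfg.target_domain]
        report = evaluate_sequence(rec, hit, cfg)
        reports.append(report)
        if report.passed:
            survivors.append(rec)
    return survivors, reports
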