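"""Synthetic data generation for every stage of the pipeline.

Generates, under explicit seeds and stated distributions:

* realizations of the four subfamily motifs embedded in random
  background sequences (truth = planted pattern and coordinates);
* star-topology protein families with a controlled per-site substitution
  probability ``p`` per lineage, so the expected pairwise p-distance
  between two descendants is the closed form
  ``1 - [(1 - p)^2 + p^2 / 19]``;
* domain-hit tables whose rows violate exactly one filter criterion by
  exactly one unit (or pass with every measured value exactly at its
  threshold);
* MSAs with planted residue distributions at the nine active-site
  columns of an ungapped reference row.

The star topology (rather than a tree-shaped genealogy) is deliberate:
it yields closed-form expected distances, which is what makes the
fixtures checkable.  Background residue frequencies default to uniform
(1/20) for the same reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import PlacementError, ValidationError
from .io_core import GAP, DomainHit, Msa, SequenceRecord
from .motif_engine import ElementKind, MotifPattern
from .domain_filter import (
    ARCHITECTURE, FAILURE_CODES, FLANK, INTERNAL_INDEL, LENGTH, MISSING_SIDE,
    FilterConfig,
)

RESIDUES = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    background_freqs: tuple[float, ...] = tuple([0.05] * 20)
    sub_rate: float = 0.05  # per-site substitution probability per lineage
    family_size: int = 10
    seq_length: int = 500

    def __post_init__(self):
        if abs(sum(self.background_freqs) - 1.0) > 1e-9:
            raise ValidationError("background frequencies must sum to 1")
        if len(self.background_freqs) != 20:
            raise ValidationError("background needs 20 frequencies")
        if not (0.0 <= self.sub_rate <= 0.95):
            raise ValidationError("sub_rate outside [0, 0.95]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def expected_within_family_distance(p: float) -> float:
    """Closed-form expected p-distance between two star descendants."""
    return 1.0 - ((1.0 - p) ** 2 + p ** 2 / 19.0)


def expected_background_distance(freqs: tuple[float, ...]) -> float:
    """Expected distance between two unrelated background sequences."""
    return 1.0 - sum(f * f for f in freqs)


def random_residues(rng: np.random.Generator, length: int,
                    freqs: tuple[float, ...] | None = None) -> str:
    probs = None if freqs is None else np.asarray(freqs)
    return "".join(rng.choice(RESIDUES, size=length, p=probs))


# ---------------------------------------------------------------------------
# Motifs

def realize_motif(pattern: MotifPattern, rng: np.random.Generator,
                  background_freqs: tuple[float, ...] | None = None) -> str:
    """Draw one string matching the pattern.

    Literals emit themselves, sets a uniform member, wildcards a
    background residue; repeats draw a uniform length in [min, max].
    """
    probs = None if background_freqs is None else np.asarray(background_freqs)
    out = []
    for el in pattern.elements:
        count = int(rng.integers(el.min_repeat, el.max_repeat + 1))
        for _ in range(count):
            if el.kind is ElementKind.ANY:
                out.append(str(rng.choice(RESIDUES, p=probs)))
            elif el.kind is ElementKind.SET:
                out.append(str(rng.choice(sorted(el.residues))))
            else:
                out.append(next(iter(el.residues)))
    return "".join(out)


def embed_motif(pattern: MotifPattern, cfg: SimConfig,
                rng: np.random.Generator, seq_id: str = "synthetic",
                position: int | None = None
                ) -> tuple[SequenceRecord, dict]:
    """Splice a motif realization into a background sequence.

    ``position`` is 1-based; None draws it uniformly among the feasible
    starts.  Returns the record plus a truth dict with the planted
    pattern_id and 1-based inclusive coordinates.
    """
    realization = realize_motif(pattern, rng, cfg.background_freqs)
    L = cfg.seq_length
    if len(realization) > L:
        raise PlacementError(
            f"realization of {pattern.pattern_id} (length {len(realization)}) "
            f"exceeds seq_length {L}")
    if position is None:
        position = int(rng.integers(1, L - len(realization) + 2))
    if position < 1 or position + len(realization) - 1 > L:
        raise PlacementError(
            f"realization does not fit at position {position}")
    background = random_residues(rng, L, cfg.background_freqs)
    start0 = position - 1
    residues = (background[:start0] + realization
                + background[start0 + len(realization):])
    truth = {
        "pattern_id": pattern.pattern_id,
        "start": position,
        "end": position + len(realization) - 1,
    }
    return SequenceRecord(seq_id, "", residues), truth


# ---------------------------------------------------------------------------
# Families

def mutate_family(cfg: SimConfig, rng: np.random.Generator | None = None,
                  prefix: str = "fam"
                  ) -> tuple[list[SequenceRecord], SequenceRecord]:
    """Star-topology family: each descendant independently substitutes
    each ancestral site with probability ``sub_rate``, replacing it by a
    uniformly chosen *different* residue."""
    if rng is None:
        rng = cfg.rng()
    anc = random_residues(rng, cfg.seq_length, cfg.background_freqs)
    anc_arr = np.array(list(anc))
    descendants = []
    for k in range(cfg.family_size):
        mask = rng.random(cfg.seq_length) < cfg.sub_rate
        seq = anc_arr.copy()
        for i in np.nonzero(mask)[0]:
            choices = RESIDUES[RESIDUES != seq[i]]
            seq[i] = rng.choice(choices)
        descendants.append(
            SequenceRecord(f"{prefix}_{k}", "", "".join(seq)))
    return descendants, SequenceRecord(f"{prefix}_ancestor", "", anc)


# ---------------------------------------------------------------------------
# Filter tables

def make_filter_table(case_codes: list[str],
                      cfg: FilterConfig = FilterConfig(),
                      prefix: str = "case"
                      ) -> tuple[list[SequenceRecord], list[DomainHit],
                                 list[tuple[str, str]]]:
    """Boundary-adjacent filter cases with known outcomes.

    ``case_codes`` lists, per sequence, either ``"PASS"`` or one failure
    code; the constructed coordinates violate exactly that criterion by
    exactly one unit and hold every other measured value exactly at its
    threshold.  Returns (records, hits, [(seq_id, intended_code)]).
    Sequences are filled with 'A' — the filter never reads residues.
    """
    records: list[SequenceRecord] = []
    hits: list[DomainHit] = []
    truth: list[tuple[str, str]] = []
    for k, code in enumerate(case_codes):
        if code != "PASS" and code not in FAILURE_CODES:
            raise ValidationError(f"unknown case code {code!r}")
        seq_id = f"{prefix}_{k}_{code}"
        ml = mr = cfg.max_missing_per_side
        fl = fr = cfg.min_flank
        L = cfg.max_length
        d = cfg.max_internal_indel
        if code == MISSING_SIDE:
            ml += 1
        elif code == INTERNAL_INDEL:
            d += 1
        elif code == FLANK:
            fl -= 1
        elif code == LENGTH:
            L += 1
        env_from = fl + 1
        env_to = L - fr
        env_span = env_to - env_from
        hmm_span = env_span - d
        if hmm_span < 0:
            raise ValidationError(
                f"case {code}: indel target {d} exceeds envelope span")
        hmm_from = ml + 1
        hmm_to = hmm_from + hmm_span
        model_len = hmm_to + mr
        records.append(SequenceRecord(seq_id, "", "A" * L))
        hits.append(DomainHit(
            seq_id=seq_id, seq_len=L, domain_acc=cfg.target_domain,
            domain_name="Amino_oxidase", model_len=model_len,
            hmm_from=hmm_from, hmm_to=hmm_to,
            env_from=env_from, env_to=env_to))
        if code == ARCHITECTURE:
            # extra SWIRM-like domain on an otherwise clean sequence
            hits.append(DomainHit(
                seq_id=seq_id, seq_len=L, domain_acc="PF04433",
                domain_name="SWIRM", model_len=85,
                hmm_from=1, hmm_to=85, env_from=1, env_to=85))
        truth.append((seq_id, code))
    return records, hits, truth


# ---------------------------------------------------------------------------
# Planted active-site MSAs

def plant_active_site_msa(clade_specs: dict[str, dict[int, dict[str, float]]],
                          n_per_clade: int,
                          rng: np.random.Generator,
                          ref_id: str = "O64411",
                          ref_positions: tuple[tuple[int, str], ...] = (
                              (437, "Y"), (401, "F"), (168, "E"), (296, "Y"),
                              (60, "E"), (167, "Y"), (163, "Y"), (232, "N"),
                              (300, "K")),
                          width: int = 450,
                          background_freqs: tuple[float, ...] | None = None,
                          ) -> tuple[Msa, dict[str, list[str]]]:
    """Build an MSA with planted residue distributions at site columns.

    The reference row is ungapped and carries the expected residues at
    its nine positions (so reference position p sits in column p); clade
    rows draw each site column from the clade's planted distribution
    (which may include the gap symbol) and background residues
    elsewhere.  Returns the MSA plus clade membership.
    """
    for cid, spec in clade_specs.items():
        for pos, dist in spec.items():
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValidationError(
                    f"clade {cid!r}, position {pos}: distribution does not "
                    f"sum to 1")
            if pos > width:
                raise ValidationError(
                    f"clade {cid!r}: position {pos} beyond width {width}")
    site_cols = {pos: pos - 1 for pos, _ in ref_positions}
    ref_row = list(random_residues(rng, width, background_freqs))
    for pos, expected in ref_positions:
        ref_row[pos - 1] = expected
    rows = [(ref_id, "".join(ref_row))]
    membership: dict[str, list[str]] = {}
    for cid, spec in clade_specs.items():
        members = []
        for k in range(n_per_clade):
            row = list(random_residues(rng, width, background_freqs))
            for pos in site_cols:
                dist = spec.get(pos)
                if dist is None:
                    continue
                symbols = sorted(dist)
                probs = np.array([dist[s] for s in symbols])
                row[site_cols[pos]] = str(rng.choice(symbols, p=probs))
            rid = f"{cid}_{k}"
            members.append(rid)
            rows.append((rid, "".join(row)))
        membership[cid] = members
    return Msa(tuple(rows)), membership
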