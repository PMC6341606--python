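"""Active-site residue profiling against the ZmPAO1 reference.

The nine catalytically relevant positions of the maize apoplastic PAO
(ZmPAO1, UniProtKB O64411) — Tyr437, Phe401, Glu168, Tyr296, Glu60,
Tyr167, Tyr163, Asn232, Lys300 — are mapped through an MSA onto each
clade, and per-position residue frequency tables are summarized.

Two structure/function heuristics operate on the profiles:

* the *aromatic sandwich* — Phe401 and Tyr437 flank the catalytic tunnel
  in ZmPAO1; a clade "has the sandwich" when aromatic residues (F/Y/W)
  dominate both positions;
* the reaction mode — a conserved Glu at the 60-position (hydrogen bond
  to the substrate N5) indicates terminal catabolism (TC); His or any
  other conserved non-gap residue indicates back-conversion (BC);
  no consensus means UNKNOWN.

Summary-cell thresholds (gap majority prints an en dash; residues at
frequency >= 0.2 are listed as three-letter codes joined by "/") are
this package's explicit stand-ins for an unstated table-formatting rule,
and are configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .errors import EmptyCladeError, MissingReferenceError, ValidationError
from .io_core import GAP, Msa

THREE_LETTER = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "X": "Xaa",
}

AROMATIC = frozenset("FYW")
GAP_DASH = "–"  # en dash printed for gap-majority cells


@dataclass(frozen=True)
class ActiveSitePositions:
    """Reference positions (1-based, ungapped) and expected residues."""

    ref_id: str = "O64411"
    positions: tuple[tuple[int, str], ...] = (
        (437, "Y"), (401, "F"), (168, "E"), (296, "Y"), (60, "E"),
        (167, "Y"), (163, "Y"), (232, "N"), (300, "K"),
    )
    sandwich_positions: tuple[int, int] = (401, 437)
    gate_position: int = 60
    lysine_position: int = 300

    def __post_init__(self):
        pos = [p for p, _ in self.positions]
        if len(set(pos)) != len(pos) or any(p <= 0 for p in pos):
            raise ValidationError("positions must be unique and positive")


#: MmAPAO (Q8C0L6) equivalents, shipped for reference display only; the
#: sandwich/gate heuristics are defined on the ZmPAO1 frame.  MmAPAO has
#: no equivalent of Phe401.
MMAPAO_POSITIONS = ActiveSitePositions(
    ref_id="Q8C0L6",
    positions=(
        (469, "T"), (182, "V"), (428, "Y"), (59, "H"),
        (194, "Y"), (468, "S"), (179, "E"), (305, "K"),
    ),
    sandwich_positions=(469, 428),
    gate_position=59,
    lysine_position=305,
)


@dataclass(frozen=True)
class ActiveSiteProfile:
    """Per-reference-position residue frequencies for one clade."""

    clade_id: str
    n_sequences: int
    #: reference position -> {symbol: frequency}; symbols are residues,
    #: 'X' and the gap character; frequencies sum to 1 per position.
    frequencies: dict[int, dict[str, float]]
    #: reference position -> printable summary ("Tyr", "Phe/Tyr", "–")
    summaries: dict[int, str]


def map_reference_columns(msa: Msa, spec: ActiveSitePositions
                          ) -> dict[int, int]:
    """Map each reference position to its 0-based alignment column.

    The p-th non-gap character of the reference row sits in the returned
    column; the mapping is strictly increasing.  A warning (not an
    error) is emitted when the reference residue differs from the
    expected one.
    """
    if spec.ref_id not in msa.ids:
        raise MissingReferenceError(
            f"reference {spec.ref_id!r} absent from alignment")
    row = msa.row(spec.ref_id)
    ungapped_cols = [c for c, ch in enumerate(row) if ch != GAP]
    out: dict[int, int] = {}
    for pos, expected in spec.positions:
        if pos > len(ungapped_cols):
            raise ValidationError(
                f"position {pos} beyond ungapped reference length "
                f"{len(ungapped_cols)}")
        col = ungapped_cols[pos - 1]
        if row[col] != expected:
            warnings.warn(
                f"reference residue at position {pos} is {row[col]!r}, "
                f"expected {expected!r}", stacklevel=2)
        out[pos] = col
    return out


def profile_clade(msa: Msa, columns: dict[int, int], clade_ids: list[str],
                  clade_id: str = "", ref_id: str | None = None,
                  gap_majority: float = 0.5, list_cutoff: float = 0.2
                  ) -> ActiveSiteProfile:
    """Residue frequency tables for one clade at the mapped columns.

    The reference row is excluded from frequencies when ``ref_id`` is
    given.  Summary rule: gap frequency >= ``gap_majority`` prints an en
    dash; otherwise residues at frequency >= ``list_cutoff`` are listed
    in descending frequency (ties alphabetical by three-letter code),
    joined by "/".
    """
    members = [i for i in clade_ids if i != ref_id]
    unknown = [i for i in members if i not in msa.ids]
    if unknown:
        raise ValidationError(f"clade ids absent from alignment: {unknown}")
    if not members:
        raise EmptyCladeError(f"clade {clade_id!r} has no members")
    rows = {i: msa.row(i) for i in members}
    freqs: dict[int, dict[str, float]] = {}
    summaries: dict[int, str] = {}
    n = len(members)
    for pos, col in columns.items():
        counts: dict[str, int] = {}
        for i in members:
            ch = rows[i][col]
            counts[ch] = counts.get(ch, 0) + 1
        table = {ch: c / n for ch, c in counts.items()}
        freqs[pos] = table
        summaries[pos] = _summarize(table, gap_majority, list_cutoff)
    return ActiveSiteProfile(
        clade_id=clade_id, n_sequences=n,
        frequencies=freqs, summaries=summaries)


def _summarize(table: dict[str, float], gap_majority: float,
               list_cutoff: float) -> str:
    if table.get(GAP, 0.0) >= gap_majority:
        return GAP_DASH
    listed = [(ch, f) for ch, f in table.items()
              if ch != GAP and f >= list_cutoff]
    listed.sort(key=lambda t: (-t[1], THREE_LETTER.get(t[0], t[0])))
    if not listed:
        return GAP_DASH
    return "/".join(THREE_LETTER.get(ch, ch) for ch, _ in listed)


def has_aromatic_sandwich(profile: ActiveSiteProfile,
                          spec: ActiveSitePositions = ActiveSitePositions(),
                          min_aromatic: float = 0.9) -> bool:
    """True iff F/Y/W dominate both tunnel-flanking positions.

    Requires combined aromatic frequency >= ``min_aromatic`` and gap
    frequency < 0.5 at both sandwich positions.
    """
    for pos in spec.sandwich_positions:
        table = profile.frequencies.get(pos)
        if table is None:
            raise ValidationError(f"profile lacks sandwich position {pos}")
        aromatic = sum(f for ch, f in table.items() if ch in AROMATIC)
        if aromatic < min_aromatic or table.get(GAP, 0.0) >= 0.5:
            return False
    return True


def predict_reaction_mode(profile: ActiveSiteProfile,
                          spec: ActiveSitePositions = ActiveSitePositions(),
                          modal_cutoff: float = 0.5) -> str:
    """TC / BC / UNKNOWN from the modal residue at the gate position.

    Glu -> TC (substrate N5 interaction); His or any other conserved
    non-gap residue -> BC; gap-majority or no residue reaching
    ``modal_cutoff`` -> UNKNOWN.
    """
    table = profile.frequencies.get(spec.gate_position)
    if table is None:
        raise ValidationError(
            f"profile lacks gate position {spec.gate_position}")
    modal = max(table.items(), key=lambda t: (t[1], t[0]))
    if modal[0] == GAP or modal[1] < modal_cutoff:
        return "UNKNOWN"
    return "TC" if modal[0] == "E" else "BC"


def lysine_conservation(profile: ActiveSiteProfile,
                        spec: ActiveSitePositions = ActiveSitePositions()
                        ) -> float:
    """Combined K frequency at the Lys300-equivalent position.

    A conserved lysine there forms the catalytically essential
    Lys-H2O-FAD motif; this is a report, not a gate.
    """
    table = profile.frequencies.get(spec.lysine_position)
    if table is None:
        raise ValidationError(
            f"profile lacks lysine position {spec.lysine_position}")
    return table.get("K", 0.0)
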