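"""Reference-position mapping, clade profiles, sandwich and mode calls."""

import numpy as np
import pytest

from conftest import EXPECTED_MODE, EXPECTED_SANDWICH, TABLE2_LIKE_CLADES
from paofam.active_site import (
    ActiveSitePositions, MMAPAO_POSITIONS, has_aromatic_sandwich,
    lysine_conservation, map_reference_columns, predict_reaction_mode,
    profile_clade,
)
from paofam.errors import (
    EmptyCladeError, MissingReferenceError, ValidationError,
)
from paofam.io_core import Msa
from paofam.synthetic import plant_active_site_msa


class TestMapReferenceColumns:
    def test_ungapped_reference_is_identity(self):
        spec = ActiveSitePositions(ref_id="r", positions=((2, "C"), (4, "E")))
        msa = Msa((("r", "ACDEF"), ("s", "ACDEF")))
        cols = map_reference_columns(msa, spec)
        assert cols == {2: 1, 4: 3}  # 0-based columns

    def test_gapped_reference_shifts_columns(self):
        spec = ActiveSitePositions(ref_id="r", positions=((3, "D"),))
        msa = Msa((("r", "-AC-D"), ("s", "AACAD")))
        cols = map_reference_columns(msa, spec)
        assert cols == {3: 4}  # 1-based column 5

    def test_unexpected_reference_residue_warns(self):
        spec = ActiveSitePositions(ref_id="r", positions=((1, "K"),))
        msa = Msa((("r", "A"), ("s", "A")))
        with pytest.warns(UserWarning, match="position 1"):
            map_reference_columns(msa, spec)

    def test_missing_reference_raises(self):
        spec = ActiveSitePositions(ref_id="missing", positions=((1, "A"),))
        with pytest.raises(MissingReferenceError):
            map_reference_columns(Msa((("s", "A"),)), spec)

    def test_position_beyond_reference_raises(self):
        spec = ActiveSitePositions(ref_id="r", positions=((4, "A"),))
        msa = Msa((("r", "AC-"), ("s", "ACA")))
        with pytest.raises(ValidationError):
            map_reference_columns(msa, spec)

    def test_mapping_strictly_increasing_on_planted_msa(self, rng):
        msa, _ = plant_active_site_msa(
            {"c": {60: {"E": 1.0}}}, 3, rng)
        cols = map_reference_columns(msa, ActiveSitePositions())
        ordered = [cols[p] for p, _ in sorted(ActiveSitePositions().positions)]
        assert ordered == sorted(ordered)
        assert len(set(ordered)) == len(ordered)


class TestProfileClade:
    def test_single_member_identical_to_reference(self):
        spec = ActiveSitePositions(ref_id="r", positions=((1, "E"), (3, "K")))
        msa = Msa((("r", "EAK"), ("m", "EAK")))
        cols = map_reference_columns(msa, spec)
        prof = profile_clade(msa, cols, ["m"], clade_id="c", ref_id="r")
        assert prof.summaries == {1: "Glu", 3: "Lys"}

    def test_planted_60_40_mixture_prints_both(self):
        spec = ActiveSitePositions(ref_id="r", positions=((1, "M"),))
        rows = [("r", "M")] + [(f"m{i}", "M") for i in range(6)] \
            + [(f"l{i}", "L") for i in range(4)]
        msa = Msa(tuple(rows))
        cols = map_reference_columns(msa, spec)
        prof = profile_clade(msa, cols, [i for i, _ in rows], clade_id="c",
                             ref_id="r")
        assert prof.summaries[1] == "Met/Leu"
        assert prof.frequencies[1] == {"M": 0.6, "L": 0.4}

    def test_gap_majority_prints_dash(self):
        spec = ActiveSitePositions(ref_id="r", positions=((1, "A"),))
        rows = [("r", "A"), ("m0", "-"), ("m1", "-"), ("m2", "A")]
        msa = Msa(tuple(rows))
        cols = map_reference_columns(msa, spec)
        prof = profile_clade(msa, cols, ["m0", "m1", "m2"], ref_id="r")
        assert prof.summaries[1] == "–"

    def test_reference_excluded_and_permutation_invariant(self, rng):
        msa, membership = plant_active_site_msa(
            {"c": {60: {"E": 0.5, "H": 0.5}}}, 40, rng)
        cols = map_reference_columns(msa, ActiveSitePositions())
        members = membership["c"]
        p1 = profile_clade(msa, cols, members, ref_id="O64411")
        p2 = profile_clade(msa, cols, list(reversed(members)),
                           ref_id="O64411")
        assert p1.frequencies == p2.frequencies
        assert p1.n_sequences == 40
        for pos in p1.frequencies:
            assert sum(p1.frequencies[pos].values()) == pytest.approx(1.0)

    def test_empty_clade_raises(self):
        msa = Msa((("r", "A"), ("m", "A")))
        with pytest.raises(EmptyCladeError):
            profile_clade(msa, {1: 0}, ["r"], ref_id="r")


@pytest.fixture(scope="module")
def profiles():
    rng = np.random.default_rng(2026)
    msa, membership = plant_active_site_msa(TABLE2_LIKE_CLADES, 50, rng)
    spec = ActiveSitePositions()
    cols = map_reference_columns(msa, spec)
    return {
        cid: profile_clade(msa, cols, members, clade_id=cid,
                           ref_id=spec.ref_id)
        for cid, members in membership.items()
    }


class TestHeuristics:
    def test_sandwich_calls_match_clade_character(self, profiles):
        got = {cid: has_aromatic_sandwich(p) for cid, p in profiles.items()}
        assert got == EXPECTED_SANDWICH

    def test_reaction_modes_match_clade_character(self, profiles):
        got = {cid: predict_reaction_mode(p) for cid, p in profiles.items()}
        assert got == EXPECTED_MODE

    def test_lysine_conserved_across_all_clades(self, profiles):
        for cid, prof in profiles.items():
            assert lysine_conservation(prof) == pytest.approx(1.0)

    def test_gap_majority_gate_position_is_unknown(self):
        spec = ActiveSitePositions(ref_id="r", positions=((60, "E"),))
        rows = [("r", "E")] + [(f"m{i}", "-") for i in range(4)]
        # place the single column at reference position 60 via direct cols
        msa = Msa(tuple(rows))
        prof = profile_clade(msa, {60: 0}, [f"m{i}" for i in range(4)],
                             ref_id="r")
        assert predict_reaction_mode(prof, spec) == "UNKNOWN"

    def test_all_gap_sandwich_is_false(self):
        spec = ActiveSitePositions(ref_id="r",
                                   positions=((401, "F"), (437, "Y")),
                                   sandwich_positions=(401, 437))
        rows = [("r", "FY")] + [(f"m{i}", "--") for i in range(3)]
        msa = Msa(tuple(rows))
        prof = profile_clade(msa, {401: 0, 437: 1},
                             [f"m{i}" for i in range(3)], ref_id="r")
        assert has_aromatic_sandwich(prof, spec) is False

    def test_mmapao_preset_is_consistent(self):
        assert MMAPAO_POSITIONS.gate_position == 59
        assert MMAPAO_POSITIONS.lysine_position == 305
        positions = dict(MMAPAO_POSITIONS.positions)
        assert positions[59] == "H" and positions[305] == "K"
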