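import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from paofam.motif_engine import load_packaged_motifs


@pytest.fixture(scope="session")
def packaged_motifs():
    return load_packaged_motifs()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)


#: Residue states at the active-site columns mimicking the five clades'
#: published character: gate residue (60-position), tunnel flanks
#: (401/437), and a conserved Lys300.  Used by profiler and acceptance
#: tests alike.
TABLE2_LIKE_CLADES = {
    "cladeI": {437: {"Y": 1.0}, 401: {"Y": 1.0}, 168: {"E": 1.0},
               296: {"Y": 1.0}, 60: {"A": 1.0}, 167: {"F": 1.0},
               163: {"I": 1.0}, 232: {"N": 1.0}, 300: {"K": 1.0}},
    "cladeII": {437: {"Y": 1.0}, 401: {"F": 0.6, "Y": 0.4},
                168: {"E": 1.0}, 296: {"Y": 1.0}, 60: {"E": 1.0},
                167: {"Y": 1.0}, 163: {"Y": 0.6, "F": 0.4},
                232: {"N": 1.0}, 300: {"K": 1.0}},
    "cladeIII": {437: {"T": 1.0}, 401: {"-": 1.0}, 168: {"Y": 1.0},
                 296: {"Y": 1.0}, 60: {"H": 1.0}, 167: {"Y": 1.0},
                 163: {"S": 1.0}, 232: {"Q": 1.0}, 300: {"K": 1.0}},
    "cladeIV": {437: {"S": 1.0}, 401: {"-": 1.0},
                168: {"M": 0.6, "L": 0.4}, 296: {"Y": 1.0},
                60: {"H": 1.0}, 167: {"E": 1.0}, 163: {"G": 1.0},
                232: {"-": 1.0}, 300: {"K": 1.0}},
    "cladeV": {437: {"T": 1.0}, 401: {"-": 1.0}, 168: {"D": 1.0},
               296: {"Y": 1.0}, 60: {"Q": 1.0}, 167: {"Y": 1.0},
               163: {"S": 1.0}, 232: {"E": 1.0}, 300: {"K": 1.0}},
}

EXPECTED_SANDWICH = {"cladeI": True, "cladeII": True, "cladeIII": False,
                     "cladeIV": False, "cladeV": False}
EXPECTED_MODE = {"cladeI": "BC", "cladeII": "TC", "cladeIII": "BC",
                 "cladeIV": "BC", "cladeV": "BC"}
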