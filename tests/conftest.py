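"""Shared fixtures: synthetic constructs and small hand-built peak lists."""

import pytest

from nmrbind import ConstructSequence, Peak, PeakList

# Synthetic stand-in for the ZnF2 construct sequence (the real sequence is
# not redistributed here): 29 residues spanning 1293-1321, proline-free,
# with the residue identities fixed at the positions used elsewhere in the
# analyses (C2, C3, R4, V5, G7, G10, H11, Y12, M13, K14, D15, K18, R19).
ZNF2_SYNTHETIC_SEQ = "ACCRVEGKLGHYMKDSEKRCFINSLQVTW"


@pytest.fixture
def znf2_construct() -> ConstructSequence:
    return ConstructSequence(
        construct_id="ZnF2", span_start=1293, span_end=1321, sequence=ZNF2_SYNTHETIC_SEQ
    )


@pytest.fixture
def small_peak_list() -> PeakList:
    return PeakList(
        "fixture",
        [
            Peak("C2", 8.72, 118.4, 105.0),
            Peak("C3", 8.15, 121.9, 98.0),
            Peak("R4", 7.93, 117.2, 110.0),
            Peak("G10", 8.41, 109.8, 95.0, overlapped=True),
            Peak("M13", 8.02, 122.5, 102.0),
        ],
    )
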