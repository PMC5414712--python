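"""Published reference data used for calibration checks.

``REFERENCE_LIRS`` holds the 17 long inverted repeats reported for the
3.8-4.0 Mb region of human chromosome 4 contig NT_022853.16, exactly as
printed in the published survey: 1-based inclusive copy positions, repeat
(stem) length, mismatch rate to three decimals, internal spacer size, and
whether the repeat was flagged recombinogenic (two of the 17 are).

Notes on the printed values, preserved verbatim here:

- the printed "repeat length" equals the length of the *shorter* copy
  wherever the two copies differ (rows with coordinates 3808004..,
  3809775.., 3812968.., 3979626.., 3989493..);
- printed mismatch rates are truncated, not rounded, to three decimals
  (e.g. 5/35 = 0.14285... prints as 0.142);
- the last row's printed spacer (811) differs by one from the value implied
  by its own printed coordinates (3990425 - 3989614 - 1 = 810); the printed
  number is kept as-is and consistency checks surface the discrepancy.

``PUBLISHED_CONTIG_COUNTS`` are the full-contig tallies reported for the
same 7,084,842-bp accession under default settings.
"""

from __future__ import annotations

from typing import NamedTuple


class ReferenceLIR(NamedTuple):
    left_start: int
    left_end: int
    right_start: int
    right_end: int
    repeat_length: int
    mismatch_rate: float
    spacer: int
    recombinogenic: bool


REFERENCE_LIRS: tuple[ReferenceLIR, ...] = (
    ReferenceLIR(3801595, 3801626, 3801662, 3801693, 32, 0.031, 35, False),
    ReferenceLIR(3808004, 3808036, 3809074, 3809108, 33, 0.121, 1037, False),
    ReferenceLIR(3809309, 3809356, 3809684, 3809731, 48, 0.083, 327, False),
    ReferenceLIR(3809775, 3809812, 3810283, 3810317, 35, 0.142, 470, False),
    ReferenceLIR(3809920, 3809972, 3810588, 3810640, 53, 0.056, 615, False),
    ReferenceLIR(3812968, 3813016, 3813948, 3813994, 47, 0.148, 931, False),
    ReferenceLIR(3834774, 3834814, 3835410, 3835450, 41, 0.024, 595, False),
    ReferenceLIR(3861385, 3861419, 3863345, 3863379, 35, 0.085, 1925, False),
    ReferenceLIR(3868611, 3868644, 3869190, 3869223, 34, 0.058, 545, False),
    ReferenceLIR(3880525, 3880559, 3880580, 3880614, 35, 0.0, 20, True),
    ReferenceLIR(3892447, 3892480, 3894367, 3894400, 34, 0.088, 1886, False),
    ReferenceLIR(3894385, 3894435, 3894952, 3895002, 51, 0.058, 516, False),
    ReferenceLIR(3903431, 3903467, 3903482, 3903518, 37, 0.0, 14, True),
    ReferenceLIR(3906855, 3906912, 3908736, 3908793, 58, 0.068, 1823, False),
    ReferenceLIR(3970674, 3970704, 3971538, 3971568, 31, 0.096, 833, False),
    ReferenceLIR(3979626, 3979672, 3979822, 3979866, 45, 0.133, 149, False),
    ReferenceLIR(3989493, 3989614, 3990425, 3990548, 122, 0.047, 811, False),
)

#: Whole-contig tallies published for NT_022853.16 with default settings.
PUBLISHED_CONTIG_COUNTS = {
    "primary": 1443,
    "perfect": 28,
    "imperfect": 1415,
    "filtered": 656,
    "recombinogenic": 4,
}


def computed_repeat_length(row: ReferenceLIR) -> int:
    """Shorter-copy length implied by the printed coordinates."""
    return min(
        row.left_end - row.left_start + 1, row.right_end - row.right_start + 1
    )


def computed_spacer(row: ReferenceLIR) -> int:
    """Spacer implied by the printed coordinates (right_start - left_end - 1)."""
    return row.right_start - row.left_end - 1
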