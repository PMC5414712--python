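"""Recombinogenicity calls from stem length, arm identity and spacer size.

Inverted repeats drive DNA recombination when the two copies are close
together (small loop) and highly identical. Classical assays on inverted Alu
pairs found structures with spacers under ~20 bp and arm identity above 85%
to be labile, and strong recombinogenic capacity when the stem-to-loop ratio
delta = L/spacer exceeds ~16.

The binary call used here, calibrated on a published reference table of 17
repeats from human contig NT_022853.16 (of which exactly two are flagged
recombinogenic):

- perfect arms (no defects): recombinogenic iff delta > 1, i.e. the stem is
  longer than the loop (delta is taken as +inf when the spacer is 0);
- imperfect arms: recombinogenic iff delta >= the mismatch rate expressed in
  percent (delta >= 100 * N/L).

Comparing delta against the percent-scale rate is the only reading that
reproduces the reference flags: against the plain fraction, nearly every
repeat with a modest spacer would be called recombinogenic (e.g. L=32,
N/L=0.031, spacer=35 gives delta=0.914 >= 0.031, yet that repeat is a
published negative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .seed_extend import LIR


@dataclass(frozen=True)
class RecombinogenicCall:
    """delta (L/spacer, +inf sentinel for spacer 0) and the binary verdict."""

    delta: float
    recombinogenic: bool


def delta(arm_length: int, spacer: int) -> float:
    """Stem-to-loop ratio L/spacer; +inf when the spacer is 0."""
    if arm_length <= 0:
        raise ValueError(f"arm_length must be positive, got {arm_length}")
    if spacer < 0:
        raise ValueError(f"spacer must be non-negative, got {spacer}")
    return math.inf if spacer == 0 else arm_length / spacer


def call_from_stats(
    arm_length: int, mismatch_rate: float, spacer: int
) -> RecombinogenicCall:
    """Recombinogenicity from summary statistics (stem L, N/L, loop size)."""
    if not (0 <= mismatch_rate < 1):
        raise ValueError(f"mismatch_rate must lie in [0, 1), got {mismatch_rate}")
    d = delta(arm_length, spacer)
    if mismatch_rate == 0:
        verdict = d > 1
    else:
        verdict = d >= 100 * mismatch_rate
    return RecombinogenicCall(delta=d, recombinogenic=verdict)


def is_recombinogenic(lir: LIR) -> RecombinogenicCall:
    """Recombinogenicity call for a repeat that passed the primary filters."""
    return call_from_stats(lir.arm_length, lir.mismatch_rate, lir.spacer)
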