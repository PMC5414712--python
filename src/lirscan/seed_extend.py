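"""Seed-pair discovery and mismatch/indel-tolerant extension.

The search identifies long inverted repeats (LIRs): two nearby copies on the
same strand where one is the reverse complement of the other, separated by an
internal spacer (the loop of the stem-loop the repeat can fold into).

The algorithm is seed-and-extend:

1. every exact k-mer whose reverse complement occurs downstream within one
   window-size span nucleates a seed pair;
2. the pair is extended outward (away from the spacer) and inward (into the
   spacer) one column at a time, pairing the left-arm base against the
   complement of the right-arm base;
3. a failed pairing may be repaired by a single substitution or a single-base
   gap in either arm, but only when the position immediately after the repair
   pairs again — so two consecutive defects always terminate extension;
4. the extended stem is kept when the arm is long enough, arm identity is
   high enough (mismatch rate N/L below threshold) and the stem GC content
   clears the low-complexity floor (which discards (TA)n-type junk).

Inward extension additionally stops when the two cursors meet, so the spacer
never goes negative; a spacer of zero (a true palindrome) is allowed.
"""

from __future__ import annotations

import re
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterator, Literal, NamedTuple, Optional

from .sequence_io import GenomeSequence, gc_fraction, reverse_complement

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: IUPAC nucleotide codes and the base sets they denote.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class SearchParams:
    """Search thresholds, with defaults matching the published calibration.

    Parameters
    ----------
    window_size : int
        Maximum span (bp) from the start of the left seed to the end of the
        right seed; the sliding window inside which a seed pair must lie.
    min_arm_length : int
        Minimum stem (arm) length in bp for a primary LIR; the threshold is
        inclusive. The conventional LIR definition is arms longer than ~30 bp.
    seed_size : int
        Exact k-mer size nucleating extension.
    max_mismatch_rate : float
        Strict upper bound on N/L, defects over stem length (0.15 means arm
        identity must exceed 85%).
    min_gc : float
        Strict lower bound on the GC fraction of the two arms combined.
    max_consecutive_defects : int
        Number of consecutive defect columns that terminates extension.
        Fixed at 2 by the extension rule (a defect must be followed by a
        match); exposed for documentation, not tunable.
    merge_gap : int
        Maximum same-side arm separation (bp) at which a repeat nested in
        another's spacer is merged into the outer one during redundancy
        removal.
    restart_spacer_threshold : int
        Spacer size below which the original published scanner moved its
        window past the whole repeat before re-seeding. Recorded for
        completeness; this implementation enumerates every admissible seed
        pair, which subsumes that restart shortcut.
    """

    window_size: int = 2000
    min_arm_length: int = 30
    seed_size: int = 5
    max_mismatch_rate: float = 0.15
    min_gc: float = 0.20
    max_consecutive_defects: int = 2
    merge_gap: int = 5
    restart_spacer_threshold: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.seed_size <= self.min_arm_length <= self.window_size):
            raise ValueError(
                "need 0 < seed_size <= min_arm_length <= window_size, got "
                f"{self.seed_size}/{self.min_arm_length}/{self.window_size}"
            )
        if not (0 < self.max_mismatch_rate < 1):
            raise ValueError("max_mismatch_rate must lie in (0, 1)")
        if not (0 <= self.min_gc < 1):
            raise ValueError("min_gc must lie in [0, 1)")
        if self.merge_gap < 0 or self.restart_spacer_threshold < 0:
            raise ValueError("gap thresholds must be non-negative")
        if self.max_consecutive_defects != 2:
            raise ValueError("the extension rule fixes max_consecutive_defects at 2")


class SeedPair(NamedTuple):
    """An exact k-mer at ``left_start`` whose reverse complement sits at
    ``right_start`` (both 1-based), disjoint and within one window span."""

    left_start: int
    right_start: int
    k: int


ColumnKind = Literal["match", "mismatch", "gap_left", "gap_right"]


class AlignmentColumn(NamedTuple):
    """One column of the arm-vs-arm alignment, ordered 5'->3' on the left arm.

    ``gap_left`` means the left arm lacks a base (only ``right_pos`` set);
    ``gap_right`` the converse.
    """

    kind: ColumnKind
    left_pos: Optional[int]
    right_pos: Optional[int]


@dataclass(frozen=True)
class LIR:
    """A long inverted repeat: two arm intervals plus the defect alignment.

    ``arm_length`` (the stem length L, and the mismatch-rate denominator) is
    the length of the *shorter* arm; with indels the two copies differ in
    length and the published tables report the shorter one. ``spacer`` is the
    loop size, ``right_start - left_end - 1``. ``delta`` is L/spacer with an
    infinity sentinel for spacer 0; large delta (stem long relative to loop)
    marks recombinogenic potential.
    """

    seq_id: str
    left_start: int
    left_end: int
    right_start: int
    right_end: int
    columns: tuple[AlignmentColumn, ...]
    n_defects: int
    arm_length: int
    mismatch_rate: float
    spacer: int
    gc: float
    is_perfect: bool

    @property
    def left_arm_length(self) -> int:
        return self.left_end - self.left_start + 1

    @property
    def right_arm_length(self) -> int:
        return self.right_end - self.right_start + 1

    @property
    def delta(self) -> float:
        return float("inf") if self.spacer == 0 else self.arm_length / self.spacer

    @property
    def coords(self) -> tuple[int, int, int, int]:
        return (self.left_start, self.left_end, self.right_start, self.right_end)

    def sort_key(self) -> tuple[str, int, int, int, int]:
        return (self.seq_id, self.left_start, self.right_start,
                self.left_end, self.right_end)


def build_lir(seq: GenomeSequence, columns: tuple[AlignmentColumn, ...]) -> LIR:
    """Assemble an :class:`LIR` record from an alignment column list.

    Derived statistics (defect count, stem length, mismatch rate, spacer, GC)
    are recomputed here from the columns and raw sequence; callers never set
    them directly.
    """
    left = [c.left_pos for c in columns if c.left_pos is not None]
    right = [c.right_pos for c in columns if c.right_pos is not None]
    left_start, left_end = min(left), max(left)
    right_start, right_end = min(right), max(right)
    n_defects = sum(1 for c in columns if c.kind != "match")
    arm_length = min(left_end - left_start + 1, right_end - right_start + 1)
    gc = gc_fraction(
        seq.fragment(left_start, left_end) + seq.fragment(right_start, right_end)
    )
    return LIR(
        seq_id=seq.id,
        left_start=left_start,
        left_end=left_end,
        right_start=right_start,
        right_end=right_end,
        columns=columns,
        n_defects=n_defects,
        arm_length=arm_length,
        mismatch_rate=n_defects / arm_length,
        spacer=right_start - left_end - 1,
        gc=gc,
        is_perfect=n_defects == 0
        and (left_end - left_start) == (right_end - right_start),
    )


def _pairs(res: str, l: int, r: int) -> bool:
    a = res[l - 1]
    b = res[r - 1]
    return a != "N" and b != "N" and _COMP[a] == b


def _extend_direction(
    res: str, l: int, r: int, dl: int, dr: int, inward: bool
) -> list[AlignmentColumn]:
    """Grow the alignment from cursors (l, r) in one direction.

    Returns columns in traversal order. Outward: dl=-1, dr=+1 (left cursor
    walks 5' on the left arm, right cursor 3' on the right arm). Inward:
    dl=+1, dr=-1, stopping before the cursors cross so the spacer stays
    non-negative.
    """
    n = len(res)

    def ok(a: int, b: int) -> bool:
        return 1 <= a <= n and 1 <= b <= n and (not inward or a < b)

    def run_length(a: int, b: int) -> int:
        c = 0
        while ok(a, b) and _pairs(res, a, b):
            c += 1
            a += dl
            b += dr
        return c

    cols: list[AlignmentColumn] = []
    while ok(l, r):
        if _pairs(res, l, r):
            cols.append(AlignmentColumn("match", l, r))
            l += dl
            r += dr
            continue
        # Repair candidates; each must be followed immediately by a match,
        # which enforces the two-consecutive-defects stopping rule.
        if ok(l + dl, r + dr) and _pairs(res, l + dl, r + dr):
            cols.append(AlignmentColumn("mismatch", l, r))
            l += dl
            r += dr
            continue
        gl_ok = ok(l, r + dr) and _pairs(res, l, r + dr)
        gr_ok = ok(l + dl, r) and _pairs(res, l + dl, r)
        if gl_ok and gr_ok:
            # tie-break: prefer the gap whose subsequent exact run is longer.
            # On an exact tie, compare the left base against the complement
            # of the right base (never equal at a defect): this choice maps
            # onto itself under reverse complement, keeping the whole scan
            # strand-symmetric, and is deterministic.
            run_r, run_l = run_length(l + dl, r), run_length(l, r + dr)
            if run_r > run_l or (run_r == run_l and res[l - 1] < _COMP[res[r - 1]]):
                gl_ok = False
            else:
                gr_ok = False
        if gl_ok:
            cols.append(AlignmentColumn("gap_left", None, r))
            r += dr
        elif gr_ok:
            cols.append(AlignmentColumn("gap_right", l, None))
            l += dl
        else:
            break
    return cols


def _trim_defects(cols: list[AlignmentColumn]) -> list[AlignmentColumn]:
    """Drop leading/trailing defect columns so arms start and end on matches.

    The extension rule already guarantees this (a repair is only taken when
    its following match is consumed too); kept as a safety net so arm
    coordinates are always well defined.
    """
    lo, hi = 0, len(cols)
    while lo < hi and cols[lo].kind != "match":
        lo += 1
    while hi > lo and cols[hi - 1].kind != "match":
        hi -= 1
    return cols[lo:hi]


def extend_alignment(res: str, pair: SeedPair) -> tuple[AlignmentColumn, ...]:
    """Full bidirectional extension of a seed pair into alignment columns."""
    ls, rs, k = pair
    seed = [AlignmentColumn("match", ls + i, rs + k - 1 - i) for i in range(k)]
    outward = _extend_direction(res, ls - 1, rs + k, dl=-1, dr=+1, inward=False)
    inward = _extend_direction(res, ls + k, rs - 1, dl=+1, dr=-1, inward=True)
    cols = _trim_defects(outward[::-1] + seed + inward)
    return tuple(cols)


def extend_seed(
    seq: GenomeSequence, pair: SeedPair, params: SearchParams
) -> Optional[LIR]:
    """Extend one seed pair; return the LIR if it passes the primary filters.

    Acceptance requires stem length >= ``min_arm_length``, mismatch rate
    strictly below ``max_mismatch_rate`` and stem GC strictly above
    ``min_gc``; otherwise ``None``.
    """
    ls, rs, k = pair
    if not (1 <= ls and ls + k - 1 < rs and rs + k - 1 <= len(seq)):
        raise ValueError(f"seed pair {pair} out of range or overlapping")
    res = seq.residues
    if reverse_complement(res[ls - 1 : ls - 1 + k]) != res[rs - 1 : rs - 1 + k]:
        raise ValueError(f"seed pair {pair} is not a reverse-complement match")
    lir = build_lir(seq, extend_alignment(res, pair))
    if lir.arm_length < params.min_arm_length:
        return None
    if lir.mismatch_rate >= params.max_mismatch_rate:
        return None
    if lir.gc <= params.min_gc:
        return None
    return lir


def _kmer_positions(res: str, k: int, start: int, end: int) -> dict[str, list[int]]:
    """1-based start positions of every N-free k-mer within [start, end]."""
    index: dict[str, list[int]] = {}
    for pos in range(start, end - k + 2):
        kmer = res[pos - 1 : pos - 1 + k]
        if "N" not in kmer:
            index.setdefault(kmer, []).append(pos)
    return index


def enumerate_seed_pairs(
    seq: GenomeSequence, window_start: int, params: SearchParams
) -> list[SeedPair]:
    """All reverse-complement seed pairs inside one window.

    The window is ``[window_start, window_start + window_size - 1]`` clipped
    to the sequence end. Pairs are disjoint (left seed strictly before the
    right seed), contain no N, and are ordered by (left_start, right_start).
    """
    n = len(seq)
    if not (1 <= window_start <= n):
        raise ValueError(f"window_start {window_start} outside 1..{n}")
    k = params.seed_size
    window_end = min(window_start + params.window_size - 1, n)
    if window_end - window_start + 1 < 2 * k:
        return []
    index = _kmer_positions(seq.residues, k, window_start, window_end)
    out: list[SeedPair] = []
    for kmer in index:
        partner = index.get(reverse_complement(kmer))
        if not partner:
            continue
        for ls in index[kmer]:
            lo = bisect_left(partner, ls + k)
            for rs in partner[lo:]:
                out.append(SeedPair(ls, rs, k))
    out.sort()
    return out


def _admissible_pairs(seq: GenomeSequence, params: SearchParams) -> Iterator[SeedPair]:
    """Seed pairs whose span fits inside one window, sequence-wide.

    Equivalent to sliding the window one base at a time: a pair is admissible
    iff the stretch from the left seed's start to the right seed's end is at
    most ``window_size`` bp.
    """
    res = seq.residues
    k = params.seed_size
    index = _kmer_positions(res, k, 1, len(res))
    for kmer, starts in index.items():
        partner = index.get(reverse_complement(kmer))
        if not partner:
            continue
        for ls in starts:
            lo = bisect_left(partner, ls + k)
            hi = bisect_right(partner, ls + params.window_size - k)
            for rs in partner[lo:hi]:
                yield SeedPair(ls, rs, k)


def scan_sequence(seq: GenomeSequence, params: SearchParams) -> list[LIR]:
    """Exhaustive scan: extend every admissible seed pair across the sequence.

    Returns the primary (pre-redundancy-filter) LIR list, deduplicated on
    exact coordinates and sorted by (left_start, right_start). Deterministic:
    no randomness anywhere in the pipeline.
    """
    found: dict[tuple[int, int, int, int], LIR] = {}
    for pair in _admissible_pairs(seq, params):
        lir = extend_seed(seq, pair, params)
        if lir is not None and lir.coords not in found:
            found[lir.coords] = lir
    return sorted(found.values(), key=LIR.sort_key)


def iupac_regex(motif: str) -> "re.Pattern[str]":
    """Compile an IUPAC motif into a regex over {A,C,G,T}."""
    parts = []
    for ch in motif.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC character {ch!r} in motif {motif!r}")
        bases = IUPAC[ch]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("".join(parts))


def filter_by_motif(
    seq: GenomeSequence, lirs: list[LIR], motif: str
) -> list[LIR]:
    """Keep repeats in which at least one arm contains an IUPAC motif match."""
    pattern = iupac_regex(motif)
    kept = []
    for lir in lirs:
        left = seq.fragment(lir.left_start, lir.left_end)
        right = seq.fragment(lir.right_start, lir.right_end)
        if pattern.search(left) or pattern.search(right):
            kept.append(lir)
    return kept


def motif_search(
    seq: GenomeSequence, motif: str, params: SearchParams
) -> list[LIR]:
    """Scan, remove redundancy, then keep repeats with a motif-bearing arm."""
    from .redundancy import filter_redundant  # deferred: avoids import cycle

    pattern_check = iupac_regex(motif)  # validate before the expensive scan
    del pattern_check
    if len(motif) > params.window_size:
        raise ValueError("motif longer than the search window")
    filtered = filter_redundant(scan_sequence(seq, params), params)
    return filter_by_motif(seq, filtered, motif)
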