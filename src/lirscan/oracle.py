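"""Exhaustive brute-force repeat finder: the correctness oracle.

This module re-derives the LIR set on small sequences with deliberately
separate code from :mod:`.seed_extend`: candidate seed pairs are located by
direct substring search against the reverse complement (no k-mer index), the
defect walk is a separately written stepper, and every derived statistic is
recomputed from scratch. Equality between :func:`brute_force_search` and
``scan_sequence`` on the same input is the package's strongest internal
consistency check.

Guarded to short sequences: the enumeration is quadratic and exists to
validate the scanner, not to scan genomes.
"""

from __future__ import annotations

from .seed_extend import LIR, AlignmentColumn, SearchParams
from .sequence_io import GenomeSequence, reverse_complement

_PAIRS = frozenset({"AT", "TA", "CG", "GC"})

MAX_ORACLE_LENGTH = 2500


def _complementary(a: str, b: str) -> bool:
    return a + b in _PAIRS


def _exact_run(res: str, l: int, r: int, dl: int, dr: int, inward: bool) -> int:
    n = len(res)
    count = 0
    while 1 <= l <= n and 1 <= r <= n and (l < r or not inward):
        if not _complementary(res[l - 1], res[r - 1]):
            break
        count += 1
        l += dl
        r += dr
    return count


def _walk(res: str, l: int, r: int, dl: int, dr: int, inward: bool) -> list[AlignmentColumn]:
    """Stepper for one extension direction under the single-defect rules.

    A failed pairing may be bridged by one substitution or a one-base gap in
    either arm, provided the position right after the bridge pairs; the
    substitution bridge wins over gaps, and of two viable gaps the one with
    the longer following exact run wins (ties broken by the strand-symmetric
    base comparison, as in the scanner).
    """
    n = len(res)
    cols: list[AlignmentColumn] = []

    def live(a: int, b: int) -> bool:
        return 1 <= a <= n and 1 <= b <= n and (a < b or not inward)

    while live(l, r):
        if _complementary(res[l - 1], res[r - 1]):
            cols.append(AlignmentColumn("match", l, r))
            l, r = l + dl, r + dr
            continue
        sub_ok = live(l + dl, r + dr) and _complementary(res[l + dl - 1], res[r + dr - 1])
        if sub_ok:
            cols.append(AlignmentColumn("mismatch", l, r))
            l, r = l + dl, r + dr
            continue
        gap_l = live(l, r + dr) and _complementary(res[l - 1], res[r + dr - 1])
        gap_r = live(l + dl, r) and _complementary(res[l + dl - 1], res[r - 1])
        if gap_l and gap_r:
            run_after_left = _exact_run(res, l, r + dr, dl, dr, inward)
            run_after_right = _exact_run(res, l + dl, r, dl, dr, inward)
            comp_r = {"A": "T", "C": "G", "G": "C", "T": "A"}[res[r - 1]]
            if run_after_right > run_after_left or (
                run_after_right == run_after_left and res[l - 1] < comp_r
            ):
                gap_l = False
            else:
                gap_r = False
        if gap_l:
            cols.append(AlignmentColumn("gap_left", None, r))
            r += dr
        elif gap_r:
            cols.append(AlignmentColumn("gap_right", l, None))
            l += dl
        else:
            break
    return cols


def _assemble(seq: GenomeSequence, cols: list[AlignmentColumn]) -> LIR:
    """Build the LIR record with statistics recomputed independently."""
    res = seq.residues
    lpos = [c.left_pos for c in cols if c.left_pos is not None]
    rpos = [c.right_pos for c in cols if c.right_pos is not None]
    ls, le = min(lpos), max(lpos)
    rs, re = min(rpos), max(rpos)
    defects = sum(c.kind != "match" for c in cols)
    stem = min(le - ls + 1, re - rs + 1)
    both_arms = res[ls - 1 : le] + res[rs - 1 : re]
    acgt = sum(both_arms.count(b) for b in "ACGT")
    gc = 0.0 if acgt == 0 else (both_arms.count("G") + both_arms.count("C")) / acgt
    return LIR(
        seq_id=seq.id,
        left_start=ls,
        left_end=le,
        right_start=rs,
        right_end=re,
        columns=tuple(cols),
        n_defects=defects,
        arm_length=stem,
        mismatch_rate=defects / stem,
        spacer=rs - le - 1,
        gc=gc,
        is_perfect=defects == 0 and (le - ls) == (re - rs),
    )


def brute_force_search(seq: GenomeSequence, params: SearchParams) -> list[LIR]:
    """All LIRs passing the acceptance filters, by exhaustive enumeration.

    Every position pair (l, r) with ``res[r:r+k] == rc(res[l:l+k])``, the
    seeds disjoint and the seed span within one window size, is extended
    under the defect rules and filtered. Refuses sequences longer than
    ``MAX_ORACLE_LENGTH`` bp.
    """
    n = len(seq)
    if n > MAX_ORACLE_LENGTH:
        raise ValueError(
            f"brute-force oracle is limited to {MAX_ORACLE_LENGTH} bp "
            f"(got {n} bp); use scan_sequence for real inputs"
        )
    res = seq.residues
    k = params.seed_size
    w = params.window_size
    found: dict[tuple[int, int, int, int], LIR] = {}
    for l in range(1, n - 2 * k + 2):
        kmer = res[l - 1 : l - 1 + k]
        if "N" in kmer:
            continue
        target = reverse_complement(kmer)
        # right seed start r must satisfy: disjoint (r >= l + k) and the
        # span from l to r + k - 1 at most one window (r <= l + w - k)
        lo0 = l + k - 1  # 0-based index of the earliest admissible r
        hi0 = min(n - k, l + w - k - 1)  # 0-based index of the latest one
        at = res.find(target, lo0, hi0 + k)
        while at != -1 and at <= hi0:
            r = at + 1
            seed_cols = [
                AlignmentColumn("match", l + i, r + k - 1 - i) for i in range(k)
            ]
            outward = _walk(res, l - 1, r + k, dl=-1, dr=+1, inward=False)
            inward = _walk(res, l + k, r - 1, dl=+1, dr=-1, inward=True)
            cols = outward[::-1] + seed_cols + inward
            while cols and cols[0].kind != "match":
                cols.pop(0)
            while cols and cols[-1].kind != "match":
                cols.pop()
            lir = _assemble(seq, cols)
            if (
                lir.arm_length >= params.min_arm_length
                and lir.mismatch_rate < params.max_mismatch_rate
                and lir.gc > params.min_gc
                and lir.coords not in found
            ):
                found[lir.coords] = lir
            at = res.find(target, at + 1, hi0 + k)
    return sorted(found.values(), key=LIR.sort_key)
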