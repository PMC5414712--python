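"""Redundancy removal among primary LIRs.

Repeat-rich genomes yield many overlapping primary calls describing the same
underlying structure. Four overlap scenarios are distinguished between two
repeats a and b (a being the one with the smaller left_start):

- ``scenario_A`` — arms of the two repeats overlap across sides (the end of
  one structure runs into the start of the other);
- ``scenario_B`` — an arm of one repeat is contained inside an arm of the
  other (a short copy participating in a longer copy);
- ``scenario_C`` — same-side arms overlap, shifted by some offset;
- ``scenario_D`` — b lies entirely inside a's internal spacer (a nested
  stem-loop).

For A-C the member with the longer spacer is discarded. For D the two are
merged into the outer repeat when their same-side arms are separated by at
most ``merge_gap`` bp on both sides; nested stems further apart are kept as
distinct structures.
"""

from __future__ import annotations

from .seed_extend import LIR, SearchParams

SCENARIOS = ("none", "scenario_A", "scenario_B", "scenario_C", "scenario_D")


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def _contains(outer: tuple[int, int], inner: tuple[int, int]) -> bool:
    return outer[0] <= inner[0] and inner[1] <= outer[1]


def classify_overlap(a: LIR, b: LIR) -> str:
    """Classify the redundancy relationship between two repeats.

    The pair is normalized so that ``a`` has the smaller (left_start,
    right_start); scenario D tests b against a's spacer. Containment (B)
    takes precedence over plain same-side overlap (C), which takes
    precedence over cross-side overlap (A); the downstream filtering action
    is identical for A-C.
    """
    if a.seq_id != b.seq_id:
        raise ValueError("cannot compare repeats on different sequences")
    if (a.left_start, a.right_start) > (b.left_start, b.right_start):
        a, b = b, a
    aL, aR = (a.left_start, a.left_end), (a.right_start, a.right_end)
    bL, bR = (b.left_start, b.left_end), (b.right_start, b.right_end)

    if b.left_start > a.left_end and b.right_end < a.right_start:
        return "scenario_D"
    for x in (aL, aR):
        for y in (bL, bR):
            if _contains(x, y) or _contains(y, x):
                return "scenario_B"
    if _overlap(aL, bL) or _overlap(aR, bR):
        return "scenario_C"
    if _overlap(aR, bL) or _overlap(aL, bR):
        return "scenario_A"
    return "none"


def _keep_preference(lir: LIR) -> tuple[int, int, int]:
    # smaller is better: shorter spacer, then longer arm, then leftmost
    return (lir.spacer, -lir.arm_length, lir.left_start)


def _resolve_pair(a: LIR, b: LIR, params: SearchParams) -> LIR | None:
    """The member to DROP (or the merge survivor's partner), else None."""
    scenario = classify_overlap(a, b)
    if scenario in ("scenario_A", "scenario_B", "scenario_C"):
        ka, kb = _keep_preference(a), _keep_preference(b)
        if ka == kb:  # fully tied: drop the later one in sort order
            return b if a.sort_key() <= b.sort_key() else a
        return b if ka < kb else a
    if scenario == "scenario_D":
        outer, inner = (a, b) if a.left_start <= b.left_start else (b, a)
        left_gap = inner.left_start - outer.left_end - 1
        right_gap = outer.right_start - inner.right_end - 1
        if left_gap <= params.merge_gap and right_gap <= params.merge_gap:
            return inner  # combined into one repeat, represented by the outer
    return None


def filter_redundant(lirs: list[LIR], params: SearchParams) -> list[LIR]:
    """Remove redundant repeats, iterating pairwise decisions to a fixpoint.

    Deterministic and independent of input order: the working list is kept
    sorted and re-examined after every removal, so chained overlaps
    (a-b, b-c) resolve the same way regardless of how the input arrived.
    Output is sorted by (left_start, right_start).
    """
    unique: dict[tuple, LIR] = {}
    for lir in lirs:
        unique.setdefault((lir.seq_id,) + lir.coords, lir)
    items = sorted(unique.values(), key=LIR.sort_key)

    changed = True
    while changed:
        changed = False
        n = len(items)
        for i in range(n):
            for j in range(i + 1, n):
                drop = _resolve_pair(items[i], items[j], params)
                if drop is not None:
                    items.remove(drop)
                    changed = True
                    break
            if changed:
                break
    return items
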