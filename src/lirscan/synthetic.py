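"""Synthetic genomes with planted inverted repeats, plus ground truth.

The generator emits an i.i.d. random background and embeds stem-loop
structures with known coordinates: a left arm, a random spacer, and the
mutated reverse complement of the arm as the right copy. Two design points
make the recorded truth exact rather than approximate:

- non-pairing guard bases (A opposite A can never form a Watson-Crick pair)
  are written at the two positions flanking each planted structure on the
  outside, and at the first/last two spacer positions on the inside, so
  extension cannot creep past the planted boundaries by chance;
- planted defects are kept at least ``seed_size`` apart and away from the
  arm ends, so a clean seed always survives, no two defects are adjacent,
  and substitution-only plants are recovered at exactly the recorded
  coordinates.

These guards define what the recall tests show: recovery of repeats whose
boundaries are crisp. Real genomic repeats embedded in repeat-rich context
can extend beyond any annotated boundary, and the tool reports whatever the
extension rules support there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence, Union

import numpy as np

from .sequence_io import GenomeSequence, reverse_complement

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantSpec:
    """Recipe for one planted inverted repeat.

    ``n_substitutions``/``n_indels`` mutate the right copy relative to the
    exact reverse complement of the left arm. ``arm_gc`` is the expected GC
    of the arm. ``insert_position`` is the 1-based start of the left arm, or
    "random".
    """

    arm_length: int
    spacer: int
    n_substitutions: int = 0
    n_indels: int = 0
    arm_gc: float = 0.5
    insert_position: Union[int, Literal["random"]] = "random"

    def __post_init__(self) -> None:
        if self.arm_length < 1:
            raise ValueError("arm_length must be >= 1")
        if self.spacer < 0:
            raise ValueError("spacer must be >= 0")
        if self.n_substitutions < 0 or self.n_indels < 0:
            raise ValueError("defect counts must be >= 0")
        if not (0 <= self.arm_gc <= 1):
            raise ValueError("arm_gc must lie in [0, 1]")


@dataclass(frozen=True)
class PlantedTruth:
    """Recorded coordinates (1-based inclusive) of one planted repeat."""

    left_start: int
    left_end: int
    right_start: int
    right_end: int
    spec: PlantSpec

    @property
    def coords(self) -> tuple[int, int, int, int]:
        return (self.left_start, self.left_end, self.right_start, self.right_end)


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p)) if n else ""


def _defect_positions(
    rng: np.random.Generator, arm_length: int, count: int, min_sep: int
) -> list[int]:
    """0-based defect positions, >= min_sep from either arm end and pairwise
    >= min_sep apart; raises when the arm cannot host them."""
    if count == 0:
        return []
    lo, hi = min_sep, arm_length - 1 - min_sep
    if hi - lo + 1 < count or lo > hi:
        raise ValueError(
            f"arm of {arm_length} bp cannot host {count} defects "
            f"separated by >= {min_sep} bp"
        )
    for _ in range(200):
        pos = sorted(rng.choice(np.arange(lo, hi + 1), size=count, replace=False))
        if all(b - a >= min_sep for a, b in zip(pos, pos[1:])):
            return [int(p) for p in pos]
    raise ValueError(
        f"could not place {count} defects >= {min_sep} bp apart in a "
        f"{arm_length} bp arm"
    )


def _mutate_right_copy(
    rng: np.random.Generator, right: str, spec: PlantSpec, min_sep: int
) -> str:
    """Apply substitutions then indels to the reverse-complement copy."""
    chars = list(right)
    n_def = spec.n_substitutions + spec.n_indels
    positions = _defect_positions(rng, len(chars), n_def, min_sep)
    rng.shuffle(positions)
    subs = sorted(positions[: spec.n_substitutions])
    indels = sorted(positions[spec.n_substitutions :], reverse=True)
    for p in subs:
        alternatives = [b for b in "ACGT" if b != chars[p]]
        chars[p] = alternatives[int(rng.integers(len(alternatives)))]
    for p in indels:
        if rng.random() < 0.5:
            del chars[p]  # deletion in the right copy
        else:
            chars.insert(p, str(rng.choice(_BASES)))  # insertion
    return "".join(chars)


def _build_plant(
    rng: np.random.Generator, spec: PlantSpec, min_sep: int
) -> tuple[str, int, int]:
    """Return (planted fragment, left arm length, right arm length)."""
    arm = _random_dna(rng, spec.arm_length, spec.arm_gc)
    right = _mutate_right_copy(rng, reverse_complement(arm), spec, min_sep)
    spacer = list(_random_dna(rng, spec.spacer, 0.5))
    # interior guards: A opposite A never pairs, so inward extension stops
    # exactly at the recorded arm ends
    for i in range(min(2, spec.spacer)):
        spacer[i] = "A"
        spacer[-1 - i] = "A"
    return arm + "".join(spacer) + right, len(arm), len(right)


def plant_lirs(
    genome_length: int,
    specs: Sequence[PlantSpec],
    rng_seed: int,
    *,
    background_gc: float = 0.5,
    defect_min_separation: int = 5,
) -> tuple[GenomeSequence, list[PlantedTruth]]:
    """Generate a random genome carrying the requested planted repeats.

    The background is i.i.d. with expected GC ``background_gc`` (0.5 by
    default so the low-complexity GC filter never fires on the plants).
    Deterministic given ``rng_seed``. Raises ``ValueError`` when the plants
    (plus their 2-bp outer guard zones) cannot be placed without overlap.
    """
    rng = np.random.default_rng(rng_seed)
    genome = list(_random_dna(rng, genome_length, background_gc))

    built = []
    for spec in specs:
        fragment, left_len, right_len = _build_plant(rng, spec, defect_min_separation)
        built.append((spec, fragment, left_len, right_len))

    guard = 2
    placed: list[tuple[int, int]] = []  # 0-based [start, end) incl. guards

    def fits(start0: int, total: int) -> bool:
        lo, hi = start0 - guard, start0 + total + guard
        if lo < 0 or hi > genome_length:
            return False
        return all(hi <= s or e <= lo for s, e in placed)

    truths: list[PlantedTruth] = []
    for spec, fragment, left_len, right_len in built:
        total = len(fragment)
        if spec.insert_position == "random":
            start0 = None
            for _ in range(500):
                cand = int(rng.integers(guard, max(guard + 1, genome_length - total - guard + 1)))
                if fits(cand, total):
                    start0 = cand
                    break
            if start0 is None:
                raise ValueError("planted repeats do not fit in the genome")
        else:
            start0 = int(spec.insert_position) - 1
            if not fits(start0, total):
                raise ValueError(
                    f"plant at position {spec.insert_position} overlaps another "
                    "plant or falls outside the genome"
                )
        placed.append((start0 - guard, start0 + total + guard))
        genome[start0 : start0 + total] = fragment
        # outer guards on both flanks: A opposite A cannot pair
        for off in (1, 2):
            genome[start0 - off] = "A"
            if start0 + total - 1 + off < genome_length:
                genome[start0 + total - 1 + off] = "A"
        left_start = start0 + 1
        left_end = left_start + left_len - 1
        right_start = left_end + spec.spacer + 1
        truths.append(
            PlantedTruth(left_start, left_end, right_start,
                         right_start + right_len - 1, spec)
        )

    seq = GenomeSequence(f"synthetic_seed{rng_seed}", "".join(genome))
    truths.sort(key=lambda t: t.coords)
    return seq, truths
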