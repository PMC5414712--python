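"""FASTA input, alphabet normalization, and report writers.

All coordinates exchanged through this package are 1-based and inclusive on
both ends, the convention used in the reference tables this tool is calibrated
against. The BED writer converts to the BED standard (0-based, half-open) at
the boundary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

if TYPE_CHECKING:  # pragma: no cover
    from .seed_extend import LIR

logger = logging.getLogger(__name__)

#: Canonical alphabet after normalization.
ALPHABET = frozenset("ACGTN")

#: IUPAC ambiguity codes collapsed to N (they can never form a certain pair).
_AMBIGUITY = frozenset("RYSWKMBDHV")

_COMPLEMENT_TABLE = str.maketrans("ACGTN", "TGCAN")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

TSV_COLUMNS = (
    "seq_id",
    "left_start",
    "left_end",
    "right_start",
    "right_end",
    "repeat_length",
    "n_defects",
    "mismatch_rate",
    "spacer",
    "gc",
    "delta",
    "recombinogenic",
)


@dataclass(frozen=True)
class GenomeSequence:
    """A named DNA sequence over {A, C, G, T, N}.

    Parameters
    ----------
    id : str
        Record identifier (FASTA header up to the first whitespace).
    residues : str
        Normalized residues; see :func:`normalize_residues`.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid characters {sorted(bad)}; "
                "call normalize_residues() first"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def fragment(self, start: int, end: int) -> str:
        """Residues of the 1-based inclusive interval ``[start, end]``."""
        if not (1 <= start <= end <= len(self.residues)):
            raise ValueError(f"interval {start}..{end} outside 1..{len(self.residues)}")
        return self.residues[start - 1 : end]


def normalize_residues(raw: str, *, context: str = "sequence") -> str:
    """Uppercase ``raw`` and collapse IUPAC ambiguity codes to N.

    U is treated as T. Any character outside the IUPAC nucleotide set raises
    ``ValueError``. A warning is logged when ambiguity codes are collapsed,
    because an N can never take part in a certain base pair and therefore
    never seeds or extends a repeat.
    """
    up = raw.upper().replace("U", "T")
    residues = []
    n_ambiguous = 0
    for ch in up:
        if ch in ALPHABET:
            residues.append(ch)
        elif ch in _AMBIGUITY:
            residues.append("N")
            n_ambiguous += 1
        else:
            raise ValueError(f"{context}: invalid nucleotide character {ch!r}")
    if n_ambiguous:
        logger.warning(
            "%s: %d IUPAC ambiguity characters collapsed to N", context, n_ambiguous
        )
    return "".join(residues)


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a FASTA file into a list of :class:`GenomeSequence`.

    Records are returned in file order. Lowercase is uppercased and
    ambiguity codes other than N are mapped to N. A record with an empty
    sequence, or a file with no FASTA records, raises ``ValueError``.
    """
    path = Path(path)
    with open(path) as handle:
        first = handle.read(1)
        if first not in (">", ";"):
            raise ValueError(f"{path}: not FASTA (does not start with '>')")
        handle.seek(0)
        records = []
        for header, seq in SimpleFastaParser(handle):
            rec_id = header.split()[0] if header.split() else header
            if not seq:
                raise ValueError(f"{path}: record {rec_id!r} has an empty sequence")
            records.append(
                GenomeSequence(rec_id, normalize_residues(seq, context=rec_id))
            )
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def reverse_complement(s: str) -> str:
    """Reverse complement of a DNA string over {A, C, G, T, N}; N maps to N."""
    bad = set(s) - ALPHABET
    if bad:
        raise ValueError(f"invalid characters for reverse_complement: {sorted(bad)}")
    return s.translate(_COMPLEMENT_TABLE)[::-1]


def complement_base(a: str) -> str:
    """Watson-Crick complement of one base (N maps to N)."""
    return _COMPLEMENT[a]


def gc_fraction(s: str) -> float:
    """(G + C) / (A + C + G + T) of ``s``; N is excluded from the denominator.

    Empty input raises ``ValueError``. An all-N string has no defined GC
    content and returns 0.0 (such a fragment can never form a stem anyway).
    """
    if not s:
        raise ValueError("gc_fraction of an empty string is undefined")
    bad = set(s) - ALPHABET
    if bad:
        raise ValueError(f"invalid characters for gc_fraction: {sorted(bad)}")
    denom = len(s) - s.count("N")
    if denom == 0:
        return 0.0
    return (s.count("G") + s.count("C")) / denom


def truncate3(x: float) -> str:
    """Format a fraction truncated (not rounded) to three decimals.

    The reference repeat tables print mismatch rates this way (e.g. 5/35 =
    0.14285... prints as 0.142), so the TSV writer follows suit.
    """
    return f"{math.floor(x * 1000 + 1e-9) / 1000:.3f}"


def _format_delta(d: float) -> str:
    return "inf" if math.isinf(d) else f"{d:.3f}"


def write_lir_table(lirs: Sequence["LIR"], path: str | Path) -> None:
    """Write the canonical TSV report, one row per repeat.

    Columns: seq_id, left_start, left_end, right_start, right_end,
    repeat_length, n_defects, mismatch_rate, spacer, gc, delta,
    recombinogenic. Rows are written in the given order, which callers keep
    sorted by (seq_id, left_start).
    """
    from .classify import is_recombinogenic  # deferred: avoids import cycle

    with open(path, "w") as out:
        out.write("\t".join(TSV_COLUMNS) + "\n")
        for lir in lirs:
            call = is_recombinogenic(lir)
            row = (
                lir.seq_id,
                str(lir.left_start),
                str(lir.left_end),
                str(lir.right_start),
                str(lir.right_end),
                str(lir.arm_length),
                str(lir.n_defects),
                truncate3(lir.mismatch_rate),
                str(lir.spacer),
                f"{lir.gc:.3f}",
                _format_delta(call.delta),
                "yes" if call.recombinogenic else "no",
            )
            out.write("\t".join(row) + "\n")


def write_bed(lirs: Iterable["LIR"], path: str | Path) -> None:
    """Write BED6 (0-based, half-open): one line per arm.

    Both arms of a repeat share a name; the left arm is reported on "+" and
    the right arm (the reverse-complement copy) on "-". The score column
    carries percent identity between the arms (100 x (1 - mismatch rate)).
    """
    with open(path, "w") as out:
        for i, lir in enumerate(lirs, start=1):
            name = f"LIR{i}"
            score = str(int(round(100 * (1 - lir.mismatch_rate))))
            out.write(
                f"{lir.seq_id}\t{lir.left_start - 1}\t{lir.left_end}\t{name}\t{score}\t+\n"
            )
            out.write(
                f"{lir.seq_id}\t{lir.right_start - 1}\t{lir.right_end}\t{name}\t{score}\t-\n"
            )
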