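# Methods

## Problem and model

`lirscan` annotates long inverted repeats (LIRs): pairs of reverse-
complementary sequence copies ("arms") on the same strand, separated by an
internal spacer ("loop"). The quantities attached to each repeat are

- arm intervals, 1-based inclusive: `left_start..left_end` and
  `right_start..right_end`;
- stem length **L** = length of the *shorter* arm (with indels the two
  copies differ in length);
- defect count **N** = substitution plus gap columns in the arm-vs-arm
  alignment, and mismatch rate **N/L**;
- spacer = `right_start − left_end − 1` (≥ 0; 0 is a true palindrome);
- GC fraction of the two arms concatenated;
- **δ = L/spacer**, with +∞ as the sentinel for spacer 0.

## Search procedure

**Seeding.** All exact k-mer pairs (default k = 5, no N allowed in a seed)
where the downstream k-mer is the reverse complement of the upstream one and
the span from left-seed start to right-seed end is at most the window size
(default 2000 bp). This span criterion is equivalent to sliding the window
one base at a time, so any repeat whose seed pair fits in a window is found
regardless of phase; it subsumes the restart shortcuts a windowed
implementation would use to save time, at the cost of extending duplicate
seeds (deduplicated on coordinates afterwards).

**Extension.** Two cursor pairs move outward (5′ on the left arm, 3′ on the
right arm) and inward from the seed. At each step the left base is compared
with the complement of the right base. On failure three repairs are
evaluated — substitution (advance both cursors), gap in the left arm
(advance the right cursor only), gap in the right arm (advance the left
cursor only) — and a repair is accepted only if the position immediately
following it pairs; this makes two consecutive defects a terminating event
and guarantees alignments begin and end with match columns. Preference:
substitution first; between two viable gaps, the one with the longer
subsequent exact pairing run; on an exact run-length tie, the gap in the
right arm is taken iff the left base sorts lexicographically before the
complement of the right base. Because that comparison inverts under reverse
complement (the two bases are never complementary at a defect), the whole
scan is strand-symmetric: scanning the reverse complement yields the
mirrored repeat set exactly. A fixed "always prefer one side" tie-break
would be simpler but breaks that symmetry. N never pairs; it can only be
consumed inside a substitution column.

**Primary filters.** L ≥ `min_arm_length` (inclusive at the default 30 bp),
N/L strictly below `max_mismatch_rate` (default 0.15), arm GC strictly above
`min_gc` (default 0.20, which removes low-complexity (TA)n-type candidates).
The GC denominator excludes N.

**Redundancy removal.** Between two repeats on one sequence: containment of
an arm in an arm, same-side arm overlap, or cross-side arm overlap causes
the member with the longer spacer to be dropped (ties: keep the longer arm,
then the leftmost). A repeat lying entirely inside another's spacer is
merged into the outer repeat when the same-side arms are ≤ `merge_gap`
(5 bp) apart on *both* sides — single-sided merging would join unrelated
stems; nested stems further apart are legitimate distinct structures and
both are kept. Pairs are re-examined until a fixpoint, with the working list
kept sorted, so the result is independent of input order and idempotent.

**Recombinogenicity.** Perfect arms: recombinogenic iff δ > 1. Imperfect
arms: recombinogenic iff δ ≥ 100·N/L, i.e. δ compared against the mismatch
rate *in percent*. The percent scale is a deliberate calibration decision:
against the plain fraction, almost any repeat with a moderate spacer would
be flagged (δ = 0.914 ≥ 0.031 for a known negative), contradicting the
published reference flags; with the percent scale all 17 published reference
calls are reproduced, consistent with the classical findings that inverted
Alu pairs separated by < 20 bp with identity > 85% are labile and that
recombinogenic capacity is strong for δ > 16. This reading of the published
rule is the package's single largest interpretive commitment; the reference
calibration test pins it.

## Reference data

`lirscan.benchmark` bundles the 17-row published reference table for the
3.8–4.0 Mb region of human contig NT_022853.16 verbatim. Three printing
conventions of that table are mirrored by the package: repeat length is the
shorter copy; mismatch rates are *truncated* to three decimals (5/35 prints
as 0.142, not 0.143), which the TSV writer follows; and one row (left copy
at 3,989,493) prints a spacer of 811 where its own printed coordinates give
810 — an internal off-by-one in the source table. The values are stored as
printed, and the consistency checks report the discrepancy rather than
silently correcting either side.

## Synthetic genomes and what the tests show

`plant_lirs` writes arm + random spacer + mutated reverse complement into an
i.i.d. background (GC 0.5 by default so the GC filter never fires on a
plant). Non-pairing guard bases (A opposite A) flank each plant outside and
line the first/last two spacer positions inside, so extension stops exactly
at the planted boundaries; planted defects sit ≥ 5 bp from arm ends and from
each other, so a clean seed always survives and no two defects are adjacent.
Under these conditions recall is 100% at exact coordinates for
substitution-type plants, and that is what the recall tests demonstrate:
recovery of repeats with crisp boundaries and discoverable defect spacing.
Real repeats embedded in repeat-rich context have no such guards — the
scanner reports whatever maximal extension the rules support, which may
extend past any annotated boundary, and defects closer together than the
seed size can make a short repeat unseedable. The background model has no
repeat families, transposons or isochores.

Test problem sizes — 100 random 1–2-kb sequences for scanner-vs-oracle
equality, 50 ten-kb genomes × 3 plants for recall, 15 fixtures for strand
symmetry — were chosen to exercise hundreds of thousands of extensions while
keeping the default suite around a minute; the acceptance script uses the
same sizes.

## Numerical and edge-case conventions

- Coordinates 1-based inclusive everywhere except BED output (0-based
  half-open, per the BED standard).
- IUPAC ambiguity codes other than N are collapsed to N on input (logged);
  N never pairs and never appears in a seed.
- `gc_fraction` of an all-N string is 0.0 (such a fragment cannot form a
  stem, so the value is never load-bearing).
- Threshold comparisons: arm length inclusive (≥), mismatch rate and GC
  strict (<, >).
- All pipelines are deterministic; the only randomness in the package is the
  synthetic generator's, driven by an explicit seed.
- The brute-force oracle refuses sequences over 2.5 kb: it is quadratic by
  design and exists to validate the scanner, not to replace it.

## Known limitations

- The scan is pure Python and exhaustive: a multi-megabase contig takes
  hours. `scripts/benchmark_contig.py` supports sub-region scanning for
  spot checks against the published full-contig tallies (1443 primary, 656
  filtered, 4 recombinogenic); exact reproduction of those counts is not
  expected, since the extension repair preferences, the tie-breaks, the
  window stride and the merge bookkeeping of the original tool are not
  specified at that level of detail anywhere, and each choice shifts counts
  at the margin.
- Whether N should count only substitutions or also indel columns is
  ambiguous in the source material; both are counted here, since an
  unpenalized indel would make the identity criterion gameable. The bundled
  reference rows are consistent with either convention.
- Extension through an indel can, with ~1/4 probability per step, take a
  chance substitution bridge before re-anchoring; coordinates of
  indel-containing repeats are therefore rule-determined but not always the
  minimal-defect alignment a full dynamic program would produce.
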