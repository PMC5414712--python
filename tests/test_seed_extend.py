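import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lirscan import (
    GenomeSequence,
    PlantSpec,
    SearchParams,
    SeedPair,
    enumerate_seed_pairs,
    extend_seed,
    gc_fraction,
    motif_search,
    plant_lirs,
    reverse_complement,
    scan_sequence,
)


class TestSearchParams:
    def test_defaults_are_the_published_calibration(self):
        p = SearchParams()
        assert (p.window_size, p.min_arm_length, p.seed_size) == (2000, 30, 5)
        assert (p.max_mismatch_rate, p.min_gc) == (0.15, 0.20)
        assert (p.merge_gap, p.restart_spacer_threshold) == (5, 5)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"seed_size": 0},
            {"seed_size": 40, "min_arm_length": 30},
            {"min_arm_length": 3000},
            {"max_mismatch_rate": 0.0},
            {"max_mismatch_rate": 1.0},
            {"min_gc": -0.1},
            {"max_consecutive_defects": 3},
        ],
    )
    def test_invalid_combinations_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SearchParams(**kwargs)


class TestEnumerateSeedPairs:
    def test_single_reverse_complement_pair(self):
        seq = GenomeSequence("s", "ACGAAACGT")
        p = SearchParams(window_size=9, min_arm_length=3, seed_size=3)
        assert enumerate_seed_pairs(seq, 1, p) == [SeedPair(1, 7, 3)]

    def test_poly_a_has_no_pairs(self):
        seq = GenomeSequence("s", "AAAAAAAA")
        p = SearchParams(window_size=8, min_arm_length=3, seed_size=3)
        assert enumerate_seed_pairs(seq, 1, p) == []

    def test_seeds_containing_n_are_skipped(self):
        # N-free seeds may still pair: ACG at 1 with its reverse complement
        # CGT at 6; the k-mers crossing the N block are excluded
        seq = GenomeSequence("s", "ACGNNCGT")
        p = SearchParams(window_size=8, min_arm_length=3, seed_size=3)
        assert enumerate_seed_pairs(seq, 1, p) == [SeedPair(1, 6, 3)]
        all_n = GenomeSequence("s", "ANGNNCNT")
        assert enumerate_seed_pairs(all_n, 1, p) == []

    def test_window_confines_pairs(self):
        # pair spans the whole sequence; a window half as long cannot hold it
        seq = GenomeSequence("s", "ACGTT" + "A" * 20 + "AACGT")
        p = SearchParams(window_size=12, min_arm_length=4, seed_size=4)
        assert enumerate_seed_pairs(seq, 1, p) == []
        wide = SearchParams(window_size=30, min_arm_length=4, seed_size=4)
        pairs = enumerate_seed_pairs(seq, 1, wide)
        assert SeedPair(1, 27, 4) in pairs

    def test_out_of_range_window_start(self):
        seq = GenomeSequence("s", "ACGT")
        with pytest.raises(ValueError):
            enumerate_seed_pairs(seq, 5, SearchParams(window_size=4,
                                                      min_arm_length=2,
                                                      seed_size=2))

    def test_invariants_hold_by_construction(self):
        rng = np.random.default_rng(0)
        seq = GenomeSequence("s", "".join(rng.choice(list("ACGT"), size=400)))
        p = SearchParams(window_size=200, min_arm_length=4, seed_size=4)
        pairs = enumerate_seed_pairs(seq, 100, p)
        assert pairs == sorted(pairs)
        for ls, rs, k in pairs:
            assert ls + k - 1 < rs
            assert 100 <= ls and rs + k - 1 <= 299
            assert seq.fragment(rs, rs + k - 1) == reverse_complement(
                seq.fragment(ls, ls + k - 1)
            )


class TestExtendSeed:
    def test_perfect_extension_of_toy(self, toy_palindrome):
        p = SearchParams(window_size=16, min_arm_length=6, seed_size=3)
        lir = extend_seed(toy_palindrome, SeedPair(3, 12, 3), p)
        assert lir.coords == (1, 6, 11, 16)
        assert (lir.spacer, lir.n_defects, lir.arm_length) == (4, 0, 6)
        assert lir.is_perfect

    def test_below_min_arm_length_returns_none(self, toy_palindrome):
        p = SearchParams(window_size=100, min_arm_length=30, seed_size=3)
        assert extend_seed(toy_palindrome, SeedPair(3, 12, 3), p) is None

    def test_single_internal_substitution_is_bridged(self):
        rng = np.random.default_rng(5)
        arm = "".join(rng.choice(list("ACGT"), size=32))
        right = list(reverse_complement(arm))
        right[15] = {"A": "C", "C": "A", "G": "T", "T": "G"}[right[15]]
        seq = GenomeSequence("s", "AA" + arm + "AATTAA"[:6] + "".join(right) + "AA")
        # guard flanks: A opposite A never pairs, so coordinates are crisp
        residues = list(seq.residues)
        residues[0] = residues[1] = residues[-1] = residues[-2] = "A"
        seq = GenomeSequence("s", "".join(residues))
        p = SearchParams(window_size=200, min_arm_length=30, seed_size=5)
        lirs = scan_sequence(seq, p)
        target = [x for x in lirs if x.coords == (3, 34, 41, 72)]
        assert target, [x.coords for x in lirs]
        lir = target[0]
        assert lir.n_defects == 1
        assert [c.kind for c in lir.columns].count("mismatch") == 1

    def test_invalid_seed_pair_rejected(self, toy_palindrome):
        p = SearchParams(window_size=16, min_arm_length=3, seed_size=3)
        with pytest.raises(ValueError):
            extend_seed(toy_palindrome, SeedPair(1, 4, 3), p)  # not rc partners


class TestScanSequence:
    def test_planted_perfect_repeat_recovered_exactly(self):
        seq, truths = plant_lirs(
            5000, [PlantSpec(arm_length=40, spacer=10)], rng_seed=11
        )
        found = {x.coords for x in scan_sequence(seq, SearchParams())}
        assert truths[0].coords in found

    def test_ta_microsatellite_removed_by_gc_filter(self):
        from lirscan.seed_extend import build_lir, extend_alignment

        seq = GenomeSequence("ta", "TA" * 60)
        params = SearchParams()
        assert scan_sequence(seq, params) == []
        # the GC filter, not a lack of candidates, removes them: seed pairs
        # exist and extend into long zero-GC stems
        pairs = enumerate_seed_pairs(seq, 1, params)
        assert pairs
        widest = max(pairs, key=lambda p: p.right_start - p.left_start)
        candidate = build_lir(seq, extend_alignment(seq.residues, widest))
        assert candidate.arm_length >= params.min_arm_length
        assert candidate.gc == 0.0 <= params.min_gc

    def test_sequence_shorter_than_two_arms(self):
        seq = GenomeSequence("s", "ACGTACGTAA")
        assert scan_sequence(seq, SearchParams()) == []

    def test_emitted_lirs_satisfy_their_own_invariants(self, planted_genome):
        seq, _ = planted_genome
        params = SearchParams()
        for lir in scan_sequence(seq, params):
            assert lir.left_start <= lir.left_end < lir.right_start <= lir.right_end
            assert lir.spacer == lir.right_start - lir.left_end - 1 >= 0
            assert lir.arm_length >= params.min_arm_length
            assert lir.mismatch_rate < params.max_mismatch_rate
            assert lir.gc > params.min_gc
            # stored statistics reproducible from coordinates + raw sequence
            assert lir.arm_length == min(lir.left_arm_length, lir.right_arm_length)
            assert lir.n_defects == sum(c.kind != "match" for c in lir.columns)
            assert lir.mismatch_rate == lir.n_defects / lir.arm_length
            arms = seq.fragment(lir.left_start, lir.left_end) + seq.fragment(
                lir.right_start, lir.right_end
            )
            assert lir.gc == pytest.approx(gc_fraction(arms))
            # no two consecutive defect columns; terminal columns match
            kinds = [c.kind for c in lir.columns]
            assert kinds[0] == kinds[-1] == "match"
            assert all(
                not (a != "match" and b != "match")
                for a, b in zip(kinds, kinds[1:])
            )
            # match columns are genuine Watson-Crick pairs
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            for c in lir.columns:
                if c.kind == "match":
                    left = seq.residues[c.left_pos - 1]
                    right = seq.residues[c.right_pos - 1]
                    assert comp.get(left) == right

    def test_deterministic(self, planted_genome):
        seq, _ = planted_genome
        assert scan_sequence(seq, SearchParams()) == scan_sequence(
            seq, SearchParams()
        )


class TestMotifSearch:
    @pytest.fixture
    def genome_with_motif(self):
        rng = np.random.default_rng(3)
        arm = list(rng.choice(list("ACGT"), size=40))
        arm[10:15] = "GAATC"
        arm = "".join(arm)
        filler = "".join(rng.choice(list("ACGT"), size=300))
        # AAAA spacer and AA flanks cannot pair with themselves, so the
        # planted repeat has crisp boundaries at 3..42 / 47..86
        res = "AA" + arm + "AAAA" + reverse_complement(arm) + "AA" + filler
        return GenomeSequence("m", res)

    def test_motif_present_in_arm(self, genome_with_motif):
        p = SearchParams(window_size=200, min_arm_length=30, seed_size=5)
        hits = motif_search(genome_with_motif, "GAATC", p)
        assert len(hits) == 1
        assert hits[0].left_start == 3

    def test_degenerate_iupac_motif(self, genome_with_motif):
        p = SearchParams(window_size=200, min_arm_length=30, seed_size=5)
        # W = {A, T}: the planted GAATC satisfies GAWTC
        hits = motif_search(genome_with_motif, "GAWTC", p)
        assert [x.left_start for x in hits] == [3]

    def test_absent_motif_returns_nothing(self, genome_with_motif):
        p = SearchParams(window_size=200, min_arm_length=30, seed_size=5)
        assert motif_search(genome_with_motif, "CCCCCCCCCC", p) == []

    def test_invalid_iupac_character(self, genome_with_motif):
        with pytest.raises(ValueError):
            motif_search(genome_with_motif, "GA?TC", SearchParams())


@settings(derandomize=True, max_examples=20, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_strand_symmetry_on_random_sequences(seed):
    """Scanning the reverse complement yields the mirrored repeat set."""
    rng = np.random.default_rng(seed)
    res = "".join(rng.choice(list("ACGT"), size=600))
    seq = GenomeSequence("f", res)
    rc = GenomeSequence("r", reverse_complement(res))
    p = SearchParams(window_size=400, min_arm_length=12, seed_size=4)
    n = len(res)
    fwd = {x.coords for x in scan_sequence(seq, p)}
    rev = {
        (n - x.right_end + 1, n - x.right_start + 1,
         n - x.left_end + 1, n - x.left_start + 1)
        for x in scan_sequence(rc, p)
    }
    assert fwd == rev
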