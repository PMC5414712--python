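import numpy as np
import pytest

from lirscan import GenomeSequence, PlantSpec, SearchParams, plant_lirs
from lirscan.seed_extend import LIR


@pytest.fixture
def default_params():
    return SearchParams()


@pytest.fixture
def toy_palindrome():
    """GCCATT + AAAA + AATGGC: a perfect 6-bp-arm repeat with a 4-bp spacer."""
    return GenomeSequence("toy", "GCCATTAAAAAATGGC")


def make_lir(left_start, left_end, right_start, right_end, *, seq_id="chr",
             n_defects=0, gc=0.5):
    """Bare LIR record for interval-logic tests (no alignment columns)."""
    arm = min(left_end - left_start + 1, right_end - right_start + 1)
    return LIR(
        seq_id=seq_id,
        left_start=left_start,
        left_end=left_end,
        right_start=right_start,
        right_end=right_end,
        columns=(),
        n_defects=n_defects,
        arm_length=arm,
        mismatch_rate=n_defects / arm,
        spacer=right_start - left_end - 1,
        gc=gc,
        is_perfect=n_defects == 0
        and (left_end - left_start) == (right_end - right_start),
    )


def random_plant_specs(rng, n_plants=3, max_subs=3):
    """Arm 30-80 bp, spacer 0-500 bp, 0-max_subs well-separated substitutions."""
    return [
        PlantSpec(
            arm_length=int(rng.integers(30, 81)),
            spacer=int(rng.integers(0, 501)),
            n_substitutions=int(rng.integers(0, max_subs + 1)),
        )
        for _ in range(n_plants)
    ]


@pytest.fixture
def planted_genome():
    """One deterministic 10-kb genome with three substitution-mutated plants."""
    rng = np.random.default_rng(42)
    return plant_lirs(10_000, random_plant_specs(rng), rng_seed=42)
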