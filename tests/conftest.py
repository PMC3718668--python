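"""Shared fixtures: toy genomes, per-category site constructions."""

import numpy as np
import pytest
from hypothesis import settings

from mspjiseq.genome import Genome, GenomeSequence

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

#: Minimal concrete instantiation of each symmetric-category pattern, with
#: the index of the plus-strand C inside the sequence and the expected
#: paired-C offset d and two-way fragment length (L = 33 - d).
CATEGORY_EXAMPLES = {
    "YNCGNR": ("TACGTA", 2, 1, 32),
    "YCHGR": ("TCAGA", 1, 2, 31),
    "CHHG": ("CTTG", 0, 3, 30),
    "CYHAG": ("CTTAG", 0, 4, 29),
    "CHYAHG": ("CTTATG", 0, 5, 28),
    "TDDGCHHA": ("TAAGCTTA", 4, -1, 34),
    "TDDGNCHHA": ("TAAGACTTA", 5, -2, 35),
}

FLANK = 20  # inert poly-A flank: no C or G on either strand


@pytest.fixture(scope="session")
def toy_genome():
    """40-bp genome with a single symmetric CG site at positions 18/19."""
    return Genome([GenomeSequence("toy", "A" * 16 + "TACGTA" + "A" * 18)])


def category_genome(name: str) -> tuple[Genome, int, int]:
    """(genome, plus_C_pos, minus_C_pos) for one isolated category site."""
    core, c_idx, d, _ = CATEGORY_EXAMPLES[name]
    seq = "A" * FLANK + core + "A" * FLANK
    plus_pos = FLANK + c_idx
    return Genome([GenomeSequence(name, seq)]), plus_pos, plus_pos + d


def random_genome(seed: int, length: int = 2000, gc: float = 0.36,
                  name: str = "rand") -> Genome:
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])
    return Genome([GenomeSequence(name, seq)])
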