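import random
import warnings

import numpy as np
import pytest

from pddkit.probescan import Probe, TranscriptCategory, TranscriptRecord


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20140526)


@pytest.fixture
def small_pool(rng) -> list[TranscriptRecord]:
    """One dominant rRNA-like transcript plus a handful of mRNAs."""
    pool = [
        TranscriptRecord(
            id="rRNA",
            sequence=random_dna(rng, 800),
            category=TranscriptCategory.rRNA_target,
            abundance_weight=200.0,
        )
    ]
    for i in range(5):
        pool.append(
            TranscriptRecord(
                id=f"mRNA_{i}",
                sequence=random_dna(rng, 600),
                category=TranscriptCategory.mRNA,
            )
        )
    return pool


def make_probe(pid: str, seq: str, targets=()) -> Probe:
    """Probe constructor that silences the short-probe advisory warning."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return Probe(id=pid, sequence=seq, intended_target_ids=frozenset(targets))
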