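import numpy as np
import pytest

from pepwords import (
    CohortSpec,
    Orf,
    Proteome,
    build_dictionary,
    free_living_composition,
    generate_proteome,
    uniform_composition,
)


@pytest.fixture
def tiny_proteome() -> Proteome:
    """Two short ORFs with known word structure (hand-countable)."""
    return Proteome("tiny", (Orf("a", "AAAA"), Orf("b", "MKVMKV")))


@pytest.fixture
def random_proteome() -> Proteome:
    """~1,000-residue i.i.d. proteome at realistic composition."""
    return generate_proteome(
        free_living_composition(), n_orfs=10, length_dist=(100.0, 25.0),
        seed=42, genome_id="rand",
    )


@pytest.fixture
def uniform_proteome() -> Proteome:
    return generate_proteome(
        uniform_composition(), n_orfs=8, length_dist=(120.0, 30.0),
        seed=7, genome_id="unif",
    )


@pytest.fixture
def random_dictionary(random_proteome):
    return build_dictionary(random_proteome)


@pytest.fixture
def null_cohort_spec() -> CohortSpec:
    """Small two-group cohort with no planted contrast (the null)."""
    return CohortSpec(
        n_genomes_per_group=4,
        n_orfs=12,
        orf_length_distribution=(80.0, 20.0),
        seed=5,
    )


def brute_force_counts(sequences, n):
    """Independent oracle: enumerate every length-n window explicitly."""
    counts = {}
    for seq in sequences:
        for i in range(len(seq)):
            w = seq[i : i + n]
            if len(w) == n:
                counts[w] = counts.get(w, 0) + 1
    return counts
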