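"""Residual word-distance statistics and repeat-spectrum vectors.

The over/under-representation of a single word is measured as the
perpendicular distance of its (observed, expected) point from the 1:1
equilibrium line,

    d(w) = |observed(w) - expected(w)| / sqrt(2),

and a genome's total word distance is the sum of d(w) over all retained
words.  Subtracting the total distance of the genome's shuffled copy
("adjusted distance") isolates repetition structure beyond what amino acid
composition alone produces.

For cross-genome comparison the dictionary is condensed into a fixed-length
repeat vector: element i summarizes the words observed exactly i times —
either how many unique words sit at that repetition level (COUNT mode) or
how much residual distance they carry (DISTANCE mode) — normalized by the
proteome's total residue count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from .word_dictionary import SQRT2, WordDictionary

MAX_REPEAT_DEFAULT = 30_000


class VectorMode(str, Enum):
    COUNT = "COUNT"
    DISTANCE = "DISTANCE"


def residual_distance(observed: float, expected: float) -> float:
    """Perpendicular distance of (observed, expected) from the 1:1 line."""
    if observed < 0 or expected < 0:
        raise ValueError("observed and expected must be non-negative")
    return abs(observed - expected) / SQRT2


def total_word_distance(dictionary: WordDictionary) -> float:
    """Sum of residual distances over all retained words (the genome statistic)."""
    return float(sum(e.residual for e in dictionary.entries.values()))


@dataclass(frozen=True)
class DistanceSummary:
    """Native, randomized and adjusted total word distance of one genome."""

    genome_id: str
    total_distance: float
    random_distance: float
    genome_size_aa: int

    @property
    def adjusted_distance(self) -> float:
        return self.total_distance - self.random_distance

    @property
    def genome_size_nt(self) -> int:
        return 3 * self.genome_size_aa


def adjusted_distance(
    native: WordDictionary, random: WordDictionary
) -> DistanceSummary:
    """Total word distance of the native genome minus its shuffled copy's.

    Both dictionaries must derive from the same genome (equal residue
    totals); the shuffled copy preserves composition, ORF count and
    lengths, so any surplus distance reflects non-random repetition.
    """
    if native.total_residues != random.total_residues:
        raise ValueError(
            "native and random dictionaries have different residue totals "
            f"({native.total_residues} vs {random.total_residues})"
        )
    return DistanceSummary(
        genome_id=native.genome_id,
        total_distance=total_word_distance(native),
        random_distance=total_word_distance(random),
        genome_size_aa=native.total_residues,
    )


@dataclass(frozen=True)
class RepeatVector:
    """Fixed-length word-repetition fingerprint of one genome.

    ``bins[i]`` holds the statistic for words observed exactly i times
    (levels 0 and 1 are identically zero — only words observed at least
    twice are retained); repetition levels at or above ``max_repeat - 1``
    accumulate in the last element.  Values are divided by ``normalizer``
    (total residues of the non-redundant proteome).
    """

    genome_id: str
    bins: np.ndarray = field(repr=False)
    mode: VectorMode
    normalizer: int

    def __post_init__(self) -> None:
        if self.normalizer <= 0:
            raise ValueError("normalizer must be positive")
        b = np.asarray(self.bins, dtype=float)
        object.__setattr__(self, "bins", b)
        if b[0] != 0.0 or b[1] != 0.0:
            raise ValueError("repetition levels 0 and 1 must be empty")
        if (b < 0).any():
            raise ValueError("bin values must be >= 0")

    @property
    def max_repeat(self) -> int:
        return len(self.bins)


def repeat_vector(
    dictionary: WordDictionary,
    mode: VectorMode = VectorMode.DISTANCE,
    max_repeat: int = MAX_REPEAT_DEFAULT,
) -> RepeatVector:
    """Condense a dictionary into a repeat-level vector.

    COUNT mode bins the number of unique retained words per repetition
    level; DISTANCE mode bins their summed residual distance.  Both are
    normalized by total residues so vectors are comparable across genome
    sizes.
    """
    if max_repeat < 2:
        raise ValueError("max_repeat must be >= 2")
    mode = VectorMode(mode)
    bins = np.zeros(max_repeat, dtype=float)
    last = max_repeat - 1
    for e in dictionary.entries.values():
        i = e.observed if e.observed < last else last
        bins[i] += 1.0 if mode is VectorMode.COUNT else e.residual
    bins /= dictionary.total_residues
    return RepeatVector(dictionary.genome_id, bins, mode, dictionary.total_residues)


def group_mean_vector(
    vectors: list[RepeatVector], genome_id: str = "group_mean"
) -> RepeatVector:
    """Element-wise arithmetic mean of a group's repeat vectors."""
    if not vectors:
        raise ValueError("cannot average an empty list of vectors")
    modes = {v.mode for v in vectors}
    if len(modes) != 1:
        raise ValueError(f"mixed vector modes: {sorted(m.value for m in modes)}")
    lengths = {v.max_repeat for v in vectors}
    if len(lengths) != 1:
        raise ValueError(f"mixed vector lengths: {sorted(lengths)}")
    mean = np.mean([v.bins for v in vectors], axis=0)
    # the mean of normalized vectors has no single normalizer; carry the mean
    norm = max(1, round(np.mean([v.normalizer for v in vectors])))
    return RepeatVector(genome_id, mean, vectors[0].mode, norm)


# ---------------------------------------------------------------------------
# Serialization: sparse "i:value" rows, one genome per line
# ---------------------------------------------------------------------------


def write_repeat_vectors(vectors: list[RepeatVector], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("genome_id\tmode\tmax_repeat\tnormalizer\tbins\n")
        for v in vectors:
            nz = np.nonzero(v.bins)[0]
            sparse = " ".join(f"{i}:{v.bins[i]:.12g}" for i in nz)
            fh.write(
                f"{v.genome_id}\t{v.mode.value}\t{v.max_repeat}\t{v.normalizer}\t{sparse}\n"
            )
    return path


def read_repeat_vectors(path: str | Path) -> list[RepeatVector]:
    vectors: list[RepeatVector] = []
    with open(path) as fh:
        fh.readline()  # header
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            gid, mode, max_repeat, norm = fields[:4]
            sparse = fields[4] if len(fields) > 4 else ""
            bins = np.zeros(int(max_repeat))
            if sparse:
                for item in sparse.split(" "):
                    i, _, val = item.partition(":")
                    bins[int(i)] = float(val)
            vectors.append(RepeatVector(gid, bins, VectorMode(mode), int(norm)))
    return vectors


def vectors_to_matrix(vectors: list[RepeatVector]) -> np.ndarray:
    """Dense n-genomes x max_repeat matrix for the discrimination stage."""
    if not vectors:
        raise ValueError("no vectors")
    return np.vstack([v.bins for v in vectors])
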