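"""Synthetic proteome and cohort generation with known ground truth.

Real cohorts of predicted proteomes cannot ship with the package, so every
pipeline stage is exercised on synthetic data: proteomes drawn i.i.d. from
a chosen amino acid composition, with ORF counts and truncated-normal
length distributions at bacterial scale, into which repeated words can be
planted at known positions and copy numbers.  Planting more copies of a
word in one group creates a lifestyle-like word-repetition contrast at a
controlled effect size; an i.i.d. cohort with no planting is the null.

A ground-truth manifest (word, ORF index, position per insertion) is
emitted so every planted occurrence can be verified in the output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .proteome_io import (
    AMINO_ACIDS,
    Gram,
    GroupTable,
    Label,
    Orf,
    Proteome,
    write_fasta,
    write_group_table,
)
from .word_dictionary import CompositionTable

MIN_ORF_LENGTH = 12  # shortest ORF able to hold the longest (12-mer) word

#: Mean amino acid frequencies of free-living microbial proteomes
#: (renormalized); used as the realistic composition preset.
FREE_LIVING_FREQUENCIES: dict[str, float] = {
    "A": 0.0948, "C": 0.0094, "D": 0.0539, "E": 0.0635, "F": 0.0396,
    "G": 0.0756, "H": 0.0199, "I": 0.0647, "K": 0.0515, "L": 0.1021,
    "M": 0.0237, "N": 0.0373, "P": 0.0453, "Q": 0.0341, "R": 0.0576,
    "S": 0.0589, "T": 0.0526, "V": 0.0725, "W": 0.0120, "Y": 0.0301,
}


def uniform_composition(total_residues: int = 1) -> CompositionTable:
    return CompositionTable({aa: 1 / 20 for aa in AMINO_ACIDS}, total_residues)


def free_living_composition(total_residues: int = 1) -> CompositionTable:
    s = sum(FREE_LIVING_FREQUENCIES.values())
    return CompositionTable(
        {aa: f / s for aa, f in FREE_LIVING_FREQUENCIES.items()}, total_residues
    )


def _draw_lengths(
    rng: np.random.Generator, n_orfs: int, mean: float, sd: float
) -> np.ndarray:
    lengths = np.rint(rng.normal(mean, sd, size=n_orfs)).astype(int)
    return np.clip(lengths, MIN_ORF_LENGTH, None)


def generate_proteome(
    composition: CompositionTable,
    n_orfs: int = 60,
    length_dist: tuple[float, float] = (300.0, 100.0),
    seed: int | np.random.SeedSequence = 0,
    genome_id: str = "synthetic",
    label: Label = Label.UNLABELED,
    gram: Gram = Gram.UNKNOWN,
) -> Proteome:
    """Draw a proteome i.i.d. from `composition`.

    ORF lengths are truncated normal (rounded, minimum 12 residues);
    residues are sampled independently with the composition probabilities.
    """
    if n_orfs < 1:
        raise ValueError("n_orfs must be >= 1")
    probs = np.array([composition[aa] for aa in AMINO_ACIDS])
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("composition frequencies must sum to 1")
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    lengths = _draw_lengths(rng, n_orfs, *length_dist)
    letters = np.frombuffer(AMINO_ACIDS.encode("ascii"), dtype=np.uint8)
    flat = rng.choice(letters, size=int(lengths.sum()), p=probs)
    orfs = []
    pos = 0
    for i, ln in enumerate(lengths):
        orfs.append(
            Orf(f"{genome_id}_orf{i:05d}", flat[pos : pos + ln].tobytes().decode())
        )
        pos += ln
    return Proteome(genome_id, tuple(orfs), label=label, gram=gram)


def plant_motifs(
    proteome: Proteome,
    motifs: list[tuple[str, int]],
    seed: int | np.random.SeedSequence = 0,
    max_tries_per_insertion: int = 1000,
) -> tuple[Proteome, list[dict]]:
    """Overwrite random non-overlapping in-ORF windows with repeated words.

    Each (word, insertions) pair places `insertions` copies of the word at
    uniformly chosen positions; planted windows never overlap each other.
    ORF count and lengths are unchanged.  Returns the modified proteome and
    a manifest of dicts (word, orf_index, position) recording ground truth.
    Raises if non-overlapping space runs out.
    """
    for word, ins in motifs:
        if not 2 <= len(word) <= 12:
            raise ValueError(f"planted word {word!r} length must be in [2, 12]")
        if ins < 0:
            raise ValueError("insertion counts must be >= 0")
    rng = np.random.default_rng(seed)
    seqs = [bytearray(o.sequence, "ascii") for o in proteome.orfs]
    occupied: list[list[tuple[int, int]]] = [[] for _ in seqs]
    manifest: list[dict] = []

    # ORFs weighted by capacity so long ORFs absorb proportionally more copies
    weights = np.array([len(s) for s in seqs], dtype=float)
    weights /= weights.sum()

    for word, insertions in motifs:
        wlen = len(word)
        wordb = word.encode("ascii")
        for _ in range(insertions):
            placed = False
            for _try in range(max_tries_per_insertion):
                oi = int(rng.choice(len(seqs), p=weights))
                room = len(seqs[oi]) - wlen
                if room < 0:
                    continue
                pos = int(rng.integers(0, room + 1))
                if any(pos < e and p < pos + wlen for p, e in occupied[oi]):
                    continue
                seqs[oi][pos : pos + wlen] = wordb
                occupied[oi].append((pos, pos + wlen))
                manifest.append({"word": word, "orf_index": oi, "position": pos})
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    f"could not place all copies of {word!r}: insufficient "
                    "non-overlapping space"
                )
    orfs = tuple(
        Orf(o.id, s.decode("ascii")) for o, s in zip(proteome.orfs, seqs)
    )
    return replace(proteome, orfs=orfs), manifest


@dataclass(frozen=True)
class CohortSpec:
    """Two-group synthetic cohort definition.

    Defaults emulate a desk-scale lifestyle contrast: 15 genomes per group,
    60 ORFs per genome with truncated-normal lengths (mean 300, sd 100,
    min 12), free-living-like composition in both groups, and no planted
    motifs (the null).  ``planted_motifs`` entries are
    (word, insertions_per_genome_A, insertions_per_genome_B).
    """

    n_genomes_per_group: int = 15
    n_orfs: int = 60
    orf_length_distribution: tuple[float, float] = (300.0, 100.0)
    composition_a: CompositionTable = field(default_factory=free_living_composition)
    composition_b: CompositionTable = field(default_factory=free_living_composition)
    planted_motifs: tuple[tuple[str, int, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes_per_group < 1:
            raise ValueError("n_genomes_per_group must be >= 1")
        for word, ia, ib in self.planted_motifs:
            if not 2 <= len(word) <= 12:
                raise ValueError(f"planted word {word!r} length must be in [2, 12]")
            if ia < 0 or ib < 0:
                raise ValueError("insertion counts must be >= 0")


def _genome_seeds(spec_seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(spec_seed).spawn(n)


def generate_cohort_proteomes(
    spec: CohortSpec,
) -> tuple[list[Proteome], dict[str, list[dict]]]:
    """Generate the cohort in memory: group A labeled FREE, group B PATH.

    Per-genome randomness is derived deterministically from ``spec.seed``.
    Returns (proteomes, manifest keyed by genome_id).
    """
    n = spec.n_genomes_per_group
    seeds = _genome_seeds(spec.seed, 2 * n)
    proteomes: list[Proteome] = []
    manifest: dict[str, list[dict]] = {}
    for gi in range(2 * n):
        group = "A" if gi < n else "B"
        label = Label.FREE if group == "A" else Label.PATH
        comp = spec.composition_a if group == "A" else spec.composition_b
        genome_id = f"{'free' if group == 'A' else 'path'}_{gi % n:03d}"
        child = seeds[gi].spawn(2)
        p = generate_proteome(
            comp,
            n_orfs=spec.n_orfs,
            length_dist=spec.orf_length_distribution,
            seed=child[0],
            genome_id=genome_id,
            label=label,
        )
        motifs = [
            (word, ia if group == "A" else ib)
            for word, ia, ib in spec.planted_motifs
        ]
        motifs = [(w, i) for w, i in motifs if i > 0]
        if motifs:
            p, m = plant_motifs(p, motifs, seed=child[1])
        else:
            m = []
        proteomes.append(p)
        manifest[genome_id] = m
    return proteomes, manifest


def generate_cohort(
    spec: CohortSpec, outdir: str | Path
) -> tuple[Path, Path, dict[str, list[dict]]]:
    """Write the cohort to disk: FASTA per genome, group table, manifest.

    Returns (group_table_path, manifest_path, manifest).  Regeneration with
    the same spec yields identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    proteomes, manifest = generate_cohort_proteomes(spec)
    rows = []
    for p in proteomes:
        fasta = outdir / f"{p.genome_id}.faa"
        write_fasta(p, fasta)
        rows.append(
            {
                "genome_id": p.genome_id,
                # relative to the group table's own directory, so the cohort moves as a unit
                "fasta_path": fasta.name,
                "label": p.label.value,
                "gram": p.gram.value,
            }
        )
    table_path = outdir / "group_table.tsv"
    write_group_table(GroupTable(pd.DataFrame(rows)), table_path)
    manifest_path = outdir / "ground_truth.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return table_path, manifest_path, manifest
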