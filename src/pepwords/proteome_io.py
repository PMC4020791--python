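"""Proteome input/output and redundancy filtering.

A proteome is an ordered collection of predicted protein sequences (ORFs)
together with genome-level metadata: a lifestyle label (free-living vs
pathogen) and an optional gram stain.  Before any word counting the
proteome is reduced to a non-redundant set by greedy clustering at a
sequence-identity threshold (default 95%), mirroring the CD-HIT
preprocessing that removes near-duplicate proteins which would otherwise
inflate word repetition counts.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("pepwords")

#: The 20 standard one-letter amino acid codes; the word alphabet.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)


class Label(str, Enum):
    """Lifestyle label of a genome."""

    FREE = "FREE"
    PATH = "PATH"
    UNLABELED = "UNLABELED"


class Gram(str, Enum):
    """Gram-stain classification of a genome."""

    POS = "POS"
    NEG = "NEG"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class Orf:
    """One predicted protein: an identifier and its amino acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"ORF {self.id!r} has an empty sequence")
        bad = set(self.sequence) - _AA_SET
        if bad:
            raise ValueError(
                f"ORF {self.id!r} contains non-standard residues {sorted(bad)}; "
                "sanitize before constructing"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Proteome:
    """An ordered set of ORFs with genome metadata."""

    genome_id: str
    orfs: tuple[Orf, ...]
    label: Label = Label.UNLABELED
    gram: Gram = Gram.UNKNOWN

    def __post_init__(self) -> None:
        if not self.orfs:
            raise ValueError(f"proteome {self.genome_id!r} has no ORFs")
        object.__setattr__(self, "orfs", tuple(self.orfs))

    @property
    def total_residues(self) -> int:
        return sum(len(o) for o in self.orfs)

    @property
    def sequences(self) -> tuple[str, ...]:
        return tuple(o.sequence for o in self.orfs)

    def __len__(self) -> int:
        return len(self.orfs)


@dataclass(frozen=True)
class GroupTable:
    """Assignment of genomes to FASTA files and group labels."""

    rows: pd.DataFrame = field(repr=False)

    COLUMNS = ("genome_id", "fasta_path", "label", "gram")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.rows.columns]
        if missing:
            raise ValueError(f"group table missing columns {missing}")
        ids = self.rows["genome_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].tolist()
            raise ValueError(f"duplicate genome_id values: {dup}")

    def __len__(self) -> int:
        return len(self.rows)


def sanitize_sequence(raw: str) -> str:
    """Upper-case and strip every character outside the 20-letter alphabet.

    Ambiguity codes (B, J, O, U, X, Z), stop marks and gap characters are
    removed rather than substituted: the null recombination model requires
    an exactly 20-letter alphabet.
    """
    return "".join(c for c in raw.upper() if c in _AA_SET)


def read_fasta(
    path: str | Path,
    genome_id: str | None = None,
    label: Label = Label.UNLABELED,
    gram: Gram = Gram.UNKNOWN,
) -> Proteome:
    """Read a multi-record amino acid FASTA file into a :class:`Proteome`.

    Sequences are upper-cased and sanitized; records whose sequence becomes
    empty after sanitization are dropped with a warning.  A record that is
    empty *before* sanitization is an error (malformed input), as is an
    empty file.
    """
    path = Path(path)
    orfs: list[Orf] = []
    n_records = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_records += 1
        raw = str(rec.seq)
        if not raw:
            raise ValueError(f"record {rec.id!r} in {path} has an empty sequence")
        clean = sanitize_sequence(raw)
        if not clean:
            logger.warning(
                "dropping ORF %r from %s: no standard residues remain after sanitization",
                rec.id,
                path.name,
            )
            continue
        orfs.append(Orf(rec.id, clean))
    if n_records == 0:
        raise ValueError(f"no records in FASTA file {path}")
    if not orfs:
        raise ValueError(f"all records in {path} were dropped by sanitization")
    return Proteome(genome_id or path.stem, tuple(orfs), label=label, gram=gram)


def write_fasta(proteome: Proteome, path: str | Path, wrap: int = 60) -> Path:
    """Write a proteome as FASTA, one record per ORF, 60-column wrapped."""
    path = Path(path)
    with open(path, "w") as fh:
        for orf in proteome.orfs:
            fh.write(f">{orf.id}\n")
            for i in range(0, len(orf.sequence), wrap):
                fh.write(orf.sequence[i : i + wrap] + "\n")
    return path


def read_group_table(path: str | Path) -> GroupTable:
    """Read the TSV metadata table (genome_id, fasta_path, label, gram)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    if "gram" not in df.columns:
        df["gram"] = Gram.UNKNOWN.value
    df["label"] = df["label"].replace("", Label.UNLABELED.value)
    df["gram"] = df["gram"].replace("", Gram.UNKNOWN.value)
    return GroupTable(df)


def write_group_table(table: GroupTable, path: str | Path) -> Path:
    path = Path(path)
    table.rows.to_csv(path, sep="\t", index=False)
    return path


def resolve_group_table(table: GroupTable, base: str | Path | None = None) -> None:
    """Check that every fasta_path in the table exists (pipeline precondition)."""
    base = Path(base) if base is not None else None
    missing = []
    for p in table.rows["fasta_path"]:
        fp = Path(p)
        if base is not None and not fp.is_absolute():
            fp = base / fp
        if not fp.exists():
            missing.append(str(fp))
    if missing:
        raise FileNotFoundError(f"unresolvable FASTA paths in group table: {missing}")


# ---------------------------------------------------------------------------
# Redundancy clustering (greedy, CD-HIT style)
# ---------------------------------------------------------------------------

_SEED_K = 4  # exact-match seed length used to enumerate candidate offsets


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _identity_at_offset(a: np.ndarray, b: np.ndarray, offset: int) -> float:
    """Ungapped identity of b aligned against a at `offset`, over the shorter length."""
    # offset = position in a where b[0] aligns (may be negative)
    start_a = max(0, offset)
    start_b = max(0, -offset)
    overlap = min(len(a) - start_a, len(b) - start_b)
    if overlap <= 0:
        return 0.0
    matches = int(
        np.count_nonzero(a[start_a : start_a + overlap] == b[start_b : start_b + overlap])
    )
    return matches / min(len(a), len(b))


def pairwise_identity(seq_a: str, seq_b: str, max_shift: int | None = None) -> float:
    """Best ungapped sliding identity between two sequences.

    Identity is exact matches at the best offset divided by the length of
    the shorter sequence (the CD-HIT convention).  Scans all offsets; used
    as the exact kernel and as an oracle for the seeded fast path.
    """
    a, b = _encode(seq_a), _encode(seq_b)
    best = 0.0
    lo, hi = -(len(b) - 1), len(a) - 1
    if max_shift is not None:
        lo, hi = max(lo, -max_shift), min(hi, max_shift)
    for off in range(lo, hi + 1):
        best = max(best, _identity_at_offset(a, b, off))
        if best == 1.0:
            break
    return best


def cluster_redundant(proteome: Proteome, identity_threshold: float = 0.95) -> Proteome:
    """Remove near-duplicate ORFs by greedy incremental clustering.

    ORFs are visited longest-first; each candidate joins the first existing
    cluster whose representative shares at least ``identity_threshold``
    ungapped identity (relative to the shorter sequence), otherwise it
    founds a new cluster.  The representative (longest member) of each
    cluster survives, in original ORF order.

    For thresholds >= 0.85 candidate offsets are taken from shared exact
    4-mers: any ungapped alignment at >= 85% identity over the shorter
    sequence must contain an exact run of >= 4 residues, so the seed index
    cannot miss a qualifying offset.  Lower thresholds fall back to a full
    offset scan.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must be in (0, 1]")
    orfs = proteome.orfs
    if len(orfs) == 1:
        return proteome

    order = sorted(range(len(orfs)), key=lambda i: (-len(orfs[i]), i))
    encoded = [_encode(o.sequence) for o in orfs]
    use_seeds = identity_threshold >= 0.85

    rep_indices: list[int] = []  # in cluster-creation order
    # seed k-mer -> list of (rep position in rep_indices, position in rep sequence)
    seed_index: dict[str, list[tuple[int, int]]] = defaultdict(list)

    def _add_rep(orf_idx: int) -> None:
        rep_pos = len(rep_indices)
        rep_indices.append(orf_idx)
        if use_seeds:
            s = orfs[orf_idx].sequence
            for j in range(len(s) - _SEED_K + 1):
                seed_index[s[j : j + _SEED_K]].append((rep_pos, j))

    for idx in order:
        seq = orfs[idx].sequence
        assigned = False
        if use_seeds:
            # candidate (rep, offset) pairs implied by shared exact 4-mers
            offsets: dict[int, set[int]] = defaultdict(set)
            for j in range(len(seq) - _SEED_K + 1):
                for rep_pos, rep_j in seed_index.get(seq[j : j + _SEED_K], ()):
                    offsets[rep_pos].add(rep_j - j)
            for rep_pos in sorted(offsets):  # first cluster wins
                rep_arr = encoded[rep_indices[rep_pos]]
                cand_arr = encoded[idx]
                best = max(
                    _identity_at_offset(rep_arr, cand_arr, off)
                    for off in offsets[rep_pos]
                )
                if best >= identity_threshold:
                    assigned = True
                    break
        else:
            for rep_pos, rep_idx in enumerate(rep_indices):
                if (
                    pairwise_identity(orfs[rep_idx].sequence, seq)
                    >= identity_threshold
                ):
                    assigned = True
                    break
        if not assigned:
            _add_rep(idx)

    survivors = sorted(rep_indices)
    n_removed = len(orfs) - len(survivors)
    if n_removed:
        logger.info(
            "%s: redundancy clustering removed %d/%d ORFs at %.0f%% identity",
            proteome.genome_id,
            n_removed,
            len(orfs),
            identity_threshold * 100,
        )
    return replace(proteome, orfs=tuple(orfs[i] for i in survivors))
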