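"""Amino acid word dictionaries: observed counts and null-model expectations.

A "word" is a contiguous run of N residues (2 <= N <= 12) inside a single
ORF; windows never cross ORF boundaries.  The dictionary of a genome maps
every word observed at least twice to its observed sliding-window count,
its expected count under a null recombination model, and the residual
distance between the two (see :mod:`pepwords.word_statistics`).

The expected frequency of a length-N word w is the mean of two terms, one
per (N-1)-submer: the frequency of the prefix times the composition
frequency of the last residue, and the frequency of the suffix times the
composition frequency of the first residue,

    p_exp(w) = 1/2 * [ f(w[:-1]) * a(w[-1]) + f(w[1:]) * a(w[0]) ]

where f(s) = count(s) / windows(N-1) is the raw observed submer frequency
(for N-1 = 1 it collapses to the composition frequency a).  For a
dipeptide both terms equal a(x)*a(y): a genome using alanine at 5% expects
the homodipeptide AA at 0.05^2 = 0.25% of dipeptide windows.  The expected
count is p_exp(w) times the number of length-N windows.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .proteome_io import AMINO_ACIDS, Proteome

NMIN_DEFAULT = 2
NMAX_DEFAULT = 12

SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class CompositionTable:
    """Single-residue amino acid frequencies of a proteome."""

    freq: dict[str, float]
    total_residues: int

    def __post_init__(self) -> None:
        if self.total_residues <= 0:
            raise ValueError("total_residues must be positive")
        if any(v < 0 for v in self.freq.values()):
            raise ValueError("composition frequencies must be >= 0")
        s = sum(self.freq.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"composition frequencies sum to {s}, not 1")

    @classmethod
    def from_proteome(cls, proteome: Proteome) -> "CompositionTable":
        counts = Counter()
        for seq in proteome.sequences:
            counts.update(seq)
        total = sum(counts.values())
        return cls({aa: counts.get(aa, 0) / total for aa in AMINO_ACIDS}, total)

    def __getitem__(self, letter: str) -> float:
        return self.freq.get(letter, 0.0)


@dataclass(frozen=True)
class WordEntry:
    """One retained word: observed count, expected count, residual distance."""

    word: str
    observed: int
    expected: float
    residual: float


@dataclass(frozen=True)
class WordDictionary:
    """Per-genome word dictionary over the 2-12 mer range."""

    genome_id: str
    entries: dict[str, WordEntry]
    composition: CompositionTable
    window_totals: dict[int, int]
    nmin: int = NMIN_DEFAULT
    nmax: int = NMAX_DEFAULT
    # ORF sequences kept for on-demand counting of unretained submers;
    # absent (None) for dictionaries re-read from disk.
    sequences: tuple[str, ...] | None = field(default=None, repr=False)

    @property
    def total_residues(self) -> int:
        return self.composition.total_residues

    def __contains__(self, word: str) -> bool:
        return word in self.entries

    def observed(self, word: str) -> int:
        """Raw sliding-window count of any word, retained or not."""
        entry = self.entries.get(word)
        if entry is not None:
            return entry.observed
        if self.sequences is None:
            return 0  # unretained words are unrecoverable from a serialized dictionary
        return count_word(self.sequences, word)


def count_word(sequences: tuple[str, ...], word: str) -> int:
    """Overlapping occurrences of `word` across ORFs (windows stay in-ORF)."""
    n = 0
    for seq in sequences:
        start = 0
        while True:
            i = seq.find(word, start)
            if i < 0:
                break
            n += 1
            start = i + 1
    return n


def window_total(proteome_or_sequences, n: int) -> int:
    """Number of length-n windows: sum over ORFs of max(0, len - n + 1)."""
    seqs = (
        proteome_or_sequences.sequences
        if isinstance(proteome_or_sequences, Proteome)
        else proteome_or_sequences
    )
    return sum(max(0, len(s) - n + 1) for s in seqs)


def count_words(sequences: tuple[str, ...], n: int) -> Counter:
    """Counter of all length-n windows over the ORFs (no retention filter)."""
    c: Counter = Counter()
    for seq in sequences:
        if len(seq) >= n:
            c.update(seq[i : i + n] for i in range(len(seq) - n + 1))
    return c


def build_dictionary(
    proteome: Proteome, nmin: int = NMIN_DEFAULT, nmax: int = NMAX_DEFAULT
) -> WordDictionary:
    """Count 2-12 mer words and retain those observed at least twice.

    Counting is overlapping (stride-1 sliding window) and per-ORF.  The
    expected count and residual distance of every retained word are
    computed against the same proteome's composition and submer counts.
    """
    if not (2 <= nmin <= nmax):
        raise ValueError(f"need 2 <= nmin <= nmax, got nmin={nmin}, nmax={nmax}")
    seqs = proteome.sequences
    composition = CompositionTable.from_proteome(proteome)
    window_totals = {n: window_total(seqs, n) for n in range(nmin, nmax + 1)}

    entries: dict[str, WordEntry] = {}
    prev_counts: Counter | None = None  # raw (unfiltered) counts at length n-1
    for n in range(nmin, nmax + 1):
        counts = count_words(seqs, n)
        if n == nmin:
            prev = count_words(seqs, n - 1) if n - 1 >= 2 else None
        else:
            prev = prev_counts
        wn = window_totals[n]
        wprev = window_total(seqs, n - 1)
        for word, obs in counts.items():
            if obs < 2:
                continue
            p = _expected_frequency(word, composition, prev, wprev)
            exp = p * wn
            entries[word] = WordEntry(word, obs, exp, abs(obs - exp) / SQRT2)
        prev_counts = counts

    return WordDictionary(
        proteome.genome_id,
        entries,
        composition,
        window_totals,
        nmin=nmin,
        nmax=nmax,
        sequences=seqs,
    )


def _expected_frequency(
    word: str,
    composition: CompositionTable,
    submer_counts: Counter | None,
    submer_windows: int,
) -> float:
    n = len(word)
    a_first = composition[word[0]]
    a_last = composition[word[-1]]
    if n == 2:
        # both (N-1)-submers are single residues: f = a
        return 0.5 * (a_first * a_last + a_last * a_first)
    assert submer_counts is not None
    f_prefix = submer_counts.get(word[:-1], 0) / submer_windows
    f_suffix = submer_counts.get(word[1:], 0) / submer_windows
    return 0.5 * (f_prefix * a_last + f_suffix * a_first)


def expected_frequency(word: str, dictionary: WordDictionary) -> float:
    """Null-model frequency of `word` per length-N window.

    Submer frequencies are raw observed frequencies; a submer that fell
    below the retention filter is recounted on demand from the stored ORF
    sequences.  A word containing a residue with zero composition
    frequency has expected frequency 0.
    """
    n = len(word)
    if not (2 <= n <= 12):
        raise ValueError(f"word length must be in [2, 12], got {n}")
    comp = dictionary.composition
    if any(comp[c] == 0.0 for c in word):
        return 0.0
    if n == 2:
        return comp[word[0]] * comp[word[-1]]
    wprev = dictionary.window_totals.get(n - 1)
    if wprev is None:
        if dictionary.sequences is None:
            raise ValueError(f"no window total for length {n - 1}")
        wprev = window_total(dictionary.sequences, n - 1)
    f_prefix = dictionary.observed(word[:-1]) / wprev
    f_suffix = dictionary.observed(word[1:]) / wprev
    return 0.5 * (f_prefix * comp[word[-1]] + f_suffix * comp[word[0]])


def expected_count(word: str, dictionary: WordDictionary) -> float:
    """Expected observed count: expected frequency times the window total."""
    n = len(word)
    wn = dictionary.window_totals.get(n)
    if wn is None:
        if dictionary.sequences is None:
            raise ValueError(f"no window total for length {n}")
        wn = window_total(dictionary.sequences, n)
    return expected_frequency(word, dictionary) * wn


# ---------------------------------------------------------------------------
# Serialization (TSV, one file per genome)
# ---------------------------------------------------------------------------


def write_dictionary(dictionary: WordDictionary, path: str | Path) -> Path:
    """Write a dictionary as TSV (word, length, observed, expected, residual).

    Rows are ordered by length then lexicographically; header comment lines
    carry the metadata needed to rebuild the dictionary for downstream
    statistics (composition, window totals, total residues).
    """
    path = Path(path)
    comp = dictionary.composition
    with open(path, "w") as fh:
        fh.write(f"#genome_id={dictionary.genome_id}\n")
        fh.write(f"#nmin={dictionary.nmin}\tnmax={dictionary.nmax}\n")
        fh.write(f"#total_residues={comp.total_residues}\n")
        fh.write(
            "#composition="
            + ",".join(f"{aa}:{comp[aa]:.12g}" for aa in AMINO_ACIDS)
            + "\n"
        )
        fh.write(
            "#window_totals="
            + ",".join(f"{n}:{w}" for n, w in sorted(dictionary.window_totals.items()))
            + "\n"
        )
        fh.write("word\tlength\tobserved\texpected\tresidual\n")
        for word in sorted(dictionary.entries, key=lambda w: (len(w), w)):
            e = dictionary.entries[word]
            fh.write(f"{e.word}\t{len(e.word)}\t{e.observed}\t{e.expected:.10g}\t{e.residual:.10g}\n")
    return path


def read_dictionary(path: str | Path) -> WordDictionary:
    """Read a dictionary written by :func:`write_dictionary`.

    The re-read dictionary carries no ORF sequences, so raw counts of
    unretained words are unavailable (``observed`` returns 0 for them).
    """
    path = Path(path)
    meta: dict[str, str] = {}
    entries: dict[str, WordEntry] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                for part in line[1:].split("\t"):
                    k, _, v = part.partition("=")
                    meta[k] = v
                continue
            if line.startswith("word\t") or not line:
                continue
            word, _length, obs, exp, res = line.split("\t")
            entries[word] = WordEntry(word, int(obs), float(exp), float(res))
    total = int(meta["total_residues"])
    freq = {
        k: float(v)
        for k, v in (p.split(":") for p in meta["composition"].split(","))
    }
    # renormalize away serialization rounding so the invariant holds exactly
    s = sum(freq.values())
    freq = {k: v / s for k, v in freq.items()}
    window_totals = {
        int(k): int(v)
        for k, v in (p.split(":") for p in meta["window_totals"].split(","))
    }
    return WordDictionary(
        meta["genome_id"],
        entries,
        CompositionTable(freq, total),
        window_totals,
        nmin=int(meta.get("nmin", NMIN_DEFAULT)),
        nmax=int(meta.get("nmax", NMAX_DEFAULT)),
        sequences=None,
    )
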