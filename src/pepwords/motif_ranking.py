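"""Ranking of shared over-represented words between two genome groups.

Each word retained in at least one genome of each group gets a per-group
score: the mean residual distance of the word over the genomes in which it
is retained (genomes lacking the word are excluded from the mean by
default).  Ranking the shared words by their score ratio highlights motifs
disproportionately retained in one lifestyle — candidate functional or
structural building blocks characteristic of that group.  Scores are group
means of the residual-distance statistic; only their ranking, not their
absolute magnitude, is meaningful across datasets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .word_dictionary import WordDictionary


@dataclass(frozen=True)
class MotifScore:
    word: str
    score_a: float
    score_b: float
    ratio: float
    n_genomes_a: int
    n_genomes_b: int


def word_group_score(
    word: str,
    dictionaries: list[WordDictionary],
    include_missing_as_zero: bool = False,
) -> tuple[float, int]:
    """Group-mean residual distance of one word.

    Returns (score, number of genomes whose dictionary retains the word).
    With ``include_missing_as_zero`` genomes lacking the word contribute 0
    to the mean instead of being excluded.  A word retained nowhere scores
    0 (flagged by the zero genome count).
    """
    residuals = []
    n_with = 0
    for d in dictionaries:
        e = d.entries.get(word)
        if e is not None:
            residuals.append(e.residual)
            n_with += 1
        elif include_missing_as_zero:
            residuals.append(0.0)
    if not residuals:
        return 0.0, 0
    return float(np.mean(residuals)), n_with


def _shared_words(
    dicts_a: list[WordDictionary],
    dicts_b: list[WordDictionary],
    length: int,
) -> set[str]:
    words_a = set()
    for d in dicts_a:
        words_a.update(w for w in d.entries if len(w) == length)
    words_b = set()
    for d in dicts_b:
        words_b.update(w for w in d.entries if len(w) == length)
    return words_a & words_b


def rank_shared_words(
    dicts_a: list[WordDictionary],
    dicts_b: list[WordDictionary],
    lengths: tuple[int, int] = (6, 6),
    top_k: int = 10,
    include_missing_as_zero: bool = False,
) -> tuple[list[MotifScore], list[MotifScore]]:
    """Top-k group-A-enriched and group-B-enriched shared words.

    Words present (retained) in at least one genome of each group are
    scored in both groups; the ratio score_a/score_b ranks A-enrichment
    descending (ties broken lexicographically) and B-enrichment by the
    reciprocal.  Returns (top_a, top_b); both empty if no words are shared.
    """
    if not dicts_a or not dicts_b:
        raise ValueError("both groups must be non-empty")
    scores: list[MotifScore] = []
    for length in range(lengths[0], lengths[1] + 1):
        for word in _shared_words(dicts_a, dicts_b, length):
            sa, na = word_group_score(word, dicts_a, include_missing_as_zero)
            sb, nb = word_group_score(word, dicts_b, include_missing_as_zero)
            if sb > 0:
                ratio = sa / sb
            else:
                ratio = float("inf") if sa > 0 else 1.0
            scores.append(MotifScore(word, sa, sb, ratio, na, nb))
    if not scores:
        import logging

        logging.getLogger("pepwords").warning(
            "no shared words between the two groups in length range %s", lengths
        )
        return [], []
    top_a = sorted(scores, key=lambda s: (-s.ratio, s.word))[:top_k]
    inv = lambda s: s.score_b / s.score_a if s.score_a > 0 else (
        float("inf") if s.score_b > 0 else 1.0
    )  # noqa: E731
    top_b = sorted(scores, key=lambda s: (-inv(s), s.word))[:top_k]
    return top_a, top_b


def accumulate_by_length(
    dicts_a: list[WordDictionary],
    dicts_b: list[WordDictionary],
    lengths: tuple[int, int] = (6, 8),
    top_k: int = 10,
    include_missing_as_zero: bool = False,
) -> pd.DataFrame:
    """Per-length ranked shared-word table over a word-length range.

    Runs the shared-word ranking independently at each length and stacks
    the results; suitable input for downstream annotation of the motifs.
    """
    frames = []
    for length in range(lengths[0], lengths[1] + 1):
        top_a, top_b = rank_shared_words(
            dicts_a, dicts_b, (length, length), top_k, include_missing_as_zero
        )
        for direction, items in (("A", top_a), ("B", top_b)):
            for rank, s in enumerate(items, start=1):
                frames.append(
                    {
                        "word": s.word,
                        "length": length,
                        "enriched_in": direction,
                        "rank": rank,
                        "score_a": s.score_a,
                        "score_b": s.score_b,
                        "ratio": s.ratio,
                        "n_genomes_a": s.n_genomes_a,
                        "n_genomes_b": s.n_genomes_b,
                    }
                )
    return pd.DataFrame(
        frames,
        columns=[
            "word", "length", "enriched_in", "rank",
            "score_a", "score_b", "ratio", "n_genomes_a", "n_genomes_b",
        ],
    )


def write_motif_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path
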