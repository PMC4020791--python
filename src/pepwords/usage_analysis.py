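"""Amino acid usage profiles and between-group comparison.

Single-residue frequencies vary systematically between free-living and
pathogenic microbes (e.g. cheap-to-synthesize glycine and alanine enriched
in free-living genomes), so usage is profiled per genome and compared
between groups with Welch's unequal-variance two-sample t-test, one letter
at a time.  No multiple-testing correction is applied: the per-letter
p-values are reported raw, with an NS flag at p >= 0.05.  The report also
carries each residue's gram formula mass (GFM) so the usage ratio can be
examined against biosynthetic cost.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .proteome_io import AMINO_ACIDS, Proteome

#: Gram formula mass of each amino acid (g/mol of the free residue).
AA_MASS: dict[str, int] = {
    "A": 89, "C": 121, "D": 133, "E": 147, "F": 165, "G": 75, "H": 155,
    "I": 131, "K": 146, "L": 131, "M": 149, "N": 132, "P": 115, "Q": 147,
    "R": 174, "S": 105, "T": 119, "V": 117, "W": 181, "Y": 204,
}


@dataclass(frozen=True)
class AAUsageProfile:
    genome_id: str
    freq: dict[str, float]

    def __post_init__(self) -> None:
        s = sum(self.freq.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"usage frequencies sum to {s}, not 1")

    def __getitem__(self, letter: str) -> float:
        return self.freq.get(letter, 0.0)


def aa_frequencies(proteome: Proteome) -> AAUsageProfile:
    """Residue counts divided by total residues, over the 20-letter alphabet."""
    counts = Counter()
    for seq in proteome.sequences:
        counts.update(seq)
    total = sum(counts.values())
    return AAUsageProfile(
        proteome.genome_id, {aa: counts.get(aa, 0) / total for aa in AMINO_ACIDS}
    )


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch's two-sample t statistic, Welch-Satterthwaite df and two-sided p.

    t = (m_a - m_b) / sqrt(s_a^2/n_a + s_b^2/n_b); degenerate zero-variance
    inputs return t = 0, p = 1 when the means are equal.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    diff = a.mean() - b.mean()
    if se2 == 0.0:
        if diff == 0.0:
            return 0.0, float(na + nb - 2), 1.0
        return math_inf_signed(diff), float(na + nb - 2), 0.0
    t = diff / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def math_inf_signed(x: float) -> float:
    return float("inf") if x > 0 else float("-inf")


def group_usage_test(
    profiles_a: list[AAUsageProfile],
    profiles_b: list[AAUsageProfile],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-letter Welch comparison of mean usage between two genome groups.

    Returns a table with columns letter, GFM, mean_a, mean_b, ratio
    (mean_a / mean_b), t, df, p and a significance flag; p-values are
    uncorrected.
    """
    if len(profiles_a) < 2 or len(profiles_b) < 2:
        raise ValueError("each group needs at least 2 profiles")
    rows = []
    for aa in AMINO_ACIDS:
        xa = np.array([p[aa] for p in profiles_a])
        xb = np.array([p[aa] for p in profiles_b])
        t, df, p = welch_t(xa, xb)
        ma, mb = xa.mean(), xb.mean()
        rows.append(
            {
                "letter": aa,
                "GFM": AA_MASS[aa],
                "mean_a": ma,
                "mean_b": mb,
                "ratio": ma / mb if mb > 0 else np.nan,
                "t": t,
                "df": df,
                "p": p,
                "significance": "NS" if p >= alpha else f"p<{alpha:g}",
            }
        )
    return pd.DataFrame(rows)


def write_usage_report(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# Welch two-sample t-test per amino acid; p-values are raw "
                 "(no multiple-testing correction applied)\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    return path
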