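# Methods

## Model and procedure

`pepwords` treats a proteome as a corpus of amino acid "words": contiguous
runs of 2–12 residues inside single proteins. The quantity of interest is
how far a genome's word usage departs from a **null recombination model**
in which words arise by chance combination of their parts.

**Expected counts.** The expected frequency of a length-*N* word is the
arithmetic mean over its two (N−1)-submers of (submer frequency × terminal
residue composition frequency):

    p_exp(w) = ½ [ f(prefix) · a(last) + f(suffix) · a(first) ]

Submer frequencies are *raw* observed window frequencies (count divided by
the number of (N−1)-windows), even when the submer itself fell below the
retention filter — the filter governs which entries are stored, not the
expectation model. For N = 2 both terms collapse to the product of
composition frequencies, reproducing the 0.25% expectation for a
homodipeptide of a residue used at 5%. Expected counts are expected
frequencies times the number of length-N windows; summed over all possible
words of one length they reproduce the window total exactly, which the test
suite asserts.

**Residual distance.** Per word, over/under-representation is the
perpendicular distance of (observed, expected) from the 1:1 line,
d = |O − E| / √2; it is symmetric in sign of the deviation and zero exactly
on the equilibrium line. The genome statistic is the sum of d over all
retained words. The typeset form of this definition is implemented from its
prose statement (perpendicular point-to-line distance, then a plain sum).

**Null subtraction.** Each genome's shuffled copy — concatenate all
residues, Fisher–Yates shuffle, re-divide into the original ORF lengths —
preserves composition, protein count and protein lengths exactly, so the
adjusted distance (native minus shuffled) isolates repetition structure
that composition cannot explain. Ten shuffle passes are applied as
configured; a single correct Fisher–Yates pass already yields a uniform
permutation, so the extra passes are statistically redundant but kept for
procedural fidelity. One seeded replicate is the default; a config option
averages the random distance over several replicates.

**Repeat vectors.** Dictionaries are condensed into fixed-length vectors
indexed by repetition level i (default length 30,000): either the number of
unique words observed exactly i times (COUNT mode) or their summed residual
distance (DISTANCE mode, the default used for group comparison — the two
readings of the bin content coexist behind the `mode` switch because both
are legitimate summaries; DISTANCE carries the effect-size information).
Levels 0 and 1 are empty by construction (retention requires ≥ 2
observations); levels at or above `max_repeat − 1` accumulate in the last
element rather than erroring, since an array of length `max_repeat` cannot
index level `max_repeat` itself. Bins are normalized by the non-redundant
proteome's residue count so genomes of different sizes are comparable.

**Discrimination.** Euclidean (default) or Bray–Curtis distances between
repeat vectors feed an MDS embedding: classical Torgerson double-centering
eigendecomposition (default; deterministic up to sign, fixed by orienting
each axis so its largest-magnitude coordinate is positive) or scikit-learn's
non-metric MDS from a seeded start. In the embedding, the two-class Fisher
axis w ∝ S_w⁻¹(μ₁ − μ₂) is computed with a ridge of 1e-8 · tr(S_w)/k on the
within-class scatter (degenerate scatters can arise under permutation), and
the statistic is the centroid separation |w·(μ₁ − μ₂)| along the
unit-normalized axis. Significance is a Monte-Carlo permutation test with
group sizes preserved and the add-one estimator
p = (1 + #{null ≥ observed}) / (1 + M), which is exactly valid and never
returns zero. An MRPP-style alternative statistic (group-size-weighted
within-group mean distance) is available behind the `statistic` option as a
cross-check; the LDA path is canonical. The multi-group variant (lifestyle
× gram) runs all pairwise tests plus an omnibus statistic, the mean
pairwise centroid separation, permuted over the full label vector.

**Usage comparison.** Per-letter Welch (unequal-variance) t-tests on
per-genome frequencies, with the Welch–Satterthwaite df computed in closed
form and p from the t distribution. p-values are reported raw — no
multiple-testing correction — with an NS flag at p ≥ 0.05; the report
includes each residue's gram formula mass so usage ratios can be related to
biosynthetic cost. Frequencies are computed on the redundancy-filtered
proteome by default (consistent with every other stage); a flag computes
them before clustering instead, since usage tables are sometimes defined
over all annotated proteins.

**Motif ranking.** A word's group score is the mean residual distance over
the genomes in which it is retained; genomes lacking the word are excluded
from the mean by default (a flag counts them as zero instead — exclusion
was chosen because a word absent from a small genome says little about
selection on it). Shared words (retained in ≥ 1 genome of each group) are
ranked by score ratio in both directions. Score magnitudes depend on genome
size and corpus; only rankings are comparable across datasets.

## Redundancy clustering

The 95%-identity preprocessing is re-implemented rather than shelling out
to CD-HIT: greedy incremental clustering, ORFs visited longest-first, each
candidate joining the first cluster whose representative shares ≥ threshold
ungapped identity at the best offset, measured against the shorter
sequence's length (CD-HIT's convention); the longest member represents each
cluster and survivors keep their original order. Candidate offsets are
enumerated from shared exact 4-mers: at ≥ 85% identity over the shorter
sequence, any qualifying ungapped alignment must contain an exact run of at
least 4 residues, so the seed index can only skip offsets that could not
qualify — it never causes a false merge, and identity is always computed
exactly at the evaluated offsets. Thresholds below 0.85 fall back to a full
offset scan. A global-alignment identity is not used; for the
near-duplicate regime this filter targets, ungapped comparison is the
appropriate kernel.

## Sanitization

Non-standard residues (B, J, O, U, X, Z, stop `*`, gaps) are removed before
any counting, because the expectation model requires an exactly 20-letter
alphabet; ORFs emptied by removal are dropped with a warning. A record that
is empty before sanitization is treated as malformed input and raises.

## Synthetic data: what it emulates, and what it does not

The generator draws ORF lengths from a truncated normal (defaults mean 300,
sd 100, minimum 12 — typical bacterial protein scale) and residues i.i.d.
from a composition preset: uniform, or an empirical free-living-like
composition. Planted motifs overwrite uniformly chosen non-overlapping
in-ORF windows, leaving ORF counts and lengths untouched and recording
every insertion in a ground-truth manifest. Cohort defaults are 15 genomes
per group and 60 ORFs per genome — deliberately desk-scale; real bacterial
proteomes have thousands of proteins, and the statistical tests in this
package scale with no change to the code.

What the synthetic data does **not** emulate: phylogenetic correlation
among genomes (each genome is independent), real protein domain structure
and amino acid autocorrelation (residues are i.i.d. given composition),
codon/nucleotide-level effects, and the long-tailed word-repetition spectra
of real genomes. Passing tests therefore demonstrate correctness of the
statistics and calibration of the tests under exchangeable nulls — not that
real free-living and pathogen genomes separate; that is an empirical claim
about real data.

## Numerical and design choices

- **Determinism.** Every source of randomness is seeded; per-genome and
  per-stage seeds are derived from the run seed via `numpy`'s
  `SeedSequence` spawning, so a config + seed reproduces every output file
  byte for byte.
- **Expectation at the range boundary.** `build_dictionary` computes
  expectations for retained words from the unfiltered (N−1) counts of the
  same pass; every submer of a retained word is itself observed ≥ 2 times,
  so serialized dictionaries are self-contained for all stored entries.
  On-demand queries of arbitrary words re-count submers from the retained
  ORF sequences.
- **Zero-composition letters** give expected frequency 0 rather than an
  error; a word absent from the alphabet cannot recombine.
- **Degenerate Welch inputs** (zero variance in both groups) return t = 0,
  p = 1 when the means agree, ±∞ and p = 0 when they differ.
- **Ties in motif ranking** are broken lexicographically for reproducible
  output.
- **Problem sizes in the statistical test suite** (e.g. 200 calibration
  replicates of 15+15 genomes with 20 ORFs of ~80 residues; 20-seed effect
  recovery with 60 ORFs of ~200 residues) are the package's chosen
  desk-scale study conditions: large enough for the binomial/KS bands used,
  small enough to run routinely.

## Known limitations

- The expectation model is first-order in the submers; higher-order
  dependence (real proteins are not Markovian in their residues) inflates
  residual distances for all genomes alike, which is why the shuffled-copy
  subtraction, not the raw total, is the comparable statistic.
- Greedy clustering is order-dependent (longest-first), as is CD-HIT's; a
  different visiting order can produce slightly different survivor sets
  near the threshold.
- The non-metric MDS path inherits scikit-learn's local-minimum behaviour;
  the classical path is the deterministic default.
- Score magnitudes in the motif ranking are not comparable across corpora
  of different sizes; only within-analysis rankings are meaningful.
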