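# pepwords

Comparative analysis of **peptide word usage** in microbial proteomes.

Free-living and pathogenic microbes differ in how strongly they reuse short
amino acid "words" (peptide N-mers) across their proteins. `pepwords`
quantifies that repetition structure genome by genome and tests whether it
separates lifestyle groups. It is aimed at comparative genomicists working
with predicted proteomes (multi-FASTA amino acid files) and a metadata table
assigning each genome a lifestyle label (`FREE` / `PATH`) and optionally a
gram stain.

## The method

For each genome the pipeline:

1. **Removes redundant proteins** by greedy clustering at 95% sequence
   identity (CD-HIT-style, longest-first representatives), so duplicated
   genes do not masquerade as word repetition.
2. **Counts words**: every contiguous window of *N* = 2…12 residues within
   a protein (sliding window, stride 1; windows never cross protein
   boundaries). Words observed at least twice are retained in the genome's
   dictionary.
3. **Computes each word's expected count** under a null recombination
   model. For a word *w* of length *N* with prefix/suffix (N−1)-submers,

   ```
   p_exp(w) = ½ [ f(w[1..N−1]) · a(w[N])  +  f(w[2..N]) · a(w[1]) ]
   ```

   where *f* is the raw submer window frequency and *a* the single-residue
   composition frequency; the expected count is `p_exp(w)` times the number
   of length-*N* windows. For a dipeptide this reduces to `a(x)·a(y)` — a
   genome using alanine at 5% expects the homodipeptide `AA` at 0.25% of
   dipeptide windows.
4. **Measures over-representation** as the perpendicular residual distance
   of the (observed, expected) point from the 1:1 line,
   `d(w) = |O − E| / √2`, and sums it over all retained words. Subtracting
   the same statistic computed on a **shuffled copy** of the proteome
   (Fisher–Yates shuffle of the concatenated residues, 10 passes, re-divided
   into the original ORF lengths) gives the *adjusted distance*: repetition
   beyond what composition alone produces.
5. **Condenses each dictionary into a 30,000-bin repeat vector**: element
   *i* holds the residual distance (or unique-word count) of words observed
   exactly *i* times, normalized by proteome size — a genome fingerprint
   comparable across genomes.
6. **Tests group separation**: pairwise distances between repeat vectors →
   MDS embedding → two-class Fisher LDA axis → distance between group
   centroids along the axis, with a Monte-Carlo permutation test
   (10,000 label reshuffles by default; p-value from the add-one
   estimator). Gram labels, when present, trigger the four-group
   (lifestyle × gram) variant. Per-letter amino acid usage is compared with
   Welch's t-test, and shared 6-mers are ranked by their group score ratio
   to surface lifestyle-enriched motifs.

A synthetic-data module generates proteome cohorts with controlled
composition, ORF structure and *planted* repeated words at known copy
numbers, so every stage is testable at known effect sizes without any
genome downloads.

## Worked example

Generate a 16-genome synthetic cohort in which the free-living group
carries two planted 6-mer words at 25 copies per genome (the pathogen
group carries 3 copies), then run the full pipeline:

```python
from pathlib import Path
from pepwords import CohortSpec, PipelineConfig, generate_cohort, run_pipeline

spec = CohortSpec(
    n_genomes_per_group=8,
    n_orfs=40,
    orf_length_distribution=(200.0, 50.0),
    planted_motifs=(("MKVLAW", 25, 3), ("QQQPPP", 25, 3)),
    seed=42,
)
table, manifest, _ = generate_cohort(spec, "example/cohort")
cfg = PipelineConfig(group_table_path=str(table), output_dir="example/run",
                     permutations=999, seed=7)
run_dir = run_pipeline(cfg)
print((run_dir / "summary.txt").read_text())
```

which prints:

```
pepwords run summary

  FREE: n=8  mean adjusted distance=628.7
  PATH: n=8  mean adjusted distance=71.56

  MDS-LDA centroid separation: 0.0325703
  permutation p-value: 0.001 (999 permutations)
```

The planted repetition raises the free-living group's adjusted word
distance roughly nine-fold above the pathogen group's, and no label
permutation out of 999 matches the observed centroid separation
(p = 1/1000, the smallest value the add-one estimator can return). The
ranked-motif table (`ranked_motifs.tsv`) recovers the planted words at the
top of the free-living-enriched list:

```
  word  length enriched_in  rank  score_a  score_b   ratio
MKVLAW       6           A     1 17.32400  2.08200 8.32084
QQQPPP       6           A     2 16.83260  2.03673 8.26450
```

The same pipeline is available from the shell via the `pepwords` command
(`generate`, `dict`, `distance`, `vectors`, `discriminate`, `usage`,
`motifs`, `run`, `summarize`).

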