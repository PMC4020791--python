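"""End-to-end pipeline: ingest, cluster, shuffle, count, compare, report.

Stages, in run order: read the group table and FASTA files; remove
redundant proteins; profile amino acid usage and compare groups; shuffle
each proteome into its randomized copy; build native and random word
dictionaries; summarize total/adjusted word distances; condense
dictionaries to repeat vectors and group means; embed and test group
separation (MDS + LDA + permutation test, plus the four-group variant when
gram labels are present); rank shared 6-mer motifs between groups.  All
outputs are plain tabular files in the run directory, and a given config
and seed reproduce them byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    group_discrimination as gd,
    motif_ranking,
    null_model,
    proteome_io,
    usage_analysis,
    word_dictionary,
    word_statistics as ws,
)
from .proteome_io import Gram, GroupTable, Label, Proteome

logger = logging.getLogger("pepwords")


@dataclass
class PipelineConfig:
    """Run parameters; defaults follow the method's canonical settings
    (2-12 mer words, 30,000 repeat bins, 10 shuffle passes, 10,000
    permutations, 95% identity clustering)."""

    group_table_path: str = ""
    output_dir: str = "pepwords_run"
    nmin: int = 2
    nmax: int = 12
    max_repeat: int = 30_000
    vector_mode: str = "DISTANCE"
    metric: str = "EUCLIDEAN"
    mds_method: str = "CLASSICAL"
    mds_k: int = 2
    permutations: int = 10_000
    shuffle_iterations: int = 10
    shuffle_replicates: int = 1
    identity_threshold: float = 0.95
    usage_before_clustering: bool = False
    single_chromosome_only: bool = False
    motif_lengths: tuple[int, int] = (6, 6)
    motif_top_k: int = 10
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "motif_lengths" in raw:
            raw["motif_lengths"] = tuple(raw["motif_lengths"])
        return cls(**raw)

    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["motif_lengths"] = list(self.motif_lengths)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)
        return path


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return out
        return wrapper
    return deco


@_stage("ingest")
def load_proteomes(table: GroupTable, base: Path | None = None) -> list[Proteome]:
    proteome_io.resolve_group_table(table, base)
    proteomes = []
    for row in table.rows.itertuples(index=False):
        fp = Path(row.fasta_path)
        if base is not None and not fp.is_absolute():
            fp = base / fp
        proteomes.append(
            proteome_io.read_fasta(
                fp,
                genome_id=row.genome_id,
                label=Label(row.label),
                gram=Gram(row.gram),
            )
        )
    logger.info("loaded %d proteomes", len(proteomes))
    return proteomes


def _seed_of(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % 2**31)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and write all reports into the run directory."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_file(outdir / "config.yaml")
    shuffle_root, mds_ss, perm_ss, mg_ss = np.random.SeedSequence(config.seed).spawn(4)

    table = proteome_io.read_group_table(config.group_table_path)
    if config.single_chromosome_only and "single_chromosome" in table.rows.columns:
        keep = table.rows["single_chromosome"].astype(str).str.lower().isin(
            ("1", "true", "yes")
        )
        table = GroupTable(table.rows[keep].reset_index(drop=True))
        logger.info("single-chromosome filter kept %d genomes", len(table))
    proteomes = load_proteomes(table, Path(config.group_table_path).parent)

    # -- redundancy clustering ------------------------------------------------
    raw = proteomes
    proteomes = [
        proteome_io.cluster_redundant(p, config.identity_threshold) for p in raw
    ]

    # -- amino acid usage ------------------------------------------------------
    usage_source = raw if config.usage_before_clustering else proteomes
    profiles = {p.genome_id: usage_analysis.aa_frequencies(p) for p in usage_source}
    free_profiles = [profiles[p.genome_id] for p in proteomes if p.label is Label.FREE]
    path_profiles = [profiles[p.genome_id] for p in proteomes if p.label is Label.PATH]
    if len(free_profiles) >= 2 and len(path_profiles) >= 2:
        usage_table = usage_analysis.group_usage_test(free_profiles, path_profiles)
        usage_analysis.write_usage_report(usage_table, outdir / "usage_test.tsv")

    # -- dictionaries and distances -------------------------------------------
    dict_dir = outdir / "dictionaries"
    dict_dir.mkdir(exist_ok=True)
    native_dicts: dict[str, word_dictionary.WordDictionary] = {}
    random_dicts: dict[str, word_dictionary.WordDictionary] = {}
    summaries: list[ws.DistanceSummary] = []
    shuffle_seeds = shuffle_root.spawn(len(proteomes))
    for i, p in enumerate(proteomes):
        nd = word_dictionary.build_dictionary(p, config.nmin, config.nmax)
        native_dicts[p.genome_id] = nd
        word_dictionary.write_dictionary(nd, dict_dir / f"{p.genome_id}.tsv")

        # one or more shuffle replicates; distances averaged over replicates
        rep_dicts = []
        replicate_seeds = shuffle_seeds[i].spawn(config.shuffle_replicates)
        for r in range(config.shuffle_replicates):
            shuffled = null_model.shuffle_proteome(
                p,
                null_model.ShuffleSpec(
                    config.shuffle_iterations, _seed_of(replicate_seeds[r])
                ),
            )
            rep_dicts.append(
                word_dictionary.build_dictionary(shuffled, config.nmin, config.nmax)
            )
        rd = rep_dicts[0]
        random_dicts[p.genome_id] = rd
        word_dictionary.write_dictionary(rd, dict_dir / f"{p.genome_id}_random.tsv")
        mean_random = float(
            np.mean([ws.total_word_distance(d) for d in rep_dicts])
        )
        summaries.append(
            ws.DistanceSummary(
                genome_id=p.genome_id,
                total_distance=ws.total_word_distance(nd),
                random_distance=mean_random,
                genome_size_aa=p.total_residues,
            )
        )

    dist_df = pd.DataFrame(
        {
            "genome_id": [s.genome_id for s in summaries],
            "label": [p.label.value for p in proteomes],
            "gram": [p.gram.value for p in proteomes],
            "total_distance": [s.total_distance for s in summaries],
            "random_distance": [s.random_distance for s in summaries],
            "adjusted_distance": [s.adjusted_distance for s in summaries],
            "genome_size_aa": [s.genome_size_aa for s in summaries],
            "genome_size_nt": [s.genome_size_nt for s in summaries],
        }
    )
    dist_df.to_csv(outdir / "distance_summary.tsv", sep="\t", index=False,
                   float_format="%.10g")

    # -- repeat vectors ---------------------------------------------------------
    mode = ws.VectorMode(config.vector_mode)
    vectors = [
        ws.repeat_vector(native_dicts[p.genome_id], mode, config.max_repeat)
        for p in proteomes
    ]
    ws.write_repeat_vectors(vectors, outdir / "repeat_vectors.tsv")
    group_means = []
    for lab in (Label.FREE, Label.PATH):
        group = [v for v, p in zip(vectors, proteomes) if p.label is lab]
        if group:
            group_means.append(
                ws.group_mean_vector(group, genome_id=f"{lab.value}_mean")
            )
    if group_means:
        ws.write_repeat_vectors(group_means, outdir / "group_mean_vectors.tsv")

    # -- discrimination ---------------------------------------------------------
    labeled = [
        (v, p) for v, p in zip(vectors, proteomes) if p.label is not Label.UNLABELED
    ]
    n_excluded = len(proteomes) - len(labeled)
    if n_excluded:
        logger.info("%d UNLABELED genomes excluded from group tests", n_excluded)
    result_meta: dict = {"n_labeled": len(labeled), "n_unlabeled": n_excluded}
    labels = np.array([p.label.value for _, p in labeled])
    if len(labeled) >= 4 and len(set(labels)) == 2 and min(
        np.count_nonzero(labels == l) for l in set(labels)
    ) >= 2:
        dm = gd.vector_distance_matrix([v for v, _ in labeled], gd.Metric(config.metric))
        coords = gd.mds_embed(
            dm, k=config.mds_k, method=gd.MdsMethod(config.mds_method),
            seed=_seed_of(mds_ss),
        )
        res = gd.permutation_test(
            coords,
            labels,
            m_permutations=config.permutations,
            seed=_seed_of(perm_ss),
            genome_ids=tuple(p.genome_id for _, p in labeled),
        )
        coord_df = pd.DataFrame(
            coords, columns=[f"dim{i+1}" for i in range(coords.shape[1])]
        )
        coord_df.insert(0, "genome_id", [p.genome_id for _, p in labeled])
        coord_df["label"] = labels
        coord_df["projection"] = res.projections
        coord_df.to_csv(outdir / "mds_coordinates.tsv", sep="\t", index=False,
                        float_format="%.10g")
        hist, edges = np.histogram(res.null_separations, bins=50)
        pd.DataFrame(
            {"bin_left": edges[:-1], "bin_right": edges[1:], "count": hist}
        ).to_csv(outdir / "null_separation_histogram.tsv", sep="\t", index=False,
                 float_format="%.10g")
        result_meta.update(
            {
                "centroid_separation": res.centroid_separation,
                "p_value": res.p_value,
                "permutations": res.n_permutations,
                "seed": config.seed,
            }
        )

        # four-group variant when gram labels are present
        grams = np.array([p.gram.value for _, p in labeled])
        if set(grams) - {Gram.UNKNOWN.value}:
            combo = np.array(
                [f"{l}_{g}" for l, g in zip(labels, grams) if g != Gram.UNKNOWN.value]
            )
            mask = grams != Gram.UNKNOWN.value
            counts = pd.Series(combo).value_counts()
            if len(counts) >= 2 and counts.min() >= 2:
                mg = gd.multigroup_test(
                    coords[mask],
                    combo,
                    m_permutations=config.permutations,
                    seed=_seed_of(mg_ss),
                )
                result_meta["multigroup"] = {
                    "groups": list(mg.groups),
                    "pairwise": [
                        {
                            "group_1": g1,
                            "group_2": g2,
                            "separation": mg.pairwise_separation[(g1, g2)],
                            "p_value": mg.pairwise_p[(g1, g2)],
                        }
                        for g1, g2 in mg.pairwise_separation
                    ],
                    "omnibus_separation": mg.omnibus_separation,
                    "omnibus_p": mg.omnibus_p,
                }
    with open(outdir / "discrimination.json", "w") as fh:
        json.dump(result_meta, fh, indent=1, sort_keys=True)

    # -- motif ranking -----------------------------------------------------------
    dicts_free = [
        native_dicts[p.genome_id] for p in proteomes if p.label is Label.FREE
    ]
    dicts_path = [
        native_dicts[p.genome_id] for p in proteomes if p.label is Label.PATH
    ]
    if dicts_free and dicts_path:
        motif_table = motif_ranking.accumulate_by_length(
            dicts_free, dicts_path, config.motif_lengths, config.motif_top_k
        )
        motif_ranking.write_motif_table(motif_table, outdir / "ranked_motifs.tsv")

    summary = summarize_run(outdir)
    (outdir / "summary.txt").write_text(summary)
    return outdir


REQUIRED_ARTIFACTS = ("config.yaml", "distance_summary.tsv", "repeat_vectors.tsv",
                      "discrimination.json")


def summarize_run(run_dir: str | Path) -> str:
    """One-page text summary of a completed run directory."""
    run_dir = Path(run_dir)
    missing = [a for a in REQUIRED_ARTIFACTS if not (run_dir / a).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run {run_dir}: missing {missing}")
    dist = pd.read_csv(run_dir / "distance_summary.tsv", sep="\t")
    with open(run_dir / "discrimination.json") as fh:
        disc = json.load(fh)

    lines = ["pepwords run summary", ""]
    for lab, sub in dist.groupby("label"):
        lines.append(
            f"  {lab}: n={len(sub)}  mean adjusted distance="
            f"{sub['adjusted_distance'].mean():.4g}"
        )
    if disc.get("n_unlabeled"):
        lines.append(
            f"  ({disc['n_unlabeled']} UNLABELED genomes excluded from group tests)"
        )
    if "centroid_separation" in disc:
        lines.append("")
        lines.append(
            f"  MDS-LDA centroid separation: {disc['centroid_separation']:.6g}"
        )
        lines.append(
            f"  permutation p-value: {disc['p_value']:.6g} "
            f"({disc['permutations']} permutations)"
        )
    if "multigroup" in disc:
        lines.append("  four-group (lifestyle x gram) omnibus "
                     f"p = {disc['multigroup']['omnibus_p']:.6g}")
    return "\n".join(lines) + "\n"
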