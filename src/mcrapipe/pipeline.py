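"""End-to-end orchestration: merge -> size-select -> chimera -> ORF ->
cluster -> parsimony taxonomy -> community statistics.

Stages operate on dereplicated representations (sequence -> per-sample
counts); identical reads process identically, so this matches per-read
processing while keeping deep libraries tractable.  Every stage emits a
:class:`StageReport` whose counts are conserved (input = output + sum of
rejections), and all randomness derives from the single configured seed.
"""

from __future__ import annotations

import time
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .chimera import DerepAmplicon, filter_chimeras, verdicts_frame
from .cluster import (
    ClusterCountMatrix,
    DerepPeptide,
    MCRACluster,
    apply_min_fraction,
    build_count_matrix,
    greedy_cluster,
)
from .config import PipelineConfig
from .io import ReadPair, SampleSheet, read_fastq_pairs, write_fasta
from .merge import length_filter, merge_pairs
from .orf import MCRAPeptide, PrimerPair, screen_orf
from .phylo import (
    SupportedTree,
    align_to_panel,
    assign_taxonomy,
    bootstrap_support,
    mask_columns,
    mp_search,
)
from .stats import (
    anova_tukey,
    braycurtis_matrix,
    diversity_table,
    group_means,
    heatmap_export,
    kruskal_bh,
    nmds,
    pairwise_wilcoxon_bh,
    pcoa,
)


@dataclass
class StageReport:
    stage: str
    n_in: int
    n_out: int
    rejected: dict[str, int] = field(default_factory=dict)
    wall_time: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_in != self.n_out + sum(self.rejected.values()):
            raise ValueError(
                f"stage {self.stage}: {self.n_in} in != {self.n_out} out "
                f"+ {sum(self.rejected.values())} rejected"
            )

    def log_line(self) -> str:
        rej = " ".join(f"{k}={v}" for k, v in sorted(self.rejected.items()))
        return (f"[{self.stage}] in={self.n_in} out={self.n_out} {rej} "
                f"time={self.wall_time:.1f}s")


@dataclass
class PipelineResult:
    reports: list[StageReport]
    matrix: ClusterCountMatrix
    clusters: list[MCRACluster]
    verdicts: pd.DataFrame
    abundance: pd.DataFrame | None = None
    taxonomy: dict | None = None
    tree: SupportedTree | None = None
    alignment_positions: int | None = None
    stats: dict | None = None

    def log(self) -> str:
        return "\n".join(r.log_line() for r in self.reports)


def _prepare_sample(sample: str, pairs: Iterable[ReadPair],
                    cfg: PipelineConfig) -> tuple[Counter, dict[str, int], int]:
    """Merge and size-select one library; returns (sequence counts,
    rejection counts, input count)."""
    merged, rejected = merge_pairs(pairs, cfg.min_overlap, cfg.max_mismatch_rate)
    retained, off_length = length_filter(merged, cfg.amplicon_length,
                                         cfg.amplicon_tolerance)
    rej: dict[str, int] = Counter(r.reason for r in rejected)
    rej["length"] = len(off_length)
    seqs = Counter(a.sequence for a in retained)
    return seqs, dict(rej), len(merged) + len(rejected)


def run_pipeline(
    sample_reads: Mapping[str, Iterable[ReadPair]],
    treatments: Mapping[str, str],
    config: PipelineConfig | None = None,
    panel=None,
    run_phylo: bool = True,
    run_stats: bool = True,
) -> PipelineResult:
    """Run the full pipeline on per-sample read iterables.

    ``panel`` (a ReferencePanel) supplies both the reference chimera pool
    and the labelled leaves for taxonomy assignment; without it the
    chimera filter runs de novo only and the phylogeny stage is skipped.
    """
    cfg = config or PipelineConfig()
    if not sample_reads:
        raise ValueError("no samples")
    unknown = set(sample_reads) - set(treatments)
    if unknown:
        raise ValueError(f"samples without treatment label: {sorted(unknown)}")
    reports: list[StageReport] = []

    # merge + size selection, per sample
    t0 = time.time()
    per_sample: dict[str, Counter] = {}
    merge_rej: Counter = Counter()
    n_pairs = 0
    for sample in sorted(sample_reads):
        seqs, rej, n_in = _prepare_sample(sample, sample_reads[sample], cfg)
        per_sample[sample] = seqs
        merge_rej.update(rej)
        n_pairs += n_in
    n_merged = sum(sum(c.values()) for c in per_sample.values())
    reports.append(StageReport("merge+size", n_pairs, n_merged,
                               dict(merge_rej), time.time() - t0))

    # pooled dereplication
    pooled: dict[str, dict[str, int]] = {}
    for sample, seqs in per_sample.items():
        for seq, n in seqs.items():
            pooled.setdefault(seq, {})[sample] = n
    ordered = sorted(pooled, key=lambda s: (-sum(pooled[s].values()), s))
    dereps = [DerepAmplicon(f"amp{i + 1}", seq, sum(pooled[seq].values()))
              for i, seq in enumerate(ordered)]

    # chimera removal (de novo + reference)
    t0 = time.time()
    panel_pool = None
    if panel is not None:
        panel_pool = [DerepAmplicon(e.id, panel.template(e.id), 1) for e in panel]
    clean, flagged, verdicts = filter_chimeras(dereps, panel_pool, cfg)
    n_clean = sum(a.abundance for a in clean)
    reports.append(StageReport(
        "chimera", n_merged, n_clean,
        {"chimera": sum(a.abundance for a in flagged)}, time.time() - t0))

    # six-frame primer-anchored translation
    t0 = time.time()
    primers = PrimerPair.from_config(cfg)
    length_range = (cfg.peptide_length_min, cfg.peptide_length_max)
    pep_counts: dict[str, dict[str, int]] = {}
    orf_rej: Counter = Counter()
    n_peptides = 0
    for amp in clean:
        outcome = screen_orf(amp.sequence, primers, length_range, amp.id)
        counts = pooled[amp.sequence]
        if isinstance(outcome, MCRAPeptide):
            acc = pep_counts.setdefault(outcome.sequence, {})
            for sample, n in counts.items():
                acc[sample] = acc.get(sample, 0) + n
            n_peptides += sum(counts.values())
        else:
            orf_rej[outcome.reason] += sum(counts.values())
    reports.append(StageReport("orf", n_clean, n_peptides, dict(orf_rej),
                               time.time() - t0))

    # greedy clustering + abundance floor
    t0 = time.time()
    peptides = [DerepPeptide(seq, counts) for seq, counts in pep_counts.items()]
    if not peptides:
        raise ValueError("no peptides survived the ORF screen")
    clusters = greedy_cluster(peptides, cfg.cluster_identity)
    retained, retained_fraction = apply_min_fraction(clusters,
                                                     cfg.cluster_min_fraction)
    matrix = build_count_matrix(retained, dict(treatments), retained_fraction)
    n_retained = sum(c.total for c in retained)
    reports.append(StageReport("cluster", n_peptides, n_retained,
                               {"below_floor": n_peptides - n_retained},
                               time.time() - t0))

    result = PipelineResult(reports, matrix, retained, verdicts_frame(verdicts))

    # parsimony placement + taxonomy
    if run_phylo and panel is not None:
        t0 = time.time()
        seed = cfg.stage_seed("phylo")
        centroids = {c.cluster_id: c.centroid for c in retained}
        alignment = mask_columns(align_to_panel(centroids, panel),
                                 cfg.site_coverage_min)
        result.alignment_positions = alignment.n_positions
        best, _ = mp_search(alignment, cfg.random_addition_reps, cfg.spr_level,
                            seed=seed)
        supported = bootstrap_support(
            alignment, reps=cfg.bootstrap_reps,
            collapse_below=cfg.collapse_support,
            seed=cfg.stage_seed("bootstrap"),
            addition_reps=cfg.bootstrap_addition_reps, best_trees=best)
        result.tree = supported
        result.taxonomy = assign_taxonomy(supported, panel.taxonomy_map())
        reports.append(StageReport("phylo", len(retained), len(retained), {},
                                   time.time() - t0, seed))

    # community statistics
    if run_stats:
        t0 = time.time()
        abundance = matrix.relative_abundance()
        result.abundance = abundance
        stats_treatments = {s: t for s, t in treatments.items()
                            if s in abundance.index}
        stats: dict = {"group_means": group_means(abundance, stats_treatments)}
        stats["kruskal"] = kruskal_bh(abundance, stats_treatments, cfg.fdr_alpha)
        stats["wilcoxon"], stats["letters"] = pairwise_wilcoxon_bh(
            abundance, stats_treatments, cfg.fdr_alpha)
        diversity = diversity_table(matrix.counts.loc[abundance.index])
        stats["diversity"] = diversity
        stats["anova"], stats["diversity_letters"] = anova_tukey(
            diversity, stats_treatments, cfg.fdr_alpha)
        bray = braycurtis_matrix(abundance)
        stats["braycurtis"] = bray
        stats["pcoa_coords"], stats["pcoa_eigvals"] = pcoa(bray)
        coords, stress, _ = nmds(bray, k=2, n_restarts=cfg.nmds_restarts,
                                 seed=cfg.stage_seed("nmds"),
                                 max_iter=cfg.nmds_max_iter, tol=cfg.nmds_tol)
        stats["nmds_coords"], stats["nmds_stress"] = coords, stress
        stats["heatmap"] = heatmap_export(abundance)
        result.stats = stats
        reports.append(StageReport("stats", len(abundance), len(abundance), {},
                                   time.time() - t0))
    return result


def run_pipeline_from_sheet(sheet: SampleSheet, config: PipelineConfig,
                            panel=None, out_dir: str | Path | None = None,
                            **kwargs) -> PipelineResult:
    """File-based entry point: stream FASTQ pairs per sample-sheet row."""
    if len(sheet) == 0:
        raise ValueError("no samples")
    sample_reads = {
        row.sample: read_fastq_pairs(row.path_r1, row.path_r2) for row in sheet
    }
    result = run_pipeline(sample_reads, sheet.treatments(), config, panel,
                          **kwargs)
    if out_dir is not None:
        write_outputs(result, Path(out_dir))
    return result


def write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    from .io import write_count_matrix

    write_count_matrix(result.matrix.counts, out_dir / "cluster_counts.tsv")
    write_fasta([(c.cluster_id, c.centroid) for c in result.clusters],
                out_dir / "centroids.faa")
    result.verdicts.to_csv(out_dir / "chimera_verdicts.tsv", sep="\t", index=False)
    if result.taxonomy is not None:
        frame = pd.DataFrame(
            [(a.cluster_id, a.family, a.genus, a.clade, a.support)
             for a in result.taxonomy.values()],
            columns=["cluster", "family", "genus", "clade", "support"])
        frame.to_csv(out_dir / "taxonomy.tsv", sep="\t", index=False)
    if result.tree is not None:
        (out_dir / "tree.nwk").write_text(result.tree.newick() + "\n")
    if result.stats is not None:
        s = result.stats
        s["group_means"].to_csv(out_dir / "table2_group_means.tsv", sep="\t")
        s["diversity"].to_csv(out_dir / "table3_diversity.tsv", sep="\t")
        s["braycurtis"].to_csv(out_dir / "braycurtis.tsv", sep="\t")
        s["pcoa_coords"].to_csv(out_dir / "pcoa_coords.tsv", sep="\t")
        s["nmds_coords"].to_csv(out_dir / "nmds_coords.tsv", sep="\t")
        s["heatmap"].to_csv(out_dir / "heatmap_grid.tsv", sep="\t")
    (out_dir / "pipeline.log").write_text(result.log() + "\n")
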