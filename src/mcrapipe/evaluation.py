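"""Study-scale evaluation runs: the 54-library recovery experiment and
the chimera-filter benchmark.

These drive the whole pipeline on simulated data under the study design
(13 R / 12 A / 15 RA / 14 AA libraries, Table-2 community profiles) and
measure how well the generating truth is recovered; the same entry points
back the acceptance checks and the reproduction script.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from .chimera import DerepAmplicon, filter_chimeras
from .config import TREATMENT_SIZES, PipelineConfig
from .pipeline import PipelineResult, run_pipeline
from .seqs import hamming_identity
from .simulate import (
    CladeSpec,
    generate_reference_panel,
    make_study_panel,
    simulate_sample,
    table2_profiles,
)


def run_study_recovery(seed: int, n_reads: int = 50_000,
                       config: PipelineConfig | None = None,
                       ) -> tuple[dict, PipelineResult]:
    """Simulate the full 54-library study noise-free and run the pipeline.

    Reads are drawn multinomially from the Table-2 treatment profiles over
    the synthetic 25-cluster panel; placement runs against the labelled
    references only.  Returns (metrics, pipeline result); the z statistics
    compare recovered group-mean cluster abundances with the generating
    proportions on the per-cell multinomial standard error of the mean.
    """
    cfg = config or PipelineConfig(seed=seed)
    panel, community, refs = make_study_panel(seed=seed)
    profiles = table2_profiles()
    reads, treatments = {}, {}
    for treatment, n_samples in TREATMENT_SIZES.items():
        for k in range(n_samples):
            sample = f"{treatment}{k + 1:02d}"
            pairs, _ = simulate_sample(
                panel, profiles[treatment], n_reads, sample_id=sample,
                seed=cfg.stage_seed(f"sim_{sample}"))
            reads[sample] = pairs
            treatments[sample] = treatment
    result = run_pipeline(reads, treatments, cfg, panel=panel.subset(refs))

    pepmap = {panel.get(c).peptide: c for c in community}
    gm = result.stats["group_means"]
    z_values = []
    cluster1_r = float("nan")
    for cluster in result.clusters:
        source = pepmap.get(cluster.centroid)
        if source is None:
            continue
        for treatment in TREATMENT_SIZES:
            p = profiles[treatment].proportions[source]
            se = np.sqrt(p * (1 - p) / n_reads / TREATMENT_SIZES[treatment])
            got = gm.loc[treatment, cluster.cluster_id] / 100.0
            z_values.append(abs(got - p) / se if se > 0 else 0.0)
        if source == "1":
            cluster1_r = float(gm.loc["R", cluster.cluster_id])
    z = np.array(z_values)
    n_correct = 0
    for cluster in result.clusters:
        source = pepmap.get(cluster.centroid)
        assignment = result.taxonomy[cluster.cluster_id]
        if source is not None and (assignment.family, assignment.genus,
                                   assignment.clade) == panel.get(source).taxonomy:
            n_correct += 1
    metrics = {
        "n_clusters": len(result.clusters),
        "retained_fraction": result.matrix.retained_fraction,
        "n_cells": len(z),
        "max_z": float(z.max()),
        "frac_within_3se": float((z <= 3.0).mean()),
        "taxonomy_accuracy": n_correct / len(result.clusters),
        "nmds_stress": float(result.stats["nmds_stress"]),
        "cluster1_R_mean": cluster1_r,
        "alignment_positions": result.alignment_positions,
    }
    return metrics, result


def chimera_benchmark(seed: int, n_bimeras: int = 400,
                      config: PipelineConfig | None = None) -> dict:
    """Operating characteristics of the chimera filter on error-free
    bimeras of two well-separated clades (parent identity <= 0.92).

    Parents are abundant (20x); bimeras are single uniform-interior
    crossovers of cross-clade parent pairs at unit abundance; the clean
    negatives are rare (1x) genuine clade members.  Returns sensitivity,
    false-positive rate and the parent identity actually realised.
    """
    cfg = config or PipelineConfig()
    rng = np.random.default_rng(seed)
    specs = [
        CladeSpec("cladeA", "FamX", "GenA", "cladeA", 26, 0.18, 3 / 157),
        CladeSpec("cladeB", "FamX", "GenB", "cladeB", 26, 0.20, 3 / 157),
    ]
    panel = generate_reference_panel(specs, peptide_length=157, seed=seed)
    by_clade: dict[str, list[str]] = {"cladeA": [], "cladeB": []}
    for entry in panel:
        by_clade[entry.clade].append(entry.id)
    abundant = by_clade["cladeA"][:4] + by_clade["cladeB"][:4]
    rare = by_clade["cladeA"][4:] + by_clade["cladeB"][4:]
    templates = {i: panel.template(i) for i in abundant + rare}
    identities = [
        hamming_identity(templates[a], templates[b])
        for a in by_clade["cladeA"][:4] for b in by_clade["cladeB"][:4]
    ]
    max_parent_identity = max(identities)

    pool = [DerepAmplicon(i, templates[i], 20) for i in abundant]
    pool += [DerepAmplicon(i, templates[i], 1) for i in rare]
    known = {d.sequence for d in pool}
    bimeras: Counter[str] = Counter()
    amp_len = len(next(iter(templates.values())))
    for _ in range(n_bimeras):
        a = abundant[int(rng.integers(4))]
        b = abundant[4 + int(rng.integers(4))]
        x = int(rng.integers(1, amp_len))
        seq = templates[a][:x] + templates[b][x:]
        bimeras[seq] += 1
    bimera_seqs = {s for s in bimeras if s not in known}
    pool += [DerepAmplicon(f"bim{i}", s, int(bimeras[s]))
             for i, s in enumerate(sorted(bimera_seqs))]

    _, flagged, _ = filter_chimeras(pool, None, cfg)
    flagged_seqs = {d.sequence for d in flagged}
    tp = sum(1 for s in bimera_seqs if s in flagged_seqs)
    fp = sum(1 for i in abundant + rare if templates[i] in flagged_seqs)
    return {
        "sensitivity": tp / len(bimera_seqs),
        "false_positive_rate": fp / len(abundant + rare),
        "n_bimeras": len(bimera_seqs),
        "n_clean": len(abundant + rare),
        "max_parent_identity": float(max_parent_identity),
    }
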