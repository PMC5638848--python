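"""Greedy centroid clustering of MCRA peptides at 97% identity.

UCLUST-style: dereplicated peptides are visited in decreasing total
abundance (ties broken lexicographically) and join the first centroid
within the identity threshold, else found a new cluster.  Identity is
global-alignment matches over alignment columns, terminal-gap columns
excluded.  Clusters below the 0.1% total-abundance floor are discarded;
survivors form the sample x cluster count matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import Align

_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1.0
_aligner.mismatch_score = 0.0
# affine gap: length-k gap costs 10 + k on the unit match scale
_aligner.open_gap_score = -11.0
_aligner.extend_gap_score = -1.0


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity, terminal-gap columns excluded."""
    if not a or not b:
        raise ValueError("empty sequence")
    if a == b:
        return 1.0
    alignment = _aligner.align(a, b)[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    non_terminal = [i for i in range(len(row_a))
                    if row_a[i] != "-" and row_b[i] != "-"]
    # terminal-gap columns are those outside the span where both rows have
    # started and not yet ended
    start_a = len(row_a) - len(row_a.lstrip("-"))
    start_b = len(row_b) - len(row_b.lstrip("-"))
    end_a = len(row_a.rstrip("-"))
    end_b = len(row_b.rstrip("-"))
    lo = max(start_a, start_b)
    hi = min(end_a, end_b)
    if hi <= lo:
        return 0.0
    matches = sum(row_a[i] == row_b[i] for i in range(lo, hi))
    return matches / (hi - lo)


@dataclass(frozen=True)
class DerepPeptide:
    """One dereplicated peptide with per-sample occurrence counts."""

    sequence: str
    counts: Mapping[str, int]

    @property
    def abundance(self) -> int:
        return sum(self.counts.values())


@dataclass
class MCRACluster:
    cluster_id: str
    centroid: str
    members: list[DerepPeptide] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(m.abundance for m in self.members)

    @property
    def per_sample(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for m in self.members:
            for sample, n in m.counts.items():
                out[sample] = out.get(sample, 0) + n
        return out


def dereplicate(peptides: Iterable[tuple[str, str]]) -> list[DerepPeptide]:
    """Collapse (sequence, sample) observations into dereplicated records."""
    acc: dict[str, dict[str, int]] = {}
    for sequence, sample in peptides:
        per_sample = acc.setdefault(sequence, {})
        per_sample[sample] = per_sample.get(sample, 0) + 1
    return [DerepPeptide(seq, counts) for seq, counts in acc.items()]


def greedy_cluster(peptides: Iterable[DerepPeptide],
                   threshold: float = 0.97) -> list[MCRACluster]:
    """Abundance-sorted greedy centroid clustering.

    Deterministic: order is (descending abundance, lexicographic sequence);
    a peptide joins the first (oldest) centroid with identity >= threshold.
    Cluster ids are assigned by descending total abundance afterwards.
    """
    ordered = sorted(peptides, key=lambda p: (-p.abundance, p.sequence))
    clusters: list[MCRACluster] = []
    for pep in ordered:
        for cluster in clusters:
            if pairwise_identity(pep.sequence, cluster.centroid) >= threshold:
                cluster.members.append(pep)
                break
        else:
            clusters.append(MCRACluster("", pep.sequence, [pep]))
    ranked = sorted(clusters, key=lambda c: (-c.total, c.centroid))
    width = len(str(len(ranked)))
    for i, cluster in enumerate(ranked):
        cluster.cluster_id = f"c{i + 1:0{width}d}"
    return ranked


def apply_min_fraction(clusters: list[MCRACluster], min_fraction: float = 0.001,
                       ) -> tuple[list[MCRACluster], float]:
    """Discard clusters below the pooled-run abundance floor (inclusive >=).

    Returns the retained clusters and the fraction of all peptides they
    account for.
    """
    grand_total = sum(c.total for c in clusters)
    if grand_total == 0:
        raise ValueError("no peptides to filter")
    retained = [c for c in clusters if c.total / grand_total >= min_fraction]
    retained_fraction = sum(c.total for c in retained) / grand_total
    return retained, retained_fraction


@dataclass
class ClusterCountMatrix:
    """Sample x cluster integer counts plus treatment labels."""

    counts: pd.DataFrame
    treatments: dict[str, str]
    retained_fraction: float = 1.0

    @property
    def empty_samples(self) -> list[str]:
        sums = self.counts.sum(axis=1)
        return list(sums.index[sums == 0])

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundance (%, rows sum to 100); samples with
        zero retained reads are dropped (flagged via ``empty_samples``)."""
        counts = self.counts.drop(index=self.empty_samples)
        return counts.div(counts.sum(axis=1), axis=0) * 100.0


def build_count_matrix(clusters: list[MCRACluster],
                       sample_treatments: Mapping[str, str],
                       retained_fraction: float = 1.0) -> ClusterCountMatrix:
    """Assemble the counts matrix; member samples must appear in the map."""
    samples = list(sample_treatments)
    data = np.zeros((len(samples), len(clusters)), dtype=int)
    sample_index = {s: i for i, s in enumerate(samples)}
    for j, cluster in enumerate(clusters):
        for sample, n in cluster.per_sample.items():
            if sample not in sample_index:
                raise ValueError(f"unknown sample id {sample!r} in cluster "
                                 f"{cluster.cluster_id}")
            data[sample_index[sample], j] = n
    counts = pd.DataFrame(data, index=samples,
                          columns=[c.cluster_id for c in clusters])
    return ClusterCountMatrix(counts, dict(sample_treatments), retained_fraction)
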