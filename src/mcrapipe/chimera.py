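"""PCR chimera detection on dereplicated amplicons.

Two-parent single-crossover model: for a query and each candidate parent
pair, the best split of the query into a left segment matching parent A
and a right segment matching parent B gives the two-parent identity b2;
b1 is the best single-parent identity.  A query is flagged when the
two-parent model is near-perfect (b2 >= min_score), beats the best single
parent by at least delta, and each side of the crossover carries at least
``min_diag`` diagnostic positions (query matches one parent but not the
other).  Candidates come either from more-abundant co-occurring sequences
(de novo mode, abundance skew rule) or from a reference panel; removal is
the union of both modes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import Align

from .config import PipelineConfig


@dataclass(frozen=True)
class DerepAmplicon:
    id: str
    sequence: str
    abundance: int


@dataclass(frozen=True)
class ChimeraVerdict:
    query_id: str
    b1: float
    b2: float
    crossover: int
    parent_a: str
    parent_b: str
    is_chimera: bool
    left_votes: int = 0
    right_votes: int = 0


def _kmers(seq: str, k: int = 8) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def candidate_parents(
    query: DerepAmplicon,
    pool: Sequence[DerepAmplicon],
    mode: str = "denovo",
    abundance_skew: float = 2.0,
    k: int = 4,
) -> list[DerepAmplicon]:
    """Top-k candidate parents by shared 8-mer count.

    De novo mode only admits sequences at >= skew x the query abundance
    (a chimera cannot outnumber its parents); reference mode admits the
    whole panel.  Ties break by abundance, then id.
    """
    if mode not in ("denovo", "reference"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "denovo":
        eligible = [p for p in pool
                    if p.abundance >= abundance_skew * query.abundance
                    and p.sequence != query.sequence]
    else:
        eligible = [p for p in pool if p.id != query.id]
    if not eligible:
        return []
    qmers = _kmers(query.sequence)
    scored = sorted(
        eligible,
        key=lambda p: (-len(qmers & _kmers(p.sequence)), -p.abundance, p.id),
    )
    return scored[:k]


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = -1
_aligner.open_gap_score = -5
_aligner.extend_gap_score = -2


def _project(query: str, parent: str) -> np.ndarray:
    """Boolean match profile of the parent along query coordinates
    (query-anchored global alignment; gap columns count as mismatches)."""
    if len(query) == len(parent):
        q = np.frombuffer(query.encode(), dtype=np.uint8)
        p = np.frombuffer(parent.encode(), dtype=np.uint8)
        return q == p
    alignment = _aligner.align(query, parent)[0]
    match = np.zeros(len(query), dtype=bool)
    for (qs, qe), (ps, pe) in zip(*alignment.aligned):
        block_q = np.frombuffer(query[qs:qe].encode(), dtype=np.uint8)
        block_p = np.frombuffer(parent[ps:pe].encode(), dtype=np.uint8)
        match[qs:qe] = block_q == block_p
    return match


def score_chimera(query: str, parent_a: str, parent_b: str,
                  query_id: str = "", id_a: str = "", id_b: str = "",
                  config: PipelineConfig | None = None) -> ChimeraVerdict:
    """Score the two-parent single-crossover model for one parent pair."""
    cfg = config or PipelineConfig()
    if not query:
        raise ValueError("empty query")
    ma = _project(query, parent_a)
    mb = _project(query, parent_b)
    L = len(query)
    id_qa = ma.mean()
    id_qb = mb.mean()
    b1 = max(id_qa, id_qb)
    cum_a = np.concatenate([[0], np.cumsum(ma)])
    cum_b = np.concatenate([[0], np.cumsum(mb)])
    # crossover after position x (0..L): left from A, right from B, and the
    # mirrored direction; x indexes prefix length
    f_ab = (cum_a + (cum_b[-1] - cum_b)) / L
    f_ba = (cum_b + (cum_a[-1] - cum_a)) / L
    if f_ab.max() >= f_ba.max():
        f, left, right = f_ab, (ma, mb), (id_a, id_b)
    else:
        f, left, right = f_ba, (mb, ma), (id_b, id_a)
    x = int(f.argmax())
    b2 = float(f[x])
    m_left, m_right = left
    diag_left = int(np.sum(m_left[:x] & ~m_right[:x]))
    diag_right = int(np.sum(m_right[x:] & ~m_left[x:]))
    is_chim = (
        b2 - b1 >= cfg.chimera_delta
        and b2 >= cfg.chimera_min_score
        and diag_left >= cfg.chimera_min_diag
        and diag_right >= cfg.chimera_min_diag
    )
    return ChimeraVerdict(query_id, float(b1), b2, x, right[0], right[1],
                          is_chim, diag_left, diag_right)


def _residual_candidates(query: DerepAmplicon, primary: DerepAmplicon,
                         eligible: list[DerepAmplicon], k: int
                         ) -> list[DerepAmplicon]:
    """Candidates ranked by shared 8-mers over the query region the primary
    parent fails to explain (the would-be second parent's segment)."""
    mism = _project(query.sequence, primary.sequence)
    positions = np.nonzero(~mism)[0]
    if positions.size == 0:
        return []
    windows: set[str] = set()
    for p in positions:
        lo = max(0, int(p) - 7)
        for i in range(lo, min(int(p) + 1, len(query.sequence) - 7)):
            windows.add(query.sequence[i : i + 8])
    scored = sorted(
        eligible,
        key=lambda c: (-len(windows & _kmers(c.sequence)), -c.abundance, c.id),
    )
    return scored[:k]


def _best_verdict(query: DerepAmplicon, candidates: list[DerepAmplicon],
                  eligible: list[DerepAmplicon], cfg: PipelineConfig
                  ) -> ChimeraVerdict | None:
    """Best two-parent verdict over candidate pairs.

    The pair pool is the k-mer ranked candidates plus, for each of them as
    primary parent, the candidates covering its unexplained residual; this
    keeps the minority parent reachable when the crossover is off-centre.
    """
    if not candidates:
        return None
    pool: dict[str, DerepAmplicon] = {c.id: c for c in candidates}
    for primary in candidates[:2]:
        for extra in _residual_candidates(query, primary, eligible,
                                          cfg.chimera_k):
            pool.setdefault(extra.id, extra)
    ranked = sorted(pool.values(), key=lambda c: c.id)
    best: ChimeraVerdict | None = None
    for i, pa in enumerate(ranked):
        for pb in ranked[i + 1 :]:
            v = score_chimera(query.sequence, pa.sequence, pb.sequence,
                              query.id, pa.id, pb.id, cfg)
            if best is None or (v.b2, v.b2 - v.b1) > (best.b2, best.b2 - best.b1):
                best = v
    return best


def filter_chimeras(
    amplicons: Iterable[DerepAmplicon],
    panel: Sequence[DerepAmplicon] | None = None,
    config: PipelineConfig | None = None,
) -> tuple[list[DerepAmplicon], list[DerepAmplicon], list[ChimeraVerdict]]:
    """Partition dereplicated amplicons into (clean, flagged, verdicts).

    De novo detection against more-abundant co-occurring amplicons first,
    then detection against the reference panel; a sequence flagged by
    either mode is removed.  A query whose sequence occurs verbatim in the
    panel is never flagged.
    """
    cfg = config or PipelineConfig()
    pool = sorted(amplicons, key=lambda a: (-a.abundance, a.id))
    panel_seqs = {p.sequence for p in panel} if panel else set()
    clean: list[DerepAmplicon] = []
    flagged: list[DerepAmplicon] = []
    verdicts: list[ChimeraVerdict] = []
    for query in pool:
        if query.sequence in panel_seqs:
            clean.append(query)
            verdicts.append(ChimeraVerdict(query.id, 1.0, 1.0, 0, "", "", False))
            continue
        verdict: ChimeraVerdict | None = None
        for mode, ref_pool in (("denovo", pool), ("reference", panel or [])):
            if not ref_pool:
                continue
            cands = candidate_parents(query, ref_pool, mode,
                                      cfg.chimera_abundance_skew, cfg.chimera_k)
            if mode == "denovo":
                eligible = [p for p in ref_pool
                            if p.abundance >= cfg.chimera_abundance_skew * query.abundance
                            and p.sequence != query.sequence]
            else:
                eligible = [p for p in ref_pool if p.id != query.id]
            v = _best_verdict(query, cands, eligible, cfg)
            if v is not None and (verdict is None
                                  or (v.b2, v.b2 - v.b1) > (verdict.b2, verdict.b2 - verdict.b1)):
                verdict = v
            if v is not None and v.is_chimera:
                break
        if verdict is None:
            verdict = ChimeraVerdict(query.id, 0.0, 0.0, 0, "", "", False)
        verdicts.append(verdict)
        (flagged if verdict.is_chimera else clean).append(query)
    return clean, flagged, verdicts


def verdicts_frame(verdicts: list[ChimeraVerdict]):
    import pandas as pd

    return pd.DataFrame(
        [(v.query_id, v.b1, v.b2, v.crossover, v.parent_a, v.parent_b, v.is_chimera)
         for v in verdicts],
        columns=["query", "b1", "b2", "crossover", "parent_a", "parent_b", "is_chimera"],
    )
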