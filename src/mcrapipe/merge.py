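"""Overlap merging of read pairs and amplicon size selection.

The merger scans every candidate overlap between the 3' end of R1 and the
reverse-complemented R2, keeps those with mismatch rate <= the configured
maximum and length >= the minimum, and chooses the longest (ties: fewer
mismatches).  At overlap mismatches the consensus takes the higher-quality
base.  Rejection is a value with a reason code, never an exception, so
every input pair is exactly one of {merged, rejected-with-reason}.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .io import ReadPair
from .seqs import revcomp


@dataclass(frozen=True)
class MergedAmplicon:
    id: str
    sequence: str
    qualities: str
    overlap: int
    mismatches: int
    sample: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MergeRejection:
    id: str
    reason: str  # no_overlap | too_short
    sample: str = ""


def merge_pair(pair: ReadPair, min_overlap: int = 20,
               max_mismatch_rate: float = 0.1) -> MergedAmplicon | MergeRejection:
    """Merge one read pair into a full-length amplicon, or reject it."""
    if not pair.seq1 or not pair.seq2:
        raise ValueError(f"{pair.id}: empty read")
    r1, q1 = pair.seq1, pair.qual1
    r2 = revcomp(pair.seq2)
    q2 = pair.qual2[::-1]
    a1 = np.frombuffer(r1.encode(), dtype=np.uint8)
    a2 = np.frombuffer(r2.encode(), dtype=np.uint8)
    max_olap = min(len(r1), len(r2))
    best: tuple[int, int] | None = None  # (overlap, mismatches)
    for olap in range(max_olap, min_overlap - 1, -1):
        mism = int((a1[len(r1) - olap:] != a2[:olap]).sum())
        if mism <= max_mismatch_rate * olap:
            best = (olap, mism)
            break  # longest acceptable overlap found (scan is descending)
    if best is None:
        reason = "no_overlap" if max_olap >= min_overlap else "too_short"
        return MergeRejection(pair.id, reason, pair.sample)
    olap, mism = best
    left = r1[: len(r1) - olap]
    right = r2[olap:]
    cons = []
    consq = []
    for i in range(olap):
        c1, c2 = r1[len(r1) - olap + i], r2[i]
        p1, p2 = q1[len(r1) - olap + i], q2[i]
        if c1 == c2 or p1 >= p2:
            cons.append(c1)
            consq.append(max(p1, p2) if c1 == c2 else p1)
        else:
            cons.append(c2)
            consq.append(p2)
    sequence = left + "".join(cons) + right
    qualities = q1[: len(r1) - olap] + "".join(consq) + q2[olap:]
    return MergedAmplicon(pair.id, sequence, qualities, olap, mism, pair.sample)


def merge_pairs(pairs: Iterable[ReadPair], min_overlap: int = 20,
                max_mismatch_rate: float = 0.1,
                ) -> tuple[list[MergedAmplicon], list[MergeRejection]]:
    """Merge a stream of pairs, dereplicating identical (R1, R2) mates.

    Identical input pairs merge identically, so each distinct mate pair is
    merged once and the result fanned back out; behaviour matches merging
    every pair individually.
    """
    groups: Counter[tuple[str, str]] = Counter()
    members: dict[tuple[str, str], list[ReadPair]] = {}
    for pair in pairs:
        key = (pair.seq1, pair.seq2)
        groups[key] += 1
        members.setdefault(key, []).append(pair)
    merged: list[MergedAmplicon] = []
    rejected: list[MergeRejection] = []
    for key, reps in members.items():
        proto = merge_pair(reps[0], min_overlap, max_mismatch_rate)
        for rep in reps:
            if isinstance(proto, MergedAmplicon):
                merged.append(MergedAmplicon(rep.id, proto.sequence, proto.qualities,
                                             proto.overlap, proto.mismatches,
                                             rep.sample))
            else:
                rejected.append(MergeRejection(rep.id, proto.reason, rep.sample))
    return merged, rejected


def length_filter(amplicons: Iterable[MergedAmplicon], target_length: int = 472,
                  tolerance: int = 1,
                  ) -> tuple[list[MergedAmplicon], list[MergedAmplicon]]:
    """Size selection: retain iff |length - target| <= tolerance."""
    retained, rejected = [], []
    for amp in amplicons:
        (retained if abs(len(amp) - target_length) <= tolerance else rejected).append(amp)
    return retained, rejected


def quality_summary(pairs: Iterable[ReadPair]) -> dict[str, np.ndarray]:
    """Per-cycle min/mean/max Phred summary for each mate (reporting only;
    no reads are dropped on quality)."""
    acc: dict[str, list[np.ndarray]] = {"R1": [], "R2": []}
    for pair in pairs:
        acc["R1"].append(np.frombuffer(pair.qual1.encode(), dtype=np.uint8) - 33)
        acc["R2"].append(np.frombuffer(pair.qual2.encode(), dtype=np.uint8) - 33)
    out = {}
    for mate, rows in acc.items():
        if not rows:
            out[mate] = np.zeros((3, 0))
            continue
        length = max(len(r) for r in rows)
        mat = np.full((len(rows), length), np.nan)
        for i, r in enumerate(rows):
            mat[i, : len(r)] = r
        out[mate] = np.vstack([
            np.nanmin(mat, axis=0), np.nanmean(mat, axis=0), np.nanmax(mat, axis=0)
        ])
    return out
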