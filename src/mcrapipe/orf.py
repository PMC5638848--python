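"""Six-frame translation and primer-anchored open-reading-frame screening.

A merged amplicon is kept only if exactly one of its six reading frames is
stop-free, in the expected 155-160 aa window, and begins/ends with the
conserved translations of the forward/reverse primers.  Ambiguity (no
frame, or more than one) is a rejection, since the assay guarantees a
single reading frame per genuine mcrA amplicon.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import cached_property

from .config import (
    DEFAULT_FORWARD_PRIMER,
    DEFAULT_REVERSE_PRIMER,
    PipelineConfig,
)
from .seqs import CODON_TO_AA, IUPAC_NT, check_iupac, revcomp, translate_six_frames

__all__ = ["PrimerPair", "MCRAPeptide", "OrfRejection", "screen_orf",
           "translate_six_frames"]


def _codon_residues(pattern: str) -> frozenset[str]:
    """Residues encoded by one degenerate codon pattern."""
    residues = {
        CODON_TO_AA["".join(c)]
        for c in itertools.product(*(IUPAC_NT[p] for p in pattern))
    }
    return frozenset(residues - {"*"})


@dataclass(frozen=True)
class PrimerPair:
    """Degenerate primer pair plus the derived amino-acid anchor motifs.

    ``forward_offset`` / ``reverse_offset`` give the first in-frame base of
    the primer (the reverse offset applies to the reverse complement as it
    appears at the amplicon 3' end); trailing partial codons are dropped
    from the motifs.
    """

    forward: str = DEFAULT_FORWARD_PRIMER
    reverse: str = DEFAULT_REVERSE_PRIMER
    forward_offset: int = 0
    reverse_offset: int = 2
    max_motif_mismatches: int = 0

    def __post_init__(self) -> None:
        check_iupac(self.forward)
        check_iupac(self.reverse)

    @cached_property
    def forward_motif(self) -> tuple[frozenset[str], ...]:
        region = self.forward[self.forward_offset:]
        k = len(region) // 3
        motif = tuple(_codon_residues(region[3 * i : 3 * i + 3]) for i in range(k))
        if not motif or any(not m for m in motif):
            raise ValueError("forward primer yields an empty motif")
        return motif

    @cached_property
    def reverse_motif(self) -> tuple[frozenset[str], ...]:
        region = revcomp(self.reverse)[self.reverse_offset:]
        k = len(region) // 3
        motif = tuple(_codon_residues(region[3 * i : 3 * i + 3]) for i in range(k))
        if not motif or any(not m for m in motif):
            raise ValueError("reverse primer yields an empty motif")
        return motif

    @classmethod
    def from_config(cls, cfg: PipelineConfig) -> "PrimerPair":
        return cls(cfg.forward_primer, cfg.reverse_primer, cfg.forward_offset,
                   cfg.reverse_offset, cfg.max_motif_mismatches)


@dataclass(frozen=True)
class MCRAPeptide:
    sequence: str
    source_id: str
    frame: int  # in {+1,+2,+3,-1,-2,-3}
    sample: str = ""


@dataclass(frozen=True)
class OrfRejection:
    source_id: str
    reason: str  # no_frame | multiple_frames | stop_codon | length | motif
    sample: str = ""


def _motif_mismatches(residues: str, motif: tuple[frozenset[str], ...]) -> int:
    return sum(res not in allowed for res, allowed in zip(residues, motif))


def screen_orf(
    sequence: str,
    primers: PrimerPair,
    length_range: tuple[int, int] = (155, 160),
    source_id: str = "",
    sample: str = "",
) -> MCRAPeptide | OrfRejection:
    """Keep the single stop-free, primer-anchored reading frame, if any."""
    lo, hi = length_range
    try:
        frames = translate_six_frames(sequence)
    except ValueError:
        return OrfRejection(source_id, "no_frame", sample)
    passing: list[tuple[int, str]] = []
    failures: list[str] = []
    n_fwd = len(primers.forward_motif)
    n_rev = len(primers.reverse_motif)
    for frame in (1, 2, 3, -1, -2, -3):
        pep = frames[frame]
        if "*" in pep:
            failures.append("stop_codon")
            continue
        if not lo <= len(pep) <= hi:
            failures.append("length")
            continue
        mm = (_motif_mismatches(pep[:n_fwd], primers.forward_motif)
              + _motif_mismatches(pep[-n_rev:], primers.reverse_motif))
        if mm > primers.max_motif_mismatches:
            failures.append("motif")
            continue
        passing.append((frame, pep))
    if len(passing) == 1:
        frame, pep = passing[0]
        return MCRAPeptide(pep, source_id, frame, sample)
    if len(passing) > 1:
        return OrfRejection(source_id, "multiple_frames", sample)
    for reason in ("motif", "length", "stop_codon"):
        if reason in failures:
            return OrfRejection(source_id, reason, sample)
    return OrfRejection(source_id, "no_frame", sample)
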