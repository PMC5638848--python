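"""Shared nucleotide/peptide helpers: IUPAC handling, codons, translation."""

from __future__ import annotations

import itertools

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

IUPAC_NT = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "D": "H", "H": "D", "V": "B", "N": "N",
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: codon -> amino acid ('*' for stop), standard genetic code
CODON_TO_AA = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TO_AA[_stop] = "*"

#: amino acid -> sorted list of synonymous codons
AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, []).append(_codon)


def revcomp(seq: str) -> str:
    """Reverse complement; accepts IUPAC degenerate codes."""
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"non-IUPAC nucleotide {exc.args[0]!r}") from None


def check_iupac(seq: str) -> None:
    bad = set(seq.upper()) - set(IUPAC_NT)
    if bad:
        raise ValueError(f"non-IUPAC nucleotide(s) {sorted(bad)!r}")


def expand_degenerate(pattern: str) -> list[str]:
    """All concrete realisations of an IUPAC degenerate pattern."""
    check_iupac(pattern)
    pools = [IUPAC_NT[c] for c in pattern.upper()]
    return ["".join(p) for p in itertools.product(*pools)]


def translate(nt: str) -> str:
    """Frame +1 translation, stops as '*', trailing partial codon dropped."""
    usable = len(nt) - len(nt) % 3
    return str(Seq(nt[:usable]).translate())


def translate_six_frames(nt: str) -> dict[int, str]:
    """Translations keyed by frame in {+1,+2,+3,-1,-2,-3}.

    Frames +1..+3 read the sequence starting at 1-based positions 1..3;
    -1..-3 read the reverse complement the same way.
    """
    if len(nt) < 3:
        raise ValueError("sequence shorter than one codon")
    check_iupac(nt)
    nt = nt.upper()
    if set(nt) - set("ACGT"):
        # degenerate bases translate as X via Biopython; keep them explicit
        pass
    rc = revcomp(nt)
    out: dict[int, str] = {}
    for off in range(3):
        out[off + 1] = translate(nt[off:])
        out[-(off + 1)] = translate(rc[off:])
    return out


def closest_codon(target_aa: str, old_codon: str) -> str:
    """Synonymous codon for ``target_aa`` with minimal Hamming distance to
    ``old_codon`` (ties broken lexicographically)."""
    options = AA_TO_CODONS[target_aa]
    return min(options, key=lambda c: (sum(a != b for a, b in zip(c, old_codon)), c))


def hamming_identity(a: str, b: str) -> float:
    """Fraction of matching positions for equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    if not a:
        raise ValueError("empty sequence")
    return sum(x == y for x, y in zip(a, b)) / len(a)
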