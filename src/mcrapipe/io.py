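"""Readers/writers for the formats the pipeline touches.

FASTQ (gzip-transparent, Illumina paired dialect), wrapped FASTA, TSV
count matrices, the sample sheet, panel FASTA + taxonomy TSV and the
simulation truth table.  Parsers reject malformed input rather than
silently truncating.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO


@dataclass(frozen=True)
class ReadPair:
    id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str
    sample: str = ""

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"{self.id}: sequence/quality length mismatch")


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _pair_key(read_id: str) -> str:
    """Illumina pairing key: first whitespace token, '/1' or '/2' stripped."""
    token = read_id.split()[0]
    if token.endswith("/1") or token.endswith("/2"):
        token = token[:-2]
    return token


def read_fastq_pairs(path_r1: str | Path, path_r2: str | Path) -> Iterator[ReadPair]:
    """Stream synchronised read pairs from two FASTQ files.

    Raises on desynchronised ids or unequal record counts, naming the
    1-based record index.
    """
    with _open_text(path_r1) as h1, _open_text(path_r2) as h2:
        it1 = SeqIO.parse(h1, "fastq")
        it2 = SeqIO.parse(h2, "fastq")
        index = 0
        while True:
            rec1 = next(it1, None)
            rec2 = next(it2, None)
            index += 1
            if rec1 is None and rec2 is None:
                return
            if rec1 is None or rec2 is None:
                longer = "R2" if rec1 is None else "R1"
                raise ValueError(
                    f"desynchronised FASTQ pair: {longer} has extra record {index}"
                )
            key1, key2 = _pair_key(rec1.id), _pair_key(rec2.id)
            if key1 != key2:
                raise ValueError(
                    f"desynchronised FASTQ pair at record {index}: {key1!r} vs {key2!r}"
                )
            yield ReadPair(
                key1,
                str(rec1.seq),
                "".join(chr(q + 33) for q in rec1.letter_annotations["phred_quality"]),
                str(rec2.seq),
                "".join(chr(q + 33) for q in rec2.letter_annotations["phred_quality"]),
            )


def write_fastq_pairs(pairs: Iterable[ReadPair], path_r1: str | Path,
                      path_r2: str | Path) -> int:
    """Write 4-line FASTQ mates (_R1/_R2); gzip if paths end in .gz."""
    n = 0
    with _open_text(path_r1, "wt") as h1, _open_text(path_r2, "wt") as h2:
        for pair in pairs:
            h1.write(f"@{pair.id}/1\n{pair.seq1}\n+\n{pair.qual1}\n")
            h2.write(f"@{pair.id}/2\n{pair.seq2}\n+\n{pair.qual2}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(entries: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) entries, 60-column wrapped; duplicate ids error."""
    seen: set[str] = set()
    with _open_text(path, "wt") as handle:
        for name, seq in entries:
            if name in seen:
                raise ValueError(f"duplicate FASTA id {name!r}")
            seen.add(name)
            handle.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                handle.write(seq[i : i + 60] + "\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    with _open_text(path) as handle:
        entries = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")]
    ids = [name for name, _ in entries]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate FASTA ids")
    return entries


# ---------------------------------------------------------------------------
# count matrices (samples x clusters)


def write_count_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Lossless TSV serialisation; rows samples, columns clusters."""
    if (matrix.to_numpy() < 0).any():
        raise ValueError("negative counts")
    matrix.to_csv(path, sep="\t", index_label="sample")


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col="sample")
    frame.columns = [str(c) for c in frame.columns]
    if (frame.to_numpy() < 0).any():
        raise ValueError("negative counts")
    return frame


# ---------------------------------------------------------------------------
# sample sheet


@dataclass(frozen=True)
class SampleSheetRow:
    sample: str
    treatment: str
    path_r1: str
    path_r2: str


class SampleSheet:
    """Sample -> (treatment, R1 path, R2 path) table."""

    def __init__(self, rows: list[SampleSheetRow],
                 treatments: tuple[str, ...] = ("R", "A", "RA", "AA")) -> None:
        ids = [r.sample for r in rows]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate sample ids in sample sheet")
        for r in rows:
            if r.treatment not in treatments:
                raise ValueError(
                    f"sample {r.sample}: treatment {r.treatment!r} not in {treatments}"
                )
        self.rows = rows

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def treatments(self) -> dict[str, str]:
        return {r.sample: r.treatment for r in self.rows}

    @classmethod
    def read(cls, path: str | Path, **kwargs) -> "SampleSheet":
        frame = pd.read_csv(path, sep="\t", dtype=str)
        required = ["sample", "treatment", "path_r1", "path_r2"]
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise ValueError(f"sample sheet missing column(s) {missing}")
        rows = [SampleSheetRow(r.sample, r.treatment, r.path_r1, r.path_r2)
                for r in frame.itertuples()]
        return cls(rows, **kwargs)

    def write(self, path: str | Path) -> None:
        frame = pd.DataFrame(
            [(r.sample, r.treatment, r.path_r1, r.path_r2) for r in self.rows],
            columns=["sample", "treatment", "path_r1", "path_r2"],
        )
        frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# panel + truth


def write_panel(panel, fasta_path: str | Path, taxonomy_path: str | Path,
                nucleotide: bool = False) -> None:
    """Panel as FASTA (peptide by default) plus taxonomy TSV."""
    seqs = [(e.id, e.nucleotide if nucleotide else e.peptide) for e in panel]
    write_fasta(seqs, fasta_path)
    frame = pd.DataFrame(
        [(e.id, e.family, e.genus, e.clade) for e in panel],
        columns=["id", "family", "genus", "clade"],
    )
    frame.to_csv(taxonomy_path, sep="\t", index=False)


def read_taxonomy(path: str | Path) -> dict[str, tuple[str, str, str]]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return {r.id: (r.family, r.genus, r.clade) for r in frame.itertuples()}


def write_truth(truth, path: str | Path) -> None:
    frame = pd.DataFrame(
        [(t.read_id, t.sample_id, t.source_id, t.is_chimera, t.parent_a,
          t.parent_b, t.is_offlength, t.is_frameshifted) for t in truth],
        columns=["read_id", "sample_id", "source_id", "is_chimera",
                 "parent_a", "parent_b", "is_offlength", "is_frameshifted"],
    )
    frame.to_csv(path, sep="\t", index=False)
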