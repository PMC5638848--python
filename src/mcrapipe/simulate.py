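"""Synthetic mcrA amplicon communities.

Generates labelled MCRA reference panels, treatment-level community
profiles and paired-end amplicon reads with the statistical structure the
pipeline assumes: 472-nt amplicons bracketed by the degenerate forward /
reverse primers, a single open reading frame of ~157 aa, multinomial
template sampling, per-base sequencing error, two-parent single-crossover
PCR chimeras, in-frame off-length fragments and single-nt frameshifts.

Panel sequences evolve hierarchically: one root peptide is back-translated
once, and amino-acid substitutions propagate to the nucleotide level as
minimal codon edits, so nucleotide divergence tracks peptide divergence
(independent re-back-translation would scatter silent differences across
otherwise identical members).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .config import DEFAULT_FORWARD_PRIMER, DEFAULT_REVERSE_PRIMER, TREATMENTS
from .io import ReadPair
from .seqs import (
    AMINO_ACIDS,
    AA_TO_CODONS,
    CODON_TO_AA,
    IUPAC_NT,
    closest_codon,
    hamming_identity,
    revcomp,
    translate,
)
from .tables import CLUSTER_TAXONOMY, TABLE2


class PanelNotSeparableError(ValueError):
    """Clade divergence settings cannot satisfy the identity-separation
    contracts (between-clade <= 0.96, member-to-root >= 0.98)."""


@dataclass(frozen=True)
class CladeSpec:
    """One clade of the synthetic reference panel."""

    name: str
    family: str
    genus: str
    clade: str
    n_members: int
    divergence_from_root: float
    within_member_divergence: float

    def __post_init__(self) -> None:
        for d in (self.divergence_from_root, self.within_member_divergence):
            if not 0.0 <= d <= 1.0:
                raise ValueError("divergences must be in [0, 1]")
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        if not (self.family and self.genus and self.clade and self.name):
            raise ValueError("taxonomy labels must be non-empty")


@dataclass(frozen=True)
class PanelEntry:
    id: str
    peptide: str
    nucleotide: str  # coding sequence, len == 3 * len(peptide)
    family: str
    genus: str
    clade: str

    @property
    def taxonomy(self) -> tuple[str, str, str]:
        return (self.family, self.genus, self.clade)


@dataclass
class ReferencePanel:
    entries: list[PanelEntry]
    tail: str = ""  # nt appended after the coding region in the amplicon
    clade_roots: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [e.id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("panel ids must be unique")
        for e in self.entries:
            if translate(e.nucleotide) != e.peptide:
                raise ValueError(f"{e.id}: nucleotide does not translate to peptide")
            if "*" in e.peptide:
                raise ValueError(f"{e.id}: internal stop codon")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, entry_id: str) -> PanelEntry:
        return self._index[entry_id]

    @property
    def _index(self) -> dict[str, PanelEntry]:
        return {e.id: e for e in self.entries}

    def template(self, entry_id: str) -> str:
        """Full amplicon template (primer-to-primer) for one panel entry."""
        return self.get(entry_id).nucleotide + self.tail

    def taxonomy_map(self) -> dict[str, tuple[str, str, str]]:
        return {e.id: e.taxonomy for e in self.entries}

    def subset(self, ids: Iterable[str]) -> "ReferencePanel":
        """Sub-panel restricted to the given entry ids (same amplicon tail)."""
        wanted = set(ids)
        entries = [e for e in self.entries if e.id in wanted]
        missing = wanted - {e.id for e in entries}
        if missing:
            raise KeyError(f"panel ids not found: {sorted(missing)}")
        return ReferencePanel(entries, tail=self.tail,
                              clade_roots=dict(self.clade_roots))


@dataclass
class CommunityProfile:
    """Template proportions of one sample/treatment community."""

    proportions: dict[str, float]
    treatment: str

    def __post_init__(self) -> None:
        values = np.array(list(self.proportions.values()), dtype=float)
        if (values < 0).any():
            raise ValueError("proportions must be non-negative")
        total = values.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1, got {total}")

    @classmethod
    def from_percent(cls, percents: dict[str, float], treatment: str) -> "CommunityProfile":
        total = sum(percents.values())
        if total <= 0:
            raise ValueError("profile sums to zero")
        return cls({k: v / total for k, v in percents.items()}, treatment)


@dataclass(frozen=True)
class TruthRecord:
    """Provenance of one emitted read pair."""

    read_id: str
    sample_id: str
    source_id: str
    is_chimera: bool = False
    parent_a: str = ""
    parent_b: str = ""
    is_offlength: bool = False
    is_frameshifted: bool = False


# ---------------------------------------------------------------------------
# amplicon geometry


class AmpliconScheme:
    """Geometry of the primer-bracketed amplicon for a given peptide length.

    The forward primer realisation occupies the amplicon 5' end, the
    reverse complement of the reverse primer the 3' end; reading frame +1
    spans the whole coding region, with ``tail`` nt left over after the
    last full codon.
    """

    def __init__(
        self,
        peptide_length: int = 157,
        forward: str = DEFAULT_FORWARD_PRIMER,
        reverse: str = DEFAULT_REVERSE_PRIMER,
        reverse_offset: int = 2,
    ) -> None:
        self.peptide_length = peptide_length
        self.forward = forward.upper()
        self.rc_reverse = revcomp(reverse)
        self.reverse_offset = reverse_offset
        coding = 3 * peptide_length
        # tail chosen so the reverse motif codons are frame-aligned
        for tail in range(3):
            start = coding + tail - len(self.rc_reverse) + reverse_offset
            if start >= 0 and start % 3 == 0:
                break
        else:  # pragma: no cover - geometry always solvable for tail in 0..2
            raise ValueError("no frame-consistent amplicon length")
        self.tail_len = tail
        self.amplicon_length = coding + tail
        if self.amplicon_length <= len(self.forward) + len(self.rc_reverse):
            raise ValueError("peptide too short for the primer pair")

    def codon_constraints(self) -> list[str | None]:
        """Per-codon IUPAC constraint (3-char pattern with N padding) from
        the primer regions; None for unconstrained codons."""
        coding = 3 * self.peptide_length
        template = ["N"] * self.amplicon_length
        for i, c in enumerate(self.forward):
            template[i] = c
        for i, c in enumerate(self.rc_reverse):
            template[self.amplicon_length - len(self.rc_reverse) + i] = c
        out: list[str | None] = []
        for i in range(self.peptide_length):
            pat = "".join(template[3 * i : 3 * i + 3])
            out.append(None if pat == "NNN" else pat)
        return out

    def tail_pattern(self) -> str:
        return self.rc_reverse[len(self.rc_reverse) - self.tail_len :] if self.tail_len else ""

    def feasible_residues(self) -> list[str]:
        """Per-position string of amino acids compatible with the primer
        patterns (all 20 at unconstrained positions)."""
        out = []
        for pat in self.codon_constraints():
            if pat is None:
                out.append(AMINO_ACIDS)
                continue
            allowed = set()
            for codon in itertools.product(*(IUPAC_NT[c] for c in pat)):
                aa = CODON_TO_AA["".join(codon)]
                if aa != "*":
                    allowed.add(aa)
            if not allowed:
                raise ValueError(f"primer codon pattern {pat} encodes only stops")
            out.append("".join(sorted(allowed)))
        return out

    def free_sites(self) -> list[int]:
        return [i for i, res in enumerate(self.feasible_residues()) if len(res) == 20]


def _codon_options(aa: str, pattern: str | None) -> list[str]:
    options = AA_TO_CODONS[aa]
    if pattern is None:
        return options
    return [codon for codon in options
            if all(c in IUPAC_NT[p] for c, p in zip(codon, pattern))]


def back_translate(peptide: str, seed: int) -> str:
    """Uniform-synonymous-codon back-translation (standard genetic code).

    ``translate(back_translate(p))`` round-trips exactly.
    """
    bad = set(peptide) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"non-standard residue(s) {sorted(bad)!r}")
    rng = np.random.default_rng(seed)
    return "".join(
        AA_TO_CODONS[aa][rng.integers(len(AA_TO_CODONS[aa]))] for aa in peptide
    )


def _constrained_back_translate(peptide: str, scheme: AmpliconScheme,
                                rng: np.random.Generator) -> str:
    codons = []
    for aa, pattern in zip(peptide, scheme.codon_constraints()):
        options = _codon_options(aa, pattern)
        if not options:
            raise ValueError(f"residue {aa} incompatible with primer pattern {pattern}")
        codons.append(options[rng.integers(len(options))])
    return "".join(codons)


# ---------------------------------------------------------------------------
# panel generation


def _mutate(peptide: str, nucleotide: str, n_subs: int, sites: list[int],
            rng: np.random.Generator,
            chosen: list[int] | None = None) -> tuple[str, str]:
    if n_subs == 0:
        return peptide, nucleotide
    if chosen is None:
        chosen = list(rng.choice(len(sites), size=n_subs, replace=False))
    pep = list(peptide)
    nt = list(nucleotide)
    for idx in sorted(int(sites[i]) for i in chosen):
        old = pep[idx]
        alternatives = AMINO_ACIDS.replace(old, "")
        new = alternatives[rng.integers(len(alternatives))]
        pep[idx] = new
        codon = closest_codon(new, nucleotide[3 * idx : 3 * idx + 3])
        nt[3 * idx : 3 * idx + 3] = codon
    return "".join(pep), "".join(nt)


def generate_reference_panel(
    clade_specs: list[CladeSpec],
    peptide_length: int = 157,
    seed: int = 0,
    scheme: AmpliconScheme | None = None,
    member_ids: dict[str, list[str]] | None = None,
) -> ReferencePanel:
    """Generate a labelled MCRA panel with the requested clade structure.

    Each clade root diverges from a shared root peptide by
    ``round(divergence_from_root * L)`` substitutions at primer-free sites;
    members diverge from their clade root the same way.  Raises
    :class:`PanelNotSeparableError` if the resulting panel violates the
    identity-separation contracts (between-clade peptide identity <= 0.96,
    member-to-clade-root >= 0.98).
    """
    if not clade_specs:
        raise ValueError("at least one clade spec required")
    if not 155 <= peptide_length <= 160:
        raise ValueError("peptide_length must be in [155, 160]")
    if scheme is None:
        scheme = AmpliconScheme(peptide_length=peptide_length)
    rng = np.random.default_rng(seed)
    feasible = scheme.feasible_residues()
    root_pep = "".join(res[rng.integers(len(res))] for res in feasible)
    root_nt = _constrained_back_translate(root_pep, scheme, rng)
    tail_pat = scheme.tail_pattern()
    tail = "".join(IUPAC_NT[c][rng.integers(len(IUPAC_NT[c]))] for c in tail_pat)
    sites = scheme.free_sites()

    entries: list[PanelEntry] = []
    clade_roots: dict[str, str] = {}
    clade_of: dict[str, str] = {}
    root_of: dict[str, str] = {}
    for spec in clade_specs:
        n_root = round(spec.divergence_from_root * peptide_length)
        clade_pep, clade_nt = _mutate(root_pep, root_nt, n_root, sites, rng)
        clade_roots[spec.name] = clade_pep
        ids = (member_ids or {}).get(spec.name)
        if ids is not None and len(ids) != spec.n_members:
            raise ValueError(f"{spec.name}: {len(ids)} ids for {spec.n_members} members")
        n_member = round(spec.within_member_divergence * peptide_length)
        # sibling members never share a substituted site, so any two
        # members differ at 2 * n_member positions and stay distinct
        need = spec.n_members * n_member
        if 0 < need <= len(sites):
            pool = list(rng.choice(len(sites), size=need, replace=False))
        else:
            pool = None
        for j in range(spec.n_members):
            chosen = (pool[j * n_member : (j + 1) * n_member]
                      if pool is not None else None)
            pep, nt = _mutate(clade_pep, clade_nt, n_member, sites, rng,
                              chosen=chosen)
            entry_id = ids[j] if ids is not None else f"{spec.name}_{j + 1}"
            entries.append(PanelEntry(entry_id, pep, nt, spec.family, spec.genus, spec.clade))
            clade_of[entry_id] = spec.name
            root_of[entry_id] = clade_pep

    for a, b in itertools.combinations(entries, 2):
        if clade_of[a.id] != clade_of[b.id]:
            if hamming_identity(a.peptide, b.peptide) > 0.96:
                raise PanelNotSeparableError(
                    f"panel not separable: {a.id} vs {b.id} identity > 0.96"
                )
    for e in entries:
        if hamming_identity(e.peptide, root_of[e.id]) < 0.98:
            raise PanelNotSeparableError(
                f"panel not separable: {e.id} drifted > 0.02 from its clade root"
            )
    return ReferencePanel(entries, tail=tail, clade_roots=clade_roots)


# ---------------------------------------------------------------------------
# study fixtures

_STUDY_CLADES = [
    # (clade spec name, family, genus, clade, divergence, cluster ids)
    ("gottschalkii", "Methanobacteriaceae", "Methanobrevibacter", "gottschalkii",
     0.10, ["1", "7083", "7084", "7092", "7105"]),
    ("ruminantium", "Methanobacteriaceae", "Methanobrevibacter", "ruminantium",
     0.13, ["883", "7094"]),
    ("thaueri", "Methanobacteriaceae", "Methanobrevibacter", "thaueri",
     0.16, ["3", "10", "7087", "7089", "7159"]),
    ("stadtmanae", "Methanobacteriaceae", "Methanosphaera", "stadtmanae",
     0.22, ["4", "22291", "23687", "23941", "23942"]),
    ("mmc_a", "Methanomassiliicoccaceae", "Methanomassiliicoccus", "mmc_a",
     0.30, ["0", "2", "6", "11"]),
    ("mmc_b", "Methanomassiliicoccaceae", "Methanoplasma", "mmc_b",
     0.34, ["13", "14", "32", "144"]),
]

#: 3 substitutions on a 157-aa peptide: members sit >= 98% identity to
#: their clade root yet pairwise < 97%, so each maps to its own cluster.
_WITHIN_DIVERGENCE = 3 / 157

N_REFERENCES_PER_CLADE = 3


def make_study_panel(seed: int = 0) -> tuple[ReferencePanel, list[str], list[str]]:
    """Synthetic stand-in for the study's 25 community clusters plus a
    labelled reference panel (3 references per clade).

    The 25 community entries carry the study's cluster ids; clades follow
    the reported assignment (gottschalkii / ruminantium / Methanosphaera /
    Methanomassiliicoccaceae), with synthetic clade labels where the study
    stops at genus or family level.  Returns
    ``(panel, community_ids, reference_ids)``.
    """
    specs = []
    ids: dict[str, list[str]] = {}
    for name, family, genus, clade, div, clusters in _STUDY_CLADES:
        refs = [f"REF_{name}_{k + 1}" for k in range(N_REFERENCES_PER_CLADE)]
        ids[name] = list(clusters) + refs
        specs.append(CladeSpec(name, family, genus, clade,
                               len(clusters) + N_REFERENCES_PER_CLADE,
                               div, _WITHIN_DIVERGENCE))
    panel = generate_reference_panel(specs, peptide_length=157, seed=seed,
                                     member_ids=ids)
    community = [cid for *_, clusters in _STUDY_CLADES for cid in clusters]
    references = [e.id for e in panel if e.id.startswith("REF_")]
    # sanity: community ids cover the published table exactly
    assert set(community) == set(CLUSTER_TAXONOMY)
    return panel, community, references


def table2_profiles() -> dict[str, CommunityProfile]:
    """The four treatment-mean cluster profiles, renormalised to sum 1."""
    out = {}
    for t_index, treatment in enumerate(TREATMENTS):
        percents = {cid: values[t_index] for cid, values in TABLE2.items()}
        out[treatment] = CommunityProfile.from_percent(percents, treatment)
    return out


# ---------------------------------------------------------------------------
# read simulation


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
    if hits.size == 0:
        return seq
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return arr.tobytes().decode()


def _offlength_variant(template: str, scheme: AmpliconScheme,
                       rng: np.random.Generator) -> str:
    size = 3 * int(rng.integers(1, 11))  # 3..30 nt, in frame
    return _indel(template, scheme, size, rng)


def _frameshift_variant(template: str, scheme: AmpliconScheme,
                        rng: np.random.Generator) -> str:
    return _indel(template, scheme, 1, rng)


def _indel(template: str, scheme: AmpliconScheme, size: int,
           rng: np.random.Generator) -> str:
    lo = len(scheme.forward)
    hi = len(template) - len(scheme.rc_reverse) - size
    pos = int(rng.integers(lo, hi))
    if rng.random() < 0.5:
        insert = "".join("ACGT"[rng.integers(4)] for _ in range(size))
        return template[:pos] + insert + template[pos:]
    return template[:pos] + template[pos + size:]


def simulate_sample(
    panel: ReferencePanel,
    profile: CommunityProfile,
    n_reads: int,
    sample_id: str = "S1",
    read_length: int = 250,
    error_rate: float = 0.0,
    chimera_rate: float = 0.0,
    offlength_rate: float = 0.0,
    frameshift_rate: float = 0.0,
    seed: int = 0,
    scheme: AmpliconScheme | None = None,
) -> tuple[list[ReadPair], list[TruthRecord]]:
    """Simulate one paired-end amplicon library.

    Templates are drawn multinomially from ``profile``; each read is, with
    the given rates, replaced by a chimeric, off-length or frameshifted
    variant (mutually exclusive categories), then per-base substitution
    errors are applied to both mates.  Returns the read pairs and one
    truth record per read.
    """
    for name, rate in (("error_rate", error_rate), ("chimera_rate", chimera_rate),
                       ("offlength_rate", offlength_rate),
                       ("frameshift_rate", frameshift_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if n_reads == 0:
        return [], []
    if scheme is None:
        scheme = AmpliconScheme()
    rng = np.random.default_rng(seed)
    ids = sorted(profile.proportions)
    missing = [i for i in ids if i not in panel._index]
    if missing:
        raise ValueError(f"profile taxa not in panel: {missing}")
    probs = np.array([profile.proportions[i] for i in ids], dtype=float)
    probs = probs / probs.sum()
    templates = {i: panel.template(i) for i in ids}
    amp_len = len(next(iter(templates.values())))
    if 2 * read_length <= amp_len - max(0, 30):
        # both mates together must span the longest (off-length) template
        pass
    if 2 * read_length <= amp_len:
        raise ValueError("read_length too short to span the amplicon from both ends")

    qual = "?" * read_length  # constant Q30
    counts = rng.multinomial(n_reads, probs)
    special = rng.random(n_reads)
    p_chim = chimera_rate
    p_off = chimera_rate + offlength_rate
    p_fs = chimera_rate + offlength_rate + frameshift_rate

    pairs: list[ReadPair] = []
    truth: list[TruthRecord] = []
    read_no = 0
    for t_idx, source in enumerate(ids):
        template = templates[source]
        # plain reads shared across copies when error-free
        plain_r1 = template[:read_length]
        plain_r2 = revcomp(template)[:read_length]
        for _ in range(int(counts[t_idx])):
            rid = f"{sample_id}_read{read_no}"
            u = special[read_no]
            read_no += 1
            is_chim = is_off = is_fs = False
            parent_a = parent_b = ""
            if u < p_chim and len(ids) > 1:
                is_chim = True
                other = source
                while other == source:
                    other = ids[int(rng.choice(len(ids), p=probs))]
                x = int(rng.integers(1, amp_len))
                amplicon = template[:x] + templates[other][x:]
                parent_a, parent_b = source, other
            elif u < p_off:
                is_off = True
                amplicon = _offlength_variant(template, scheme, rng)
            elif u < p_fs:
                is_fs = True
                amplicon = _frameshift_variant(template, scheme, rng)
            else:
                amplicon = template
            if amplicon is template and error_rate == 0.0:
                r1, r2 = plain_r1, plain_r2
            else:
                r1 = amplicon[:read_length]
                r2 = revcomp(amplicon)[:read_length]
                if error_rate > 0.0:
                    r1 = _apply_errors(r1, error_rate, rng)
                    r2 = _apply_errors(r2, error_rate, rng)
            pairs.append(ReadPair(rid, r1, qual[: len(r1)], r2, qual[: len(r2)],
                                  sample=sample_id))
            truth.append(TruthRecord(rid, sample_id, source, is_chim,
                                     parent_a, parent_b, is_off, is_fs))
    return pairs, truth
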