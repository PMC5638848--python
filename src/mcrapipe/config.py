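"""Run configuration and reproducible seed derivation.

Every tunable the pipeline consumes lives on :class:`PipelineConfig`, with
defaults matching the study protocol: 472 +/- 1 nt amplicons, 155-160 aa
peptides, 97% peptide clustering with a 0.1% cluster floor, 500 parsimony
bootstraps collapsed below 30% support, an 85% site-coverage mask, 10
random-addition starts and SPR search level 1.
"""

from __future__ import annotations

import dataclasses
import hashlib
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

#: Primer pair of the amplicon assay (degenerate IUPAC), taken from the
#: published Mlas / mcrA-rev primer set; user-verifiable configuration.
DEFAULT_FORWARD_PRIMER = "GGTGGTGTMGGDTTCACMCARTA"
DEFAULT_REVERSE_PRIMER = "CGTTCATBGCGTAGTTVGGRTAGT"


def derive_seed(seed: int, label: str) -> int:
    """Derive a per-stage seed (< 2**31) from a global seed and a label.

    Splitmix-style: hash the (seed, label) pair so stages are individually
    reproducible and statistically independent.
    """
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    # amplicon geometry
    amplicon_length: int = 472
    amplicon_tolerance: int = 1
    peptide_length_min: int = 155
    peptide_length_max: int = 160

    # read merging
    min_overlap: int = 20
    max_mismatch_rate: float = 0.1

    # chimera filter (UCHIME-style two-parent single-crossover model)
    chimera_abundance_skew: float = 2.0
    chimera_k: int = 4
    chimera_delta: float = 0.004
    chimera_min_score: float = 0.998
    chimera_min_diag: int = 2

    # primers / ORF screen
    forward_primer: str = DEFAULT_FORWARD_PRIMER
    reverse_primer: str = DEFAULT_REVERSE_PRIMER
    forward_offset: int = 0
    reverse_offset: int = 2
    max_motif_mismatches: int = 0

    # peptide clustering
    cluster_identity: float = 0.97
    cluster_min_fraction: float = 0.001

    # parsimony placement
    bootstrap_reps: int = 500
    bootstrap_addition_reps: int = 2
    collapse_support: float = 0.30
    site_coverage_min: float = 0.85
    random_addition_reps: int = 10
    spr_level: int = 1

    # statistics
    fdr_alpha: float = 0.05
    nmds_restarts: int = 50
    nmds_max_iter: int = 500
    nmds_tol: float = 1e-6

    seed: int = 0

    def __post_init__(self) -> None:
        fractions = {
            "max_mismatch_rate": self.max_mismatch_rate,
            "chimera_delta": self.chimera_delta,
            "chimera_min_score": self.chimera_min_score,
            "cluster_identity": self.cluster_identity,
            "cluster_min_fraction": self.cluster_min_fraction,
            "collapse_support": self.collapse_support,
            "site_coverage_min": self.site_coverage_min,
            "fdr_alpha": self.fdr_alpha,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        for name in ("amplicon_length", "peptide_length_min", "peptide_length_max",
                     "min_overlap", "bootstrap_reps", "random_addition_reps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.peptide_length_min > self.peptide_length_max:
            raise ValueError("peptide length range inverted")

    def stage_seed(self, label: str) -> int:
        return derive_seed(self.seed, label)

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        """Load from a flat TOML key-value file; unknown keys are an error,
        omitted keys take the documented defaults."""
        with open(path, "rb") as handle:
            data = tomllib.load(handle)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_toml(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if isinstance(value, str):
                lines.append(f'{f.name} = "{value}"')
            elif isinstance(value, bool):
                lines.append(f"{f.name} = {str(value).lower()}")
            else:
                lines.append(f"{f.name} = {value}")
        Path(path).write_text("\n".join(lines) + "\n")


#: treatment groups: feed-restricted, ad libitum, restricted-then-
#: realimented, and ad libitum throughout
TREATMENTS = ("R", "A", "RA", "AA")

#: library counts per treatment after animal exclusions (54 total)
TREATMENT_SIZES = {"R": 13, "A": 12, "RA": 15, "AA": 14}
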