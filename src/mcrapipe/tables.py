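"""Published summary tables of the study, as in-package fixtures.

These are the printed group-level numbers the pipeline's outputs mirror:
mean relative abundances of the 25 MCRA peptide clusters per treatment
(Table 2), the family/genus/clade aggregation of those clusters (Table 1),
group-mean alpha diversity (Table 3), and the phylogenetic assignment of
each cluster.  They serve as simulation profiles and as cross-check
targets; cluster ids are the study's opaque labels.
"""

from __future__ import annotations

import pandas as pd

from .config import TREATMENTS

#: Mean relative abundance (%) of each MCRA cluster by treatment (Table 2).
TABLE2 = {
    #        R      A      RA     AA
    "0":     (0.5,  0.8,   1.0,  0.9),
    "1":     (56.1, 21.0, 30.7, 28.6),
    "2":     (0.2,  0.3,   0.9,  0.9),
    "3":     (17.4, 34.7, 23.6, 25.3),
    "4":     (3.1,  3.2,   3.4,  3.6),
    "6":     (4.0,  4.0,   8.0,  9.0),
    "10":    (1.2,  3.9,   2.7,  2.9),
    "11":    (2.4,  0.5,   2.0,  2.8),
    "13":    (0.1,  0.5,   0.8,  1.6),
    "14":    (0.0,  0.6,   0.4,  0.5),
    "32":    (0.0,  0.7,   1.2,  0.8),
    "144":   (0.0,  3.4,   3.8,  4.63),
    "883":   (0.0,  4.1,   3.8,  3.5),
    "7083":  (11.5, 3.6,   4.6,  2.7),
    "7084":  (1.9,  0.3,   0.7,  1.0),
    "7087":  (0.2,  0.1,   0.2,  0.2),
    "7089":  (0.3,  0.2,   0.2,  0.4),
    "7092":  (0.4,  0.1,   0.1,  0.1),
    "7094":  (0.0,  10.0,  7.8,  6.8),
    "7105":  (0.2,  0.2,   0.1,  0.3),
    "7159":  (0.1,  0.6,   0.5,  0.4),
    "22291": (0.3,  2.8,   1.1,  0.9),
    "23687": (0.0,  4.1,   2.3,  1.8),
    "23941": (0.0,  0.1,   0.1,  0.4),
    "23942": (0.0,  0.2,   0.2,  0.1),
}

#: Mean relative abundance (%) at family/genus/clade level (Table 1).
TABLE1 = {
    ("family", "Methanobacteriaceae"):      (92.7, 89.4, 81.9, 79.0),
    ("family", "Methanomassiliicoccaceae"): (7.3, 10.7, 18.1, 21.1),
    ("genus", "Methanobrevibacter"):        (89.2, 79.0, 74.8, 72.1),
    ("clade", "ruminantium"):               (0.1, 14.2, 11.6, 10.3),
    ("clade", "gottschalkii"):              (70.0, 25.3, 36.1, 32.6),
    ("genus", "Methanosphaera"):            (3.5, 10.4, 7.1, 6.9),
}

#: Group-mean alpha diversity (Table 3): observed clusters, Margalef
#: richness, Shannon (natural log) and Simpson 1-lambda.  Structure-only
#: reference: per-sample read depths are unpublished so these group means
#: are not recomputable from the printed tables.
TABLE3 = {
    "observed": (21, 24, 24, 24),
    "margalef": (1.41, 2.22, 2.09, 2.05),
    "shannon":  (1.41, 1.83, 1.85, 1.96),
    "simpson":  (0.62, 0.74, 0.72, 0.76),
}

#: Phylogenetic assignment of the 25 clusters as reported: family for all,
#: genus for the Methanobacteriaceae clusters, clade where the study names
#: one (gottschalkii / ruminantium); None marks levels left unassigned.
CLUSTER_TAXONOMY: dict[str, tuple[str, str | None, str | None]] = {}
for _cid in ("1", "7083", "7084", "7092", "7105"):
    CLUSTER_TAXONOMY[_cid] = ("Methanobacteriaceae", "Methanobrevibacter", "gottschalkii")
for _cid in ("883", "7094"):
    CLUSTER_TAXONOMY[_cid] = ("Methanobacteriaceae", "Methanobrevibacter", "ruminantium")
for _cid in ("3", "10", "7087", "7089", "7159"):
    CLUSTER_TAXONOMY[_cid] = ("Methanobacteriaceae", "Methanobrevibacter", None)
for _cid in ("4", "22291", "23687", "23941", "23942"):
    CLUSTER_TAXONOMY[_cid] = ("Methanobacteriaceae", "Methanosphaera", None)
for _cid in ("0", "2", "6", "11", "13", "14", "32", "144"):
    CLUSTER_TAXONOMY[_cid] = ("Methanomassiliicoccaceae", None, None)

CLUSTER_IDS = tuple(TABLE2)


def table2_frame() -> pd.DataFrame:
    """Table 2 as a treatments x clusters DataFrame of printed percentages."""
    return pd.DataFrame(TABLE2, index=list(TREATMENTS)).astype(float)


def table1_frame() -> pd.DataFrame:
    idx = pd.MultiIndex.from_tuples(TABLE1.keys(), names=["rank", "taxon"])
    return pd.DataFrame(list(TABLE1.values()), index=idx, columns=list(TREATMENTS))
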