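"""Treatment-level community statistics.

Aggregation of cluster abundances to family/genus/clade, alpha diversity
(observed clusters, Margalef richness, Shannon, Simpson), Bray-Curtis
dissimilarity on square-root-transformed relative abundances, metric
(PCoA) and non-metric (nMDS, Kruskal stress-1) ordination, group-average
dendrograms, heatmap export, and the hypothesis-test layer:
Kruskal-Wallis with Benjamini-Hochberg correction, pairwise Wilcoxon
rank-sum with BH and a compact letter display, and one-way ANOVA with
Tukey HSD for the diversity indices.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from scipy.cluster.hierarchy import cophenet, leaves_list, linkage
from scipy.spatial.distance import pdist, squareform
from skbio.diversity import alpha as skbio_alpha
from skbio.stats.distance import DistanceMatrix
from skbio.stats.ordination import pcoa as skbio_pcoa
from sklearn.isotonic import IsotonicRegression
from statsmodels.stats.multitest import multipletests

RANKS = ("family", "genus", "clade")


# ---------------------------------------------------------------------------
# aggregation


def aggregate_taxa(abundance: pd.DataFrame,
                   taxonomy: Mapping[str, tuple],
                   rank: str) -> pd.DataFrame:
    """Sum cluster relative abundances into taxa at the given rank.

    Clusters without a label at that rank pool into "unassigned"; row sums
    are preserved exactly.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    level = RANKS.index(rank)
    labels = {}
    for cluster in abundance.columns:
        tax = taxonomy.get(cluster)
        label = tax[level] if tax is not None else None
        labels[cluster] = label if label not in (None, "unassigned") else "unassigned"
    return abundance.T.groupby(pd.Series(labels)).sum().T


# ---------------------------------------------------------------------------
# alpha diversity


@dataclass(frozen=True)
class DiversityRow:
    sample: str
    observed: int
    margalef: float  # (S-1)/ln N; NaN when N <= 1
    shannon: float   # natural log
    simpson: float   # 1 - sum p_i^2


def alpha_diversity(counts: Sequence[int], sample: str = "") -> DiversityRow:
    arr = np.asarray(counts)
    if (arr < 0).any():
        raise ValueError("negative counts")
    total = int(arr.sum())
    observed = int((arr > 0).sum())
    margalef = float(skbio_alpha.margalef(arr)) if total > 1 else float("nan")
    shannon = float(skbio_alpha.shannon(arr, base=np.e)) if total > 0 else 0.0
    simpson = float(skbio_alpha.simpson(arr)) if total > 0 else 0.0
    return DiversityRow(sample, observed, margalef, shannon, simpson)


def diversity_table(counts: pd.DataFrame) -> pd.DataFrame:
    rows = [alpha_diversity(counts.loc[s].to_numpy(), s) for s in counts.index]
    return pd.DataFrame(
        [(r.sample, r.observed, r.margalef, r.shannon, r.simpson) for r in rows],
        columns=["sample", "observed", "margalef", "shannon", "simpson"],
    ).set_index("sample")


# ---------------------------------------------------------------------------
# ordination


def braycurtis_matrix(abundance: pd.DataFrame, transform: str = "sqrt") -> pd.DataFrame:
    """Bray-Curtis dissimilarities between samples, after an optional
    square-root transform of the abundances."""
    data = abundance.to_numpy(dtype=float)
    if (data < 0).any():
        raise ValueError("negative abundances")
    zero_rows = list(abundance.index[data.sum(axis=1) == 0])
    if len(zero_rows) >= 2:
        raise ValueError(f"Bray-Curtis undefined between all-zero samples {zero_rows}")
    if transform == "sqrt":
        data = np.sqrt(data)
    elif transform not in (None, "none"):
        raise ValueError(f"unknown transform {transform!r}")
    condensed = pdist(data, metric="braycurtis")
    return pd.DataFrame(squareform(condensed), index=abundance.index,
                        columns=abundance.index)


def pcoa(dissimilarity: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical scaling; returns coordinates and the full eigenvalue
    spectrum (negative eigenvalues reported, not dropped)."""
    mat = dissimilarity.to_numpy(dtype=float)
    if not np.allclose(mat, mat.T):
        raise ValueError("dissimilarity matrix is not symmetric")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        result = skbio_pcoa(
            DistanceMatrix(mat, ids=[str(i) for i in dissimilarity.index]),
            method="eigh")
    coords = pd.DataFrame(result.samples.to_numpy(), index=dissimilarity.index,
                          columns=[f"PCo{i + 1}" for i in range(result.samples.shape[1])])
    return coords, result.eigvals.to_numpy()


def _stress1(dist_config: np.ndarray, disparities: np.ndarray) -> float:
    denom = (dist_config ** 2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((dist_config - disparities) ** 2).sum() / denom))


def nmds(dissimilarity: pd.DataFrame, k: int = 2, n_restarts: int = 50,
         seed: int = 0, max_iter: int = 500, tol: float = 1e-6,
         ) -> tuple[pd.DataFrame, float, list[float]]:
    """Non-metric MDS minimising Kruskal stress-1.

    SMACOF iterations with monotone (isotonic) regression of configuration
    distances on dissimilarity ranks; best of ``n_restarts`` random starts.
    Returns (coordinates, stress, stress history of the best start).
    """
    mat = dissimilarity.to_numpy(dtype=float)
    if not np.allclose(mat, mat.T):
        raise ValueError("dissimilarity matrix is not symmetric")
    n = mat.shape[0]
    if k >= n - 1 and n > 2:
        raise ValueError(f"k={k} too large for n={n}")
    iu = np.triu_indices(n, 1)
    diss = mat[iu]
    if n == 2:
        coords = np.zeros((2, k))
        coords[1, 0] = mat[0, 1]
        return (pd.DataFrame(coords, index=dissimilarity.index,
                             columns=[f"MDS{i + 1}" for i in range(k)]), 0.0, [0.0])
    order = np.argsort(diss, kind="stable")
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, list[float]] | None = None
    iso = IsotonicRegression(increasing=True)
    for _ in range(max(1, n_restarts)):
        X = rng.normal(size=(n, k))
        history: list[float] = []
        prev = np.inf
        for _ in range(max_iter):
            d = squareform(pdist(X))
            dv = d[iu]
            # monotone regression: disparities follow dissimilarity order
            fitted = iso.fit_transform(np.arange(diss.size), dv[order])
            disp = np.empty_like(dv)
            disp[order] = fitted
            stress = _stress1(dv, disp)
            history.append(stress)
            if prev - stress < tol:
                break
            prev = stress
            # Guttman transform
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(d[iu] > 0, disp / dv, 0.0)
            B = np.zeros((n, n))
            B[iu] = -ratio
            B += B.T
            np.fill_diagonal(B, -B.sum(axis=1))
            X = B @ X / n
        if best is None or history[-1] < best[0]:
            best = (history[-1], X.copy(), history)
    stress, X, history = best
    X = X - X.mean(axis=0)
    coords = pd.DataFrame(X, index=dissimilarity.index,
                          columns=[f"MDS{i + 1}" for i in range(k)])
    return coords, stress, history


def upgma_dendrogram(dissimilarity: pd.DataFrame) -> tuple[np.ndarray, list]:
    """Group-average agglomeration; returns (linkage matrix, leaf order)."""
    mat = dissimilarity.to_numpy(dtype=float)
    Z = linkage(squareform(mat, checks=False), method="average")
    order = [dissimilarity.index[i] for i in leaves_list(Z)]
    return Z, order


def cophenetic(dissimilarity: pd.DataFrame) -> pd.DataFrame:
    Z, _ = upgma_dendrogram(dissimilarity)
    coph = squareform(cophenet(Z))
    return pd.DataFrame(coph, index=dissimilarity.index, columns=dissimilarity.index)


def heatmap_export(abundance: pd.DataFrame, transform: str = "sqrt") -> pd.DataFrame:
    """Square-root-transformed abundance grid with rows (samples) and
    columns (clusters) ordered by their group-average dendrograms."""
    values = np.sqrt(abundance.to_numpy(dtype=float)) if transform == "sqrt" \
        else abundance.to_numpy(dtype=float)
    grid = pd.DataFrame(values, index=abundance.index, columns=abundance.columns)
    if grid.shape[0] > 2:
        _, row_order = upgma_dendrogram(braycurtis_matrix(abundance))
    else:
        row_order = list(grid.index)
    if grid.shape[1] > 2:
        col_diss = braycurtis_matrix(abundance.T.loc[abundance.T.sum(axis=1) > 0])
        _, col_order = upgma_dendrogram(col_diss)
        col_order += [c for c in grid.columns if c not in col_order]
    else:
        col_order = list(grid.columns)
    return grid.loc[row_order, col_order]


# ---------------------------------------------------------------------------
# hypothesis tests


@dataclass(frozen=True)
class TestResult:
    feature: str
    statistic: float
    p_raw: float
    p_adjusted: float
    letters: dict | None = None


def _check_groups(groups: Mapping[str, Sequence[float]]) -> None:
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    small = [g for g, vals in groups.items() if len(vals) < 2]
    if small:
        raise ValueError(f"group(s) with fewer than 2 samples: {small}")


def _split(values: pd.Series, treatments: Mapping[str, str]) -> dict[str, np.ndarray]:
    groups: dict[str, list[float]] = {}
    for sample, value in values.items():
        groups.setdefault(treatments[sample], []).append(float(value))
    return {g: np.asarray(v) for g, v in sorted(groups.items())}


def compact_letters(group_names: Sequence[str],
                    significant_pairs: set[tuple[str, str]]) -> dict[str, str]:
    """Compact letter display: groups sharing a letter are not
    significantly different (insert-and-absorb algorithm)."""
    letters: list[set[str]] = [set(group_names)]
    for a, b in sorted(significant_pairs):
        for block in list(letters):
            if a in block and b in block:
                letters.remove(block)
                without_a = block - {a}
                without_b = block - {b}
                for cand in (without_a, without_b):
                    if not any(cand <= other for other in letters):
                        letters.append(cand)
                letters = [blk for blk in letters
                           if not any(blk < other for other in letters)]
    letters.sort(key=lambda blk: sorted(blk))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in group_names}
    for i, block in enumerate(letters):
        for g in block:
            out[g] += alphabet[i % len(alphabet)]
    return out


def kruskal_bh(abundance: pd.DataFrame, treatments: Mapping[str, str],
               alpha: float = 0.05) -> list[TestResult]:
    """Kruskal-Wallis omnibus test per cluster, BH-corrected across
    clusters."""
    stats_, pvals, features = [], [], []
    for cluster in abundance.columns:
        groups = _split(abundance[cluster], treatments)
        _check_groups(groups)
        values = list(groups.values())
        if all(np.all(v == values[0][0]) for v in values):
            h, p = 0.0, 1.0
        else:
            h, p = scipy.stats.kruskal(*values)
        features.append(cluster)
        stats_.append(float(h))
        pvals.append(float(p))
    adjusted = multipletests(pvals, alpha=alpha, method="fdr_bh")[1]
    return [TestResult(f, s, p, float(q))
            for f, s, p, q in zip(features, stats_, pvals, adjusted)]


def pairwise_wilcoxon_bh(abundance: pd.DataFrame, treatments: Mapping[str, str],
                         alpha: float = 0.05
                         ) -> tuple[list[TestResult], dict[str, dict[str, str]]]:
    """Wilcoxon rank-sum per cluster per treatment pair, BH across all
    pairs x clusters; compact letters per cluster at the alpha level."""
    records = []
    for cluster in abundance.columns:
        groups = _split(abundance[cluster], treatments)
        _check_groups(groups)
        for a, b in itertools.combinations(sorted(groups), 2):
            ga, gb = groups[a], groups[b]
            if np.all(ga == gb[0]) and np.all(gb == gb[0]):
                stat, p = 0.0, 1.0
            else:
                stat, p = scipy.stats.mannwhitneyu(ga, gb, alternative="two-sided")
            records.append([cluster, a, b, float(stat), float(p)])
    pvals = [r[4] for r in records]
    adjusted = multipletests(pvals, alpha=alpha, method="fdr_bh")[1]
    results = [TestResult(f"{c}:{a}-{b}", s, p, float(q))
               for (c, a, b, s, p), q in zip(records, adjusted)]
    letters: dict[str, dict[str, str]] = {}
    group_names = sorted(set(treatments.values()))
    for cluster in abundance.columns:
        sig = {(r[1], r[2]) for r, q in zip(records, adjusted)
               if r[0] == cluster and q < alpha}
        letters[cluster] = compact_letters(group_names, sig)
    return results, letters


def anova_tukey(table: pd.DataFrame, treatments: Mapping[str, str],
                alpha: float = 0.05
                ) -> tuple[list[TestResult], dict[str, dict[str, str]]]:
    """One-way ANOVA per diversity index with Tukey HSD pairwise letters."""
    results: list[TestResult] = []
    letters: dict[str, dict[str, str]] = {}
    group_names = sorted(set(treatments.values()))
    for index_name in table.columns:
        values = table[index_name].dropna()
        groups = _split(values, treatments)
        _check_groups(groups)
        arrays = list(groups.values())
        if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
            results.append(TestResult(index_name, 0.0, 1.0, 1.0))
            letters[index_name] = {g: "a" for g in group_names}
            continue
        f_stat, p = scipy.stats.f_oneway(*arrays)
        with np.errstate(divide="ignore", invalid="ignore"):
            hsd = scipy.stats.tukey_hsd(*arrays)
        names = sorted(groups)
        sig = set()
        pairwise: list[TestResult] = []
        for i, j in itertools.combinations(range(len(names)), 2):
            q = float(hsd.pvalue[i, j])
            pairwise.append(TestResult(f"{index_name}:{names[i]}-{names[j]}",
                                       float(hsd.statistic[i, j]), q, q))
        for i, j in itertools.combinations(range(len(names)), 2):
            if hsd.pvalue[i, j] < alpha:
                sig.add((names[i], names[j]))
        results.append(TestResult(index_name, float(f_stat), float(p), float(p)))
        results.extend(pairwise)
        letters[index_name] = compact_letters(group_names, sig)
    return results, letters


def group_means(abundance: pd.DataFrame, treatments: Mapping[str, str]) -> pd.DataFrame:
    """Treatment-mean relative abundances (the Table 1/2 layout)."""
    frame = abundance.copy()
    frame["__treatment"] = [treatments[s] for s in frame.index]
    return frame.groupby("__treatment").mean().rename_axis("treatment")
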