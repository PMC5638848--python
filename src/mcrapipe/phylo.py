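"""Maximum-parsimony placement of cluster centroids among labelled
references, and clade/genus/family assignment.

Centroids and reference peptides are aligned progressively (pairwise
profile alignments with BLOSUM62 and affine gaps, guided by a UPGMA tree
of k-mer distances), gappy columns are masked at 85% site coverage, and
the masked alignment is searched with Fitch parsimony: random-addition
starting trees refined by first-improvement SPR hill-climbing.  Split
support comes from bootstrap resampling of the kept columns; branches
below the support floor collapse to polytomies, and each cluster inherits
the taxonomy labels shared by the reference members of the smallest
surviving clade that contains it.

Gaps are treated as missing data in parsimony (each gap cell is
compatible with every residue), so masking or removing columns can never
add changes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .seqs import AMINO_ACIDS

# ---------------------------------------------------------------------------
# alignments


@dataclass
class MaskedAlignment:
    """Aligned rows (id -> gapped string) plus the kept-column indices."""

    ids: list[str]
    rows: dict[str, str]
    kept_columns: list[int]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")
        if set(self.ids) != set(self.rows):
            raise ValueError("ids do not match rows")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def n_positions(self) -> int:
        return len(self.kept_columns)

    def masked_rows(self) -> dict[str, str]:
        cols = self.kept_columns
        return {i: "".join(row[c] for c in cols) for i, row in self.rows.items()}


_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_B62 = np.zeros((20, 20))
for _i, _a in enumerate(AMINO_ACIDS):
    for _j, _b in enumerate(AMINO_ACIDS):
        _B62[_i, _j] = _BLOSUM62[_a][_b]

# profile-level affine gap costs on the BLOSUM62 scale; strong enough
# that equal-length amplicon peptides align gap-free while genuine
# insertions (conserved flanks out of register) still open a gap
_GAP_OPEN = -13.0
_GAP_EXTEND = -2.0
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def _profile(rows: list[str]) -> np.ndarray:
    """Column frequency profile over the 20 residues (gaps weight zero)."""
    L = len(rows[0])
    prof = np.zeros((L, 20))
    for row in rows:
        for c, char in enumerate(row):
            idx = _AA_INDEX.get(char)
            if idx is not None:
                prof[c, idx] += 1.0
    return prof / len(rows)


def _align_profiles(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    """Gotoh affine profile-profile alignment; deterministic tie-breaks."""
    pa, pb = _profile(rows_a), _profile(rows_b)
    la, lb = pa.shape[0], pb.shape[0]
    score = pa @ _B62 @ pb.T  # (la, lb) expected column score
    NEG = -1e9
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)  # gap in B (consume A)
    Y = np.full((la + 1, lb + 1), NEG)  # gap in A (consume B)
    M[0, 0] = 0.0
    X[1:, 0] = _GAP_OPEN + _GAP_EXTEND * np.arange(la)
    Y[0, 1:] = _GAP_OPEN + _GAP_EXTEND * np.arange(lb)
    ptr_m = np.zeros((la + 1, lb + 1), dtype=np.uint8)  # 0=M 1=X 2=Y
    ptr_x = np.zeros((la + 1, lb + 1), dtype=np.uint8)  # 0=M 1=X
    ptr_y = np.zeros((la + 1, lb + 1), dtype=np.uint8)  # 0=M 1=Y
    for i in range(1, la + 1):
        prev_m, prev_x, prev_y = M[i - 1], X[i - 1], Y[i - 1]
        # X: vertical moves (vectorised over j)
        from_m = prev_m + _GAP_OPEN
        from_x = prev_x + _GAP_EXTEND
        X[i] = np.maximum(from_m, from_x)
        ptr_x[i] = (from_x > from_m).astype(np.uint8)
        # M: diagonal
        diag = np.maximum.reduce([prev_m[:-1], prev_x[:-1], prev_y[:-1]])
        choice = np.select(
            [prev_m[:-1] >= np.maximum(prev_x[:-1], prev_y[:-1]),
             prev_x[:-1] >= prev_y[:-1]],
            [0, 1], default=2,
        )
        M[i, 1:] = diag + score[i - 1]
        ptr_m[i, 1:] = choice
        # Y: horizontal, sequential in j
        row_m, row_y = M[i], Y[i]
        for j in range(1, lb + 1):
            fm = row_m[j - 1] + _GAP_OPEN
            fy = row_y[j - 1] + _GAP_EXTEND
            if fy > fm:
                row_y[j] = fy
                ptr_y[i, j] = 1
            else:
                row_y[j] = fm
    # traceback from the best final state (prefer M, then X, then Y)
    i, j = la, lb
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    ops: list[str] = []
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            ops.append("M")
            state = int(ptr_m[i, j])
            i, j = i - 1, j - 1
        elif state == 1 and i > 0:
            ops.append("X")
            state = int(ptr_x[i, j])
            i -= 1
        else:
            ops.append("Y")
            state = int(ptr_y[i, j]) * 2  # 0 -> M, 1 -> Y
            j -= 1
    ops.reverse()
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op == "M":
            for k, row in enumerate(rows_a):
                out_a[k] += row[ia]
            for k, row in enumerate(rows_b):
                out_b[k] += row[ib]
            ia += 1
            ib += 1
        elif op == "X":
            for k, row in enumerate(rows_a):
                out_a[k] += row[ia]
            for k in range(len(rows_b)):
                out_b[k] += "-"
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += "-"
            for k, row in enumerate(rows_b):
                out_b[k] += row[ib]
            ib += 1
    return out_a, out_b


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def align_sequences(sequences: Mapping[str, str]) -> MaskedAlignment:
    """Progressive multiple alignment guided by a UPGMA k-mer-distance tree."""
    ids = list(sequences)
    if len(ids) < 2:
        raise ValueError("need at least two sequences to align")
    seqs = [sequences[i].upper() for i in ids]
    n = len(ids)
    dist = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        dist[i, j] = dist[j, i] = _kmer_distance(seqs[i], seqs[j])
    Z = linkage(squareform(dist, checks=False), method="average")
    # merge profiles bottom-up following the UPGMA tree
    profiles: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [seqs[i]]) for i in range(n)
    }
    for step, (left, right, _, _) in enumerate(Z):
        ids_l, rows_l = profiles.pop(int(left))
        ids_r, rows_r = profiles.pop(int(right))
        new_l, new_r = _align_profiles(rows_l, rows_r)
        profiles[n + step] = (ids_l + ids_r, new_l + new_r)
    member_ids, rows = profiles.popitem()[1]
    aligned = {ids[m]: row for m, row in zip(member_ids, rows)}
    ncol = len(next(iter(aligned.values())))
    return MaskedAlignment(ids, aligned, list(range(ncol)))


def align_to_panel(centroids: Mapping[str, str], panel) -> MaskedAlignment:
    """Align cluster centroid peptides with the labelled reference panel."""
    entries = list(panel)
    if not entries:
        raise ValueError("empty reference panel")
    sequences: dict[str, str] = {e.id: e.peptide for e in entries}
    for cid, seq in centroids.items():
        if cid in sequences:
            raise ValueError(f"centroid id {cid!r} collides with a panel id")
        sequences[cid] = seq
    if len(sequences) < 3:
        raise ValueError("need at least three sequences")
    return align_sequences(sequences)


def mask_columns(alignment: MaskedAlignment,
                 site_coverage_min: float = 0.85) -> MaskedAlignment:
    """Keep columns whose non-gap fraction is >= the coverage floor."""
    n = len(alignment.ids)
    kept = []
    for c in range(alignment.n_columns):
        cover = sum(alignment.rows[i][c] != "-" for i in alignment.ids)
        if cover / n >= site_coverage_min:
            kept.append(c)
    if not kept:
        raise ValueError("no informative positions: all columns masked")
    return MaskedAlignment(alignment.ids, alignment.rows, kept)


# ---------------------------------------------------------------------------
# trees

_FULL_MASK = np.uint32((1 << 20) - 1)


def encode_alignment(alignment: MaskedAlignment) -> np.ndarray:
    """Bitmask state matrix (taxa x kept columns); gaps/unknowns are
    missing data (all states allowed)."""
    rows = alignment.masked_rows()
    codes = np.full((len(alignment.ids), alignment.n_positions), _FULL_MASK,
                    dtype=np.uint32)
    for t, name in enumerate(alignment.ids):
        for c, char in enumerate(rows[name]):
            idx = _AA_INDEX.get(char)
            if idx is not None:
                codes[t, c] = np.uint32(1 << idx)
    return codes


class Tree:
    """Unrooted tree over leaf indices 0..n-1; internal nodes get ids >= n.

    Binary during search; polytomies only appear after support collapsing.
    """

    def __init__(self, adjacency: dict[int, list[int]], n_leaves: int,
                 names: Sequence[str]) -> None:
        self.adj = adjacency
        self.n_leaves = n_leaves
        self.names = list(names)

    def copy(self) -> "Tree":
        return Tree({k: list(v) for k, v in self.adj.items()}, self.n_leaves,
                    self.names)

    def edges(self) -> list[tuple[int, int]]:
        out = []
        for u, nbrs in self.adj.items():
            for v in nbrs:
                if u < v:
                    out.append((u, v))
        return sorted(out)

    def leaves(self) -> list[int]:
        return [u for u, nbrs in self.adj.items() if len(nbrs) == 1]

    def _side_leaves(self, u: int, v: int) -> frozenset[int]:
        """Leaves on the v side of edge (u, v)."""
        seen = {u, v}
        stack = [v]
        leaves = set()
        while stack:
            node = stack.pop()
            if node < self.n_leaves:
                leaves.add(node)
            for nxt in self.adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        if v < self.n_leaves:
            leaves.add(v)
        return frozenset(leaves)

    def splits(self) -> set[frozenset[int]]:
        """Non-trivial splits, canonicalised to the side without leaf 0."""
        all_leaves = frozenset(self.leaves())
        out = set()
        for u, v in self.edges():
            if u < self.n_leaves or v < self.n_leaves:
                continue
            side = self._side_leaves(u, v)
            if 0 in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                out.add(side)
        return out

    def edge_splits(self) -> dict[tuple[int, int], frozenset[int]]:
        all_leaves = frozenset(self.leaves())
        out = {}
        for u, v in self.edges():
            side = self._side_leaves(u, v)
            if 0 in side:
                side = all_leaves - side
            out[(u, v)] = side
        return out

    def newick(self, supports: Mapping[frozenset[int], float] | None = None) -> str:
        """Newick string rooted at the neighbour of leaf 0, supports (%)
        as internal node labels."""
        all_leaves = frozenset(self.leaves())

        def label(node: int, parent: int) -> str:
            if supports is None:
                return ""
            side = self._side_leaves(parent, node)
            if 0 in side:
                side = all_leaves - side
            if side in supports:
                return f"{supports[side]:.0f}"
            return ""

        def render(node: int, parent: int) -> str:
            if node < self.n_leaves:
                return self.names[node]
            parts = [render(c, node) for c in self.adj[node] if c != parent]
            return "(" + ",".join(parts) + ")" + label(node, parent)

        root = self.adj[0][0]
        parts = [self.names[0]] + [render(c, root) for c in self.adj[root] if c != 0]
        return "(" + ",".join(parts) + ");"


def parse_newick(text: str, names: Sequence[str]) -> Tree:
    """Parse a newick string over the given leaf names (labels ignored)."""
    name_index = {n: i for i, n in enumerate(names)}
    n = len(names)
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    counter = itertools.count(n)
    pos = 0
    text = text.strip().rstrip(";")

    def parse() -> int:
        nonlocal pos
        if text[pos] == "(":
            node = next(counter)
            adj[node] = []
            pos += 1
            while True:
                child = parse()
                adj[node].append(child)
                adj[child].append(node)
                if text[pos] == ",":
                    pos += 1
                    continue
                break
            assert text[pos] == ")"
            pos += 1
            # skip internal label / branch length
            while pos < len(text) and text[pos] not in ",()":
                pos += 1
            return node
        start = pos
        while pos < len(text) and text[pos] not in ",()":
            pos += 1
        token = text[start:pos].split(":")[0]
        return name_index[token]

    root = parse()
    # suppress a degree-2 root if present
    if len(adj[root]) == 2:
        a, b = adj[root]
        adj[a].remove(root)
        adj[b].remove(root)
        adj[a].append(b)
        adj[b].append(a)
        del adj[root]
    return Tree(adj, n, list(names))


# ---------------------------------------------------------------------------
# Fitch parsimony


def _postorder(adj: dict[int, list[int]], root_leaf: int
               ) -> tuple[int, list[tuple[int, int]]]:
    """(start node, postorder list of (node, parent)) rooted at a leaf."""
    start = adj[root_leaf][0]
    order: list[tuple[int, int]] = []
    stack = [(start, root_leaf, False)]
    while stack:
        node, parent, processed = stack.pop()
        if processed or len(adj[node]) == 1:
            order.append((node, parent))
        else:
            stack.append((node, parent, True))
            for child in adj[node]:
                if child != parent:
                    stack.append((child, node, False))
    return start, order


def _fitch(adj: dict[int, list[int]], codes: np.ndarray,
           weights: np.ndarray | None, root_leaf: int) -> int:
    start, order = _postorder(adj, root_leaf)
    masks: dict[int, np.ndarray] = {}
    changes = np.zeros(codes.shape[1], dtype=np.int64)
    for node, parent in order:
        if len(adj[node]) == 1 and node != start:
            masks[node] = codes[node]
            continue
        children = [c for c in adj[node] if c != parent]
        if not children:  # start node is a leaf (two-taxon tree)
            masks[node] = codes[node]
            continue
        acc = masks.pop(children[0]) if children[0] in masks else codes[children[0]]
        for child in children[1:]:
            m = masks.pop(child) if child in masks else codes[child]
            inter = acc & m
            empty = inter == 0
            changes += empty
            acc = np.where(empty, acc | m, inter)
        masks[node] = acc
    top = masks[start]
    empty = (top & codes[root_leaf]) == 0
    changes += empty
    if weights is None:
        return int(changes.sum())
    return int((changes * weights).sum())


def fitch_length(tree: Tree, alignment: MaskedAlignment,
                 weights: np.ndarray | None = None) -> int:
    """Parsimony length of the tree on the masked alignment."""
    leaves = set(tree.leaves())
    if leaves != set(range(len(alignment.ids))):
        raise ValueError("tree leaves do not match alignment rows")
    codes = encode_alignment(alignment)
    return _fitch(tree.adj, codes, weights, 0)


# ---------------------------------------------------------------------------
# array-based search engine (numba-accelerated Fitch)
#
# During tree search the topology lives in a (2n, 3) int32 adjacency array
# (leaves 0..n-1 with one neighbour, internal nodes with three; -1 marks
# empty slots).  The Fitch kernel runs the post-order pass in nopython
# mode; the dict-based _fitch above is the plain reference implementation
# used by the public fitch_length.

from numba import njit


@njit(cache=True)
def _fitch_kernel(adj, n_leaves, codes, weights, root_leaf, masks,
                  st_node, st_parent, st_state):  # pragma: no cover - jitted
    C = codes.shape[1]
    start = -1
    for j in range(3):
        if adj[root_leaf, j] != -1:
            start = adj[root_leaf, j]
            break
    changes = np.zeros(C, np.int64)
    if start < n_leaves:  # two-taxon tree
        total = 0
        for c in range(C):
            if (codes[start, c] & codes[root_leaf, c]) == 0:
                changes[c] = 1
            total += changes[c] * weights[c]
        return total
    top = 0
    st_node[top] = start
    st_parent[top] = root_leaf
    st_state[top] = 0
    top = 1
    while top > 0:
        top -= 1
        node = st_node[top]
        parent = st_parent[top]
        state = st_state[top]
        if node < n_leaves:
            for c in range(C):
                masks[node, c] = codes[node, c]
            continue
        if state == 0:
            st_node[top] = node
            st_parent[top] = parent
            st_state[top] = 1
            top += 1
            for j in range(3):
                ch = adj[node, j]
                if ch != -1 and ch != parent:
                    st_node[top] = ch
                    st_parent[top] = node
                    st_state[top] = 0
                    top += 1
        else:
            first = True
            for j in range(3):
                ch = adj[node, j]
                if ch == -1 or ch == parent:
                    continue
                if first:
                    for c in range(C):
                        masks[node, c] = masks[ch, c]
                    first = False
                else:
                    for c in range(C):
                        inter = masks[node, c] & masks[ch, c]
                        if inter == np.uint32(0):
                            changes[c] += 1
                            masks[node, c] = masks[node, c] | masks[ch, c]
                        else:
                            masks[node, c] = inter
    total = 0
    for c in range(C):
        if (masks[start, c] & codes[root_leaf, c]) == 0:
            changes[c] += 1
        total += changes[c] * weights[c]
    return total


class _Workspace:
    """Reusable buffers for the jitted Fitch kernel."""

    def __init__(self, n_leaves: int, n_cols: int) -> None:
        cap = 2 * n_leaves + 2
        self.masks = np.empty((cap, n_cols), dtype=np.uint32)
        self.st_node = np.empty(4 * cap, dtype=np.int64)
        self.st_parent = np.empty(4 * cap, dtype=np.int64)
        self.st_state = np.empty(4 * cap, dtype=np.uint8)


def _arr_fitch(adj: np.ndarray, n_leaves: int, codes: np.ndarray,
               weights: np.ndarray, root_leaf: int, ws: _Workspace) -> int:
    return int(_fitch_kernel(adj, n_leaves, codes, weights, root_leaf,
                             ws.masks, ws.st_node, ws.st_parent, ws.st_state))


def _arr_replace(adj: np.ndarray, node: int, old: int, new: int) -> None:
    for j in range(3):
        if adj[node, j] == old:
            adj[node, j] = new
            return
    raise AssertionError("neighbour not found")


def _arr_neighbors(adj: np.ndarray, node: int) -> list[int]:
    return [int(v) for v in adj[node] if v != -1]


def _arr_edges(adj: np.ndarray, n_nodes_hint: int | None = None) -> list[tuple[int, int]]:
    out = []
    for u in range(adj.shape[0]):
        for v in adj[u]:
            if v != -1 and u < v:
                out.append((u, int(v)))
    return out


def _arr_insert_leaf(adj: np.ndarray, leaf: int, u: int, v: int, w: int) -> None:
    _arr_replace(adj, u, v, w)
    _arr_replace(adj, v, u, w)
    adj[w, 0] = u
    adj[w, 1] = v
    adj[w, 2] = leaf
    adj[leaf, 0] = w


def _arr_to_tree(adj: np.ndarray, n_leaves: int, names: Sequence[str]) -> Tree:
    mapping: dict[int, list[int]] = {}
    for u in range(adj.shape[0]):
        nbrs = _arr_neighbors(adj, u)
        if nbrs:
            mapping[u] = nbrs
    return Tree(mapping, n_leaves, names)


def _arr_random_addition(codes: np.ndarray, weights: np.ndarray,
                         order: Sequence[int], ws: _Workspace) -> np.ndarray:
    n = codes.shape[0]
    cap = 2 * n + 2
    adj = np.full((cap, 3), -1, dtype=np.int32)
    center = n
    for j, t in enumerate(order[:3]):
        adj[center, j] = t
        adj[t, 0] = center
    root_leaf = int(order[0])
    next_id = n + 1
    for i, leaf in enumerate(order[3:]):
        best_len = None
        best_edge = None
        for (u, v) in _arr_edges(adj):
            cand = adj.copy()
            _arr_insert_leaf(cand, int(leaf), u, v, next_id)
            length = _arr_fitch(cand, n, codes, weights, root_leaf, ws)
            if best_len is None or length < best_len:
                best_len, best_edge = length, (u, v)
        _arr_insert_leaf(adj, int(leaf), *best_edge, next_id)
        next_id += 1
    return adj


def _arr_spr_moves(adj: np.ndarray):
    """Yield (junction, pruned, bridge, target) descriptors as in
    _spr_moves, on the array representation."""
    edges = _arr_edges(adj)
    for u, v in edges:
        for junction, pruned in ((u, v), (v, u)):
            nbrs = _arr_neighbors(adj, junction)
            if len(nbrs) != 3:
                continue
            a, b = [w for w in nbrs if w != pruned]
            seen = {junction, pruned}
            stack = [a, b]
            comp = set()
            while stack:
                node = stack.pop()
                if node in seen:
                    continue
                seen.add(node)
                comp.add(node)
                stack.extend(_arr_neighbors(adj, node))
            for x, y in edges:
                if x not in comp or y not in comp:
                    continue
                if {x, y} == {a, b}:
                    continue
                yield junction, pruned, (a, b), (x, y)


def _arr_apply_spr(adj: np.ndarray, junction: int, pruned: int,
                   bridge: tuple[int, int], target: tuple[int, int]) -> np.ndarray:
    out = adj.copy()
    a, b = bridge
    x, y = target
    _arr_replace(out, a, junction, b)
    _arr_replace(out, b, junction, a)
    _arr_replace(out, x, y, junction)
    _arr_replace(out, y, x, junction)
    out[junction, 0] = pruned
    out[junction, 1] = x
    out[junction, 2] = y
    return out


def _arr_hill_climb(adj: np.ndarray, codes: np.ndarray, weights: np.ndarray,
                    root_leaf: int, ws: _Workspace,
                    max_passes: int | None = None) -> tuple[np.ndarray, int]:
    current = adj
    length = _arr_fitch(current, codes.shape[0], codes, weights, root_leaf, ws)
    passes = 0
    improved = True
    n = codes.shape[0]
    while improved and (max_passes is None or passes < max_passes):
        improved = False
        passes += 1
        for move in _arr_spr_moves(current):
            cand = _arr_apply_spr(current, *move)
            cand_len = _arr_fitch(cand, n, codes, weights, root_leaf, ws)
            if cand_len < length:
                current, length = cand, cand_len
                improved = True
                break
    return current, length


def _insert_leaf(tree: Tree, leaf: int, edge: tuple[int, int],
                 new_internal: int) -> None:
    u, v = edge
    tree.adj[u].remove(v)
    tree.adj[v].remove(u)
    tree.adj[new_internal] = [u, v, leaf]
    tree.adj[u].append(new_internal)
    tree.adj[v].append(new_internal)
    tree.adj[leaf] = [new_internal]


def _random_addition_tree(codes: np.ndarray, weights: np.ndarray | None,
                          order: Sequence[int], names: Sequence[str]) -> Tree:
    n = codes.shape[0]
    order = list(order)
    if n < 3:
        adj = {order[0]: [order[1]], order[1]: [order[0]]} if n == 2 else {0: []}
        return Tree(adj, n, names)
    center = n
    adj = {center: list(order[:3])}
    for t in order[:3]:
        adj[t] = [center]
    tree = Tree(adj, n, names)
    next_id = n + 1
    root_leaf = order[0]
    for leaf in order[3:]:
        best_len = None
        best_edge = None
        for edge in tree.edges():
            cand = tree.copy()
            _insert_leaf(cand, leaf, edge, next_id)
            length = _fitch(cand.adj, codes, weights, root_leaf)
            if best_len is None or length < best_len:
                best_len, best_edge = length, edge
        _insert_leaf(tree, leaf, best_edge, next_id)
        next_id += 1
    return tree


def mp_search(alignment: MaskedAlignment, random_addition_reps: int = 10,
              spr_level: int = 1, seed: int = 0,
              weights: np.ndarray | None = None,
              max_spr_passes: int | None = None) -> tuple[list[Tree], int]:
    """Best parsimony tree(s): random-addition starts + SPR hill-climbing.

    Returns every distinct minimum-length topology found and the length.
    Deterministic given the seed.  With fewer than 4 taxa the single
    unrooted topology is returned.
    """
    codes = encode_alignment(alignment)
    n = codes.shape[0]
    names = alignment.ids
    rng = np.random.default_rng(seed)
    if n < 4:
        tree = _random_addition_tree(codes, weights, list(range(n)), names)
        return [tree], _fitch(tree.adj, codes, weights, 0) if n >= 2 else 0
    w = (np.ones(codes.shape[1], dtype=np.int64) if weights is None
         else np.asarray(weights, dtype=np.int64))
    ws = _Workspace(n, codes.shape[1])
    best_arrs: list[np.ndarray] = []
    best_splits: set[frozenset[frozenset[int]]] = set()
    best_len: int | None = None
    for _ in range(random_addition_reps):
        order = [int(i) for i in rng.permutation(n)]
        start = _arr_random_addition(codes, w, order, ws)
        arr, length = _arr_hill_climb(start, codes, w, order[0], ws,
                                      max_passes=max_spr_passes)
        if best_len is None or length < best_len:
            best_arrs, best_len = [arr], length
            best_splits = {frozenset(_arr_to_tree(arr, n, names).splits())}
        elif length == best_len:
            key = frozenset(_arr_to_tree(arr, n, names).splits())
            if key not in best_splits:
                best_splits.add(key)
                best_arrs.append(arr)
    return [_arr_to_tree(a, n, names) for a in best_arrs], best_len


def strict_consensus(trees: list[Tree]) -> Tree:
    """Contract edges of the first tree whose splits are not in all trees."""
    base = trees[0].copy()
    if len(trees) == 1:
        return base
    common = set.intersection(*(t.splits() for t in trees))
    return _contract_edges(base, keep=common)


def _contract_edges(tree: Tree, keep: set[frozenset[int]]) -> Tree:
    out = tree.copy()
    changed = True
    while changed:
        changed = False
        for (u, v), split in out.edge_splits().items():
            if u < out.n_leaves or v < out.n_leaves:
                continue
            all_leaves = frozenset(out.leaves())
            if not (2 <= len(split) <= len(all_leaves) - 2):
                continue
            if split not in keep:
                # merge v into u
                out.adj[u].remove(v)
                for w in out.adj[v]:
                    if w != u:
                        out.adj[w].remove(v)
                        out.adj[w].append(u)
                        out.adj[u].append(w)
                del out.adj[v]
                changed = True
                break
    return out


@dataclass
class SupportedTree:
    """Tree (possibly with polytomies after collapsing) plus bootstrap
    supports in percent for the surviving splits."""

    tree: Tree
    supports: dict[frozenset[int], float] = field(default_factory=dict)

    def newick(self) -> str:
        return self.tree.newick(self.supports)


def bootstrap_support(alignment: MaskedAlignment, reps: int = 500,
                      collapse_below: float = 0.30, seed: int = 0,
                      addition_reps: int = 2,
                      best_trees: list[Tree] | None = None,
                      max_spr_passes: int | None = 2) -> SupportedTree:
    """Bootstrap the kept columns, re-search each replicate, and attach
    split supports to the (consensus) best tree; splits under the support
    floor collapse to polytomies.

    Replicates use fewer random-addition starts and bounded SPR passes than
    the headline search; resampling is column reweighting, which leaves
    Fitch lengths identical to explicit resampling.
    """
    if best_trees is None:
        best_trees, _ = mp_search(alignment, seed=derive_int(seed, 1))
    main = strict_consensus(best_trees)
    target_splits = main.splits()
    counts = {s: 0 for s in target_splits}
    n_cols = alignment.n_positions
    rng = np.random.default_rng(seed)
    for _ in range(reps):
        weights = np.bincount(rng.integers(0, n_cols, size=n_cols),
                              minlength=n_cols)
        rep_trees, _ = mp_search(alignment, random_addition_reps=addition_reps,
                                 seed=int(rng.integers(2**31)), weights=weights,
                                 max_spr_passes=max_spr_passes)
        rep_splits = rep_trees[0].splits()
        for s in target_splits:
            if s in rep_splits:
                counts[s] += 1
    supports = {s: 100.0 * c / reps for s, c in counts.items()}
    keep = {s for s, pct in supports.items() if pct >= 100.0 * collapse_below}
    collapsed = _contract_edges(main, keep=keep)
    surviving = collapsed.splits()
    return SupportedTree(collapsed, {s: supports[s] for s in surviving})


def derive_int(seed: int, salt: int) -> int:
    return int(np.random.default_rng([seed, salt]).integers(2**31))


# ---------------------------------------------------------------------------
# taxonomy assignment


@dataclass(frozen=True)
class TaxonomyAssignment:
    cluster_id: str
    family: str
    genus: str
    clade: str
    support: float


def assign_taxonomy(supported: SupportedTree,
                    panel_taxonomy: Mapping[str, tuple[str, str, str]]
                    ) -> dict[str, TaxonomyAssignment]:
    """Assign each non-panel leaf the labels shared by the panel members of
    the smallest surviving clade containing it.

    Label levels that disagree within that clade become "unassigned".
    """
    tree = supported.tree
    names = tree.names
    leaf_ids = tree.leaves()
    panel_leaves = {i for i in leaf_ids if names[i] in panel_taxonomy}
    if not panel_leaves:
        raise ValueError("tree contains no panel leaves")
    cluster_leaves = [i for i in leaf_ids if i not in panel_leaves]
    all_leaves = frozenset(leaf_ids)
    # candidate clades: both sides of every internal edge (leaf edges give
    # only trivial splits, not clades)
    sides = []
    for (u, v) in tree.edges():
        if u < tree.n_leaves or v < tree.n_leaves:
            continue
        side = tree._side_leaves(u, v)
        sides.append(side)
        sides.append(all_leaves - side)
    out: dict[str, TaxonomyAssignment] = {}
    for leaf in sorted(cluster_leaves, key=lambda i: names[i]):
        candidates = [s for s in sides if leaf in s and s & panel_leaves]
        candidates.sort(key=lambda s: (len(s), sorted(names[i] for i in s)))
        if candidates:
            clade_set = candidates[0]
            canonical = clade_set if 0 not in clade_set else all_leaves - clade_set
            support = supported.supports.get(frozenset(canonical), 100.0)
        else:  # fully collapsed (star) tree: only the whole leaf set remains
            clade_set = all_leaves
            support = 0.0
        labels = []
        for level in range(3):
            values = {panel_taxonomy[names[i]][level]
                      for i in clade_set & panel_leaves}
            values.discard(None)
            labels.append(values.pop() if len(values) == 1 else "unassigned")
        out[names[leaf]] = TaxonomyAssignment(names[leaf], labels[0], labels[1],
                                              labels[2], support)
    return out
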