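"""Distance-based phylogenetics for short miRNA sequences.

A center-star multiple alignment (center = sequence with the smallest
summed pairwise edit distance; pairwise global alignment with match +1,
mismatch -1, gap -2; merged under once-a-gap-always-a-gap) feeds
p-distances (proportion of differing sites over columns where both taxa
are ungapped; Jukes-Cantor correction optional) into Saitou-Nei
neighbor joining with a deterministic lowest-index tie-break.  Edge
supports come from column-resampling bootstrap: the percentage of
replicate NJ trees containing each internal bipartition of the original
tree.  Negative NJ branch-length estimates are clamped to zero and
flagged rather than propagated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align


# --------------------------------------------------------------------------
# tree representation

@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    support: int | None = None
    children: list["TreeNode"] = field(default_factory=list)
    length_clamped: bool = False

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        return [lf for c in self.children for lf in c.leaves()]

    def leaf_names(self) -> frozenset[str]:
        return frozenset(lf.name for lf in self.leaves())

    def _newick(self, with_length: bool = True) -> str:
        if self.is_leaf():
            label = self.name or ""
        else:
            inner = ",".join(c._newick(with_length) for c in self.children)
            label = f"({inner})"
            if self.support is not None:
                label += str(self.support)
        if with_length:
            label += f":{self.length:.6g}"
        return label

    def to_newick(self) -> str:
        if self.is_leaf():
            return (self.name or "") + ";"
        inner = ",".join(c._newick() for c in self.children)
        return f"({inner});"


@dataclass
class PhyloTree:
    root: TreeNode  # unrooted: root is an internal node of degree >= 3
    n_clamped: int = 0

    def to_newick(self) -> str:
        return self.root.to_newick()

    def leaf_names(self) -> frozenset[str]:
        return self.root.leaf_names()

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each encoded by its lexicographically smaller side."""
        all_leaves = self.leaf_names()
        n = len(all_leaves)
        out: set[frozenset[str]] = set()
        def walk(node: TreeNode):
            for child in node.children:
                side = child.leaf_names()
                if 2 <= len(side) <= n - 2:
                    other = all_leaves - side
                    out.add(min(side, other, key=lambda s: sorted(s)))
                walk(child)
        walk(self.root)
        return out


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0) or np.any(self.d < -1e-12):
            raise ValueError("distances must be non-negative with zero diagonal")


# --------------------------------------------------------------------------
# alignment and distances

def _pair_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def _edit_cost(ga: str, gb: str) -> int:
    return sum(1 for a, b in zip(ga, gb) if a != b)


def _merge_into_master(master: str, rows: list[str], gc: str, gs: str):
    """Merge a (center,seq) pairwise alignment into the running MSA.

    ``master`` is the center with all gaps accumulated so far; ``gc``/``gs``
    are the new pairwise gapped center and sequence.  Existing rows gain
    gaps wherever gc introduces new ones, and gs gains gaps wherever the
    master already had them (once a gap, always a gap)."""
    i = j = 0
    new_master: list[str] = []
    new_rows: list[list[str]] = [[] for _ in rows]
    new_gs: list[str] = []
    while i < len(master) or j < len(gc):
        mc = master[i] if i < len(master) else None
        cc = gc[j] if j < len(gc) else None
        if mc is not None and cc is not None and mc == cc:
            new_master.append(mc)
            for r, row in zip(new_rows, rows):
                r.append(row[i])
            new_gs.append(gs[j])
            i += 1
            j += 1
        elif mc == "-" and cc != "-":
            new_master.append("-")
            for r, row in zip(new_rows, rows):
                r.append(row[i])
            new_gs.append("-")
            i += 1
        elif cc == "-":
            new_master.append("-")
            for r in new_rows:
                r.append("-")
            new_gs.append(gs[j])
            j += 1
        else:  # both non-gap, same residue stream => must match
            new_master.append(mc)
            for r, row in zip(new_rows, rows):
                r.append(row[i])
            new_gs.append(gs[j])
            i += 1
            j += 1
    return "".join(new_master), ["".join(r) for r in new_rows], "".join(new_gs)


@dataclass
class Alignment:
    names: list[str]
    rows: list[str]  # equal-length gapped strings

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        cols = rng.integers(0, self.n_columns, size=self.n_columns)
        return Alignment(
            self.names, ["".join(r[c] for c in cols) for r in self.rows]
        )


def p_distance_matrix(alignment: Alignment, jukes_cantor: bool = False) -> DistanceMatrix:
    names, rows = alignment.names, alignment.rows
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = [(a, b) for a, b in zip(rows[i], rows[j]) if a != "-" and b != "-"]
            if both:
                p = sum(1 for a, b in both if a != b) / len(both)
            else:
                p = 0.0
            if jukes_cantor:
                p = -0.75 * math.log(max(1e-12, 1 - 4 * p / 3)) if p < 0.75 else 3.0
            d[i, j] = d[j, i] = p
    return DistanceMatrix(list(names), d)


def align_and_distance(
    sequences: list[tuple[str, str]], jukes_cantor: bool = False
) -> tuple[Alignment, DistanceMatrix]:
    """Center-star MSA and the resulting p-distance matrix."""
    if len(sequences) < 3:
        raise ValueError("need at least 3 sequences")
    names = [n for n, _ in sequences]
    seqs = [s.upper().replace("U", "T") for _, s in sequences]
    aligner = _pair_aligner()
    n = len(seqs)
    cost = np.zeros((n, n))
    pairs: dict[tuple[int, int], tuple[str, str]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            aln = aligner.align(seqs[i], seqs[j])[0]
            ga, gb = str(aln[0]), str(aln[1])
            pairs[(i, j)] = (ga, gb)
            cost[i, j] = cost[j, i] = _edit_cost(ga, gb)
    center = int(np.argmin(cost.sum(axis=1)))
    master = seqs[center]
    order = [center]
    rows: list[str] = []
    for k in range(n):
        if k == center:
            continue
        if (center, k) in pairs:
            gc, gs = pairs[(center, k)]
        else:
            gs, gc = pairs[(k, center)]
        master, rows, new_row = _merge_into_master(master, rows, gc, gs)
        rows.append(new_row)
        order.append(k)
    all_rows = {order[0]: master}
    for idx, row in zip(order[1:], rows):
        all_rows[idx] = row
    alignment = Alignment(names, [all_rows[i] for i in range(n)])
    return alignment, p_distance_matrix(alignment, jukes_cantor)


# --------------------------------------------------------------------------
# neighbor joining

def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei NJ with the standard Q-criterion.

    Ties in Q resolve to the lowest (i, j) index pair; negative branch
    estimates are clamped to zero and counted in ``n_clamped``."""
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.taxa]
    d = dm.d.astype(float).copy()
    active = list(range(n))
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        r = {a: sum(d[a, b] for b in active if b != a) for a in active}
        best = None
        for ai in range(m):
            for bi in range(ai + 1, m):
                a, b = active[ai], active[bi]
                q = (m - 2) * d[a, b] - r[a] - r[b]
                if best is None or q < best[0] - 1e-12:
                    best = (q, a, b)
        _, a, b = best
        la = 0.5 * d[a, b] + (r[a] - r[b]) / (2 * (m - 2))
        lb = d[a, b] - la
        na, nb = nodes[a], nodes[b]
        na.length, nb.length = clamp(la), clamp(lb)
        parent = TreeNode(children=[na, nb])
        # grow matrix with the new node
        d = np.pad(d, ((0, 1), (0, 1)))
        u = d.shape[0] - 1
        for c in active:
            if c in (a, b):
                continue
            d[u, c] = d[c, u] = 0.5 * (d[a, c] + d[b, c] - d[a, b])
        nodes.append(parent)
        active = [c for c in active if c not in (a, b)] + [u]

    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for idx, l in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = clamp(l)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return PhyloTree(root, n_clamped=clamped)


def bootstrap(
    alignment: Alignment,
    n_replicates: int = 1000,
    seed: int = 0,
    jukes_cantor: bool = False,
) -> PhyloTree:
    """Column-resampling bootstrap supports on the NJ tree of an alignment."""
    tree = neighbor_joining(p_distance_matrix(alignment, jukes_cantor))
    if n_replicates <= 0:
        return tree
    rng = np.random.default_rng(seed)
    originals = tree.bipartitions()
    counts = {bp: 0 for bp in originals}
    for _ in range(n_replicates):
        rep = alignment.resample_columns(rng)
        rep_tree = neighbor_joining(p_distance_matrix(rep, jukes_cantor))
        for bp in rep_tree.bipartitions():
            if bp in counts:
                counts[bp] += 1
    all_leaves = tree.leaf_names()
    n = len(all_leaves)

    def annotate(node: TreeNode):
        for child in node.children:
            side = child.leaf_names()
            if not child.is_leaf() and 2 <= len(side) <= n - 2:
                key = min(side, all_leaves - side, key=lambda s: sorted(s))
                child.support = round(100 * counts[key] / n_replicates)
            annotate(child)

    annotate(tree.root)
    return tree
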