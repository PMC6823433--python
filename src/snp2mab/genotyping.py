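"""KASP allele-call analysis: homozygosity, dissimilarity, UPGMA, Newick.

Calls are the four KASP states ``AA``/``BB`` (homozygous), ``AB``
(heterozygous) and ``NA`` (failed/missing).  Missing calls are pairwise-
deleted: each pair of lines is compared only over markers called in both.

UPGMA is implemented directly (size-weighted average linkage, merge height =
distance/2, deterministic lexicographic tie-break on the smallest leaf labels)
so that trees are reproducible bit-for-bit across platforms; the generic
average-linkage routines in scipy serve as an independent cross-check in the
test suite, not as the implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import round_half_away

__all__ = [
    "CALL_CODES",
    "AlleleCallMatrix",
    "DistanceMatrix",
    "TreeNode",
    "UltrametricTree",
    "homozygosity",
    "dissimilarity",
    "upgma",
    "to_newick",
    "cut_tree",
    "read_calls_tsv",
    "write_calls_tsv",
    "write_distance_tsv",
]

#: integer codes used internally; -1 is missing
CALL_CODES = {"AA": 0, "BB": 1, "AB": 2, "NA": -1}
CODE_CALLS = {v: k for k, v in CALL_CODES.items()}

#: alleles carried by each call state, for allele-sharing distances
_ALLELES = {0: ("A", "A"), 1: ("B", "B"), 2: ("A", "B")}


@dataclass
class AlleleCallMatrix:
    """Lines x markers KASP call matrix (codes per :data:`CALL_CODES`)."""

    lines: list[str]
    markers: list[str]
    calls: np.ndarray  # int8, shape (n_lines, n_markers)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.lines), len(self.markers)):
            raise ValueError(
                f"call matrix shape {self.calls.shape} does not match "
                f"{len(self.lines)} lines x {len(self.markers)} markers"
            )
        if len(set(self.lines)) != len(self.lines) or len(set(self.markers)) != len(self.markers):
            raise ValueError("line and marker IDs must be unique")

    @property
    def shape(self) -> tuple[int, int]:
        return self.calls.shape

    def to_frame(self) -> pd.DataFrame:
        tokens = np.vectorize(CODE_CALLS.get)(self.calls)
        return pd.DataFrame(tokens, index=self.lines, columns=self.markers)


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"distance matrix shape {v.shape} for {n} ids")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.nanmin(v) < 0 or np.nanmax(v) > 1:
            raise ValueError("dissimilarities must lie in [0, 1]")
        self.values = v


def homozygosity(matrix: AlleleCallMatrix) -> pd.Series:
    """Per-line percentage of homozygous calls among non-missing calls (1 dp).

    Lines with no calls get NaN.
    """
    out = {}
    for i, line in enumerate(matrix.lines):
        row = matrix.calls[i]
        called = row[row >= 0]
        if called.size == 0:
            out[line] = float("nan")
        else:
            hom = int(np.sum((called == 0) | (called == 1)))
            out[line] = round_half_away(100.0 * hom / called.size, 1)
    return pd.Series(out, name="homozygosity_pct")


def dissimilarity(matrix: AlleleCallMatrix, mode: str = "simple_mismatch") -> DistanceMatrix:
    """Pairwise per-cent dissimilarity on shared (both-called) markers.

    ``simple_mismatch``: fraction of shared markers whose call states differ.
    ``allele_sharing``: 1 - (number of shared alleles / 2) averaged over
    shared markers (AA vs AB -> 0.5, AA vs BB -> 1.0, AB vs AB -> 0.0).
    """
    if mode not in ("simple_mismatch", "allele_sharing"):
        raise ValueError(f"unknown mode {mode!r}")
    n = len(matrix.lines)
    if n < 2:
        raise ValueError("need at least two lines")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = matrix.calls[i], matrix.calls[j]
            shared = (a >= 0) & (b >= 0)
            if not np.any(shared):
                raise ValueError(
                    f"lines {matrix.lines[i]} and {matrix.lines[j]} share no called markers"
                )
            if mode == "simple_mismatch":
                d[i, j] = d[j, i] = float(np.mean(a[shared] != b[shared]))
            else:
                vals = []
                for ca, cb in zip(a[shared], b[shared]):
                    pa, pb = _ALLELES[int(ca)], _ALLELES[int(cb)]
                    shared_alleles = 0
                    remaining = list(pb)
                    for allele in pa:
                        if allele in remaining:
                            remaining.remove(allele)
                            shared_alleles += 1
                    vals.append(1.0 - shared_alleles / 2.0)
                d[i, j] = d[j, i] = float(np.mean(vals))
    return DistanceMatrix(list(matrix.lines), d)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    height: float
    name: Optional[str] = None  # leaf label
    children: tuple["TreeNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class UltrametricTree:
    root: TreeNode
    leaf_names: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.leaf_names = self.root.leaves()
        self._check_heights(self.root)

    def _check_heights(self, node: TreeNode) -> None:
        for c in node.children:
            if c.height > node.height + 1e-12:
                raise ValueError("node heights must be non-decreasing toward the root")
            self._check_heights(c)

    def internal_heights(self) -> list[float]:
        out: list[float] = []

        def walk(n: TreeNode) -> None:
            if not n.is_leaf:
                out.append(n.height)
                for c in n.children:
                    walk(c)

        walk(self.root)
        return sorted(out)


def upgma(distances: DistanceMatrix) -> UltrametricTree:
    """Size-weighted (proportional) average-linkage agglomeration.

    At every step the closest pair of clusters merges at height d/2; the new
    cluster's distance to any other is the member-count-weighted mean of the
    two old distances.  Distance ties are broken toward the lexicographically
    smallest (min-leaf-label) pair, so the tree is deterministic.
    """
    d = distances.values
    if np.any(np.isnan(d)):
        raise ValueError("distance matrix contains NaN")
    n = len(distances.ids)
    if n == 1:
        return UltrametricTree(TreeNode(0.0, name=distances.ids[0]))
    clusters: dict[int, TreeNode] = {
        i: TreeNode(0.0, name=distances.ids[i]) for i in range(n)
    }
    sizes = {i: 1 for i in range(n)}
    labels = {i: distances.ids[i] for i in range(n)}  # min leaf label per cluster
    dist = {
        (i, j): float(d[i, j]) for i in range(n) for j in range(i + 1, n)
    }

    def key(i: int, j: int) -> tuple[float, str, str]:
        la, lb = sorted((labels[i], labels[j]))
        return (dist[(min(i, j), max(i, j))], la, lb)

    next_id = n
    while len(clusters) > 1:
        ids = sorted(clusters)
        best = min(
            ((i, j) for a, i in enumerate(ids) for j in ids[a + 1 :]),
            key=lambda p: key(*p),
        )
        i, j = best
        h = dist[(i, j)] / 2.0
        a, b = clusters[i], clusters[j]
        # child order: smaller min-leaf-label first
        if labels[j] < labels[i]:
            a, b = b, a
        merged = TreeNode(h, children=(a, b))
        si, sj = sizes[i], sizes[j]
        for k in ids:
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dist[(min(next_id, k), max(next_id, k))] = (si * dik + sj * djk) / (si + sj)
        clusters.pop(i), clusters.pop(j)
        clusters[next_id] = merged
        sizes[next_id] = si + sj
        labels[next_id] = min(labels[i], labels[j])
        next_id += 1
    return UltrametricTree(next(iter(clusters.values())))


def _fmt(x: float) -> str:
    s = f"{round(x, 6):.6f}".rstrip("0")
    return s + "0" if s.endswith(".") else s


def to_newick(tree: UltrametricTree) -> str:
    """Newick with branch lengths parent height - child height (6 dp)."""

    def render(node: TreeNode, parent_height: Optional[float]) -> str:
        if node.is_leaf:
            core = node.name
        else:
            core = "(" + ",".join(render(c, node.height) for c in node.children) + ")"
        bl = (parent_height - node.height) if parent_height is not None else 0.0
        return f"{core}:{_fmt(bl)}"

    root = tree.root
    if root.is_leaf:
        return f"{root.name}:{_fmt(0.0)};"
    inner = ",".join(render(c, root.height) for c in root.children)
    return f"({inner});"


def cut_tree(tree: UltrametricTree, k: int) -> dict[str, int]:
    """Leaf -> cluster index (0-based) for the k-cluster cut.

    The cut sits between the (n-k)-th and (n-k+1)-th merge heights; equal
    heights straddling the cut are ambiguous and raise.
    """
    n = len(tree.leaf_names)
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if k == n:
        return {name: i for i, name in enumerate(sorted(tree.leaf_names))}
    if k == 1:
        return {name: 0 for name in tree.leaf_names}
    heights = tree.internal_heights()  # n-1 merges, ascending
    lo, hi = heights[n - k - 1], heights[n - k]
    if abs(hi - lo) < 1e-12:
        raise ValueError(
            f"tied merge heights ({lo}) straddle the {k}-cluster cut; "
            "supply an explicit cut height"
        )
    threshold = (lo + hi) / 2.0

    groups: list[list[str]] = []

    def walk(node: TreeNode) -> None:
        if node.is_leaf or node.height < threshold:
            groups.append(node.leaves())
        else:
            for c in node.children:
                walk(c)

    walk(tree.root)
    assert len(groups) == k
    groups.sort(key=lambda g: min(g))
    return {leaf: idx for idx, group in enumerate(groups) for leaf in group}


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------


def read_calls_tsv(path: str) -> AlleleCallMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str).fillna("NA")
    codes = df.apply(lambda col: col.map(CALL_CODES)).to_numpy()
    if np.any(pd.isna(codes)):
        bad = df.to_numpy()[pd.isna(codes)]
        raise ValueError(f"unknown call token(s): {sorted(set(bad))[:5]}")
    return AlleleCallMatrix(list(df.index), list(df.columns), codes.astype(np.int8))


def write_calls_tsv(matrix: AlleleCallMatrix, path: str) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="line")


def write_distance_tsv(dm: DistanceMatrix, path: str) -> None:
    pd.DataFrame(dm.values, index=dm.ids, columns=dm.ids).to_csv(
        path, sep="\t", index_label="line", float_format="%.6f"
    )
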