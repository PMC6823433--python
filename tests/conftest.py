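"""Shared fixtures and independent brute-force oracles.

The oracle functions here are deliberately naive re-statements of the filter
predicates and of UPGMA, kept free of any code from the package's own
implementations so that agreement is meaningful.
"""

from __future__ import annotations

import numpy as np
import pytest

from snp2mab.model import GenotypeMatrix, VariantRecord


def V(chrom, pos, ref, alts, calls):
    return VariantRecord(chrom, pos, ref, tuple(alts), tuple(calls))


def single_snp_matrix(calls, ref="A", alts=("G",), chrom="Chr1", pos=1000, size=100000):
    v = V(chrom, pos, ref, alts, calls)
    acc = [f"K{i:02d}" for i in range(len(calls))]
    return GenotypeMatrix([v], acc, {chrom: size})


def matrix_of(variants, n_acc, sizes):
    acc = [f"K{i:02d}" for i in range(n_acc)]
    return GenotypeMatrix(list(variants), acc, dict(sizes))


# ---------------------------------------------------------------------------
# Brute-force filter oracles
# ---------------------------------------------------------------------------


def oracle_hom_diallelic(v) -> bool:
    genos = [c for c in v.calls if c is not None]
    if any(a != b for a, b in genos):
        return False
    alleles = sorted({a for c in genos for a in c})
    if len(alleles) != 2:
        return False
    return all(any(c == (x, x) for c in genos) for x in alleles)


def oracle_distinguishable(v, k, mode) -> bool:
    genos = [c for c in v.calls if c is not None]
    if mode == "callable":
        return len(genos) >= k
    classes = {}
    for c in genos:
        classes[c] = classes.get(c, 0) + 1
    if len(classes) < 2:
        return False
    return min(classes.values()) >= k


def oracle_seg_ratio(v, lo, hi) -> bool:
    genos = [c for c in v.calls if c is not None]
    if not genos:
        return False
    classes = {}
    for c in genos:
        classes[c] = classes.get(c, 0) + 1
    if len(classes) < 2:
        return False
    minor = min(classes.values()) / len(genos)
    return lo <= minor <= hi


def oracle_prune(variants, window):
    """Quadratic pairwise check; returns the set of retained (chrom, pos)."""
    keep = set()
    for v in variants:
        close = any(
            u is not v and u.chrom == v.chrom and abs(u.pos - v.pos) <= window
            for u in variants
        )
        if not close:
            keep.add((v.chrom, v.pos))
    return keep


# ---------------------------------------------------------------------------
# Naive UPGMA reference (merge order + heights)
# ---------------------------------------------------------------------------


def oracle_upgma_merges(ids, d):
    """Return [(frozenset_left, frozenset_right, height), ...] by the plain
    textbook algorithm with lexicographic min-leaf tie-break."""
    d = {(i, j): d[i][j] for i in range(len(ids)) for j in range(len(ids)) if i != j}
    clusters = {i: frozenset([ids[i]]) for i in range(len(ids))}
    sizes = {i: 1 for i in range(len(ids))}
    merges = []
    nid = len(ids)
    while len(clusters) > 1:
        keys = sorted(clusters)
        best, best_key = None, None
        for a_i, i in enumerate(keys):
            for j in keys[a_i + 1 :]:
                tie = tuple(sorted((min(clusters[i]), min(clusters[j]))))
                cand = (d[(i, j)],) + tie
                if best_key is None or cand < best_key:
                    best_key, best = cand, (i, j)
        i, j = best
        h = d[(i, j)] / 2
        merges.append((clusters[i], clusters[j], h))
        for k in keys:
            if k in (i, j):
                continue
            val = (sizes[i] * d[(i, k)] + sizes[j] * d[(j, k)]) / (sizes[i] + sizes[j])
            d[(nid, k)] = d[(k, nid)] = val
        clusters[nid] = clusters.pop(i) | clusters.pop(j)
        sizes[nid] = sizes.pop(i) + sizes.pop(j)
        nid += 1
    return merges


def tree_merges(tree):
    """Extract (left leafset, right leafset, height) of every internal node,
    in ascending height order (stable on construction order)."""
    out = []

    def walk(n):
        if n.children:
            out.append(
                (frozenset(n.children[0].leaves()), frozenset(n.children[1].leaves()), n.height)
            )
            for c in n.children:
                walk(c)

    walk(tree.root)
    out.sort(key=lambda t: (t[2], sorted(t[0] | t[1])))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
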