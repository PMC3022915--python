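"""Distance-based phylogenetics: p-distances, neighbor joining, bootstrap.

The tree builder is the Saitou-Nei neighbor-joining algorithm on p-distances
(proportion of mismatched sites, gapped sites pairwise-deleted; an optional
Poisson correction −ln(1−p) is available).  Joins minimise the Q criterion
with a deterministic tie-break on the lexicographically smallest pair of
subtree labels, so results are reproducible across platforms.  Negative
branch-length estimates are clamped to zero and the deficit moved to the
sister branch, preserving the path length between the joined nodes.

Bootstrap support of an internal edge is the percentage of
column-resampled replicates whose NJ tree contains the same bipartition of
the taxon set.  Replicate *r* draws its columns from an RNG substream seeded
by (seed, r), so supports do not depend on evaluation order.
"""

from __future__ import annotations

import math

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .seqio import NamedSequence


def _rows(msa):
    out = []
    for s in msa:
        if isinstance(s, NamedSequence):
            out.append((s.id, s.seq))
        else:
            out.append((f"seq{len(out)}", str(s)))
    return out


def distance_matrix(msa, model: str = "p") -> DistanceMatrix:
    """Pairwise distances from an alignment.

    ``model="p"`` gives the p-distance with pairwise deletion of gapped
    sites; ``model="poisson"`` applies the correction −ln(1−p).  A pair with
    no comparable sites, or p = 1 under the Poisson model, is an error.
    """
    rows = _rows(msa)
    if len({len(seq) for _, seq in rows}) != 1:
        raise ValueError("alignment rows differ in length")
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = rows[i][1], rows[j][1]
            comp = mism = 0
            for x, y in zip(a, b):
                if x == "-" or y == "-":
                    continue
                comp += 1
                if x != y:
                    mism += 1
            if comp == 0:
                raise ValueError(
                    f"no comparable sites between {rows[i][0]!r} and {rows[j][0]!r}"
                )
            p = mism / comp
            if model == "p":
                d[i, j] = d[j, i] = p
            elif model == "poisson":
                if p >= 1.0:
                    raise ValueError("Poisson correction undefined at p = 1")
                d[i, j] = d[j, i] = -np.log(1.0 - p)
            else:
                raise ValueError(f"unknown distance model {model!r}")
    return DistanceMatrix(d, ids=[name for name, _ in rows])


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; returns an unrooted tree (trifurcating
    root node) with branch lengths."""
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    d = dm.data.astype(float).copy()
    nodes = [TreeNode(name=name) for name in dm.ids]
    # tie-break key: smallest leaf label in each subtree
    keys = list(dm.ids)
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        # fsum: exact summation, so results do not depend on taxon order
        r = {i: math.fsum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((keys[i], keys[j])))
                cand = (q, pair_key, i, j)
                if best is None or cand < best:
                    best = cand
        _, _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        nodes[i].length = li
        nodes[j].length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        # new distances
        new = np.zeros(d.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            new[k] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        d = np.pad(d, ((0, 1), (0, 1)))
        u = d.shape[0] - 1
        d[u, : u] = new[: u]
        d[: u, u] = new[: u]
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for idx, length in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = max(length, 0.0)
    return TreeNode(children=[nodes[i], nodes[j], nodes[k]])


def bipartitions(tree: TreeNode) -> set:
    """Non-trivial bipartitions of the leaf set, canonicalised so that a
    bipartition compares equal regardless of which side is listed."""
    leaves = frozenset(t.name for t in tree.tips())
    bips = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(leaves) - 1:
            other = leaves - side
            bips.add(min(tuple(sorted(side)), tuple(sorted(other))))
    return bips


def bootstrap_support(msa, n_reps: int = 1000, seed: int = 0,
                      model: str = "p") -> TreeNode:
    """NJ tree with bootstrap supports on its internal edges.

    Columns are resampled with replacement ``n_reps`` times; each internal
    edge of the reference tree is annotated (``node.support`` and the node
    name) with the percentage of replicates containing its bipartition.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rows = _rows(msa)
    ncol = len(rows[0][1])
    ref = neighbor_joining(distance_matrix(msa, model=model))
    counts = {bip: 0 for bip in bipartitions(ref)}
    for rep in range(n_reps):
        rng = np.random.default_rng((int(seed), rep))
        cols = rng.integers(0, ncol, size=ncol)
        resampled = [
            NamedSequence(name, "".join(seq[c] for c in cols), "aa")
            for name, seq in rows
        ]
        try:
            rep_bips = bipartitions(
                neighbor_joining(distance_matrix(resampled, model=model))
            )
        except ValueError:  # replicate with no comparable sites for a pair
            continue
        for bip in counts:
            if bip in rep_bips:
                counts[bip] += 1
    _annotate_supports(ref, {b: 100.0 * c / n_reps for b, c in counts.items()})
    return ref


def _annotate_supports(tree: TreeNode, support_by_bip: dict) -> None:
    leaves = frozenset(t.name for t in tree.tips())
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if not (1 < len(side) < len(leaves) - 1):
            continue
        key = min(tuple(sorted(side)), tuple(sorted(leaves - side)))
        if key in support_by_bip:
            pct = support_by_bip[key]
            node.support = pct
            node.name = f"{pct:g}"


def root_with_outgroup(tree: TreeNode, label: str) -> TreeNode:
    """Root a tree on the pendant edge of the outgroup leaf *label*.

    Bipartition supports are preserved: they are re-attached to the
    corresponding internal nodes of the rooted tree.
    """
    try:
        tree.find(label)
    except Exception as exc:
        raise ValueError(f"outgroup {label!r} not in tree") from exc
    supports = {}
    leaves = frozenset(t.name for t in tree.tips())
    for node in tree.non_tips(include_self=False):
        if hasattr(node, "support"):
            side = frozenset(t.name for t in node.tips())
            key = min(tuple(sorted(side)), tuple(sorted(leaves - side)))
            supports[key] = node.support
    work = tree.copy()
    rooted = work.root_at(work.find(label), above=True)
    _annotate_supports(rooted, supports)
    return rooted


def unroot(tree: TreeNode) -> TreeNode:
    """Collapse a bifurcating root into the usual unrooted (trifurcating)
    representation."""
    t = tree.copy()
    t.unroot()
    return t
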