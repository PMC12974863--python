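"""Distance-based trees and backbone quantification.

Trees are built with neighbor joining from a strain-by-strain Hamming
distance matrix — the goal is tree *shape* diagnostics on binary simulated
data, not substitution-model inference, so a fast distance method is the
appropriate tool. The backbone score quantifies how much of a tree's
internal branch length can be collected on one simple path: a tree whose
internal branches all lie on a single path (a caterpillar) scores 1, a
star scores 0, and a value near 1 on a data tree indicates the backboned
shape where lineages radiate from points along a central line.
"""

from __future__ import annotations

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

__all__ = ["nj_tree", "backbone_score", "read_newick", "write_newick"]


def nj_tree(dist, ids=None) -> TreeNode:
    """Neighbor-joining tree from a symmetric zero-diagonal distance matrix.

    Negative branch-length estimates are clamped to zero. Requires at least
    three strains.
    """
    dist = np.asarray(dist, dtype=np.float64)
    n = dist.shape[0]
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 strains")
    if dist.shape != (n, n) or not np.allclose(dist, dist.T) or np.any(np.diag(dist) != 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if ids is None:
        ids = [f"strain_{i}" for i in range(n)]
    tree = nj(DistanceMatrix(dist, ids=list(ids)))
    for node in tree.traverse(include_self=True):
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def _edges(tree: TreeNode):
    """(parent, child, length) triples with a degree-2 root suppressed, so
    the edge set matches the unrooted topology."""
    root = tree
    edges = []
    for node in root.traverse(include_self=False):
        edges.append((node.parent, node, float(node.length or 0.0)))
    children = root.children
    if len(children) == 2:
        a, b = children
        merged = float(a.length or 0.0) + float(b.length or 0.0)
        edges = [e for e in edges if e[1] is not a and e[1] is not b]
        edges.append((a, b, merged))
    return edges


def backbone_score(tree: TreeNode) -> float:
    """Fraction of total internal branch length carried by the best single
    connected path of branches.

    Internal branches are those with no tip endpoint (unrooted reading; a
    degree-2 root is suppressed). The maximum over simple paths of the
    internal length collected along the path — the weighted diameter of the
    internal-branch subtree — is divided by the total internal branch
    length. Returns 0 when there is no internal branch length (a star).
    """
    tips = [t for t in tree.tips()]
    if len(tips) < 3:
        raise ValueError("backbone score requires a tree with at least 3 tips")
    edges = _edges(tree)
    internal = [
        (u, v, w) for (u, v, w) in edges if not u.is_tip() and not v.is_tip()
    ]
    total = sum(w for _, _, w in internal)
    if not internal or total <= 0:
        return 0.0
    adj: dict[int, list[tuple[int, float]]] = {}
    nodes: dict[int, TreeNode] = {}
    for u, v, w in internal:
        for a in (u, v):
            nodes.setdefault(id(a), a)
            adj.setdefault(id(a), [])
        adj[id(u)].append((id(v), w))
        adj[id(v)].append((id(u), w))

    def farthest(start: int) -> tuple[int, float]:
        best, best_d = start, 0.0
        stack = [(start, -1, 0.0)]
        while stack:
            node, prev, d = stack.pop()
            if d > best_d:
                best, best_d = node, d
            for nxt, w in adj[node]:
                if nxt != prev:
                    stack.append((nxt, node, d + w))
        return best, best_d

    seen: set[int] = set()
    diameter = 0.0
    for start in adj:  # the internal subgraph is a forest; scan components
        if start in seen:
            continue
        stack = [start]
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            stack.extend(n for n, _ in adj[v] if n not in seen)
        a, _ = farthest(start)
        _, d = farthest(a)
        diameter = max(diameter, d)
    return diameter / total


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")
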