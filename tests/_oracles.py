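"""Independent brute-force oracles used to validate the fast implementations.

Each function here recomputes a quantity by exhaustive enumeration or
naive recursion, sharing no code with the package internals.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np


def exhaustive_motif_scan(protein: str, motif: str, matrix):
    """(best_offset_1based, best_score) by scoring every window naively."""
    L = len(motif)
    best = None
    for off in range(len(protein) - L + 1):
        window = protein[off:off + L]
        score = sum(matrix[m, p] for m, p in zip(motif, window))
        if best is None or score > best[1]:
            best = (off + 1, score)
    return best


def affine_dp_score(a: str, b: str, matrix, gap_open: float,
                    gap_extend: float) -> float:
    """Global affine-gap alignment score by plain 3-state recursion.

    A gap of length g costs gap_open + (g-1)*gap_extend.
    """
    NEG = float("-inf")

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, state: str) -> float:
        # score of aligning a[:i], b[:j] ending in the given state
        if i == 0 and j == 0:
            return 0.0 if state == "M" else NEG
        best = NEG
        if state == "M" and i > 0 and j > 0:
            sub = matrix[a[i - 1], b[j - 1]]
            best = max(rec(i - 1, j - 1, s) for s in "MXY") + sub
        elif state == "X" and i > 0:   # gap in b
            best = max(rec(i - 1, j, "M") - gap_open,
                       rec(i - 1, j, "Y") - gap_open,
                       rec(i - 1, j, "X") - gap_extend)
        elif state == "Y" and j > 0:   # gap in a
            best = max(rec(i, j - 1, "M") - gap_open,
                       rec(i, j - 1, "X") - gap_open,
                       rec(i, j - 1, "Y") - gap_extend)
        return best

    return max(rec(len(a), len(b), s) for s in "MXY")


def _tree_edges(tree):
    """(parent_key, child_key) pairs and per-node identity keys."""
    edges = []
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            edges.append((id(node), id(child)))
    return edges


def fitch_bruteforce(tree, leaf_states: dict[str, str],
                     alphabet: set[str]) -> int:
    """Minimal edge changes over all assignments; leaves absent from
    ``leaf_states`` (missing data) are free to take any state."""
    nodes = list(tree.preorder_node_iter())
    fixed = {}
    free = []
    for n in nodes:
        if n.is_leaf() and n.taxon.label in leaf_states:
            fixed[id(n)] = leaf_states[n.taxon.label]
        else:
            free.append(id(n))
    edges = _tree_edges(tree)
    states = sorted(alphabet)
    best = None
    for combo in itertools.product(states, repeat=len(free)):
        assign = dict(fixed)
        assign.update(zip(free, combo))
        changes = sum(1 for p, c in edges if assign[p] != assign[c])
        if best is None or changes < best:
            best = changes
    return best


def dollo_bruteforce(tree, possessing: set[str]):
    """(min_losses, gain_node_key) over all single-gain 0/1 assignments.

    A gain is an edge with parent 0 and child 1 (the root being 1 counts
    as a gain at the root); losses are 1→0 edges. Returns the minimum
    loss count and the gain node of an optimal assignment.
    """
    nodes = list(tree.preorder_node_iter())
    leaves = {id(n): n.taxon.label for n in nodes if n.is_leaf()}
    internal = [id(n) for n in nodes if not n.is_leaf()]
    edges = _tree_edges(tree)
    root = id(tree.seed_node)
    best = None
    for combo in itertools.product((0, 1), repeat=len(internal)):
        assign = dict(zip(internal, combo))
        for key, label in leaves.items():
            assign[key] = 1 if label in possessing else 0
        gains = [c for p, c in edges if assign[p] == 0 and assign[c] == 1]
        if assign[root] == 1:
            gains.append(root)
        if len(gains) != 1:
            continue
        losses = sum(1 for p, c in edges if assign[p] == 1 and assign[c] == 0)
        if best is None or losses < best[0]:
            best = (losses, gains[0])
    return best


def average_linkage_bruteforce(dist: np.ndarray):
    """Merge sequence of naive average linkage on a square distance matrix.

    Returns a list of (merged_member_sets, height). Ties break toward the
    smallest member indices.
    """
    n = len(dist)
    clusters: list[frozenset[int]] = [frozenset((i,)) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([dist[a, b] for a in clusters[i]
                             for b in clusters[j]])
                key = (d, tuple(sorted(clusters[i])), tuple(sorted(clusters[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        (d, _, _), i, j = best
        merged = clusters[i] | clusters[j]
        merges.append((merged, float(d)))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return merges


def optimal_1d_partition(columns: list[int], window: int) -> int:
    """Minimal number of classes for sorted 1-D points such that every
    member of a class lies within ``window`` of the class mean.

    Classes of an optimal solution are contiguous in sorted order, so we
    enumerate contiguous partitions.
    """
    cols = sorted(columns)
    n = len(cols)

    def valid(block: list[int]) -> bool:
        mean = sum(block) / len(block)
        return all(abs(c - mean) <= window for c in block)

    @lru_cache(maxsize=None)
    def min_classes(start: int) -> int:
        if start == n:
            return 0
        best = None
        for end in range(start + 1, n + 1):
            if valid(cols[start:end]):
                rest = min_classes(end)
                if best is None or 1 + rest < best:
                    best = 1 + rest
        return best

    return min_classes(0)
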