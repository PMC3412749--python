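"""Distance-based phylogeny for the family alignment.

Pairwise distances (p-distance or Dayhoff-corrected), Saitou–Nei
neighbour-joining with deterministic tie-breaking, nonparametric bootstrap
supports, a Fitch small-parsimony column score for tree/alignment
consistency checks, and clade-based group assignment against reference
anchor sequences.

Trees are dendropy objects throughout; bootstrap supports live both in the
``support`` attribute and the label of internal nodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np

from .formats import ProteinAlignment


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray    # symmetric, zero diagonal

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T) or not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.ids.index(a), self.ids.index(b)])


def pairwise_distances(alignment: ProteinAlignment,
                       model: str = "p_distance") -> DistanceMatrix:
    """Pairwise-deletion distances between alignment rows.

    Sites where either row has a gap are excluded for that pair.
    ``p_distance`` is mismatches / compared sites; ``dayhoff_corrected``
    applies d = −ln(1 − p − 0.2 p²), falling back to p (flagged on the
    matrix as ``saturated_pairs``) when the log argument is ≤ 0.
    """
    if model not in ("p_distance", "dayhoff_corrected"):
        raise ValueError(f"unknown distance model {model!r}")
    ids = alignment.ids
    if len(ids) < 3:
        raise ValueError("need at least 3 sequences")
    mat = np.array([list(alignment.rows[i]) for i in ids])
    isres = mat != "-"
    n = len(ids)
    d = np.zeros((n, n))
    saturated: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            both = isres[i] & isres[j]
            compared = int(both.sum())
            if compared == 0:
                raise ValueError(
                    f"no comparable sites between {ids[i]} and {ids[j]}")
            p = float((mat[i, both] != mat[j, both]).sum()) / compared
            if model == "dayhoff_corrected":
                arg = 1.0 - p - 0.2 * p * p
                if arg <= 0:
                    saturated.append((ids[i], ids[j]))
                    dist = p
                else:
                    dist = -math.log(arg)
            else:
                dist = p
            d[i, j] = d[j, i] = dist
    dm = DistanceMatrix(ids=list(ids), d=d)
    dm.saturated_pairs = saturated
    return dm


# ---------------------------------------------------------------------------
# neighbour joining
# ---------------------------------------------------------------------------

def build_nj(distances: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbour joining.

    Q-matrix ties are broken toward the lexicographically smallest pair of
    cluster keys (a cluster's key is its smallest member id). Negative
    branch-length estimates are clamped to 0 and recorded on the returned
    tree as ``clamped_branches``.
    """
    ids = list(distances.ids)
    n = len(ids)
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    D = distances.d.astype(float).copy()
    keys = list(ids)                       # cluster key = min member id
    frags = {k: k for k in ids}            # newick fragment per cluster
    active = list(range(n))
    clamped: list[str] = []

    def clamp(x: float) -> float:
        if x < 0:
            clamped.append(f"{x:.6g}")
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                if Q[ai, aj] <= qmin + 1e-12:
                    ki, kj = keys[active[ai]], keys[active[aj]]
                    pair_key = (min(ki, kj), max(ki, kj))
                    if best is None or pair_key < best[0]:
                        best = (pair_key, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = clamp(li), clamp(lj)
        new_frag = f"({frags[keys[i]]}:{li:.10g},{frags[keys[j]]}:{lj:.10g})"
        new_key = min(keys[i], keys[j])
        # distances to the new cluster (stored in slot i)
        for ak in range(m):
            k = active[ak]
            if k in (i, j):
                continue
            D[i, k] = D[k, i] = 0.5 * (D[i, k] + D[j, k] - dij)
        keys[i] = new_key
        frags[new_key] = new_frag
        active.remove(j)

    a, b, c = active
    da = clamp(0.5 * (D[a, b] + D[a, c] - D[b, c]))
    db = clamp(0.5 * (D[a, b] + D[b, c] - D[a, c]))
    dc = clamp(0.5 * (D[a, c] + D[b, c] - D[a, b]))
    newick = (f"({frags[keys[a]]}:{da:.10g},{frags[keys[b]]}:{db:.10g},"
              f"{frags[keys[c]]}:{dc:.10g});")
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    tree.clamped_branches = clamped
    return tree


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap(alignment: ProteinAlignment, n_reps: int = 1000, seed: int = 0,
              model: str = "p_distance") -> dendropy.Tree:
    """NJ tree with bootstrap supports on internal edges.

    Columns are resampled with replacement per replicate; replicate ``r``
    draws from an independent substream seeded by (seed, r) so changing
    ``n_reps`` never reshuffles earlier replicates. Supports are the
    percentage of replicate trees containing each internal bipartition of
    the full-data tree, attached as ``node.support`` and the node label.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    full = build_nj(pairwise_distances(alignment, model))
    tns = full.taxon_namespace
    full.encode_bipartitions()
    counts = {int(e.bipartition.split_bitmask): 0
              for e in full.preorder_edge_iter()
              if e.head_node is not full.seed_node
              and not e.head_node.is_leaf()}
    ncols = alignment.n_cols
    for r in range(n_reps):
        rng = np.random.default_rng([seed, r])
        cols = rng.integers(0, ncols, size=ncols)
        rep_aln = alignment.take_columns(cols)
        rep_tree = build_nj(pairwise_distances(rep_aln, model))
        rep_tree.migrate_taxon_namespace(tns)
        rep_tree.encode_bipartitions()
        seen = {int(e.bipartition.split_bitmask)
                for e in rep_tree.preorder_edge_iter()}
        for mask in counts:
            if mask in seen:
                counts[mask] += 1
    for edge in full.preorder_edge_iter():
        node = edge.head_node
        if node is full.seed_node or node.is_leaf():
            continue
        pct = 100.0 * counts[int(edge.bipartition.split_bitmask)] / n_reps
        node.support = pct
        node.label = f"{pct:g}"
    return full


# ---------------------------------------------------------------------------
# parsimony
# ---------------------------------------------------------------------------

def parsimony_score(tree: dendropy.Tree, alignment: ProteinAlignment) -> int:
    """Fitch small-parsimony change count summed over alignment columns.

    Gaps are treated as missing data: a gapped leaf is unconstrained for
    that column (its state set is the full set of residues observed in the
    column), so it never forces a change on its own.
    """
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if leaves != set(alignment.ids):
        raise ValueError("tree leaves do not match alignment ids")
    rows = {i: alignment.rows[i] for i in alignment.ids}
    total = 0
    postorder = list(tree.postorder_node_iter())
    for col in range(alignment.n_cols):
        observed = {rows[i][col] for i in alignment.ids} - {"-"}
        if len(observed) <= 1:
            continue
        sets: dict[int, frozenset[str]] = {}
        changes = 0
        for node in postorder:
            if node.is_leaf():
                aa = rows[node.taxon.label][col]
                sets[id(node)] = (frozenset(observed) if aa == "-"
                                  else frozenset((aa,)))
            else:
                child_sets = [sets[id(c)] for c in node.child_nodes()]
                inter = frozenset.intersection(*child_sets)
                if inter:
                    sets[id(node)] = inter
                else:
                    # pairwise Fitch fold over children
                    acc = child_sets[0]
                    for cs in child_sets[1:]:
                        both = acc & cs
                        if both:
                            acc = both
                        else:
                            acc = acc | cs
                            changes += 1
                    sets[id(node)] = acc
        total += changes
    return total


# ---------------------------------------------------------------------------
# group assignment
# ---------------------------------------------------------------------------

def _node_support(node: dendropy.Node) -> float | None:
    sup = getattr(node, "support", None)
    if sup is not None:
        return float(sup)
    if node.label is not None:
        try:
            return float(node.label)
        except ValueError:
            return None
    return None


def assign_groups(tree: dendropy.Tree, reference_map: dict[str, str],
                  support_threshold: float = 85.0,
                  root: str = "midpoint") -> dict[str, str]:
    """Label each non-reference leaf by its smallest well-supported clade.

    ``reference_map`` maps reference leaf ids to group labels. A leaf gets
    group X when the smallest clade with support ≥ ``support_threshold``
    containing it also contains references of exactly one group (X);
    otherwise it is "unassigned". The tree is midpoint rooted by default;
    pass ``root=<leaf_id>`` to use an outgroup instead.
    """
    work = tree.clone(depth=1)
    leaf_labels = {lf.taxon.label for lf in work.leaf_node_iter()}
    missing = set(reference_map) - leaf_labels
    if missing:
        raise KeyError(f"reference leaves absent from tree: {sorted(missing)}")
    if root == "midpoint":
        work.reroot_at_midpoint(update_bipartitions=False)
    else:
        og = next(lf for lf in work.leaf_node_iter() if lf.taxon.label == root)
        work.to_outgroup_position(og, update_bipartitions=False)
    assignments: dict[str, str] = {}
    for leaf in work.leaf_node_iter():
        name = leaf.taxon.label
        if name in reference_map:
            assignments[name] = reference_map[name]
            continue
        label = "unassigned"
        node = leaf.parent_node
        while node is not None:
            sup = _node_support(node)
            if sup is not None and sup >= support_threshold:
                clade = {lf.taxon.label for lf in node.leaf_iter()}
                groups = {reference_map[r] for r in clade & set(reference_map)}
                if len(groups) == 1:
                    label = groups.pop()
                    break
                if len(groups) > 1:
                    break
            node = node.parent_node
        assignments[name] = label
    return assignments
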