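"""Intron architecture: extraction, phases, alignment projection, conserved
intron classes, gain/loss inference on the family tree, and the census.

Intron phase follows the codon-boundary convention: phase 0 lies between
two codons, phase 1 after the first base of a codon, phase 2 after the
second. An intron's protein position is the residue *following* the
splice point, ``floor(cds_offset/3) + 1``, one uniform formula for all
phases.

Introns from different genes projecting to nearby columns of the family
alignment are clustered into *intron classes*, interpreted as single
ancestral insertions; their gain and loss events are reconstructed on the
tree under Dollo parsimony (one gain, any number of losses) or
unconstrained Fitch parsimony.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .formats import GeneModel, ProteinAlignment


@dataclass
class IntronRecord:
    """A single intron located on its gene's CDS and protein."""

    gene_id: str
    intron_index: int      # 1-based, transcription order
    cds_offset: int        # nt of CDS preceding the intron
    phase: int
    protein_pos: int       # 1-based residue following the splice point
    length_bp: int
    column: int | None = None   # alignment column once projected


@dataclass
class IntronClass:
    """A cross-gene cluster of equivalent introns."""

    class_id: int
    mean_column: float
    members: list[IntronRecord]
    conserved: bool = False


@dataclass
class EventSet:
    """Per-class and per-branch intron gain/loss reconstruction.

    Branches are identified by their head node: the taxon label for leaf
    edges, the node label for internal edges ("root" for the root).
    """

    model: str
    gain_branch: dict[int, str | None]        # class -> branch (None if absent)
    loss_branches: dict[int, set[str]]
    branch_events: dict[str, dict[str, list[int]]]  # branch -> {gains, losses}
    ancestral_classes: set[int] = field(default_factory=set)

    @property
    def total_events(self) -> int:
        return (sum(1 for g in self.gain_branch.values() if g is not None)
                + sum(len(v) for v in self.loss_branches.values()))


# ---------------------------------------------------------------------------
# extraction and projection
# ---------------------------------------------------------------------------

def extract_introns(gene_model: GeneModel) -> list[IntronRecord]:
    """One record per gap between consecutive CDS intervals.

    Requires a complete CDS (length divisible by 3); callers should skip
    models flagged incomplete.
    """
    if not gene_model.complete:
        raise ValueError(
            f"{gene_model.gene_id}: incomplete CDS; intron phases undefined")
    records: list[IntronRecord] = []
    offset = 0
    lengths = gene_model.intron_lengths()
    for i, (s, e) in enumerate(gene_model.cds_intervals[:-1]):
        offset += e - s + 1
        phase = offset % 3
        protein_pos = offset // 3 + 1
        records.append(IntronRecord(
            gene_id=gene_model.gene_id, intron_index=i + 1,
            cds_offset=offset, phase=phase, protein_pos=protein_pos,
            length_bp=lengths[i]))
    return records


def project_to_alignment(record: IntronRecord,
                         alignment: ProteinAlignment) -> int:
    """Alignment column of the residue at the intron's protein position."""
    if record.gene_id not in alignment.rows:
        raise KeyError(f"{record.gene_id} absent from alignment")
    pos = min(record.protein_pos, alignment.ungapped_length(record.gene_id))
    return alignment.res_to_col(record.gene_id, pos)


# ---------------------------------------------------------------------------
# intron classes
# ---------------------------------------------------------------------------

def cluster_intron_classes(records: Sequence[IntronRecord],
                           window_aa: int = 45,
                           group_map: Mapping[str, str] | None = None,
                           min_groups: int = 2,
                           min_members: int = 10) -> list[IntronClass]:
    """Cluster projected introns into classes by alignment column.

    Introns are sorted by column and partitioned into the minimal number
    of contiguous classes such that every member lies within ``window_aa``
    of its class mean (the conserved-position criterion). In one dimension
    an optimal partition is always contiguous, so this is solved exactly
    by dynamic programming; among minimal partitions the leftmost class is
    made as large as possible, which makes the result deterministic.
    Classes are serially numbered by mean column.

    A class is flagged conserved when its members span at least
    ``min_groups`` phylogenetic groups (if ``group_map`` is given) or when
    it has at least ``min_members`` members.
    """
    if window_aa <= 0:
        raise ValueError("window_aa must be positive")
    recs = [r for r in records if r.column is not None]
    if len(recs) < len(records):
        raise ValueError("all records must be projected before clustering")
    if not recs:
        return []
    recs = sorted(recs, key=lambda r: (r.column, r.gene_id, r.intron_index))
    cols = [r.column for r in recs]
    n = len(cols)
    prefix = np.concatenate(([0.0], np.cumsum(cols)))

    def feasible(i: int, j: int) -> bool:
        # block cols[i:j]: extreme members are the only candidates to violate
        mean = (prefix[j] - prefix[i]) / (j - i)
        return (mean - cols[i] <= window_aa) and (cols[j - 1] - mean <= window_aa)

    INF = n + 1
    min_classes = [INF] * (n + 1)
    min_classes[n] = 0
    for i in range(n - 1, -1, -1):
        for j in range(i + 1, n + 1):
            if feasible(i, j) and 1 + min_classes[j] < min_classes[i]:
                min_classes[i] = 1 + min_classes[j]
    clusters: list[list[IntronRecord]] = []
    i = 0
    while i < n:
        j = max(jj for jj in range(i + 1, n + 1)
                if feasible(i, jj) and 1 + min_classes[jj] == min_classes[i])
        clusters.append(recs[i:j])
        i = j
    classes: list[IntronClass] = []
    for ci, members in enumerate(clusters, start=1):
        mean = sum(r.column for r in members) / len(members)
        if group_map is not None:
            groups = {group_map[r.gene_id] for r in members
                      if r.gene_id in group_map}
            conserved = len(groups) >= min_groups or len(members) >= min_members
        else:
            conserved = len(members) >= min_members
        classes.append(IntronClass(class_id=ci, mean_column=mean,
                                   members=list(members), conserved=conserved))
    return classes


def presence_matrix(classes: Sequence[IntronClass],
                    genes: Iterable[str]) -> pd.DataFrame:
    """Gene × class boolean matrix of intron-class possession."""
    genes = list(genes)
    data = {}
    for c in classes:
        possess = {r.gene_id for r in c.members}
        data[c.class_id] = [g in possess for g in genes]
    return pd.DataFrame(data, index=genes)


# ---------------------------------------------------------------------------
# gain/loss inference
# ---------------------------------------------------------------------------

def _node_id(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    return node.label if node.label else f"node{id(node) % 10 ** 6}"


def _ensure_internal_labels(tree: dendropy.Tree) -> None:
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.label:
            continue
        node.label = "root" if node is tree.seed_node else None
        if node.label is None:
            i += 1
            node.label = f"N{i}"


def infer_events(tree: dendropy.Tree, presence: pd.DataFrame,
                 model: str = "dollo") -> EventSet:
    """Reconstruct per-branch intron gains and losses on a rooted tree.

    ``presence`` rows are tree leaves, columns are intron class ids.
    Under Dollo each class is gained exactly once at the MRCA of the
    possessing leaves, and losses are the minimal set of branches whose
    removal explains every absent descendant (one post-order pass). Under
    Fitch, gains and losses are the minimal unconstrained 0/1 changes with
    a root-prefers-absent tie-break.
    """
    if model not in ("dollo", "fitch"):
        raise ValueError(f"unknown model {model!r}")
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if set(presence.index) != leaves:
        raise ValueError("presence matrix rows do not match tree leaves")
    tree.is_rooted = True      # event polarity requires a rooted tree
    _ensure_internal_labels(tree)
    gain_branch: dict[int, str | None] = {}
    loss_branches: dict[int, set[str]] = {}
    branch_events: dict[str, dict[str, list[int]]] = {}
    ancestral: set[int] = set()

    def record(branch: str, kind: str, cls) -> None:
        branch_events.setdefault(branch, {"gains": [], "losses": []})
        branch_events[branch][kind].append(cls)

    for cls in presence.columns:
        possessing = set(presence.index[presence[cls]])
        if not possessing:
            gain_branch[cls] = None
            loss_branches[cls] = set()
            continue
        if model == "dollo":
            if len(possessing) == len(leaves):
                gain = tree.seed_node
            else:
                gain = tree.mrca(taxon_labels=possessing)
            gain_id = _node_id(gain)
            losses: set[str] = set()

            def descend(node: dendropy.Node) -> None:
                for child in node.child_nodes():
                    sub = {lf.taxon.label for lf in child.leaf_iter()}
                    if sub & possessing:
                        descend(child)
                    else:
                        losses.add(_node_id(child))

            descend(gain)
            gain_branch[cls] = gain_id
            loss_branches[cls] = losses
            record(gain_id, "gains", cls)
            for br in losses:
                record(br, "losses", cls)
            if gain is tree.seed_node:
                ancestral.add(cls)
        else:
            states = _fitch_binary(tree, possessing)
            gains, losses = set(), set()
            for node in tree.preorder_node_iter():
                if node is tree.seed_node:
                    if states[id(node)] == 1:
                        gains.add(_node_id(node))
                    continue
                parent = node.parent_node
                if states[id(parent)] == 0 and states[id(node)] == 1:
                    gains.add(_node_id(node))
                elif states[id(parent)] == 1 and states[id(node)] == 0:
                    losses.add(_node_id(node))
            gain_branch[cls] = sorted(gains)[0] if len(gains) == 1 else None
            loss_branches[cls] = losses
            for br in gains:
                record(br, "gains", cls)
            for br in losses:
                record(br, "losses", cls)
            if _node_id(tree.seed_node) in gains:
                ancestral.add(cls)
    ev = EventSet(model=model, gain_branch=gain_branch,
                  loss_branches=loss_branches, branch_events=branch_events,
                  ancestral_classes=ancestral)
    if model == "fitch":
        # total events for fitch counts every gain, not only unique ones
        ev.total_fitch_changes = sum(
            len(v["gains"]) + len(v["losses"]) for v in branch_events.values())
    return ev


def _fitch_binary(tree: dendropy.Tree, possessing: set[str]) -> dict[int, int]:
    """Minimal-change 0/1 state assignment (Fitch with downward pass).

    Ambiguous nodes resolve to the parent's state; the root prefers 0.
    """
    sets: dict[int, frozenset[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[id(node)] = frozenset(
                (1,) if node.taxon.label in possessing else (0,))
        else:
            child_sets = [sets[id(c)] for c in node.child_nodes()]
            inter = frozenset.intersection(*child_sets)
            sets[id(node)] = inter if inter else frozenset.union(*child_sets)
    states: dict[int, int] = {}
    for node in tree.preorder_node_iter():
        s = sets[id(node)]
        if node is tree.seed_node:
            states[id(node)] = 0 if 0 in s else 1
        else:
            p = states[id(node.parent_node)]
            states[id(node)] = p if p in s else min(s)
    return states


# ---------------------------------------------------------------------------
# census
# ---------------------------------------------------------------------------

def _round2(x: float, truncate: bool = False) -> float:
    mode = ROUND_DOWN if truncate else ROUND_HALF_UP
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=mode))


@dataclass
class IntronCensus:
    """Summary of intron content across a gene set."""

    n_genes: int
    genes_by_introns: dict[int, int]     # 0/1/2/… intron count -> gene count
    total_introns: int
    mean_per_gene: float
    pct_intronless: float
    length_min: int | None
    length_max: int | None
    length_mean: float | None
    phase_histogram: dict[int, int]

    @classmethod
    def from_distribution(cls, dist: Mapping[int, int],
                          truncate: bool = False) -> "IntronCensus":
        """Census arithmetic from a genes-per-intron-count distribution."""
        n_genes = sum(dist.values())
        total = sum(k * v for k, v in dist.items())
        mean = _round2(total / n_genes, truncate) if n_genes else 0.0
        pct0 = (_round2(100.0 * dist.get(0, 0) / n_genes, truncate)
                if n_genes else 0.0)
        return cls(n_genes=n_genes, genes_by_introns=dict(dist),
                   total_introns=total, mean_per_gene=mean,
                   pct_intronless=pct0, length_min=None, length_max=None,
                   length_mean=None, phase_histogram={})


def intron_census(records: Sequence[IntronRecord], genes: Iterable[str],
                  truncate: bool = False) -> IntronCensus:
    """Count introns per gene, lengths and phases over ``genes``."""
    genes = list(genes)
    gene_set = set(genes)
    stray = {r.gene_id for r in records} - gene_set
    if stray:
        raise ValueError(f"records for genes outside the set: {sorted(stray)}")
    per_gene = {g: 0 for g in genes}
    for r in records:
        per_gene[r.gene_id] += 1
    dist: dict[int, int] = {}
    for count in per_gene.values():
        dist[count] = dist.get(count, 0) + 1
    census = IntronCensus.from_distribution(dist, truncate=truncate)
    lengths = [r.length_bp for r in records]
    census.length_min = min(lengths) if lengths else None
    census.length_max = max(lengths) if lengths else None
    census.length_mean = (_round2(sum(lengths) / len(lengths), truncate)
                          if lengths else None)
    census.phase_histogram = {p: sum(1 for r in records if r.phase == p)
                              for p in (0, 1, 2)}
    return census
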