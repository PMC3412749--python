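"""Digital expression profiling and relative quantification.

* EST reads are mapped to family coding sequences by exact k-mer seeding
  and ungapped diagonal extension; each EST counts toward exactly one
  (gene, tissue) cell or is discarded (tie) / unmapped.
* Summaries reproduce the family-level arithmetic typically reported for
  such surveys: expressed-gene fractions, mean ESTs per expressed gene,
  per-group and per-tissue breakdowns (with both ESTs and genes as the
  per-tissue denominator, since both conventions are in circulation).
* Expression matrices are ordered by average-linkage hierarchical
  clustering on 1 − Pearson r (scipy backend).
* Relative transcript abundance from qPCR CT tables uses the comparative
  ΔCT method: technical replicates averaged within biological replicate,
  abundance 2^(−ΔCT), mean ± standard error across biological replicates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .formats import ESTRecord, ExpressionTable

logger = logging.getLogger(__name__)


def round2(x: float, truncate: bool = False) -> float:
    """Round to 2 decimals, half-up by default; truncation reproduces
    report styles that drop rather than round trailing digits."""
    mode = ROUND_DOWN if truncate else ROUND_HALF_UP
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"),
                                                  rounding=mode))


# ---------------------------------------------------------------------------
# EST mapping
# ---------------------------------------------------------------------------

@dataclass
class MappingResult:
    assignments: dict[str, tuple[str, float, int] | None]  # est -> (gene, id, len)
    counts: ExpressionTable
    unmapped: int
    discarded_ties: int

    @property
    def n_input(self) -> int:
        return len(self.assignments) + self.discarded_ties


def map_ests(ests: Sequence[ESTRecord], gene_cds_sequences: Mapping[str, str],
             k: int = 11, min_identity: float = 0.95,
             min_match_len: int = 100) -> MappingResult:
    """Assign each EST to its best gene by seeded ungapped alignment.

    Exact k-mers of the EST are looked up in an index of the coding
    sequences; every seeded diagonal is scored as identity × overlap
    length over the full ungapped overlap. An EST is assigned to the
    single best-scoring gene passing ``min_identity`` and
    ``min_match_len`` (or the full EST length if shorter); equal-best
    ties across different genes are discarded and counted separately.
    """
    if k < 8:
        raise ValueError("k must be >= 8 (seed too unspecific)")
    if not gene_cds_sequences:
        raise ValueError("empty gene set")
    index: dict[str, list[tuple[str, int]]] = {}
    for gid, cds in gene_cds_sequences.items():
        for i in range(len(cds) - k + 1):
            index.setdefault(cds[i:i + k], []).append((gid, i))
    tissues = sorted({e.tissue for e in ests})
    genes = sorted(gene_cds_sequences)
    counts = pd.DataFrame(0, index=genes, columns=tissues or ["NA"])
    assignments: dict[str, tuple[str, float, int] | None] = {}
    discarded_ties = 0
    unmapped = 0
    for est in ests:
        seq = est.sequence
        diagonals: set[tuple[str, int]] = set()
        for i in range(0, len(seq) - k + 1):
            for gid, pos in index.get(seq[i:i + k], ()):
                diagonals.add((gid, pos - i))
        best_per_gene: dict[str, tuple[float, float, int]] = {}
        need_len = min(min_match_len, len(seq))
        for gid, diag in diagonals:
            cds = gene_cds_sequences[gid]
            e_start = max(0, -diag)
            e_end = min(len(seq), len(cds) - diag)
            overlap = e_end - e_start
            if overlap < need_len:
                continue
            matches = sum(1 for i in range(e_start, e_end)
                          if seq[i] == cds[i + diag])
            identity = matches / overlap
            if identity < min_identity:
                continue
            score = identity * overlap
            cur = best_per_gene.get(gid)
            if cur is None or score > cur[0]:
                best_per_gene[gid] = (score, identity, overlap)
        if not best_per_gene:
            assignments[est.est_id] = None
            unmapped += 1
            continue
        ranked = sorted(best_per_gene.items(),
                        key=lambda kv: (-kv[1][0], kv[0]))
        if len(ranked) > 1 and math.isclose(ranked[0][1][0], ranked[1][1][0]):
            discarded_ties += 1
            continue
        gid, (score, identity, overlap) = ranked[0]
        assignments[est.est_id] = (gid, identity, overlap)
        counts.loc[gid, est.tissue] += 1
    table = ExpressionTable(values=counts, kind="est_counts")
    return MappingResult(assignments=assignments, counts=table,
                         unmapped=unmapped, discarded_ties=discarded_ties)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSummary:
    total_ests: int
    family_size: int
    expressed_genes: int
    pct_expressed: float
    mean_per_expressed: float
    per_gene: pd.Series                 # total ESTs per gene
    per_group: pd.DataFrame             # ests, members, expressed, mean
    per_tissue: pd.DataFrame            # ests, pct_of_ests, genes, pct_of_genes


def expression_summary(counts: ExpressionTable,
                       group_map: Mapping[str, str] | None = None,
                       truncate: bool = False,
                       family_size: int | None = None) -> ExpressionSummary:
    """Family-level digital expression summary from an EST count table."""
    df = counts.values
    per_gene = df.sum(axis=1)
    total = int(per_gene.sum())
    family = family_size if family_size is not None else len(df.index)
    expressed = int((per_gene > 0).sum())
    pct = round2(100.0 * expressed / family, truncate) if family else 0.0
    mean = round2(total / expressed, truncate) if expressed else 0.0

    group_rows = []
    if group_map:
        by_group: dict[str, list[str]] = {}
        for g in df.index:
            grp = group_map.get(g, "ungrouped")
            by_group.setdefault(grp, []).append(g)
        for grp in sorted(by_group):
            members = by_group[grp]
            g_tot = int(per_gene[members].sum())
            g_exp = int((per_gene[members] > 0).sum())
            g_mean = round2(g_tot / g_exp, truncate) if g_exp else 0.0
            group_rows.append((grp, g_tot, len(members), g_exp, g_mean))
    per_group = pd.DataFrame(group_rows, columns=[
        "group", "ests", "members", "expressed", "mean_per_expressed",
    ]).set_index("group") if group_rows else pd.DataFrame(
        columns=["ests", "members", "expressed", "mean_per_expressed"])

    tissue_rows = []
    for tissue in df.columns:
        t_tot = int(df[tissue].sum())
        t_genes = int((df[tissue] > 0).sum())
        tissue_rows.append((
            tissue, t_tot,
            round2(100.0 * t_tot / total, truncate) if total else 0.0,
            t_genes,
            round2(100.0 * t_genes / family, truncate) if family else 0.0))
    per_tissue = pd.DataFrame(tissue_rows, columns=[
        "tissue", "ests", "pct_of_ests", "genes", "pct_of_genes",
    ]).set_index("tissue")

    return ExpressionSummary(
        total_ests=total, family_size=family, expressed_genes=expressed,
        pct_expressed=pct, mean_per_expressed=mean, per_gene=per_gene,
        per_group=per_group, per_tissue=per_tissue)


def expressed_fraction(table: ExpressionTable, threshold: float,
                       family_size: int | None = None,
                       truncate: bool = False) -> tuple[int, float]:
    """Genes with any value above ``threshold`` and their percentage of the
    family (microarray-style expression evidence)."""
    expressed = int((table.values.max(axis=1) > threshold).sum())
    family = family_size if family_size is not None else len(table.values)
    return expressed, round2(100.0 * expressed / family, truncate)


# ---------------------------------------------------------------------------
# correlation clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    order: list[str]           # row ids in dendrogram leaf order
    linkage: np.ndarray
    distances: np.ndarray      # condensed 1 − r distances
    constant_rows: list[str]
    newick: str


def _linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    n = len(labels)
    frags = {i: f"{labels[i]}" for i in range(n)}
    heights = {i: 0.0 for i in range(n)}
    for m, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = max(h - heights[a], 0.0)
        lb = max(h - heights[b], 0.0)
        frags[n + m] = f"({frags[a]}:{la:.6g},{frags[b]}:{lb:.6g})"
        heights[n + m] = h
    return frags[n + len(Z) - 1] + ";"


def cluster_expression(matrix: ExpressionTable,
                       metric: str = "pearson",
                       linkage: str = "average") -> ClusterResult:
    """Order expression rows by correlation-based hierarchical clustering.

    Distance is 1 − Pearson r between gene rows; agglomeration is
    average-linkage by default (scipy, deterministic). EST count tables
    are log2(x+1)-transformed first, with a logged notice. Constant rows,
    whose correlation is undefined, are assigned the maximum distance
    (2.0) to every other row and reported in ``constant_rows``.
    """
    if metric != "pearson":
        raise ValueError("only the pearson metric is supported")
    df = matrix.values.astype(float)
    if matrix.kind == "est_counts":
        logger.info("clustering EST counts: applying log2(x+1) transform")
        df = np.log2(df + 1.0)
    if len(df) < 2:
        raise ValueError("need at least 2 rows to cluster")
    vals = df.to_numpy()
    sd = vals.std(axis=1)
    constant = sd == 0
    n = len(vals)
    dist = np.full((n, n), 2.0)
    np.fill_diagonal(dist, 0.0)
    ok = ~constant
    if ok.sum() >= 2:
        r = np.corrcoef(vals[ok])
        dist[np.ix_(ok, ok)] = np.clip(1.0 - r, 0.0, 2.0)
        np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = sch.linkage(condensed, method=linkage)
    order = [df.index[i] for i in sch.leaves_list(Z)]
    return ClusterResult(order=order, linkage=Z, distances=condensed,
                         constant_rows=list(df.index[constant]),
                         newick=_linkage_to_newick(Z, list(df.index)))


# ---------------------------------------------------------------------------
# comparative CT (ΔCT) quantification
# ---------------------------------------------------------------------------

def delta_ct(measurements: pd.DataFrame, reference_gene: str) -> pd.DataFrame:
    """Relative transcript abundance per (gene, tissue) by the ΔCT method.

    Technical replicates are averaged within each biological replicate;
    ΔCT = mean CT(target) − mean CT(reference) per biological replicate;
    relative abundance is 2^(−ΔCT), reported as mean ± standard error
    across biological replicates. Biological replicates lacking the
    reference are dropped with a warning; if all are dropped for a
    (gene, tissue) cell, that is an error.
    """
    required = {"gene", "tissue", "bio_rep", "tech_rep", "ct"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"CT table missing columns: {sorted(missing)}")
    bio_means = (measurements
                 .groupby(["gene", "tissue", "bio_rep"])["ct"]
                 .mean())
    if reference_gene not in bio_means.index.get_level_values("gene"):
        raise ValueError(f"reference gene {reference_gene!r} not measured")
    ref = bio_means.loc[reference_gene]
    rows = []
    targets = [g for g in measurements["gene"].unique() if g != reference_gene]
    for gene in targets:
        gdata = bio_means.loc[gene]
        for tissue in gdata.index.get_level_values("tissue").unique():
            cts = gdata.loc[tissue]
            ras = []
            for bio, ct in cts.items():
                try:
                    ref_ct = float(ref.loc[(tissue, bio)])
                except KeyError:
                    logger.warning(
                        "no reference CT for tissue %s bio_rep %s; dropped",
                        tissue, bio)
                    continue
                ras.append(2.0 ** (-(ct - ref_ct)))
            if not ras:
                raise ValueError(
                    f"no usable biological replicates for {gene}/{tissue}")
            ras = np.asarray(ras)
            se = (float(ras.std(ddof=1) / math.sqrt(len(ras)))
                  if len(ras) > 1 else 0.0)
            rows.append((gene, tissue, len(ras), float(ras.mean()), se))
    return pd.DataFrame(rows, columns=["gene", "tissue", "n_bio",
                                       "abundance_mean", "abundance_se"])
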