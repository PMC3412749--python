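"""Synthetic gene-family generator with known evolutionary ground truth.

Produces everything the downstream pipeline consumes — a genome FASTA,
GFF3 gene models, a protein family evolved along a known birth–death tree
carrying a planted 44-residue signature motif, intron positions/phases with
a known gain/loss history, decoy genes that fail the candidate filters,
tissue-weighted EST reads with sequencing error, and qPCR CT tables with
known fold changes — so every stage has a recovery test against truth.

The sequence model is deliberately simple: site-independent substitutions
whose exchange probabilities are derived from the Dayhoff PAM250 score
matrix, single-residue indels outside the motif, uniform synonymous codons
on back-translation, and canonical GT..AG introns with log-uniform lengths
in the 65–2258 bp range typical of compact plant gene families. It is
adequate for testing recovery of trees, intron histories and expression
profiles, not for biological realism.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table
from dendropy.simulate import treesim

from .formats import (DEFAULT_TISSUES, ESTRecord, GeneModel, ProteinAlignment,
                      write_est_fasta, write_gene_models, write_genome_fasta,
                      write_newick, write_protein_fasta)

#: Consensus of the 44-residue plant secondary product glycosyltransferase
#: (PSPG) box, the C-terminal signature used as the family mining probe.
PSPG_CONSENSUS = "WAPQVEVLAHPAVGCFVTHCGWNSTLESISAGVPMVAWPFFADQ"

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_STOPS = ("TAA", "TAG", "TGA")


def _codon_table() -> dict[str, list[str]]:
    table: dict[str, list[str]] = {aa: [] for aa in AMINO_ACIDS}
    for codon, aa in standard_dna_table.forward_table.items():
        if aa in table:
            table[aa].append(codon)
    return {aa: sorted(cods) for aa, cods in table.items()}


_CODONS = _codon_table()


def _exchange_matrix() -> np.ndarray:
    """Row-stochastic amino-acid exchange probabilities from PAM250 scores.

    Off-diagonal weights are exp(score/2); the diagonal is excluded so that
    a substitution event always changes the residue.
    """
    pam = substitution_matrices.load("PAM250")
    idx = [pam.alphabet.index(a) for a in AMINO_ACIDS]
    scores = np.asarray(pam)[np.ix_(idx, idx)]
    w = np.exp(scores / 2.0)
    np.fill_diagonal(w, 0.0)
    return w / w.sum(axis=1, keepdims=True)


_EXCHANGE = _exchange_matrix()
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


# ---------------------------------------------------------------------------
# truth containers
# ---------------------------------------------------------------------------

@dataclass
class IntronClassTruth:
    """Planted history of one intron class."""

    class_id: int
    anchor_pos: int            # 1-based residue anchor on the root protein
    phase: int
    gain_branch: str           # head-node label of the gain edge ("root" ok)
    loss_branches: list[str]
    leaves: set[str]           # leaves possessing the intron


@dataclass
class FamilySimTruth:
    """Ground truth emitted next to the simulated data files."""

    tree: dendropy.Tree
    group_map: dict[str, str]
    true_alignment: ProteinAlignment
    motif_window: dict[str, int]            # gene -> 1-based window start
    intron_classes: list[IntronClassTruth]
    presence: pd.DataFrame                  # leaves × class ids (bool)
    decoys: dict[str, str]                  # gene -> no_motif|length|intron_count
    expression_weights: pd.DataFrame        # gene × tissue; columns sum to 1
    qpcr_truth: pd.DataFrame                # gene × tissue relative abundance


@dataclass
class FamilySim:
    """A simulated family: genome + gene models + proteins + truth."""

    genome: dict[str, str]
    gene_models: list[GeneModel]
    proteins: dict[str, str]
    truth: FamilySimTruth
    cds: dict[str, str] = field(default_factory=dict)

    @property
    def family_genes(self) -> list[str]:
        return [g for g in self.proteins if g not in self.truth.decoys]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fasta",
            "gff3": outdir / "models.gff3",
            "proteins": outdir / "proteins.fasta",
            "alignment": outdir / "true_alignment.fasta",
            "tree": outdir / "true_tree.nwk",
            "groups": outdir / "true_groups.tsv",
        }
        write_genome_fasta(self.genome, paths["genome"])
        write_gene_models(self.gene_models, paths["gff3"])
        write_protein_fasta(self.proteins, paths["proteins"])
        self.truth.true_alignment.to_fasta(paths["alignment"])
        write_newick(self.truth.tree, paths["tree"])
        with open(paths["groups"], "w") as fh:
            fh.write("group\tleaf_id\n")
            for leaf, grp in sorted(self.truth.group_map.items()):
                fh.write(f"{grp}\t{leaf}\n")
        return paths


# ---------------------------------------------------------------------------
# sequence evolution along the tree
# ---------------------------------------------------------------------------

def _evolve_along_tree(tree: dendropy.Tree, root_seq: str, motif_start: int,
                       subst_rate: float, indel_rate: float,
                       motif_rate_factor: float,
                       rng: np.random.Generator,
                       ) -> tuple[dict[str, list[tuple[float, str]]], set[float]]:
    """Evolve a protein along ``tree``; returns per-leaf (column key, residue)
    lists plus the set of motif column keys.

    Column keys are floats shared across lineages, so the union of leaf keys
    defines the true alignment. The motif region accepts neither indels nor
    full-rate substitution (rate is scaled by ``motif_rate_factor``).
    """
    L = len(root_seq)
    root_cols = [(float(i + 1), root_seq[i]) for i in range(L)]
    motif_keys = {float(i + 1) for i in range(motif_start - 1,
                                              motif_start - 1 + 44)}
    lo_m, hi_m = min(motif_keys), max(motif_keys)
    leaf_seqs: dict[str, list[tuple[float, str]]] = {}

    def descend(node: dendropy.Node, seq: list[tuple[float, str]]) -> None:
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            s = list(seq)
            # substitutions
            for i, (key, aa) in enumerate(s):
                rate = subst_rate * (motif_rate_factor if key in motif_keys else 1.0)
                if rng.random() < 1.0 - math.exp(-rate * t):
                    new = AMINO_ACIDS[rng.choice(len(AMINO_ACIDS),
                                                 p=_EXCHANGE[_AA_INDEX[aa]])]
                    s[i] = (key, new)
            # indels: single-residue events outside the motif
            n_events = rng.poisson(indel_rate * t * len(s))
            for _ in range(n_events):
                if len(s) <= 2:
                    break
                if rng.random() < 0.5:   # deletion
                    j = int(rng.integers(len(s)))
                    if s[j][0] in motif_keys:
                        continue
                    del s[j]
                else:                     # insertion
                    j = int(rng.integers(len(s) + 1))
                    left = s[j - 1][0] if j > 0 else s[0][0] - 1.0
                    right = s[j][0] if j < len(s) else s[-1][0] + 1.0
                    key = (left + right) / 2.0
                    if lo_m < key < hi_m:
                        continue
                    aa = AMINO_ACIDS[int(rng.integers(len(AMINO_ACIDS)))]
                    s.insert(j, (key, aa))
            if child.is_leaf():
                leaf_seqs[child.taxon.label] = s
            else:
                descend(child, s)

    seed_node = tree.seed_node
    if seed_node.is_leaf():
        leaf_seqs[seed_node.taxon.label] = root_cols
    descend(seed_node, root_cols)
    return leaf_seqs, motif_keys


def _alignment_from_leaf_cols(leaf_cols: dict[str, list[tuple[float, str]]],
                              order: list[str]) -> ProteinAlignment:
    all_keys = sorted({k for cols in leaf_cols.values() for k, _ in cols})
    key_idx = {k: i for i, k in enumerate(all_keys)}
    rows = []
    for leaf in order:
        row = ["-"] * len(all_keys)
        for k, aa in leaf_cols[leaf]:
            row[key_idx[k]] = aa
        rows.append("".join(row))
    return ProteinAlignment(order, rows)


# ---------------------------------------------------------------------------
# tree, groups and intron history
# ---------------------------------------------------------------------------

def _label_internal_nodes(tree: dendropy.Tree) -> None:
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if node is tree.seed_node:
            node.label = "root"
        else:
            i += 1
            node.label = f"N{i}"


def _node_id(node: dendropy.Node) -> str:
    return node.taxon.label if node.is_leaf() else node.label


def _leafset(node: dendropy.Node) -> set[str]:
    return {lf.taxon.label for lf in node.leaf_iter()}


def _make_groups(tree: dendropy.Tree, n_groups: int) -> dict[str, str]:
    """Label leaves by deep clade: split the largest clade until n_groups."""
    clades = list(tree.seed_node.child_nodes())
    while len(clades) < n_groups:
        clades.sort(key=lambda n: -len(_leafset(n)))
        big = clades.pop(0)
        kids = big.child_nodes()
        if not kids:
            clades.append(big)
            break
        clades.extend(kids)
    clades.sort(key=lambda n: sorted(_leafset(n))[0])
    labels = "ABCDEFGHIJKLMN"
    group_map = {}
    for lab, clade in zip(labels, clades):
        for leaf in _leafset(clade):
            group_map[leaf] = lab
    return group_map


def _plant_intron_history(tree: dendropy.Tree, n_classes: int, p_loss: float,
                          anchors: list[int], rng: np.random.Generator,
                          ) -> list[IntronClassTruth]:
    """Plant ≤ n_classes intron classes so every leaf carries at most two.

    Classes 1 and 2 are "ancestral": gained on the two sides of the root
    (mutually exclusive, mirroring the two deep conserved introns seen in
    real plant UGT families). Extra classes are gained on small subtrees
    nested within one side each, so per-leaf counts stay ≤ 2.
    """
    kids = tree.seed_node.child_nodes()
    if len(kids) < 2:
        raise ValueError("tree root must have at least two children")
    c1, c2 = kids[0], kids[1]
    phases = [0, 1, 2]
    classes: list[IntronClassTruth] = []

    def small_subtrees(side: dendropy.Node) -> list[dendropy.Node]:
        return [n for n in side.preorder_internal_node_iter()
                if n is not side and 2 <= len(_leafset(n)) <= 3]

    gain_nodes: list[dendropy.Node] = [c1, c2]
    sides = [c1, c2]
    for i in range(2, n_classes):
        side = sides[i % 2]
        cands = small_subtrees(side)
        if not cands:
            cands = [lf for lf in side.leaf_iter()]
        gain_nodes.append(cands[int(rng.integers(len(cands)))])

    for ci, gain in enumerate(gain_nodes[:n_classes], start=1):
        possess = _leafset(gain)
        losses: list[str] = []
        if not gain.is_leaf() and rng.random() < p_loss:
            # candidate loss edges: proper descendants whose removal leaves
            # every child of the gain node with at least one possessing leaf
            cands = []
            for node in gain.preorder_iter():
                if node is gain:
                    continue
                removed = _leafset(node)
                ok = all((_leafset(ch) - removed) for ch in gain.child_nodes())
                if ok:
                    cands.append(node)
            if cands:
                loss = cands[int(rng.integers(len(cands)))]
                losses.append(_node_id(loss))
                possess = possess - _leafset(loss)
        classes.append(IntronClassTruth(
            class_id=ci, anchor_pos=anchors[ci - 1],
            phase=phases[int(rng.integers(3))],
            gain_branch=_node_id(gain), loss_branches=losses,
            leaves=possess))
    return classes


# ---------------------------------------------------------------------------
# back-translation and genome assembly
# ---------------------------------------------------------------------------

def _back_translate(protein: str, rng: np.random.Generator) -> str:
    codons = [_CODONS[aa][int(rng.integers(len(_CODONS[aa])))] for aa in protein]
    codons.append(_STOPS[int(rng.integers(3))])
    return "".join(codons)


def _random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _intron_seq(length: int, rng: np.random.Generator) -> str:
    return "GT" + _random_dna(length - 4, rng) + "AG"


def _intron_length(rng: np.random.Generator,
                   lo: int = 65, hi: int = 2258) -> int:
    """Log-uniform intron length in [lo, hi] bp."""
    return int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))


def _build_gene(gene_id: str, protein: str,
                introns: list[tuple[int, int]],   # (cds_offset, length)
                strand: str, rng: np.random.Generator, flank: int = 60,
                ) -> tuple[str, GeneModel, str]:
    """Assemble one scaffold carrying one gene; returns (scaffold, model, cds)."""
    cds = _back_translate(protein, rng)
    introns = sorted(introns)
    # genomic layout on the + orientation of the transcript
    pieces = []
    prev = 0
    for off, ln in introns:
        pieces.append(("exon", cds[prev:off]))
        pieces.append(("intron", _intron_seq(ln, rng)))
        prev = off
    pieces.append(("exon", cds[prev:]))
    tx_region = "".join(seq for _, seq in pieces)
    scaffold_plus = _random_dna(flank, rng) + tx_region + _random_dna(flank, rng)
    # exon intervals on the + orientation
    pos = flank + 1
    plus_ivs: list[tuple[int, int]] = []
    for kind, seq in pieces:
        if kind == "exon" and seq:
            plus_ivs.append((pos, pos + len(seq) - 1))
        pos += len(seq)
    L = len(scaffold_plus)
    if strand == "+":
        scaffold = scaffold_plus
        ivs = plus_ivs                       # transcription order
    else:
        from .formats import _revcomp
        scaffold = _revcomp(scaffold_plus)
        ivs = [(L - e + 1, L - s + 1) for s, e in plus_ivs]  # tx order kept
    model = GeneModel(
        gene_id=gene_id, seq_id=f"scf_{gene_id}", strand=strand,
        exons=list(ivs), cds_intervals=list(ivs),
        protein=protein, cds_length=len(cds), complete=True, has_stop=True)
    return scaffold, model, cds


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, length))


def simulate_family(n_leaves: int = 16,
                    birth_death_params: tuple[float, float] = (1.0, 0.3),
                    subst_rate: float = 0.5,
                    indel_rate: float = 0.01,
                    motif_consensus: str = PSPG_CONSENSUS,
                    seed: int = 0,
                    *,
                    tree: dendropy.Tree | None = None,
                    root_length: int = 470,
                    motif_rate_factor: float = 0.1,
                    n_intron_classes: int = 4,
                    p_loss: float = 0.3,
                    jitter: int = 5,
                    decoy_frac: float = 0.30,
                    n_groups: int = 4,
                    tissues: list[str] | None = None,
                    ) -> FamilySim:
    """Simulate a gene family with full ground truth.

    Proteins evolve along a birth–death tree (or a user-supplied ``tree``)
    with the 44-residue motif region held at ``motif_rate_factor`` of the
    global substitution rate. Genes are back-translated with uniform
    synonymous codons, introns are inserted per the planted gain/loss
    history with ±``jitter`` residues of positional drift, and decoy genes
    (out-of-range length, >2 introns, or motif-free) are appended so the
    candidate filters can be tested in both directions.
    """
    if tree is None and n_leaves < 3:
        raise ValueError("n_leaves must be >= 3")
    if subst_rate < 0 or indel_rate < 0:
        raise ValueError("rates must be non-negative")
    if len(motif_consensus) != 44:
        raise ValueError("motif consensus must be 44 residues")
    rng = np.random.default_rng([seed, 7])
    if tree is None:
        birth, death = birth_death_params
        tree = treesim.birth_death_tree(
            birth_rate=birth, death_rate=death, num_extant_tips=n_leaves,
            rng=random.Random(seed % (2 ** 31)))
        # normalise depth so subst_rate is expected subs/site root-to-tip
        depth = max(lf.distance_from_root() for lf in tree.leaf_node_iter())
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length /= depth
        for i, leaf in enumerate(sorted(tree.leaf_node_iter(),
                                        key=lambda n: n.taxon.label), 1):
            leaf.taxon.label = f"G{i:02d}"
    else:
        tree = tree.clone(depth=1)
    n_leaves = len(tree.leaf_nodes())
    _label_internal_nodes(tree)
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())

    # root protein with motif near the C-terminus
    motif_start = root_length - 44 - 46       # e.g. 380 for a 470-aa root
    root = (random_protein(motif_start - 1, rng) + motif_consensus
            + random_protein(root_length - motif_start + 1 - 44, rng))
    leaf_cols, motif_keys = _evolve_along_tree(
        tree, root, motif_start, subst_rate, indel_rate, motif_rate_factor, rng)
    alignment = _alignment_from_leaf_cols(leaf_cols, leaves)

    group_map = _make_groups(tree, n_groups)

    # intron history: anchors spread evenly over the pre-motif region so
    # classes stay separable after jitter (adjacent classes can only merge
    # into one conserved-position window when closer than twice the
    # clustering window plus twice the jitter)
    spacing = ((motif_start - 60) // (n_intron_classes - 1)
               if n_intron_classes > 1 else 0)
    anchors = [30 + i * spacing for i in range(n_intron_classes)]
    if anchors and anchors[-1] > motif_start - 30:
        raise ValueError("too many intron classes for this root length")
    classes = _plant_intron_history(tree, n_intron_classes, p_loss, anchors, rng)
    presence = pd.DataFrame(
        {f"class{c.class_id}": [leaf in c.leaves for leaf in leaves]
         for c in classes}, index=leaves)

    # per-gene sequences, intron placements, genome
    genome: dict[str, str] = {}
    models: list[GeneModel] = []
    proteins: dict[str, str] = {}
    cds_map: dict[str, str] = {}
    motif_window: dict[str, int] = {}
    anchor_key = {c.class_id: float(c.anchor_pos) for c in classes}

    for leaf in leaves:
        cols = leaf_cols[leaf]
        protein = "".join(aa for _, aa in cols)
        proteins[leaf] = protein
        keys = [k for k, _ in cols]
        motif_window[leaf] = 1 + sum(1 for k in keys if k < min(motif_keys))
        introns: list[tuple[int, int]] = []
        for c in classes:
            if leaf not in c.leaves:
                continue
            # residue index at/after the anchor column, then jitter
            idx = next((i for i, k in enumerate(keys) if k >= anchor_key[c.class_id]),
                       len(keys) - 1)
            pos = idx + 1 + int(rng.integers(-jitter, jitter + 1))
            pos = max(2, min(len(protein) - 1, pos))
            cds_offset = (pos - 1) * 3 + c.phase
            introns.append((cds_offset, _intron_length(rng)))
        strand = "+" if rng.random() < 0.5 else "-"
        scaffold, model, cds = _build_gene(leaf, protein, introns, strand, rng)
        genome[model.seq_id] = scaffold
        models.append(model)
        cds_map[leaf] = cds

    # decoys: split across the three failure modes
    n_decoys = int(round(n_leaves * decoy_frac / (1.0 - decoy_frac)))
    decoys: dict[str, str] = {}
    modes = ["length", "intron_count", "no_motif"]
    for di in range(n_decoys):
        mode = modes[di % 3]
        gid = f"D{di + 1:02d}"
        if mode == "length":
            base = proteins[leaves[di % n_leaves]]
            if di % 2 == 0:
                prot = base[-300:]                       # too short, motif kept
            else:
                prot = base + random_protein(120, rng)   # too long
            introns = []
        elif mode == "intron_count":
            prot = proteins[leaves[di % n_leaves]]
            offs = sorted(rng.choice(np.arange(30, len(prot) * 3 - 30, 3),
                                     size=3, replace=False).tolist())
            introns = [(int(o), _intron_length(rng)) for o in offs]
        else:
            prot = random_protein(450, rng)
            introns = []
        strand = "+" if rng.random() < 0.5 else "-"
        scaffold, model, cds = _build_gene(gid, prot, introns, strand, rng)
        genome[model.seq_id] = scaffold
        models.append(model)
        proteins[gid] = prot
        cds_map[gid] = cds
        decoys[gid] = mode

    # expression ground truth over family genes only
    tissues = list(tissues or ["FL", "GE", "TC", "ST", "LE"])
    unknown = set(tissues) - set(DEFAULT_TISSUES)
    if unknown:
        raise ValueError(f"unknown tissue codes: {sorted(unknown)}")
    weights = rng.dirichlet(np.full(len(leaves), 0.5), size=len(tissues)).T
    expression_weights = pd.DataFrame(weights, index=leaves, columns=tissues)
    qpcr_truth = pd.DataFrame(
        2.0 ** rng.uniform(-3, 3, size=(len(leaves), len(tissues))),
        index=leaves, columns=tissues)

    truth = FamilySimTruth(
        tree=tree, group_map=group_map, true_alignment=alignment,
        motif_window=motif_window, intron_classes=classes, presence=presence,
        decoys=decoys, expression_weights=expression_weights,
        qpcr_truth=qpcr_truth)
    return FamilySim(genome=genome, gene_models=models, proteins=proteins,
                     truth=truth, cds=cds_map)


@dataclass
class ESTSim:
    """Simulated EST set plus the per-(gene, tissue) sampling truth."""

    records: list[ESTRecord]
    planted_counts: pd.DataFrame   # gene × tissue integers

    def write(self, path: str | Path) -> None:
        write_est_fasta(self.records, path)


def simulate_ests(sim: FamilySim, n_ests: int = 2000,
                  read_length_range: tuple[int, int] = (150, 500),
                  error_rate: float = 0.01, seed: int = 0) -> ESTSim:
    """Sample ESTs: tissue uniform, gene per tissue weights, uniform substring
    of the gene's CDS, per-base substitution errors at ``error_rate``."""
    if n_ests <= 0:
        raise ValueError("n_ests must be positive")
    rng = np.random.default_rng([seed, 11])
    weights = sim.truth.expression_weights
    genes = list(weights.index)
    tissues = list(weights.columns)
    counts = pd.DataFrame(0, index=genes, columns=tissues)
    records: list[ESTRecord] = []
    lo, hi = read_length_range
    for i in range(n_ests):
        tissue = tissues[int(rng.integers(len(tissues)))]
        gene = genes[int(rng.choice(len(genes), p=weights[tissue].to_numpy()))]
        cds = sim.cds[gene]
        rl = min(int(rng.integers(lo, hi + 1)), len(cds))
        start = int(rng.integers(0, len(cds) - rl + 1))
        read = list(cds[start:start + rl])
        for j in range(len(read)):
            if rng.random() < error_rate:
                read[j] = "ACGT"[(("ACGT".index(read[j])) +
                                  1 + int(rng.integers(3))) % 4]
        counts.loc[gene, tissue] += 1
        records.append(ESTRecord(
            est_id=f"EST{i + 1:06d}", sequence="".join(read),
            library_id=f"LIB_{tissue}", tissue=tissue))
    return ESTSim(records=records, planted_counts=counts)


def simulate_qpcr(sim: FamilySim, reference_gene: str = "ETIF5A",
                  n_bio: int = 3, n_tech: int = 2, sd_ct: float = 0.1,
                  seed: int = 0, baseline_ct: float = 20.0,
                  genes: list[str] | None = None,
                  tissues: list[str] | None = None) -> pd.DataFrame:
    """Emit a CT table with CT_target = CT_ref − log2(relative abundance)
    plus Gaussian replicate noise. The reference gene's bio-replicate CT is
    shared between reference and target rows, as in a real plate."""
    if sd_ct < 0:
        raise ValueError("sd_ct must be non-negative")
    rng = np.random.default_rng([seed, 13])
    truth = sim.truth.qpcr_truth
    genes = list(genes or truth.index[:4])
    tissues = list(tissues or truth.columns[:3])
    rows = []
    for tissue in tissues:
        for b in range(1, n_bio + 1):
            ct_ref = baseline_ct + rng.normal(0.0, sd_ct)
            for t in range(1, n_tech + 1):
                rows.append((reference_gene, tissue, b, t,
                             ct_ref + rng.normal(0.0, sd_ct)))
            for gene in genes:
                ra = float(truth.loc[gene, tissue])
                if ra <= 0:
                    raise ValueError("relative abundances must be positive")
                base = ct_ref - math.log2(ra)
                for t in range(1, n_tech + 1):
                    rows.append((gene, tissue, b, t,
                                 base + rng.normal(0.0, sd_ct)))
    return pd.DataFrame(rows, columns=["gene", "tissue", "bio_rep",
                                       "tech_rep", "ct"])


# ---------------------------------------------------------------------------
# auxiliary panels for homology tests
# ---------------------------------------------------------------------------

def mutate_protein(protein: str, n_subs: int, rng: np.random.Generator) -> str:
    """Apply exactly ``n_subs`` substitutions at distinct positions."""
    seq = list(protein)
    for i in rng.choice(len(seq), size=n_subs, replace=False):
        seq[i] = AMINO_ACIDS[rng.choice(len(AMINO_ACIDS),
                                        p=_EXCHANGE[_AA_INDEX[seq[i]]])]
    return "".join(seq)


def simulate_duplicate_panel(seed: int = 0, n_base: int = 6,
                             length: int = 420,
                             dup_identity: tuple[float, float] = (0.92, 0.95),
                             ) -> tuple[dict[str, str], set[frozenset[str]]]:
    """Unrelated base proteins plus planted near-identical duplicate pairs.

    Returns (proteins, truth pairs); duplicates differ by 5–8% substitutions,
    all other pairs are unrelated random sequences (identity ≪ 0.8).
    """
    rng = np.random.default_rng([seed, 17])
    proteins: dict[str, str] = {}
    pairs: set[frozenset[str]] = set()
    for i in range(n_base):
        base = random_protein(length, rng)
        gid = f"P{i + 1:02d}"
        proteins[gid] = base
        if i % 2 == 0:   # every other base gene gets a duplicate
            ident = rng.uniform(*dup_identity)
            n_subs = int(round(length * (1.0 - ident)))
            did = f"{gid}d"
            proteins[did] = mutate_protein(base, n_subs, rng)
            pairs.add(frozenset((gid, did)))
    return proteins, pairs


def simulate_ortholog_panel(sim: FamilySim, n_comparators: int = 2,
                            k_diverged: int = 3, divergence_subs: int = 40,
                            seed: int = 0,
                            ) -> tuple[dict[str, str],
                                       dict[str, dict[str, str]], set[str]]:
    """Query set = family proteins + ``k_diverged`` lineage-specific genes.

    Comparator proteomes carry perturbed copies of every family protein plus
    unrelated padding, but no homolog of the diverged genes, which are built
    on unrelated backbones (sharing only the short signature motif) so no
    cross-hit can reach a significant score.
    """
    rng = np.random.default_rng([seed, 19])
    queries = {g: sim.proteins[g] for g in sim.family_genes}
    diverged: set[str] = set()
    for i in range(k_diverged):
        gid = f"X{i + 1:02d}"
        backbone = random_protein(430, rng)
        prot = backbone[:370] + PSPG_CONSENSUS + backbone[370:386]
        queries[gid] = prot
        diverged.add(gid)
    comparators: dict[str, dict[str, str]] = {}
    for c in range(1, n_comparators + 1):
        prot_map = {}
        for g in sim.family_genes:
            prot_map[f"C{c}_{g}"] = mutate_protein(
                sim.proteins[g], divergence_subs, rng)
        for j in range(3):   # unrelated padding
            prot_map[f"C{c}_rand{j}"] = random_protein(420, rng)
        comparators[f"comparator{c}"] = prot_map
    return queries, comparators, diverged
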