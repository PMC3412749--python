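"""Family mining: conserved-motif scanning, candidate filtering, and
duplicate / ortholog / diverged-gene detection.

The mining probe is a single 44-residue consensus scored against every
ungapped window of each protein with a substitution matrix (BLOSUM62 by
default). Candidates must additionally fall in a protein-length range
(default 375–530 aa) and carry at most two CDS-interrupting introns.
Pairwise homology uses Biopython's global affine-gap aligner; E-values use
the ungapped Karlin–Altschul form, adequate for ordering desk-scale
comparisons, not a BLAST reimplementation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from numpy.lib.stride_tricks import sliding_window_view

from .formats import GeneModel

logger = logging.getLogger(__name__)

MOTIF_LENGTH = 44

#: Ungapped Karlin–Altschul parameters for BLOSUM62 in half-bit units.
KA_LAMBDA = 0.318
KA_K = 0.13


def load_matrix(matrix):
    """Accept a matrix name or a Biopython substitution matrix object."""
    if isinstance(matrix, str):
        return substitution_matrices.load(matrix)
    return matrix


@dataclass
class MotifHit:
    """Best-scoring ungapped 44-aa window of one protein."""

    gene_id: str
    offset: int      # 1-based window start
    score: float
    window: str


@dataclass
class CandidateSet:
    accepted: set[str]
    rejected: dict[str, str]   # gene -> no_motif | length | intron_count


@dataclass
class HomologyCall:
    query_id: str
    subject_id: str
    identity: float
    score: float
    e_value: float


def motif_self_score(motif: str, matrix="BLOSUM62") -> float:
    mat = load_matrix(matrix)
    return float(sum(mat[a, a] for a in motif))


def _encode(seq: str, alphabet: str) -> np.ndarray:
    lut = np.full(128, alphabet.index("X") if "X" in alphabet else 0,
                  dtype=np.int64)
    for i, c in enumerate(alphabet):
        lut[ord(c)] = i
    return lut[np.frombuffer(seq.encode("ascii", "replace"), dtype=np.uint8)]


def scan_motif(proteins: Mapping[str, str], motif_consensus: str,
               matrix="BLOSUM62", min_score: float | None = None,
               ) -> list[MotifHit]:
    """Best ungapped 44-aa window per protein, reported if score ≥ min_score.

    ``min_score`` defaults to half the consensus self-score, which tolerates
    the divergence seen within a real family while excluding random windows.
    Ties are broken toward the smallest offset.
    """
    if len(motif_consensus) != MOTIF_LENGTH:
        raise ValueError(f"motif must be exactly {MOTIF_LENGTH} residues")
    mat = load_matrix(matrix)
    alpha = str(mat.alphabet)
    if min_score is None:
        min_score = 0.5 * motif_self_score(motif_consensus, mat)
    midx = _encode(motif_consensus, alpha)
    profile = np.asarray(mat)[midx, :]          # 44 × |alphabet|
    hits: list[MotifHit] = []
    for gid, prot in proteins.items():
        if len(prot) < MOTIF_LENGTH:
            continue
        pidx = _encode(prot, alpha)
        windows = sliding_window_view(pidx, MOTIF_LENGTH)
        scores = profile[np.arange(MOTIF_LENGTH)[None, :], windows].sum(axis=1)
        best = int(np.argmax(scores))            # first maximum → smallest offset
        if scores[best] >= min_score:
            hits.append(MotifHit(gene_id=gid, offset=best + 1,
                                 score=float(scores[best]),
                                 window=prot[best:best + MOTIF_LENGTH]))
    return hits


def filter_candidates(hits: Iterable[MotifHit],
                      gene_models: Mapping[str, GeneModel] | Iterable[GeneModel],
                      length_range: tuple[int, int] = (375, 530),
                      max_introns: int = 2) -> CandidateSet:
    """Apply the family candidate filters to motif hits.

    A gene is accepted iff it has a motif hit, its protein length lies in
    ``length_range`` (inclusive) and it has at most ``max_introns``
    CDS-interrupting introns. The rejection reason is the first failing
    check in the order no_motif, length, intron_count.
    """
    if not isinstance(gene_models, Mapping):
        gene_models = {m.gene_id: m for m in gene_models}
    hit_genes = {h.gene_id for h in hits}
    missing = hit_genes - set(gene_models)
    if missing:
        raise KeyError(f"no gene model for hit gene(s): {sorted(missing)}")
    lo, hi = length_range
    accepted: set[str] = set()
    rejected: dict[str, str] = {}
    for gid in sorted(gene_models):
        model = gene_models[gid]
        if gid not in hit_genes:
            rejected[gid] = "no_motif"
        elif not lo <= len(model.protein) <= hi:
            rejected[gid] = "length"
        elif model.n_introns > max_introns:
            rejected[gid] = "intron_count"
        else:
            accepted.add(gid)
    return CandidateSet(accepted=accepted, rejected=rejected)


def align_pair(a_protein: str, b_protein: str,
               gap_open: float = 11.0, gap_extend: float = 1.0,
               matrix="BLOSUM62", search_space: float | None = None,
               query_id: str = "query", subject_id: str = "subject",
               ) -> HomologyCall:
    """Optimal global affine-gap alignment of two proteins.

    Gap of length g costs ``gap_open + (g-1)·gap_extend``. Identity is
    matches / aligned (non-gap) columns. The E-value uses the ungapped
    Karlin–Altschul form E = K·m·n·exp(−λS) with BLOSUM62 half-bit
    constants and search space m·n unless ``search_space`` is given.
    """
    if not a_protein or not b_protein:
        raise ValueError("empty sequence")
    mat = load_matrix(matrix)
    aligner = PairwiseAligner(mode="global", substitution_matrix=mat,
                              open_gap_score=-gap_open,
                              extend_gap_score=-gap_extend)
    aln = aligner.align(a_protein, b_protein)[0]
    matches = 0
    aligned_cols = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        aligned_cols += a1 - a0
        matches += sum(1 for i, j in zip(range(a0, a1), range(b0, b1))
                       if a_protein[i] == b_protein[j])
    identity = matches / aligned_cols if aligned_cols else 0.0
    if search_space is None:
        search_space = len(a_protein) * len(b_protein)
    exponent = KA_LAMBDA * aln.score - math.log(KA_K * search_space)
    e_value = math.exp(-exponent) if exponent < 700 else 0.0
    return HomologyCall(query_id=query_id, subject_id=subject_id,
                        identity=identity, score=float(aln.score),
                        e_value=e_value)


def detect_duplicates(accepted_proteins: Mapping[str, str],
                      min_identity: float = 0.90,
                      **align_kwargs) -> list[tuple[str, str]]:
    """All unordered pairs with global-alignment identity ≥ ``min_identity``."""
    pairs = []
    for a, b in combinations(sorted(accepted_proteins), 2):
        call = align_pair(accepted_proteins[a], accepted_proteins[b],
                         query_id=a, subject_id=b, **align_kwargs)
        if call.identity >= min_identity:
            pairs.append((a, b))
    return pairs


def detect_orthologs(queries: Mapping[str, str],
                     comparator_proteomes: Mapping[str, Mapping[str, str]],
                     e_max: float = 1e-100,
                     **align_kwargs,
                     ) -> tuple[dict[str, dict[str, HomologyCall]], set[str]]:
    """Best qualifying hit per comparator for each query, plus the diverged set.

    A query is *diverged* when no comparator yields a hit with
    ``e_value < e_max``. Empty comparator proteomes are skipped with a
    warning.
    """
    ortho: dict[str, dict[str, HomologyCall]] = {q: {} for q in queries}
    for comp_name, proteome in comparator_proteomes.items():
        if not proteome:
            logger.warning("comparator %s is empty; skipped", comp_name)
            continue
        for q, qseq in queries.items():
            best: HomologyCall | None = None
            for s, sseq in proteome.items():
                call = align_pair(qseq, sseq, query_id=q, subject_id=s,
                                  **align_kwargs)
                if call.e_value < e_max and (best is None
                                             or call.score > best.score):
                    best = call
            if best is not None:
                ortho[q][comp_name] = best
    diverged = {q for q, hits in ortho.items() if not hits}
    return ortho, diverged
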