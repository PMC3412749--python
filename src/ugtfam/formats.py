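"""Standard-format I/O and the shared in-memory domain types.

Coordinate conventions used throughout the package:

* Genomic intervals follow GFF3 — 1-based, fully closed (inclusive on both
  ends).
* Protein positions and alignment columns are 1-based.
* Minus-strand gene models are normalised to *transcription order* at parse
  time: exon/CDS interval lists run 5'→3' on the mRNA, so downstream modules
  never have to reason about genomic orientation.

Parsing of the standard formats is delegated to Biopython (FASTA), gffutils
(GFF3), dendropy (Newick) and pandas (tabular files); this module only adds
the domain-specific validation and the thin writers needed for round-trips.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

#: The 15 EST library tissue codes used for digital expression profiling
#: (flower, embryo stages, seed-coat stages, endosperm, seedling, stem,
#: leaf, peeled stem, bolls, outer fibrous stem).
DEFAULT_TISSUES: dict[str, str] = {
    "FL": "flower",
    "GE": "globular embryo",
    "HE": "heart embryo",
    "TE": "torpedo embryo",
    "BE": "bent embryo",
    "ME": "mature embryo",
    "GC": "seed coat, globular stage",
    "TC": "seed coat, torpedo stage",
    "EN": "pooled endosperm",
    "ES": "etiolated seedling",
    "ST": "stem",
    "LE": "leaf",
    "PS": "peeled stem",
    "BO": "12 DAF bolls",
    "OF": "outer fibrous stem tissue",
}

Interval = tuple[int, int]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """One gene's exon/CDS structure plus its protein translation.

    ``exons`` and ``cds_intervals`` are genomic (seq_id) coordinates but
    listed in transcription order; for ``strand == '-'`` the first interval
    is therefore the one with the *largest* genomic start.
    """

    gene_id: str
    seq_id: str
    strand: str
    exons: list[Interval]
    cds_intervals: list[Interval]
    protein: str
    cds_length: int
    complete: bool = True     # CDS length divisible by 3
    has_stop: bool = True     # trailing stop codon removed from ``protein``

    @property
    def n_introns(self) -> int:
        """Number of CDS-interrupting introns."""
        return len(self.cds_intervals) - 1

    def intron_lengths(self) -> list[int]:
        """Genomic lengths (bp) of the gaps between consecutive CDS chunks."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.cds_intervals, self.cds_intervals[1:]):
            if self.strand == "+":
                out.append(s2 - e1 - 1)
            else:
                out.append(s1 - e2 - 1)
        return out


@dataclass
class ESTRecord:
    """A single expressed sequence tag with its library/tissue annotation."""

    est_id: str
    sequence: str
    library_id: str
    tissue: str


@dataclass
class ExpressionTable:
    """Gene × tissue expression values.

    ``kind`` is ``est_counts`` (non-negative integers) or ``log2_intensity``
    (reals). Stored as a pandas DataFrame with genes as the index.
    """

    values: pd.DataFrame
    kind: str = "est_counts"

    def __post_init__(self) -> None:
        if self.kind not in ("est_counts", "log2_intensity"):
            raise ValueError(f"unknown expression kind: {self.kind!r}")
        if self.values.isna().any().any():
            raise ValueError("expression table contains missing values")
        if self.kind == "est_counts":
            vals = self.values.to_numpy()
            if (vals < 0).any() or not np.allclose(vals, np.round(vals)):
                raise ValueError("est_counts must be non-negative integers")
            self.values = self.values.astype(int)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)


class ProteinAlignment:
    """A protein multiple alignment with column ↔ residue index maps.

    Rows must be equal length; gaps are ``-``. All positions are 1-based.
    """

    GAP = "-"

    def __init__(self, ids: Sequence[str], rows: Sequence[str]):
        ids = list(ids)
        rows = [str(r).upper() for r in rows]
        if len(ids) != len(rows):
            raise ValueError("ids and rows differ in number")
        lengths = {len(r) for r in rows}
        if len(lengths) > 1:
            offenders = [i for i, r in zip(ids, rows)
                         if len(r) != len(rows[0])]
            raise ValueError(
                f"alignment rows are not equal length; offenders: {offenders}")
        self.ids = ids
        self.rows = dict(zip(ids, rows))
        self.n_cols = len(rows[0]) if rows else 0
        # per-sequence maps
        self._res2col: dict[str, np.ndarray] = {}
        self._col2res: dict[str, np.ndarray] = {}
        for sid, row in self.rows.items():
            arr = np.frombuffer(row.encode(), dtype="S1")
            isres = arr != b"-"
            res2col = np.flatnonzero(isres) + 1           # residue i -> col
            col2res = np.cumsum(isres)                    # col -> residue
            col2res[~isres] = 0                           # 0 = gap
            self._res2col[sid] = res2col
            self._col2res[sid] = col2res

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ProteinAlignment":
        recs = list(SeqIO.parse(str(path), "fasta"))
        return cls([r.id for r in recs], [str(r.seq) for r in recs])

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sid in self.ids:
                fh.write(f">{sid}\n{self.rows[sid]}\n")

    def ungapped(self, seq_id: str) -> str:
        return self.rows[seq_id].replace(self.GAP, "")

    def ungapped_length(self, seq_id: str) -> int:
        return len(self._res2col[seq_id])

    def res_to_col(self, seq_id: str, pos: int) -> int:
        """Alignment column (1-based) of residue ``pos`` (1-based)."""
        r2c = self._res2col[seq_id]
        if not 1 <= pos <= len(r2c):
            raise IndexError(f"residue {pos} out of range for {seq_id}")
        return int(r2c[pos - 1])

    def col_to_res(self, seq_id: str, col: int) -> int | None:
        """Residue index at column ``col``; None if the row has a gap there."""
        if not 1 <= col <= self.n_cols:
            raise IndexError(f"column {col} out of range")
        row = self.rows[seq_id]
        if row[col - 1] == self.GAP:
            return None
        return int(self._col2res[seq_id][col - 1])

    def take_columns(self, cols: Sequence[int]) -> "ProteinAlignment":
        """New alignment from 0-based column indices (bootstrap resampling)."""
        idx = np.asarray(cols, dtype=int)
        rows = ["".join(np.array(list(self.rows[sid]))[idx]) for sid in self.ids]
        return ProteinAlignment(self.ids, rows)

    def subset(self, ids: Sequence[str]) -> "ProteinAlignment":
        return ProteinAlignment(list(ids), [self.rows[i] for i in ids])

    def drop_gappy_columns(self, max_gap_frac: float = 0.20) -> "ProteinAlignment":
        """Column-occupancy filter standing in for manual alignment trimming.

        Keeps columns whose gap fraction is strictly below ``max_gap_frac``.
        """
        mat = np.array([list(self.rows[sid]) for sid in self.ids])
        gap_frac = (mat == self.GAP).mean(axis=0)
        keep = np.flatnonzero(gap_frac < max_gap_frac)
        if len(keep) == 0:
            raise ValueError("no columns survive the gap filter")
        return self.take_columns(keep)


# ---------------------------------------------------------------------------
# gene models (GFF3 + genome FASTA)
# ---------------------------------------------------------------------------

def read_genome_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for sid, seq in seqs.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def read_gene_models(gff3_path: str | Path,
                     genome_fasta_path: str | Path) -> list[GeneModel]:
    """Parse GFF3 gene models and translate their spliced CDS.

    One GeneModel is produced per mRNA feature. Minus-strand models are
    reverse-complemented before translation and their interval lists are
    returned in transcription order. Models whose CDS length is not a
    multiple of 3 are flagged ``complete=False`` but retained.
    """
    genome = read_genome_fasta(genome_fasta_path)
    db = gffutils.create_db(str(gff3_path), ":memory:",
                            merge_strategy="create_unique", keep_order=True)
    models: list[GeneModel] = []
    for mrna in db.features_of_type(("mRNA", "transcript"), order_by="start"):
        if mrna.seqid not in genome:
            raise KeyError(f"sequence {mrna.seqid!r} missing from genome FASTA")
        exons = sorted((f.start, f.end)
                       for f in db.children(mrna, featuretype="exon"))
        cds = sorted((f.start, f.end)
                     for f in db.children(mrna, featuretype="CDS"))
        if not cds:
            logger.warning("mRNA %s has no CDS; skipped", mrna.id)
            continue
        if not exons:
            exons = list(cds)
        contig = genome[mrna.seqid]
        spliced = "".join(contig[s - 1:e] for s, e in cds)
        if mrna.strand == "-":
            spliced = _revcomp(spliced)
            exons = exons[::-1]
            cds = cds[::-1]
        cds_length = len(spliced)
        complete = cds_length % 3 == 0
        coding = spliced[:cds_length - cds_length % 3]
        protein = str(Seq(coding).translate())
        has_stop = protein.endswith("*")
        if has_stop:
            protein = protein[:-1]
        models.append(GeneModel(
            gene_id=mrna.id, seq_id=mrna.seqid, strand=mrna.strand,
            exons=exons, cds_intervals=cds, protein=protein,
            cds_length=cds_length, complete=complete, has_stop=has_stop))
    return models


def write_gene_models(models: Iterable[GeneModel], gff3_path: str | Path) -> None:
    """Emit gene/mRNA/exon/CDS GFF3 for a set of gene models."""
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            ivs = sorted(m.exons)
            cds = sorted(m.cds_intervals)
            start = min(s for s, _ in ivs + cds)
            end = max(e for _, e in ivs + cds)
            gid = m.gene_id
            fh.write(f"{m.seq_id}\tugtfam\tgene\t{start}\t{end}\t.\t"
                     f"{m.strand}\t.\tID=gene:{gid}\n")
            fh.write(f"{m.seq_id}\tugtfam\tmRNA\t{start}\t{end}\t.\t"
                     f"{m.strand}\t.\tID={gid};Parent=gene:{gid}\n")
            for i, (s, e) in enumerate(ivs, 1):
                fh.write(f"{m.seq_id}\tugtfam\texon\t{s}\t{e}\t.\t"
                         f"{m.strand}\t.\tID={gid}.exon{i};Parent={gid}\n")
            # GFF3 phase column: running frame along transcription order
            running = 0
            lines = []
            for i, (s, e) in enumerate(m.cds_intervals, 1):
                frame = (3 - running % 3) % 3
                lines.append((s, e, frame, i))
                running += e - s + 1
            for s, e, frame, i in sorted(lines):
                fh.write(f"{m.seq_id}\tugtfam\tCDS\t{s}\t{e}\t.\t"
                         f"{m.strand}\t{frame}\tID={gid}.cds{i};Parent={gid}\n")


def write_protein_fasta(proteins: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid, seq in proteins.items():
            fh.write(f">{gid}\n{seq}\n")


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# alignment / tree / tabular readers
# ---------------------------------------------------------------------------

def read_alignment(path: str | Path) -> ProteinAlignment:
    """Read an aligned protein FASTA; unequal row lengths are a hard error."""
    return ProteinAlignment.from_fasta(path)


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick",
               suppress_rooting=True, unquoted_underscores=True)


def read_expression_tsv(path: str | Path, kind: str = "est_counts") -> ExpressionTable:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    return ExpressionTable(values=df, kind=kind)


def write_expression_tsv(table: ExpressionTable, path: str | Path,
                         header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        table.values.to_csv(fh, sep="\t", index_label="gene")


def read_est_fasta(path: str | Path,
                   library_map: Mapping[str, str],
                   ) -> tuple[list[ESTRecord], int]:
    """Read EST FASTA whose deflines carry a library id as the second token.

    ``library_map`` resolves library id → tissue code. ESTs with a missing
    or unresolvable library id are skipped with a logged warning; the count
    of skipped records is returned alongside the parsed list.
    """
    records: list[ESTRecord] = []
    skipped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = rec.description.split()
        lib = tokens[1] if len(tokens) > 1 else None
        if lib is None or lib not in library_map:
            logger.warning("EST %s: unresolvable library id %r; skipped",
                           rec.id, lib)
            skipped += 1
            continue
        records.append(ESTRecord(est_id=rec.id, sequence=str(rec.seq).upper(),
                                 library_id=lib, tissue=library_map[lib]))
    return records, skipped


def write_est_fasta(records: Iterable[ESTRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.est_id} {r.library_id}\n{r.sequence}\n")


CT_COLUMNS = ["gene", "tissue", "bio_rep", "tech_rep", "ct"]


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a qPCR CT table (columns gene, tissue, bio_rep, tech_rep, ct)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"CT table missing columns: {sorted(missing)}")
    if (df["ct"] <= 0).any():
        raise ValueError("CT values must be positive")
    return df


def write_ct_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
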