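# ugtfam

Gene-family phylogenomics for motif-defined plant multigene families, built
around the analysis style used for UDP-glycosyltransferase (UGT) family
surveys: mine candidate genes from an annotated genome with the 44-residue
PSPG (plant secondary product glycosyltransferase) box, build the family
phylogeny, map intron architecture and infer intron gain/loss, detect
duplicates and lineage-diverged genes, and profile expression digitally
from EST counts, expression matrices and qPCR.

It is aimed at researchers characterising a gene family in a newly
sequenced genome who want the whole desk analysis — mining, phylogeny,
intron evolution, expression — reproducible from one seeded command, plus
a synthetic-data generator that plants known ground truth so every stage
can be validated before touching real data.

## What it computes

* **Mining** — each protein's best ungapped 44-aa window against a motif
  consensus scored with BLOSUM62; candidates must score above threshold,
  fall in a 375–530 aa length range and carry ≤ 2 CDS-interrupting introns.
* **Phylogeny** — pairwise-deletion p-distances (or the Dayhoff correction
  d = −ln(1 − p − 0.2p²)), Saitou–Nei neighbour joining, nonparametric
  bootstrap supports, a Fitch small-parsimony score, and group assignment
  of each gene to the smallest well-supported clade (support ≥ 85)
  containing reference anchors of exactly one named group.
* **Intron architecture** — intron phase (0/1/2 relative to codon
  boundaries), protein position `floor(cds_offset/3) + 1`, projection onto
  the family alignment, clustering into conserved intron classes (every
  member within 45 aa of the class mean position), and per-branch gain/loss
  reconstruction under Dollo parsimony (one gain, minimal losses) or
  unconstrained Fitch parsimony.
* **Expression** — EST reads mapped to coding sequences by k-mer seeding
  and ungapped extension (k = 11, identity ≥ 0.95, match ≥ 100 nt);
  family/group/tissue summaries; average-linkage clustering on 1 − Pearson
  r for heat-map ordering; and relative transcript abundance
  2^(−ΔCT) ± SE from replicated CT tables.
* **Simulation** — a family evolved along a birth–death tree with the
  motif region conserved, planted intron histories, decoy genes failing
  each mining filter, tissue-weighted ESTs with sequencing error, and CT
  tables with known fold changes.

## Worked example

```bash
ugtfam simulate --outdir sim --seed 3
# wrote 6 files to sim (23 genes, 7 decoys)

ugtfam mine --gff sim/models.gff3 --genome sim/genome.fasta --out mined.tsv
# accepted 16, rejected 7

ugtfam tree --alignment sim/true_alignment.fasta --reps 50 --seed 3 \
    --refs sim/true_groups.tsv --out-tree tree.nwk --out-groups groups.tsv
# tree with 16 leaves written to tree.nwk

ugtfam introns --gff sim/models.gff3 --genome sim/genome.fasta \
    --alignment sim/true_alignment.fasta --tree sim/true_tree.nwk \
    --outdir introns_out
# 19 introns in 4 classes
```

The 23 simulated genes include 7 decoys (too short/long, too many introns,
or motif-free); mining accepts exactly the 16 planted family members and
rejects each decoy with its planted reason. The 19 extracted introns
cluster into the 4 planted conserved-position classes, and
`introns_out/census.tsv` reports the per-gene distribution (here
`mean_per_gene 1.19`, i.e. 19 introns over 16 genes). `ugtfam run-all
--outdir full --seed 3` chains every stage and writes `manifest.json` with
SHA-256 digests of all outputs; rerunning with the same seed reproduces
the digests byte-for-byte.

From Python the same objects are available directly:

```python
from ugtfam import simkit, mining

sim = simkit.simulate_family(seed=3)
hits = mining.scan_motif(sim.proteins, simkit.PSPG_CONSENSUS)
cands = mining.filter_candidates(hits, {m.gene_id: m for m in sim.gene_models})
assert cands.accepted == set(sim.family_genes)
```

## Layout

| Module | Role |
| --- | --- |
| `ugtfam.formats` | domain types (GeneModel, alignment, expression tables) and GFF3/FASTA/Newick/TSV I/O |
| `ugtfam.simkit` | synthetic family/EST/qPCR generator with ground truth |
| `ugtfam.mining` | motif scan, candidate filters, duplicates, orthologs |
| `ugtfam.phylo` | distances, NJ, bootstrap, parsimony score, groups |
| `ugtfam.intronics` | intron phases, classes, Dollo/Fitch events, census |
| `ugtfam.expressionx` | EST mapping, summaries, clustering, ΔCT |
| `ugtfam.pipeline` / `ugtfam.cli` | orchestration, manifest, CLI |

See `docs/methods.md` for the models, parameter defaults and known
limitations.
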