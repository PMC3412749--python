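# Methods

This note records the models and procedures the package implements, the
defaults that matter, and what the synthetic-data generator does and does
not emulate.

## Mining model

The family probe is a single 44-residue consensus of the PSPG box, scored
against every ungapped window of each protein with a substitution matrix
(BLOSUM62 by default, half-bit units). A profile (PSSM) model would be a
natural extension, but a single consensus mirrors how such families are
usually probed in practice (one conserved signature queried against a
predicted proteome) and keeps the score interpretable; the matrix is a
parameter. The reporting threshold defaults to **50 % of the consensus
self-score** (≈ 119 of 238 for the shipped consensus under BLOSUM62).
There is no canonical value for this cutoff; half the self-score accepts
the drift observed within real families and in the simulator's conserved
motif region (which evolves at 10 % of the global rate) while random
44-aa windows score near or below zero — the margin is several hundred
half-bits, so the exact fraction is not delicate.

Candidate filters: protein length within **375–530 aa inclusive** and at
most **2 CDS-interrupting introns**, the length/intron envelope typical
of compact plant UGT genes. Rejection reasons are reported in the fixed
order `no_motif`, `length`, `intron_count` so a gene failing several
checks is attributed deterministically.

Pairwise homology (duplicates, orthologs) uses global affine-gap
alignment (open 11, extend 1, BLOSUM62; a gap of length *g* costs
11 + (*g*−1)). Identity is matches over aligned (non-gap) columns.
E-values use the ungapped Karlin–Altschul form E = K·m·n·e^(−λS) with
λ = 0.318, K = 0.13 and search space m·n. This reproduces the *ordering*
a local-alignment search would give at desk scale; it is not a BLAST
reimplementation and the absolute E-values should not be compared with
BLAST output. Duplicates are unordered pairs with identity ≥ 0.90;
diverged genes are queries with no comparator hit below E = 1e−100.

## Phylogeny

Distances are computed with pairwise deletion (sites gapped in either
sequence are skipped for that pair). Two models are exposed: the raw
p-distance and the Dayhoff correction d = −ln(1 − p − 0.2p²), which
falls back to p (and flags the pair) when the argument is non-positive.
Which correction a published MEGA-style analysis actually applied is
generally not recoverable, so neither model is privileged.

Neighbour joining follows Saitou–Nei with two deterministic choices: ties
in the Q matrix break toward the lexicographically smallest pair of
cluster keys (a cluster's key is its smallest member id), and negative
branch-length estimates are clamped to zero and recorded on the tree.
On additive matrices the algorithm recovers the generating tree exactly
(branch lengths to 1e−9; verified against scikit-bio's NJ as an
independent implementation).

Bootstrap replicates resample alignment columns with replacement.
Replicate *r* uses an RNG substream seeded by (seed, *r*), so increasing
the replicate count extends rather than reshuffles the series, and
supports are invariant to input row order. Support is the percentage of
replicate trees containing each internal bipartition of the full-data
tree.

"Unambiguous alignment regions" are operationalised as a column-occupancy
filter (keep columns with < 20 % gaps), a reproducible surrogate for
manual trimming.

The Fitch parsimony score treats gaps as missing data (a gapped leaf is
unconstrained in that column). It is used as a tree/alignment consistency
statistic only; no parsimony tree search is performed.

Group assignment midpoint-roots the tree (an outgroup id may be supplied
instead) and labels each gene by the smallest clade with bootstrap
support ≥ 85 that contains reference anchors of exactly one group;
genes attaching outside all reference clades, or inside clades mixing
groups, are "unassigned". One caveat: support values are stored on nodes,
and rerooting can in principle reassociate a support value with the edge
on the other side of the root; with the high supports the criterion
requires this has no practical effect, but trees with marginal supports
near the root should be rooted with an explicit outgroup.

## Intron architecture

Phase follows the codon convention (0 between codons, 1 after the first
base, 2 after the second); the protein position of an intron is the
residue following the splice point, `floor(cds_offset/3) + 1`, one
formula for all phases. Only CDS-interrupting introns are counted; UTR
exons are parsed but never enter the census or the filters.

Conserved intron classes are defined positionally: introns from different
genes whose projected alignment columns all lie within **45 aa** of the
class mean. The clustering solves this criterion exactly — sorted columns
are partitioned by dynamic programming into the minimal number of
contiguous classes satisfying the member-to-mean window, with the
leftmost class made as large as possible among minimal solutions so the
result is deterministic. (Plain single-linkage chaining was rejected
because chains can violate the member-to-mean window that defines
positional conservation; the DP satisfies it by construction.) The window
is configurable — published practice quotes a 40–45 aa tolerance and the
permissive end is taken as default — and a 40 vs 45 sensitivity check is
part of the shipped tests via the configurable parameter. A class is
flagged *conserved* when its members span ≥ 2 phylogenetic groups or
number ≥ 10 genes; breadth across groups, not any single count, is what
the designation means in the literature, so both knobs are exposed.

Gain/loss inference runs on a rooted tree (the simulator's true tree, or
a midpoint-rooted inferred tree). Under **Dollo** each class is gained
exactly once at the MRCA of its possessing leaves; losses are the maximal
absent subtrees below the gain, which is the minimal loss set (verified
against exhaustive single-gain enumeration on small trees). Classes whose
gain maps to the root are flagged *ancestral* — this is derived, never
assumed. **Fitch** gives the unconstrained minimal 0/1 changes; Dollo's
event total is never smaller, and the comparison of the two is a useful
diagnostic for histories that Dollo forces to multiply-lose.

Census arithmetic rounds to two decimals, half-up by default; a truncate
flag reproduces summary styles that drop trailing digits (e.g. 55 of 137
intron-less genes printed as 40.14 %).

## Digital expression

EST mapping seeds on exact 11-mers (k < 8 is rejected as unspecific) and
scores each seeded diagonal as identity × overlap over the full ungapped
overlap; thresholds are identity ≥ 0.95 and overlap ≥ 100 nt (or the
whole EST if shorter). There is no canonical threshold set for this kind
of survey; these defaults make recovery on the simulator exact at 1 %
per-base error while rejecting paralog cross-mapping, whose nucleotide
identity after synonymous-site divergence sits far below 95 %. Equal-best
ties across genes are discarded and counted rather than split, keeping
per-gene counts integral; a fractional-split option exists but is off by
default. Mapping is sense-strand only (spliced-alignment and
reverse-complement handling are out of scope); the conservation
invariant mapped + unmapped + ties = input holds for every run.

Summaries report both possible denominators for per-tissue percentages
(fraction of ESTs and fraction of genes), since published per-tissue
figures are ambiguous between the two.

Heat-map ordering uses average-linkage agglomeration (scipy) on
1 − Pearson r between gene rows; EST count tables are log2(x+1)
transformed first. Constant rows, whose correlation is undefined, are
assigned the maximum distance 2.0 to every other row and flagged rather
than dropped.

ΔCT quantification averages technical replicates within each biological
replicate, forms ΔCT = CT(target) − CT(reference) per biological
replicate, and reports the mean and standard error of 2^(−ΔCT) across
biological replicates. Biological replicates missing the reference are
dropped with a warning; a cell with no usable replicate is an error.

## Synthetic-data generator

The generator emulates the *inputs* of a family survey, not the biology:

* **Tree** — birth–death (rates 1.0/0.3) conditioned on the leaf count,
  depth-normalised so the substitution rate is expected substitutions per
  site from root to tip; or any user-supplied tree.
* **Sequences** — site-independent substitutions with exchange
  probabilities proportional to exp(PAM250 score/2) (a Dayhoff-flavoured
  stand-in adequate for testing tree recovery, not a calibrated model);
  single-residue indels at a low rate (0.01) outside the motif; the
  44-residue motif region substitutes at 10 % of the global rate and
  never gains or loses residues, so every gene carries exactly one motif
  window. The root protein is 470 aa with the motif near the C-terminus,
  matching where the signature sits in real family members.
* **Introns** — classes anchored at codon-aligned root positions spread
  evenly across the pre-motif region (adjacent classes can only become
  positionally confusable when anchors sit closer than twice the
  clustering window plus twice the jitter, which the default geometry
  avoids); per-gene positions jittered ±5 residues by default; gains
  planted on the two root-child branches ("ancestral" classes, mutually
  exclusive across the two sides like the two deep conserved introns of
  real plant UGT families) plus small nested subtrees, so no gene exceeds
  the 2-intron filter; at most one loss per class, placed so it never
  relocates the possessing-leaf MRCA (otherwise the planted gain would be
  unidentifiable even in principle). Intron sequences are GT..AG with
  log-uniform lengths in 65–2258 bp, the size range typical of compact
  plant genes.
* **Back-translation** — uniform synonymous codons (no codon-usage bias),
  one gene per scaffold with 60 bp flanks, random strand.
* **Decoys** — 30 % of emitted genes, cycling through the three failure
  modes (length out of range with motif intact, > 2 introns, motif-free
  random sequence), so the filters are tested in both directions.
* **Expression** — per-tissue Dirichlet(0.5) weights over family genes
  (columns sum to 1); ESTs drawn tissue-uniform, gene-per-weights, with a
  uniform substring of the CDS and per-base substitution errors. qPCR
  truth is an independent 2^U(−3,3) fold-change grid; CT tables share the
  reference gene's biological-replicate CT between reference and target
  rows, as on a real plate, so biological noise cancels in ΔCT exactly as
  it should.

Because the generator omits codon bias, rate heterogeneity across
lineages, UTRs, alternative splicing, EST library-size imbalance and
chimeric reads, passing the recovery suite demonstrates algorithmic
correctness under the stated model — not performance on real survey data,
where alignment quality and annotation errors dominate.

Determinism: every stochastic step draws from `numpy` generators seeded
from the user seed (plus a fixed per-operation tag), and the tree
simulator uses a `random.Random` seeded the same way, so identical seeds
give byte-identical FASTA/GFF3/TSV outputs; the pipeline manifest's
SHA-256 digests verify this end to end.

## Problem sizes

Default test/acceptance problem sizes — 16-leaf families (plus 7 decoys),
12-leaf families for bootstrap and intron-history recovery, 200 bootstrap
replicates, 1500–2000 ESTs, 4 genes × 3 tissues × 3 biological × 2
technical qPCR replicates — were chosen as the smallest sizes at which
every recovery property is comfortably non-marginal (e.g. planted deep
clades reach 100 % support, EST count z-scores stay below 1). The
recovery bound for ΔCT uses the known replicate noise (sd_ct/√n_bio on
the ΔCT scale) rather than the per-cell estimated SE, because with three
biological replicates the estimated SE has heavy-tailed (t with 2 df)
behaviour that would make an exhaustive per-cell 3-SE check fail a few
per cent of the time even for a correct implementation.

## Known limitations

* The multiple alignment is consumed, not computed; the simulator's true
  alignment stands in for an external aligner.
* E-values are ungapped Karlin–Altschul on global scores: useful for
  thresholding at desk scale, not comparable to BLAST.
* No probabilistic (rate-based) intron gain/loss model; Dollo and Fitch
  only.
* Group assignment inherits the node-support rerooting caveat above.
* EST mapping is ungapped and sense-strand; reads spanning indels or
  antisense reads will not map.
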