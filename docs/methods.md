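# Methods

## The detection problem

Given gene models and sequences for two closely related genomes (the
ingroups) and several outgroup genomes, the pipeline identifies introns
present in one ingroup but absent from the other, decides by outgroup
parsimony whether each such *unique position* is a loss or a gain, and then
tests the reverse-transcriptase (RT) model of intron loss: losses should
concentrate in genes with many processed pseudogenes (PPs), cluster in
adjacent runs, sit near the 3' end of the mRNA, and occur in
germline-expressed, cytosolically translated genes.

## Orthology

One-to-one orthologs are reciprocal best hits under global protein
alignment (BLOSUM62, gap open −11, extend −1).  A shared-k-mer prefilter
(k = 6, ≥ 4 shared k-mers) limits the exhaustive search to plausible
homologs; a raw-score floor — the score of a perfect 40-residue
self-alignment at the mean matrix diagonal — replaces the database-size
dependent E-value cutoff of heuristic search tools.  Pairs need protein
identity > 0.35 (matches over non-gap columns; the package-wide identity
convention).  Equal-score ties are resolved by genomic context: the tied
candidate whose neighbours (±2 genes) pair with the query's neighbours
wins; unresolved ties are dropped.

Synteny blocks are maximal runs (≥ 2 pairs) of paired genes collinear in
both genomes, chained greedily in one orientation of the partner
chromosome (forward or reversed, whichever covers more genes), allowing
one intervening gene by default.  Orientation is fixed per chromosome
pair; a transposed adjacent pair therefore does not form a spurious
two-gene "inversion" block.

## Intron mapping

Each ortholog pair gets a protein-anchored codon alignment: the protein
alignment is back-threaded onto the CDS (residues → codons, gaps → 3-nt
gaps), so ungapping a CDS row reproduces the input and reading frame is
preserved through every gap.  An intron position is its insertion point in
spliced-CDS coordinates projected to an alignment column; two introns mark
the same position iff they land in the same nucleotide column, which
automatically enforces equal phase.  Positions present in both genes are
shared; in one, unique.

Reliability: a position is kept only if the aligned exon identity within
45 columns on each side exceeds the cutoff on both sides (gap columns are
excluded from identity; at least 20 comparable nt per side are required,
so near-terminal sites with shorter flanks are unreliable).  The cutoff
defaults to the first quintile (20th percentile, nearest rank) of all
ortholog mRNA identities — a data-driven notion of "the most diverged
fifth is not trustworthy" — and may be overridden with a fixed value.

## Loss calling and filters

For each unique position the intron-retaining gene is aligned to its best
hit in every outgroup; the outgroup state is *present* (an intron projects
to the same column), *absent* (reliable flanks, no intron) or
*unalignable* (flank filter fails, or no hit).  Majority vote over
alignable outgroups: more present than absent ⇒ loss in the lacking
genome; more absent ⇒ gain candidate (computed, exported, excluded from
loss statistics); ties and all-unalignable ⇒ ambiguous, excluded.

Retrogene screens: an intronless candidate gene must sit in a synteny
block with at least one neighbouring pair or it is discarded as a possible
retrogene; a discarded candidate may be replaced by an intron-containing
paralog that lies in a block and matches the ortholog with higher global
identity (identity, not score, decides the rescue — score is
length-dependent and a truncated paralog would never win it).  A gene
losing more than half its introns faces the same synteny requirement.

A called loss is *precise* if the codon alignment has no gap column within
15 nt of the lost position on either side, else *imprecise*.  Within a
gene, losses at consecutive ordinals of the retaining ortholog are
*adjacent* (a run of n losses = one cluster, n − 1 adjacent pairs), others
*solitary*.

## The adjacency null

Under independent loss of each intron, losing k of n introns produces c
maximal runs with probability P(c) = C(k−1, c−1)·C(n−k+1, c)/C(n, k)
(support c = 1 … min(k, n−k+1); verified against exhaustive subset
enumeration for all n ≤ 12).  Per-gene pmfs over cluster counts c and
adjacent-pair counts a = k − c are convolved across genes; the report
gives P(total pairs ≥ observed) and P(total clusters ≤ observed).  Both
tails are computed because either can be read as "the" adjacency
statistic.

## Statistical conventions

* Fisher's exact two-sided p defaults to tail doubling
  (min(1, 2·min(lower, upper)) of the hypergeometric tails); the
  minimum-likelihood convention is available as an option.  The choice is
  visible: the two conventions differ by up to a factor of two on skewed
  tables.
* The 2×2 chi-square uses Yates' continuity correction by default (the
  focal groups are small).
* Mann-Whitney U is exact (full enumeration) when min(n, m) ≤ 8 and the
  data are tie-free, otherwise the normal approximation with tie
  correction.
* Spearman uses midranks; p by the t approximation.
* No multiple-testing correction is applied; every table is emitted with
  raw counts so any correction can be applied downstream.
* Micro-homology: a direct repeat is an identical substring of ≥ 6 nt
  occurring within 15 nt of the 5' splice site and within 15 nt of the 3'
  splice site (both parameters configurable and echoed in the report).
* Housekeeping = expression > 200 (strict) in every surveyed tissue after
  dropping reproductive organs (default: testis, ovary), which are
  germline/soma mixtures.
* Positional bias uses two measures, both reported: relative position
  (distance to the mRNA 5' end / mRNA length) and absolute distance to
  the 3' end.  "3' side" means relative position > 0.5; "3'-most" is the
  gene's last intron.

## The synthetic cohort generator

The generator emulates the study design, not any particular genome.  An
ancestral gene set (truncated-Poisson intron counts, mean 6, min 1; exon
lengths min 45 nt, mean 450 nt, so mean mRNA ≈ 3 kb exceeds the mean cDNA
length — the geometry that makes 3'-truncation informative; random
stop-free codons; GT…AG introns) descends to each species by uniform
per-site substitutions (stop codons reverted), with no indels outside
engineered imprecise losses, so codon alignments are exact and tests
isolate the detection logic.  Root-to-tip divergence: 0.05 per ingroup,
0.06 + 0.015·(rank − 1) for outgroups on a ladder.

Latent per-gene factors: RT accessibility r (lognormal, zero for
membrane/secreted genes, which carry a signal peptide or TM annotation),
expression e (lognormal; ×3 for housekeeping genes, ×0.01 for the
fast-evolving class — the well-known expression/rate anticorrelation),
plus a lineage-specific expression factor per ingroup (expression itself
evolves, so RT activity concentrates on partly different genes in the two
genomes).  A fast-evolving class (35% of genes, rate ×3, never
housekeeping) gives the pair-identity distribution the broad lower tail
that makes a first-quintile reliability cutoff meaningful — without rate
heterogeneity the quintile would sit at the bulk median and the flank
filter would be noise.

Planted events per ingroup genome: 11 RT events (gene ∝ r·e; cDNA length
exponential with mean 1,900 nt measured from the 3' end, re-drawn until it
covers at least one intron; all wholly covered introns spliced out
precisely — one event, several adjacent losses) and 3 genomic deletions
(uniform intron; with probability 0.5 imprecise, trimming 3/6/9 exonic nt
at one boundary — frame-preserving, because a frameshifting deletion would
be removed by the annotation sanity filter and could never be observed).
PP counts are Poisson with rate 0.5·r·e/mean(r·e) per ingroup; expression
matrices put housekeeping genes above the 200 cutoff in all 12 tissues and
other genes in a random subset.  Decoys: 2% of genes are replaced in one
ingroup by an intronless retrocopy at a non-syntenic locus (half
additionally leave a truncated, slower-evolving intron-containing paralog
at the original slot, which out-scores on identity but not on alignment
score — exercising the rescue path).  Gene order is shared apart from
small segment shuffles (rate 0.005 per gene).

What the generator does **not** model: indel evolution, codon/composition
bias, alternative splicing, UTRs, real LINE sequences, rate variation
within genes.  Passing tests therefore demonstrate the correctness of the
detection and statistics logic under the stated generative assumptions,
not performance on real annotation noise or alignment-difficult loci.

### Evaluation metrics

Calls are matched to the truth by (species, ancestral gene, ancestral
ordinal), converting called ordinals through the retaining gene's
remaining-intron list.  Two sensitivities are reported: over all planted
losses, and over *detectable* ones — those whose intron is retained in the
partner ingroup.  A loss planted at the same ancestral intron in both
ingroups leaves no unique position and is invisible to any outgroup
comparison (real surveys count losses only at unique positions); at the
package's cohort scale such coincidences are 5–7% of planted sites,
whereas at genome scale they are negligible.  The false-call rate is
spurious calls over all calls.

## Problem sizes and determinism

Default validation runs use 300-gene cohorts with two ingroups and five
outgroups, 20 seeds for the recovery suites and smaller zero-loss cohorts
for specificity; a cohort simulates in ~2 s and analyses in ~20 s on one
core.  All randomness flows from the single seed in the simulation config
(the analysis stages are deterministic); rerunning with the same seed
reproduces every output byte-for-byte, which the manifest digests record.

## Known limitations

* The aligner stand-in is exhaustive pairwise alignment; on real proteomes
  a proper search tool with E-value statistics would be substituted behind
  the same interface.
* Outgroup states come from pairwise ingroup-outgroup projection, not a
  joint multiple alignment; deeply diverged outgroups go unalignable at
  the flank filter rather than contributing noisy votes.
* The intronless-candidate filter requires synteny evidence and therefore
  discards true whole-gene losses at rearranged loci (the conservative
  choice made in the original analysis as well).
* Gains are polarized and exported but not further analysed.
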