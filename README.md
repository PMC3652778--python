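# ilrt — intron-loss detection and tests of the reverse-transcriptase model

Spliceosomal introns are occasionally lost from genes during evolution.
The leading mechanistic explanation, the **reverse-transcriptase (RT)
model**, holds that a cDNA reverse-transcribed from spliced mRNA recombines
with the genomic locus, deleting one or more introns precisely — the same
LINE-encoded machinery that creates **processed pseudogenes (PPs)**.  The
model makes testable predictions: genes that spawn more PPs should lose
introns more often; adjacent introns should be lost simultaneously;
3'-truncated cDNAs should bias losses towards the 3' end of the mRNA;
losing genes should be germline-expressed (housekeeping) and translated on
free cytoplasmic ribosomes (no signal peptide or transmembrane domain).

`ilrt` is a complete, tested implementation of that analysis for a pair of
sister genomes ("ingroups") plus outgroup genomes:

1. **Orthology** — reciprocal-best-hit one-to-one orthologs from exhaustive
   pairwise protein alignment (BLOSUM62, affine gaps, shared-k-mer
   prefilter), identity > 0.35, equal-score ties resolved by synteny;
   collinear synteny blocks support the retrogene filters.
2. **Intron mapping** — protein-anchored codon alignments; intron
   positions projected into alignment columns and classified shared /
   unique / unreliable, with a 45-nt exon-flank identity filter whose
   cutoff is the first quintile of all ortholog mRNA identities.
3. **Loss calling** — unique positions polarized by majority outgroup
   parsimony (present in more outgroups than absent ⇒ loss in the lacking
   genome); intronless candidates outside synteny blocks discarded as
   putative retrogenes, with rescue by syntenic intron-containing paralogs
   of higher identity; losses classified precise/imprecise (indels near
   the lost junction) and adjacent/solitary.
4. **Statistics** — Fisher's exact test (tail-doubling two-sided
   convention by default), Pearson chi-square with continuity correction,
   Mann-Whitney U (exact for small tie-free samples), Spearman rank
   correlation; the combinatorial null for simultaneous adjacent intron
   loss

   P(c clusters | k of n introns lost independently)
       = C(k−1, c−1) · C(n−k+1, c) / C(n, k),

   convolved across genes to give tail probabilities for the observed
   adjacent-pair and cluster totals; micro-homology (direct-repeat)
   scanning around splice sites; positional-bias measures; housekeeping
   and soluble-protein enrichment.
5. **Synthetic cohorts** — a truth-tagged generator that plants RT-mediated
   losses (gene choice ∝ RT accessibility × expression; exponential
   3'-truncated cDNA deleting a contiguous 3' run of introns, always
   precisely) and genomic deletions (uniform, optionally imprecise),
   Poisson pseudogene counts driven by the same latent factor, expression
   matrices with housekeeping structure, annotation tables, and
   retrogene/intronless decoys — so every pipeline stage is testable
   without external data.

## Worked example

```bash
ilrt run --seed 5 --out cohort_run
```

simulates a default cohort (300 genes, two ingroups, seven outgroups),
runs the full detection pipeline and prints

```json
{
  "losses_called": 84,
  "sensitivity": 0.9545,
  "sensitivity_detectable": 0.9767,
  "false_call_rate": 0.0
}
```

84 intron losses were called across the two ingroup genomes; 95.5% of all
planted losses were recovered — 97.7% of the losses that are detectable in
principle (a loss planted at the same intron in *both* ingroups leaves no
unique position and is invisible to any outgroup comparison) — with no
spurious calls.  `cohort_run/report.json` contains the per-species
statistics: the parental-PP contingency table with its Fisher p, mean PP
counts per gene, soluble-protein and housekeeping enrichment, mRNA-length
confounder checks, the positional-bias comparisons and the adjacent-loss
null.  `cohort_run/loss_events.tsv` lists every polarized site with its
votes, precision and adjacency class.

The same stages are available individually (`ilrt simulate`, `orthologs`,
`introns`, `losses`, `stats`, `evaluate`) over the on-disk cohort layout,
and as library functions (`ilrt.simulate.simulate_cohort`,
`ilrt.pipeline.analyze_cohort`, `ilrt.stats.*`).

Worked statistical examples on the bundled published tables:

```python
>>> from ilrt.datasets import microhomology_table, multi_loss_gene_summary
>>> from ilrt.stats import fisher_exact_2x2
>>> round(fisher_exact_2x2(microhomology_table("mouse")), 2)
0.32
>>> multi_loss_gene_summary("rat")["has_adjacent"].sum()
8
```

The first number is the two-sided Fisher p for micro-homology occurring at
similar rates around lost and conserved mouse introns (no evidence for the
double-strand-break-repair route); the second is the count of rat
multi-loss genes containing adjacent losses (8 of 10), the raw observation
behind the adjacent-loss test.

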