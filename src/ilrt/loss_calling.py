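"""Outgroup-parsimony polarization of unique intron positions into losses.

A unique intron position between the two ingroups is a loss in the lacking
genome if the intron is present in more outgroup genomes than it is absent
from (majority parsimony; ties and all-unalignable sites are ambiguous and
excluded, as are gain candidates).  Intronless candidate genes must sit in
a synteny block with at least one neighbour or they are discarded as
possible retrogenes, with an optional rescue by a syntenic intron-containing
paralog that matches the ortholog better; genes losing more than half their
introns face the same synteny requirement.  Surviving losses are classified
precise/imprecise (indels near the lost junction) and adjacent/solitary
(consecutive ordinals in the retaining ortholog).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .align import KmerIndex, protein_score
from .config import Thresholds
from .intron_mapping import (
    align_pair,
    classify_pair_sites,
    identity_quintile,
    is_nil_pair,
    reliability_filter,
)
from .models import (
    CodonAlignment,
    GeneModel,
    IntronSite,
    LossEvent,
    MappedSite,
    OrthologPair,
    SiteClass,
    SyntenyBlock,
)
from .orthology import rbh_orthologs, synteny_blocks

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OutgroupState:
    """Presence state of one unique intron position in one outgroup."""

    species: str
    state: str  # present | absent | unalignable


def polarize(states: list[OutgroupState]) -> tuple[str, int, int]:
    """Majority vote over alignable outgroups.

    Returns ``(call, present, absent)`` where call is ``loss`` (the species
    lacking the intron lost it), ``gain`` (the species carrying it gained
    it) or ``ambiguous`` (tie, or no alignable outgroup).
    """
    present = sum(s.state == "present" for s in states)
    absent = sum(s.state == "absent" for s in states)
    if present > absent:
        return "loss", present, absent
    if absent > present:
        return "gain", present, absent
    return "ambiguous", present, absent


def intronless_filter(gene_id: str, blocks: list[SyntenyBlock]) -> bool:
    """Keep an intronless candidate only if it has a conserved neighbourhood.

    True iff the gene sits in a synteny block (length >= 2, so with at least
    one neighbouring ortholog pair); otherwise it may be a retrogene.
    """
    return any(gene_id in blk.genes_a or gene_id in blk.genes_b for blk in blocks)


def paralog_replacement(
    ortholog: GeneModel,
    candidate_identity: float,
    species_genes: dict[str, GeneModel],
    kmer_index: KmerIndex,
    blocks: list[SyntenyBlock],
    exclude: set[str],
) -> str | None:
    """Rescue a discarded retrogene-like candidate with a syntenic paralog.

    Scans the candidate's species for intron-containing genes in synteny
    blocks whose global alignment identity to the ortholog exceeds the
    discarded candidate's; returns the best such gene id, or None.
    """
    from .align import align_proteins

    in_block = {g for blk in blocks for pair in blk.pairs for g in pair}
    best_id, best_identity = None, candidate_identity
    for gid in kmer_index.candidates(ortholog.protein):
        if gid in exclude or gid not in in_block:
            continue
        g = species_genes[gid]
        if g.n_introns == 0:
            continue
        _, _, identity = align_proteins(ortholog.protein, g.protein)
        if identity > best_identity:
            best_id, best_identity = gid, identity
    return best_id


def precision_classify(alignment: CodonAlignment, column: int,
                       window_nt: int = 15) -> str:
    """Precise iff no indel lies within ``window_nt`` nt of the lost position."""
    return "imprecise" if alignment.has_gap_near(column, window_nt) else "precise"


def adjacency_classify(lost_ordinals: list[int]) -> tuple[dict[int, str], int, int]:
    """Label losses adjacent/solitary; count maximal clusters and pairs.

    A run of n adjacent lost introns is one cluster contributing n - 1
    adjacent pairs.  Returns ``(labels, n_clusters, n_pairs)``.
    """
    ords = sorted(set(lost_ordinals))
    labels: dict[int, str] = {}
    clusters = 0
    i = 0
    while i < len(ords):
        j = i
        while j + 1 < len(ords) and ords[j + 1] == ords[j] + 1:
            j += 1
        run = ords[i : j + 1]
        clusters += 1
        for o in run:
            labels[o] = "adjacent" if len(run) > 1 else "solitary"
        i = j + 1
    pairs = len(ords) - clusters
    return labels, clusters, pairs


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class LossCallResult:
    """Everything the statistics stage consumes."""

    pairs: list[OrthologPair]
    losses: list[LossEvent]
    gains: list[LossEvent]
    ambiguous: list[LossEvent]
    nil_pairs: list[tuple[str, str]]
    conserved_sites: list[tuple[str, str, MappedSite]]  # (gene_a, gene_b, site)
    gene_nk: dict[tuple[str, str], tuple[int, int]]  # (species, retaining gene) -> (n, k)
    min_identity: float
    dropped_candidates: list[str] = field(default_factory=list)
    replacements: dict[str, str] = field(default_factory=dict)  # candidate -> paralog

    @property
    def il_genes(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for ev in self.losses:
            out.setdefault(ev.species, set()).add(ev.gene_id)
        return out


class _OutgroupProjector:
    """Cached best-hit search and codon alignment against each outgroup."""

    def __init__(self, outgroup_genes: dict[str, dict[str, GeneModel]],
                 thresholds: Thresholds, min_identity: float):
        self.outgroups = outgroup_genes
        self.th = thresholds
        self.min_identity = min_identity
        self.indexes = {
            sp: KmerIndex({g.gene_id: g.protein for g in genes.values()})
            for sp, genes in outgroup_genes.items()
        }
        self._aln_cache: dict[tuple[str, str], tuple[CodonAlignment, GeneModel] | None] = {}

    def _alignment(self, gene: GeneModel, sp: str):
        key = (gene.gene_id, sp)
        if key not in self._aln_cache:
            idx = self.indexes[sp]
            best, best_score = None, None
            for gid in idx.candidates(gene.protein):
                s = protein_score(gene.protein, idx.proteome[gid])
                if best_score is None or s > best_score:
                    best, best_score = gid, s
            if best is None:
                self._aln_cache[key] = None
            else:
                og = self.outgroups[sp][best]
                self._aln_cache[key] = (align_pair(gene, og), og)
        return self._aln_cache[key]

    def state(self, gene: GeneModel, site: IntronSite, sp: str) -> OutgroupState:
        hit = self._alignment(gene, sp)
        if hit is None:
            return OutgroupState(sp, "unalignable")
        aln, og = hit
        col = aln.boundary_column("A", site.cds_offset)
        ok, _, _ = reliability_filter(aln, col, self.min_identity,
                                      self.th.flank_nt, self.th.min_flank_nt)
        if not ok:
            return OutgroupState(sp, "unalignable")
        og_cols = {aln.boundary_column("B", s.cds_offset) for s in og.introns}
        return OutgroupState(sp, "present" if col in og_cols else "absent")


def call_losses(
    genes_a: dict[str, GeneModel],
    genes_b: dict[str, GeneModel],
    order_a: dict[str, list[str]],
    order_b: dict[str, list[str]],
    outgroup_genes: dict[str, dict[str, GeneModel]],
    species_a: str,
    species_b: str,
    thresholds: Thresholds | None = None,
    pairs: list[OrthologPair] | None = None,
) -> LossCallResult:
    """Run orthology, intron mapping, polarization and all filters."""
    th = thresholds or Thresholds()
    prot_a = {gid: g.protein for gid, g in genes_a.items()}
    prot_b = {gid: g.protein for gid, g in genes_b.items()}
    if pairs is None:
        pairs = rbh_orthologs(prot_a, prot_b, min_identity=th.rbh_min_identity,
                              order_a=order_a, order_b=order_b)

    # mRNA identities for the quintile threshold
    alignments: dict[tuple[str, str], CodonAlignment] = {}
    for p in pairs:
        alignments[(p.gene_a, p.gene_b)] = align_pair(genes_a[p.gene_a], genes_b[p.gene_b])
    min_identity = th.min_identity
    if min_identity is None:
        min_identity = identity_quintile([a.mrna_identity for a in alignments.values()])

    pairing = {p.gene_a: p.gene_b for p in pairs}
    blocks = synteny_blocks(order_a, order_b, pairing, max_gap=th.synteny_max_gap)

    b_index = KmerIndex(prot_b)
    a_index = KmerIndex(prot_a)
    projector = _OutgroupProjector(outgroup_genes, th, min_identity)

    result = LossCallResult(pairs=[], losses=[], gains=[], ambiguous=[],
                            nil_pairs=[], conserved_sites=[], gene_nk={},
                            min_identity=min_identity)
    paired_b = set(pairing.values())

    for pair in pairs:
        ga, gb = genes_a[pair.gene_a], genes_b[pair.gene_b]
        if ga.n_introns == 0 and gb.n_introns == 0:
            continue  # no intron positions to study
        aln = alignments[(pair.gene_a, pair.gene_b)]

        # retrogene screen for intronless candidates, with paralog rescue
        replaced = False
        for gene, other, species_side in ((gb, ga, "B"), (ga, gb, "A")):
            if gene.n_introns > 0:
                continue
            if intronless_filter(gene.gene_id, blocks):
                continue
            result.dropped_candidates.append(gene.gene_id)
            if species_side == "B":
                repl = paralog_replacement(ga, pair.identity, genes_b, b_index,
                                           blocks, exclude=paired_b)
                if repl:
                    result.replacements[gene.gene_id] = repl
                    gb = genes_b[repl]
                    pair = OrthologPair(gene_a=pair.gene_a, gene_b=repl,
                                        identity=pair.identity, score=pair.score)
                    aln = align_pair(ga, gb)
                    replaced = True
                else:
                    pair = None
            else:
                repl = paralog_replacement(gb, pair.identity, genes_a, a_index,
                                           blocks, exclude=set(pairing))
                if repl:
                    result.replacements[gene.gene_id] = repl
                    ga = genes_a[repl]
                    pair = OrthologPair(gene_a=repl, gene_b=pair.gene_b,
                                        identity=pair.identity, score=pair.score)
                    aln = align_pair(ga, gb)
                    replaced = True
                else:
                    pair = None
            break
        if pair is None:
            continue

        _, sites = classify_pair_sites(ga, gb, min_identity, th, alignment=aln)
        unique_sites = [s for s in sites if s.cls in (SiteClass.UNIQUE_A, SiteClass.UNIQUE_B)]

        # a gene losing more than half its introns must be syntenic
        for lacking_gene, retaining in ((gb, ga), (ga, gb)):
            lost_here = sum(
                1 for s in unique_sites
                if (s.site_a is None) == (lacking_gene is ga)
            )
            if retaining.n_introns and lost_here > retaining.n_introns / 2:
                if not intronless_filter(lacking_gene.gene_id, blocks):
                    pair = None
                    break
        if pair is None:
            result.dropped_candidates.append((ga if ga.n_introns < gb.n_introns else gb).gene_id)
            continue

        result.pairs.append(pair)
        if is_nil_pair(sites):
            result.nil_pairs.append((pair.gene_a, pair.gene_b))
        for s in sites:
            if s.cls is SiteClass.SHARED:
                result.conserved_sites.append((pair.gene_a, pair.gene_b, s))

        per_gene_losses: dict[tuple[str, str], list[LossEvent]] = {}
        for s in unique_sites:
            if s.cls is SiteClass.UNIQUE_A:
                retaining, site = ga, s.site_a
                ret_sp, lack_sp, lacking = species_a, species_b, gb
            else:
                retaining, site = gb, s.site_b
                ret_sp, lack_sp, lacking = species_b, species_a, ga
            states = [projector.state(retaining, site, sp) for sp in outgroup_genes]
            call, n_pres, n_abs = polarize(states)
            ev = LossEvent(
                species=lack_sp if call == "loss" else ret_sp,
                gene_id=(lacking if call == "loss" else retaining).gene_id,
                retaining_species=ret_sp, retaining_gene=retaining.gene_id,
                site=site, call=call, votes_present=n_pres, votes_absent=n_abs,
            )
            if call == "loss":
                ev.precision = precision_classify(aln, s.column, th.precision_window_nt)
                per_gene_losses.setdefault((lack_sp, retaining.gene_id), []).append(ev)
                result.losses.append(ev)
            elif call == "gain":
                result.gains.append(ev)
            else:
                result.ambiguous.append(ev)

        for (lack_sp, ret_gene), events in per_gene_losses.items():
            labels, _, _ = adjacency_classify([e.ordinal for e in events])
            for e in events:
                e.adjacency = labels[e.ordinal]
            retaining = ga if ret_gene == pair.gene_a else gb
            result.gene_nk[(lack_sp, ret_gene)] = (retaining.n_introns, len(events))

    return result
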