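"""Projection of intron positions through protein-anchored codon alignments.

Intron positions are compared in spliced-CDS coordinates projected into
alignment columns: two introns mark the same position iff their insertion
points fall in the same nucleotide column (which, because protein gaps
expand to 3-nt gaps, also forces equal phase).  Each distinct position is
classified shared / unique-to-A / unique-to-B, then positions whose 45-nt
exon flanks do not align above the identity threshold are demoted to
unreliable and excluded from loss calling.
"""

from __future__ import annotations

import math

from .align import codon_align
from .config import Thresholds
from .models import CodonAlignment, GeneModel, IntronSite, MappedSite, SiteClass


def align_pair(gene_a: GeneModel, gene_b: GeneModel) -> CodonAlignment:
    """Protein-anchored codon alignment of an ortholog pair."""
    return codon_align(gene_a.protein, gene_b.protein, gene_a.cds, gene_b.cds)


def identity_quintile(identities: list[float]) -> float:
    """First quintile (20th percentile, nearest rank) of pair identities.

    This is the data-driven reliability cutoff: the bulk of genuine
    ortholog alignments sit well above it, while the most diverged fifth
    defines what "unreliable" means for flank alignments.
    """
    if not identities:
        raise ValueError("no identities supplied")
    ranked = sorted(identities)
    k = math.ceil(0.2 * len(ranked))
    return ranked[max(0, k - 1)]


def reliability_filter(
    alignment: CodonAlignment,
    column: int,
    min_identity: float,
    flank_nt: int = 45,
    min_flank_nt: int = 20,
) -> tuple[bool, float, float]:
    """Check the exon flanks around an intron position.

    Passes iff the aligned exon identity within ``flank_nt`` columns on each
    side exceeds ``min_identity`` (gap columns excluded from the identity,
    as everywhere else in the package).  Terminal sites with fewer than
    ``min_flank_nt`` comparable nucleotides on a side fail.
    """
    id5, n5 = alignment.window_identity(column, "5", flank_nt)
    id3, n3 = alignment.window_identity(column, "3", flank_nt)
    ok = n5 >= min_flank_nt and n3 >= min_flank_nt and id5 > min_identity and id3 > min_identity
    return ok, id5, id3


def map_intron_sites(
    alignment: CodonAlignment,
    introns_a: list[IntronSite],
    introns_b: list[IntronSite],
) -> list[MappedSite]:
    """Project both intron lists into alignment columns and pair them up."""
    cols_a = {alignment.boundary_column("A", s.cds_offset): s for s in introns_a}
    cols_b = {alignment.boundary_column("B", s.cds_offset): s for s in introns_b}
    sites = []
    for col in sorted(set(cols_a) | set(cols_b)):
        sa, sb = cols_a.get(col), cols_b.get(col)
        cls = SiteClass.SHARED if sa and sb else (
            SiteClass.UNIQUE_A if sa else SiteClass.UNIQUE_B)
        sites.append(MappedSite(column=col, site_a=sa, site_b=sb, cls=cls))
    return sites


def classify_pair_sites(
    gene_a: GeneModel,
    gene_b: GeneModel,
    min_identity: float,
    thresholds: Thresholds | None = None,
    alignment: CodonAlignment | None = None,
) -> tuple[CodonAlignment, list[MappedSite]]:
    """Full per-pair site classification: shared / unique / unreliable."""
    th = thresholds or Thresholds()
    aln = alignment or align_pair(gene_a, gene_b)
    sites = map_intron_sites(aln, gene_a.introns, gene_b.introns)
    for site in sites:
        ok, id5, id3 = reliability_filter(
            aln, site.column, min_identity, th.flank_nt, th.min_flank_nt)
        site.flank5_identity, site.flank3_identity = id5, id3
        if not ok:
            site.cls = SiteClass.UNRELIABLE
    return aln, sites


def is_nil_pair(sites: list[MappedSite]) -> bool:
    """A pair with introns, all of them shared and reliable: definitely no
    intron was lost or gained between the two genes."""
    return bool(sites) and all(s.cls is SiteClass.SHARED for s in sites)
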