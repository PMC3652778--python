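"""Core domain objects: gene models, intron sites, alignments, loss events.

Coordinate conventions
----------------------
All in-memory coordinates are 0-based half-open and strand-normalized to
transcript orientation (5'→3' of the mRNA).  Reported intron positions are
1-based nt offsets within the unspliced gene.  GFF3 on disk is 1-based
inclusive in genomic orientation; the conversion lives in :mod:`ilrt.io`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from Bio.Seq import Seq

FLANK_NT = 45


class SiteClass(enum.Enum):
    """Classification of one mapped intron position in an ortholog pair."""

    SHARED = "shared"
    UNIQUE_A = "uniqueA"
    UNIQUE_B = "uniqueB"
    UNRELIABLE = "unreliable"


@dataclass(frozen=True)
class IntronSite:
    """One intron's identity within its host gene.

    ``position_nt`` is the 1-based offset of the last exonic nucleotide
    before the intron in the unspliced gene; ``cds_offset`` is the number of
    spliced CDS nucleotides 5' of the intron (0 < cds_offset < CDS length);
    ``phase`` is ``cds_offset % 3``.  ``flank5``/``flank3`` hold up to 45 nt
    of exon sequence on each side of the splice junction.
    """

    gene_id: str
    ordinal: int
    position_nt: int
    cds_offset: int
    phase: int
    flank5: str
    flank3: str
    donor: str
    acceptor: str
    length: int

    def __post_init__(self) -> None:
        if self.phase != self.cds_offset % 3:
            raise ValueError(
                f"phase {self.phase} inconsistent with cds_offset {self.cds_offset}"
            )


@dataclass
class GeneModel:
    """One gene's exon-intron structure with sequences.

    ``seq`` is the unspliced gene in transcript orientation; ``exons`` are
    0-based half-open spans within ``seq``, ordered 5'→3'.  ``cds`` is the
    spliced coding sequence (these genes carry no UTR) and ``protein`` its
    translation.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int  # genomic start of the gene span (0-based)
    seq: str
    exons: list[tuple[int, int]]
    cds: str = ""
    protein: str = ""

    def __post_init__(self) -> None:
        if not self.cds:
            self.cds = "".join(self.seq[a:b] for a, b in self.exons)
        if not self.protein:
            self.protein = str(Seq(self.cds).translate())

    # -- structure ---------------------------------------------------------

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def mrna_length(self) -> int:
        """Spliced mRNA length in nt (equals CDS length here)."""
        return len(self.cds)

    def intron_span(self, i: int) -> tuple[int, int]:
        """0-based half-open span of intron ``i`` (0-based index) in ``seq``."""
        return self.exons[i][1], self.exons[i + 1][0]

    def intron_seq(self, i: int) -> str:
        a, b = self.intron_span(i)
        return self.seq[a:b]

    @property
    def introns(self) -> list[IntronSite]:
        sites = []
        cds_off = 0
        for i in range(self.n_introns):
            a, b = self.exons[i]
            cds_off += b - a
            iv0, iv1 = self.intron_span(i)
            intron = self.seq[iv0:iv1]
            sites.append(
                IntronSite(
                    gene_id=self.gene_id,
                    ordinal=i + 1,
                    position_nt=iv0,  # 1-based offset of last exonic nt == 0-based intron start
                    cds_offset=cds_off,
                    phase=cds_off % 3,
                    flank5=self.cds[max(0, cds_off - FLANK_NT) : cds_off],
                    flank3=self.cds[cds_off : cds_off + FLANK_NT],
                    donor=intron[:2],
                    acceptor=intron[-2:],
                    length=iv1 - iv0,
                )
            )
        return sites

    # -- validation --------------------------------------------------------

    def is_valid(self) -> bool:
        """Annotation sanity: frame, translation consistency, exon order."""
        if len(self.cds) % 3 != 0 or not self.cds:
            return False
        if str(Seq(self.cds).translate()) != self.protein:
            return False
        prev_end = 0
        for a, b in self.exons:
            if a < prev_end or b <= a or b > len(self.seq):
                return False
            prev_end = b
        if "".join(self.seq[a:b] for a, b in self.exons) != self.cds:
            return False
        return True


@dataclass(frozen=True)
class OrthologPair:
    """A one-to-one ortholog pair between the two ingroup gene sets."""

    gene_a: str
    gene_b: str
    identity: float  # protein identity, gap columns excluded
    score: float
    in_synteny: bool = False
    tie_resolved_by_synteny: bool = False


@dataclass(frozen=True)
class SyntenyBlock:
    """A maximal collinear run (length >= 2) of paired genes."""

    chrom_a: str
    chrom_b: str
    pairs: tuple[tuple[str, str], ...]
    orientation: int = 1  # +1 forward, -1 chromosome-reversed in B

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def genes_a(self) -> frozenset[str]:
        return frozenset(a for a, _ in self.pairs)

    @property
    def genes_b(self) -> frozenset[str]:
        return frozenset(b for _, b in self.pairs)


@dataclass
class CodonAlignment:
    """Protein-anchored codon alignment of an ortholog pair.

    The CDS rows are the protein rows back-threaded to nucleotides: each
    residue expands to its codon and each protein gap to three nt gaps, so
    ungapping a CDS row reproduces the input CDS and the nt alignment length
    is three times the protein alignment length.
    """

    protein_a: str
    protein_b: str
    cds_a: str
    cds_b: str
    identity: float  # protein identity over non-gap columns
    mrna_identity: float  # nt identity over non-gap columns

    def __post_init__(self) -> None:
        if len(self.cds_a) != len(self.cds_b):
            raise ValueError("aligned CDS rows differ in length")
        if len(self.cds_a) != 3 * len(self.protein_a):
            raise ValueError("CDS alignment length must be 3x protein alignment length")

    @property
    def n_columns(self) -> int:
        return len(self.cds_a)

    def boundary_column(self, row: str, cds_offset: int) -> int:
        """Alignment nt column of an intron insertion point.

        ``cds_offset`` counts spliced CDS nt 5' of the intron in sequence
        coordinates of ``row`` ('A' or 'B'); the returned column ``c`` is the
        number of alignment columns strictly 5' of the insertion point, with
        the convention that the boundary sits immediately after the
        ``cds_offset``-th nucleotide of that row.
        """
        aligned = self.cds_a if row == "A" else self.cds_b
        if not 0 < cds_offset < sum(ch != "-" for ch in aligned):
            raise ValueError(f"cds_offset {cds_offset} outside CDS")
        seen = 0
        for c, ch in enumerate(aligned):
            if ch != "-":
                seen += 1
                if seen == cds_offset:
                    return c + 1
        raise AssertionError("unreachable")

    def window_identity(self, col: int, side: str, flank_nt: int = FLANK_NT) -> tuple[float, int]:
        """Nt identity in the exon window on one side of a boundary column.

        Returns ``(identity, n_comparable)`` where identity is matches over
        columns with both rows non-gap within ``flank_nt`` alignment columns
        5' (``side='5'``) or 3' (``side='3'``) of the boundary.
        """
        if side == "5":
            lo, hi = max(0, col - flank_nt), col
        else:
            lo, hi = col, min(self.n_columns, col + flank_nt)
        matches = comparable = 0
        for x, y in zip(self.cds_a[lo:hi], self.cds_b[lo:hi]):
            if x != "-" and y != "-":
                comparable += 1
                if x == y:
                    matches += 1
        return (matches / comparable if comparable else 0.0), comparable

    def has_gap_near(self, col: int, window_nt: int = 15) -> bool:
        """True if any gap column lies within ``window_nt`` nt of ``col``."""
        lo = max(0, col - window_nt)
        hi = min(self.n_columns, col + window_nt)
        return any(
            x == "-" or y == "-" for x, y in zip(self.cds_a[lo:hi], self.cds_b[lo:hi])
        )


@dataclass
class MappedSite:
    """One distinct intron position projected into an ortholog alignment."""

    column: int
    site_a: IntronSite | None
    site_b: IntronSite | None
    cls: SiteClass
    flank5_identity: float = float("nan")
    flank3_identity: float = float("nan")


@dataclass
class LossEvent:
    """A polarized unique intron position.

    ``species`` is the genome lacking the intron; the ``site`` (and hence
    ``ordinal``/``position_nt``) refers to the intron-retaining ortholog in
    ``retaining_species``.  ``precision`` and ``adjacency`` are defined only
    for ``call == 'loss'``.
    """

    species: str
    gene_id: str
    retaining_species: str
    retaining_gene: str
    site: IntronSite
    call: str  # loss | gain | ambiguous
    votes_present: int
    votes_absent: int
    precision: str | None = None  # precise | imprecise
    adjacency: str | None = None  # adjacent | solitary

    def __post_init__(self) -> None:
        if self.call != "loss" and (self.precision or self.adjacency):
            raise ValueError("precision/adjacency defined only for loss calls")

    @property
    def ordinal(self) -> int:
        return self.site.ordinal

    @property
    def position_nt(self) -> int:
        return self.site.position_nt
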