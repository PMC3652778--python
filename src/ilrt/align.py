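"""Pairwise protein alignment and codon back-threading.

Stand-in for BLAST/Clustal at desk scale: exhaustive global alignment with
BLOSUM62 and affine gaps, plus a shared-k-mer prefilter so all-vs-all
searches only score plausible homologs.  E-value thresholds (database-size
dependent) are replaced by a raw-score floor, by default the score of a
perfect 40-residue self-alignment under the average matrix diagonal.
"""

from __future__ import annotations

from collections import defaultdict
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .models import CodonAlignment

GAP_OPEN = -11.0
GAP_EXTEND = -1.0


@lru_cache(maxsize=1)
def _matrix():
    return substitution_matrices.load("BLOSUM62")


@lru_cache(maxsize=1)
def default_min_score() -> float:
    """Score floor standing in for an E-value cutoff.

    The score a perfect 40-residue self-alignment would reach with the mean
    BLOSUM62 diagonal; shorter or weaker hits than that are discarded.
    """
    m = _matrix()
    aas = "ACDEFGHIKLMNPQRSTVWY"
    diag = np.mean([m[a, a] for a in aas])
    return float(40 * diag)


def make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _matrix()
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


_ALIGNER = make_aligner()


def protein_score(a: str, b: str) -> float:
    return _ALIGNER.score(a, b)


def align_proteins(a: str, b: str) -> tuple[str, str, float]:
    """Global protein alignment; returns aligned rows and identity.

    Identity is matches over aligned columns excluding gap columns.  The
    first optimal traceback is taken, which is deterministic for a given
    input.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aln = _ALIGNER.align(a, b)[0]
    ra, rb = str(aln[0]), str(aln[1])
    matches = comparable = 0
    for x, y in zip(ra, rb):
        if x != "-" and y != "-":
            comparable += 1
            if x == y:
                matches += 1
    return ra, rb, (matches / comparable if comparable else 0.0)


def thread_codons(aligned_protein: str, cds: str) -> str:
    """Expand an aligned protein row to its aligned CDS row."""
    out = []
    pos = 0
    for ch in aligned_protein:
        if ch == "-":
            out.append("---")
        else:
            out.append(cds[pos : pos + 3])
            pos += 3
    if pos != len(cds):
        raise ValueError("CDS length does not match protein row")
    return "".join(out)


def codon_align(protein_a: str, protein_b: str, cds_a: str, cds_b: str) -> CodonAlignment:
    """Protein-anchored codon alignment of two coding genes."""
    ra, rb, identity = align_proteins(protein_a, protein_b)
    ca = thread_codons(ra, cds_a)
    cb = thread_codons(rb, cds_b)
    matches = comparable = 0
    for x, y in zip(ca, cb):
        if x != "-" and y != "-":
            comparable += 1
            if x == y:
                matches += 1
    return CodonAlignment(
        protein_a=ra,
        protein_b=rb,
        cds_a=ca,
        cds_b=cb,
        identity=identity,
        mrna_identity=matches / comparable if comparable else 0.0,
    )


class KmerIndex:
    """Shared-k-mer prefilter over a proteome.

    Candidate hits for a query are subjects sharing at least ``min_shared``
    k-mers; unrelated random proteins essentially never pass, so the
    exhaustive aligner only scores plausible homologs.
    """

    def __init__(self, proteome: dict[str, str], k: int = 6):
        self.k = k
        self.proteome = proteome
        self._index: dict[str, set[str]] = defaultdict(set)
        for gid, seq in proteome.items():
            for kmer in self._kmers(seq):
                self._index[kmer].add(gid)

    def _kmers(self, seq: str) -> set[str]:
        return {seq[i : i + self.k] for i in range(len(seq) - self.k + 1)}

    def candidates(self, query: str, min_shared: int = 4) -> list[str]:
        counts: dict[str, int] = defaultdict(int)
        for kmer in self._kmers(query):
            for gid in self._index.get(kmer, ()):
                counts[gid] += 1
        return sorted(gid for gid, n in counts.items() if n >= min_shared)
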