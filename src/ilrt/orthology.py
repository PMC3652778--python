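"""One-to-one orthology between the two ingroups.

Reciprocal best hit over exhaustively scored protein alignments (shared
k-mer prefilter, BLOSUM62 affine-gap global alignment, raw-score floor in
place of an E-value cutoff, identity > 0.35), with synteny used to resolve
equal-score ties and to build collinear blocks for the downstream retrogene
filters.
"""

from __future__ import annotations

import logging
from collections import defaultdict

from .align import KmerIndex, align_proteins, default_min_score, protein_score
from .models import GeneModel, OrthologPair, SyntenyBlock

logger = logging.getLogger(__name__)


def sanity_filter(genes: list[GeneModel]) -> dict[str, GeneModel]:
    """Drop genes with annotation errors; keep the longest mRNA per gene.

    A gene is kept only if its CDS length is a multiple of three, the CDS
    translates exactly to the stored protein and the exon structure is
    consistent.  Where several isoforms share a gene id the longest spliced
    mRNA survives.
    """
    by_gene: dict[str, list[GeneModel]] = defaultdict(list)
    for g in genes:
        if g.is_valid():
            by_gene[g.gene_id].append(g)
    return {
        gid: max(isoforms, key=lambda g: g.mrna_length)
        for gid, isoforms in by_gene.items()
    }


def _best_hits(
    queries: dict[str, str],
    index: KmerIndex,
    min_score: float,
) -> dict[str, tuple[float, list[str]]]:
    """For each query: best raw score and all subjects attaining it."""
    hits: dict[str, tuple[float, list[str]]] = {}
    for qid, qseq in queries.items():
        best, best_ids = None, []
        for sid in index.candidates(qseq):
            s = protein_score(qseq, index.proteome[sid])
            if s < min_score:
                continue
            if best is None or s > best:
                best, best_ids = s, [sid]
            elif s == best:
                best_ids.append(sid)
        if best is not None:
            hits[qid] = (best, best_ids)
    return hits


def _neighbors(order: dict[str, list[str]], window: int = 2) -> dict[str, set[str]]:
    nb: dict[str, set[str]] = {}
    for ids in order.values():
        for i, gid in enumerate(ids):
            nb[gid] = set(ids[max(0, i - window) : i] + ids[i + 1 : i + 1 + window])
    return nb


def rbh_orthologs(
    proteome_a: dict[str, str],
    proteome_b: dict[str, str],
    min_identity: float = 0.35,
    min_score: float | None = None,
    order_a: dict[str, list[str]] | None = None,
    order_b: dict[str, list[str]] | None = None,
) -> list[OrthologPair]:
    """Reciprocal-best-hit one-to-one ortholog pairs.

    Equal-score ties are resolved by genomic context when gene orders are
    supplied (the tied candidate whose neighbours pair with the query's
    neighbours wins); ties that synteny cannot resolve are dropped.  The
    result is symmetric in A and B and strictly one-to-one.
    """
    if not proteome_a or not proteome_b:
        return []
    if min_score is None:
        min_score = default_min_score()
    idx_a = KmerIndex(proteome_a)
    idx_b = KmerIndex(proteome_b)
    hits_ab = _best_hits(proteome_a, idx_b, min_score)
    hits_ba = _best_hits(proteome_b, idx_a, min_score)

    # unambiguous reciprocal pairs first; they anchor tie resolution
    unambiguous: dict[str, str] = {}
    for a, (_, bs) in hits_ab.items():
        if len(bs) == 1:
            b = bs[0]
            back = hits_ba.get(b)
            if back and len(back[1]) == 1 and back[1][0] == a:
                unambiguous[a] = b

    nb_a = _neighbors(order_a) if order_a else {}
    nb_b = _neighbors(order_b) if order_b else {}

    def resolve(a: str, candidates: list[str]) -> tuple[str | None, bool]:
        if len(candidates) == 1:
            return candidates[0], False
        if not (order_a and order_b):
            return None, False
        partners = {unambiguous[x] for x in nb_a.get(a, ()) if x in unambiguous}
        matches = [b for b in candidates if partners & nb_b.get(b, set())]
        if len(matches) == 1:
            return matches[0], True
        return None, False  # unresolved tie: conservative drop

    pairs: list[OrthologPair] = []
    taken_b: set[str] = set()
    for a in sorted(hits_ab):
        score, bs = hits_ab[a]
        b, by_synteny = resolve(a, bs)
        if b is None or b in taken_b:
            continue
        back = hits_ba.get(b)
        if not back:
            continue
        b_back, _ = resolve(b, back[1])
        if b_back != a:
            continue
        _, _, identity = align_proteins(proteome_a[a], proteome_b[b])
        if identity <= min_identity:
            continue
        taken_b.add(b)
        pairs.append(OrthologPair(gene_a=a, gene_b=b, identity=identity,
                                  score=score, tie_resolved_by_synteny=by_synteny))
    return pairs


def synteny_blocks(
    order_a: dict[str, list[str]],
    order_b: dict[str, list[str]],
    pairing: dict[str, str],
    max_gap: int = 1,
) -> list[SyntenyBlock]:
    """Maximal collinear runs (length >= 2) of paired genes.

    For each chromosome pair the B orientation (forward or reversed) that
    covers more paired genes is chosen — so a whole reversed chromosome
    yields the same blocks — and runs are chained greedily in A order,
    allowing up to ``max_gap`` intervening genes on either side between
    consecutive members.
    """
    pos_b: dict[str, tuple[str, int]] = {}
    for chrom, ids in order_b.items():
        for i, gid in enumerate(ids):
            pos_b[gid] = (chrom, i)

    blocks: list[SyntenyBlock] = []
    for chrom_a, ids_a in order_a.items():
        anchored = [
            (i, gid, pairing[gid], *pos_b[pairing[gid]])
            for i, gid in enumerate(ids_a)
            if gid in pairing and pairing[gid] in pos_b
        ]
        by_chrom_b: dict[str, list] = defaultdict(list)
        for rec in anchored:
            by_chrom_b[rec[3]].append(rec)
        for chrom_b, recs in by_chrom_b.items():
            best_runs, best_cover, best_orient = [], -1, 1
            n_b = len(order_b[chrom_b])
            for orient in (1, -1):
                runs = _chain(recs, orient, n_b, max_gap)
                cover = sum(len(r) for r in runs)
                if cover > best_cover:
                    best_runs, best_cover, best_orient = runs, cover, orient
            for run in best_runs:
                blocks.append(SyntenyBlock(
                    chrom_a=chrom_a, chrom_b=chrom_b,
                    pairs=tuple((a, b) for _, a, b, _, _ in run),
                    orientation=best_orient))
    return blocks


def _chain(recs: list, orient: int, n_b: int, max_gap: int) -> list[list]:
    """Greedy chaining of strictly advancing runs in one B orientation."""
    runs: list[list] = []
    current: list = []
    prev_ia = prev_jb = None
    for rec in recs:
        ia, jb = rec[0], rec[4]
        j = jb if orient == 1 else n_b - 1 - jb
        if current and prev_ia is not None:
            step_a = ia - prev_ia
            step_b = j - prev_jb
            if 1 <= step_a <= max_gap + 1 and 1 <= step_b <= max_gap + 1:
                current.append(rec)
                prev_ia, prev_jb = ia, j
                continue
            if len(current) >= 2:
                runs.append(current)
            current = []
        current = current or []
        current.append(rec)
        prev_ia, prev_jb = ia, j
    if len(current) >= 2:
        runs.append(current)
    return runs


def block_membership(blocks: list[SyntenyBlock]) -> dict[str, int]:
    """Map every gene (either species) to the size of its block."""
    member: dict[str, int] = {}
    for blk in blocks:
        for a, b in blk.pairs:
            member[a] = max(member.get(a, 0), len(blk))
            member[b] = max(member.get(b, 0), len(blk))
    return member
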