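"""Orthology: annotation sanity filter, reciprocal best hit, synteny blocks."""

import numpy as np
import pytest

from ilrt.models import GeneModel
from ilrt.orthology import rbh_orthologs, sanity_filter, synteny_blocks
from ilrt.simulate import _random_cds, ancestral_id, mutate_cds


def make_gene(gene_id, cds, exon_lens=None, chrom="chr1"):
    exon_lens = exon_lens or [len(cds)]
    exons, pos = [], 0
    parts = []
    for i, ln in enumerate(exon_lens):
        exons.append((pos, pos + ln))
        parts.append(cds[sum(exon_lens[:i]) : sum(exon_lens[: i + 1])])
        pos += ln
    return GeneModel(gene_id=gene_id, chrom=chrom, strand="+", start=0,
                     seq="".join(parts), exons=exons)


def random_proteome(seed, n, length=300):
    rng = np.random.default_rng(seed)
    return {f"g{i}": _random_cds(rng, length) for i in range(n)}


class TestSanityFilter:
    def test_frame_violation_removed(self):
        rng = np.random.default_rng(0)
        bad = make_gene("bad", _random_cds(rng, 102)[:100])
        good = make_gene("good", _random_cds(rng, 102))
        kept = sanity_filter([bad, good])
        assert set(kept) == {"good"}

    def test_translation_mismatch_removed(self):
        rng = np.random.default_rng(1)
        g = make_gene("g", _random_cds(rng, 90))
        g.protein = "M" * 30  # conflicts with the CDS
        assert sanity_filter([g]) == {}

    def test_longest_isoform_retained(self):
        rng = np.random.default_rng(2)
        short = make_gene("g", _random_cds(rng, 900))
        long_ = make_gene("g", _random_cds(rng, 1200))
        kept = sanity_filter([short, long_])
        assert kept["g"].mrna_length == 1200


class TestRBH:
    def test_identical_proteomes_pair_identically(self):
        rng = np.random.default_rng(3)
        cds = {f"g{i}": _random_cds(rng, 240) for i in range(6)}
        pa = {g: make_gene(g, c).protein for g, c in cds.items()}
        pb = {g.replace("g", "h"): p for g, p in pa.items()}
        pairs = rbh_orthologs(pa, pb)
        assert {(p.gene_a, p.gene_b) for p in pairs} == {
            (f"g{i}", f"h{i}") for i in range(6)}
        assert all(p.identity == 1.0 for p in pairs)

    def test_identity_threshold_excludes_weak_pairs(self):
        rng = np.random.default_rng(4)
        cds = _random_cds(rng, 300)
        a = make_gene("a", cds)
        b = make_gene("b", mutate_cds(rng, cds, 0.04))
        pairs = rbh_orthologs({"a": a.protein}, {"b": b.protein})
        assert len(pairs) == 1 and pairs[0].identity > 0.85
        # same hit fails when the floor sits above its identity
        assert rbh_orthologs({"a": a.protein}, {"b": b.protein},
                             min_identity=0.99) == []

    def test_equal_score_tie_resolved_by_neighborhood(self):
        rng = np.random.default_rng(5)
        cds = {f"g{i}": _random_cds(rng, 240) for i in range(4)}
        pa = {g: make_gene(g, c).protein for g, c in cds.items()}
        # b1 and b2 are identical copies of g0's protein: an exact score tie
        pb = {"b1": pa["g0"], "b2": pa["g0"],
              "h1": pa["g1"], "h2": pa["g2"], "h3": pa["g3"]}
        order_a = {"chr1": ["g0", "g1", "g2", "g3"]}
        order_b = {"chr1": ["b1", "h1", "h2", "h3"], "chr2": ["b2"]}
        pairs = rbh_orthologs(pa, pb, order_a=order_a, order_b=order_b)
        match = {p.gene_a: p.gene_b for p in pairs}
        assert match["g0"] == "b1"
        assert any(p.tie_resolved_by_synteny for p in pairs)
        # without genomic context the tie is conservatively dropped
        pairs_nc = rbh_orthologs(pa, pb)
        assert "g0" not in {p.gene_a for p in pairs_nc}

    def test_symmetric_in_species_and_one_to_one(self, small_clean_cohort):
        cohort, _ = small_clean_cohort
        a, b = cohort.ingroups
        pa = {g: m.protein for g, m in cohort.genes[a].items()}
        pb = {g: m.protein for g, m in cohort.genes[b].items()}
        fwd = rbh_orthologs(pa, pb)
        rev = rbh_orthologs(pb, pa)
        assert {(p.gene_a, p.gene_b) for p in fwd} == {
            (p.gene_b, p.gene_a) for p in rev}
        assert len({p.gene_a for p in fwd}) == len(fwd)
        assert len({p.gene_b for p in fwd}) == len(fwd)

    def test_recovers_planted_orthology_without_rearrangements(self):
        # all genes within the stated divergence bound (no fast class)
        from ilrt import SimConfig
        from ilrt.simulate import simulate_cohort

        cohort, _ = simulate_cohort(SimConfig(
            seed=11, n_genes=40, n_outgroups=1, rearrangement_rate=0.0,
            retrogene_frac=0.0, fast_gene_frac=0.0))
        a, b = cohort.ingroups
        pairs = rbh_orthologs({g: m.protein for g, m in cohort.genes[a].items()},
                              {g: m.protein for g, m in cohort.genes[b].items()})
        correct = sum(ancestral_id(p.gene_a) == ancestral_id(p.gene_b) for p in pairs)
        assert correct / len(cohort.genes[a]) >= 0.99

    def test_empty_proteome_gives_empty_result(self):
        assert rbh_orthologs({}, {"b": "MKLV" * 30}) == []


class TestSyntenyBlocks:
    def test_identical_orders_give_one_block_per_chromosome(self):
        order = {"chr1": ["g1", "g2", "g3"], "chr2": ["g4", "g5"]}
        order_b = {"chr1": ["h1", "h2", "h3"], "chr2": ["h4", "h5"]}
        pairing = {f"g{i}": f"h{i}" for i in range(1, 6)}
        blocks = synteny_blocks(order, order_b, pairing)
        assert sorted(len(b) for b in blocks) == [2, 3]

    def test_reversed_chromosome_gives_same_blocks(self):
        order = {"chr1": ["g1", "g2", "g3", "g4"]}
        pairing = {f"g{i}": f"h{i}" for i in range(1, 5)}
        fwd = synteny_blocks(order, {"chr1": ["h1", "h2", "h3", "h4"]}, pairing)
        rev = synteny_blocks(order, {"chr1": ["h4", "h3", "h2", "h1"]}, pairing)
        assert [{a for a, _ in b.pairs} for b in fwd] == \
               [{a for a, _ in b.pairs} for b in rev]

    def test_transposed_middle_pair_breaks_collinearity(self):
        # B carries the middle genes swapped: no block may join g2 and g3
        order_a = {"chr1": ["g1", "g2", "g3", "g4"]}
        order_b = {"chr1": ["h1", "h3", "h2", "h4"]}
        pairing = {f"g{i}": f"h{i}" for i in range(1, 5)}
        blocks = synteny_blocks(order_a, order_b, pairing)
        for blk in blocks:
            genes = {a for a, _ in blk.pairs}
            assert not {"g2", "g3"} <= genes

    def test_brute_force_agreement_on_strict_runs(self):
        """max_gap=0 blocks equal exhaustively enumerated collinear runs."""
        rng = np.random.default_rng(8)
        ids = [f"g{i}" for i in range(12)]
        perm = list(ids)
        rng.shuffle(perm)
        order_a = {"c": ids}
        order_b = {"c": [g.replace("g", "h") for g in perm]}
        pairing = {g: g.replace("g", "h") for g in ids}
        blocks = synteny_blocks(order_a, order_b, pairing, max_gap=0)
        pos_b = {g: i for i, g in enumerate(order_b["c"])}
        # brute force: for the better global orientation, maximal runs with
        # consecutive A positions and consecutive B positions
        def runs(orient):
            out, cur = [], [ids[0]]
            for prev, nxt in zip(ids, ids[1:]):
                d = (pos_b[pairing[nxt]] - pos_b[pairing[prev]]) * orient
                if d == 1:
                    cur.append(nxt)
                else:
                    if len(cur) >= 2:
                        out.append(tuple(cur))
                    cur = [nxt]
            if len(cur) >= 2:
                out.append(tuple(cur))
            return out
        best = max((runs(1), runs(-1)), key=lambda r: sum(len(x) for x in r))
        assert sorted(tuple(a for a, _ in b.pairs) for b in blocks) == sorted(best)
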