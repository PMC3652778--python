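"""Synthetic two-ingroup cohort generator with a truth table.

The generator emulates the study design the analysis assumes: two sister
ingroup genomes plus outgroups of increasing divergence on a fixed ladder
tree, intron losses planted by the RT mechanism (3'-truncated cDNA
recombination, always precise, simultaneous for contiguous 3' intron runs)
and by genomic deletion (uniform, optionally imprecise), processed
pseudogenes Poisson in the same RT-accessibility x expression factor,
housekeeping expression structure, soluble/membrane labels tied to RT
accessibility, and retrogene/intronless decoys that exercise the synteny
filters.

Substitutions are uniform per site per branch (Jukes-Cantor-like) with no
indels outside engineered imprecise-loss boundaries, so alignment
projection stays exact and tests stay focused on the detection logic.
Evolutionary rate varies across genes: a fast-evolving class (never
housekeeping) gives the ortholog identity distribution the broad lower tail
seen in real proteome comparisons, which is what makes a first-quintile
identity threshold meaningful.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .config import ConfigError, SimConfig

INGROUP_A = "ingroup_a"
INGROUP_B = "ingroup_b"

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

_TISSUE_NAMES = [
    "brain", "liver", "kidney", "heart", "lung",
    "spleen", "muscle", "skin", "thymus", "gut",
]


class EmptyCohortError(ConfigError):
    pass


@dataclass(frozen=True)
class PlantedLoss:
    species: str
    gene_id: str
    ancestral_gene: str
    ordinal: int  # ancestral intron ordinal (1-based)
    mechanism: str  # "rt" | "deletion"
    precise: bool
    event_id: int


@dataclass
class TruthTable:
    """Ground truth of the planted cohort.

    ``remaining_ordinals`` maps each species gene to the ancestral ordinals
    of the introns it still carries, which converts ordinals in a derived
    gene structure back to ancestral numbering.
    """

    planted_losses: list[PlantedLoss] = field(default_factory=list)
    pp_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    retrogenes: dict[str, list[str]] = field(default_factory=dict)
    latent: dict[str, dict] = field(default_factory=dict)  # ancestral gene -> factors
    remaining_ordinals: dict[str, dict[str, list[int]]] = field(default_factory=dict)

    def losses_by_species(self, species: str) -> list[PlantedLoss]:
        return [pl for pl in self.planted_losses if pl.species == species]


@dataclass
class Cohort:
    """In-memory multi-species gene sets plus per-ingroup auxiliary tables."""

    config: SimConfig
    species: list[str]
    genes: dict[str, dict[str, "GeneModel"]]  # species -> gene_id -> model
    gene_order: dict[str, dict[str, list[str]]]  # species -> chrom -> ids
    expression: dict[str, "pd.DataFrame"]  # ingroup -> gene x tissue
    pp_map: dict[str, "pd.DataFrame"]  # ingroup -> (parent_gene_id, pp_id)
    annotations: dict[str, "pd.DataFrame"]  # ingroup -> SP/TM flags

    @property
    def ingroups(self) -> tuple[str, str]:
        return INGROUP_A, INGROUP_B

    @property
    def outgroups(self) -> list[str]:
        return [s for s in self.species if s.startswith("outgroup")]


def ancestral_id(gene_id: str) -> str:
    """Ancestral gene label shared by orthologs/paralogs ('g00042')."""
    m = re.search(r"[grp](\d+)$", gene_id)
    if not m:
        raise ValueError(f"cannot parse gene id {gene_id!r}")
    return f"g{m.group(1)}"


# ---------------------------------------------------------------------------
# sequence helpers


_SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
]


def _random_cds(rng: np.random.Generator, length: int) -> str:
    """Random stop-free CDS of ``length`` nt (multiple of 3), starting ATG."""
    n_codons = length // 3
    idx = rng.integers(0, len(_SENSE_CODONS), size=max(0, n_codons - 1))
    return "ATG" + "".join(_SENSE_CODONS[j] for j in idx)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def mutate_dna(rng: np.random.Generator, seq: str, p: float) -> str:
    """Uniform substitutions: each site mutates with probability ``p``."""
    if not seq or p <= 0:
        return seq
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)].copy()
    mask = rng.random(codes.size) < p
    n = int(mask.sum())
    if n:
        codes[mask] = (codes[mask] + rng.integers(1, 4, size=n)) % 4
    return _BASES[codes].tobytes().decode()


def mutate_cds(rng: np.random.Generator, cds: str, p: float) -> str:
    """Mutate a CDS, reverting any codon that would become a stop."""
    out = mutate_dna(rng, cds, p)
    if out == cds:
        return out
    codons = [out[i : i + 3] for i in range(0, len(out), 3)]
    orig = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for i, c in enumerate(codons):
        if c in _STOPS:
            codons[i] = orig[i]
    return "".join(codons)


def _has_stop(cds: str) -> bool:
    return any(cds[i : i + 3] in _STOPS for i in range(0, len(cds) - 2, 3))


# ---------------------------------------------------------------------------
# internal gene representation during simulation


@dataclass
class _Gene:
    anc: int
    tag: str  # g = ortholog, r = retrogene decoy, p = paralog decoy
    exon_lens: list[int]
    cds: str
    introns: list[str]
    anc_ordinals: list[int]

    @property
    def n_introns(self) -> int:
        return len(self.introns)

    def cds_offsets(self) -> list[int]:
        offs, total = [], 0
        for ln in self.exon_lens[:-1]:
            total += ln
            offs.append(total)
        return offs

    def splice_out(self, idx: int) -> int:
        """Remove intron ``idx`` precisely; returns its ancestral ordinal."""
        self.exon_lens[idx] += self.exon_lens[idx + 1]
        del self.exon_lens[idx + 1]
        del self.introns[idx]
        return self.anc_ordinals.pop(idx)

    def delete_exonic(self, idx: int, side: str, k: int) -> bool:
        """Trim ``k`` exonic nt abutting intron ``idx`` (imprecise loss).

        Returns False (and leaves the gene untouched) if the trim would
        create a stop codon or leave a degenerate exon.
        """
        off = self.cds_offsets()[idx]
        if side == "5":
            if self.exon_lens[idx] - k < 20:
                return False
            new_cds = self.cds[: off - k] + self.cds[off:]
        else:
            if self.exon_lens[idx + 1] - k < 20:
                return False
            new_cds = self.cds[:off] + self.cds[off + k :]
        if _has_stop(new_cds):
            return False
        self.cds = new_cds
        if side == "5":
            self.exon_lens[idx] -= k
        else:
            self.exon_lens[idx + 1] -= k
        return True


def _assemble_seq(g: _Gene) -> tuple[str, list[tuple[int, int]]]:
    parts, exons, pos, cds_pos = [], [], 0, 0
    for i, ln in enumerate(g.exon_lens):
        parts.append(g.cds[cds_pos : cds_pos + ln])
        exons.append((pos, pos + ln))
        pos += ln
        cds_pos += ln
        if i < len(g.introns):
            parts.append(g.introns[i])
            pos += len(g.introns[i])
    return "".join(parts), exons


# ---------------------------------------------------------------------------
# cohort generation


def simulate_cohort(config: SimConfig) -> tuple[Cohort, TruthTable]:
    """Generate a truth-tagged multi-species cohort.

    Deterministic for a fixed ``config.seed``: the same configuration twice
    yields byte-identical outputs.
    """
    import pandas as pd

    config.validate()
    if config.n_genes == 0:
        raise EmptyCohortError("n_genes = 0: refusing to build an empty cohort")
    rng = np.random.default_rng(config.seed)
    n = config.n_genes

    species = [INGROUP_A, INGROUP_B] + [
        f"outgroup_{i}" for i in range(1, config.n_outgroups + 1)
    ]
    divergence = {INGROUP_A: config.ingroup_divergence, INGROUP_B: config.ingroup_divergence}
    for i in range(1, config.n_outgroups + 1):
        divergence[f"outgroup_{i}"] = config.outgroup_divergence(i)

    # latent gene factors -------------------------------------------------
    soluble = rng.random(n) < config.soluble_frac
    housekeeping = rng.random(n) < config.housekeeping_frac
    fast = (rng.random(n) < config.fast_gene_frac) & ~housekeeping
    r = np.where(soluble, rng.lognormal(0.0, config.rt_affinity_sigma, size=n), 0.0)
    e = rng.lognormal(0.0, config.expression_sigma, size=n)
    e[housekeeping] *= config.hk_expression_boost  # germline-accessible transcription
    e[fast] *= config.fast_expression_factor  # expression/rate anticorrelation
    # lineage-specific expression divergence: each ingroup re-draws part of
    # its expression level, so RT activity concentrates on partly different
    # genes in the two genomes (as expression itself evolves)
    e_sp = {
        INGROUP_A: e * rng.lognormal(0.0, config.expression_divergence_sigma, size=n),
        INGROUP_B: e * rng.lognormal(0.0, config.expression_divergence_sigma, size=n),
    }
    strands = np.where(rng.random(n) < 0.5, "+", "-")

    # ancestral gene structures -------------------------------------------
    ancestors: list[_Gene] = []
    for i in range(n):
        k = 0
        while k < config.intron_min:
            k = int(rng.poisson(config.intron_mean))
        exon_lens = [
            int(config.exon_len_min + rng.poisson(config.exon_len_mean - config.exon_len_min))
            for _ in range(k + 1)
        ]
        total = sum(exon_lens)
        exon_lens[-1] += (3 - total % 3) % 3
        cds = _random_cds(rng, sum(exon_lens))
        introns = [
            "GT"
            + _random_dna(
                rng,
                int(config.intron_len_min + rng.poisson(config.intron_len_mean - config.intron_len_min)) - 4,
            )
            + "AG"
            for _ in range(k)
        ]
        ancestors.append(
            _Gene(anc=i, tag="g", exon_lens=exon_lens, cds=cds, introns=introns,
                  anc_ordinals=list(range(1, k + 1)))
        )

    # descend to each species ---------------------------------------------
    cohort_genes: dict[str, dict[int, _Gene]] = {}
    for sp in species:
        p_sp = divergence[sp]
        genes = {}
        for i, anc in enumerate(ancestors):
            rate = config.fast_rate_multiplier if fast[i] else 1.0
            p = min(0.75, p_sp * rate)
            genes[i] = _Gene(
                anc=i,
                tag="g",
                exon_lens=list(anc.exon_lens),
                cds=mutate_cds(rng, anc.cds, p),
                introns=[mutate_dna(rng, s, p) for s in anc.introns],
                anc_ordinals=list(anc.anc_ordinals),
            )
        cohort_genes[sp] = genes

    # base gene order ------------------------------------------------------
    chrom_of = [f"chr{1 + (i * config.n_chromosomes) // n}" for i in range(n)]
    base_order: dict[str, list[tuple[int, str]]] = {}
    for i in range(n):
        base_order.setdefault(chrom_of[i], []).append((i, "g"))
    order = {sp: {c: list(v) for c, v in base_order.items()} for sp in species}

    truth = TruthTable(
        retrogenes={INGROUP_A: [], INGROUP_B: []},
        pp_counts={},
        latent={
            f"g{i:05d}": {
                "r": float(r[i]),
                "e": float(e[i]),
                "e_ingroup_a": float(e_sp[INGROUP_A][i]),
                "e_ingroup_b": float(e_sp[INGROUP_B][i]),
                "soluble": bool(soluble[i]),
                "housekeeping": bool(housekeeping[i]),
                "fast": bool(fast[i]),
            }
            for i in range(n)
        },
    )

    # retrogene / intronless decoys ---------------------------------------
    decoy = np.zeros(n, dtype=bool)
    n_decoys = int(round(config.retrogene_frac * n))
    eligible = [i for i in range(n) if ancestors[i].n_introns >= 2 and not fast[i]]
    rng.shuffle(eligible)
    extra_genes: dict[str, dict[tuple[str, int], _Gene]] = {INGROUP_A: {}, INGROUP_B: {}}
    for d in range(min(n_decoys, len(eligible))):
        i = eligible[d]
        decoy[i] = True
        sp = INGROUP_A if d % 2 else INGROUP_B
        with_paralog = d % 4 < 2
        g = cohort_genes[sp][i]
        # intronless retrocopy of the spliced mRNA, extra neutral divergence
        retro = _Gene(anc=i, tag="r", exon_lens=[len(g.cds)],
                      cds=mutate_cds(rng, g.cds, 0.08), introns=[], anc_ordinals=[])
        # remove the original from its slot, drop retro at a random locus
        chrom = chrom_of[i]
        slot = order[sp][chrom].index((i, "g"))
        order[sp][chrom].remove((i, "g"))
        del cohort_genes[sp][i]
        # the retrocopy lands at a random locus, but never adjacent to the
        # parent's original slot (that would be genuinely syntenic and no
        # longer exercise the retrogene filter)
        for _try in range(50):
            tgt_chrom = f"chr{1 + rng.integers(0, config.n_chromosomes)}"
            pos = int(rng.integers(0, len(order[sp][tgt_chrom]) + 1))
            if tgt_chrom != chrom or abs(pos - slot) > 3:
                break
        order[sp][tgt_chrom].insert(pos, (i, "r"))
        extra_genes[sp][("r", i)] = retro
        truth.retrogenes[sp].append(f"{sp}_r{i:05d}")
        if with_paralog:
            # half the decoys keep a truncated intron-containing paralog at
            # the original (syntenic) slot: higher identity, lower score
            m = max(2, int(np.ceil(0.7 * len(g.exon_lens))))
            keep = list(g.exon_lens[:m])
            cds_len = sum(keep)
            trim = cds_len % 3
            keep[-1] -= trim
            para = _Gene(
                anc=i, tag="p", exon_lens=keep,
                cds=mutate_cds(rng, g.cds[: cds_len - trim], 0.01),
                introns=list(g.introns[: m - 1]),
                anc_ordinals=list(g.anc_ordinals[: m - 1]),
            )
            order[sp][chrom].insert(slot, (i, "p"))
            extra_genes[sp][("p", i)] = para

    # planted intron losses ------------------------------------------------
    event_id = 0
    for sp in (INGROUP_A, INGROUP_B):
        genes = cohort_genes[sp]
        # RT-mediated: gene ~ r*e (housekeeping genes enter via their higher
        # expression); membrane genes have r = 0 and are never chosen
        rt_pool = [i for i in genes if r[i] > 0 and not decoy[i]]
        n_rt = int(round(config.rt_loss_events)) if rt_pool else 0
        for _ in range(n_rt):
            pool = [i for i in rt_pool if genes[i].n_introns > 0]
            if not pool:
                break
            w = np.array([r[i] * e_sp[sp][i] for i in pool])
            i = pool[rng.choice(len(pool), p=w / w.sum())]
            g = genes[i]
            offs = g.cds_offsets()
            cds_len = len(g.cds)
            covered: list[int] = []
            for _try in range(200):
                L = rng.exponential(config.cdna_len_mean)
                covered = [j for j, off in enumerate(offs) if cds_len - off <= L]
                if covered:
                    break
            if not covered:
                continue
            event_id += 1
            for j in sorted(covered, reverse=True):
                anc_ord = g.splice_out(j)
                truth.planted_losses.append(PlantedLoss(
                    species=sp, gene_id=f"{sp}_g{i:05d}", ancestral_gene=f"g{i:05d}",
                    ordinal=anc_ord, mechanism="rt", precise=True, event_id=event_id))
        # genomic deletion: uniform intron, imprecise with imprecise_prob
        n_del = int(round(config.deletion_loss_events))
        for _ in range(n_del):
            pool = [i for i in genes if genes[i].n_introns > 0 and not decoy[i]]
            if not pool:
                break
            w = np.array([genes[i].n_introns for i in pool], dtype=float)
            i = pool[rng.choice(len(pool), p=w / w.sum())]
            g = genes[i]
            j = int(rng.integers(0, g.n_introns))
            event_id += 1
            precise = True
            if rng.random() < config.imprecise_prob:
                options = [(s, k) for s in "53" for k in (3, 6, 9)]
                rng.shuffle(options)
                for s, k in options:
                    if g.delete_exonic(j, s, int(k)):
                        precise = False
                        break
            anc_ord = g.splice_out(j)
            truth.planted_losses.append(PlantedLoss(
                species=sp, gene_id=f"{sp}_g{i:05d}", ancestral_gene=f"g{i:05d}",
                ordinal=anc_ord, mechanism="deletion", precise=precise, event_id=event_id))

    # processed pseudogenes and expression ---------------------------------
    n_somatic = max(1, config.n_tissues - 2)
    somatic = (_TISSUE_NAMES + [f"tissue{j}" for j in range(11, n_somatic + 1)])[:n_somatic]
    tissues = somatic + ["testis", "ovary"]
    for sp in (INGROUP_A, INGROUP_B):
        re_factor = r * e_sp[sp]
        mean_re = re_factor.mean() if re_factor.mean() > 0 else 1.0
        lam = config.pp_rate * re_factor / mean_re
        counts = rng.poisson(lam)
        counts[decoy] = 0
        truth.pp_counts[sp] = {
            f"g{i:05d}": int(counts[i]) for i in range(n)
        }
        rows = []
        k = 0
        for i in range(n):
            gid = f"{sp}_g{i:05d}"
            for _ in range(int(counts[i])):
                rows.append((gid, f"{sp}_pp{k:05d}"))
                k += 1
        truth_pp_df = pd.DataFrame(rows, columns=["parent_gene_id", "pp_id"])
        # expression matrix: housekeeping > cutoff everywhere, others in a
        # random tissue subset (the threshold-200 convention)
        mat = np.round(rng.uniform(0.0, 200.0, size=(n, len(tissues))), 1)
        expressed = rng.random((n, len(tissues))) < config.tissue_expressed_prob
        expressed[housekeeping, :] = True
        u = rng.uniform(0.2, 1.0, size=(n, len(tissues)))
        hi = np.round(201.0 + 1200.0 * e_sp[sp][:, None] * u, 1)
        mat = np.where(expressed, hi, mat)
        expr = pd.DataFrame(mat, columns=tissues,
                            index=[f"{sp}_g{i:05d}" for i in range(n)])
        expr.index.name = "gene_id"
        # SP/TM annotation: membrane genes carry at least one of the two
        has_sp = np.zeros(n, dtype=bool)
        has_tm = np.zeros(n, dtype=bool)
        memb = ~soluble
        which = rng.integers(0, 3, size=n)  # 0: SP, 1: TM, 2: both
        has_sp[memb] = (which[memb] != 1)
        has_tm[memb] = (which[memb] != 0)
        annot = pd.DataFrame({
            "gene_id": [f"{sp}_g{i:05d}" for i in range(n)],
            "has_signal_peptide": has_sp,
            "has_tm_domain": has_tm,
        })
        cohort_expr = expr
        if sp == INGROUP_A:
            expr_a, pp_a, annot_a = cohort_expr, truth_pp_df, annot
        else:
            expr_b, pp_b, annot_b = cohort_expr, truth_pp_df, annot

    # gene-order rearrangements (ingroup B and outgroups) -------------------
    for sp in [INGROUP_B] + [s for s in species if s.startswith("outgroup")]:
        n_ev = int(rng.poisson(config.rearrangement_rate * n))
        for _ in range(n_ev):
            chrom = f"chr{1 + rng.integers(0, config.n_chromosomes)}"
            lst = order[sp][chrom]
            if len(lst) < 4:
                continue
            seg_len = int(rng.integers(1, min(8, len(lst) // 2) + 1))
            start = int(rng.integers(0, len(lst) - seg_len + 1))
            seg = lst[start : start + seg_len]
            rest = lst[:start] + lst[start + seg_len :]
            pos = int(rng.integers(0, len(rest) + 1))
            order[sp][chrom] = rest[:pos] + seg + rest[pos:]

    # assemble GeneModel objects -------------------------------------------
    from .models import GeneModel

    spacer = 200
    genes_out: dict[str, dict[str, GeneModel]] = {}
    order_out: dict[str, dict[str, list[str]]] = {}
    for sp in species:
        genes_out[sp] = {}
        order_out[sp] = {}
        truth.remaining_ordinals.setdefault(sp, {})
        for chrom in sorted(order[sp], key=lambda c: int(c[3:])):
            ids = []
            pos = 0
            for i, tag in order[sp][chrom]:
                if tag == "g":
                    g = cohort_genes[sp][i]
                else:
                    g = extra_genes[sp][(tag, i)]
                gid = f"{sp}_{tag}{i:05d}"
                seq, exons = _assemble_seq(g)
                start = pos + spacer
                pos = start + len(seq)
                genes_out[sp][gid] = GeneModel(
                    gene_id=gid, chrom=chrom, strand=str(strands[i]),
                    start=start, seq=seq, exons=exons,
                )
                truth.remaining_ordinals[sp][gid] = list(g.anc_ordinals)
                ids.append(gid)
            order_out[sp][chrom] = ids

    cohort = Cohort(
        config=config,
        species=species,
        genes=genes_out,
        gene_order=order_out,
        expression={INGROUP_A: expr_a, INGROUP_B: expr_b},
        pp_map={INGROUP_A: pp_a, INGROUP_B: pp_b},
        annotations={INGROUP_A: annot_a, INGROUP_B: annot_b},
    )
    return cohort, truth
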