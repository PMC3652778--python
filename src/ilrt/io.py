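"""Readers and writers for the on-disk cohort layout.

Formats: FASTA (genomic, CDS, protein), GFF3 (gene/mRNA/exon/CDS, 1-based
inclusive, genomic orientation), TSV (gene order, processed-pseudogene map,
expression matrix, signal-peptide/TM annotation, truth tables, analysis
outputs).  Internal coordinates are 0-based half-open in transcript
orientation; conversion is confined to this module.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import dump_config
from .models import GeneModel, LossEvent, OrthologPair
from .simulate import Cohort, PlantedLoss, TruthTable

SPACER = 200


# ---------------------------------------------------------------------------
# cohort writing


def _gene_to_gff_lines(gene: GeneModel) -> list[str]:
    length = len(gene.seq)
    g0, g1 = gene.start, gene.start + length  # 0-based half-open genomic span
    lines = [
        "\t".join([gene.chrom, "ilrt", "gene", str(g0 + 1), str(g1), ".",
                   gene.strand, ".", f"ID={gene.gene_id}"]),
        "\t".join([gene.chrom, "ilrt", "mRNA", str(g0 + 1), str(g1), ".",
                   gene.strand, ".", f"ID={gene.gene_id}.t1;Parent={gene.gene_id}"]),
    ]
    cds_before = 0
    for k, (a, b) in enumerate(gene.exons):
        if gene.strand == "+":
            s, t = g0 + a, g0 + b
        else:
            s, t = g1 - b, g1 - a
        phase = (3 - cds_before % 3) % 3
        for feat in ("exon", "CDS"):
            lines.append("\t".join([
                gene.chrom, "ilrt", feat, str(s + 1), str(t), ".", gene.strand,
                str(phase) if feat == "CDS" else ".",
                f"ID={gene.gene_id}.{feat}{k + 1};Parent={gene.gene_id}.t1",
            ]))
        cds_before += b - a
    return lines


def write_species(genes: dict[str, GeneModel], order: dict[str, list[str]],
                  out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # chromosome sequences: spacer + gene (reverse-complemented on '-')
    chrom_records = []
    for chrom in sorted(order, key=lambda c: (len(c), c)):
        parts = []
        for gid in order[chrom]:
            g = genes[gid]
            parts.append("N" * SPACER)
            gseq = g.seq if g.strand == "+" else str(Seq(g.seq).reverse_complement())
            parts.append(gseq)
        chrom_records.append(SeqRecord(Seq("".join(parts)), id=chrom, description=""))
    SeqIO.write(chrom_records, out_dir / "genome.fa", "fasta")

    ordered_ids = [gid for chrom in sorted(order, key=lambda c: (len(c), c))
                   for gid in order[chrom]]
    SeqIO.write([SeqRecord(Seq(genes[g].cds), id=g, description="") for g in ordered_ids],
                out_dir / "cds.fa", "fasta")
    SeqIO.write([SeqRecord(Seq(genes[g].protein), id=g, description="") for g in ordered_ids],
                out_dir / "proteins.fa", "fasta")

    with open(out_dir / "genes.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for gid in ordered_ids:
            fh.write("\n".join(_gene_to_gff_lines(genes[gid])) + "\n")

    rows = []
    for chrom in sorted(order, key=lambda c: (len(c), c)):
        for idx, gid in enumerate(order[chrom]):
            rows.append((chrom, idx, gid))
    pd.DataFrame(rows, columns=["chrom", "index", "gene_id"]).to_csv(
        out_dir / "gene_order.tsv", sep="\t", index=False)


def write_cohort(cohort: Cohort, truth: TruthTable, out_dir: str | Path) -> Path:
    """Emit the full cohort file set; round-trips losslessly via the readers."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for sp in cohort.species:
        write_species(cohort.genes[sp], cohort.gene_order[sp], out_dir / sp)
    for sp in cohort.ingroups:
        cohort.pp_map[sp].to_csv(out_dir / sp / "pp_map.tsv", sep="\t", index=False)
        cohort.expression[sp].to_csv(out_dir / sp / "expression.tsv", sep="\t")
        cohort.annotations[sp].to_csv(out_dir / sp / "annotations.tsv", sep="\t", index=False)

    tdir = out_dir / "truth"
    tdir.mkdir(exist_ok=True)
    pd.DataFrame([dataclasses.asdict(pl) for pl in truth.planted_losses]).to_csv(
        tdir / "losses.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(sp, gid) for sp, gids in truth.retrogenes.items() for gid in gids],
        columns=["species", "gene_id"],
    ).to_csv(tdir / "retrogenes.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(sp, g, c) for sp, m in truth.pp_counts.items() for g, c in m.items()],
        columns=["species", "ancestral_gene", "pp_count"],
    ).to_csv(tdir / "pp_counts.tsv", sep="\t", index=False)
    lat = pd.DataFrame.from_dict(truth.latent, orient="index")
    lat.index.name = "ancestral_gene"
    lat.to_csv(tdir / "latent.tsv", sep="\t")
    pd.DataFrame(
        [(sp, gid, ",".join(map(str, o)))
         for sp, m in truth.remaining_ordinals.items() for gid, o in m.items()],
        columns=["species", "gene_id", "ancestral_ordinals"],
    ).to_csv(tdir / "remaining_ordinals.tsv", sep="\t", index=False)
    dump_config(cohort.config, out_dir / "config.yaml")
    return out_dir


# ---------------------------------------------------------------------------
# cohort reading


def read_species(dir_path: str | Path) -> tuple[dict[str, GeneModel], dict[str, list[str]]]:
    dir_path = Path(dir_path)
    genome = {rec.id: str(rec.seq) for rec in SeqIO.parse(dir_path / "genome.fa", "fasta")}
    cds = {rec.id: str(rec.seq) for rec in SeqIO.parse(dir_path / "cds.fa", "fasta")}
    prot = {rec.id: str(rec.seq) for rec in SeqIO.parse(dir_path / "proteins.fa", "fasta")}

    db = gffutils.create_db(str(dir_path / "genes.gff3"), ":memory:",
                            merge_strategy="create_unique", keep_order=True)
    genes: dict[str, GeneModel] = {}
    for gf in db.features_of_type("gene"):
        gid = gf.id
        g0, g1 = gf.start - 1, gf.end  # to 0-based half-open
        strand = gf.strand
        gseq = genome[gf.seqid][g0:g1]
        if strand == "-":
            gseq = str(Seq(gseq).reverse_complement())
        exons = []
        for ex in db.children(db[gid + ".t1"], featuretype="exon"):
            e0, e1 = ex.start - 1, ex.end
            if strand == "+":
                exons.append((e0 - g0, e1 - g0))
            else:
                exons.append((g1 - e1, g1 - e0))
        exons.sort()
        genes[gid] = GeneModel(
            gene_id=gid, chrom=gf.seqid, strand=strand, start=g0, seq=gseq,
            exons=exons, cds=cds[gid], protein=prot[gid],
        )

    order_df = pd.read_csv(dir_path / "gene_order.tsv", sep="\t")
    order: dict[str, list[str]] = {}
    for chrom, sub in order_df.sort_values(["chrom", "index"]).groupby("chrom"):
        order[chrom] = list(sub["gene_id"])
    return genes, order


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def read_pp_map(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def read_annotations(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_id": str,
                                              "has_signal_peptide": bool,
                                              "has_tm_domain": bool})


def read_truth(out_dir: str | Path) -> TruthTable:
    tdir = Path(out_dir) / "truth"
    truth = TruthTable()
    df = pd.read_csv(tdir / "losses.tsv", sep="\t")
    for row in df.itertuples(index=False):
        truth.planted_losses.append(PlantedLoss(
            species=row.species, gene_id=row.gene_id,
            ancestral_gene=row.ancestral_gene, ordinal=int(row.ordinal),
            mechanism=row.mechanism, precise=bool(row.precise),
            event_id=int(row.event_id)))
    rg = pd.read_csv(tdir / "retrogenes.tsv", sep="\t")
    for row in rg.itertuples(index=False):
        truth.retrogenes.setdefault(row.species, []).append(row.gene_id)
    pc = pd.read_csv(tdir / "pp_counts.tsv", sep="\t")
    for row in pc.itertuples(index=False):
        truth.pp_counts.setdefault(row.species, {})[row.ancestral_gene] = int(row.pp_count)
    lat = pd.read_csv(tdir / "latent.tsv", sep="\t", index_col="ancestral_gene")
    truth.latent = {g: dict(r) for g, r in lat.iterrows()}
    ro = pd.read_csv(tdir / "remaining_ordinals.tsv", sep="\t",
                     dtype={"ancestral_ordinals": str}, keep_default_na=False)
    for row in ro.itertuples(index=False):
        ords = [int(x) for x in row.ancestral_ordinals.split(",") if x]
        truth.remaining_ordinals.setdefault(row.species, {})[row.gene_id] = ords
    return truth


# ---------------------------------------------------------------------------
# analysis-stage tables


def write_pairs(pairs: list[OrthologPair], path: str | Path) -> None:
    pd.DataFrame(
        [(p.gene_a, p.gene_b, round(p.identity, 6), round(p.score, 1), p.in_synteny)
         for p in pairs],
        columns=["gene_a", "gene_b", "identity", "score", "in_synteny"],
    ).to_csv(path, sep="\t", index=False)


def read_pairs(path: str | Path) -> list[OrthologPair]:
    df = pd.read_csv(path, sep="\t")
    return [OrthologPair(gene_a=r.gene_a, gene_b=r.gene_b, identity=float(r.identity),
                         score=float(r.score), in_synteny=bool(r.in_synteny))
            for r in df.itertuples(index=False)]


LOSS_COLUMNS = ["species", "gene_id", "retaining_species", "retaining_gene",
                "position_nt", "ordinal", "call", "precision", "adjacency",
                "votes_present", "votes_absent"]


def losses_to_frame(events: list[LossEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [(ev.species, ev.gene_id, ev.retaining_species, ev.retaining_gene,
          ev.position_nt, ev.ordinal, ev.call, ev.precision or "",
          ev.adjacency or "", ev.votes_present, ev.votes_absent)
         for ev in events],
        columns=LOSS_COLUMNS,
    )


def write_losses(events: list[LossEvent], path: str | Path) -> None:
    losses_to_frame(events).to_csv(path, sep="\t", index=False)
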