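"""End-to-end orchestration: simulate → orthologs → introns → losses → stats.

All randomness derives from the single seed in the simulation config; the
analysis stages are deterministic.  A manifest records package and library
versions, thresholds and SHA-256 digests of every written output, so a
rerun with the same seed produces identical digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from .config import SimConfig, Thresholds
from .loss_calling import LossCallResult, adjacency_classify, call_losses
from .models import GeneModel, LossEvent
from .orthology import sanity_filter
from .simulate import Cohort, TruthTable, ancestral_id, simulate_cohort
from .stats import (
    SitePosition,
    adjacency_pvalue,
    association_suite,
    fisher_exact_2x2,
    microhomology_scan,
    positional_bias,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


# ---------------------------------------------------------------------------
# per-species statistics assembly


def _pp_counts_from_map(pp_map) -> dict[str, int]:
    return pp_map.groupby("parent_gene_id").size().to_dict() if len(pp_map) else {}


def _site_position(gene: GeneModel, ordinal: int) -> SitePosition:
    site = gene.introns[ordinal - 1]
    return SitePosition(gene_id=gene.gene_id, cds_offset=site.cds_offset,
                        mrna_length=gene.mrna_length,
                        is_last=(ordinal == gene.n_introns))


def _microhomology(gene: GeneModel, ordinal: int, min_len: int, window: int) -> bool:
    site = gene.introns[ordinal - 1]
    up = gene.cds[: site.cds_offset]
    down = gene.cds[site.cds_offset :]
    found, _ = microhomology_scan(up, gene.intron_seq(ordinal - 1), down,
                                  min_len=min_len, window=window)
    return found


def species_statistics(
    species: str,
    result: LossCallResult,
    cohort: Cohort,
    thresholds: Thresholds,
) -> dict:
    """All per-species statistics: association suite, positional bias,
    adjacency null, micro-homology contingency."""
    a_sp, b_sp = cohort.ingroups
    genes_a, genes_b = cohort.genes[a_sp], cohort.genes[b_sp]
    losses = [ev for ev in result.losses if ev.species == species]
    report: dict = {"n_losses": len(losses)}

    # IL / NIL gene sets in this species' gene ids
    il = {ev.gene_id for ev in losses}
    side = 0 if species == a_sp else 1
    nil = {pair[side] for pair in result.nil_pairs}
    nil -= il
    losses_per_gene: dict[str, int] = {}
    for ev in losses:
        losses_per_gene[ev.gene_id] = losses_per_gene.get(ev.gene_id, 0) + 1

    own_genes = genes_a if species == a_sp else genes_b
    mrna_lengths = {g: m.mrna_length for g, m in own_genes.items()}
    intron_counts = {g: m.n_introns for g, m in own_genes.items()}
    pp_counts = _pp_counts_from_map(cohort.pp_map[species])

    if il and nil:
        report["association"] = association_suite(
            il, nil, pp_counts,
            cohort.annotations[species], cohort.expression[species],
            mrna_lengths, intron_counts, losses_per_gene,
            expression_cutoff=thresholds.expression_cutoff,
            excluded_tissues=thresholds.excluded_tissues,
            fisher_convention=thresholds.fisher_convention,
        )
    else:
        logger.warning("species %s: empty IL or NIL set, group tests skipped", species)
        report["association"] = None

    # positions measured on the intron-retaining ortholog
    lost_positions, lost_mh = [], 0
    for ev in losses:
        gene = cohort.genes[ev.retaining_species][ev.retaining_gene]
        lost_positions.append(_site_position(gene, ev.ordinal))
        lost_mh += _microhomology(gene, ev.ordinal, thresholds.microhomology_min_len,
                                  thresholds.microhomology_window)
    cons_positions, cons_mh = [], 0
    ret_side_idx = 1 if species == a_sp else 0  # conserved measured on the partner
    for gene_a_id, gene_b_id, site in result.conserved_sites:
        gid = (gene_a_id, gene_b_id)[ret_side_idx]
        gene = cohort.genes[(a_sp, b_sp)[ret_side_idx]][gid]
        s = site.site_a if ret_side_idx == 0 else site.site_b
        cons_positions.append(SitePosition(
            gene_id=gid, cds_offset=s.cds_offset, mrna_length=gene.mrna_length,
            is_last=(s.ordinal == gene.n_introns)))
        cons_mh += _microhomology(gene, s.ordinal, thresholds.microhomology_min_len,
                                  thresholds.microhomology_window)

    if lost_positions and cons_positions:
        report["positional_bias"] = positional_bias(lost_positions, cons_positions)
        mh_table = [[lost_mh, len(lost_positions) - lost_mh],
                    [cons_mh, len(cons_positions) - cons_mh]]
        report["microhomology"] = {
            "table": mh_table,
            "fisher_p": fisher_exact_2x2(mh_table, thresholds.fisher_convention),
        }
    else:
        report["positional_bias"] = None
        report["microhomology"] = None

    # adjacency null over genes with >= 1 loss in this species
    nk = [(n, k) for (sp, _), (n, k) in result.gene_nk.items()
          if sp == species and 1 <= k <= n]
    if nk:
        by_gene: dict[str, list[int]] = {}
        for ev in losses:
            by_gene.setdefault(ev.retaining_gene, []).append(ev.ordinal)
        obs_pairs = obs_clusters = 0
        for ords in by_gene.values():
            _, clusters, pairs = adjacency_classify(ords)
            obs_pairs += pairs
            obs_clusters += clusters
        null = adjacency_pvalue(nk, observed_pairs=obs_pairs,
                                observed_clusters=obs_clusters)
        report["adjacency"] = {
            "observed_pairs": obs_pairs,
            "observed_clusters": obs_clusters,
            "p_pairs": null.p_pairs,
            "p_clusters": null.p_clusters,
            "n_multi_loss_genes": sum(1 for _, k in nk if k >= 2),
        }
    else:
        report["adjacency"] = None
    report["n_il_genes"] = len(il)
    report["n_nil_genes"] = len(nil)
    return report


# ---------------------------------------------------------------------------
# full pipeline


def analyze_cohort(cohort: Cohort, thresholds: Thresholds | None = None) -> tuple[LossCallResult, dict]:
    """Run orthology, intron mapping, loss calling and statistics in memory."""
    th = thresholds or Thresholds()
    th.validate()
    a_sp, b_sp = cohort.ingroups
    try:
        genes_a = sanity_filter(list(cohort.genes[a_sp].values()))
        genes_b = sanity_filter(list(cohort.genes[b_sp].values()))
        outgroups = {
            sp: sanity_filter(list(cohort.genes[sp].values()))
            for sp in cohort.outgroups
        }
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError(f"stage 'sanity_filter' failed: {exc}") from exc
    try:
        result = call_losses(genes_a, genes_b, cohort.gene_order[a_sp],
                             cohort.gene_order[b_sp], outgroups,
                             a_sp, b_sp, thresholds=th)
    except Exception as exc:
        raise StageError(f"stage 'loss_calling' failed: {exc}") from exc
    try:
        report = {
            "min_identity": result.min_identity,
            "n_pairs": len(result.pairs),
            "n_nil_pairs": len(result.nil_pairs),
            "n_conserved_sites": len(result.conserved_sites),
            "n_losses": len(result.losses),
            "n_gains": len(result.gains),
            "species": {
                sp: species_statistics(sp, result, cohort, th)
                for sp in cohort.ingroups
            },
        }
    except Exception as exc:
        raise StageError(f"stage 'stats' failed: {exc}") from exc
    return result, report


def run_pipeline(
    sim_config: SimConfig,
    thresholds: Thresholds | None = None,
    out_dir: str | Path | None = None,
) -> tuple[LossCallResult, dict, Cohort, TruthTable]:
    """Simulate a cohort, analyze it and (optionally) write everything.

    When ``out_dir`` is given, the cohort file set, loss table, report JSON
    and a digest manifest are written; rerunning with the same seed yields
    identical digests.
    """
    try:
        cohort, truth = simulate_cohort(sim_config)
    except Exception as exc:
        raise StageError(f"stage 'simulate' failed: {exc}") from exc
    result, report = analyze_cohort(cohort, thresholds)
    report["evaluation"] = evaluate_against_truth(result.losses, truth)
    if out_dir is not None:
        from . import __version__
        from .io import write_cohort, write_losses

        out_dir = Path(out_dir)
        write_cohort(cohort, truth, out_dir)
        write_losses(result.losses + result.gains + result.ambiguous,
                     out_dir / "loss_events.tsv")
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_jsonable)
        manifest = {
            "package_version": __version__,
            "numpy_version": np.__version__,
            "seed": sim_config.seed,
            "thresholds": dataclasses.asdict(thresholds or Thresholds()),
            "digests": {
                str(p.relative_to(out_dir)): _sha256(p)
                for p in sorted(out_dir.rglob("*"))
                if p.is_file() and p.name != "manifest.json"
            },
        }
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return result, report, cohort, truth


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# truth evaluation


def evaluate_against_truth(losses: list[LossEvent], truth: TruthTable) -> dict:
    """Site-level comparison of called losses with the planted truth.

    Calls are matched by (species, ancestral gene, ancestral ordinal); the
    called ordinal, which numbers introns of the retaining ortholog, is
    mapped back to ancestral numbering through the retaining gene's
    remaining-ordinal list.
    """
    planted = {(pl.species, pl.ancestral_gene, pl.ordinal): pl
               for pl in truth.planted_losses}
    called: dict[tuple[str, str, int], LossEvent] = {}
    unmappable = 0
    for ev in losses:
        try:
            anc = ancestral_id(ev.retaining_gene)
            remaining = truth.remaining_ordinals[ev.retaining_species][ev.retaining_gene]
            anc_ord = remaining[ev.ordinal - 1]
        except (KeyError, IndexError, ValueError):
            unmappable += 1
            continue
        called[(ev.species, anc, anc_ord)] = ev

    hits = set(called) & set(planted)
    n_planted, n_called = len(planted), len(called) + unmappable
    # a loss planted at the same ancestral intron in BOTH ingroups leaves no
    # unique position between them and is invisible to any outgroup
    # comparison; detectable-site sensitivity scores the caller only on
    # sites that present a unique position
    other = {"ingroup_a": "ingroup_b", "ingroup_b": "ingroup_a"}
    detectable = {
        (sp, g, o) for (sp, g, o) in planted
        if (other.get(sp, ""), g, o) not in planted
    }
    det_hits = hits & detectable
    by_mech = {"rt": [0, 0], "deletion": [0, 0]}
    for key, pl in planted.items():
        by_mech[pl.mechanism][1] += 1
        if key in hits:
            by_mech[pl.mechanism][0] += 1
    precision_confusion = {"precise_as_precise": 0, "precise_as_imprecise": 0,
                           "imprecise_as_imprecise": 0, "imprecise_as_precise": 0}
    for key in hits:
        pl, ev = planted[key], called[key]
        truth_cls = "precise" if pl.precise else "imprecise"
        called_cls = ev.precision or "precise"
        precision_confusion[f"{truth_cls}_as_{called_cls}"] += 1
    return {
        "n_planted": n_planted,
        "n_called": n_called,
        "n_matched": len(hits),
        "n_detectable": len(detectable),
        "n_detectable_matched": len(det_hits),
        "sensitivity": len(hits) / n_planted if n_planted else (1.0 if not n_called else 0.0),
        "sensitivity_detectable": (
            len(det_hits) / len(detectable) if detectable
            else (1.0 if not n_called else 0.0)
        ),
        "false_call_rate": (n_called - len(hits)) / n_called if n_called else 0.0,
        "sensitivity_by_mechanism": {
            m: (v[0] / v[1] if v[1] else None) for m, v in by_mech.items()
        },
        "precision_confusion": precision_confusion,
    }
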