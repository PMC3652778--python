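import logging

import numpy as np
import pytest

from ilrt import SimConfig
from ilrt.config import Thresholds
from ilrt.pipeline import analyze_cohort, evaluate_against_truth
from ilrt.simulate import simulate_cohort
from ilrt.stats import fisher_exact_2x2, mann_whitney_u

logging.getLogger("ilrt").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort():
    """A fast cohort for unit-level pipeline checks."""
    cfg = SimConfig(seed=7, n_genes=40, n_outgroups=3)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_clean_cohort():
    """No rearrangements, no decoys: planted orthology fully recoverable."""
    cfg = SimConfig(seed=11, n_genes=40, n_outgroups=2,
                    rearrangement_rate=0.0, retrogene_frac=0.0)
    return simulate_cohort(cfg)


def run_default_seed(seed: int) -> dict:
    """One default-condition cohort (300 genes, 5 outgroups) end to end.

    Returns the truth evaluation plus the cohort-level (two-ingroup pooled)
    parental-pseudogene Fisher p and the pooled lost-vs-conserved
    positional Mann-Whitney p-values for both positional measures.
    """
    cfg = SimConfig(seed=seed, n_genes=300, n_outgroups=5)
    cohort, truth = simulate_cohort(cfg)
    result, report = analyze_cohort(cohort, Thresholds())
    evr = evaluate_against_truth(result.losses, truth)

    table = np.zeros((2, 2), dtype=int)
    for sp in cohort.ingroups:
        assoc = report["species"][sp]["association"]
        if assoc:
            table += np.array(assoc["parental_pp"]["table"])
    rel_lost, rel_cons, d3_lost, d3_cons = [], [], [], []
    for ev in result.losses:
        gene = cohort.genes[ev.retaining_species][ev.retaining_gene]
        rel_lost.append(ev.site.cds_offset / gene.mrna_length)
        d3_lost.append(gene.mrna_length - ev.site.cds_offset)
    a_sp = cohort.ingroups[0]
    for gene_a_id, _, site in result.conserved_sites:
        gene = cohort.genes[a_sp][gene_a_id]
        rel_cons.append(site.site_a.cds_offset / gene.mrna_length)
        d3_cons.append(gene.mrna_length - site.site_a.cds_offset)
    return {
        "evaluation": evr,
        "fisher_p": fisher_exact_2x2(table.tolist()),
        "posbias_rel_p": mann_whitney_u(rel_lost, rel_cons) if rel_lost else 1.0,
        "posbias_d3_p": mann_whitney_u(d3_lost, d3_cons) if d3_lost else 1.0,
        "n_losses": len(result.losses),
        "report": report,
    }


@pytest.fixture(scope="session")
def default_batch():
    """Twenty default-condition cohorts for the recovery suite."""
    return [run_default_seed(seed) for seed in range(1, 21)]
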