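"""Configuration objects for the simulator and the pipeline."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Parameters of the synthetic two-ingroup cohort.

    The generator plants intron losses by two mechanisms: RT-mediated events
    (gene chosen proportionally to RT accessibility x expression among
    housekeeping genes; a 3'-truncated cDNA of exponential length deletes
    the contiguous 3'-terminal run of introns it covers, always precisely)
    and genomic deletions (uniform intron choice, imprecise with probability
    ``imprecise_prob``).  Processed-pseudogene counts are Poisson in the same
    RT-accessibility x expression factor, so the pseudogene-abundance /
    intron-loss association that the statistics stage tests is planted by
    construction.  Membrane/secreted genes (signal peptide or TM domain)
    have zero RT accessibility.
    """

    seed: int = 0
    n_genes: int = 300
    n_outgroups: int = 7
    n_chromosomes: int = 4
    n_tissues: int = 12

    # gene architecture
    intron_mean: float = 6.0  # truncated-Poisson mean intron count
    intron_min: int = 1
    exon_len_min: int = 45
    exon_len_mean: float = 450.0  # mean mRNA ~3.1 kb, above cdna_len_mean
    intron_len_min: int = 60
    intron_len_mean: float = 200.0

    # divergence (per-branch substitution probability per site)
    ingroup_divergence: float = 0.05
    outgroup_divergence_base: float = 0.06
    outgroup_divergence_step: float = 0.015
    fast_gene_frac: float = 0.35  # fast-evolving class (never housekeeping)
    fast_rate_multiplier: float = 3.0

    # planted events
    rt_loss_events: float = 11.0  # RT-mediated events per ingroup genome
    deletion_loss_events: float = 3.0  # genomic-deletion events per genome
    imprecise_prob: float = 0.5
    cdna_len_mean: float = 1900.0  # exponential 3'-truncation mean, nt

    # latent gene properties
    soluble_frac: float = 0.75  # genes lacking signal peptide / TM domain
    rt_affinity_sigma: float = 0.5  # lognormal sigma of RT accessibility r_g
    expression_sigma: float = 0.5  # lognormal sigma of expression e_g (shared)
    expression_divergence_sigma: float = 1.0  # lineage-specific expression noise
    hk_expression_boost: float = 3.0  # housekeeping genes are expressed higher
    fast_expression_factor: float = 0.01  # expression/rate anticorrelation
    pp_rate: float = 0.5  # mean processed-pseudogene count per gene
    housekeeping_frac: float = 0.2
    tissue_expressed_prob: float = 0.4  # per-tissue expression prob, non-housekeeping

    # decoys and rearrangements
    retrogene_frac: float = 0.02
    rearrangement_rate: float = 0.005  # segment-shuffle events per gene per genome

    def validate(self) -> None:
        probs = {
            "imprecise_prob": self.imprecise_prob,
            "soluble_frac": self.soluble_frac,
            "housekeeping_frac": self.housekeeping_frac,
            "fast_gene_frac": self.fast_gene_frac,
            "retrogene_frac": self.retrogene_frac,
            "tissue_expressed_prob": self.tissue_expressed_prob,
            "ingroup_divergence": self.ingroup_divergence,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} outside [0, 1]")
        counts = {
            "n_genes": self.n_genes,
            "n_outgroups": self.n_outgroups,
            "n_chromosomes": self.n_chromosomes,
            "n_tissues": self.n_tissues,
            "intron_min": self.intron_min,
        }
        for name, c in counts.items():
            if c < 0:
                raise ConfigError(f"{name}={c} negative")
        if self.cdna_len_mean <= 0:
            raise ConfigError("cdna_len_mean must be positive")
        if self.rt_loss_events < 0 or self.deletion_loss_events < 0:
            raise ConfigError("expected event counts must be non-negative")
        if self.exon_len_mean < self.exon_len_min:
            raise ConfigError("exon_len_mean below exon_len_min")
        if self.intron_mean < self.intron_min:
            raise ConfigError("intron_mean below intron_min")

    def outgroup_divergence(self, rank: int) -> float:
        """Root-to-tip substitution probability for outgroup ``rank`` (1-based)."""
        return self.outgroup_divergence_base + self.outgroup_divergence_step * (rank - 1)


@dataclass
class Thresholds:
    """Analysis cutoffs.

    ``min_identity=None`` means the flank reliability cutoff is computed as
    the first quintile of all ortholog mRNA identities (nearest rank); a
    fixed value (the published analysis used 0.43) may be supplied instead.
    """

    rbh_min_identity: float = 0.35
    min_identity: float | None = None
    flank_nt: int = 45
    min_flank_nt: int = 20  # shorter terminal flanks are unreliable
    expression_cutoff: float = 200.0
    excluded_tissues: tuple[str, ...] = ("testis", "ovary")
    precision_window_nt: int = 15
    microhomology_min_len: int = 6
    microhomology_window: int = 15
    synteny_max_gap: int = 1
    fisher_convention: str = "doubling"  # or "min-likelihood"

    def validate(self) -> None:
        for name in ("flank_nt", "min_flank_nt", "precision_window_nt",
                     "microhomology_min_len", "microhomology_window"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.fisher_convention not in ("doubling", "min-likelihood"):
            raise ConfigError(f"unknown fisher_convention {self.fisher_convention!r}")


def _from_mapping(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    if cls is Thresholds and isinstance(data.get("excluded_tissues"), list):
        data = dict(data, excluded_tissues=tuple(data["excluded_tissues"]))
    return cls(**data)


def load_sim_config(path: str | Path) -> SimConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = _from_mapping(SimConfig, data)
    cfg.validate()
    return cfg


def dump_config(cfg, path: str | Path) -> None:
    data = dataclasses.asdict(cfg)
    if isinstance(data.get("excluded_tissues"), tuple):
        data["excluded_tissues"] = list(data["excluded_tissues"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
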