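"""Bundled reference data from the published mouse/rat intron-loss survey.

Two small tables ship with the package for validation and worked examples:
the multi-intron-loss events called in mouse and rat genes (Ensembl gene
ids, intron positions in nt within the unspliced gene, and the
adjacent/solitary classification) and the splice-site micro-homology counts
among lost and conserved introns in each species.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    with resources.files("ilrt.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_multi_loss_events() -> pd.DataFrame:
    """Reported multi-intron-loss events in mouse and rat genes.

    Columns: gene_id, species, position_nt, loss_type ("adjacent loss" /
    "solitary loss"), gene_symbol.  One row per lost intron; genes appear
    in as many rows as they lost introns.
    """
    return _read("multi_intron_loss_events.tsv")


def load_microhomology_counts() -> pd.DataFrame:
    """Splice-site direct-repeat counts among lost and conserved introns.

    Columns: species, lost_with_repeat, lost_total, conserved_with_repeat,
    conserved_total.
    """
    return _read("microhomology_counts.tsv")


def multi_loss_gene_summary(species: str | None = None) -> pd.DataFrame:
    """Group the bundled loss events by gene.

    Returns one row per multi-loss gene with its loss count and whether any
    of its losses is classified adjacent.
    """
    df = load_multi_loss_events()
    if species is not None:
        df = df[df["species"] == species]
    out = df.groupby("gene_id").agg(
        species=("species", "first"),
        n_losses=("position_nt", "size"),
        has_adjacent=("loss_type", lambda s: bool((s == "adjacent loss").any())),
    )
    return out.reset_index()


def microhomology_table(species: str) -> list[list[int]]:
    """2x2 contingency table [[lost w/ repeat, lost w/o], [conserved w/, w/o]]."""
    df = load_microhomology_counts()
    row = df[df["species"] == species].iloc[0]
    return [
        [int(row.lost_with_repeat), int(row.lost_total - row.lost_with_repeat)],
        [int(row.conserved_with_repeat),
         int(row.conserved_total - row.conserved_with_repeat)],
    ]
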