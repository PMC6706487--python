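"""Published summary characteristics of Senecioneae plastomes.

A small bundled table of the deposited genome records (GenBank accessions
KY434193-95, MG560049-51, MH483946-50 plus three comparison genomes) with
their reported sizes, GC percentages and region lengths, for desk-level
comparative arithmetic without downloading the full records.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["genome_characteristics", "genus_size_spans"]


def genome_characteristics() -> pd.DataFrame:
    """The bundled per-genome summary table (one row per accession)."""
    ref = resources.files("plastokit.data") / "senecioneae_plastomes.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def genus_size_spans() -> dict[str, int]:
    """Genome-size arithmetic across the genera.

    Returns the within-genus size span (largest minus smallest genome, bp)
    for the two sequenced genera, and the gap between the largest
    Dendrosenecio plastome and the next-larger genome in the tribe
    (Jacobaea vulgaris).
    """
    df = genome_characteristics()
    by_genus = df.groupby("genus")["genome_size"]
    spans = {
        f"{genus.lower()}_span_bp": int(g.max() - g.min())
        for genus, g in by_genus
        if genus in ("Dendrosenecio", "Senecio")
    }
    dendro_max = df.loc[df.genus == "Dendrosenecio", "genome_size"].max()
    jacobaea = df.loc[df.genus == "Jacobaea", "genome_size"].iloc[0]
    spans["gap_to_jacobaea_bp"] = int(jacobaea - dendro_max)
    return spans
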