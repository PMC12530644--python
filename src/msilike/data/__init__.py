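"""Packaged data: synthetic stand-ins for the gene panel tables and the
reconstructed Table-1-style cohort fixture.

``synthetic_gene_frequencies.csv`` and ``synthetic_gene_classes.csv`` are
synthetic: plausible status-conditioned mutation frequencies and
functional-class assignments over 37 canonical colorectal-cancer gene
symbols, shipped so the package is exercisable end-to-end. Real analyses
should supply measured frequency tables and curated class maps.
"""

from __future__ import annotations

from importlib import resources

from ..core_data import (
    Cohort,
    GeneClassMap,
    GeneFrequencyTable,
    read_cohort,
    read_frequency_table,
)

import pandas as pd


def _path(name: str):
    return resources.files(__package__) / name


def load_default_frequency_table() -> GeneFrequencyTable:
    """Synthetic status-conditioned gene mutation frequencies
    (default priors 0.83 / 0.17)."""
    with resources.as_file(_path("synthetic_gene_frequencies.csv")) as p:
        return read_frequency_table(p)


def load_default_class_map() -> GeneClassMap:
    """Synthetic two-stringency gene functional-class map."""
    with resources.as_file(_path("synthetic_gene_classes.csv")) as p:
        df = pd.read_csv(p)
    maps: dict[int, dict[str, str]] = {1: {}, 2: {}}
    for _, row in df.iterrows():
        maps[1][str(row["gene"])] = str(row["class_s1"])
        maps[2][str(row["gene"])] = str(row["class_s2"])
    return GeneClassMap(stringency_maps=maps)


def load_table1_cohort() -> Cohort:
    """The 188-record categorical-clinical fixture reconstructing the
    published cohort table (164 MSS / 24 MSI-H), with cells the table
    leaves unaccounted for encoded as missing."""
    with resources.as_file(_path("table1_cohort.csv")) as p:
        return read_cohort(p)
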