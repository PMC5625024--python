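"""Probe-level cleanup: filtering, gene collapsing, ortholog mapping.

Mirrors standard microarray handling: probes mapping to multiple genes or
with missing values in over 20% of samples are removed; multiple probes of
one gene are averaged; model-organism genes are relabelled to their human
orthologs and genes without an ortholog are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING_FRACTION_MAX = 0.20  # strictly-over-20% rule


@dataclass
class ProbeMatrix:
    values: pd.DataFrame          # probe x sample, may contain NaN
    labels: pd.Series             # sample -> 'case' / 'control'
    species: str = "human"
    name: str = ""

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError(f"duplicate probe ids in {self.name or 'matrix'}")
        missing = set(self.values.columns) - set(self.labels.index)
        if missing:
            raise ValueError(f"samples without labels: {sorted(missing)[:3]}")


@dataclass
class ExpressionDataset:
    values: pd.DataFrame          # gene x sample, complete
    labels: pd.Series
    species: str = "human"
    name: str = ""
    provenance: dict = field(default_factory=dict)


def filter_probes(matrix: ProbeMatrix,
                  probe_map: dict[str, list[str]]) -> ProbeMatrix:
    """Keep probes that map to exactly one gene and are <=20% missing."""
    n_samples = matrix.values.shape[1]
    keep = []
    for probe in matrix.values.index:
        genes = probe_map.get(probe, [])
        if len(set(genes)) != 1:
            continue
        n_missing = int(matrix.values.loc[probe].isna().sum())
        if n_missing / n_samples > MISSING_FRACTION_MAX:
            continue
        keep.append(probe)
    if not keep:
        warnings.warn(f"no probes survive filtering in {matrix.name or 'matrix'}")
    return ProbeMatrix(values=matrix.values.loc[keep], labels=matrix.labels,
                       species=matrix.species, name=matrix.name)


def collapse_to_genes(matrix: ProbeMatrix,
                      probe_map: dict[str, list[str]]) -> ExpressionDataset:
    """Average a gene's probes per sample, ignoring missing entries.

    Entries still missing after collapsing (all probes of a gene missing in
    one sample) are imputed with the gene's row mean; genes missing
    everywhere are dropped with a warning.
    """
    gene_of = {p: probe_map[p][0] for p in matrix.values.index
               if p in probe_map and len(set(probe_map[p])) == 1}
    grouped = matrix.values.groupby(
        matrix.values.index.map(gene_of)).mean()  # NaN-ignoring mean
    all_missing = grouped.isna().all(axis=1)
    if all_missing.any():
        warnings.warn(
            f"dropping {int(all_missing.sum())} gene(s) with all-missing rows")
        grouped = grouped.loc[~all_missing]
    row_means = grouped.mean(axis=1)
    grouped = grouped.apply(lambda col: col.fillna(row_means))
    grouped.index.name = "gene"
    return ExpressionDataset(values=grouped.sort_index(), labels=matrix.labels,
                             species=matrix.species, name=matrix.name)


def map_orthologs(dataset: ExpressionDataset,
                  ortholog_table: dict[str, list[str]] | None) -> ExpressionDataset:
    """Relabel model-organism genes to human orthologs; drop unmapped genes.

    Human datasets pass through unchanged. Several model genes mapping to
    one human gene are averaged after relabelling.
    """
    if dataset.species == "human":
        return dataset
    if not ortholog_table:
        raise ValueError(
            f"dataset {dataset.name or '?'} is {dataset.species} but no "
            "ortholog table was provided")
    human_of = {g: ortholog_table[g][0] for g in dataset.values.index
                if g in ortholog_table and ortholog_table[g]}
    kept = [g for g in dataset.values.index if g in human_of]
    if not kept:
        raise ValueError(
            f"no genes of dataset {dataset.name or '?'} have human orthologs")
    values = dataset.values.loc[kept]
    values = values.groupby(values.index.map(human_of)).mean()
    values.index.name = "gene"
    return ExpressionDataset(values=values.sort_index(), labels=dataset.labels,
                             species="human", name=dataset.name,
                             provenance=dict(dataset.provenance,
                                             mapped_from=dataset.species))


def preprocess(matrix: ProbeMatrix, probe_map: dict[str, list[str]],
               ortholog_table: dict[str, list[str]] | None = None
               ) -> ExpressionDataset:
    """filter -> collapse -> ortholog-map, the full cleanup chain."""
    filtered = filter_probes(matrix, probe_map)
    dataset = collapse_to_genes(filtered, probe_map)
    return map_orthologs(dataset, ortholog_table)
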