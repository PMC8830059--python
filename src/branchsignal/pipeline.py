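"""End-to-end convenience wrappers used by the CLI and analysis scripts."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .branch_stats import stats_table
from .species_tree import SpeciesTreeEstimate, estimate_species_tree
from .synthetic import SimulatedDataset
from .tree_distance import distance_table

__all__ = ["DatasetTables", "analyze_dataset", "pooled_tables"]


@dataclass
class DatasetTables:
    dataset_id: str
    stats: pd.DataFrame
    distances: pd.DataFrame
    reference: SpeciesTreeEstimate


def analyze_dataset(
    gene_trees,
    locus_ids,
    dataset_id: str = "dataset",
    reference: SpeciesTreeEstimate | None = None,
) -> DatasetTables:
    """Branch statistics, reference species tree, and both distance
    responses for one dataset of gene trees."""
    stats = stats_table(gene_trees, locus_ids)
    stats.insert(0, "dataset", dataset_id)
    if reference is None:
        reference = estimate_species_tree(gene_trees)
    dist = distance_table(gene_trees, reference.tree, locus_ids)
    dist.insert(0, "dataset", dataset_id)
    return DatasetTables(dataset_id, stats, dist, reference)


def analyze_simulated(ds: SimulatedDataset) -> DatasetTables:
    return analyze_dataset(ds.gene_trees, ds.locus_ids, ds.dataset_id)


def pooled_tables(tables: list[DatasetTables]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Concatenate per-dataset stats/distance tables for the pooled model."""
    stats = pd.concat([t.stats for t in tables], ignore_index=True)
    dist = pd.concat([t.distances for t in tables], ignore_index=True)
    return stats, dist
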