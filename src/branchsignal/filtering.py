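"""Locus-filtering experiment.

Loci are ranked by one of three metrics — normalized RF to the reference
species tree (a topology-based control), root-to-tip CoV, or mean branch
support — and species trees are re-estimated from the top-ranked,
bottom-ranked, and random 20/40/60/80% subsets. With one random subset per
size this yields 3 metrics x {top, bottom} x 4 fractions + 4 random = 28
subsets per dataset. Each subset's species tree is compared with the
reference tree (estimated from all loci with the same estimator) via
normalized RF and via its mean branch support, and the direction groups are
contrasted with one-way ANOVA and Tukey HSD per (metric, fraction).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .regression import AnovaResult, TukeyResult, one_way_anova, tukey_hsd
from .species_tree import (
    SpeciesTreeEstimate,
    estimate_from_matrices,
    tree_internode_matrix,
)
from .tree_core import leaf_labels
from .tree_distance import normalized_rf

__all__ = [
    "FilterExperimentRecord",
    "RANKING_METRICS",
    "FRACTIONS",
    "rank_loci",
    "make_subsets",
    "run_experiment",
    "compare_filtering_methods",
    "records_frame",
]

logger = logging.getLogger(__name__)

RANKING_METRICS = ("nrf_to_reference", "cov_rtt", "mean_support")
FRACTIONS = (0.2, 0.4, 0.6, 0.8)

# orientation of "top" = most favorable signal for species-tree inference
_ASCENDING_IS_TOP = {
    "nrf_to_reference": True,  # low distance to reference is good
    "cov_rtt": True,  # low rate variation is good
    "mean_support": False,  # high support is good
}


@dataclass
class FilterExperimentRecord:
    dataset_id: str
    metric: str  # ranking metric, or "random"
    direction: str  # top | bottom | random
    fraction: float
    locus_ids: list[str]
    estimate: SpeciesTreeEstimate | None
    nrf_to_reference: float
    mean_branch_support: float
    seed: int | None = None  # random subsets only
    extras: dict = field(default_factory=dict)


def rank_loci(
    stats: pd.DataFrame, distances: pd.DataFrame, metric: str
) -> list[str]:
    """Locus ids ordered from most to least favorable signal.

    Ties are broken by locus id; loci with a missing metric value are
    excluded with a warning.
    """
    if metric not in RANKING_METRICS:
        raise ValueError(
            f"unknown metric {metric!r}; valid metrics: {list(RANKING_METRICS)}"
        )
    df = stats.merge(distances, on="locus", how="inner", suffixes=("", "_d"))
    col = "nrf_to_species_tree" if metric == "nrf_to_reference" else metric
    missing = df[col].isna()
    if missing.any():
        logger.warning("%d loci missing %s; excluded from ranking", missing.sum(), metric)
        df = df[~missing]
    df = df.sort_values(
        [col, "locus"], ascending=[_ASCENDING_IS_TOP[metric], True], kind="mergesort"
    )
    return df["locus"].tolist()


def _subset_size(fraction: float, n: int) -> int:
    size = int(math.floor(fraction * n + 0.5))  # round half up
    if size < 4:
        raise ValueError(
            f"fraction {fraction} of {n} loci gives {size} < 4 loci"
        )
    return size


@dataclass
class SubsetSpec:
    metric: str
    direction: str
    fraction: float
    locus_ids: list[str]
    seed: int | None = None


def make_subsets(
    rankings: dict[str, list[str]],
    fractions=FRACTIONS,
    n_random_per_size: int = 1,
    seed: int = 0,
) -> list[SubsetSpec]:
    """Build the experiment's locus subsets (28 under the default design).

    ``rankings`` maps each ranking metric to its top-first locus order.
    Random subsets are drawn without replacement, reproducibly from
    ``seed``; with ``n_random_per_size`` > 1 the design grows accordingly.
    """
    subsets: list[SubsetSpec] = []
    all_loci = None
    for metric, ranked in rankings.items():
        if metric not in RANKING_METRICS:
            raise ValueError(f"unknown metric {metric!r}")
        if all_loci is None:
            all_loci = sorted(ranked)
        n = len(ranked)
        if n < 5:
            raise ValueError("need at least 5 ranked loci")
        for frac in fractions:
            size = _subset_size(frac, n)
            subsets.append(SubsetSpec(metric, "top", frac, ranked[:size]))
            subsets.append(SubsetSpec(metric, "bottom", frac, ranked[-size:][::-1]))
    rng = np.random.default_rng(seed)
    n = len(all_loci)
    for frac in fractions:
        size = _subset_size(frac, n)
        for r in range(n_random_per_size):
            sub_seed = int(rng.integers(1 << 31))
            pick = np.random.default_rng(sub_seed).choice(n, size=size, replace=False)
            subsets.append(
                SubsetSpec(
                    "random", "random", frac, [all_loci[i] for i in sorted(pick)],
                    seed=sub_seed,
                )
            )
    return subsets


def run_experiment(
    gene_trees: list[dendropy.Tree],
    locus_ids: list[str],
    stats: pd.DataFrame,
    distances: pd.DataFrame,
    dataset_id: str = "dataset",
    seed: int = 0,
    reference: SpeciesTreeEstimate | None = None,
    n_random_per_size: int = 1,
) -> tuple[list[FilterExperimentRecord], SpeciesTreeEstimate]:
    """Estimate a species tree per subset and score it against the reference.

    The reference tree is estimated from all loci with the same estimator
    (or passed in precomputed). Returns the records plus the reference.
    """
    taxa = sorted(set().union(*(leaf_labels(t) for t in gene_trees)))
    by_id = dict(zip(locus_ids, range(len(locus_ids))))
    mats = np.stack([tree_internode_matrix(t, taxa) for t in gene_trees])
    if reference is None:
        reference = estimate_from_matrices(mats, taxa, gene_trees)
    rankings = {m: rank_loci(stats, distances, m) for m in RANKING_METRICS}
    subsets = make_subsets(
        rankings, FRACTIONS, n_random_per_size=n_random_per_size, seed=seed
    )
    records = []
    for spec in subsets:
        idx = [by_id[l] for l in spec.locus_ids]
        try:
            est = estimate_from_matrices(
                mats[idx], taxa, [gene_trees[i] for i in idx]
            )
            nrf = normalized_rf(est.tree, reference.tree)
            msup = est.mean_support
        except ValueError as exc:
            logger.warning(
                "%s %s/%s/%.0f%%: estimation failed (%s)",
                dataset_id, spec.metric, spec.direction, 100 * spec.fraction, exc,
            )
            est, nrf, msup = None, math.nan, math.nan
        records.append(
            FilterExperimentRecord(
                dataset_id=dataset_id,
                metric=spec.metric,
                direction=spec.direction,
                fraction=spec.fraction,
                locus_ids=spec.locus_ids,
                estimate=est,
                nrf_to_reference=nrf,
                mean_branch_support=msup,
                seed=spec.seed,
            )
        )
    return records, reference


def records_frame(records: list[FilterExperimentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "dataset": [r.dataset_id for r in records],
            "metric": [r.metric for r in records],
            "direction": [r.direction for r in records],
            "fraction": [r.fraction for r in records],
            "n_loci": [len(r.locus_ids) for r in records],
            "nrf_to_reference": [r.nrf_to_reference for r in records],
            "mean_branch_support": [r.mean_branch_support for r in records],
        }
    )


def compare_filtering_methods(
    records: list[FilterExperimentRecord],
    response: str = "nrf_to_reference",
) -> dict[tuple[str, float], tuple[AnovaResult, TukeyResult, list[str]]]:
    """ANOVA + Tukey HSD across direction groups, per (metric, fraction).

    For each ranking metric and subset fraction, the groups are the
    top-ranked, bottom-ranked, and random subsets' ``response`` values
    across datasets. Returns {(metric, fraction): (anova, tukey, group
    names)}.
    """
    df = records_frame(records)
    if df["dataset"].nunique() < 2:
        raise ValueError("need records from >= 2 datasets")
    out = {}
    for metric in RANKING_METRICS:
        for frac in sorted(df["fraction"].unique()):
            groups, names = [], []
            for direction, sub in (
                ("top", df[(df.metric == metric) & (df.direction == "top")]),
                ("bottom", df[(df.metric == metric) & (df.direction == "bottom")]),
                ("random", df[df.direction == "random"]),
            ):
                vals = sub[sub.fraction == frac][response].dropna().values
                if len(vals) >= 2:
                    groups.append(vals)
                    names.append(direction)
            if len(groups) < 2:
                continue
            out[(metric, frac)] = (
                one_way_anova(groups),
                tukey_hsd(groups),
                names,
            )
    return out
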