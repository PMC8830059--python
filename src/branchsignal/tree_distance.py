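"""Robinson-Foulds distances and the two per-locus discordance responses.

The RF distance between two unrooted trees on the same leaf set is the size
of the symmetric difference of their nontrivial bipartition sets; the
normalized version divides by the maximum attainable value, ``2(n-3)`` for
two binary trees on ``n`` leaves (for non-binary inputs the denominator is
the sum of the two bipartition-set sizes). Branch lengths play no role.

The two responses mirror how discordance is quantified in phylogenomic
screens: distance of each gene tree to a reference species tree, and mean
distance of each gene tree to all other gene trees of its dataset.
"""

from __future__ import annotations

import logging
import math

import numpy as np

import dendropy
import pandas as pd

from .tree_core import bipartition_sides, leaf_labels

__all__ = [
    "rf_distance",
    "normalized_rf",
    "distances_to_reference",
    "mean_pairwise_distances",
    "distance_table",
    "prune_to_taxa",
]

logger = logging.getLogger(__name__)


def prune_to_taxa(tree: dendropy.Tree, taxa: set[str]) -> dendropy.Tree:
    """Copy of ``tree`` restricted to the given leaf labels."""
    tree = tree.clone(depth=1)
    keep = [lf.taxon for lf in tree.leaf_node_iter() if lf.taxon.label in taxa]
    tree.retain_taxa(keep)
    return tree


def _shared_sides(t1, t2):
    taxa1, taxa2 = set(leaf_labels(t1)), set(leaf_labels(t2))
    shared = taxa1 & taxa2
    if len(shared) < 4:
        raise ValueError(
            f"fewer than 4 shared taxa ({len(shared)}); RF distance undefined"
        )
    if taxa1 != shared:
        t1 = prune_to_taxa(t1, shared)
    if taxa2 != shared:
        t2 = prune_to_taxa(t2, shared)
    return bipartition_sides(t1), bipartition_sides(t2)


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unnormalized RF: |B(t1) Δ B(t2)| after pruning to shared taxa."""
    b1, b2 = _shared_sides(t1, t2)
    return len(b1 ^ b2)


def normalized_rf(t1: dendropy.Tree, t2: dendropy.Tree) -> float:
    """RF divided by its maximum, |B(t1)| + |B(t2)| (= 2(n-3) when binary)."""
    b1, b2 = _shared_sides(t1, t2)
    denom = len(b1) + len(b2)
    if denom == 0:
        raise ValueError("no nontrivial bipartitions in either tree; nRF undefined")
    return len(b1 ^ b2) / denom


def _nrf_from_sides(b1, b2) -> float:
    denom = len(b1) + len(b2)
    if denom == 0:
        raise ValueError("no nontrivial bipartitions; nRF undefined")
    return len(b1 ^ b2) / denom


def distances_to_reference(
    gene_trees: list[dendropy.Tree], reference: dendropy.Tree
) -> list[float]:
    """Per-locus normalized RF to the reference tree (pruned per locus).

    Loci failing the shared-taxon requirement yield NaN with a warning.
    """
    out = []
    ref_taxa = set(leaf_labels(reference))
    ref_sides = bipartition_sides(reference)
    for i, gt in enumerate(gene_trees):
        gt_taxa = set(leaf_labels(gt))
        try:
            if gt_taxa == ref_taxa:
                out.append(_nrf_from_sides(bipartition_sides(gt), ref_sides))
            else:
                out.append(normalized_rf(gt, reference))
        except ValueError as exc:
            logger.warning("locus %d: distance to reference failed (%s)", i, exc)
            out.append(math.nan)
    return out


def mean_pairwise_distances(
    gene_trees: list[dendropy.Tree],
    subsample: int | None = None,
    seed: int = 0,
) -> list[float]:
    """For each locus, mean normalized RF to every other locus.

    Pairs with fewer than 4 shared taxa are skipped (logged); a locus with
    no valid partner gets NaN. All pairs are computed exactly by default;
    ``subsample`` caps the number of partners per locus (drawn without
    replacement, reproducibly from ``seed``) for very large collections.
    """
    k = len(gene_trees)
    if k < 2:
        raise ValueError("need at least 2 gene trees")
    taxa = [frozenset(leaf_labels(t)) for t in gene_trees]
    sides = [bipartition_sides(t) for t in gene_trees]

    if subsample is not None and subsample < k - 1:
        rng = np.random.default_rng(seed)
        out = []
        for i in range(k):
            partners = np.setdiff1d(np.arange(k), [i])
            pick = rng.choice(partners, size=subsample, replace=False)
            vals = []
            for j in pick:
                try:
                    if taxa[i] == taxa[j]:
                        vals.append(_nrf_from_sides(sides[i], sides[j]))
                    else:
                        vals.append(normalized_rf(gene_trees[i], gene_trees[j]))
                except ValueError as exc:
                    logger.warning("pair (%d, %d) skipped: %s", i, j, exc)
            out.append(float(np.mean(vals)) if vals else math.nan)
        return out

    sums = [0.0] * k
    counts = [0] * k
    for i in range(k):
        for j in range(i + 1, k):
            try:
                if taxa[i] == taxa[j]:
                    d = _nrf_from_sides(sides[i], sides[j])
                else:
                    d = normalized_rf(gene_trees[i], gene_trees[j])
            except ValueError as exc:
                logger.warning("pair (%d, %d) skipped: %s", i, j, exc)
                continue
            sums[i] += d
            sums[j] += d
            counts[i] += 1
            counts[j] += 1
    return [s / c if c else math.nan for s, c in zip(sums, counts)]


def distance_table(
    gene_trees: list[dendropy.Tree],
    reference: dendropy.Tree,
    ids: list[str] | None = None,
) -> pd.DataFrame:
    """Both responses per locus: nRF to reference and mean pairwise nRF."""
    if ids is None:
        ids = [f"locus_{i:04d}" for i in range(len(gene_trees))]
    ref_taxa = set(leaf_labels(reference))
    return pd.DataFrame(
        {
            "locus": ids,
            "nrf_to_species_tree": distances_to_reference(gene_trees, reference),
            "mean_nrf_to_gene_trees": mean_pairwise_distances(gene_trees),
            "n_shared_taxa": [
                len(set(leaf_labels(t)) & ref_taxa) for t in gene_trees
            ],
        }
    )
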