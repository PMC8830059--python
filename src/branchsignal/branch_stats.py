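"""Per-locus branch statistics.

Four per-gene-tree summaries of branch-length signal:

* ``cov_root_to_tip`` — coefficient of variation of root-to-tip distances
  after midpoint rooting; a scale-free measure of among-lineage rate
  variation (0 for a clock-like, ultrametric tree).
* ``tree_length`` — sum of all branch lengths (substitutions/site); a proxy
  for the overall substitution rate at the locus.
* ``stemminess`` — ratio of the summed internal to summed terminal branch
  lengths.
* ``mean_support`` — arithmetic mean of the internal-edge support labels
  (0-100 scale, e.g. SH-aLRT).

Plus the number of variable alignment columns, which is computed but — like
in typical phylogenomic screens — usually set aside because it tracks mean
branch support closely.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from Bio import AlignIO

from .tree_core import (
    edge_supports,
    leaf_labels,
    midpoint_root,
    root_to_tip_distances,
)

__all__ = [
    "GeneTreeStats",
    "cov_root_to_tip",
    "tree_length",
    "mean_branch_length",
    "stemminess",
    "mean_support",
    "count_variable_sites",
    "stats_table",
    "STATS_COLUMNS",
]

logger = logging.getLogger(__name__)

STATS_COLUMNS = [
    "locus",
    "cov_rtt",
    "tree_length",
    "mean_branch_length",
    "stemminess",
    "mean_support",
    "n_taxa",
    "n_variable_sites",
]


@dataclass
class GeneTreeStats:
    locus: str
    cov_rtt: float
    tree_length: float
    mean_branch_length: float
    stemminess: float
    mean_support: float | None
    n_taxa: int
    n_variable_sites: int | None = None


def cov_root_to_tip(tree: dendropy.Tree, ddof: int = 1) -> float:
    """CoV (SD/mean) of midpoint-root-to-tip distances.

    ``ddof=1`` (sample standard deviation) by default; ``ddof=0`` gives the
    population version.
    """
    rooted = midpoint_root(tree)
    d = np.array(list(root_to_tip_distances(rooted).values()))
    m = d.mean()
    if m <= 0:
        raise ValueError("degenerate tree: mean root-to-tip distance is 0")
    return float(d.std(ddof=ddof) / m)


def tree_length(tree: dendropy.Tree) -> float:
    return float(
        sum(e.length or 0.0 for e in tree.preorder_edge_iter() if e.head_node.parent_node is not None)
    )


def _n_branches(tree: dendropy.Tree) -> int:
    return sum(1 for e in tree.preorder_edge_iter() if e.head_node.parent_node is not None)


def mean_branch_length(tree: dendropy.Tree) -> float:
    nb = _n_branches(tree)
    if nb == 0:
        raise ValueError("tree has no branches")
    return tree_length(tree) / nb


def stemminess(tree: dendropy.Tree) -> float:
    """Sum of internal branch lengths over sum of terminal branch lengths."""
    internal = 0.0
    terminal = 0.0
    for e in tree.preorder_edge_iter():
        if e.head_node.parent_node is None:
            continue
        if e.head_node.is_leaf():
            terminal += e.length or 0.0
        else:
            internal += e.length or 0.0
    if terminal <= 0:
        raise ValueError("terminal branch lengths sum to 0; stemminess undefined")
    return internal / terminal


def mean_support(tree: dendropy.Tree) -> float | None:
    """Mean of internal-edge supports; ``None`` when no edge carries one."""
    vals = edge_supports(tree)
    if not vals:
        return None
    return float(np.mean(vals))


_UNAMBIGUOUS = set("ACGTUacgtu")


def count_variable_sites(alignment) -> int:
    """Number of alignment columns with >= 2 distinct unambiguous bases.

    ``alignment`` is a Biopython ``MultipleSeqAlignment`` or a path to a
    FASTA alignment. Gaps and ambiguity codes never count as states.
    """
    if isinstance(alignment, (str, bytes)) or hasattr(alignment, "__fspath__"):
        alignment = AlignIO.read(alignment, "fasta")
    lengths = {len(rec.seq) for rec in alignment}
    if len(lengths) > 1:
        raise ValueError(f"ragged alignment: sequence lengths {sorted(lengths)}")
    if not lengths:
        return 0
    ncol = lengths.pop()
    count = 0
    for j in range(ncol):
        states = {
            str(rec.seq[j]).upper()
            for rec in alignment
            if str(rec.seq[j]) in _UNAMBIGUOUS
        }
        if len(states) >= 2:
            count += 1
    return count


def stats_table(
    trees: list[dendropy.Tree],
    ids: list[str] | None = None,
    n_variable_sites: list[int] | None = None,
    ddof: int = 1,
) -> pd.DataFrame:
    """One row of branch statistics per locus, in input order.

    Per-locus failures (degenerate trees) yield NaN fields and a logged
    warning instead of aborting the table.
    """
    if not trees:
        raise ValueError("empty tree list")
    if ids is None:
        ids = [f"locus_{i:04d}" for i in range(len(trees))]
    rows = []
    for i, (locus, tree) in enumerate(zip(ids, trees)):
        row = {c: math.nan for c in STATS_COLUMNS}
        row["locus"] = locus
        row["n_taxa"] = len(leaf_labels(tree))
        try:
            row["cov_rtt"] = cov_root_to_tip(tree, ddof=ddof)
        except ValueError as exc:
            logger.warning("locus %s: cov_rtt failed (%s)", locus, exc)
        row["tree_length"] = tree_length(tree)
        try:
            row["mean_branch_length"] = mean_branch_length(tree)
        except ValueError as exc:
            logger.warning("locus %s: mean_branch_length failed (%s)", locus, exc)
        try:
            row["stemminess"] = stemminess(tree)
        except ValueError as exc:
            logger.warning("locus %s: stemminess failed (%s)", locus, exc)
        ms = mean_support(tree)
        row["mean_support"] = math.nan if ms is None else ms
        if n_variable_sites is not None:
            row["n_variable_sites"] = n_variable_sites[i]
        rows.append(row)
    return pd.DataFrame(rows, columns=STATS_COLUMNS)
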