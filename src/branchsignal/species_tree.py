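"""Summary species-tree estimation from gene trees.

The estimator is a distance-based summary-coalescent method: average the
per-gene-tree internode distances (number of internal nodes on the path
between two taxa, in the unrooted tree) across loci, then build the topology
with neighbor joining. Averaged internode distances converge to an additive
distance on the species-tree topology under the multispecies coalescent, so
the estimator is statistically consistent, like the quartet-based tools
(ASTRAL) used in large empirical studies; an adapter to an external ASTRAL
binary is provided for users who want the original tool.

Branch supports on the estimate are gene-tree bipartition frequencies in
[0, 1]: the fraction of input gene trees whose topology contains the edge's
split.
"""

from __future__ import annotations

import json
import subprocess
import tempfile
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import dendropy
import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj

from .tree_core import bipartition_sides, leaf_labels, parse_newick, write_newick

__all__ = [
    "SpeciesTreeEstimate",
    "tree_internode_matrix",
    "internode_distance_matrix",
    "neighbor_joining",
    "estimate_species_tree",
    "estimate_from_matrices",
    "bipartition_frequencies",
    "quartet_score",
    "external_astral_adapter",
]


@dataclass
class SpeciesTreeEstimate:
    """Species-tree topology with bipartition-frequency supports."""

    tree: dendropy.Tree
    supports: dict[frozenset, float]
    n_input_trees: int
    metadata: dict = field(default_factory=dict)

    @property
    def mean_support(self) -> float:
        if not self.supports:
            return float("nan")
        return float(np.mean(list(self.supports.values())))

    def as_newick(self) -> str:
        return write_newick(self.tree)


def tree_internode_matrix(tree: dendropy.Tree, taxa: list[str]) -> np.ndarray:
    """Internode distances of one tree, NaN where a taxon is absent.

    Entry (a, b) counts the internal nodes strictly between leaves a and b
    in the unrooted tree (a degree-2 root does not count).
    """
    idx = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    mat = np.full((n, n), np.nan)
    np.fill_diagonal(mat, 0.0)
    seed = tree.seed_node
    root_deg2 = len(seed.child_nodes()) == 2
    depth = {id(seed): 0}
    anc: dict[int, list] = {id(seed): []}
    leaves = []
    for nd in tree.preorder_node_iter():
        p = nd.parent_node
        if p is not None:
            depth[id(nd)] = depth[id(p)] + 1
            anc[id(nd)] = anc[id(p)] + [p]
        if nd.is_leaf() and nd.taxon.label in idx:
            leaves.append(nd)
    for a, b in combinations(leaves, 2):
        aa, ab = anc[id(a)], anc[id(b)]
        k = 0
        while k < len(aa) and k < len(ab) and aa[k] is ab[k]:
            k += 1
        lca = aa[k - 1]
        d = depth[id(a)] + depth[id(b)] - 2 * depth[id(lca)] - 1
        if lca is seed and root_deg2:
            d -= 1
        i, j = idx[a.taxon.label], idx[b.taxon.label]
        mat[i, j] = mat[j, i] = float(d)
    return mat


def internode_distance_matrix(
    gene_trees: list[dendropy.Tree], taxa: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Mean internode distance over the gene trees containing each pair."""
    if taxa is None:
        taxa = sorted(set().union(*(leaf_labels(t) for t in gene_trees)))
    else:
        taxa = sorted(taxa)
    mats = np.stack([tree_internode_matrix(t, taxa) for t in gene_trees])
    counts = np.sum(~np.isnan(mats), axis=0)
    missing = np.argwhere(counts == 0)
    missing = [(taxa[i], taxa[j]) for i, j in missing if i < j]
    if missing:
        raise ValueError(f"taxon pairs co-occurring in no gene tree: {missing}")
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(mats, axis=0)
    return mean, taxa


def neighbor_joining(matrix: np.ndarray, taxa: list[str]) -> dendropy.Tree:
    """Unrooted NJ topology for a symmetric distance matrix.

    Taxa are processed in sorted-label order, which fixes tie-breaking and
    makes the result invariant to the caller's taxon ordering. Negative NJ
    branch lengths are clamped to zero (topology is what matters here).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.all(np.isfinite(matrix)):
        raise ValueError("distance matrix contains non-finite entries")
    if not np.allclose(matrix, matrix.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if len(taxa) < 4:
        raise ValueError("need at least 4 taxa for neighbor joining")
    order = np.argsort(np.asarray(taxa, dtype=object))
    labels = [taxa[i] for i in order]
    dm = DistanceMatrix(matrix[np.ix_(order, order)], ids=labels)
    newick = str(nj(dm)).strip()
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    for e in tree.preorder_edge_iter():
        if e.length is not None and e.length < 0:
            e.length = 0.0
    tree.is_rooted = False
    return tree


def bipartition_frequencies(
    estimate_tree: dendropy.Tree, gene_trees: list[dendropy.Tree]
) -> dict[frozenset, float]:
    """Fraction of gene trees containing each internal edge of the estimate.

    Gene trees missing taxa are counted against the split restricted to
    their own taxon set; trees for which the restriction is trivial do not
    enter that edge's denominator.
    """
    est_taxa = frozenset(leaf_labels(estimate_tree))
    gt_info = []
    for gt in gene_trees:
        gt_taxa = frozenset(leaf_labels(gt))
        gt_info.append((gt_taxa, bipartition_sides(gt)))
    freqs: dict[frozenset, float] = {}
    for side in bipartition_sides(estimate_tree):
        other = est_taxa - side
        hits = 0
        total = 0
        for gt_taxa, gt_sides in gt_info:
            s = side & gt_taxa
            o = other & gt_taxa
            if len(s) < 2 or len(o) < 2:
                continue
            if len(o) < len(s) or (len(o) == len(s) and sorted(o) < sorted(s)):
                canon = o
            else:
                canon = s
            total += 1
            if canon in gt_sides:
                hits += 1
        freqs[side] = hits / total if total else float("nan")
    return freqs


def _annotate_supports(tree: dendropy.Tree, freqs: dict[frozenset, float]) -> None:
    est_taxa = frozenset(leaf_labels(tree))
    below: dict[int, frozenset] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            below[id(nd)] = frozenset([nd.taxon.label])
        else:
            below[id(nd)] = frozenset().union(*(below[id(c)] for c in nd.child_nodes()))
    for nd in tree.preorder_internal_node_iter():
        if nd.parent_node is None:
            continue
        side = below[id(nd)]
        other = est_taxa - side
        if len(other) < len(side) or (
            len(other) == len(side) and sorted(other) < sorted(side)
        ):
            side = other
        if side in freqs:
            nd.label = f"{freqs[side]:.4f}"


def estimate_from_matrices(
    per_tree_matrices: np.ndarray,
    taxa: list[str],
    gene_trees: list[dendropy.Tree],
) -> SpeciesTreeEstimate:
    """Estimate from precomputed per-tree internode matrices (see
    :func:`tree_internode_matrix`); used to avoid recomputation when many
    overlapping subsets of the same loci are analyzed."""
    counts = np.sum(~np.isnan(per_tree_matrices), axis=0)
    if np.any(counts == 0):
        raise ValueError("taxon pair co-occurring in no gene tree")
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(per_tree_matrices, axis=0)
    tree = neighbor_joining(mean, taxa)
    for e in tree.preorder_edge_iter():
        if e.head_node.parent_node is not None:
            e.length = 1.0
    freqs = bipartition_frequencies(tree, gene_trees)
    _annotate_supports(tree, freqs)
    return SpeciesTreeEstimate(
        tree=tree,
        supports=freqs,
        n_input_trees=len(gene_trees),
        metadata={"method": "internode-nj", "distance": "internal-node-count"},
    )


def estimate_species_tree(gene_trees: list[dendropy.Tree]) -> SpeciesTreeEstimate:
    """Internode-distance + NJ summary estimate with frequency supports."""
    if not gene_trees:
        raise ValueError("need at least one gene tree")
    taxa = sorted(set().union(*(leaf_labels(t) for t in gene_trees)))
    if len(taxa) < 4:
        raise ValueError("need at least 4 taxa in the union of gene trees")
    mats = np.stack([tree_internode_matrix(t, taxa) for t in gene_trees])
    return estimate_from_matrices(mats, taxa, gene_trees)


def quartet_score(
    candidate: dendropy.Tree,
    gene_trees: list[dendropy.Tree],
    max_taxa: int = 20,
) -> int:
    """Number of (quartet, gene tree) pairs agreeing with the candidate.

    A diagnostic aligned with the quartet criterion optimized by ASTRAL;
    guarded to small taxon counts because all C(n, 4) quartets are
    enumerated.
    """
    taxa = sorted(leaf_labels(candidate))
    if len(taxa) > max_taxa:
        raise ValueError(
            f"{len(taxa)} taxa exceeds the quartet enumeration guard "
            f"({max_taxa}); raise max_taxa to override"
        )
    cand_mat = tree_internode_matrix(candidate, taxa)
    gt_mats = [tree_internode_matrix(t, taxa) for t in gene_trees]

    def induced(mat, i, j, k, l):
        s = [
            (mat[i, j] + mat[k, l], 0),
            (mat[i, k] + mat[j, l], 1),
            (mat[i, l] + mat[j, k], 2),
        ]
        if np.any(np.isnan([x for x, _ in s])):
            return None
        s.sort()
        if s[0][0] == s[1][0]:
            return None  # unresolved
        return s[0][1]

    score = 0
    for i, j, k, l in combinations(range(len(taxa)), 4):
        c = induced(cand_mat, i, j, k, l)
        if c is None:
            continue
        for mat in gt_mats:
            if induced(mat, i, j, k, l) == c:
                score += 1
    return score


def external_astral_adapter(
    gene_trees: list[dendropy.Tree], binary_path
) -> SpeciesTreeEstimate:
    """Run an external ASTRAL-style binary on the gene trees.

    The binary must accept ``-i <input> -o <output>`` with one Newick gene
    tree per input line and write a Newick species tree. Never required:
    the built-in :func:`estimate_species_tree` covers all internal uses.
    """
    binary_path = Path(binary_path)
    if not binary_path.exists():
        raise FileNotFoundError(
            f"external species-tree binary not found at {binary_path}; "
            "use the built-in estimate_species_tree instead"
        )
    with tempfile.TemporaryDirectory() as tmp:
        inp = Path(tmp) / "gene_trees.nwk"
        out = Path(tmp) / "species_tree.nwk"
        inp.write_text("".join(write_newick(t) + "\n" for t in gene_trees))
        subprocess.run(
            [str(binary_path), "-i", str(inp), "-o", str(out)],
            check=True,
            capture_output=True,
        )
        tree = parse_newick(out.read_text())
    freqs = bipartition_frequencies(tree, gene_trees)
    return SpeciesTreeEstimate(
        tree=tree,
        supports=freqs,
        n_input_trees=len(gene_trees),
        metadata={"method": "external", "binary": str(binary_path)},
    )


def write_estimate(est: SpeciesTreeEstimate, tree_path, sidecar_path=None) -> None:
    """Write the Newick estimate plus a JSON sidecar with conventions."""
    Path(tree_path).write_text(est.as_newick() + "\n")
    if sidecar_path is not None:
        Path(sidecar_path).write_text(
            json.dumps(
                {
                    "n_input_trees": est.n_input_trees,
                    "support_convention": "gene-tree bipartition frequency in [0,1]",
                    **est.metadata,
                },
                indent=2,
            )
        )
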