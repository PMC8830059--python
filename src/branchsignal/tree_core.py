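"""Tree substrate: Newick I/O, bipartitions, midpoint rooting.

Gene trees are represented as :class:`dendropy.Tree` objects. Internal-node
labels are interpreted as branch supports on the 0-100 scale (the convention
used by likelihood tree software that writes SH-aLRT or bootstrap values as
the label immediately following a closing parenthesis). Branch lengths are
in expected substitutions per site and must be non-negative.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy

__all__ = [
    "Bipartition",
    "NewickError",
    "parse_newick",
    "write_newick",
    "read_gene_trees",
    "leaf_labels",
    "nontrivial_bipartitions",
    "bipartition_sides",
    "midpoint_root",
    "root_to_tip_distances",
    "edge_supports",
    "pairwise_path_lengths",
]


class NewickError(ValueError):
    """Raised for malformed or invalid Newick input."""


@dataclass(frozen=True)
class Bipartition:
    """A nontrivial split of the taxon set, in canonical form.

    ``side`` is the smaller half of the split (the lexicographically first
    sorted half on ties), so identical splits compare equal regardless of
    which side of the edge they were read from.
    """

    side: frozenset[str]
    taxa: frozenset[str]

    @staticmethod
    def from_side(side: Iterable[str], taxa: Iterable[str]) -> "Bipartition":
        side = frozenset(side)
        taxa = frozenset(taxa)
        other = taxa - side
        if len(other) < len(side) or (
            len(other) == len(side) and sorted(other) < sorted(side)
        ):
            side = other
        return Bipartition(side=side, taxa=taxa)

    def __iter__(self):
        return iter(self.side)


def _validate(tree: dendropy.Tree) -> dendropy.Tree:
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if any(not lb for lb in labels):
        raise NewickError("empty leaf label")
    dupes = {lb for lb in labels if labels.count(lb) > 1}
    if dupes:
        raise NewickError(f"duplicate leaf names: {sorted(dupes)}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise NewickError(
                f"negative branch length {edge.length} on edge above "
                f"{edge.head_node.taxon.label if edge.head_node.taxon else 'internal node'}"
            )
    for nd in tree.preorder_internal_node_iter():
        if nd.label is not None and nd.parent_node is not None:
            try:
                val = float(nd.label)
            except ValueError:
                continue
            if not (0.0 <= val <= 100.0):
                raise NewickError(f"support {val} outside [0, 100]")
    return tree


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a single Newick string into a gene tree.

    Internal-node labels are kept verbatim; :func:`edge_supports` interprets
    the numeric ones as supports in [0, 100].
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"malformed Newick: {exc}") from exc
    return _validate(tree)


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a gene tree; supports re-emitted as internal-node labels."""
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
    return s.strip()


def read_gene_trees(path) -> list[dendropy.Tree]:
    """Read gene trees from a file with one Newick tree per line.

    A file containing a single tree (possibly spread over several lines)
    is also accepted.
    """
    with open(path) as fh:
        text = fh.read()
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if all(ln.endswith(";") for ln in lines):
        return [parse_newick(ln) for ln in lines]
    return [parse_newick(text)]


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def bipartition_sides(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Canonical sides of all nontrivial splits, as a set of frozensets.

    This is the working representation used by the distance layer; the
    richer :class:`Bipartition` objects are built on top of it.
    """
    taxa = frozenset(leaf_labels(tree))
    n = len(taxa)
    out: set[frozenset[str]] = set()
    if n < 4:
        return out
    below: dict[int, frozenset[str]] = {}
    root = tree.seed_node
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            below[id(nd)] = frozenset([nd.taxon.label])
        else:
            below[id(nd)] = frozenset().union(*(below[id(c)] for c in nd.child_nodes()))
    for nd in tree.preorder_node_iter():
        if nd is root or nd.is_leaf():
            continue
        side = below[id(nd)]
        if len(side) < 2 or len(taxa - side) < 2:
            continue
        other = taxa - side
        if len(other) < len(side) or (
            len(other) == len(side) and sorted(other) < sorted(side)
        ):
            side = other
        out.add(side)
    return out


def nontrivial_bipartitions(tree: dendropy.Tree) -> set[Bipartition]:
    """One canonical :class:`Bipartition` per internal edge (n >= 4 leaves)."""
    taxa = frozenset(leaf_labels(tree))
    return {Bipartition(side=s, taxa=taxa) for s in bipartition_sides(tree)}


def pairwise_path_lengths(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths, keyed by sorted label pairs."""
    dists: dict[tuple[str, str], float] = {}
    # per-node list of (leaf label, distance to this node); combined bottom-up
    carry: dict[int, list[tuple[str, float]]] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            carry[id(nd)] = [(nd.taxon.label, 0.0)]
            continue
        lists = []
        for c in nd.child_nodes():
            bl = c.edge.length or 0.0
            lists.append([(lb, d + bl) for lb, d in carry.pop(id(c))])
        for i in range(len(lists)):
            for j in range(i + 1, len(lists)):
                for la, da in lists[i]:
                    for lb, db in lists[j]:
                        key = (la, lb) if la < lb else (lb, la)
                        dists[key] = da + db
        carry[id(nd)] = [x for lst in lists for x in lst]
    return dists


def _path_nodes(leaf_a, leaf_b) -> list:
    """Nodes on the path between two leaves, endpoints included."""
    anc_a = [leaf_a]
    nd = leaf_a
    while nd.parent_node is not None:
        nd = nd.parent_node
        anc_a.append(nd)
    seen = {id(n): i for i, n in enumerate(anc_a)}
    path_b = [leaf_b]
    nd = leaf_b
    while id(nd) not in seen:
        nd = nd.parent_node
        path_b.append(nd)
    mrca_idx = seen[id(nd)]
    # a ... mrca, then back down to b (mrca sits at the end of path_b too)
    return anc_a[: mrca_idx + 1] + path_b[-2::-1]


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Return a copy of ``tree`` rooted at the midpoint of its longest
    leaf-to-leaf path.

    Ties among leaf pairs attaining the maximal path length are broken by
    the lexicographically smallest sorted label pair. When the midpoint
    falls exactly on a node, the tree is rooted at that node (a degree-3
    root is allowed). Multifurcating input is handled like binary input.
    """
    tree = tree.clone(depth=1)
    dists = pairwise_path_lengths(tree)
    if not dists:
        raise ValueError("midpoint undefined: fewer than 2 leaves")
    dmax = max(dists.values())
    if dmax <= 0:
        raise ValueError("midpoint undefined: all path lengths are zero")
    pair = min(k for k, v in dists.items() if v == dmax)
    leaves = {lf.taxon.label: lf
              for lf in tree.leaf_node_iter()}
    a, b = leaves[pair[0]], leaves[pair[1]]
    path = _path_nodes(a, b)
    half = dmax / 2.0
    # walk from a toward b accumulating edge lengths
    acc = 0.0
    for prev, nxt in zip(path, path[1:]):
        if nxt.parent_node is prev:
            edge = nxt.edge
            head_is_next = True
        else:
            edge = prev.edge
            head_is_next = False
        length = edge.length or 0.0
        if acc + length >= half - 1e-12:
            offset = half - acc  # distance from prev along this edge
            if abs(offset) <= 1e-12:
                tree.reroot_at_node(prev, suppress_unifurcations=True,
                                    collapse_unrooted_basal_bifurcation=False)
                break
            if abs(offset - length) <= 1e-12:
                tree.reroot_at_node(nxt, suppress_unifurcations=True,
                                    collapse_unrooted_basal_bifurcation=False)
                break
            # dendropy: length1 -> fragment toward the original parent (tail),
            # length2 -> fragment toward the original child (head)
            if head_is_next:
                l_tail = offset
            else:
                l_tail = length - offset
            tree.reroot_at_edge(edge, length1=l_tail, length2=length - l_tail,
                                suppress_unifurcations=True)
            break
        acc += length
    else:  # pragma: no cover - numerically unreachable
        raise AssertionError("midpoint not found on maximal path")
    tree.is_rooted = True
    return tree


def root_to_tip_distances(tree: dendropy.Tree) -> dict[str, float]:
    """Sum of branch lengths from the root to each leaf."""
    out: dict[str, float] = {}
    depth: dict[int, float] = {id(tree.seed_node): 0.0}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            depth[id(nd)] = depth[id(nd.parent_node)] + (nd.edge.length or 0.0)
        if nd.is_leaf():
            out[nd.taxon.label] = depth[id(nd)]
    return out


def edge_supports(tree: dendropy.Tree) -> list[float]:
    """Numeric supports attached to internal edges, in preorder.

    Unlabeled internal edges are simply absent from the list; the root node's
    label (which does not correspond to an edge) is ignored.
    """
    vals = []
    for nd in tree.preorder_internal_node_iter():
        if nd.parent_node is None or nd.label is None:
            continue
        try:
            vals.append(float(nd.label))
        except ValueError:
            continue
    return vals
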