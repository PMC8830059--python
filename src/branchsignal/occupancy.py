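"""Joint taxon/locus selection for a fully occupied data matrix.

Phylogenomic datasets rarely have every locus sequenced for every taxon.
Before analysis, a common curation step picks a subset of taxa and loci
that maximizes (number of taxa) x (number of loci) subject to the chosen
loci being present for every chosen taxon ("full occupancy").

Two solvers are provided: an exact enumerator over taxon subsets (feasible
up to ~20 taxa thanks to a subset-sum sweep over presence bitmasks) and a
deterministic greedy peeler for larger matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["OccupancyMatrix", "SubsetSolution", "select_exact", "select_greedy"]


@dataclass
class OccupancyMatrix:
    """Loci-by-taxa presence indicators."""

    loci: list[str]
    taxa: list[str]
    presence: np.ndarray  # bool, shape (n_loci, n_taxa)

    def __post_init__(self):
        self.presence = np.asarray(self.presence, dtype=bool)
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("duplicate locus ids")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        if self.presence.shape != (len(self.loci), len(self.taxa)):
            raise ValueError("presence shape does not match loci/taxa")
        if not self.presence.any():
            raise ValueError("matrix has no present entries")

    @staticmethod
    def from_tsv(path) -> "OccupancyMatrix":
        """Read a 0/1 TSV with loci as rows and taxa as columns."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        return OccupancyMatrix(
            loci=[str(x) for x in df.index],
            taxa=[str(c) for c in df.columns],
            presence=df.values.astype(bool),
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            self.presence.astype(int), index=self.loci, columns=self.taxa
        ).to_csv(path, sep="\t")


@dataclass
class SubsetSolution:
    taxa: list[str]
    loci: list[str]
    objective: int
    method: str
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "taxa": self.taxa,
            "loci": self.loci,
            "n_taxa": len(self.taxa),
            "n_loci": len(self.loci),
            "objective": self.objective,
            "method": self.method,
        }


def _locus_masks(matrix: OccupancyMatrix) -> np.ndarray:
    weights = 1 << np.arange(len(matrix.taxa), dtype=np.int64)
    return (matrix.presence.astype(np.int64) * weights).sum(axis=1)


def select_exact(
    matrix: OccupancyMatrix, max_taxa_enumerable: int = 20
) -> SubsetSolution:
    """Globally optimal full-occupancy subset.

    For every taxon subset S the eligible loci are those present on all of
    S; the count of eligible loci for all 2^T subsets is obtained with a
    superset-sum sweep, and the objective |S| x |eligible| is maximized.
    Ties favor more taxa, then the lexicographically smallest taxon set.
    """
    T = len(matrix.taxa)
    if T > max_taxa_enumerable:
        raise ValueError(
            f"{T} taxa exceeds the exact-enumeration guard "
            f"({max_taxa_enumerable}); use select_greedy"
        )
    masks = _locus_masks(matrix)
    counts = np.zeros(1 << T, dtype=np.int64)
    np.add.at(counts, masks, 1)
    # superset sum: counts[S] <- number of loci whose mask is a superset of S
    for b in range(T):
        bit = 1 << b
        idx = np.arange(1 << T)
        lo = idx[(idx & bit) == 0]
        counts[lo] += counts[lo | bit]
    popcount = np.array([bin(s).count("1") for s in range(1 << T)], dtype=np.int64)
    objective = popcount * counts
    objective[0] = 0
    best = int(objective.max())
    cand = np.flatnonzero(objective == best)
    # prefer more taxa, then lexicographically smallest sorted taxon set
    maxpop = popcount[cand].max()
    cand = cand[popcount[cand] == maxpop]
    def label_key(s):
        return sorted(matrix.taxa[i] for i in range(T) if s & (1 << i))
    sel = min((int(s) for s in cand), key=label_key)
    taxa = label_key(sel)
    loci = [matrix.loci[i] for i in np.flatnonzero((masks & sel) == sel)]
    return SubsetSolution(taxa=taxa, loci=loci, objective=best, method="exact")


def select_greedy(matrix: OccupancyMatrix) -> SubsetSolution:
    """Deterministic greedy fallback for large matrices.

    Repeatedly removes the taxon or locus with the most missing entries
    (ties: taxa before loci, then lexicographic), recording the objective
    whenever the remaining matrix is complete; returns the best recorded
    full-occupancy solution. Never beats :func:`select_exact`.
    """
    pres = matrix.presence.copy()
    taxa = list(matrix.taxa)
    loci = list(matrix.loci)
    best: tuple[int, list[str], list[str]] | None = None
    while taxa and loci:
        miss = ~pres
        if not miss.any():
            obj = len(taxa) * len(loci)
            if best is None or obj > best[0]:
                best = (obj, list(taxa), list(loci))
            break
        taxon_missing = miss.sum(axis=0)
        locus_missing = miss.sum(axis=1)
        t_max, l_max = taxon_missing.max(), locus_missing.max()
        if t_max >= l_max:
            j = min(
                (j for j in range(len(taxa)) if taxon_missing[j] == t_max),
                key=lambda j: taxa[j],
            )
            taxa.pop(j)
            pres = np.delete(pres, j, axis=1)
        else:
            i = min(
                (i for i in range(len(loci)) if locus_missing[i] == l_max),
                key=lambda i: loci[i],
            )
            loci.pop(i)
            pres = np.delete(pres, i, axis=0)
        if taxa and loci and pres.all():
            obj = len(taxa) * len(loci)
            if best is None or obj > best[0]:
                best = (obj, list(taxa), list(loci))
    if best is None:
        # peeling emptied a dimension before completeness; any present cell
        # is a valid 1x1 full-occupancy solution
        i, j = min(
            map(tuple, np.argwhere(matrix.presence)),
            key=lambda ij: (matrix.taxa[ij[1]], matrix.loci[ij[0]]),
        )
        best = (1, [matrix.taxa[j]], [matrix.loci[i]])
    return SubsetSolution(
        taxa=sorted(best[1]), loci=best[2], objective=best[0], method="greedy"
    )
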