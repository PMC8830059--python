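"""Synthetic multi-dataset gene-tree generator.

Emulates the statistical structure the analysis pipeline assumes, without
any sequence data:

1. a Yule species tree per dataset, branch lengths in coalescent units;
2. per-locus gene trees drawn under the multispecies coalescent (one
   haploid sample per species, lineages coalescing at rate k(k-1)/2 within
   each species-tree branch);
3. per-locus among-lineage rate heterogeneity: every branch is multiplied
   by ``base_rate`` times an i.i.d. lognormal multiplier with log-SD
   sigma_l (mean 1), where sigma_l is drawn per locus — the knob that
   creates variation in root-to-tip distances;
4. topology-estimation error: k ~ Poisson(lambda0 + lambda1 * sigma_l)
   random NNI moves, encoding the empirical association between
   among-lineage rate variation and gene-tree conflict;
5. synthetic branch supports that decay with the number of applied errors:
   clip(s0 * exp(-beta * k) + N(0, noise_sd), 0, 100);
6. an optional independent-Bernoulli missingness mask over the locus-by-
   taxon presence matrix (trees themselves stay complete).

Seeding is hierarchical (master seed -> dataset -> locus) so any subset of
the output is reproducible in isolation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .tree_core import parse_newick, write_newick
from .tree_distance import normalized_rf

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_species_tree",
    "simulate_msc_gene_tree",
    "apply_lineage_rates",
    "apply_estimation_error",
    "attach_supports",
    "simulate_locus",
    "generate_dataset",
    "generate_datasets",
    "write_dataset",
]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic pipeline.

    Defaults give 10 16-taxon datasets of 200 loci under moderate ILS
    (Yule species trees stretched to 2 coalescent units per unit time)
    with locus rate heterogeneity sigma_l ~ U[0, 0.8] and error/support
    links (lambda0=0.5, lambda1=4, s0=98, beta=0.35) strong enough that
    rate-variable loci carry visibly degraded topologies and supports.
    """

    n_datasets: int = 10
    n_taxa: int = 16
    n_loci: int = 200
    birth_rate: float = 1.0  # per coalescent-time unit
    branch_scale: float = 2.0  # multiplies species-tree branch lengths
    sigma_min: float = 0.0  # locus rate-heterogeneity sigma_l ~ U[min, max]
    sigma_max: float = 0.8
    base_rate: float = 0.05  # substitutions/site per coalescent unit
    locus_rate_log_sd: float = 0.5  # lognormal spread of per-locus rates
    lambda0: float = 0.5  # baseline NNI error count
    lambda1: float = 4.0  # error-count slope on sigma_l
    s0: float = 98.0  # support of an error-free tree
    beta: float = 0.35  # support decay per NNI error
    support_noise_sd: float = 10.0
    missingness: float = 0.0  # Bernoulli probability a presence entry is 0
    seed: int = 0

    def validate(self) -> None:
        if min(self.birth_rate, self.branch_scale, self.base_rate) <= 0:
            raise ValueError("rates and scales must be positive")
        if self.sigma_min < 0 or self.sigma_max < self.sigma_min:
            raise ValueError("need 0 <= sigma_min <= sigma_max")
        if not (0 < self.s0 <= 100):
            raise ValueError("s0 must be in (0, 100]")
        if not (0 <= self.missingness <= 1):
            raise ValueError("missingness must be a probability")
        if self.lambda0 < 0 or self.lambda1 < 0:
            raise ValueError("error-link parameters must be >= 0")


@dataclass
class SimulatedDataset:
    dataset_id: str
    species_tree: dendropy.Tree  # coalescent units
    gene_trees: list[dendropy.Tree]  # observed: rates + error + supports
    true_gene_trees: list[dendropy.Tree]  # coalescent units, error-free
    locus_ids: list[str]
    sigma: np.ndarray  # per-locus sigma_l
    error_counts: np.ndarray  # per-locus applied NNI count k_l
    presence: np.ndarray  # loci x taxa occupancy mask
    taxa: list[str]
    seed: int
    truth: "np.ndarray | None" = field(default=None)  # per-locus nRF to true


# ---------------------------------------------------------------------------
# species tree


def simulate_species_tree(
    n_taxa: int,
    birth_rate: float = 1.0,
    seed: int | np.random.Generator = 0,
    branch_scale: float = 1.0,
) -> dendropy.Tree:
    """Ultrametric Yule tree with branch lengths in coalescent units."""
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # forward simulation: split times of a pure-birth process
    times = [0.0]
    t = 0.0
    for k in range(1, n_taxa):
        t += rng.exponential(1.0 / (birth_rate * k))
        times.append(t)
    total = t + rng.exponential(1.0 / (birth_rate * n_taxa))  # stem to present
    # grow the tree: at each event a uniformly chosen active tip splits
    root = _YuleNode(0.0)
    active = [root]
    for k in range(1, n_taxa):
        i = int(rng.integers(len(active)))
        nd = active.pop(i)
        nd.end = times[k]
        nd.children = [_YuleNode(times[k]), _YuleNode(times[k])]
        active.extend(nd.children)
    labels = [f"T{i+1}" for i in range(n_taxa)]
    rng.shuffle(labels)
    for nd, lab in zip(active, labels):
        nd.end = total
        nd.label = lab
    return parse_newick(_render_yule(root, branch_scale) + ";")


class _YuleNode:
    __slots__ = ("birth", "end", "children", "label")

    def __init__(self, birth: float):
        self.birth = birth
        self.end = birth
        self.children: list["_YuleNode"] = []
        self.label = ""


def _render_yule(node: _YuleNode, scale: float) -> str:
    length = (node.end - node.birth) * scale
    if not node.children:
        return f"{node.label}:{length:.17g}"
    inner = ",".join(_render_yule(c, scale) for c in node.children)
    return f"({inner}):{length:.17g}"


# ---------------------------------------------------------------------------
# multispecies coalescent


def simulate_msc_gene_tree(
    species_tree: dendropy.Tree, seed: int | np.random.Generator = 0
) -> dendropy.Tree:
    """One gene tree under the MSC, one haploid sample per species.

    Within each species-tree branch of duration t (coalescent units), the
    k lineages present coalesce at rate k(k-1)/2; survivors are passed to
    the parent branch, and everything coalesces above the root.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # node age = distance above the present (species tree is ultrametric)
    age: dict[int, float] = {}
    for nd in species_tree.postorder_node_iter():
        if nd.is_leaf():
            age[id(nd)] = 0.0
        else:
            kid_ages = [age[id(c)] + (c.edge.length or 0.0) for c in nd.child_nodes()]
            if max(kid_ages) - min(kid_ages) > 1e-6:
                raise ValueError(
                    "species tree must be ultrametric (tips contemporaneous)"
                )
            age[id(nd)] = kid_ages[0]
    # lineages: (newick fragment, age at which the fragment's root sits)
    pending: dict[int, list[tuple[str, float]]] = {}
    root = species_tree.seed_node
    for nd in species_tree.postorder_node_iter():
        if nd.is_leaf():
            lineages = [(nd.taxon.label, 0.0)]
        else:
            lineages = []
            for c in nd.child_nodes():
                lineages.extend(pending.pop(id(c)))
        t_now = age[id(nd)]
        t_end = np.inf if nd is root else t_now + (nd.edge.length or 0.0)
        while len(lineages) > 1:
            k = len(lineages)
            wait = rng.exponential(2.0 / (k * (k - 1)))
            if t_now + wait > t_end:
                break
            t_now += wait
            i, j = rng.choice(k, size=2, replace=False)
            i, j = (int(i), int(j)) if i < j else (int(j), int(i))
            (fa, ta), (fb, tb) = lineages[i], lineages[j]
            merged = (
                f"({fa}:{t_now - ta:.17g},{fb}:{t_now - tb:.17g})",
                t_now,
            )
            lineages = [l for x, l in enumerate(lineages) if x not in (i, j)]
            lineages.append(merged)
        pending[id(nd)] = lineages
    (frag, _), = pending[id(root)]
    return parse_newick(frag + ";")


# ---------------------------------------------------------------------------
# rates, error, supports


def apply_lineage_rates(
    tree: dendropy.Tree,
    sigma: float,
    base_rate: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> dendropy.Tree:
    """Rescale branches to substitutions/site with lognormal multipliers.

    Each branch is multiplied by ``base_rate * m`` with ``log m ~
    N(-sigma^2/2, sigma^2)`` so that E[m] = 1; sigma = 0 is a strict clock.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tree = tree.clone(depth=1)
    for e in tree.preorder_edge_iter():
        if e.head_node.parent_node is None or e.length is None:
            continue
        m = 1.0 if sigma == 0 else float(rng.lognormal(-sigma**2 / 2.0, sigma))
        e.length = e.length * base_rate * m
    return tree


def _internal_edges(tree: dendropy.Tree) -> list:
    """Edges whose removal splits the unrooted tree into two >=2-leaf parts."""
    n = sum(1 for _ in tree.leaf_node_iter())
    below = {}
    out = []
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            below[id(nd)] = 1
        else:
            below[id(nd)] = sum(below[id(c)] for c in nd.child_nodes())
        if nd.parent_node is None or nd.is_leaf():
            continue
        if 2 <= below[id(nd)] <= n - 2:
            out.append(nd.edge)
    return out


def _random_nni(tree: dendropy.Tree, rng: np.random.Generator) -> bool:
    """Apply one NNI at a uniformly chosen internal edge, in place."""
    edges = _internal_edges(tree)
    if not edges:
        return False
    edge = edges[int(rng.integers(len(edges)))]
    child = edge.head_node
    parent = edge.tail_node
    sub_child = child.child_nodes()
    sub_parent = [c for c in parent.child_nodes() if c is not child]
    if parent.parent_node is None and len(sub_parent) < 2:
        return False
    if not sub_child or not sub_parent:
        return False
    a = sub_child[int(rng.integers(len(sub_child)))]
    b = sub_parent[int(rng.integers(len(sub_parent)))]
    # swap subtrees a (below the edge) and b (beside the edge)
    child.remove_child(a)
    parent.remove_child(b)
    child.add_child(b)
    parent.add_child(a)
    return True


def apply_estimation_error(
    tree: dendropy.Tree,
    sigma: float,
    lambda0: float,
    lambda1: float,
    seed: int | np.random.Generator = 0,
) -> tuple[dendropy.Tree, int]:
    """Perturb the topology with k ~ Poisson(lambda0 + lambda1*sigma) NNIs.

    The returned tree is derooted (unrooted representation, as an estimated
    gene tree would be); branch lengths are left untouched by the swaps.
    """
    if lambda0 < 0 or lambda1 < 0:
        raise ValueError("lambda parameters must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tree = tree.clone(depth=1)
    if len(tree.seed_node.child_nodes()) == 2:
        tree.deroot()
    rate = lambda0 + lambda1 * sigma
    k = int(rng.poisson(rate)) if rate > 0 else 0
    applied = 0
    for _ in range(k):
        if _random_nni(tree, rng):
            applied += 1
    return tree, applied


def attach_supports(
    tree: dendropy.Tree,
    k: int,
    s0: float = 98.0,
    beta: float = 0.35,
    noise_sd: float = 3.0,
    seed: int | np.random.Generator = 0,
) -> dendropy.Tree:
    """Label internal edges with clip(s0*exp(-beta*k) + noise, 0, 100)."""
    if not (0 < s0 <= 100):
        raise ValueError("s0 must be in (0, 100]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tree = tree.clone(depth=1)
    center = s0 * np.exp(-beta * k)
    for nd in tree.preorder_internal_node_iter():
        if nd.parent_node is None:
            continue
        val = center + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        nd.label = f"{float(np.clip(val, 0.0, 100.0)):.6g}"
    return tree


# ---------------------------------------------------------------------------
# dataset assembly


def simulate_locus(
    species_tree: dendropy.Tree, sigma: float, config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[dendropy.Tree, dendropy.Tree, int]:
    """(true gene tree, observed gene tree with supports, error count)."""
    true = simulate_msc_gene_tree(species_tree, rng)
    locus_rate = config.base_rate * float(
        rng.lognormal(-config.locus_rate_log_sd**2 / 2, config.locus_rate_log_sd)
    )
    scaled = apply_lineage_rates(true, sigma, locus_rate, rng)
    observed, k = apply_estimation_error(
        scaled, sigma, config.lambda0, config.lambda1, rng
    )
    observed = attach_supports(
        observed, k, config.s0, config.beta, config.support_noise_sd, rng
    )
    return true, observed, k


def generate_dataset(
    config: SimulationConfig, dataset_index: int, seed_seq: np.random.SeedSequence
) -> SimulatedDataset:
    ds_seq, = seed_seq.spawn(1)
    rng_tree, rng_sigma, rng_mask = (
        np.random.default_rng(s) for s in ds_seq.spawn(3)
    )
    sp = simulate_species_tree(
        config.n_taxa, config.birth_rate, rng_tree, config.branch_scale
    )
    taxa = sorted(lf.taxon.label for lf in sp.leaf_node_iter())
    sigma = rng_sigma.uniform(config.sigma_min, config.sigma_max, config.n_loci)
    locus_seqs = ds_seq.spawn(config.n_loci)
    true_trees, obs_trees, ks = [], [], []
    for l in range(config.n_loci):
        rng_l = np.random.default_rng(locus_seqs[l])
        true, obs, k = simulate_locus(sp, float(sigma[l]), config, rng_l)
        true_trees.append(true)
        obs_trees.append(obs)
        ks.append(k)
    presence = rng_mask.random((config.n_loci, config.n_taxa)) >= config.missingness
    truth = np.array(
        [normalized_rf(o, t) for o, t in zip(obs_trees, true_trees)]
    )
    return SimulatedDataset(
        dataset_id=f"ds{dataset_index:02d}",
        species_tree=sp,
        gene_trees=obs_trees,
        true_gene_trees=true_trees,
        locus_ids=[f"ds{dataset_index:02d}_locus_{l:04d}" for l in range(config.n_loci)],
        sigma=sigma,
        error_counts=np.array(ks),
        presence=presence,
        taxa=taxa,
        seed=int(np.asarray(ds_seq.generate_state(1))[0] % (1 << 31)),
        truth=truth,
    )


def generate_datasets(
    config: SimulationConfig, out_dir=None
) -> list[SimulatedDataset]:
    """Simulate all datasets; optionally write them to per-dataset folders."""
    config.validate()
    master = np.random.SeedSequence(config.seed)
    ds_seqs = master.spawn(config.n_datasets)
    datasets = [
        generate_dataset(config, i, ds_seqs[i]) for i in range(config.n_datasets)
    ]
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "config.json").write_text(json.dumps(asdict(config), indent=2))
        for ds in datasets:
            write_dataset(ds, out_dir / ds.dataset_id)
    return datasets


def write_dataset(ds: SimulatedDataset, folder) -> None:
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    with open(folder / "gene_trees.nwk", "w") as fh:
        for t in ds.gene_trees:
            fh.write(write_newick(t) + "\n")
    (folder / "species_tree_true.nwk").write_text(write_newick(ds.species_tree) + "\n")
    import pandas as pd

    pd.DataFrame(
        ds.presence.astype(int), index=ds.locus_ids, columns=ds.taxa
    ).to_csv(folder / "presence.tsv", sep="\t")
    pd.DataFrame(
        {
            "locus": ds.locus_ids,
            "sigma": ds.sigma,
            "n_nni_errors": ds.error_counts,
            "nrf_to_true_gene_tree": ds.truth,
        }
    ).to_csv(folder / "truth.tsv", sep="\t", index=False)
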