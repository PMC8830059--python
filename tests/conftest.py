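import numpy as np
import pytest

from branchsignal.tree_core import parse_newick


def random_binary_newick(
    rng: np.random.Generator,
    n_leaves: int,
    ultrametric: bool = False,
    with_supports: bool = False,
) -> str:
    """Random binary tree by successive joins, exponential branch lengths."""
    if ultrametric:
        # coalescent-style: join two uniformly chosen lineages, add height
        frags = [(f"L{i}", 0.0) for i in range(n_leaves)]
        h = 0.0
        while len(frags) > 1:
            h += rng.exponential(1.0)
            i, j = sorted(rng.choice(len(frags), 2, replace=False))
            (fa, ha), (fb, hb) = frags[i], frags[j]
            frags = [f for x, f in enumerate(frags) if x not in (i, j)]
            frags.append((f"({fa}:{h - ha:.12g},{fb}:{h - hb:.12g})", h))
        return frags[0][0] + ";"
    frags = [f"L{i}:{rng.exponential(1.0):.12g}" for i in range(n_leaves)]
    while len(frags) > 2:
        i, j = sorted(rng.choice(len(frags), 2, replace=False))
        fa, fb = frags[i], frags[j]
        frags = [f for x, f in enumerate(frags) if x not in (i, j)]
        sup = f"{rng.integers(0, 101)}" if with_supports else ""
        frags.append(f"({fa},{fb}){sup}:{rng.exponential(1.0):.12g}")
    return f"({','.join(frags)});"


def random_binary_tree(rng, n_leaves, **kw):
    return parse_newick(random_binary_newick(rng, n_leaves, **kw))


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def worked_tree():
    """4-taxon fixture whose statistics are known by hand:
    5 branches, length 11, stemminess 1/10, midpoint-root-to-tip
    distances {A: 2.5, B: 3.5, C: 3.5, D: 3.5}."""
    return parse_newick("((A:1,B:2):1,C:3,D:4);")


@pytest.fixture(scope="session")
def small_datasets():
    """Two small simulated datasets shared by pipeline-level tests."""
    from branchsignal import SimulationConfig, generate_datasets

    cfg = SimulationConfig(n_datasets=2, n_taxa=10, n_loci=40, seed=42)
    return generate_datasets(cfg)


@pytest.fixture(scope="session")
def small_tables(small_datasets):
    from branchsignal.pipeline import analyze_simulated

    return [analyze_simulated(ds) for ds in small_datasets]
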