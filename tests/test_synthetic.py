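import filecmp

import numpy as np
import pytest

from branchsignal.branch_stats import cov_root_to_tip, tree_length
from branchsignal.synthetic import (
    SimulationConfig,
    apply_estimation_error,
    apply_lineage_rates,
    attach_supports,
    generate_datasets,
    simulate_msc_gene_tree,
    simulate_species_tree,
)
from branchsignal.tree_core import (
    edge_supports,
    leaf_labels,
    parse_newick,
    root_to_tip_distances,
    write_newick,
)
from branchsignal.tree_distance import normalized_rf


def cherry_labels(tree):
    for nd in tree.postorder_internal_node_iter():
        ch = nd.child_nodes()
        if len(ch) == 2 and all(c.is_leaf() for c in ch):
            return frozenset(c.taxon.label for c in ch)
    return None


class TestSpeciesTree:
    def test_rooted_binary_shape(self):
        t = simulate_species_tree(4, 1.0, 0)
        internals = [n for n in t.preorder_internal_node_iter()]
        assert len(internals) == 3
        assert all(len(n.child_nodes()) == 2 for n in internals)
        assert len(leaf_labels(t)) == 4

    def test_ultrametric(self):
        t = simulate_species_tree(12, 1.0, 3)
        d = root_to_tip_distances(t)
        assert max(d.values()) - min(d.values()) < 1e-9

    def test_seed_determinism(self):
        assert write_newick(simulate_species_tree(8, 1.0, 5)) == write_newick(
            simulate_species_tree(8, 1.0, 5)
        )

    def test_yule_depth_expectation(self):
        # with k lineages the next split waits Exp(b*k); the root-split-to-
        # present depth is therefore sum_{k=2}^{n} 1/(b*k) = H_n - 1 in
        # expectation (the stem above the root split carries the 1/1 term
        # and is not part of root-to-tip distances)
        rng = np.random.default_rng(0)
        n = 8
        heights = []
        for _ in range(500):
            t = simulate_species_tree(n, 1.0, rng)
            heights.append(max(root_to_tip_distances(t).values()))
        expect = sum(1.0 / k for k in range(2, n + 1))
        se = np.std(heights) / np.sqrt(len(heights))
        assert abs(np.mean(heights) - expect) < 4 * se


class TestMsc:
    def test_two_species_depth(self):
        two = parse_newick("(A:1.5,B:1.5);")
        rng = np.random.default_rng(1)
        depths = [
            max(root_to_tip_distances(simulate_msc_gene_tree(two, rng)).values())
            for _ in range(2000)
        ]
        se = np.std(depths) / np.sqrt(len(depths))
        assert abs(np.mean(depths) - 2.5) < 3 * se

    def test_deep_split_removes_ils(self):
        deep = parse_newick("((A:10,B:10):10,(C:10,D:10):10);")
        rng = np.random.default_rng(2)
        for _ in range(50):
            gt = simulate_msc_gene_tree(deep, rng)
            assert normalized_rf(gt, deep) == 0.0

    def test_three_taxon_discordance_rate(self):
        # P(gene tree != species tree) = (2/3) exp(-t) for internal branch t
        t = 0.5
        sp = parse_newick(f"((A:{t},B:{t}):{t},C:{2*t});")
        rng = np.random.default_rng(3)
        n = 5000
        mm = sum(
            cherry_labels(simulate_msc_gene_tree(sp, rng)) != frozenset("AB")
            for _ in range(n)
        )
        p = (2 / 3) * np.exp(-t)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(mm / n - p) < 3 * se

    def test_leaf_set_preserved(self):
        sp = simulate_species_tree(9, 1.0, 4)
        gt = simulate_msc_gene_tree(sp, 7)
        assert sorted(leaf_labels(gt)) == sorted(leaf_labels(sp))


class TestLineageRates:
    def test_clock_limit(self):
        sp = simulate_species_tree(8, 1.0, 0)
        gt = simulate_msc_gene_tree(sp, 1)
        scaled = apply_lineage_rates(gt, 0.0, 0.07, 2)
        assert tree_length(scaled) == pytest.approx(0.07 * tree_length(gt))
        assert cov_root_to_tip(scaled) == pytest.approx(0.0, abs=1e-9)

    def test_expected_tree_length(self):
        sp = simulate_species_tree(8, 1.0, 0)
        gt = simulate_msc_gene_tree(sp, 1)
        rng = np.random.default_rng(5)
        base = tree_length(gt)
        lengths = [
            tree_length(apply_lineage_rates(gt, 0.6, 1.0, rng)) for _ in range(1000)
        ]
        se = np.std(lengths) / np.sqrt(len(lengths))
        assert abs(np.mean(lengths) - base) < 3 * se

    def test_cov_increases_with_sigma(self):
        sp = simulate_species_tree(10, 1.0, 0)
        rng = np.random.default_rng(6)
        means = []
        for sigma in (0.0, 0.3, 0.8):
            vals = []
            for _ in range(150):
                gt = simulate_msc_gene_tree(sp, rng)
                vals.append(cov_root_to_tip(apply_lineage_rates(gt, sigma, 1, rng)))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestEstimationError:
    def test_zero_rate_is_identity(self):
        sp = simulate_species_tree(8, 1.0, 0)
        gt = simulate_msc_gene_tree(sp, 1)
        obs, k = apply_estimation_error(gt, 0.5, 0.0, 0.0, 2)
        assert k == 0
        assert normalized_rf(obs, gt) == 0.0

    def test_single_nni_on_five_taxa(self):
        rng = np.random.default_rng(7)
        base = parse_newick("(((A:1,B:1):1,C:1):1,(D:1,E:1):1);")
        seen = set()
        for _ in range(50):
            t = base.clone(depth=1)
            t.deroot()
            from branchsignal.synthetic import _random_nni

            assert _random_nni(t, rng)
            seen.add(normalized_rf(t, base))
        assert seen <= {0.5, 1.0}
        assert 0.5 in seen

    def test_poisson_error_count_mean(self):
        sp = simulate_species_tree(8, 1.0, 0)
        gt = simulate_msc_gene_tree(sp, 1)
        rng = np.random.default_rng(8)
        lam0, lam1, sigma = 0.5, 4.0, 0.4
        ks = [
            apply_estimation_error(gt, sigma, lam0, lam1, rng)[1]
            for _ in range(1000)
        ]
        mean = lam0 + lam1 * sigma
        se = np.sqrt(mean / len(ks))
        assert abs(np.mean(ks) - mean) < 3.5 * se

    def test_leaf_set_preserved(self):
        sp = simulate_species_tree(10, 1.0, 3)
        gt = simulate_msc_gene_tree(sp, 1)
        obs, _ = apply_estimation_error(gt, 0.8, 1.0, 4.0, 9)
        assert sorted(leaf_labels(obs)) == sorted(leaf_labels(gt))


class TestSupports:
    def test_error_free_noise_free(self):
        sp = simulate_species_tree(8, 1.0, 0)
        gt, _ = apply_estimation_error(simulate_msc_gene_tree(sp, 1), 0, 0, 0, 0)
        lab = attach_supports(gt, 0, s0=98.0, beta=0.35, noise_sd=0.0, seed=1)
        assert all(s == pytest.approx(98.0) for s in edge_supports(lab))

    def test_always_clipped(self):
        sp = simulate_species_tree(8, 1.0, 0)
        gt, _ = apply_estimation_error(simulate_msc_gene_tree(sp, 1), 0, 0, 0, 0)
        rng = np.random.default_rng(2)
        for k in (0, 3, 10):
            lab = attach_supports(gt, k, noise_sd=40.0, seed=rng)
            assert all(0 <= s <= 100 for s in edge_supports(lab))

    def test_mean_support_decreases_with_k(self):
        sp = simulate_species_tree(8, 1.0, 0)
        gt, _ = apply_estimation_error(simulate_msc_gene_tree(sp, 1), 0, 0, 0, 0)
        rng = np.random.default_rng(3)
        means = []
        for k in (0, 2, 5):
            vals = [
                np.mean(edge_supports(attach_supports(gt, k, seed=rng)))
                for _ in range(100)
            ]
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]


class TestGenerateDatasets:
    def test_counts_and_files(self, tmp_path):
        cfg = SimulationConfig(n_datasets=2, n_taxa=6, n_loci=8, seed=1)
        out = tmp_path / "sim"
        dss = generate_datasets(cfg, out_dir=out)
        assert len(dss) == 2
        for ds in dss:
            assert len(ds.gene_trees) == 8
            assert ds.presence.shape == (8, 6)
            assert all(
                sorted(leaf_labels(t)) == ds.taxa for t in ds.gene_trees
            )
        assert (out / "ds00" / "gene_trees.nwk").read_text().count(";") == 8
        assert (out / "config.json").exists()
        assert (out / "ds01" / "truth.tsv").exists()

    def test_byte_identical_reruns(self, tmp_path):
        cfg = SimulationConfig(n_datasets=2, n_taxa=6, n_loci=6, seed=9)
        generate_datasets(cfg, out_dir=tmp_path / "a")
        generate_datasets(cfg, out_dir=tmp_path / "b")
        for ds in ("ds00", "ds01"):
            for fn in ("gene_trees.nwk", "species_tree_true.nwk", "presence.tsv",
                       "truth.tsv"):
                assert filecmp.cmp(
                    tmp_path / "a" / ds / fn, tmp_path / "b" / ds / fn,
                    shallow=False,
                ), fn

    def test_missingness_mask_only(self):
        cfg = SimulationConfig(
            n_datasets=1, n_taxa=8, n_loci=30, seed=2, missingness=0.3
        )
        ds = generate_datasets(cfg)[0]
        frac_missing = 1 - ds.presence.mean()
        assert 0.15 < frac_missing < 0.45
        # trees remain complete regardless of the mask
        assert all(len(leaf_labels(t)) == 8 for t in ds.gene_trees)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(sigma_min=0.5, sigma_max=0.1).validate()
        with pytest.raises(ValueError):
            SimulationConfig(s0=0).validate()
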