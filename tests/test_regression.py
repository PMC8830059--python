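import numpy as np
import pandas as pd
import pytest
import scipy.stats

from branchsignal.regression import (
    POOLED_PREDICTORS,
    ols_fit,
    one_way_anova,
    per_dataset_models,
    pooled_model,
    tukey_hsd,
)


def normal_equations(X, y, w=None):
    """Independent oracle: solve (X'WX) b = X'Wy directly."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    W = np.diag(w) if w is not None else np.eye(len(y))
    return np.linalg.solve(X.T @ W @ X, X.T @ W @ y)


def synth_tables(rng, n_datasets=3, n_loci=50, noise=0.05, beta_cov=0.3,
                 beta_sup=-0.002):
    """Small synthetic stats/distance tables with known coefficients."""
    rows_s, rows_d = [], []
    for d in range(n_datasets):
        offset = rng.normal(0, 0.1)
        for l in range(n_loci):
            cov = rng.uniform(0, 1)
            mbl = rng.uniform(0.01, 0.2)
            stem = rng.uniform(0, 1)
            sup = rng.uniform(20, 100)
            tl = mbl * 17
            resp = (
                0.3 + offset + beta_cov * cov + beta_sup * sup
                + rng.normal(0, noise)
            )
            locus = f"d{d}_l{l:03d}"
            rows_s.append(
                dict(dataset=f"d{d}", locus=locus, cov_rtt=cov,
                     mean_branch_length=mbl, tree_length=tl, stemminess=stem,
                     mean_support=sup, n_taxa=10 + d)
            )
            rows_d.append(
                dict(dataset=f"d{d}", locus=locus,
                     nrf_to_species_tree=np.clip(resp, 0, 1),
                     mean_nrf_to_gene_trees=np.clip(resp + 0.01, 0, 1))
            )
    return pd.DataFrame(rows_s), pd.DataFrame(rows_d)


class TestOlsFit:
    def test_exact_line(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0]})
        res = ols_fit(X, [0.0, 2.0, 4.0])
        assert res.coefficients["x"] == pytest.approx(2.0)
        assert res.coefficients["const"] == pytest.approx(0.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0)

    def test_flat_fit(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0]})
        res = ols_fit(X, [0.0, 1.0, 0.0])
        assert res.coefficients["x"] == pytest.approx(0.0, abs=1e-12)
        assert res.coefficients["const"] == pytest.approx(1 / 3)
        assert res.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(100):
            n, p = int(rng.integers(8, 25)), int(rng.integers(1, 4))
            X = pd.DataFrame(
                rng.normal(size=(n, p)), columns=[f"x{i}" for i in range(p)]
            )
            y = rng.normal(size=n)
            w = rng.uniform(0.5, 2.0, size=n)
            res = ols_fit(X, y, weights=w)
            Xi = np.column_stack([np.ones(n), X.values])
            expect = normal_equations(Xi, y, w)
            assert res.coefficients.values == pytest.approx(expect, abs=1e-8)
            # t = coef / SE identity
            assert res.t_statistics.values == pytest.approx(
                (res.coefficients / res.std_errors).values
            )

    def test_residual_orthogonality(self, rng):
        n = 30
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        y = rng.normal(size=n)
        res = ols_fit(X, y)
        Xi = np.column_stack([np.ones(n), X.values])
        resid = y - Xi @ res.coefficients.values
        assert np.abs(Xi.T @ resid).max() < 1e-9

    def test_rank_deficiency_names_columns(self, rng):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        with pytest.raises(ValueError, match="collinear"):
            ols_fit(X, [1.0, 2, 3, 4])


class TestPooledModel:
    def test_noiseless_recovery(self, rng):
        stats, dist = synth_tables(rng, noise=0.0)
        # rebuild an exactly linear (unclipped) response
        dist = dist.copy()
        offsets = {"d0": 0.0, "d1": 0.05, "d2": -0.04}
        dist["nrf_to_species_tree"] = (
            0.3
            + stats["dataset"].map(offsets).values
            + 0.25 * stats["cov_rtt"].values
        )
        res = pooled_model(stats, dist)
        assert res.coefficients["cov_rtt"] == pytest.approx(0.25, abs=1e-8)
        assert res.r_squared == pytest.approx(1.0)

    def test_sign_recovery_with_noise(self, rng):
        stats, dist = synth_tables(rng, n_loci=80, noise=0.03)
        res = pooled_model(stats, dist)
        assert res.t_statistics["cov_rtt"] > 0
        assert res.p_values["cov_rtt"] < 0.05
        assert res.t_statistics["mean_support"] < 0
        assert res.p_values["mean_support"] < 0.05

    def test_weighting_matches_wls_oracle(self, rng):
        stats, dist = synth_tables(rng)
        res = pooled_model(stats, dist, weighting="by-dataset-size")
        df = stats.merge(dist, on=["dataset", "locus"])
        X = pd.concat(
            [
                df[POOLED_PREDICTORS],
                pd.get_dummies(df["dataset"], prefix="ds", drop_first=True,
                               dtype=float),
            ],
            axis=1,
        )
        Xi = np.column_stack([np.ones(len(df)), X.values])
        w = df.groupby("dataset")["locus"].transform("count").values.astype(float)
        expect = normal_equations(Xi, df["nrf_to_species_tree"].values, w)
        got = np.concatenate(
            [[res.coefficients["const"]],
             [res.coefficients[c] for c in X.columns]]
        )
        assert got == pytest.approx(expect, abs=1e-8)

    def test_frisch_waugh_within_transformation(self, rng):
        # dataset-dummy coefficients equal within-dataset-centered OLS
        stats, dist = synth_tables(rng)
        res = pooled_model(stats, dist)
        df = stats.merge(dist, on=["dataset", "locus"])
        Xc = df[POOLED_PREDICTORS] - df.groupby("dataset")[
            POOLED_PREDICTORS
        ].transform("mean")
        yc = df["nrf_to_species_tree"] - df.groupby("dataset")[
            "nrf_to_species_tree"
        ].transform("mean")
        Xi = Xc.values
        beta = np.linalg.lstsq(Xi, yc.values, rcond=None)[0]
        got = np.array([res.coefficients[c] for c in POOLED_PREDICTORS])
        assert got == pytest.approx(beta, abs=1e-8)

    def test_requires_multiple_datasets(self, rng):
        stats, dist = synth_tables(rng, n_datasets=1)
        with pytest.raises(ValueError):
            pooled_model(stats, dist)


class TestPerDatasetModels:
    def test_two_models_per_dataset(self, rng):
        stats, dist = synth_tables(rng, n_datasets=3)
        results = per_dataset_models(stats, dist)
        assert len(results) == 6
        assert {r.response for r in results} == {
            "nrf_to_species_tree",
            "mean_nrf_to_gene_trees",
        }

    def test_exact_tree_length_response(self, rng):
        stats, dist = synth_tables(rng, n_datasets=2)
        dist = dist.copy()
        dist["nrf_to_species_tree"] = 2.0 * stats["tree_length"].values
        results = [
            r for r in per_dataset_models(stats, dist)
            if r.response == "nrf_to_species_tree"
        ]
        for r in results:
            assert r.r_squared == pytest.approx(1.0)
            t_abs = r.t_statistics[PER_DATASET_COLS].abs()
            assert t_abs.idxmax() == "tree_length"

    def test_small_dataset_skipped(self, rng):
        stats, dist = synth_tables(rng, n_datasets=2, n_loci=4)
        assert per_dataset_models(stats, dist) == []


PER_DATASET_COLS = ["cov_rtt", "tree_length", "stemminess", "mean_support"]


class TestAnova:
    def test_identical_groups(self):
        r = one_way_anova([np.ones(4), np.ones(4)])
        assert r.f_statistic == 0.0

    def test_hand_computed_f(self):
        r = one_way_anova([np.array([1.0, 2, 3]), np.array([4.0, 5, 6])])
        assert r.f_statistic == pytest.approx(13.5)
        assert (r.df_between, r.df_within) == (1, 4)
        expect_p = scipy.stats.f.sf(13.5, 1, 4)
        assert r.p_value == pytest.approx(expect_p)

    def test_scale_invariance(self, rng):
        groups = [rng.normal(size=6), rng.normal(1, 1, size=8)]
        f1 = one_way_anova(groups).f_statistic
        f2 = one_way_anova([2 * g for g in groups]).f_statistic
        assert f1 == pytest.approx(f2)


class TestTukey:
    def test_identical_groups_p_one(self):
        r = tukey_hsd([np.ones(5), np.ones(5), np.ones(5)])
        assert all(p == pytest.approx(1.0) for p in r.p_adjusted)

    def test_separated_groups(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(10, 1, 10)
        r = tukey_hsd([a, b])
        assert r.p_adjusted[0] < 1e-3
        assert abs(r.mean_differences[0]) == pytest.approx(
            abs(a.mean() - b.mean())
        )

    def test_adjusted_p_not_below_pairwise_t(self, rng):
        groups = [rng.normal(0, 1, 8), rng.normal(0.5, 1, 8), rng.normal(1, 1, 8)]
        r = tukey_hsd(groups)
        for (i, j), p_adj in zip(r.pairs, r.p_adjusted):
            _, p_t = scipy.stats.ttest_ind(groups[i], groups[j])
            assert p_adj >= p_t - 1e-9
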