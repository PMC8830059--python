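"""Regression and group-comparison statistics.

The central analysis regresses each per-locus discordance response
(normalized RF to the reference species tree, or mean normalized RF to the
other gene trees) on the four branch statistics. The pooled model spans
all datasets with per-dataset intercepts absorbing between-dataset
differences (tree length enters as the mean branch length so values are
comparable across datasets of different sizes); per-dataset models use raw
tree length. A weighted variant weights each locus by the size of its
source dataset. Filtering outcomes are compared with one-way ANOVA and
Tukey's HSD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "RegressionResult",
    "AnovaResult",
    "TukeyResult",
    "ols_fit",
    "pooled_model",
    "per_dataset_models",
    "one_way_anova",
    "tukey_hsd",
    "POOLED_PREDICTORS",
    "PER_DATASET_PREDICTORS",
]

logger = logging.getLogger(__name__)

POOLED_PREDICTORS = ["cov_rtt", "mean_branch_length", "stemminess", "mean_support"]
PER_DATASET_PREDICTORS = ["cov_rtt", "tree_length", "stemminess", "mean_support"]


@dataclass
class RegressionResult:
    response: str
    predictors: list[str]
    coefficients: pd.Series
    std_errors: pd.Series
    t_statistics: pd.Series
    p_values: pd.Series
    r_squared: float
    n_obs: int
    weighting: str = "none"
    dataset_effects: bool = False
    dataset: str | None = None

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coefficient": self.coefficients,
                "std_error": self.std_errors,
                "t": self.t_statistics,
                "p": self.p_values,
            }
        )


@dataclass
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    group_means: list[float]


@dataclass
class TukeyResult:
    pairs: list[tuple[int, int]]
    mean_differences: list[float]
    q_statistics: list[float]
    p_adjusted: list[float]
    alpha: float = 0.05

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pair": self.pairs,
                "mean_difference": self.mean_differences,
                "q": self.q_statistics,
                "p_adjusted": self.p_adjusted,
            }
        )


def _check_rank(X: pd.DataFrame) -> None:
    arr = np.asarray(X, dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name columns involved in the deficiency via pivoted QR
        from scipy.linalg import qr

        _, r, piv = qr(arr, pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(arr.shape) * np.finfo(float).eps if diag.size else 0
        bad = [X.columns[piv[i]] for i in range(arr.shape[1]) if i >= rank or diag[i] <= tol]
        raise ValueError(f"rank-deficient design; collinear columns include {bad}")


def ols_fit(
    design: pd.DataFrame,
    response,
    weights=None,
    response_name: str = "response",
    add_intercept: bool = True,
) -> RegressionResult:
    """(Weighted) least squares with classical SEs and two-sided p-values."""
    X = design.copy()
    y = np.asarray(response, dtype=float)
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")
    if not np.all(np.isfinite(X.values)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in design or response")
    _check_rank(X)
    if weights is None:
        fit = sm.OLS(y, X).fit()
        tag = "none"
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
        fit = sm.WLS(y, X, weights=w).fit()
        tag = "custom"
    return RegressionResult(
        response=response_name,
        predictors=[c for c in X.columns if c != "const"],
        coefficients=fit.params,
        std_errors=fit.bse,
        t_statistics=fit.tvalues,
        p_values=fit.pvalues,
        r_squared=float(fit.rsquared),
        n_obs=int(fit.nobs),
        weighting=tag,
    )


def _merge(stats: pd.DataFrame, distances: pd.DataFrame) -> pd.DataFrame:
    on = ["locus", "dataset"] if "dataset" in stats.columns and "dataset" in distances.columns else ["locus"]
    return stats.merge(distances, on=on, how="inner")


def pooled_model(
    stats: pd.DataFrame,
    distances: pd.DataFrame,
    response: str = "nrf_to_species_tree",
    weighting: str = "none",
) -> RegressionResult:
    """Pooled regression across datasets with dataset-intercept effects.

    ``stats`` must carry a ``dataset`` column labelling each locus's source
    dataset. Predictors: cov_rtt, mean_branch_length, stemminess,
    mean_support. ``weighting='by-dataset-size'`` weights each locus by the
    number of loci in its source dataset (``'by-taxa'`` uses the dataset's
    taxon count instead). Reported t-statistics for the four predictors are
    the quantities of interest; dataset intercepts are nuisance terms.
    """
    df = _merge(stats, distances)
    if "dataset" not in df.columns:
        raise ValueError("stats table must have a 'dataset' column")
    df = df.dropna(subset=POOLED_PREDICTORS + [response])
    datasets = sorted(df["dataset"].unique())
    if len(datasets) < 2:
        raise ValueError("pooled model needs >= 2 datasets")
    for p in POOLED_PREDICTORS:
        if df.groupby("dataset")[p].nunique().max() <= 1:
            raise ValueError(f"predictor {p} is constant within every dataset")
    X = df[POOLED_PREDICTORS].copy()
    dummies = pd.get_dummies(df["dataset"], prefix="ds", drop_first=True, dtype=float)
    X = pd.concat([X, dummies], axis=1)
    if weighting == "none":
        w = None
    elif weighting == "by-dataset-size":
        w = df.groupby("dataset")["locus"].transform("count").astype(float).values
    elif weighting == "by-taxa":
        if "n_taxa" not in df.columns:
            raise ValueError("by-taxa weighting needs an 'n_taxa' column")
        w = df.groupby("dataset")["n_taxa"].transform("max").astype(float).values
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    res = ols_fit(X, df[response].values, weights=w, response_name=response)
    res.weighting = weighting
    res.dataset_effects = True
    res.predictors = POOLED_PREDICTORS
    return res


def per_dataset_models(
    stats: pd.DataFrame,
    distances: pd.DataFrame,
    min_loci: int = 6,
) -> list[RegressionResult]:
    """Two models (one per response) for each dataset.

    Predictors: cov_rtt, raw tree_length, stemminess, mean_support. Loci
    with any missing value are dropped listwise (counts logged); datasets
    with fewer than ``min_loci`` complete loci are skipped with a warning.
    """
    df = _merge(stats, distances)
    if "dataset" not in df.columns:
        df = df.assign(dataset="dataset_0")
    out: list[RegressionResult] = []
    responses = ["nrf_to_species_tree", "mean_nrf_to_gene_trees"]
    for ds, sub in df.groupby("dataset", sort=True):
        complete = sub.dropna(subset=PER_DATASET_PREDICTORS + responses)
        if len(complete) < len(sub):
            logger.info(
                "dataset %s: dropped %d incomplete loci", ds, len(sub) - len(complete)
            )
        if len(complete) < min_loci:
            logger.warning("dataset %s: only %d loci; skipped", ds, len(complete))
            continue
        for resp in responses:
            res = ols_fit(
                complete[PER_DATASET_PREDICTORS],
                complete[resp].values,
                response_name=resp,
            )
            res.dataset = str(ds)
            out.append(res)
    return out


def one_way_anova(groups: list[np.ndarray]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA (F = MSB/MSW)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    k = len(groups)
    n = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb, dfw = k - 1, n - k
    scale = max(float(np.mean(np.concatenate(groups) ** 2)), 1.0)
    tol = 1e-12 * scale
    if ssw <= tol:
        f = 0.0 if ssb <= tol else float("inf")
        p = 1.0 if ssb <= tol else 0.0
    else:
        f = (ssb / dfb) / (ssw / dfw)
        p = float(scipy.stats.f.sf(f, dfb, dfw))
    return AnovaResult(
        f_statistic=float(f),
        df_between=dfb,
        df_within=dfw,
        p_value=p,
        group_means=[float(g.mean()) for g in groups],
    )


def tukey_hsd(groups: list[np.ndarray], alpha: float = 0.05) -> TukeyResult:
    """Tukey HSD pairwise contrasts with studentized-range adjusted p."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = scipy.stats.tukey_hsd(*groups)
    n = sum(len(g) for g in groups)
    k = len(groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    msw = ssw / (n - k) if n > k else 0.0
    pairs, diffs, qs, ps = [], [], [], []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(res.statistic[i, j])
            se = np.sqrt(msw / 2 * (1 / len(groups[i]) + 1 / len(groups[j])))
            q = abs(diff) / se if se > 0 else (0.0 if diff == 0 else float("inf"))
            p = float(res.pvalue[i, j])
            if np.isnan(p):  # zero within-group variance
                p = 1.0 if diff == 0 else 0.0
            pairs.append((i, j))
            diffs.append(diff)
            qs.append(float(q))
            ps.append(p)
    return TukeyResult(
        pairs=pairs, mean_differences=diffs, q_statistics=qs, p_adjusted=ps, alpha=alpha
    )
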