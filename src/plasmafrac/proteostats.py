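"""Label-free differential proteomics: filtering, MNAR imputation, S0-moderated
permutation testing and descriptive analyses.

The workflow mirrors common practice for log2 LFQ intensity matrices:

1. keep proteins with valid values in at least a fraction (default 66.67 %)
   of the replicates of at least one group;
2. impute remaining missing values from a down-shifted normal distribution
   (missing values are assumed missing-not-at-random, i.e. low abundance);
3. test group differences with a two-sample statistic whose standard error
   is damped by a constant S0 (default 0.1), and estimate q-values by
   permuting group labels and pooling the permuted statistics across
   proteins;
4. describe the data with correlation matrices, PCA, hierarchical
   clustering (1 - Pearson or Manhattan distance), kernel-density plots of
   per-protein differences, and z-score trajectories.

The filter, imputer and test are scikit-learn style estimators
(``fit``/``transform``, fitted attributes with trailing underscores) so they
compose with sklearn pipelines; the module-level functions are thin wrappers.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

__all__ = [
    "TestConfig",
    "ValidValueFilter",
    "MNARImputer",
    "PermutationTTest",
    "CorrelationSummary",
    "ClusterTree",
    "filter_valid",
    "impute_missing",
    "moderated_t",
    "permutation_fdr",
    "correlation_summary",
    "pca_scores",
    "hcluster",
    "difference_density",
    "zscore_series",
]


@dataclass(frozen=True)
class TestConfig:
    """Parameters of the differential-testing workflow.

    ``s0`` regularizes the test statistic's denominator; ``min_valid_fraction``
    is the per-group valid-value requirement of the filter;
    ``imputation_downshift``/``imputation_width`` are in units of the per-sample
    standard deviation.  When the number of distinct group-label splits is at
    most ``exhaustive_limit`` (or not larger than ``n_permutations``) the
    permutation null is enumerated exactly instead of sampled.
    """

    s0: float = 0.1
    min_valid_fraction: float = 2.0 / 3.0
    n_permutations: int = 250
    fdr_alpha: float = 0.05
    imputation_width: float = 0.3
    imputation_downshift: float = 1.8
    seed: int = 0
    exhaustive_limit: int = 10_000

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_valid_fraction <= 1.0):
            raise ValueError("min_valid_fraction must be in [0, 1]")
        if self.n_permutations < 10:
            raise ValueError("n_permutations must be >= 10")
        if self.s0 < 0:
            raise ValueError("s0 must be >= 0")
        if not (0.0 < self.fdr_alpha < 1.0):
            raise ValueError("fdr_alpha must be in (0, 1)")


# ---------------------------------------------------------------------------
# valid-value filter
# ---------------------------------------------------------------------------

class ValidValueFilter(BaseEstimator, TransformerMixin):
    """Keep features valid in at least ``min_valid_fraction`` of one group.

    A value is valid when it is not NaN.  The comparison carries a 1e-9
    tolerance so that e.g. 4/6 replicates passes a 66.67 % threshold.
    """

    def __init__(self, min_valid_fraction: float = 2.0 / 3.0):
        self.min_valid_fraction = min_valid_fraction

    def fit(self, X: pd.DataFrame, y: pd.Series | None = None) -> "ValidValueFilter":
        if y is None:
            raise ValueError("group labels (y) are required")
        groups = pd.Series(y, index=X.columns) if not isinstance(y, pd.Series) else y
        keep = np.zeros(len(X), dtype=bool)
        for g in groups.unique():
            cols = groups.index[groups == g]
            frac = X[cols].notna().sum(axis=1) / len(cols)
            keep |= (frac >= self.min_valid_fraction - 1e-9).to_numpy()
        self.keep_mask_ = keep
        self.features_ = X.index[keep]
        self.n_features_in_ = len(X)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X.loc[X.index.intersection(self.features_)]


def filter_valid(matrix: pd.DataFrame, groups: pd.Series, cfg: TestConfig | None = None) -> pd.DataFrame:
    """Functional wrapper over :class:`ValidValueFilter`."""
    cfg = cfg or TestConfig()
    return ValidValueFilter(cfg.min_valid_fraction).fit(matrix, groups).transform(matrix)


# ---------------------------------------------------------------------------
# MNAR imputation
# ---------------------------------------------------------------------------

class MNARImputer(BaseEstimator, TransformerMixin):
    """Impute missing log2 intensities from a down-shifted normal distribution.

    For each sample column with observed mean m and standard deviation s,
    missing values are drawn from ``Normal(m - downshift * s, width * s)`` —
    the conventional model for abundance-dependent dropout.  With
    ``per_matrix=True`` the moments are computed over the whole matrix
    instead of per column.
    """

    def __init__(self, width: float = 0.3, downshift: float = 1.8,
                 seed: int = 0, per_matrix: bool = False):
        self.width = width
        self.downshift = downshift
        self.seed = seed
        self.per_matrix = per_matrix

    def fit(self, X: pd.DataFrame, y=None) -> "MNARImputer":
        if self.per_matrix:
            observed = X.to_numpy().ravel()
            observed = observed[~np.isnan(observed)]
            if observed.size == 0:
                raise ValueError("matrix has no observed values")
            self.means_ = pd.Series(float(np.mean(observed)), index=X.columns)
            self.sds_ = pd.Series(float(np.std(observed, ddof=1)), index=X.columns)
        else:
            if X.isna().all(axis=0).any():
                bad = list(X.columns[X.isna().all(axis=0)])
                raise ValueError(f"columns with no observed values: {bad}")
            self.means_ = X.mean(axis=0)
            self.sds_ = X.std(axis=0, ddof=1)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        rng = np.random.default_rng(self.seed)
        out = X.copy()
        for col in X.columns:
            mask = out[col].isna()
            n_missing = int(mask.sum())
            if n_missing == 0:
                continue
            loc = self.means_[col] - self.downshift * self.sds_[col]
            scale = self.width * self.sds_[col]
            out.loc[mask, col] = rng.normal(loc, scale, size=n_missing)
        return out


def impute_missing(matrix: pd.DataFrame, cfg: TestConfig | None = None,
                   per_matrix: bool = False) -> pd.DataFrame:
    """Functional wrapper over :class:`MNARImputer`."""
    cfg = cfg or TestConfig()
    imputer = MNARImputer(cfg.imputation_width, cfg.imputation_downshift,
                          seed=cfg.seed, per_matrix=per_matrix)
    return imputer.fit(matrix).transform(matrix)


# ---------------------------------------------------------------------------
# S0-moderated statistic and permutation FDR
# ---------------------------------------------------------------------------

def moderated_t(a, b, s0: float = 0.1) -> float:
    """Two-sample statistic with an S0-damped pooled standard error.

    ``t_s0 = (mean(a) - mean(b)) / (s0 + SE_pooled)``; with ``s0 = 0`` this is
    the classical equal-variance two-sample t statistic.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    se = math.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    if se == 0.0 and s0 == 0.0:
        raise ZeroDivisionError("zero variance with s0 = 0; set s0 > 0 to regularize")
    return float((a.mean() - b.mean()) / (s0 + se))


def _t_matrix(X: np.ndarray, masks: np.ndarray, s0: float) -> np.ndarray:
    """S0-moderated statistics for every feature under every column split.

    ``X`` is features x samples, ``masks`` is splits x samples (True = group
    A).  Returns splits x features.
    """
    na = masks.sum(axis=1).astype(float)  # (P,)
    nb = masks.shape[1] - na
    M = masks.astype(float)
    s1 = X @ M.T  # features x P, group-A sums
    q1 = (X**2) @ M.T
    s_tot = X.sum(axis=1, keepdims=True)
    q_tot = (X**2).sum(axis=1, keepdims=True)
    s2 = s_tot - s1
    q2 = q_tot - q1
    mean_a = s1 / na
    mean_b = s2 / nb
    ss_a = q1 - s1**2 / na
    ss_b = q2 - s2**2 / nb
    pooled_var = np.maximum(ss_a + ss_b, 0.0) / (na + nb - 2)
    se = np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_a - mean_b) / (s0 + se)
    return t.T


def _label_splits(idx_a: np.ndarray, idx_b: np.ndarray, cfg: TestConfig,
                  rng: np.random.Generator) -> tuple[np.ndarray, bool]:
    """Boolean masks of group-A column assignments under the permutation null."""
    pool = np.concatenate([idx_a, idx_b])
    n, na = pool.size, idx_a.size
    n_distinct = math.comb(n, na)
    if n_distinct < 10:
        warnings.warn(
            f"only {n_distinct} distinct label splits; permutation null is coarse",
            stacklevel=3,
        )
    exhaustive = n_distinct <= max(cfg.exhaustive_limit, 0) or n_distinct <= cfg.n_permutations
    if exhaustive:
        combos = itertools.combinations(range(n), na)
        masks = np.zeros((n_distinct, n), dtype=bool)
        for i, combo in enumerate(combos):
            masks[i, list(combo)] = True
    else:
        masks = np.zeros((cfg.n_permutations, n), dtype=bool)
        for i in range(cfg.n_permutations):
            masks[i, rng.choice(n, size=na, replace=False)] = True
    return masks, exhaustive


def permutation_fdr(matrix: pd.DataFrame, groups: pd.Series, group_a: str,
                    group_b: str, cfg: TestConfig | None = None) -> pd.DataFrame:
    """Differential test with permutation-based q-values.

    For each feature i, the q-value compares how many statistics across the
    permuted matrices reach ``|t_i|`` (averaged over permutations, pooled
    over all features) with how many observed statistics reach it, and is
    then made monotone by a cumulative minimum running from the least to the
    most significant feature.

    Returns a DataFrame indexed by feature with columns ``diff`` (group A
    minus group B mean), ``t`` (S0-moderated statistic), ``q`` and
    ``significant`` (q < ``cfg.fdr_alpha``).
    """
    cfg = cfg or TestConfig()
    result = PermutationTTest(
        group_a=group_a, group_b=group_b, s0=cfg.s0,
        n_permutations=cfg.n_permutations, alpha=cfg.fdr_alpha,
        exhaustive_limit=cfg.exhaustive_limit, seed=cfg.seed,
    ).fit(matrix, groups)
    return result.results_


class PermutationTTest(BaseEstimator):
    """S0-moderated two-group test with pooled permutation FDR (sklearn-style).

    Fitted attributes: ``results_`` (DataFrame: diff, t, q, significant),
    ``n_splits_`` (number of label splits used) and ``exhaustive_`` (whether
    the null was enumerated exactly).
    """

    def __init__(self, group_a: str = "A", group_b: str = "B", s0: float = 0.1,
                 n_permutations: int = 250, alpha: float = 0.05,
                 exhaustive_limit: int = 10_000, seed: int = 0):
        self.group_a = group_a
        self.group_b = group_b
        self.s0 = s0
        self.n_permutations = n_permutations
        self.alpha = alpha
        self.exhaustive_limit = exhaustive_limit
        self.seed = seed

    def fit(self, X: pd.DataFrame, y: pd.Series) -> "PermutationTTest":
        groups = pd.Series(y, index=X.columns) if not isinstance(y, pd.Series) else y
        if X.isna().any().any():
            raise ValueError("matrix contains missing values; filter and impute first")
        cols = list(X.columns)
        idx_a = np.array([i for i, c in enumerate(cols) if groups[c] == self.group_a])
        idx_b = np.array([i for i, c in enumerate(cols) if groups[c] == self.group_b])
        if idx_a.size < 2 or idx_b.size < 2:
            raise ValueError("both groups need at least 2 samples")
        sub = X.to_numpy(dtype=float)[:, np.concatenate([idx_a, idx_b])]
        na = idx_a.size
        obs_mask = np.zeros((1, sub.shape[1]), dtype=bool)
        obs_mask[0, :na] = True

        cfg = TestConfig(s0=self.s0, n_permutations=self.n_permutations,
                         fdr_alpha=self.alpha, exhaustive_limit=self.exhaustive_limit,
                         seed=self.seed)
        rng = np.random.default_rng(self.seed)
        t_obs = _t_matrix(sub, obs_mask, self.s0)[0]
        diff = sub[:, :na].mean(axis=1) - sub[:, na:].mean(axis=1)

        masks, exhaustive = _label_splits(np.arange(na), np.arange(na, sub.shape[1]),
                                          cfg, rng)
        t_perm = _t_matrix(sub, masks, self.s0)
        n_splits = masks.shape[0]

        abs_obs = np.abs(t_obs)
        sorted_obs = np.sort(abs_obs)
        sorted_perm = np.sort(np.abs(t_perm).ravel())
        m = abs_obs.size
        # counts of statistics >= |t_i| (pooled over features); the threshold
        # is slackened by a relative 1e-9 so that float jitter cannot flip
        # boundary cases (e.g. a statistic failing to count itself)
        thresh = abs_obs * (1.0 - 1e-9) - 1e-12
        n_obs_ge = m - np.searchsorted(sorted_obs, thresh, side="left")
        n_perm_ge = (sorted_perm.size - np.searchsorted(sorted_perm, thresh, side="left"))
        q_raw = np.minimum((n_perm_ge / n_splits) / np.maximum(n_obs_ge, 1), 1.0)
        # monotonize: cumulative minimum from least to most significant
        order = np.argsort(abs_obs, kind="stable")  # ascending |t|
        q = np.empty_like(q_raw)
        running = np.inf
        for i in order:
            running = min(running, q_raw[i])
            q[i] = running
        results = pd.DataFrame(
            {"diff": diff, "t": t_obs, "q": q, "significant": q < self.alpha},
            index=X.index,
        )
        self.results_ = results
        self.n_splits_ = n_splits
        self.exhaustive_ = exhaustive
        return self


# ---------------------------------------------------------------------------
# descriptive analyses
# ---------------------------------------------------------------------------

@dataclass
class CorrelationSummary:
    """Pairwise sample correlations with within/between-group medians."""

    matrix: pd.DataFrame
    method: str
    within: dict[str, tuple[float, float]] = field(default_factory=dict)
    between: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)


def correlation_summary(matrix: pd.DataFrame, groups: pd.Series,
                        method: Literal["pearson", "spearman"] = "pearson") -> CorrelationSummary:
    """Pairwise sample correlations on features observed in both samples.

    Pairs sharing fewer than 3 observed features are flagged missing (NaN).
    Within-group and between-group medians (with standard deviations) are
    computed over the off-diagonal coefficients.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    corr = matrix.corr(method=method, min_periods=3)
    summary = CorrelationSummary(matrix=corr, method=method)
    labels = groups.loc[corr.index]
    uniq = list(dict.fromkeys(labels))
    arr = corr.to_numpy()
    for i, g1 in enumerate(uniq):
        for g2 in uniq[i:]:
            rows = np.where(labels.to_numpy() == g1)[0]
            cols = np.where(labels.to_numpy() == g2)[0]
            vals = []
            for r in rows:
                for c in cols:
                    if g1 == g2 and c <= r:
                        continue
                    vals.append(arr[r, c])
            vals = np.asarray(vals, dtype=float)
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                continue
            stat = (float(np.median(vals)), float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0)
            if g1 == g2:
                summary.within[g1] = stat
            else:
                summary.between[(g1, g2)] = stat
    return summary


def pca_scores(matrix: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on centered features.

    Returns sample scores (samples x components) and the explained-variance
    proportions, which sum to 1 over the returned components.
    """
    if matrix.isna().any().any():
        raise ValueError("matrix contains missing values; impute first")
    X = matrix.T.to_numpy(dtype=float)  # samples x features
    pca = PCA()
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (
        pd.DataFrame(scores, index=matrix.columns, columns=cols),
        pca.explained_variance_ratio_,
    )


@dataclass
class ClusterTree:
    """Agglomerative merge tree: scipy linkage matrix plus leaf labels."""

    linkage: np.ndarray
    labels: list[str]
    distance: str
    method: str


def hcluster(matrix: pd.DataFrame,
             distance: Literal["one_minus_pearson", "manhattan"] = "one_minus_pearson",
             method: Literal["average", "ward"] = "average",
             items: Literal["samples", "features"] = "samples") -> ClusterTree:
    """Hierarchical clustering of samples (or features) of an intensity matrix.

    ``one_minus_pearson`` uses 1 - r as the dissimilarity; items with zero
    variance have no defined correlation and are placed at the maximum
    distance (2.0) with a warning.
    """
    data = matrix.T if items == "samples" else matrix
    if data.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    X = data.to_numpy(dtype=float)
    if distance == "one_minus_pearson":
        sds = X.std(axis=1)
        if np.any(sds == 0):
            warnings.warn("constant item(s) under Pearson distance; distance set to max (2.0)")
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(X)
        dist = 1.0 - corr
        dist[np.isnan(dist)] = 2.0
        np.fill_diagonal(dist, 0.0)
        dist = np.maximum(dist, 0.0)
        condensed = squareform(dist, checks=False)
    elif distance == "manhattan":
        condensed = squareform(
            np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2), checks=False
        )
    else:
        raise ValueError(f"unknown distance {distance!r}")
    Z = _scipy_linkage(condensed, method=method)
    return ClusterTree(linkage=Z, labels=list(data.index.astype(str)),
                       distance=distance, method=method)


def difference_density(means_a, means_b, n_grid: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Kernel density of per-feature mean differences (A - B).

    Gaussian KDE with Scott's bandwidth rule; the returned curve integrates
    to 1 within 1e-3 over the grid (which extends 4 bandwidths past the data
    range).  At least 5 matched features are required.
    """
    a = np.asarray(means_a, dtype=float)
    b = np.asarray(means_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("mean vectors must be matched")
    diffs = a - b
    if diffs.size < 5:
        raise ValueError("need at least 5 features for a density estimate")
    if np.allclose(diffs, diffs[0]):
        # degenerate: all differences identical; KDE bandwidth would be zero
        spread = max(abs(diffs[0]), 1.0) * 1e-3
        grid = np.linspace(diffs[0] - 4 * spread, diffs[0] + 4 * spread, n_grid)
        dens = stats.norm.pdf(grid, loc=diffs[0], scale=spread)
        return grid, dens
    kde = stats.gaussian_kde(diffs, bw_method="scott")
    bw = kde.factor * diffs.std(ddof=1)
    grid = np.linspace(diffs.min() - 4 * bw, diffs.max() + 4 * bw, n_grid)
    return grid, kde(grid)


def zscore_series(values) -> np.ndarray:
    """Standardize an ordered series to mean 0 and unit (ddof=1) sd.

    A constant series yields all zeros with a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        warnings.warn("constant series; z-scores set to 0")
        return np.zeros_like(x)
    return (x - x.mean()) / sd
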