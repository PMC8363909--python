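"""Small-RNA landscape statistics: filtering, normalization, differential
expression, biotype composition, tRNA codon-usage profiles, permutation GSEA
and exact Mann-Whitney testing.

Count matrices are integer features x samples tables with a companion
annotation (biotype, tRNA amino-acid isotype, essentiality flag) and
sample -> group labels.  Normalization uses median-of-ratios size factors;
differential expression is a documented simplified negative-binomial Wald
test (method-of-moments dispersion) with the usual DE call criteria
(|log2FC| >= 1 and BH-adjusted p <= 0.05).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "filter_features",
    "size_factors",
    "normalize_counts",
    "nb_wald_test",
    "biotype_composition",
    "codon_usage_profile",
    "gsea_classic",
    "GSEAResult",
    "mannwhitney_exact",
    "read_gmt",
    "write_gmt",
]


def filter_features(counts: pd.DataFrame, groups: pd.Series,
                    any_group: bool = True) -> pd.DataFrame:
    """Remove features not observed in at least half of one group's samples.

    A feature is kept iff some group has count >= 1 in at least
    ``ceil(group_size / 2)`` of its samples (all-zero features always go).
    With ``any_group=False`` the requirement applies to *every* group
    instead — the stricter reading of the same rule.
    """
    keep_per_group = []
    for g in groups.unique():
        cols = groups.index[groups == g]
        need = math.ceil(len(cols) / 2)
        keep_per_group.append((counts[cols] >= 1).sum(axis=1) >= need)
    stacked = pd.concat(keep_per_group, axis=1)
    keep = stacked.any(axis=1) if any_group else stacked.all(axis=1)
    keep &= counts.sum(axis=1) > 0
    return counts.loc[keep]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors.

    Each sample's factor is the median of its ratios to the per-feature
    geometric means, computed over features with nonzero counts in all
    samples.  If no such feature exists, falls back to library-size scaling
    (factors proportional to column sums, geometric mean 1) with a warning.
    """
    X = counts.to_numpy(dtype=float)
    all_nonzero = (X > 0).all(axis=1)
    if not all_nonzero.any():
        warnings.warn("no feature with nonzero counts in all samples; "
                      "falling back to library-size scaling")
        libsize = X.sum(axis=0)
        if np.any(libsize == 0):
            raise ValueError("sample with zero total counts")
        factors = libsize / stats.gmean(libsize)
    else:
        logX = np.log(X[all_nonzero])
        log_geomeans = logX.mean(axis=1, keepdims=True)
        factors = np.exp(np.median(logX - log_geomeans, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts divided by their sample size factors."""
    factors = size_factors(counts) if factors is None else factors
    return counts / factors


def nb_wald_test(counts: pd.DataFrame, groups: pd.Series, group_a: str, group_b: str,
                 lfc_threshold: float = 1.0, alpha: float = 0.05) -> pd.DataFrame:
    """Simplified negative-binomial Wald differential-expression test.

    Per feature: log2 fold change of normalized group means (pseudo-count
    0.5), a pooled method-of-moments NB dispersion (var = mu + alpha mu^2),
    a delta-method standard error for the log2 ratio, a two-sided Wald p,
    Benjamini-Hochberg adjustment, and a DE flag requiring
    ``|log2FC| >= lfc_threshold`` and adjusted p <= ``alpha``.

    This is a deliberately lightweight stand-in for a full shrinkage-based
    NB model; the DE call criteria themselves are the conventional ones.
    """
    cols_a = groups.index[groups == group_a]
    cols_b = groups.index[groups == group_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("both groups need at least 2 samples")
    factors = size_factors(counts[list(cols_a) + list(cols_b)])
    norm = counts[list(cols_a) + list(cols_b)] / factors
    A = norm[cols_a].to_numpy(dtype=float)
    B = norm[cols_b].to_numpy(dtype=float)
    na, nb = A.shape[1], B.shape[1]
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    var_a = A.var(axis=1, ddof=1)
    var_b = B.var(axis=1, ddof=1)

    # pooled method-of-moments dispersion: alpha = (s^2 - mu) / mu^2
    with np.errstate(divide="ignore", invalid="ignore"):
        disp_a = (var_a - mean_a) / mean_a**2
        disp_b = (var_b - mean_b) / mean_b**2
    disp = np.nanmean(np.stack([disp_a, disp_b]), axis=0)
    disp = np.clip(np.nan_to_num(disp, nan=0.0), 0.0, None)

    log2fc = np.log2(mean_a + 0.5) - np.log2(mean_b + 0.5)
    # delta method on log2(mean + 0.5); NB variance of the group mean
    var_mean_a = (mean_a + disp * mean_a**2) / na
    var_mean_b = (mean_b + disp * mean_b**2) / nb
    ln2sq = math.log(2.0) ** 2
    se = np.sqrt(
        var_mean_a / ((mean_a + 0.5) ** 2 * ln2sq)
        + var_mean_b / ((mean_b + 0.5) ** 2 * ln2sq)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = log2fc / se
    z = np.nan_to_num(z, nan=0.0, posinf=np.inf, neginf=-np.inf)
    p = 2.0 * stats.norm.sf(np.abs(z))
    padj = multipletests(p, method="fdr_bh")[1]
    de = (np.abs(log2fc) >= lfc_threshold) & (padj <= alpha)
    return pd.DataFrame(
        {"log2fc": log2fc, "p": p, "padj": padj, "de": de}, index=counts.index
    )


def biotype_composition(counts: pd.DataFrame, annotation: pd.DataFrame,
                        groups: pd.Series, exclude: set[str] | None = None) -> pd.DataFrame:
    """Per-group proportion of summed counts by biotype.

    Biotypes in ``exclude`` (e.g. ribosomal reads) are dropped before
    computing proportions, which then sum to 1 per group.
    """
    missing = counts.index.difference(annotation.index)
    if len(missing) > 0:
        raise KeyError(f"{len(missing)} features lack biotype annotation")
    exclude = exclude or set()
    biotype = annotation.loc[counts.index, "biotype"]
    keep = ~biotype.isin(exclude)
    rows = {}
    for g in groups.unique():
        cols = groups.index[groups == g]
        sums = counts.loc[keep, cols].sum(axis=1).groupby(biotype[keep]).sum()
        rows[g] = sums / sums.sum()
    return pd.DataFrame(rows).fillna(0.0)


def codon_usage_profile(counts: pd.DataFrame, annotation: pd.DataFrame,
                        groups: pd.Series, group1: str, group2: str,
                        min_presence: float = 2.0 / 3.0) -> pd.DataFrame:
    """tRNA codon-usage (amino-acid isotype) proportions and fold changes.

    Size-factor-normalized tRNA counts are pooled by amino-acid isotype
    within each group.  Only isotypes detected (pooled raw count >= 1) in at
    least ``min_presence`` of *all* samples are included.  Proportions are
    relative to the included isotypes and sum to 1 per group; the fold
    change is group1 proportion / group2 proportion.  Isotypes absent from
    one group after filtering get an undefined (NaN) fold change and a
    warning.

    Returns a DataFrame indexed by amino acid with columns ``prop_<group1>``,
    ``prop_<group2>``, ``fold_change`` and ``essential``.
    """
    trna = annotation.loc[counts.index.intersection(annotation.index)]
    trna = trna[trna["biotype"] == "tRNA"]
    if trna.empty:
        raise ValueError("no annotated tRNA features in the matrix")
    sub = counts.loc[trna.index]
    iso = trna["isotype"]
    if (iso == "").any():
        raise ValueError("tRNA features without an amino-acid isotype")

    pooled_raw = sub.groupby(iso).sum()  # isotype x samples, raw counts
    presence = (pooled_raw >= 1).sum(axis=1) / pooled_raw.shape[1]
    included = presence.index[presence >= min_presence - 1e-9]

    factors = size_factors(counts[groups.index])
    norm = sub / factors
    pooled = norm.groupby(iso).sum().loc[included]

    out = {}
    for g in (group1, group2):
        cols = groups.index[groups == g]
        total = pooled[cols].sum(axis=1)
        out[f"prop_{g}"] = total / total.sum()
    profile = pd.DataFrame(out)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = profile[f"prop_{group1}"] / profile[f"prop_{group2}"]
    fc[profile[f"prop_{group2}"] == 0] = np.nan
    fc[profile[f"prop_{group1}"] == 0] = np.nan
    if fc.isna().any():
        warnings.warn("isotype(s) absent from one group; fold change undefined for them")
    profile["fold_change"] = fc
    if "essential" in trna.columns:
        ess = trna.drop_duplicates("isotype").set_index("isotype")["essential"]
        profile["essential"] = ess.reindex(profile.index)
    return profile


# ---------------------------------------------------------------------------
# classic-ES permutation GSEA
# ---------------------------------------------------------------------------

@dataclass
class GSEAResult:
    """Classic enrichment score with its permutation normalization."""

    set_name: str
    es: float
    nes: float
    p: float
    n_permutations: int
    n_hits: int


def _running_es(is_hit: np.ndarray) -> float:
    """Signed maximum deviation of the unweighted running sum."""
    n = is_hit.size
    nh = int(is_hit.sum())
    steps = np.where(is_hit, 1.0 / nh, -1.0 / (n - nh))
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def gsea_classic(ranked: list[str], gene_set: set[str] | frozenset[str] | list[str],
                 n_permutations: int = 1000, seed: int = 0,
                 set_name: str = "gene_set") -> GSEAResult:
    """Unweighted (classic) running-sum gene-set enrichment on a ranked list.

    The running sum gains 1/Nh at each gene-set hit and loses 1/(N - Nh) at
    each miss while walking down the ranking; ES is the signed maximum
    deviation (in [-1, 1]).  The null permutes which positions are hits
    (gene-label permutation); NES divides ES by the mean magnitude of
    same-sign permuted scores and the permutation p is the same-sign
    exceedance fraction with add-one smoothing.
    """
    gene_set = set(gene_set)
    ranked_arr = np.asarray(ranked, dtype=object)
    n = ranked_arr.size
    is_hit = np.isin(ranked_arr, list(gene_set))
    nh = int(is_hit.sum())
    if nh < 2:
        raise ValueError("gene set overlaps the ranked list in fewer than 2 features")
    if nh == n:
        raise ValueError("gene set covers the entire ranked list")
    es = _running_es(is_hit)

    rng = np.random.default_rng(seed)
    perm_es = np.empty(n_permutations)
    positions = np.arange(n)
    for i in range(n_permutations):
        perm_hit = np.zeros(n, dtype=bool)
        perm_hit[rng.choice(positions, size=nh, replace=False)] = True
        perm_es[i] = _running_es(perm_hit)

    same_sign = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
    if same_sign.size == 0:
        nes = math.nan
        p = 1.0 / (n_permutations + 1)
    else:
        nes = es / float(np.mean(np.abs(same_sign)))
        p = (1 + int(np.sum(np.abs(same_sign) >= abs(es)))) / (same_sign.size + 1)
    return GSEAResult(set_name=set_name, es=es, nes=nes, p=p,
                      n_permutations=n_permutations, n_hits=nh)


# ---------------------------------------------------------------------------
# exact Mann-Whitney
# ---------------------------------------------------------------------------

def mannwhitney_exact(x, y, enumeration_limit: int = 20) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test, exact by enumeration for small samples.

    For ``n1 + n2 <= enumeration_limit`` the null distribution of U is built
    from all C(n1+n2, n1) group assignments of the pooled (tie-averaged)
    ranks; the two-sided p is the probability of a U at least as far from
    its null mean as observed.  Larger samples fall back to the
    tie-corrected normal approximation.  Returns ``(U1, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    if np.unique(pooled).size == 1:
        warnings.warn("all values tied; p = 1")
        return float(u1), 1.0
    if n1 + n2 <= enumeration_limit:
        mu = n1 * n2 / 2.0
        obs_dev = abs(u1 - mu)
        count = 0
        total = 0
        base = n1 * (n1 + 1) / 2.0
        for combo in itertools.combinations(range(n1 + n2), n1):
            u = ranks[list(combo)].sum() - base
            if abs(u - mu) >= obs_dev - 1e-12:
                count += 1
            total += 1
        return float(u1), count / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# GMT gene-set files
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, tuple[str, ...]]:
    """Parse a GMT file into {set name: member tuple} (descriptions dropped)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = tuple(g for g in parts[2:] if g)
    return sets


def write_gmt(sets: dict, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")
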