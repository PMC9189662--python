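"""Normalization, negative-binomial differential abundance, and signature logic.

Counts are normalized with median-of-ratios size factors (the DESeq approach:
``s_j = median_i c_ij / geomean_i`` over features with all-positive rows).
Differential abundance is a negative-binomial Wald test: per-feature
dispersions are estimated by method of moments on normalized counts, floored,
and shrunk toward a mean-dispersion trend fitted across features; the Wald
statistic is the log2 fold change over its delta-method standard error;
Benjamini-Hochberg adjustment runs over the features that pass a
minimum-count filter.

On top of the per-contrast results sit the signature operations: direction-
stratified significant sets, multi-set overlap partitions, knockout-
dependence classification (a feature is e.g. 'induced' when it responds to a
stressor in wild-type but no longer does in the knockout), AGO2-dependence
(significantly decreased upon knockout), cross-species conserved sets, and
the replicate-wise tracking filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .naming import parse_name

__all__ = [
    "size_factors",
    "normalize_counts",
    "de_test",
    "SignatureSet",
    "signature",
    "overlap_signatures",
    "ko_dependence",
    "ago2_dependent",
    "conserved_cross_species",
    "tracking_filter",
]

MIN_DISPERSION = 1e-8


def size_factors(counts: pd.DataFrame, allow_pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors.

    Features with a zero count in any sample are excluded from the median.
    If no all-positive feature exists, either raise (default) or fall back to
    a pseudo-reference over features positive in at least half the samples
    (``allow_pseudo_reference=True``).
    """
    if counts.shape[1] < 2:
        raise ValueError("size factors require at least two samples")
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        if not allow_pseudo_reference:
            raise ValueError(
                "no feature has positive counts in every sample; rerun with "
                "allow_pseudo_reference=True to use a pseudo-reference"
            )
        positive = (mat > 0).sum(axis=1) >= mat.shape[1] / 2
        if not positive.any():
            raise ValueError("counts too sparse for size-factor estimation")
    sub = mat[positive]
    with np.errstate(divide="ignore", invalid="ignore"):
        # nanmean so the pseudo-reference path averages positive entries only
        log_geomeans = np.nanmean(np.log(np.where(sub > 0, sub, np.nan)), axis=1)
    sf = []
    for j in range(sub.shape[1]):
        with np.errstate(divide="ignore"):
            ratios = np.log(sub[:, j]) - log_geomeans
        ratios = ratios[np.isfinite(ratios)]
        if ratios.size == 0:
            raise ValueError(f"cannot estimate size factor for sample {counts.columns[j]}")
        sf.append(np.exp(np.median(ratios)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, sf: pd.Series) -> pd.DataFrame:
    return counts / sf


def _dispersion_trend(means: np.ndarray, disps: np.ndarray) -> np.ndarray:
    """Fit ``disp ~ a0 + a1/mean`` (the standard parametric NB trend)."""
    ok = (means > 0) & (disps > MIN_DISPERSION * 10)
    if ok.sum() < 10:
        level = float(np.median(disps[disps > 0])) if (disps > 0).any() else MIN_DISPERSION
        return np.full_like(means, max(level, MIN_DISPERSION))
    X = np.column_stack([np.ones(ok.sum()), 1.0 / means[ok]])
    coef, *_ = np.linalg.lstsq(X, disps[ok], rcond=None)
    a0, a1 = max(coef[0], 0.0), max(coef[1], 0.0)
    if a0 == 0.0 and a1 == 0.0:
        a0 = float(np.median(disps[ok]))
    trend = a0 + a1 / np.maximum(means, 1e-8)
    return np.maximum(trend, MIN_DISPERSION)


def de_test(
    counts: pd.DataFrame,
    sf: pd.Series,
    groups: pd.Series,
    alpha: float = 0.05,
    min_total_norm: float = 10.0,
    shrink_weight: float = 0.6,
    prior_df: float = 8.0,
) -> pd.DataFrame:
    """Two-group NB Wald test on normalized counts.

    ``groups`` maps sample names to exactly two levels; the log2 fold change
    is level2 vs level1 in sorted label order.  Features whose total
    normalized count falls below ``min_total_norm`` are excluded from
    testing and from the BH family (their p/padj are NaN).  ``shrink_weight``
    is the weight on the fitted trend when shrinking per-feature moment
    dispersions (log scale).

    Returns a DataFrame with columns ``baseMean, log2FoldChange, lfcSE,
    dispersion, stat, pvalue, padj, tested``.
    """
    groups = groups.reindex(counts.columns)
    levels = sorted(groups.dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two group levels, got {levels}")
    for lev in levels:
        if (groups == lev).sum() < 2:
            raise ValueError(f"group {lev!r} has fewer than 2 replicates")
    a_cols = groups[groups == levels[0]].index
    b_cols = groups[groups == levels[1]].index

    norm = normalize_counts(counts, sf)
    qa = norm[a_cols].to_numpy(dtype=float)
    qb = norm[b_cols].to_numpy(dtype=float)
    na, nb = qa.shape[1], qb.shape[1]
    mu_a, mu_b = qa.mean(axis=1), qb.mean(axis=1)
    base_mean = norm.mean(axis=1).to_numpy()

    # pooled within-group moment dispersion on normalized counts
    ss = ((qa - mu_a[:, None]) ** 2).sum(axis=1) + ((qb - mu_b[:, None]) ** 2).sum(axis=1)
    df = na + nb - 2
    var_pooled = ss / df
    mu_bar = (na * mu_a + nb * mu_b) / (na + nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp_raw = (var_pooled - mu_bar) / np.where(mu_bar > 0, mu_bar**2, np.nan)
    disp_raw = np.where(np.isfinite(disp_raw), disp_raw, MIN_DISPERSION)
    disp_raw = np.maximum(disp_raw, MIN_DISPERSION)

    # arithmetic shrinkage toward the trend: with few replicates the moment
    # estimate often collapses to the floor, and averaging on the log scale
    # would let those floors dominate
    trend = _dispersion_trend(mu_bar, disp_raw)
    disp = (1 - shrink_weight) * disp_raw + shrink_weight * trend

    # Wald statistic via delta method on log2 group means (0.5 pseudocount
    # stabilizes empty groups)
    pa, pb = mu_a + 0.5, mu_b + 0.5
    lfc = np.log2(pb) - np.log2(pa)
    var_log2_a = (pa + disp * pa**2) / (na * pa**2) / np.log(2) ** 2
    var_log2_b = (pb + disp * pb**2) / (nb * pb**2) / np.log(2) ** 2
    se = np.sqrt(var_log2_a + var_log2_b)
    stat = np.where(se > 0, lfc / se, 0.0)
    # moderated t reference: the shrunk dispersion borrows strength from the
    # trend fitted across all features, so its effective df is the residual
    # df plus a prior df contribution (a plain normal reference is visibly
    # anticonservative at n=3, a plain t at the residual df overcorrects)
    pvalue = 2.0 * stats.t.sf(np.abs(stat), df=df + prior_df)

    tested = norm.sum(axis=1).to_numpy() >= min_total_norm
    padj = np.full(len(counts), np.nan)
    if tested.any():
        padj[tested] = multipletests(pvalue[tested], method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FoldChange": lfc,
            "lfcSE": se,
            "dispersion": disp,
            "stat": stat,
            "pvalue": np.where(tested, pvalue, np.nan),
            "padj": padj,
            "tested": tested,
        },
        index=counts.index,
    )
    return out


@dataclass
class SignatureSet:
    """Direction-stratified significant feature sets for one contrast."""

    condition: str
    up: set = field(default_factory=set)
    down: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("a feature cannot be both up and down")


def signature(de: pd.DataFrame, condition: str = "", alpha: float = 0.05) -> SignatureSet:
    """Significant up/down sets at ``padj < alpha``."""
    sig = de["padj"] < alpha
    up = set(de.index[sig & (de["log2FoldChange"] > 0)])
    down = set(de.index[sig & (de["log2FoldChange"] < 0)])
    return SignatureSet(condition=condition, up=up, down=down)


def overlap_signatures(sets: list[SignatureSet]) -> pd.DataFrame:
    """Venn partition of >= 2 signature sets, up and down tracked separately.

    One row per direction and nonempty membership pattern, with the member
    conditions, the exclusive feature list, and its size.
    """
    if len(sets) < 2:
        raise ValueError("need at least two signature sets")
    rows = []
    for direction in ("up", "down"):
        members = {s.condition: getattr(s, direction) for s in sets}
        conditions = list(members)
        universe = set().union(*members.values())
        for k in range(1, len(conditions) + 1):
            for combo in combinations(conditions, k):
                inside = set(universe)
                for c in combo:
                    inside &= members[c]
                for c in conditions:
                    if c not in combo:
                        inside -= members[c]
                rows.append(
                    {
                        "direction": direction,
                        "pattern": "&".join(combo),
                        "n_sets": k,
                        "count": len(inside),
                        "features": ",".join(sorted(inside)),
                    }
                )
    return pd.DataFrame(rows)


def ko_dependence(
    de_wt: pd.DataFrame, de_ko: pd.DataFrame, alpha: float = 0.05
) -> pd.Series:
    """Classify features by knockout dependence of their stress response.

    Outer join over the two feature namespaces; a feature untested or absent
    in one table counts as not significant there.  Classes: ``induced`` (up
    in WT, no longer up in KO), ``depleted`` (down in WT, no longer down in
    KO), ``independent`` (same-direction significant in both), ``ko_only``
    (significant only in KO), ``unchanged``.  The classes partition the
    feature set.
    """
    features = de_wt.index.union(de_ko.index)

    def flags(de: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
        sig = (de["padj"] < alpha).reindex(features, fill_value=False)
        lfc = de["log2FoldChange"].reindex(features).fillna(0.0)
        return sig & (lfc > 0), sig & (lfc < 0)

    wt_up, wt_down = flags(de_wt)
    ko_up, ko_down = flags(de_ko)

    out = pd.Series("unchanged", index=features, name="ko_class")
    out[ko_up | ko_down] = "ko_only"
    out[wt_down] = "depleted"
    out[wt_up] = "induced"
    out[(wt_up & ko_up) | (wt_down & ko_down)] = "independent"
    return out


def ago2_dependent(de_ko_vs_wt: pd.DataFrame, alpha: float = 0.05) -> set:
    """Features significantly decreased upon knockout (AGO2-dependent set)."""
    sig = (de_ko_vs_wt["padj"] < alpha) & (de_ko_vs_wt["log2FoldChange"] < 0)
    return set(de_ko_vs_wt.index[sig])


def conserved_cross_species(set_a: set, set_b: set, relaxed: bool = False) -> set:
    """Cross-species intersection of tDR name sets.

    Exact-name intersection by default.  ``relaxed=True`` matches on
    (start, end, isotype, anticodon), ignoring transcript number and the
    multi-mapping suffix; the returned names are the set-A spellings.
    """
    if not relaxed:
        for name in set_a | set_b:
            parse_name(name)  # unparseable names are an input error
        return set_a & set_b

    def key(name: str):
        t = parse_name(name)
        return (t.start_label, t.end_label, t.isotype, t.anticodon)

    keys_b = {key(n) for n in set_b}
    return {n for n in set_a if key(n) in keys_b}


def tracking_filter(
    counts: pd.DataFrame, groups: pd.Series, min_reads: float = 5
) -> pd.Index:
    """Keep features with > ``min_reads`` in every replicate of >= 1 condition.

    This is the abundance cutoff used before tracking features across
    conditions, removing likely artifacts and degradation products.
    """
    groups = groups.reindex(counts.columns)
    keep = np.zeros(len(counts), dtype=bool)
    for lev in groups.dropna().unique():
        cols = groups[groups == lev].index
        keep |= (counts[cols] > min_reads).all(axis=1).to_numpy()
    return counts.index[keep]
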