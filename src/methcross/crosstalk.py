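"""F1/mF1 heterochromatin re-establishment statistics.

This module carries the analysis of the recovery assay: two parents that
each lack non-CpG methylation (mCH) — one missing the CHG/CHH
methyltransferases, one missing the H3K9 methyltransferases — are crossed,
and the F1 regains the full enzymatic machinery. mCH recovery in the F1,
and in the same cross performed in a *met1* (CpG-methyltransferase mutant)
background (the "mF1"), measures de novo establishment and its dependence
on residual mCG.

Operations: TE-gene level filters, recovery efficiency (F1/background),
decile partitions keyed by mCG, percentile ranks, a beta-binomial
likelihood-ratio test for differential mCH between replicate groups,
delta filters on its calls, 50-gene binned mCHG-vs-mCG
curves, and the expression join.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, betabinom_loglik, betabinom_mle_p, mom_icc, signed_rank_test

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_THRESHOLDS",
    "filter_te_genes",
    "recovery_efficiency",
    "decile_partition",
    "decile_summary",
    "rank_percentile",
    "relative_rank_comparison",
    "diff_methylation",
    "apply_delta_filters",
    "binned_scatter",
    "crossing_point",
    "expression_join",
]

#: Near-zero-denominator filter thresholds per context (level in both
#: reference methylomes must exceed these for a recovery ratio to be taken).
DEFAULT_THRESHOLDS = {"CHG": 0.1, "CHH": 0.03}

#: Delta filters for differential-mCH calls, per context.
DEFAULT_DELTAS = {"CHG": 0.1, "CHH": 0.03}


def filter_te_genes(
    levels_background_a: pd.Series,
    levels_background_b: pd.Series,
    context: str,
    threshold: float | None = None,
) -> pd.Index:
    """Regions whose level strictly exceeds *threshold* in BOTH references.

    Guards recovery ratios against division by near-zero backgrounds.
    Default thresholds: 0.1 for CHG, 0.03 for CHH. Regions missing (or with
    undefined level) in either reference are excluded and logged.
    """
    if threshold is None:
        threshold = DEFAULT_THRESHOLDS[context]
    common = levels_background_a.index.intersection(levels_background_b.index)
    n_missing = len(levels_background_a.index.union(levels_background_b.index)) - len(common)
    if n_missing:
        logger.info("filter_te_genes: %d regions absent from one methylome", n_missing)
    a = levels_background_a.loc[common]
    b = levels_background_b.loc[common]
    keep = (a > threshold) & (b > threshold)
    keep &= a.notna() & b.notna()
    return common[keep.to_numpy()]


def recovery_efficiency(level_f1, level_background):
    """Recovery ratio F1-level / background-level.

    Values above 1 (over-recovery) are legitimate. The caller must have
    applied :func:`filter_te_genes`; a zero background here is a contract
    violation and raises.
    """
    f1 = np.asarray(level_f1, dtype=float)
    bg = np.asarray(level_background, dtype=float)
    if np.any(bg == 0):
        raise ValueError("zero background level: filter_te_genes contract violated")
    out = f1 / bg
    if isinstance(level_f1, pd.Series):
        return pd.Series(out, index=level_f1.index, name="efficiency")
    if out.ndim == 0:
        return float(out)
    return out


def decile_partition(
    mcg_levels: pd.Series, region_set=None, n_quantiles: int = 10
) -> pd.DataFrame:
    """Partition regions into *n_quantiles* near-equal groups by mCG level.

    Decile 1 holds the lowest levels. Group sizes differ by at most one;
    ties are broken deterministically by region id. Raises if fewer regions
    than quantiles are supplied (override ``n_quantiles`` for small sets).
    """
    levels = mcg_levels if region_set is None else mcg_levels.loc[pd.Index(region_set)]
    levels = levels.dropna()
    n = len(levels)
    if n < n_quantiles:
        raise ValueError(
            f"only {n} regions for {n_quantiles} quantiles; lower n_quantiles"
        )
    ordered = levels.reset_index()
    ordered.columns = ["region_id", "level"]
    ordered = ordered.sort_values(["level", "region_id"], kind="mergesort")
    deciles = np.concatenate(
        [np.full(len(chunk), i + 1) for i, chunk in enumerate(np.array_split(np.arange(n), n_quantiles))]
    )
    ordered["decile"] = deciles.astype(int)
    return ordered[["region_id", "decile"]].reset_index(drop=True)


def _box_stats(values: np.ndarray) -> dict:
    """Tukey boxplot summary: quartiles plus 1.5*IQR whisker bounds."""
    v = values[np.isfinite(values)]
    if len(v) == 0:
        return {"n": 0, "q1": np.nan, "median": np.nan, "q3": np.nan,
                "whisker_lo": np.nan, "whisker_hi": np.nan}
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo = v[v >= q1 - 1.5 * iqr].min()
    hi = v[v <= q3 + 1.5 * iqr].max()
    return {"n": len(v), "q1": q1, "median": med, "q3": q3,
            "whisker_lo": lo, "whisker_hi": hi}


def decile_summary(assignments: pd.DataFrame, level_tables: dict[str, pd.Series]) -> pd.DataFrame:
    """Boxplot summaries per decile for each named level table.

    *level_tables* maps a label (e.g. ``"mCHG:F1"``) to a Series of levels
    by region id. Whiskers follow the 1.5*IQR rule.
    """
    rows = []
    for decile, group in assignments.groupby("decile"):
        ids = group["region_id"]
        for name, levels in level_tables.items():
            vals = levels.reindex(ids).to_numpy(dtype=float)
            rows.append({"decile": int(decile), "table": name, **_box_stats(vals)})
    return pd.DataFrame(rows)


def rank_percentile(levels: pd.Series, region_set=None) -> pd.Series:
    """Mid-rank percentile of each region's level within the set, in [0, 1].

    rank = (#strictly lower + 0.5 * #tied-including-self) / n; invariant to
    monotone transforms of the levels. All-equal inputs give 0.5 everywhere.
    """
    sub = levels if region_set is None else levels.loc[pd.Index(region_set)]
    sub = sub.dropna()
    if len(sub) == 0:
        raise ValueError("empty region set")
    ranks = stats.rankdata(sub.to_numpy(), method="average")
    return pd.Series((ranks - 0.5) / len(sub), index=sub.index, name="rank")


def relative_rank_comparison(
    region_subset, genotype_a_levels: pd.Series, genotype_b_levels: pd.Series
) -> dict:
    """Compare a flagged subset's percentile ranks between two methylomes.

    Each genotype's ranks are computed within its own full methylome; the
    summary reports the subset's rank distribution in each and the paired
    difference (A - B) with a two-sided signed-rank p. A positive median
    difference means the subset sits relatively higher in genotype A.
    """
    subset = pd.Index(region_subset)
    if len(subset) == 0:
        raise ValueError("empty subset")
    rank_a = rank_percentile(genotype_a_levels).reindex(subset)
    rank_b = rank_percentile(genotype_b_levels).reindex(subset)
    ok = rank_a.notna() & rank_b.notna()
    rank_a, rank_b = rank_a[ok], rank_b[ok]
    _, p = signed_rank_test(rank_a.to_numpy(), rank_b.to_numpy())
    return {
        "n": int(ok.sum()),
        "median_rank_a": float(rank_a.median()),
        "median_rank_b": float(rank_b.median()),
        "median_rank_diff": float((rank_a - rank_b).median()),
        "p": float(p),
        "ranks": pd.DataFrame({"rank_a": rank_a, "rank_b": rank_b}),
    }


def _group_counts(group) -> tuple[np.ndarray, np.ndarray, pd.Index]:
    """Stack replicate count frames into (meth, total) matrices."""
    frames = list(group)
    idx = frames[0].index
    for f in frames[1:]:
        idx = idx.intersection(f.index)
    k = np.column_stack([f.loc[idx, "n_meth"].to_numpy(dtype=float) for f in frames])
    n = np.column_stack([f.loc[idx, "n_total"].to_numpy(dtype=float) for f in frames])
    return k, n, idx


def diff_methylation(
    group_a,
    group_b,
    context: str | None = None,
    shrink_weight: float = 20.0,
    min_rho: float = 1e-4,
) -> pd.DataFrame:
    """Per-region beta-binomial likelihood-ratio test of equal methylation.

    *group_a* and *group_b* are lists of replicate count frames (columns
    ``n_meth``, ``n_total``, indexed by region id). For each region the
    intra-class correlation (overdispersion) is estimated by method of
    moments from replicate scatter and shrunk toward the cross-region
    median with prior weight *shrink_weight* (an empirical-Bayes
    compromise: per-region estimates from 2-4 replicates are noisy). The
    test statistic is twice the profiled log-likelihood-ratio at the shrunk
    dispersion, referred to chi-square(1); q-values are Benjamini-Hochberg.

    ``delta`` is the replicate-pooled level difference (B - A). Regions
    with zero total counts in every replicate of either group are skipped
    and logged. With a single replicate per group the dispersion cannot be
    estimated; a warning is issued and the shrinkage prior alone is used.
    """
    ka, na, idx_a = _group_counts(group_a)
    kb, nb, idx_b = _group_counts(group_b)
    idx = idx_a.intersection(idx_b)
    ka, na = ka[idx_a.get_indexer(idx)], na[idx_a.get_indexer(idx)]
    kb, nb = kb[idx_b.get_indexer(idx)], nb[idx_b.get_indexer(idx)]

    if ka.shape[1] < 2 and kb.shape[1] < 2:
        warnings.warn(
            "single replicate in both groups: dispersion cannot be estimated, "
            "using prior only; p-values may be anti-conservative",
            stacklevel=2,
        )

    covered = (na.sum(axis=1) > 0) & (nb.sum(axis=1) > 0)
    n_skip = int((~covered).sum())
    if n_skip:
        logger.info("diff_methylation: skipping %d regions with an all-zero group", n_skip)

    groups = np.array([0] * ka.shape[1] + [1] * kb.shape[1])
    n_reg = len(idx)
    rho_raw = np.full(n_reg, np.nan)
    df_rep = ka.shape[1] + kb.shape[1] - 2
    for i in range(n_reg):
        if covered[i]:
            rho_raw[i] = mom_icc(
                np.concatenate([ka[i], kb[i]]), np.concatenate([na[i], nb[i]]), groups
            )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rho_med = float(np.nanmedian(rho_raw)) if np.isfinite(rho_raw).any() else 0.0
    w = max(df_rep, 0)
    rho_shrunk = np.where(
        np.isfinite(rho_raw),
        (w * rho_raw + shrink_weight * rho_med) / (w + shrink_weight),
        rho_med,
    )
    rho_shrunk = np.clip(rho_shrunk, min_rho, 0.5)

    stat = np.full(n_reg, np.nan)
    p = np.full(n_reg, np.nan)
    delta = np.full(n_reg, np.nan)
    for i in range(n_reg):
        if not covered[i]:
            continue
        rho = float(rho_shrunk[i])
        pa = ka[i].sum() / na[i].sum()
        pb = kb[i].sum() / nb[i].sum()
        delta[i] = pb - pa
        _, ll_a = betabinom_mle_p(ka[i], na[i], rho)
        _, ll_b = betabinom_mle_p(kb[i], nb[i], rho)
        k0 = np.concatenate([ka[i], kb[i]])
        n0 = np.concatenate([na[i], nb[i]])
        _, ll_0 = betabinom_mle_p(k0, n0, rho)
        lr = max(0.0, 2.0 * (ll_a + ll_b - ll_0))
        stat[i] = lr
        p[i] = stats.chi2.sf(lr, df=1)

    out = pd.DataFrame(
        {
            "delta": delta,
            "statistic": stat,
            "p": p,
            "q": bh_adjust(p),
            "rho": rho_shrunk,
            "tested": covered,
        },
        index=idx,
    )
    out.index.name = "region_id"
    if context is not None:
        out["context"] = context
    return out


def apply_delta_filters(
    results: pd.DataFrame,
    levels_wt: pd.Series,
    levels_met1: pd.Series,
    levels_f1: pd.Series,
    levels_mf1: pd.Series,
    context: str = "CHG",
    delta: float | None = None,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Flag significant regions whose mCH change is not met1-driven.

    Keeps regions with q < *q_threshold*, |level_mF1 - level_F1| > delta and
    |level_WT - level_met1| < delta (delta defaults per context: 0.1 CHG,
    0.03 CHH). The second condition removes TE genes whose significant
    change merely reflects the met1 mutation itself. Replicate levels
    supplied here should be count-pooled across replicates.
    """
    if delta is None:
        delta = DEFAULT_DELTAS[context]
    out = results.copy()
    idx = out.index
    d_assay = (levels_mf1.reindex(idx) - levels_f1.reindex(idx)).abs()
    d_background = (levels_wt.reindex(idx) - levels_met1.reindex(idx)).abs()
    out["significant"] = out["q"] < q_threshold
    out["pass_delta_filters"] = (
        out["significant"].fillna(False)
        & (d_assay > delta).fillna(False)
        & (d_background < delta).fillna(False)
    )
    return out


def binned_scatter(
    mcg_levels: pd.Series, mchg_levels: pd.Series, bin_size: int = 50
) -> pd.DataFrame:
    """Mean (mCG, mCHG) in consecutive bins of *bin_size* regions sorted by mCG.

    Regions are sorted ascending by the keying mCG level (ties broken by
    region id); the last bin may be smaller. Use :func:`crossing_point` to
    read off where the binned mCHG curve reaches a query level.
    """
    common = mcg_levels.dropna().index.intersection(mchg_levels.dropna().index)
    if len(common) < 1:
        raise ValueError("no regions with both levels defined")
    df = pd.DataFrame(
        {"mcg": mcg_levels.loc[common], "mchg": mchg_levels.loc[common]}
    ).reset_index(names="region_id")
    df = df.sort_values(["mcg", "region_id"], kind="mergesort").reset_index(drop=True)
    df["bin"] = df.index // bin_size
    out = df.groupby("bin").agg(
        n=("region_id", "size"), mcg_mean=("mcg", "mean"), mchg_mean=("mchg", "mean")
    )
    return out.reset_index()


def crossing_point(curve: pd.DataFrame, query_mchg: float) -> float:
    """mCG at which a binned mCHG curve first reaches *query_mchg*.

    Linear interpolation between adjacent bin means on the first upward
    crossing; NaN if the curve never reaches the query level. A warning is
    logged when the curve is non-monotone around the crossing.
    """
    x = curve["mcg_mean"].to_numpy(dtype=float)
    y = curve["mchg_mean"].to_numpy(dtype=float)
    if len(y) == 0 or np.nanmax(y) < query_mchg:
        return float("nan")
    if y[0] >= query_mchg:
        return float(x[0])
    for i in range(1, len(y)):
        if y[i] >= query_mchg > y[i - 1]:
            if i + 1 < len(y) and y[i + 1] < y[i - 1]:
                logger.warning("crossing_point: curve non-monotone near crossing")
            f = (query_mchg - y[i - 1]) / (y[i] - y[i - 1])
            return float(x[i - 1] + f * (x[i] - x[i - 1]))
    return float("nan")


def expression_join(
    expression: pd.DataFrame, assignments: pd.DataFrame, pseudo: float = 0.001
) -> pd.DataFrame:
    """Per-decile summaries of log2(RPKM + pseudo) expression.

    *expression* has columns ``region_id``, ``genotype``, ``rpkm`` (long
    format; a frame with just ``region_id``/``rpkm`` is treated as one
    unnamed genotype). Regions absent from the expression table are dropped
    and logged.
    """
    expr = expression.copy()
    if "genotype" not in expr.columns:
        expr["genotype"] = "sample"
    known = set(expr["region_id"])
    missing = [r for r in assignments["region_id"] if r not in known]
    if missing:
        logger.info("expression_join: %d regions lack expression values", len(missing))
    expr["log2_expr"] = np.log2(expr["rpkm"].astype(float) + pseudo)
    merged = assignments.merge(expr, on="region_id", how="inner")
    rows = []
    for (decile, genotype), grp in merged.groupby(["decile", "genotype"]):
        rows.append(
            {"decile": int(decile), "genotype": genotype, **_box_stats(grp["log2_expr"].to_numpy())}
        )
    return pd.DataFrame(rows)
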