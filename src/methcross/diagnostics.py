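"""Global-feedback diagnostics.

Four read-outs of the genome-wide (as opposed to local) control of non-CpG
methylation:

* per-individual Pearson matrices of genic mCHG against mCG — if mCH is
  targeted by each plant's own mCG spectrum, each individual's mCHG should
  correlate best with its own mCG;
* generation trends — progressive genic mCHG gain and TE mCHG loss over
  *ibm1* generations;
* the crossing-point contrast — the mCG level at which the 50-gene binned
  mCHG curve reaches a query level, compared between genomes; a globally
  hypomethylated genome reaching the same mCH at lower absolute mCG is the
  signature of global negative feedback;
* the gene-vs-TE trade-off — genic mCHG gain amplified when TE methylation
  is removed (fraction of genes above the y = x line).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._stats import signed_rank_test
from .crosstalk import crossing_point

logger = logging.getLogger(__name__)

__all__ = [
    "correlation_matrix",
    "generation_trend",
    "feedback_contrast",
    "gene_te_tradeoff",
]


def correlation_matrix(
    mchg_by_sample: dict[str, pd.Series],
    mcg_by_sample: dict[str, pd.Series],
    gene_set,
) -> pd.DataFrame:
    """Pearson r between every mCHG sample (rows) and mCG sample (columns).

    All cells are computed over the identical *gene_set* (restricted to
    genes with defined levels in every sample, so the matrix is comparable
    cell to cell). A zero-variance vector yields NaN for its row/column.
    The row-wise argmax is exposed via the ``best_mcg`` column attribute
    (``DataFrame.attrs["best_mcg"]``).
    """
    if len(mchg_by_sample) < 2 or len(mcg_by_sample) < 2:
        raise ValueError("need at least two samples on each side")
    genes = pd.Index(gene_set)
    cols = {}
    for name, s in {**{f"mchg:{k}": v for k, v in mchg_by_sample.items()},
                    **{f"mcg:{k}": v for k, v in mcg_by_sample.items()}}.items():
        cols[name] = s.reindex(genes)
    frame = pd.DataFrame(cols)
    frame = frame.dropna()
    if len(frame) < 3:
        raise ValueError(f"only {len(frame)} genes with complete levels; need >= 3")
    mat = pd.DataFrame(
        index=list(mchg_by_sample), columns=list(mcg_by_sample), dtype=float
    )
    for r in mchg_by_sample:
        x = frame[f"mchg:{r}"].to_numpy()
        for c in mcg_by_sample:
            y = frame[f"mcg:{c}"].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                mat.loc[r, c] = np.nan
            else:
                mat.loc[r, c] = float(np.corrcoef(x, y)[0, 1])
    best = {}
    for r in mat.index:
        row = mat.loc[r]
        best[r] = None if row.isna().all() else row.idxmax()
    mat.attrs["best_mcg"] = best
    mat.attrs["n_genes"] = len(frame)
    return mat


def generation_trend(
    level_tables: dict, gene_set, te_set
) -> pd.DataFrame:
    """Median mCHG per generation for genes and TE genes, with paired tests.

    *level_tables* maps an orderable generation key (e.g. 1..4) to a Series
    of mCHG levels by region id. The gene and TE sets must be disjoint and
    are held fixed across the series; a generation missing part of either
    set raises. Consecutive generations are compared by two-sided Wilcoxon
    signed-rank tests on the paired per-region levels (``p_vs_prev``).
    """
    gene_set = pd.Index(gene_set)
    te_set = pd.Index(te_set)
    if len(gene_set.intersection(te_set)):
        raise ValueError("gene and TE sets overlap")
    keys = sorted(level_tables)
    if len(keys) < 2:
        raise ValueError("need at least two generations")
    rows = []
    prev = {}
    for key in keys:
        levels = level_tables[key]
        for set_name, ids in (("gene", gene_set), ("te_gene", te_set)):
            if not ids.isin(levels.index).all():
                raise ValueError(f"generation {key}: region set mismatch for {set_name} set")
            vals = levels.reindex(ids)
            if vals.isna().all():
                raise ValueError(f"generation {key}: no levels for {set_name} set")
            p = np.nan
            if set_name in prev:
                _, p = signed_rank_test(vals.to_numpy(), prev[set_name])
            rows.append(
                {
                    "generation": key,
                    "set": set_name,
                    "n": int(vals.notna().sum()),
                    "median": float(vals.median()),
                    "p_vs_prev": float(p),
                }
            )
            prev[set_name] = vals.to_numpy()
    return pd.DataFrame(rows)


def feedback_contrast(
    curve_a: pd.DataFrame, curve_b: pd.DataFrame, query_mchg: float = 0.1
) -> dict:
    """Contrast of crossing points between two binned mCHG-vs-mCG curves.

    Each curve is a :func:`methcross.crosstalk.binned_scatter` output. The
    crossing is the linearly interpolated mCG at which the curve first
    reaches *query_mchg*; the contrast is crossing_A - crossing_B (NaN if
    either curve never reaches the query). Antisymmetric under swapping the
    conditions. A negative contrast with A the globally hypomethylated
    genome means A attains the same mCH at lower absolute mCG.
    """
    ca = crossing_point(curve_a, query_mchg)
    cb = crossing_point(curve_b, query_mchg)
    return {
        "crossing_a": ca,
        "crossing_b": cb,
        "contrast": ca - cb if np.isfinite(ca) and np.isfinite(cb) else float("nan"),
        "query_mchg": query_mchg,
    }


def gene_te_tradeoff(
    levels_wt: pd.Series,
    levels_mutant_a: pd.Series,
    levels_mutant_b: pd.Series,
    gene_set,
    te_set,
) -> dict:
    """Paired gene-level contrast of two mutants (B vs A against y = x).

    For the gene set: the fraction of genes whose level in mutant B exceeds
    mutant A (ties excluded, as points on the y = x line carry no sign) and
    a two-sided signed-rank test. TE-gene medians in all three methylomes
    are reported alongside, since the expected trade-off is genic gain in B
    accompanying TE methylation loss. *levels_wt* provides the wild-type
    reference medians only.
    """
    gene_set = pd.Index(gene_set)
    te_set = pd.Index(te_set)
    a = levels_mutant_a.reindex(gene_set)
    b = levels_mutant_b.reindex(gene_set)
    ok = a.notna() & b.notna()
    a, b = a[ok], b[ok]
    diff = (b - a).to_numpy()
    nonzero = diff[diff != 0]
    frac_above = float((nonzero > 0).mean()) if len(nonzero) else float("nan")
    _, p = signed_rank_test(b.to_numpy(), a.to_numpy())
    return {
        "n_genes": int(ok.sum()),
        "fraction_above_line": frac_above,
        "p": float(p),
        "gene_median_a": float(a.median()),
        "gene_median_b": float(b.median()),
        "te_median_wt": float(levels_wt.reindex(te_set).median()),
        "te_median_a": float(levels_mutant_a.reindex(te_set).median()),
        "te_median_b": float(levels_mutant_b.reindex(te_set).median()),
    }
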