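"""Heritable gene-body mCG presence/absence across sibling individuals.

Gene-body CpG methylation (gbM) epialleles are transmitted stably over
generations, so sibling plants segregating from a *MET1/met1* heterozygote
can differ heritably in which genes carry mCG. Classifying genes by mCG
presence (level > 0.05) or absence in two individuals yields four groups —
commonly methylated, commonly hypomethylated, and specific to either
individual — and, in an *ibm1* (H3K9-demethylase mutant) background, the
individual-specific groups are where individual-specific mCH accumulation
is expected.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._stats import ranksum_test
from .crosstalk import _box_stats

logger = logging.getLogger(__name__)

__all__ = [
    "LABELS",
    "exclude_misannotated",
    "classify_pairs",
    "group_mch_summary",
]

LABELS = ("common_methylated", "common_hypomethylated", "specific_A", "specific_B")


def exclude_misannotated(
    regions, wt_mchg_levels: pd.Series, threshold: float = 0.05
) -> pd.Index:
    """Drop genes whose wild-type mCHG exceeds *threshold*.

    Genes with substantial mCHG in the wild type are in practice
    mis-annotated transposable elements; keeping them would contaminate
    every genic-mCH analysis. Returns the kept region ids; the excluded
    count is logged. Genes with undefined WT mCHG are kept (no evidence of
    mis-annotation).
    """
    regions = pd.Index(regions)
    wt = wt_mchg_levels.reindex(regions)
    drop = wt > threshold
    logger.info("exclude_misannotated: excluded %d of %d genes", int(drop.sum()), len(regions))
    return regions[~drop.to_numpy(dtype=bool)]


def classify_pairs(
    mcg_a: pd.Series, mcg_b: pd.Series, threshold: float = 0.05
) -> tuple[pd.DataFrame, dict]:
    """Four-way epivariant classification of genes across two individuals.

    Presence requires mCG strictly greater than *threshold*; a level exactly
    at the threshold counts as absence. Genes with an undefined level in
    either individual are omitted and logged. Returns the per-gene table
    (columns ``label``, ``mcg_a``, ``mcg_b``) and the group fractions, which
    sum to 1 over classified genes.

    Swapping the two individuals maps specific_A <-> specific_B and leaves
    the common classes fixed.
    """
    common = mcg_a.index.intersection(mcg_b.index)
    a = mcg_a.loc[common]
    b = mcg_b.loc[common]
    defined = a.notna() & b.notna()
    n_omit = int((~defined).sum())
    if n_omit:
        logger.info("classify_pairs: omitted %d genes with undefined mCG", n_omit)
    a, b = a[defined], b[defined]
    pres_a = a > threshold
    pres_b = b > threshold
    label = np.select(
        [pres_a & pres_b, ~pres_a & ~pres_b, pres_a & ~pres_b],
        ["common_methylated", "common_hypomethylated", "specific_A"],
        default="specific_B",
    )
    out = pd.DataFrame(
        {"label": label, "mcg_a": a.to_numpy(), "mcg_b": b.to_numpy(), "threshold": threshold},
        index=a.index,
    )
    out.index.name = "region_id"
    counts = out["label"].value_counts()
    fractions = {lab: float(counts.get(lab, 0)) / len(out) for lab in LABELS}
    return out, fractions


def group_mch_summary(
    classes: pd.DataFrame,
    mchg_a: pd.Series,
    mchg_b: pd.Series,
    min_group: int = 3,
    alpha: float = 0.01,
) -> dict:
    """Per-group mCHG distributions in each individual, with rank-sum tests.

    For each epivariant class the mCHG distribution is summarised in both
    individuals. Two-sided Wilcoxon rank-sum tests compare specific_A
    against common_hypomethylated within individual A, and mirrored for B —
    the expectation under mCG-directed establishment being that
    individual-specific gbM genes gain mCH only in the individual carrying
    the methylated epiallele. Groups smaller than *min_group* skip the test
    (NaN p) but are still summarised. ``significant`` uses p < *alpha*
    (default 0.01, the conventional starred threshold for these tests).
    """
    rows = []
    for lab in LABELS:
        ids = classes.index[classes["label"] == lab]
        for ind, levels in (("A", mchg_a), ("B", mchg_b)):
            vals = levels.reindex(ids).to_numpy(dtype=float)
            rows.append({"label": lab, "individual": ind, **_box_stats(vals)})
    dist = pd.DataFrame(rows)

    hypo = classes.index[classes["label"] == "common_hypomethylated"]
    tests = {}
    for spec_lab, ind, levels in (
        ("specific_A", "A", mchg_a),
        ("specific_B", "B", mchg_b),
        ("specific_A", "B", mchg_b),
        ("specific_B", "A", mchg_a),
    ):
        ids = classes.index[classes["label"] == spec_lab]
        x = levels.reindex(ids).to_numpy(dtype=float)
        y = levels.reindex(hypo).to_numpy(dtype=float)
        if len(ids) < min_group or len(hypo) < min_group:
            stat, p = float("nan"), float("nan")
        else:
            stat, p = ranksum_test(x, y)
        tests[f"{spec_lab}_vs_hypo_in_{ind}"] = {
            "statistic": stat,
            "p": p,
            "significant": bool(p < alpha) if np.isfinite(p) else False,
            "n_specific": int(len(ids)),
            "n_hypo": int(len(hypo)),
        }
    return {"distributions": dist, "tests": tests}
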