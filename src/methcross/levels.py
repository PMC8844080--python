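"""Weighted methylation levels, genomic bins, and metagene segment profiles.

The *weighted methylation level* of a region (per context) is the pooled
count of methylated read observations divided by the pooled total read
observations over every cytosine of that context in the region — i.e. sites
are weighted by their read coverage, the standard definition for WGBS data.
An optional per-site-call mode is provided for sensitivity analysis: each
covered site is first called methylated (level >= 0.5) or not, and the
region level is the fraction of methylated calls.

Metagene profiles divide each region body into 20 near-equal segments and
each 2 kb flank into 10 segments of 200 bp, oriented 5'→3' (minus-strand
regions are reversed so segment 1 is always the upstream flank end).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import CONTEXTS, _records_frame

__all__ = [
    "weighted_level",
    "per_site_call_level",
    "bin_levels",
    "segment_profile",
    "segment_profiles",
    "metaprofile",
]


def weighted_level(n_meth, n_total):
    """Pooled methylated counts over pooled total counts.

    Accepts scalars or arrays. Returns NaN where ``n_total`` is 0 (an
    unobserved level is undefined, never 0). Raises ``ValueError`` if any
    ``n_meth > n_total`` — that indicates corrupt counts upstream.
    """
    n_meth = np.asarray(n_meth, dtype=float)
    n_total = np.asarray(n_total, dtype=float)
    if np.any(n_meth > n_total):
        raise ValueError("n_meth exceeds n_total: corrupt counts")
    if np.any(n_meth < 0):
        raise ValueError("negative methylated count")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(n_total > 0, n_meth / np.where(n_total > 0, n_total, 1), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def per_site_call_level(site_meth, site_total):
    """Fraction of covered sites called methylated (site level >= 0.5).

    Sensitivity-analysis alternative to read-count pooling: *site_meth* and
    *site_total* are per-site count arrays; sites with zero coverage are
    ignored. Returns NaN when no site is covered.
    """
    site_meth = np.asarray(site_meth, dtype=float)
    site_total = np.asarray(site_total, dtype=float)
    covered = site_total > 0
    if not covered.any():
        return float("nan")
    calls = site_meth[covered] / site_total[covered] >= 0.5
    return float(calls.mean())


def bin_levels(records, window: int = 100) -> pd.DataFrame:
    """Pool counts into fixed-width genomic bins per chromosome and context.

    A cytosine at 1-based position ``pos`` goes to bin ``floor((pos-1)/window)``;
    the bin's interval is ``[bin_start, bin_start + window)`` in 0-based
    coordinates. Only bins containing at least one record are emitted.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    df = _records_frame(records)
    if df.empty:
        return pd.DataFrame(
            columns=["chrom", "bin_start", "bin_end", "context", "n_meth", "n_total", "level"]
        )
    df = df.assign(
        bin_start=((df["pos"] - 1) // window) * window,
        n_total=df["n_meth"] + df["n_unmeth"],
    )
    g = (
        df.groupby(["chrom", "bin_start", "context"], sort=True)[["n_meth", "n_total"]]
        .sum()
        .reset_index()
    )
    g["bin_end"] = g["bin_start"] + window
    g["level"] = weighted_level(g["n_meth"].to_numpy(), g["n_total"].to_numpy())
    return g[["chrom", "bin_start", "bin_end", "context", "n_meth", "n_total", "level"]]


def _segment_edges(start: int, end: int, n_body: int, n_flank: int, flank_bp: int):
    """Half-open segment boundaries covering [start-flank, end+flank).

    Body remainder bases go to the 5'-most (leftmost, in genome coordinates
    for '+' regions) segments. Flank segments each span flank_bp/n_flank bp.
    Edges may extend below 0; the caller clips and flags truncation.
    """
    length = end - start
    base = length // n_body
    rem = length % n_body
    widths = np.full(n_body, base, dtype=np.int64)
    widths[:rem] += 1
    body_edges = start + np.concatenate([[0], np.cumsum(widths)])
    fw = flank_bp // n_flank
    left = start - flank_bp + np.arange(n_flank + 1) * fw
    right = end + np.arange(n_flank + 1) * fw
    edges = np.concatenate([left[:-1], body_edges, right[1:]])
    return edges  # length n_flank + n_body + n_flank + 1


def segment_profile(
    records,
    annotation,
    n_body: int = 20,
    n_flank: int = 10,
    flank_bp: int = 2000,
) -> pd.DataFrame:
    """Per-segment weighted levels for one region, oriented 5'→3'.

    *annotation* is a row (anything with ``start``, ``end``, ``strand``,
    ``chrom``, ``region_id`` attributes or keys). Returns a frame with
    columns ``segment`` (1-based, 1 = 5'-most upstream flank segment),
    ``context``, ``n_meth``, ``n_total``, ``level``, ``truncated`` (flank
    segment clipped at the chromosome start). Minus-strand regions have
    their segment order reversed.

    Callers following the heatmap convention should exclude regions shorter
    than 1000 bp beforehand; this function only requires length > 0.
    """
    ann = annotation
    get = (lambda k: ann[k]) if isinstance(ann, (dict, pd.Series)) else (lambda k: getattr(ann, k))
    start, end, strand, chrom = int(get("start")), int(get("end")), get("strand"), get("chrom")
    if end <= start:
        raise ValueError("annotation has non-positive length")
    edges = _segment_edges(start, end, n_body, n_flank, flank_bp)
    n_seg = len(edges) - 1
    truncated = edges[:-1] < 0
    clipped = np.clip(edges, 0, None)

    df = _records_frame(records)
    df = df[df["chrom"] == chrom]
    pos0 = df["pos"].to_numpy() - 1
    order = np.argsort(pos0, kind="mergesort")
    pos0 = pos0[order]
    meth = df["n_meth"].to_numpy()[order]
    total = meth + df["n_unmeth"].to_numpy()[order]
    ctx_arr = df["context"].to_numpy()[order]

    rows = []
    for c in CONTEXTS:
        mask = ctx_arr == c
        m = np.where(mask, meth, 0)
        t = np.where(mask, total, 0)
        cm = np.concatenate([[0], np.cumsum(m)])
        ct = np.concatenate([[0], np.cumsum(t)])
        lo = np.searchsorted(pos0, clipped[:-1], side="left")
        hi = np.searchsorted(pos0, clipped[1:], side="left")
        seg_m = cm[hi] - cm[lo]
        seg_t = ct[hi] - ct[lo]
        if strand == "-":
            seg_m, seg_t = seg_m[::-1], seg_t[::-1]
            trunc = truncated[::-1]
        else:
            trunc = truncated
        for i in range(n_seg):
            rows.append((get("region_id"), i + 1, c, int(seg_m[i]), int(seg_t[i]), bool(trunc[i])))
    out = pd.DataFrame(rows, columns=["region_id", "segment", "context", "n_meth", "n_total", "truncated"])
    out["level"] = weighted_level(out["n_meth"].to_numpy(), out["n_total"].to_numpy())
    return out[["region_id", "segment", "context", "n_meth", "n_total", "level", "truncated"]]


def segment_profiles(records, annotations: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Concatenated :func:`segment_profile` over an annotation frame."""
    df = _records_frame(records)
    parts = [
        segment_profile(df[df["chrom"] == row.chrom], row, **kwargs)
        for row in annotations.itertuples(index=False)
    ]
    if not parts:
        return pd.DataFrame(
            columns=["region_id", "segment", "context", "n_meth", "n_total", "level", "truncated"]
        )
    return pd.concat(parts, ignore_index=True)


def metaprofile(profiles: pd.DataFrame) -> pd.DataFrame:
    """Average segment profiles over regions, per segment and context.

    Undefined (NaN) per-region segment levels are ignored; a segment with no
    defined level in any region stays NaN. Reports the number of regions
    contributing to each segment mean. Permutation-invariant in its inputs.
    """
    if profiles.empty:
        raise ValueError("metaprofile needs at least one profile")
    g = profiles.groupby(["segment", "context"])["level"]
    out = g.agg(level="mean", n="count").reset_index()
    out["n"] = out["n"].astype(int)
    return out.sort_values(["context", "segment"]).reset_index(drop=True)
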