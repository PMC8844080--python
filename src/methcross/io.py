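"""Reading, writing, and region aggregation of per-cytosine methylation data.

The on-disk interchange format is the Bismark-style cytosine ("CX") report: a
7-column TSV with one line per reference cytosine::

    chrom  pos(1-based)  strand  count_methylated  count_unmethylated  context  trinucleotide

Contexts are the three plant methylation classes ``CG``, ``CHG``, ``CHH``
(H = A, T or C). Region annotations come in as BED6+1 (7th column = region
class) or GFF3 and are normalised to 0-based half-open coordinates internally.

In memory, cytosine records and annotations are plain :class:`pandas.DataFrame`
objects with fixed column sets (``CX_COLUMNS``, ``ANNOTATION_COLUMNS``); small
frozen dataclasses (:class:`CytosineRecord`, :class:`RegionAnnotation`) are
provided for record-at-a-time use.
"""

from __future__ import annotations

import gzip
import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "CONTEXTS",
    "CX_COLUMNS",
    "ANNOTATION_COLUMNS",
    "REGION_CLASSES",
    "CytosineRecord",
    "RegionAnnotation",
    "CxReportError",
    "read_cx_report",
    "iter_cx_records",
    "write_cx_report",
    "read_annotations",
    "write_annotations",
    "aggregate_region_counts",
    "region_levels_table",
]

#: The three cytosine sequence-context classes.
CONTEXTS = ("CG", "CHG", "CHH")

#: Column order of the in-memory cytosine-record frame (mirrors the CX report).
CX_COLUMNS = ["chrom", "pos", "strand", "n_meth", "n_unmeth", "context", "tri"]

#: Column order of the in-memory annotation frame.
ANNOTATION_COLUMNS = ["region_id", "chrom", "start", "end", "strand", "region_class"]

#: Recognised region classes.
REGION_CLASSES = ("gene", "te_gene")

_STRANDS = frozenset({"+", "-"})


class CxReportError(ValueError):
    """Malformed cytosine report or annotation input."""


@dataclass(frozen=True)
class CytosineRecord:
    """One reference cytosine with its bisulfite read counts.

    ``pos`` is 1-based as in the report file; ``context`` is one of
    ``CG``/``CHG``/``CHH``; ``tri`` is the trinucleotide column, carried
    through but never interpreted.
    """

    chrom: str
    pos: int
    strand: str
    n_meth: int
    n_unmeth: int
    context: str
    tri: str = "."


@dataclass(frozen=True)
class RegionAnnotation:
    """A gene or TE-gene interval in 0-based half-open coordinates."""

    region_id: str
    chrom: str
    start: int
    end: int
    strand: str
    region_class: str

    @property
    def length(self) -> int:
        return self.end - self.start


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_cx_report(path) -> pd.DataFrame:
    """Read a Bismark-style cytosine report (plain or gzip) into a DataFrame.

    Every line becomes one row, including zero-coverage cytosines. Raises
    :class:`CxReportError` naming the offending line on malformed counts,
    unknown context strings, or bad strands.
    """
    chroms: list[str] = []
    poss: list[int] = []
    strands: list[str] = []
    meths: list[int] = []
    unmeths: list[int] = []
    contexts: list[str] = []
    tris: list[str] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise CxReportError(
                    f"{path}: line {lineno}: expected >=6 tab-separated fields, got {len(fields)}"
                )
            chrom, pos_s, strand, meth_s, unmeth_s, context = fields[:6]
            tri = fields[6] if len(fields) > 6 else "."
            try:
                pos = int(pos_s)
                n_meth = int(meth_s)
                n_unmeth = int(unmeth_s)
            except ValueError as exc:
                raise CxReportError(
                    f"{path}: line {lineno}: non-integer position or count: {exc}"
                ) from None
            if pos < 1 or n_meth < 0 or n_unmeth < 0:
                raise CxReportError(
                    f"{path}: line {lineno}: negative count or non-positive position"
                )
            if context not in CONTEXTS:
                raise CxReportError(
                    f"{path}: line {lineno}: unknown context {context!r} (expected CG/CHG/CHH)"
                )
            if strand not in _STRANDS:
                raise CxReportError(f"{path}: line {lineno}: unknown strand {strand!r}")
            chroms.append(chrom)
            poss.append(pos)
            strands.append(strand)
            meths.append(n_meth)
            unmeths.append(n_unmeth)
            contexts.append(context)
            tris.append(tri)
    return pd.DataFrame(
        {
            "chrom": pd.Series(chroms, dtype=object),
            "pos": pd.Series(poss, dtype=np.int64),
            "strand": pd.Series(strands, dtype=object),
            "n_meth": pd.Series(meths, dtype=np.int64),
            "n_unmeth": pd.Series(unmeths, dtype=np.int64),
            "context": pd.Series(contexts, dtype=object),
            "tri": pd.Series(tris, dtype=object),
        }
    )


def iter_cx_records(path) -> Iterator[CytosineRecord]:
    """Stream a cytosine report as :class:`CytosineRecord` objects."""
    df = read_cx_report(path)
    for row in df.itertuples(index=False):
        yield CytosineRecord(
            row.chrom, int(row.pos), row.strand, int(row.n_meth), int(row.n_unmeth), row.context, row.tri
        )


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        missing = [c for c in CX_COLUMNS[:6] if c not in records.columns]
        if missing:
            raise CxReportError(f"cytosine frame missing columns {missing}")
        df = records.copy()
        if "tri" not in df.columns:
            df["tri"] = "."
        return df[CX_COLUMNS]
    rows = [
        (r.chrom, r.pos, r.strand, r.n_meth, r.n_unmeth, r.context, r.tri)
        for r in records
    ]
    return pd.DataFrame(rows, columns=CX_COLUMNS)


def write_cx_report(records, path) -> None:
    """Write records as a CX report (gzip if *path* ends in ``.gz``).

    Output is sorted by (chrom, pos) and byte-stable for a fixed record set:
    integer fields are formatted plainly, so write→read round-trips exactly.
    """
    df = _records_frame(records)
    df = df.sort_values(["chrom", "pos"], kind="mergesort")
    with _open_text(path, "wt") as fh:
        _write_cx_stream(df, fh)


def _write_cx_stream(df: pd.DataFrame, fh) -> None:
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", header=False, index=False)
    fh.write(buf.getvalue())


def read_annotations(path, region_class_field: str = "auto", gff_class_map: dict | None = None) -> pd.DataFrame:
    """Read region annotations from BED6+1 or GFF3 into a unified frame.

    BED coordinates are taken as 0-based half-open with the region class in
    column 7; GFF3 lines (detected by ``##gff`` header, ``.gff``/``.gff3``
    suffix, or 9 columns with ``=`` in the attributes) are 1-based inclusive
    and converted, with the region class mapped from the feature type via
    *gff_class_map* (default: ``gene -> gene``, ``transposable_element_gene ->
    te_gene``) and the id from the ``ID`` attribute.

    Duplicate region ids and negative coordinates are rejected.
    """
    path = Path(path)
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    content = [ln for ln in lines if ln and not ln.startswith("#")]
    is_gff = (
        region_class_field == "gff"
        or path.suffix.lower() in {".gff", ".gff3"}
        or any(ln.startswith("##gff") for ln in lines)
        or (
            region_class_field == "auto"
            and content
            and len(content[0].split("\t")) == 9
            and "=" in content[0].split("\t")[8]
        )
    )
    rows = []
    if is_gff:
        class_map = gff_class_map or {"gene": "gene", "transposable_element_gene": "te_gene"}
        for lineno, ln in enumerate(content, start=1):
            f = ln.split("\t")
            if len(f) != 9:
                raise CxReportError(f"{path}: GFF line {lineno}: expected 9 columns")
            chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attrs = f
            if ftype not in class_map:
                continue
            attr_d = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            region_id = attr_d.get("ID") or attr_d.get("Name")
            if region_id is None:
                raise CxReportError(f"{path}: GFF line {lineno}: no ID attribute")
            start = int(start_s) - 1  # GFF is 1-based inclusive
            end = int(end_s)
            rows.append((region_id, chrom, start, end, strand, class_map[ftype]))
    else:
        for lineno, ln in enumerate(content, start=1):
            f = ln.split("\t")
            if len(f) < 7:
                raise CxReportError(
                    f"{path}: BED line {lineno}: expected BED6+1 (7 columns), got {len(f)}"
                )
            chrom, start_s, end_s, region_id, _score, strand, region_class = f[:7]
            rows.append((region_id, chrom, int(start_s), int(end_s), strand, region_class))
    df = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    if (df["start"] < 0).any() or (df["end"] < 0).any():
        raise CxReportError(f"{path}: negative coordinates")
    if (df["start"] >= df["end"]).any():
        bad = df.loc[df["start"] >= df["end"], "region_id"].iloc[0]
        raise CxReportError(f"{path}: empty or inverted interval for region {bad!r}")
    if df["region_id"].duplicated().any():
        dup = df.loc[df["region_id"].duplicated(), "region_id"].iloc[0]
        raise CxReportError(f"{path}: duplicate region id {dup!r}")
    df["length"] = df["end"] - df["start"]
    return df


def write_annotations(annotations: pd.DataFrame, path) -> None:
    """Write annotations as BED6+1 (score column '.')."""
    df = annotations
    with _open_text(path, "wt") as fh:
        for row in df.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.region_id}\t.\t{row.strand}\t{row.region_class}\n"
            )


def aggregate_region_counts(records, annotations: pd.DataFrame) -> pd.DataFrame:
    """Pool per-cytosine counts into per-region, per-context totals.

    A cytosine at 1-based position ``pos`` belongs to a region when
    ``pos - 1`` falls in the half-open interval ``[start, end)``. Both
    strands are pooled. Cytosines outside every region are ignored; regions
    may overlap (a site then counts toward each containing region).

    Returns a frame with one row per region x context (all three contexts for
    every region) with columns ``region_id, region_class, context, n_meth,
    n_total, level``; ``level`` is NaN where ``n_total`` is 0 — unobserved,
    not zero.
    """
    df = _records_frame(records)
    ann = annotations
    out_meth = {ctx: np.zeros(len(ann), dtype=np.int64) for ctx in CONTEXTS}
    out_total = {ctx: np.zeros(len(ann), dtype=np.int64) for ctx in CONTEXTS}
    for chrom, ann_idx in ann.groupby("chrom", sort=False).groups.items():
        sub = df[df["chrom"] == chrom]
        if sub.empty:
            continue
        pos0 = (sub["pos"].to_numpy() - 1)
        order = np.argsort(pos0, kind="mergesort")
        pos0 = pos0[order]
        meth = sub["n_meth"].to_numpy()[order]
        total = meth + sub["n_unmeth"].to_numpy()[order]
        ctx = sub["context"].to_numpy()[order]
        cum_m = {}
        cum_t = {}
        for c in CONTEXTS:
            mask = ctx == c
            m = np.where(mask, meth, 0)
            t = np.where(mask, total, 0)
            cum_m[c] = np.concatenate([[0], np.cumsum(m)])
            cum_t[c] = np.concatenate([[0], np.cumsum(t)])
        starts = ann.loc[ann_idx, "start"].to_numpy()
        ends = ann.loc[ann_idx, "end"].to_numpy()
        lo = np.searchsorted(pos0, starts, side="left")
        hi = np.searchsorted(pos0, ends, side="left")
        ann_pos = ann.index.get_indexer(ann_idx)
        for c in CONTEXTS:
            out_meth[c][ann_pos] = cum_m[c][hi] - cum_m[c][lo]
            out_total[c][ann_pos] = cum_t[c][hi] - cum_t[c][lo]
    frames = []
    for c in CONTEXTS:
        frames.append(
            pd.DataFrame(
                {
                    "region_id": ann["region_id"].to_numpy(),
                    "region_class": ann["region_class"].to_numpy(),
                    "context": c,
                    "n_meth": out_meth[c],
                    "n_total": out_total[c],
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["level"] = np.where(
            out["n_total"] > 0, out["n_meth"] / out["n_total"].replace(0, 1), np.nan
        )
    out.loc[out["n_total"] == 0, "level"] = np.nan
    return out


def region_levels_table(region_counts: pd.DataFrame, context: str) -> pd.Series:
    """Extract one context's levels as a Series indexed by region_id."""
    sub = region_counts[region_counts["context"] == context]
    return pd.Series(sub["level"].to_numpy(), index=sub["region_id"].to_numpy(), name=context)
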