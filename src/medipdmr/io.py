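"""Readers and writers: BED3+, BED12 gene models, results tables, counts.

Everything is UTF-8, tab-separated plain text.  BED is 0-based half-open.
Results tables use the published column schema::

    DMR Location  DMR Width  baseMean  log2 FoldChange  padj  Annotation  Nearest Gene

plus an optional ``pvalue`` column for tables we produce ourselves.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd

from .intervals import GenomicInterval, PeakSet, parse_location

RESULTS_COLUMNS = [
    "DMR Location",
    "DMR Width",
    "baseMean",
    "log2 FoldChange",
    "padj",
    "Annotation",
    "Nearest Gene",
]


class BedFormatError(ValueError):
    pass


class SchemaError(ValueError):
    pass


def read_bed(path: str | os.PathLike, label: str | None = None) -> PeakSet:
    """Read a BED3+ file into a PeakSet; extra columns kept as opaque payload.

    Raises :class:`BedFormatError` naming the offending line on bad
    coordinates.
    """
    intervals: list[GenomicInterval] = []
    payload: dict[GenomicInterval, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedFormatError(f"{path}: line {lineno}: fewer than 3 columns")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise BedFormatError(
                    f"{path}: line {lineno}: non-integer coordinates {start_s!r}, {end_s!r}"
                ) from None
            if start >= end or start < 0:
                raise BedFormatError(
                    f"{path}: line {lineno}: invalid span {start}-{end}"
                )
            iv = GenomicInterval(chrom, start, end)
            intervals.append(iv)
            if len(fields) > 3:
                payload[iv] = fields[3:]
    ps = PeakSet(intervals, source_label=label or os.path.basename(os.fspath(path)))
    ps.payload = payload  # type: ignore[attr-defined]
    return ps


def write_bed(peaks: PeakSet, path: str | os.PathLike) -> None:
    payload: Mapping[GenomicInterval, list[str]] = getattr(peaks, "payload", {})
    with open(path, "w", encoding="utf-8") as fh:
        for iv in peaks:
            extra = payload.get(iv)
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if extra:
                cols.extend(extra)
            fh.write("\t".join(cols) + "\n")


def read_results_table(path: str | os.PathLike, validate_width: bool = True) -> pd.DataFrame:
    """Read a DMR results TSV in the published Table 2/3 schema.

    The ``DMR Width`` column is cross-checked against the parsed location
    (width == end - start); a mismatch raises :class:`SchemaError` because it
    means the coordinates and the printed width disagree.
    """
    df = pd.read_csv(path, sep="\t", dtype={"DMR Location": str})
    missing = [c for c in RESULTS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s): {missing}")
    locs = [parse_location(t) for t in df["DMR Location"]]
    if len(set(map(str, locs))) != len(locs):
        raise SchemaError(f"{path}: duplicate DMR locations")
    df["DMR Location"] = [str(iv) for iv in locs]
    if validate_width:
        widths = [iv.width for iv in locs]
        bad = df.loc[[w != pw for w, pw in zip(widths, df["DMR Width"])]]
        if len(bad):
            raise SchemaError(
                f"{path}: width column inconsistent with location for "
                f"{len(bad)} row(s), first: {bad.iloc[0]['DMR Location']}"
            )
    return df


def write_results_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    cols = [c for c in RESULTS_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    df.loc[:, cols + extra].to_csv(path, sep="\t", index=False)


def read_count_table(path: str | os.PathLike) -> pd.DataFrame:
    """Per-replicate counts: columns chrom, start, end, count."""
    df = pd.read_csv(path, sep="\t")
    need = {"chrom", "start", "end", "count"}
    if not need.issubset(df.columns):
        raise SchemaError(f"{path}: expected columns {sorted(need)}")
    if (df["count"] < 0).any():
        row = df.loc[df["count"] < 0].iloc[0]
        raise ValueError(
            f"{path}: negative count at {row['chrom']}:{row['start']}-{row['end']}"
        )
    if not (df["count"] == df["count"].astype(int)).all():
        row = df.loc[df["count"] != df["count"].astype(int)].iloc[0]
        raise ValueError(
            f"{path}: non-integer count at {row['chrom']}:{row['start']}-{row['end']}"
        )
    df["count"] = df["count"].astype(int)
    return df


def read_samples(path: str | os.PathLike) -> pd.DataFrame:
    """Sample metadata CSV with at least sample_id, group, gestational_age."""
    df = pd.read_csv(path)
    need = {"sample_id", "group", "gestational_age"}
    if not need.issubset(df.columns):
        raise SchemaError(f"{path}: expected columns {sorted(need)}")
    bad = set(df["group"]) - {"preterm", "term"}
    if bad:
        raise SchemaError(f"{path}: unknown group label(s) {sorted(bad)}")
    return df


# ---------------------------------------------------------------------------
# BED12 gene models

BED12_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "thick_start", "thick_end", "rgb", "block_count", "block_sizes",
    "block_starts",
]


def read_bed12(path: str | os.PathLike) -> pd.DataFrame:
    """Read a BED12 gene file into a validated DataFrame (one row per gene)."""
    df = pd.read_csv(path, sep="\t", header=None, names=BED12_COLUMNS, comment="#")
    for lineno, row in enumerate(df.itertuples(index=False), start=1):
        if row.strand not in "+-":
            raise BedFormatError(f"{path}: line {lineno}: bad strand {row.strand!r}")
        sizes = [int(x) for x in str(row.block_sizes).rstrip(",").split(",")]
        starts = [int(x) for x in str(row.block_starts).rstrip(",").split(",")]
        if len(sizes) != row.block_count or len(starts) != row.block_count:
            raise BedFormatError(f"{path}: line {lineno}: block count mismatch")
        if row.start + starts[-1] + sizes[-1] > row.end:
            raise BedFormatError(f"{path}: line {lineno}: blocks exceed transcript")
    return df


def iter_bed12_exons(row) -> Iterable[GenomicInterval]:
    sizes = [int(x) for x in str(row.block_sizes).rstrip(",").split(",")]
    starts = [int(x) for x in str(row.block_starts).rstrip(",").split(",")]
    for off, size in zip(starts, sizes):
        yield GenomicInterval(row.chrom, row.start + off, row.start + off + size)
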