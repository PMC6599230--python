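"""Genomic annotation: nearest gene, region categories, CpG context, windows.

DMRs are classified by their midpoint with fixed precedence

    Promoter (<=1 kb) > Promoter (1-2 kb) > Promoter (2-3 kb)
    > 5' UTR > 3' UTR > Exon > 1st Intron > Other Intron
    > Downstream (<=3 kb) > Distal Intergenic

where promoter bins are measured upstream of the strand-aware TSS.  CpG
shores are the 0-2 kb island flanks and shelves the 2-4 kb flanks, with
island > shore > shelf precedence.  The genome is tiled into 500-bp windows
and a window is flagged for a feature if it overlaps it by >= 1 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, PeakSet, merge, subtract
from .io import iter_bed12_exons

# the ten category strings, in precedence order
CATEGORIES = [
    "Promoter (<=1 kb)",
    "Promoter (1-2 kb)",
    "Promoter (2-3 kb)",
    "5′ UTR",
    "3′ UTR",
    "Exon",
    "1st Intron",
    "Other Intron",
    "Downstream (<=3 kb)",
    "Distal Intergenic",
]


@dataclass
class Gene:
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[GenomicInterval]
    thick_start: int
    thick_end: int

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons, in transcript (strand) order."""
        ex = sorted(self.exons, key=lambda e: e.start)
        gaps = [
            GenomicInterval(self.chrom, a.end, b.start)
            for a, b in zip(ex, ex[1:])
            if b.start > a.end
        ]
        return gaps if self.strand == "+" else gaps[::-1]

    def utr5(self) -> list[GenomicInterval]:
        return self._utr(five_prime=True)

    def utr3(self) -> list[GenomicInterval]:
        return self._utr(five_prime=False)

    def _utr(self, five_prime: bool) -> list[GenomicInterval]:
        if self.thick_start >= self.thick_end:  # non-coding: no UTRs
            return []
        if (self.strand == "+") == five_prime:
            lo, hi = self.start, self.thick_start
        else:
            lo, hi = self.thick_end, self.end
        if lo >= hi:
            return []
        span = GenomicInterval(self.chrom, lo, hi)
        return [
            GenomicInterval(self.chrom, max(e.start, lo), min(e.end, hi))
            for e in self.exons
            if e.start < hi and e.end > lo
        ]


@dataclass
class GeneModel:
    genes: list[Gene]
    _by_chrom: dict[str, list[Gene]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for g in self.genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)

    @classmethod
    def from_bed12(cls, df: pd.DataFrame) -> "GeneModel":
        genes = [
            Gene(
                symbol=row.name,
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                exons=list(iter_bed12_exons(row)),
                thick_start=int(row.thick_start),
                thick_end=int(row.thick_end),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(genes)

    def on_chrom(self, chrom: str) -> list[Gene]:
        return self._by_chrom.get(chrom, [])


def _upstream_distance(mid: int, gene: Gene) -> int:
    """bp from the midpoint to the TSS, measured on the upstream side (>0)."""
    return gene.tss - mid if gene.strand == "+" else mid - gene.tss


def classify_dmr(dmr: GenomicInterval, genes: GeneModel) -> str:
    """Category of the DMR midpoint under the documented precedence."""
    mid = dmr.midpoint
    cands = genes.on_chrom(dmr.chrom)

    def in_any(ivs: Sequence[GenomicInterval]) -> bool:
        return any(iv.start <= mid < iv.end for iv in ivs)

    for lo, hi, label in ((0, 1000, CATEGORIES[0]), (1000, 2000, CATEGORIES[1]), (2000, 3000, CATEGORIES[2])):
        for g in cands:
            d = _upstream_distance(mid, g)
            if lo < d <= hi:
                return label
    if any(in_any(g.utr5()) for g in cands):
        return "5′ UTR"
    if any(in_any(g.utr3()) for g in cands):
        return "3′ UTR"
    if any(in_any(g.exons) for g in cands):
        return "Exon"
    first, other = False, False
    for g in cands:
        introns = g.introns
        if introns and introns[0].start <= mid < introns[0].end:
            first = True
        elif in_any(introns[1:]):
            other = True
    if first:
        return "1st Intron"
    if other:
        return "Other Intron"
    for g in cands:
        tes_d = mid - g.tes if g.strand == "+" else g.tes - mid
        if 0 <= tes_d <= 3000:
            return "Downstream (<=3 kb)"
    return "Distal Intergenic"


def nearest_gene(dmr: GenomicInterval, genes: GeneModel) -> tuple[str, int]:
    """(symbol, signed midpoint-to-TSS distance); 0 if inside the transcript.

    Distance sign follows genome orientation (negative if the TSS is left of
    the midpoint).  Ties go to the lexicographically smaller symbol; with no
    gene on the chromosome returns ("NA", 0).
    """
    mid = dmr.midpoint
    cands = genes.on_chrom(dmr.chrom)
    if not cands:
        return "NA", 0
    best: tuple[int, str, int] | None = None
    for g in cands:
        if g.start <= mid < g.end:
            d = 0
        else:
            d = g.tss - mid
        key = (abs(d), g.symbol)
        if best is None or key < (best[0], best[1]):
            best = (abs(d), g.symbol, d)
    return best[1], best[2]


def category_percentages(table: pd.DataFrame) -> pd.Series:
    """Percentage of records per annotation category (sums to 100)."""
    if len(table) == 0:
        raise ValueError("empty results table")
    counts = table["Annotation"].value_counts()
    return counts / counts.sum() * 100.0


def annotate_results(table: pd.DataFrame, genes: GeneModel) -> pd.DataFrame:
    """Fill the Annotation and Nearest Gene columns of a results table."""
    from .intervals import parse_location

    out = table.copy()
    locs = [parse_location(t) for t in out["DMR Location"]]
    out["Annotation"] = [classify_dmr(iv, genes) for iv in locs]
    out["Nearest Gene"] = [nearest_gene(iv, genes)[0] for iv in locs]
    return out


# ---------------------------------------------------------------------------
# CpG context

@dataclass
class CpGContext:
    islands: PeakSet
    shores: PeakSet
    shelves: PeakSet
    shore_bp: int = 2000
    shelf_bp: int = 4000


def cpg_flanks(
    islands: PeakSet,
    chrom_lengths: Mapping[str, int],
    shore_bp: int = 2000,
    shelf_bp: int = 4000,
) -> CpGContext:
    """Shores (0-2 kb flanks) and shelves (2-4 kb flanks) of CpG islands.

    Flanks from adjacent islands are merged; precedence island > shore >
    shelf keeps the three sets pairwise disjoint.  Flanks are clipped at
    chromosome bounds.
    """
    for iv in islands:
        if iv.chrom not in chrom_lengths:
            raise ValueError(f"island on unknown chromosome {iv.chrom}")
        if iv.end > chrom_lengths[iv.chrom]:
            raise ValueError(f"island {iv} outside chromosome bounds")

    merged = merge(islands)

    def expand(by: int) -> PeakSet:
        return merge(
            GenomicInterval(
                iv.chrom,
                max(0, iv.start - by),
                min(chrom_lengths[iv.chrom], iv.end + by),
            )
            for iv in merged
        )

    ring2 = expand(shore_bp)
    ring4 = expand(shelf_bp)
    shores = subtract(ring2, merged)
    shelves = subtract(ring4, ring2)
    return CpGContext(merged, shores, shelves, shore_bp, shelf_bp)


# ---------------------------------------------------------------------------
# 500-bp window grid

@dataclass
class WindowGrid:
    """Non-overlapping tiling of each chromosome plus per-feature flags."""

    chrom_lengths: dict[str, int]
    size: int
    windows: pd.DataFrame                  # chrom, start, end
    flags: pd.DataFrame = field(default_factory=pd.DataFrame)  # bool, one col/feature

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def window_index(self, iv: GenomicInterval) -> range:
        """Row indices of the windows overlapping ``iv`` (empty if none)."""
        offsets = self._offsets()
        if iv.chrom not in offsets:
            return range(0)
        off, n_chrom = offsets[iv.chrom]
        lo = iv.start // self.size
        hi = min((iv.end - 1) // self.size, n_chrom - 1)
        lo = min(lo, n_chrom - 1)
        return range(off + lo, off + hi + 1)

    def _offsets(self) -> dict[str, tuple[int, int]]:
        if not hasattr(self, "_off_cache"):
            out, off = {}, 0
            for chrom, length in self.chrom_lengths.items():
                n_chrom = -(-length // self.size)
                out[chrom] = (off, n_chrom)
                off += n_chrom
            self._off_cache = out
        return self._off_cache


def make_windows(chrom_lengths: Mapping[str, int], size: int = 500) -> WindowGrid:
    """Tile each chromosome into consecutive windows; final partial tile kept."""
    if size <= 0:
        raise ValueError("window size must be positive")
    rows = []
    for chrom, length in chrom_lengths.items():
        starts = np.arange(0, length, size)
        ends = np.minimum(starts + size, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    windows = pd.concat(rows, ignore_index=True)
    return WindowGrid(dict(chrom_lengths), size, windows)


def flag_windows(grid: WindowGrid, features: Mapping[str, PeakSet]) -> WindowGrid:
    """Flag each window for each named feature on >= 1 bp overlap."""
    flags = {}
    for name, ps in features.items():
        col = np.zeros(grid.n_windows, dtype=bool)
        for iv in ps:
            if iv.chrom not in grid.chrom_lengths:
                raise ValueError(f"feature {name!r} on unknown chromosome {iv.chrom}")
            rng = grid.window_index(iv)
            col[rng.start:rng.stop] = True
        flags[name] = col
    grid.flags = pd.DataFrame(flags)
    return grid


def states_to_features(states: pd.DataFrame, mapping: Mapping[str, str] | None = None) -> dict[str, PeakSet]:
    """Map a chromatin-state BED (name = state label) to promoter/enhancer sets.

    By default, labels containing "tss" or "promoter" (case-insensitive) map
    to ``promoters`` and labels containing "enh" to ``enhancers``.
    """
    out: dict[str, list[GenomicInterval]] = {"promoters": [], "enhancers": []}
    for row in states.itertuples(index=False):
        label = str(row.state).lower()
        if mapping is not None:
            target = mapping.get(str(row.state))
        elif "tss" in label or "promoter" in label:
            target = "promoters"
        elif "enh" in label:
            target = "enhancers"
        else:
            target = None
        if target:
            out[target].append(GenomicInterval(row.chrom, int(row.start), int(row.end)))
    return {k: merge(v) for k, v in out.items()}
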