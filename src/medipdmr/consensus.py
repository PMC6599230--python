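"""Consensus peak construction and replicate-summed count matrices.

An individual's consensus peak set keeps only regions supported by *every*
technical replicate; the cohort master set keeps merged regions supported by
at least ``min_overlap`` individuals.  Counts for each master peak are the
sum over the individual's technical replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, PeakSet, merge


@dataclass
class CountMatrix:
    """Non-negative integer read counts, peaks x samples."""

    peaks: Sequence[GenomicInterval]
    samples: Sequence[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.peaks), len(self.samples)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.peaks)} peaks x {len(self.samples)} samples"
            )
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not (self.counts == np.round(self.counts)).all():
                raise ValueError("non-integer counts")
            self.counts = self.counts.astype(np.int64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=[str(p) for p in self.peaks], columns=list(self.samples)
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        from .intervals import parse_location

        peaks = [parse_location(t) for t in df.index]
        return cls(peaks, list(df.columns), df.to_numpy())


def replicate_consensus(replicates: Sequence[PeakSet]) -> PeakSet:
    """Merged union regions present (>= 1 bp overlap) in every replicate."""
    if len(replicates) < 2:
        raise ValueError("need at least 2 replicate peak sets")
    union = merge(iv for rep in replicates for iv in rep)
    kept = [
        iv
        for iv in union
        if all(rep.any_overlap(iv) for rep in replicates)
    ]
    return PeakSet(kept, source_label="consensus", validate=False)


def cohort_consensus(individual_sets: Sequence[PeakSet], min_overlap: int = 2) -> PeakSet:
    """Merged union regions supported by >= min_overlap distinct individuals."""
    if not individual_sets:
        raise ValueError("need at least 1 individual peak set")
    if not 1 <= min_overlap <= len(individual_sets):
        raise ValueError(
            f"min_overlap={min_overlap} outside [1, {len(individual_sets)}]"
        )
    union = merge(iv for ps in individual_sets for iv in ps)
    kept = [
        iv
        for iv in union
        if sum(ps.any_overlap(iv) for ps in individual_sets) >= min_overlap
    ]
    return PeakSet(kept, source_label="cohort_consensus", validate=False)


def summed_counts(
    master: PeakSet,
    replicate_counts: Mapping[str, Sequence[pd.DataFrame]],
) -> CountMatrix:
    """Sum per-replicate region counts into a peaks x individuals matrix.

    ``replicate_counts`` maps individual sample_id -> list of per-replicate
    count tables (columns chrom, start, end, count).  A replicate region
    contributes its count to every master peak it overlaps; master peaks with
    no overlapping region in a table read as 0.
    """
    samples = list(replicate_counts)
    mat = np.zeros((len(master), len(samples)), dtype=np.int64)
    for j, sid in enumerate(samples):
        for tab in replicate_counts[sid]:
            if (tab["count"] < 0).any():
                bad = tab.loc[tab["count"] < 0].iloc[0]
                raise ValueError(
                    f"negative count at {bad['chrom']}:{bad['start']}-{bad['end']}"
                )
            regions = PeakSet(
                [GenomicInterval(c, int(s), int(e)) for c, s, e in zip(tab["chrom"], tab["start"], tab["end"])]
            )
            lookup = {
                (c, int(s), int(e)): int(n)
                for c, s, e, n in zip(tab["chrom"], tab["start"], tab["end"], tab["count"])
            }
            for i, peak in enumerate(master):
                for reg in regions.overlapping(peak):
                    mat[i, j] += lookup[(reg.chrom, reg.start, reg.end)]
    return CountMatrix(list(master), samples, mat)


def counts_from_read_positions(master: PeakSet, reads: PeakSet) -> np.ndarray:
    """Counts per master peak of reads whose start position lies in the peak."""
    starts_by_chrom: dict[str, np.ndarray] = {}
    for chrom in reads.chroms():
        starts_by_chrom[chrom] = np.array(
            [iv.start for iv in reads if iv.chrom == chrom], dtype=np.int64
        )
    out = np.zeros(len(master), dtype=np.int64)
    for i, peak in enumerate(master):
        starts = starts_by_chrom.get(peak.chrom)
        if starts is None:
            continue
        out[i] = int(((starts >= peak.start) & (starts < peak.end)).sum())
    return out
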