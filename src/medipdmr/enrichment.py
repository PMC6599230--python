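"""Window-mediated genomic-feature enrichment of DMR sets.

The enrichment score of a feature is

    (fraction of DMRs overlapping feature-flagged windows)
    / (fraction of all genome windows flagged for the feature)

A DMR "overlaps" a feature iff it overlaps at least one 500-bp window
flagged for that feature — overlap is mediated through the window grid, not
through direct DMR/feature intersection, so a DMR touching the flagged
window of a feature counts even if it misses the feature interval itself.
Scores are reported separately for hyper- and hypo-methylated DMRs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, PeakSet, parse_location
from .annotate import WindowGrid

log = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    feature: str
    direction: str               # hyper | hypo | all
    score: float
    n_dmrs_overlapping: int
    n_dmrs: int
    n_windows_flagged: int
    n_windows: int


def enrichment_score(dmrs: PeakSet, grid: WindowGrid, feature: str, direction: str = "all") -> EnrichmentResult:
    """Enrichment of one feature among a DMR set (see module doc)."""
    if len(dmrs) == 0:
        raise ValueError("no DMRs")
    if grid.n_windows == 0:
        raise ValueError("empty window grid")
    if feature not in grid.flags.columns:
        raise ValueError(f"unknown feature {feature!r}")
    col = grid.flags[feature].to_numpy()
    n_flagged = int(col.sum())
    if n_flagged == 0:
        raise ValueError(f"undefined enrichment (zero background) for {feature!r}")
    n_hit = 0
    for dmr in dmrs:
        rng = grid.window_index(dmr)
        if col[rng.start:rng.stop].any():
            n_hit += 1
    frac_dmr = n_hit / len(dmrs)
    frac_bg = n_flagged / grid.n_windows
    return EnrichmentResult(
        feature=feature,
        direction=direction,
        score=frac_dmr / frac_bg,
        n_dmrs_overlapping=n_hit,
        n_dmrs=len(dmrs),
        n_windows_flagged=n_flagged,
        n_windows=grid.n_windows,
    )


def directional_enrichment(
    table: pd.DataFrame, grid: WindowGrid, features: list[str] | None = None
) -> pd.DataFrame:
    """Feature x {hyper, hypo} enrichment scores for an annotated DMR table.

    Records need a ``direction`` column (or a ``log2 FoldChange`` column from
    which direction is derived: positive = hypo-methylated in preterm).
    Returns a feature-major tidy table ready for two-panel bar plotting.
    """
    if features is None:
        features = list(grid.flags.columns)
    t = table.copy()
    if "direction" not in t.columns:
        t["direction"] = np.where(t["log2 FoldChange"] > 0, "hypo", "hyper")
    rows = []
    for feature in features:
        for direction in ("hyper", "hypo"):
            sub = t.loc[t["direction"] == direction]
            if len(sub) == 0:
                log.warning("no %s-methylated DMRs; stratum omitted", direction)
                continue
            dmrs = PeakSet([parse_location(s) for s in sub["DMR Location"]])
            r = enrichment_score(dmrs, grid, feature, direction=direction)
            rows.append(vars(r))
    return pd.DataFrame(rows)
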