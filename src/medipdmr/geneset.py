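"""Comparative gene-set analysis and cross-model DMR comparison.

Overlap between the DMR-associated genes and an external gene set is scored
against the hypergeometric null: observed = |query ∩ target|, expected =
|query|·|target|/|universe|, p = P(X >= observed) for X hypergeometric.
Gene symbols match exactly after upper-casing; no alias resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class GeneSet:
    name: str
    genes: set[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.genes = {g.upper() for g in self.genes}


@dataclass
class OverlapResult:
    observed: int
    expected: float
    pvalue: float
    query_size: int
    set_size: int
    universe_size: int
    shared: list[str] = field(default_factory=list)


def overlap_stats(query, target: GeneSet, universe) -> OverlapResult:
    """Hypergeometric over-representation of ``target`` genes in ``query``."""
    universe = {g.upper() for g in universe}
    if not universe:
        raise ValueError("empty gene universe")
    q = {g.upper() for g in query}
    dropped_q = q - universe
    if dropped_q:
        log.warning("%d query gene(s) outside universe dropped", len(dropped_q))
    q &= universe
    t = target.genes & universe
    dropped_t = target.genes - universe
    if dropped_t:
        log.warning("%d target gene(s) outside universe dropped", len(dropped_t))
    shared = sorted(q & t)
    observed = len(shared)
    M, n, N = len(universe), len(t), len(q)
    expected = N * n / M
    # upper tail P(X >= observed)
    pvalue = float(stats.hypergeom.sf(observed - 1, M, n, N)) if observed > 0 else 1.0
    return OverlapResult(observed, expected, min(pvalue, 1.0), N, n, M, shared)


def table_intersection(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Records of ``a`` whose canonical DMR location also appears in ``b``."""
    from .intervals import parse_location

    locs_b = {str(parse_location(s)) for s in b["DMR Location"]}
    keep = [str(parse_location(s)) in locs_b for s in a["DMR Location"]]
    return a.loc[keep].reset_index(drop=True)


def unique_nearest_genes(table: pd.DataFrame) -> list[str]:
    """Sorted unique nearest-gene symbols of an annotated results table."""
    return sorted({str(g).upper() for g in table["Nearest Gene"] if str(g) != "NA"})


def read_gene_sets(path) -> dict[str, GeneSet]:
    """Two-column TSV (set name, symbol) -> named GeneSets."""
    df = pd.read_csv(path, sep="\t", header=None, names=["set", "gene"])
    out = {}
    for name, sub in df.groupby("set"):
        out[str(name)] = GeneSet(str(name), set(sub["gene"].astype(str)), provenance=str(path))
    return out
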