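"""Bundled reference tables: the published DMR result tables.

``load_ptb_dmr_table`` and ``load_ga_dmr_table`` return the 21 FDR-significant
preterm-birth DMRs and the 67 gestational-age DMRs as printed in the source
study's result tables (location, width, baseMean, log2 fold change, padj,
annotation, nearest gene).
"""

from importlib import resources

import pandas as pd

from .io import read_results_table


def _load(name: str) -> pd.DataFrame:
    with resources.as_file(resources.files("medipdmr.data") / name) as path:
        return read_results_table(path)


def load_ptb_dmr_table() -> pd.DataFrame:
    """The 21 FDR-significant DMRs of the dichotomous (preterm vs term) model."""
    return _load("table_ptb_dmrs.tsv")


def load_ga_dmr_table() -> pd.DataFrame:
    """The 67 FDR-significant DMRs of the continuous (gestational-age) model."""
    return _load("table_ga_dmrs.tsv")
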