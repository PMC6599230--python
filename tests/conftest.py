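import numpy as np
import pandas as pd
import pytest

from medipdmr import (
    CountMatrix,
    DifferentialMethylationModel,
    SimulationConfig,
    simulate_counts,
)


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic bundle: 2000 peaks, 6 preterm + 3 term, 3 reps."""
    return simulate_counts(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def default_counts(default_study):
    st = default_study
    return CountMatrix(st.peaks, list(st.samples["sample_id"]), st.totals)


@pytest.fixture(scope="session")
def ptb_results(default_study, default_counts):
    model = DifferentialMethylationModel(default_counts, default_study.samples, design="ptb")
    return model.fit()


@pytest.fixture()
def tiny_genes_bed12(tmp_path):
    """Two genes on chr1 (one per strand), BED12."""
    lines = [
        # +-strand: tx 10000-20000, exons [10000,11000) [14000,15000) [19000,20000),
        # coding 10500-19500 -> 5'UTR 10000-10500, 3'UTR 19500-20000
        "chr1\t10000\t20000\tGENE_A\t0\t+\t10500\t19500\t0\t3\t1000,1000,1000\t0,4000,9000",
        # --strand: tx 50000-60000, exons [50000,52000) [58000,60000), coding 51000-59000
        "chr1\t50000\t60000\tGENE_B\t0\t-\t51000\t59000\t0\t2\t2000,2000\t0,8000",
    ]
    p = tmp_path / "genes.bed12"
    p.write_text("\n".join(lines) + "\n")
    return p


@pytest.fixture()
def samples_df():
    return pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(1, 10)],
            "group": ["preterm"] * 6 + ["term"] * 3,
            "gestational_age": [27.0, 29.5, 31.0, 25.5, 33.0, 30.0, 38.0, 39.5, 40.5],
        }
    )
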