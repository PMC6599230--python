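"""Differential-methylation model: NB-GLM Wald tests over a count matrix.

The entry point is :class:`DifferentialMethylationModel`, built from a
peaks-x-samples count matrix plus sample metadata, with one of two designs:

``ptb``
    intercept + term indicator.  The reported log2 fold change is the
    term-vs-preterm contrast, so a *positive* value means higher methylation
    at term, i.e. the region is hypo-methylated in preterm placentas.
``ga``
    intercept + gestational age in weeks (uncentred).  The reported log2
    fold change is the per-week slope.

``fit()`` runs size-factor normalisation, dispersion estimation, per-peak
GLM fits, Wald tests and independent-filtering FDR, and returns a
:class:`DMRResults` carrying the table in the published schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import nb
from .consensus import CountMatrix
from .intervals import GenomicInterval

LN2 = float(np.log(2.0))


@dataclass
class AnalysisConfig:
    model: str = "ptb"
    alpha_fdr: float = 0.05
    alpha_nominal: float = 0.01
    filter_quantiles: np.ndarray | None = None
    independent_filtering: bool = True

    def __post_init__(self) -> None:
        if self.model not in ("ptb", "ga"):
            raise ValueError(f"unknown model {self.model!r}")
        for a in (self.alpha_fdr, self.alpha_nominal):
            if not 0 < a <= 1:
                raise ValueError(f"alpha must be in (0, 1]: {a}")


class DifferentialMethylationModel:
    """NB-GLM differential methylation over MeDIP-seq peak counts.

    Parameters
    ----------
    counts : CountMatrix
        Replicate-summed counts, peaks x individuals.
    samples : DataFrame
        One row per individual; columns ``sample_id``, ``group``
        (preterm/term) and ``gestational_age`` (weeks).
    design : str
        ``"ptb"`` (dichotomous) or ``"ga"`` (continuous), see module doc.
    """

    def __init__(self, counts: CountMatrix, samples: pd.DataFrame, design: str = "ptb"):
        self.config = AnalysisConfig(model=design)
        samples = samples.set_index("sample_id").loc[list(counts.samples)].reset_index()
        self.counts = counts
        self.samples = samples
        if design == "ptb":
            n_pre = int((samples["group"] == "preterm").sum())
            n_term = int((samples["group"] == "term").sum())
            if min(n_pre, n_term) < 2:
                raise ValueError(
                    f"need >= 2 samples per group, got {n_pre} preterm / {n_term} term"
                )
            x = (samples["group"] == "term").to_numpy(float)
        else:
            x = samples["gestational_age"].to_numpy(float)
        self.exog = np.column_stack([np.ones(len(samples)), x])

    @classmethod
    def from_dataframe(
        cls, counts: pd.DataFrame, samples: pd.DataFrame, design: str = "ptb"
    ) -> "DifferentialMethylationModel":
        """Build from a counts DataFrame indexed by ``chrN:start-end`` strings."""
        return cls(CountMatrix.from_frame(counts), samples, design=design)

    def fit(
        self,
        alpha_fdr: float = 0.05,
        independent_filtering: bool = True,
        filter_quantiles: np.ndarray | None = None,
    ) -> "DMRResults":
        cfg = self.config
        cfg.alpha_fdr = alpha_fdr
        cfg.independent_filtering = independent_filtering
        cfg.filter_quantiles = filter_quantiles

        mat = self.counts.counts.astype(float)
        sf = nb.size_factors(mat)
        norm = mat / sf[None, :]
        base_mean = norm.mean(axis=1)

        disp = nb.estimate_dispersion(mat, sf, self.exog)
        beta, se, converged = nb.fit_nb_glm(
            mat, self.exog, offsets=np.log(sf), alpha=disp["final"]
        )

        pvalue = np.full(mat.shape[0], np.nan)
        ok = converged & (se[:, 1] > 0) & (base_mean > 0)
        pvalue[ok] = nb.wald_pvalues(beta[ok, 1], se[ok, 1])

        padj = np.full(mat.shape[0], np.nan)
        threshold = 0.0
        testable = ~np.isnan(pvalue)
        if testable.any():
            if independent_filtering:
                threshold, sub_padj = nb.independent_filter(
                    base_mean[testable],
                    pvalue[testable],
                    alpha_fdr=alpha_fdr,
                    quantiles=filter_quantiles,
                )
            else:
                sub_padj = nb.bh_adjust(pvalue[testable])
            padj[testable] = sub_padj

        return DMRResults(
            model=self,
            size_factors=sf,
            dispersions=disp,
            coefficients=beta,
            standard_errors=se,
            converged=converged,
            base_mean=base_mean,
            pvalue=pvalue,
            padj=padj,
            filter_threshold=float(threshold),
        )


@dataclass
class DMRResults:
    """Fit results: per-peak estimates, tests, and the published-schema table."""

    model: DifferentialMethylationModel
    size_factors: np.ndarray
    dispersions: dict
    coefficients: np.ndarray
    standard_errors: np.ndarray
    converged: np.ndarray
    base_mean: np.ndarray
    pvalue: np.ndarray
    padj: np.ndarray
    filter_threshold: float
    _table: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def log2_fold_change(self) -> np.ndarray:
        """Tested coefficient on the log2 scale (contrast or per-week slope)."""
        return self.coefficients[:, 1] / LN2

    @property
    def direction(self) -> np.ndarray:
        """hypo/hyper in preterm: positive log2FC means hypo-methylated."""
        return np.where(self.log2_fold_change > 0, "hypo", "hyper")

    @property
    def table(self) -> pd.DataFrame:
        """Results in the published column schema, sorted by padj (NaN last)."""
        if self._table is None:
            peaks = self.model.counts.peaks
            df = pd.DataFrame(
                {
                    "DMR Location": [str(p) for p in peaks],
                    "DMR Width": [p.width for p in peaks],
                    "baseMean": self.base_mean,
                    "log2 FoldChange": self.log2_fold_change,
                    "pvalue": self.pvalue,
                    "padj": self.padj,
                    "Annotation": "",
                    "Nearest Gene": "",
                    "direction": self.direction,
                }
            )
            self._table = df.sort_values(
                ["padj", "pvalue"], na_position="last", kind="mergesort"
            ).reset_index(drop=True)
        return self._table

    def significant(self, alpha: float | None = None) -> pd.DataFrame:
        alpha = self.model.config.alpha_fdr if alpha is None else alpha
        t = self.table
        return t.loc[t["padj"] < alpha].reset_index(drop=True)

    def nominal(self, alpha: float | None = None) -> pd.DataFrame:
        alpha = self.model.config.alpha_nominal if alpha is None else alpha
        t = self.table
        return t.loc[t["pvalue"] < alpha].reset_index(drop=True)

    def normalized_counts(self) -> pd.DataFrame:
        """Size-factor-normalised counts (heat-map data layer)."""
        cm = self.model.counts
        return pd.DataFrame(
            cm.counts / self.size_factors[None, :],
            index=[str(p) for p in cm.peaks],
            columns=list(cm.samples),
        )

    def summary(self) -> str:
        cfg = self.model.config
        n_peaks, n_samples = self.model.counts.counts.shape
        sig = self.significant()
        nom = self.nominal()
        hypo = (sig["direction"] == "hypo").mean() * 100 if len(sig) else float("nan")
        lines = [
            "Differential methylation (NB GLM Wald test)",
            "=" * 47,
            f"design:               {cfg.model} "
            + ("(term vs preterm contrast)" if cfg.model == "ptb" else "(per-week GA slope)"),
            f"peaks x samples:      {n_peaks} x {n_samples}",
            f"size factors:         {np.round(self.size_factors, 3)}",
            f"median dispersion:    {np.median(self.dispersions['final']):.4g}",
            f"independent filter:   baseMean >= {self.filter_threshold:.2f}"
            if cfg.independent_filtering
            else "independent filter:   off",
            f"nominal p < {cfg.alpha_nominal:g}:     {len(nom)} peaks",
            f"FDR padj < {cfg.alpha_fdr:g}:      {len(sig)} peaks",
            f"hypo-methylated (preterm) among significant: {hypo:.0f}%",
        ]
        return "\n".join(lines)
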