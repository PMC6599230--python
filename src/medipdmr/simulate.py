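"""Synthetic MeDIP-seq study generator.

Emulates the structure of a placental MeDIP-seq cohort — 6 preterm
(25-34 wk) and 3 term (37-41 wk) individuals, 3 technical replicates each —
as a toy genome with gene models, CpG islands and chromatin states, plus
NB-distributed peak counts with planted group effects and per-week
gestational-age slopes.  The replicate-summed count per peak is a single NB
draw split multinomially across replicates, so the summed matrix is exactly
NB with the configured dispersion (the model the differential test assumes).

Counts for peak i, sample j are drawn with mean

    sf_j * 2 ** (b0_i + b1_i * I[preterm_j] + b2_i * GA_j)

where b1 (the planted log2 preterm effect) and b2 (the planted per-week
log2 slope) are zero outside the designated effect classes, and size
factors sf_j are log-uniform in [0.5, 2] to exercise normalisation.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, PeakSet, merge


def _default_chrom_lengths() -> dict[str, int]:
    return {"chr1": 3_000_000, "chr2": 3_000_000, "chr3": 3_000_000, "chr4": 3_000_000}


@dataclass
class SimulationConfig:
    seed: int = 0
    n_preterm: int = 6
    n_term: int = 3
    n_replicates: int = 3
    n_peaks: int = 2000
    chrom_lengths: dict[str, int] = field(default_factory=_default_chrom_lengths)
    frac_ptb_effect: float = 0.05
    frac_ga_effect: float = 0.05
    frac_both: float = 0.02
    lfc_ptb: float = 1.5
    slope_ga: float = 0.08
    dispersion: float = 0.1
    base_mean_range: tuple[float, float] = (200.0, 5000.0)
    replicate_dropout: float = 0.0
    peak_jitter_bp: int = 25
    window: int = 500
    shore_bp: int = 2000
    shelf_bp: int = 4000

    def __post_init__(self) -> None:
        if self.frac_ptb_effect + self.frac_ga_effect + self.frac_both > 1:
            raise ValueError("effect fractions sum to more than 1")
        for name in ("n_preterm", "n_term", "n_replicates", "n_peaks"):
            if getattr(self, name) < 0 or (name == "n_peaks" and self.n_peaks == 0):
                raise ValueError(f"{name} must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0 <= self.replicate_dropout < 1:
            raise ValueError("replicate_dropout must be in [0, 1)")


@dataclass
class GenomeBundle:
    genes: pd.DataFrame          # BED12 schema, see io.BED12_COLUMNS
    islands: PeakSet
    states: pd.DataFrame         # chrom, start, end, state


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    genome: GenomeBundle
    samples: pd.DataFrame
    truth: pd.DataFrame
    peaks: list[GenomicInterval]
    replicate_peaks: dict[str, list[PeakSet]]
    replicate_counts: dict[str, list[pd.DataFrame]]
    totals: np.ndarray           # peaks x samples, the drawn NB totals
    size_factors: np.ndarray

    def write(self, outdir: str | Path) -> Path:
        from .io import write_bed

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.genome.genes.to_csv(out / "genes.bed12", sep="\t", header=False, index=False)
        write_bed(self.genome.islands, out / "cpg_islands.bed")
        self.genome.states.to_csv(out / "chromatin_states.bed", sep="\t", header=False, index=False)
        self.samples.to_csv(out / "samples.csv", index=False)
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        with open(out / "chrom.sizes", "w", encoding="utf-8") as fh:
            for chrom, length in self.config.chrom_lengths.items():
                fh.write(f"{chrom}\t{length}\n")
        files = [
            "genes.bed12", "cpg_islands.bed", "chromatin_states.bed",
            "samples.csv", "truth.tsv", "chrom.sizes",
        ]
        for sid in self.replicate_peaks:
            for k in range(self.config.n_replicates):
                pb = out / f"peaks_{sid}_rep{k + 1}.bed"
                write_bed(self.replicate_peaks[sid][k], pb)
                ct = out / f"counts_{sid}_rep{k + 1}.tsv"
                self.replicate_counts[sid][k].to_csv(ct, sep="\t", index=False)
                files += [pb.name, ct.name]
        with open(out / "MANIFEST.tsv", "w", encoding="utf-8") as fh:
            fh.write(f"seed\t{self.config.seed}\n")
            for f in files:
                fh.write(f"file\t{f}\n")
        return out


def simulate_genome(cfg: SimulationConfig) -> GenomeBundle:
    """Toy genome: BED12 genes, disjoint CpG islands, chromatin-state track."""
    rng = np.random.default_rng(cfg.seed + 1)
    genes, islands, states = [], [], []
    gid = 0
    min_gene = 5000
    for chrom, length in cfg.chrom_lengths.items():
        if length < min_gene + 4000:
            raise ValueError(f"{chrom} too short ({length} bp) to place any gene")
        pos = int(rng.integers(2000, 10000))
        while pos + min_gene < length - 2000:
            tx_len = int(rng.integers(min_gene, min(40_000, length - pos - 2000)))
            start, end = pos, pos + tx_len
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(2, 9))
            # exon boundaries: first block at 0, last ends at tx end
            inner = np.sort(rng.choice(np.arange(200, tx_len - 200), 2 * (n_ex - 1), replace=False))
            bounds = np.concatenate([[0], inner, [tx_len]])
            block_starts = bounds[0::2]
            block_ends = bounds[1::2]
            sizes = block_ends - block_starts
            thick_lo = int(start + sizes[0] // 2)
            thick_hi = int(end - sizes[-1] // 2)
            gid += 1
            genes.append(
                dict(
                    chrom=chrom, start=start, end=end, name=f"GENE{gid:04d}",
                    score=0, strand=strand, thick_start=thick_lo, thick_end=thick_hi,
                    rgb="0", block_count=n_ex,
                    block_sizes=",".join(map(str, sizes)),
                    block_starts=",".join(map(str, block_starts)),
                )
            )
            tss = start if strand == "+" else end
            states.append((chrom, max(0, tss - 1000), min(length, tss + 1000), "promoter"))
            if rng.random() < 0.6:  # CpG island near a subset of TSSs
                iw = int(rng.integers(300, 1500))
                lo = max(0, tss - iw // 2)
                islands.append(GenomicInterval(chrom, lo, min(length, lo + iw)))
            pos = end + int(rng.integers(3000, 20_000))
        # intergenic islands and enhancers
        for _ in range(max(2, length // 300_000)):
            lo = int(rng.integers(0, length - 2000))
            islands.append(GenomicInterval(chrom, lo, lo + int(rng.integers(300, 1500))))
            elo = int(rng.integers(0, length - 3000))
            states.append((chrom, elo, elo + int(rng.integers(500, 2000)), "enhancer"))
    if not genes:
        raise ValueError("no genes placed; chromosomes too short")
    genes_df = pd.DataFrame(genes)
    islands_ps = merge(islands)
    states_df = pd.DataFrame(states, columns=["chrom", "start", "end", "state"])
    states_df = states_df.sort_values(["chrom", "start"]).reset_index(drop=True)
    return GenomeBundle(genes_df, islands_ps, states_df)


def simulate_cohort(cfg: SimulationConfig) -> pd.DataFrame:
    """Cohort metadata: preterm GA in [25, 34] wk, term in [37, 41] wk."""
    rng = np.random.default_rng(cfg.seed + 2)
    rows = []
    for i in range(cfg.n_preterm + cfg.n_term):
        preterm = i < cfg.n_preterm
        ga = rng.uniform(25, 34) if preterm else rng.uniform(37, 41)
        ga = round(float(ga), 1)
        bw = int(1541 + 166 * (ga - 30) + rng.normal(0, 150))
        rows.append(
            dict(
                sample_id=f"Sample{i + 1}",
                group="preterm" if preterm else "term",
                gestational_age=ga,
                birth_weight=bw,
            )
        )
    return pd.DataFrame(rows)


def _place_peaks(cfg: SimulationConfig, rng: np.random.Generator) -> list[GenomicInterval]:
    chroms = list(cfg.chrom_lengths)
    lengths = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    per_chrom = np.maximum(1, np.round(cfg.n_peaks * lengths / lengths.sum()).astype(int))
    while per_chrom.sum() > cfg.n_peaks:
        per_chrom[np.argmax(per_chrom)] -= 1
    while per_chrom.sum() < cfg.n_peaks:
        per_chrom[np.argmax(lengths / per_chrom)] += 1
    peaks: list[GenomicInterval] = []
    for chrom, n_here in zip(chroms, per_chrom):
        length = cfg.chrom_lengths[chrom]
        pos = int(rng.integers(500, 2000))
        placed = 0
        while placed < n_here:
            w = int(rng.integers(500, 3001))
            if pos + w > length - 500:
                raise ValueError(
                    f"{chrom} ({length} bp) too short for requested peak count"
                )
            peaks.append(GenomicInterval(chrom, pos, pos + w))
            placed += 1
            pos += w + int(rng.integers(500, 2001))
    return peaks


def simulate_counts(
    cfg: SimulationConfig,
    genome: GenomeBundle | None = None,
    samples: pd.DataFrame | None = None,
) -> SimulatedStudy:
    """Planted-effect NB counts plus replicate peak calls and count tables."""
    cfg.__post_init__()  # re-validate (configs may be mutated by callers)
    if genome is None:
        genome = simulate_genome(cfg)
    if samples is None:
        samples = simulate_cohort(cfg)
    rng = np.random.default_rng(cfg.seed + 3)
    peaks = _place_peaks(cfg, rng)
    n = len(peaks)

    # effect classes
    classes = np.array(["none"] * n, dtype=object)
    idx = rng.permutation(n)
    n_ptb = int(round(cfg.frac_ptb_effect * n))
    n_ga = int(round(cfg.frac_ga_effect * n))
    n_both = int(round(cfg.frac_both * n))
    classes[idx[:n_ptb]] = "ptb"
    classes[idx[n_ptb:n_ptb + n_ga]] = "ga"
    classes[idx[n_ptb + n_ga:n_ptb + n_ga + n_both]] = "both"

    base_mean = np.exp(
        rng.uniform(np.log(cfg.base_mean_range[0]), np.log(cfg.base_mean_range[1]), n)
    )
    sign_ptb = rng.choice([-1.0, 1.0], n)
    sign_ga = rng.choice([-1.0, 1.0], n)
    b1 = np.where(np.isin(classes, ["ptb", "both"]), sign_ptb * cfg.lfc_ptb, 0.0)
    b2 = np.where(np.isin(classes, ["ga", "both"]), sign_ga * cfg.slope_ga, 0.0)
    # anchor the baseline so that a term-reference sample (GA 39, not preterm)
    # has expected count base_mean: b0 = log2(base_mean) - b2 * 39
    b0 = np.log2(base_mean) - b2 * 39.0

    sids = list(samples["sample_id"])
    preterm = (samples["group"] == "preterm").to_numpy(float)
    ga = samples["gestational_age"].to_numpy(float)
    sf = np.exp(rng.uniform(np.log(0.5), np.log(2.0), len(sids)))

    log2_mu = b0[:, None] + b1[:, None] * preterm[None, :] + b2[:, None] * ga[None, :]
    mu = sf[None, :] * np.exp2(log2_mu)
    if cfg.dispersion > 0:
        r = 1.0 / cfg.dispersion
        totals = rng.negative_binomial(r, r / (r + mu))
    else:
        totals = rng.poisson(mu)
    totals = totals.astype(np.int64)

    truth = pd.DataFrame(
        {
            "peak": [str(p) for p in peaks],
            "chrom": [p.chrom for p in peaks],
            "start": [p.start for p in peaks],
            "end": [p.end for p in peaks],
            "base_mean": base_mean,
            "log2_ptb_effect": b1,
            "log2_ga_slope": b2,
            "effect_class": classes,
        }
    )

    replicate_peaks: dict[str, list[PeakSet]] = {}
    replicate_counts: dict[str, list[pd.DataFrame]] = {}
    probs = np.full(cfg.n_replicates, 1.0 / cfg.n_replicates)
    for j, sid in enumerate(sids):
        rep_counts = np.array(
            [rng.multinomial(t, probs) for t in totals[:, j]]
        )  # n x n_replicates
        sets, tables = [], []
        for k in range(cfg.n_replicates):
            jit_lo = rng.integers(0, cfg.peak_jitter_bp + 1, n)
            jit_hi = rng.integers(0, cfg.peak_jitter_bp + 1, n)
            called = rng.random(n) >= cfg.replicate_dropout
            ivs = [
                GenomicInterval(p.chrom, max(0, p.start - int(a)), p.end + int(bnd))
                for p, a, bnd, keep in zip(peaks, jit_lo, jit_hi, called)
                if keep
            ]
            sets.append(PeakSet(ivs, source_label=f"{sid}_rep{k + 1}", validate=False))
            tables.append(
                pd.DataFrame(
                    {
                        "chrom": [p.chrom for p in peaks],
                        "start": [p.start for p in peaks],
                        "end": [p.end for p in peaks],
                        "count": rep_counts[:, k],
                    }
                )
            )
        replicate_peaks[sid] = sets
        replicate_counts[sid] = tables

    return SimulatedStudy(
        config=cfg,
        genome=genome,
        samples=samples,
        truth=truth,
        peaks=peaks,
        replicate_peaks=replicate_peaks,
        replicate_counts=replicate_counts,
        totals=totals,
        size_factors=sf,
    )
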