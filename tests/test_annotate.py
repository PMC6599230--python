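"""Annotation: CpG context, window grid, category classification, nearest gene."""

import numpy as np
import pandas as pd
import pytest

from medipdmr.annotate import (
    CATEGORIES,
    GeneModel,
    category_percentages,
    classify_dmr,
    cpg_flanks,
    flag_windows,
    make_windows,
    nearest_gene,
    states_to_features,
)
from medipdmr.datasets import load_ga_dmr_table, load_ptb_dmr_table
from medipdmr.intervals import GenomicInterval, PeakSet, overlaps
from medipdmr.io import read_bed12


def iv(c, s, e):
    return GenomicInterval(c, s, e)


class TestCpGFlanks:
    LEN = {"c1": 1_000_000}

    def test_single_island_definition(self):
        ctx = cpg_flanks(PeakSet([iv("c1", 10000, 11000)]), self.LEN)
        assert list(ctx.shores) == [iv("c1", 8000, 10000), iv("c1", 11000, 13000)]
        assert list(ctx.shelves) == [iv("c1", 6000, 8000), iv("c1", 13000, 15000)]

    def test_island_at_chromosome_start_clips_left_flanks(self):
        ctx = cpg_flanks(PeakSet([iv("c1", 0, 500)]), self.LEN)
        assert list(ctx.shores) == [iv("c1", 500, 2500)]
        assert list(ctx.shelves) == [iv("c1", 2500, 4500)]

    def test_island_outside_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            cpg_flanks(PeakSet([iv("c1", 999_900, 1_000_200)]), self.LEN)

    @staticmethod
    def per_base_labels(islands, length, shore_bp=2000, shelf_bp=4000):
        """Brute-force per-bp labelling with island > shore > shelf precedence."""
        lab = np.zeros(length, dtype=np.int8)  # 0 none, 3 shelf, 2 shore, 1 island
        for s, e in islands:
            lo, hi = max(0, s - shelf_bp), min(length, e + shelf_bp)
            lab[lo:hi] = np.where(lab[lo:hi] == 0, 3, lab[lo:hi])
        for s, e in islands:
            lo, hi = max(0, s - shore_bp), min(length, e + shore_bp)
            lab[lo:hi] = np.where(np.isin(lab[lo:hi], (0, 3)), 2, lab[lo:hi])
        for s, e in islands:
            lab[s:e] = 1
        return lab

    def test_two_close_islands_match_per_base_oracle(self):
        islands = [(10_000, 10_500), (13_500, 14_000)]  # 3 kb apart
        length = 30_000
        ctx = cpg_flanks(
            PeakSet([iv("c1", s, e) for s, e in islands]), {"c1": length}
        )
        lab = self.per_base_labels(islands, length)
        got = np.zeros(length, dtype=np.int8)
        for code, ps in ((1, ctx.islands), (2, ctx.shores), (3, ctx.shelves)):
            for r in ps:
                assert (got[r.start:r.end] == 0).all()  # pairwise disjoint
                got[r.start:r.end] = code
        np.testing.assert_array_equal(got, lab)

    def test_random_islands_disjointness_property(self):
        length = 60_000
        for seed in range(15):
            rng = np.random.default_rng(seed)
            islands = PeakSet(
                [
                    iv("c1", int(s), int(s) + int(rng.integers(100, 2000)))
                    for s in rng.integers(0, length - 2500, 8)
                ]
            )
            ctx = cpg_flanks(islands, {"c1": length})
            lab = self.per_base_labels([(r.start, r.end) for r in islands], length)
            got = np.zeros(length, dtype=np.int8)
            for code, ps in ((1, ctx.islands), (2, ctx.shores), (3, ctx.shelves)):
                for r in ps:
                    assert (got[r.start:r.end] == 0).all()
                    got[r.start:r.end] = code
            np.testing.assert_array_equal(got, lab)


class TestWindows:
    def test_exact_tiling(self):
        grid = make_windows({"c1": 1500})
        assert grid.n_windows == 3

    def test_partial_final_tile(self):
        grid = make_windows({"c1": 1501})
        assert grid.n_windows == 4
        last = grid.windows.iloc[-1]
        assert last["end"] - last["start"] == 1

    def test_total_window_count(self):
        lengths = {"c1": 12_345, "c2": 999, "c3": 500}
        grid = make_windows(lengths)
        assert grid.n_windows == sum(-(-v // 500) for v in lengths.values())

    def test_feature_covering_chromosome_flags_all_its_windows(self):
        grid = make_windows({"c1": 5000, "c2": 5000})
        grid = flag_windows(grid, {"f": PeakSet([iv("c1", 0, 5000)])})
        flags = grid.flags["f"].to_numpy()
        on_c1 = (grid.windows["chrom"] == "c1").to_numpy()
        assert flags[on_c1].all()
        assert not flags[~on_c1].any()

    def test_one_bp_feature_flags_exactly_one_window(self):
        grid = make_windows({"c1": 5000})
        grid = flag_windows(grid, {"f": PeakSet([iv("c1", 1500, 1501)])})
        assert grid.flags["f"].sum() == 1
        assert grid.flags["f"].to_numpy()[3]

    def test_flags_match_quadratic_overlap_scan(self):
        rng = np.random.default_rng(0)
        length = 25_000  # 50 windows
        feats = PeakSet(
            [iv("c1", int(s), int(s) + int(rng.integers(1, 900))) for s in rng.integers(0, length - 1000, 12)]
        )
        grid = flag_windows(make_windows({"c1": length}), {"f": feats})
        for k, w in grid.windows.iterrows():
            wiv = iv(w["chrom"], int(w["start"]), int(w["end"]))
            expect = any(overlaps(wiv, f) for f in feats)
            assert bool(grid.flags["f"][k]) == expect


class TestClassify:
    @pytest.fixture()
    def genes(self, tiny_genes_bed12):
        return GeneModel.from_bed12(read_bed12(tiny_genes_bed12))

    def test_promoter_bin_upstream_of_plus_tss(self, genes):
        # GENE_A TSS at 10000 (+); midpoint 9500 is 500 bp upstream
        assert classify_dmr(iv("chr1", 9400, 9600), genes) == "Promoter (<=1 kb)"

    def test_promoter_bins_strand_aware(self, genes):
        # GENE_B TSS at 60000 (-); upstream extends rightwards
        assert classify_dmr(iv("chr1", 61400, 61600), genes) == "Promoter (1-2 kb)"
        assert classify_dmr(iv("chr1", 62400, 62600), genes) == "Promoter (2-3 kb)"

    def test_utrs_and_exon(self, genes):
        # GENE_A: coding 10500-19500; exon1 10000-11000 -> 5'UTR 10000-10500
        assert classify_dmr(iv("chr1", 10150, 10250), genes) == "5′ UTR"
        assert classify_dmr(iv("chr1", 19600, 19800), genes) == "3′ UTR"
        assert classify_dmr(iv("chr1", 14200, 14600), genes) == "Exon"

    def test_first_vs_other_intron_strand_aware(self, genes):
        # GENE_A (+): introns [11000,14000) then [15000,19000)
        assert classify_dmr(iv("chr1", 12000, 12100), genes) == "1st Intron"
        assert classify_dmr(iv("chr1", 16000, 16100), genes) == "Other Intron"
        # GENE_B (-): the first intron in transcript order is the right one
        assert classify_dmr(iv("chr1", 53000, 53100), genes) == "1st Intron"

    def test_downstream_and_distal(self, genes):
        # GENE_A TES at 20000 (+): within 3 kb downstream
        assert classify_dmr(iv("chr1", 21900, 22100), genes) == "Downstream (<=3 kb)"
        assert classify_dmr(iv("chr1", 900_000, 900_200), genes) == "Distal Intergenic"

    def test_category_always_defined(self, genes):
        rng = np.random.default_rng(1)
        for s in rng.integers(0, 990_000, 100):
            cat = classify_dmr(iv("chr1", int(s), int(s) + 100), genes)
            assert cat in CATEGORIES


class TestNearestGene:
    @pytest.fixture()
    def genes(self, tiny_genes_bed12):
        return GeneModel.from_bed12(read_bed12(tiny_genes_bed12))

    def test_single_gene(self, genes):
        sym, d = nearest_gene(iv("chr1", 100, 200), genes)
        assert sym == "GENE_A"

    def test_inside_transcript_distance_zero(self, genes):
        sym, d = nearest_gene(iv("chr1", 15000, 15100), genes)
        assert (sym, d) == ("GENE_A", 0)

    def test_tie_prefers_lexicographically_smaller(self, genes):
        # TSSs at 10000 (+) and 60000 (-): equidistant midpoint 35000
        sym, _ = nearest_gene(iv("chr1", 34950, 35050), genes)
        assert sym == "GENE_A"

    def test_no_gene_on_chromosome(self, genes):
        assert nearest_gene(iv("chr9", 0, 100), genes) == ("NA", 0)

    def test_matches_exhaustive_scan_on_random_gene_set(self):
        rng = np.random.default_rng(2)
        rows = []
        for i in range(20):
            s = int(rng.integers(0, 900_000))
            e = s + int(rng.integers(2000, 20_000))
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append(
                dict(chrom="c1", start=s, end=e, name=f"G{i:02d}", score=0,
                     strand=strand, thick_start=s, thick_end=e, rgb="0",
                     block_count=1, block_sizes=str(e - s), block_starts="0")
            )
        gm = GeneModel.from_bed12(pd.DataFrame(rows))
        for s in rng.integers(0, 990_000, 50):
            dmr = iv("c1", int(s), int(s) + 200)
            sym, _ = nearest_gene(dmr, gm)
            mid = dmr.midpoint
            best = min(
                gm.genes,
                key=lambda g: (0 if g.start <= mid < g.end else abs(g.tss - mid), g.symbol),
            )
            assert sym == best.symbol


class TestCategoryPercentages:
    def test_single_category(self):
        t = pd.DataFrame({"Annotation": ["Exon"] * 4})
        pct = category_percentages(t)
        assert pct["Exon"] == 100.0

    def test_fixture_modal_category_is_distal_intergenic(self):
        pct = category_percentages(load_ptb_dmr_table())
        assert pct.idxmax() == "Distal Intergenic"
        assert pct.sum() == pytest.approx(100.0)

    def test_fixture_categories_are_known_strings(self):
        # printed tables collapse the two intron classes to "Intron"
        allowed = set(CATEGORIES) | {"Intron"}
        for t in (load_ptb_dmr_table(), load_ga_dmr_table()):
            assert set(t["Annotation"]).issubset(allowed)


def test_states_to_features_default_mapping():
    states = pd.DataFrame(
        {
            "chrom": ["c1"] * 4,
            "start": [0, 1000, 2000, 3000],
            "end": [500, 1500, 2500, 3500],
            "state": ["1_TssA", "promoter", "7_Enh", "Quies"],
        }
    )
    feats = states_to_features(states)
    assert [r.start for r in feats["promoters"]] == [0, 1000]
    assert [r.start for r in feats["enhancers"]] == [2000]
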