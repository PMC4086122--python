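import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from cisenrich.regions import (assign_windows, build_target_set,
                               define_regions, gene_score, score_genes)
from cisenrich.transforms import NormalizedProfile
from cisenrich.windows import tile_windows


def genes_from(rows):
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                     "strand"])
    df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    return df


CHROM_LEN = {"chr1": 20_000}


class TestDefineRegions:
    def test_fixed_paper_example(self):
        genes = genes_from([("g", "chr1", 10_000, 11_000, "+")])
        regions = define_regions(genes, "fixed", CHROM_LEN,
                                 upstream=5000, downstream=2000)
        assert regions[0].intervals == [("chr1", 5000, 12_000)]

    def test_fixed_minus_strand_mirrored(self):
        genes = genes_from([("g", "chr1", 9_000, 10_001, "-")])  # tss 10000
        regions = define_regions(genes, "fixed", CHROM_LEN,
                                 upstream=5000, downstream=2000)
        assert regions[0].intervals == [("chr1", 8001, 15_001)]

    def test_fixed_clamped_to_chromosome(self):
        genes = genes_from([("g", "chr1", 1_000, 2_000, "+")])
        regions = define_regions(genes, "fixed", CHROM_LEN, upstream=5000)
        assert regions[0].intervals == [("chr1", 0, 1_000)]

    def test_fixed_zero_extent_rejected(self):
        genes = genes_from([("g", "chr1", 100, 200, "+")])
        with pytest.raises(ValueError):
            define_regions(genes, "fixed", CHROM_LEN, upstream=0, downstream=0)

    def test_unknown_mode_rejected(self):
        genes = genes_from([("g", "chr1", 100, 200, "+")])
        with pytest.raises(ValueError, match="mode"):
            define_regions(genes, "voronoi", CHROM_LEN)

    def test_nearest_tss_single_gene_whole_chromosome(self):
        genes = genes_from([("g", "chr1", 5_000, 6_000, "+")])
        regions = define_regions(genes, "nearest_tss", CHROM_LEN)
        assert regions[0].intervals == [("chr1", 0, 20_000)]

    def test_territory_half_gap_example(self, gene_table):
        regions = define_regions(gene_table, "territory",
                                 {"chr1": 20_000, "chr2": 5_000})
        by_id = {r.gene_id: r for r in regions}
        assert by_id["geneB"].intervals == [("chr1", 3_000, 6_500)]
        # end genes extend to the chromosome boundaries
        assert by_id["geneA"].intervals == [("chr1", 0, 3_000)]
        assert by_id["geneC"].intervals == [("chr1", 6_500, 20_000)]


class TestAssignWindows:
    def test_midpoint_count_in_fixed_region(self):
        genes = genes_from([("g", "chr1", 10_000, 11_000, "+")])
        regions = define_regions(genes, "fixed", CHROM_LEN,
                                 upstream=5000, downstream=2000)
        windows = tile_windows(CHROM_LEN)
        assignment = assign_windows(regions, windows)
        # midpoints 250k+250 in [5000, 12000): k = 19..46
        assert len(assignment["g"]) == 28

    def test_region_with_no_midpoint_is_empty(self):
        genes = genes_from([("g", "chr1", 10_010, 10_020, "+")])
        regions = define_regions(genes, "fixed", CHROM_LEN,
                                 upstream=0, downstream=10)
        assignment = assign_windows(regions, tile_windows(CHROM_LEN))
        assert len(assignment["g"]) == 0

    def test_nearest_tss_is_a_partition(self, gene_table):
        lengths = {"chr1": 20_000, "chr2": 5_000}
        regions = define_regions(gene_table, "nearest_tss", lengths)
        windows = tile_windows(lengths)
        assignment = assign_windows(regions, windows)
        counts = np.zeros(len(windows), dtype=int)
        for wins in assignment.values():
            counts[wins] += 1
        assert (counts == 1).all()

    def test_nearest_tss_midpoint_tie_goes_to_lower_tss(self):
        # TSSs at 4000 and 6000: position 5000 is equidistant
        genes = genes_from([("lo", "chr1", 4_000, 4_500, "+"),
                            ("hi", "chr1", 6_000, 6_500, "+")])
        regions = define_regions(genes, "nearest_tss", CHROM_LEN)
        by_id = {r.gene_id: r for r in regions}
        assert by_id["lo"].intervals == [("chr1", 0, 5_001)]
        assert by_id["hi"].intervals == [("chr1", 5_001, 20_000)]


class TestGeneScore:
    def test_single_window_identity(self):
        assert gene_score(0.37, 1) == pytest.approx(0.37)

    def test_perfect_window_limit(self):
        assert gene_score(1e-300, 50) == pytest.approx(0.0, abs=1e-290)

    def test_printed_formula_value(self):
        assert gene_score(0.01, 10) == pytest.approx(1 - 0.99 ** 10,
                                                     abs=1e-12)
        assert gene_score(0.01, 10) == pytest.approx(0.0956179, abs=5e-8)

    def test_no_windows_scores_one(self):
        assert gene_score(0.5, 0) == 1.0

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.floats(min_value=1e-6, max_value=0.999),
           st.floats(min_value=1e-6, max_value=0.999),
           st.integers(min_value=1, max_value=500))
    def test_strictly_increasing_in_p_and_w(self, p1, p2, w):
        lo, hi = sorted((p1, p2))
        # strictness is only observable while (1-P)^w stays above one ulp of 1
        assume((1 - hi) ** (w + 1) > 1e-12)
        if lo < hi:
            assert gene_score(lo, w) < gene_score(hi, w)
        assert gene_score(lo, w) < gene_score(lo, w + 1)

    def test_masked_window_never_decreases_s(self):
        # adding a window with normalized value 1 raises w_g only
        rng = np.random.default_rng(0)
        for _ in range(100):
            p = float(rng.uniform(1e-4, 0.99))
            w = int(rng.integers(1, 50))
            assert gene_score(p, w + 1) >= gene_score(p, w)


class TestScoreGenes:
    def test_p_is_min_and_w_counts_all(self):
        norm = NormalizedProfile("f", np.array([0.5, 0.02, 1.0, 0.3]))
        assignment = {"gA": np.array([0, 1, 2]), "gB": np.array([3]),
                      "gC": np.array([], dtype=int)}
        df = score_genes(norm, assignment).set_index("gene_id")
        assert df.loc["gA", "P_g"] == pytest.approx(0.02)
        assert df.loc["gA", "w_g"] == 3
        assert df.loc["gA", "S_g"] == pytest.approx(1 - 0.98 ** 3)
        assert df.loc["gB", "S_g"] == pytest.approx(0.3)
        assert df.loc["gC", "S_g"] == 1.0 and df.loc["gC", "w_g"] == 0


class TestBuildTargetSet:
    def scores(self, n):
        rng = np.random.default_rng(12)
        return pd.DataFrame(dict(
            gene_id=[f"g{i:04d}" for i in range(n)],
            P_g=rng.uniform(size=n), w_g=1,
            S_g=rng.permutation(np.linspace(0.001, 0.999, n))))

    def test_default_k_500(self):
        df = self.scores(1000)
        ts = build_target_set(df, df["gene_id"].tolist())
        assert len(ts) == 500
        s = df.set_index("gene_id")["S_g"]
        assert max(s[g] for g in ts.genes) < s[~s.index.isin(ts.genes)].min()

    def test_small_universe_saturates(self):
        df = self.scores(10)
        ts = build_target_set(df, df["gene_id"].tolist(), K=500)
        assert len(ts) == 10

    def test_tie_break_lexicographic(self):
        df = pd.DataFrame(dict(gene_id=["b", "a", "c"], P_g=0.5, w_g=1,
                               S_g=[0.5, 0.5, 0.1]))
        ts = build_target_set(df, ["a", "b", "c"], K=2)
        assert ts.genes == ["c", "a"]

    def test_universe_restriction(self):
        df = self.scores(20)
        ts = build_target_set(df, ["g0003", "g0007"], K=500)
        assert sorted(ts.genes) == ["g0003", "g0007"]

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            build_target_set(self.scores(5), [], K=10)
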