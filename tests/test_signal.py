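"""Windowed counting, metagene density, binning and group statistics."""
import numpy as np
import pytest

from loophub import (
    CoverageTrack,
    Gene,
    GenomicInterval,
    ReadIndex,
    bin_average,
    binding_per_interaction,
    count_in_window,
    group_compare,
    make_window,
    metagene_density,
    normalize_to_reference,
)


class TestWindows:
    def test_plus_strand_tss_window(self):
        g = Gene("g", "chr1", 10_000, 14_000, "+")
        assert make_window(g, "tss_pm", 2000) == GenomicInterval(
            "chr1", 8000, 12_000, "+"
        )

    def test_minus_strand_downstream_extends_leftward(self):
        g = Gene("g", "chr1", 10_000, 14_000, "-")
        w = make_window(g, "tss_downstream", 2000)
        assert (w.start, w.end) == (12_000, 14_000)

    def test_window_clipped_at_chromosome_edge(self):
        g = Gene("g", "chr1", 500, 3000, "+")
        w = make_window(g, "tss_pm", 2000, chrom_length=2800)
        assert (w.start, w.end) == (0, 2500)


class TestCountInWindow:
    WINDOW = GenomicInterval("chr1", 1000, 2000)

    @pytest.mark.parametrize(
        "read,expected",
        [
            (GenomicInterval("chr1", 1200, 1300), 1),  # wholly inside
            (GenomicInterval("chr1", 999, 1000), 0),   # abuts, 0 bp overlap
            (GenomicInterval("chr1", 999, 1001), 1),   # 1 bp overlap
            (GenomicInterval("chr1", 1999, 2100), 1),  # 1 bp at the far edge
            (GenomicInterval("chr2", 1200, 1300), 0),  # wrong chromosome
        ],
    )
    def test_one_bp_rule(self, read, expected):
        assert count_in_window([read], self.WINDOW) == expected

    def test_index_matches_brute_force(self):
        rng = np.random.default_rng(9)
        reads = [
            GenomicInterval("chr1", int(s), int(s) + int(w))
            for s, w in zip(rng.integers(0, 50_000, 500), rng.integers(30, 150, 500))
        ]
        idx = ReadIndex(reads)
        for _ in range(20):
            s = int(rng.integers(0, 49_000))
            win = GenomicInterval("chr1", s, s + 1000)
            assert idx.count(win) == count_in_window(reads, win)


class TestMetageneDensity:
    def _genes(self, n=4, strand="+"):
        return [
            Gene(f"g{i}", "chr1", 50_000 + 20_000 * i, 55_000 + 20_000 * i, strand)
            for i in range(n)
        ]

    def test_constant_track_flat_profile_zero_sem(self):
        track = CoverageTrack([(GenomicInterval("chr1", 0, 1_000_000), 3.0)])
        prof = metagene_density(track, self._genes(), "tss", 2000, 100)
        assert np.allclose(prof.mean, 3.0)
        assert np.allclose(prof.sem, 0.0)
        assert prof.n_genes == 4

    def test_two_gene_sem_formula(self):
        genes = [
            Gene("a", "chr1", 50_000, 55_000, "+"),
            Gene("b", "chr1", 90_000, 95_000, "+"),
        ]
        track = CoverageTrack(
            [
                (GenomicInterval("chr1", 48_000, 52_000), 2.0),
                (GenomicInterval("chr1", 88_000, 92_000), 8.0),
            ]
        )
        prof = metagene_density(track, genes, "tss", 2000, 100)
        assert np.allclose(prof.mean, 5.0)
        assert np.allclose(prof.sem, abs(2.0 - 8.0) / 2)

    def test_strand_flip_mirrors_profile(self):
        track = CoverageTrack([(GenomicInterval("chr1", 50_000, 52_000), 4.0)])
        plus = metagene_density(track, self._genes(1, "+") * 2, "tss", 2000, 100)
        # same genes flipped: TSS moves to the other end, but with a single
        # asymmetric track block the flipped profile is the mirror image
        genes_minus = [
            Gene(g.gene_id, g.chrom, g.start, g.end, "-") for g in self._genes(1) * 2
        ]
        minus = metagene_density(track, genes_minus, "tes", 2000, 100)
        assert np.allclose(minus.mean, plus.mean[::-1])

    def test_linearity_under_spike_scaling(self):
        raw = [(GenomicInterval("chr1", 49_000, 51_000), 10.0)]
        scaled = [(iv, v * 0.25) for iv, v in raw]
        genes = self._genes()
        p_raw = metagene_density(CoverageTrack(raw), genes, "tss", 2000, 100)
        p_scaled = metagene_density(CoverageTrack(scaled), genes, "tss", 2000, 100)
        assert np.allclose(p_scaled.mean, 0.25 * p_raw.mean)
        assert np.allclose(p_scaled.sem, 0.25 * p_raw.sem)

    def test_fewer_than_two_genes_errors(self):
        track = CoverageTrack([])
        with pytest.raises(ValueError):
            metagene_density(track, self._genes(1), "tss", 2000, 100)


class TestBinAverage:
    def test_six_points_bin_size_three(self):
        res = bin_average([6, 5, 4, 3, 2, 1], [60, 50, 40, 30, 20, 10], genes_per_bin=3)
        assert np.allclose(res.x_mean, [2.0, 5.0])
        assert np.allclose(res.y_mean, [20.0, 50.0])

    def test_remainder_forms_last_smaller_bin(self):
        n, size = 14_085, 150
        res = bin_average(np.arange(n), np.arange(n), genes_per_bin=size)
        assert len(res.x_mean) == 94
        assert res.bin_sizes[-1] == 135
        assert res.bin_sizes[:-1].tolist() == [150] * 93

    def test_n_bins_mode_produces_exact_count(self):
        res = bin_average(np.arange(13_239), np.ones(13_239), n_bins=20)
        assert len(res.x_mean) == 20
        assert res.bin_sizes.sum() == 13_239

    def test_constant_y_gives_constant_bins(self):
        res = bin_average(np.arange(100), np.full(100, 7.0), genes_per_bin=10)
        assert np.allclose(res.y_mean, 7.0)

    def test_bin_size_one_is_identity_on_sorted_data(self):
        x = np.array([3.0, 1.0, 2.0])
        y = np.array([30.0, 10.0, 20.0])
        res = bin_average(x, y, genes_per_bin=1)
        assert np.allclose(res.x_mean, [1, 2, 3])
        assert np.allclose(res.y_mean, [10, 20, 30])


class TestNormalizeToReference:
    def test_reference_median_maps_to_one(self):
        ref = [1.0, 2.0, 9.0]
        assert np.median(normalize_to_reference(ref, ref)) == pytest.approx(1.0)

    def test_worked_example(self):
        assert np.allclose(normalize_to_reference([2, 4, 6], [1, 2, 3]), [1, 2, 3])

    def test_rank_order_preserved(self):
        vals = [5.0, 1.0, 3.0]
        out = normalize_to_reference(vals, [2.0, 2.0, 2.0])
        assert np.argsort(out).tolist() == np.argsort(vals).tolist()

    def test_nonpositive_median_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_reference([1.0], [0.0, 0.0, 0.0])


class TestBindingPerInteraction:
    def test_global_ratio(self):
        assert binding_per_interaction([600, 400], [60, 40]) == pytest.approx(10.0)

    def test_scale_invariance_of_joint_doubling(self):
        a = binding_per_interaction([600, 400], [60, 40])
        b = binding_per_interaction([1200, 800], [120, 80])
        assert a == pytest.approx(b)

    def test_spike_factor_linearity(self):
        f = 0.37
        base = binding_per_interaction([600, 400], [60, 40])
        scaled = binding_per_interaction([600 * f, 400 * f], [60, 40])
        assert scaled == pytest.approx(f * base)

    def test_zero_interactions_advises_per_window(self):
        with pytest.raises(ValueError, match="per_window"):
            binding_per_interaction([10.0], [0.0])
        out = binding_per_interaction([10.0, 4.0], [0.0, 2.0], mode="per_window")
        assert np.isnan(out[0]) and out[1] == pytest.approx(2.0)


class TestGroupCompare:
    def test_identical_groups_ranksum_p_one(self):
        assert group_compare([1, 2, 3], [1, 2, 3], "ranksum") == pytest.approx(1.0)

    def test_welch_t_zero_statistic(self):
        assert group_compare([1, 2, 3], [1, 2, 3], "t_unpaired_unequal_var") == (
            pytest.approx(1.0)
        )

    def test_exact_ranksum_extreme_split(self):
        assert group_compare([1, 2, 3], [4, 5, 6], "ranksum") == pytest.approx(0.1)

    def test_degenerate_variance_falls_back_to_rank_test(self, caplog):
        p = group_compare([5, 5, 5], [9, 9, 9], "t_unpaired_unequal_var")
        assert 0 < p <= 1.0

    def test_welch_matches_scipy_on_random_data(self):
        from scipy import stats

        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 2, 9)
        assert group_compare(a, b, "t_unpaired_unequal_var") == pytest.approx(
            stats.ttest_ind(a, b, equal_var=False).pvalue
        )
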