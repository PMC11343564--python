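"""The synthetic-data generator: determinism and planted-truth properties."""
import numpy as np
import pytest

from loophub import (
    LIGATION_SITES,
    SyntheticSpec,
    generate_annotations,
    generate_genome,
    generate_loops,
    generate_reads,
    trim_linker,
)


class TestGenerateGenome:
    def test_planted_sites_and_nothing_else(self):
        spec = SyntheticSpec(seed=0, chrom_sizes={"chrT": 1000}, spike_chrom_sizes={})
        seqs, fm = generate_genome(spec, planted_sites={"chrT": [100, 500]})
        seq = seqs["chrT"]
        occurrences = [i for i in range(len(seq) - 3) if seq[i : i + 4] == "GATC"]
        assert occurrences == [100, 500]
        assert [(f.start, f.end) for f in fm.fragments["chrT"]] == [
            (0, 100), (100, 500), (500, 1000),
        ]

    def test_site_spacing_below_four_rejected(self):
        spec = SyntheticSpec(seed=0, chrom_sizes={"chrT": 1000}, spike_chrom_sizes={})
        with pytest.raises(ValueError, match="4 bp"):
            generate_genome(spec, planted_sites={"chrT": [100, 102]})

    def test_random_mode_gatc_rate_binomial(self):
        spec = SyntheticSpec(
            seed=8, chrom_sizes={"chrT": 100_000}, spike_chrom_sizes={}, gc_content=0.5
        )
        seqs, _ = generate_genome(spec)
        seq = seqs["chrT"]
        count = sum(1 for i in range(len(seq) - 3) if seq[i : i + 4] == "GATC")
        # oracle: per-position probability (1/4)^4 at GC = 0.5
        n = 100_000 - 3
        p = 0.25**4
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(count - n * p) < 3 * sigma

    def test_byte_identical_determinism(self):
        spec = SyntheticSpec(seed=33, chrom_sizes={"chrT": 20_000})
        a, _ = generate_genome(spec)
        b, _ = generate_genome(spec)
        assert a == b


class TestGenerateAnnotations:
    def test_promoter_truth_is_tss_window(self, default_spec, annotations, catalog):
        for g in annotations.genes[:50]:
            assert catalog.classes["promoter"].count(
                __import__("loophub").GenomicInterval(
                    g.chrom, g.tss - 500, g.tss + 500, g.strand
                )
            ) >= 1

    def test_derived_enhancers_equal_planted_truth(self, annotations):
        from loophub import derive_enhancers

        derived = derive_enhancers(
            annotations.histone_peaks["H3K4me1"],
            annotations.histone_peaks["H3K27ac"],
            annotations.histone_peaks["H3K4me3"],
        )
        assert sorted((e.chrom, e.start, e.end) for e in derived) == sorted(
            (e.chrom, e.start, e.end) for e in annotations.enhancers
        )

    def test_false_enhancers_excluded(self, default_spec, annotations):
        assert len(annotations.false_enhancers) == default_spec.n_false_enhancers
        planted = {(e.chrom, e.start, e.end) for e in annotations.enhancers}
        assert all(
            (f.chrom, f.start, f.end) not in planted
            for f in annotations.false_enhancers
        )

    def test_zero_repeats_give_empty_tracks(self):
        spec = SyntheticSpec(
            seed=1, n_genes=30, n_enhancers=5, n_false_enhancers=0,
            repeat_counts={"SINE": 0}, gene_set_sizes={"all": 30, "down": 3, "up": 5},
            chrom_sizes={"chr1": 400_000},
        )
        ann = generate_annotations(spec)
        assert ann.repeats["SINE"] == []

    def test_strata_sizes(self, default_spec, annotations):
        gs = annotations.gene_sets
        assert len(gs["all"]) == default_spec.gene_set_sizes["all"]
        assert len(gs["down"]) == default_spec.gene_set_sizes["down"]
        assert len(gs["up"]) == default_spec.gene_set_sizes["up"]
        assert not (set(gs["down"]) & set(gs["up"]))
        assert set(gs["down"]) <= set(gs["all"])

    def test_determinism(self, default_spec):
        a = generate_annotations(default_spec)
        b = generate_annotations(default_spec)
        assert a.genes == b.genes
        assert a.enhancers == b.enhancers


class TestGenerateLoops:
    def test_single_class_spec_all_loops_in_class(self):
        spec = SyntheticSpec(
            seed=6, n_loops=10, n_decoys=0,
            class_fractions={("promoter", "promoter"): 1.0},
            n_genes=100, n_enhancers=5, n_false_enhancers=0,
            repeat_counts={"SINE": 20},
            gene_set_sizes={"all": 100, "down": 5, "up": 5},
            chrom_sizes={"chr1": 800_000},
        )
        ann = generate_annotations(spec)
        truth = generate_loops(spec, ann)
        assert len(truth.loops) == 10
        assert (truth.table.class_a == "promoter").all()
        assert (truth.table.class_b == "promoter").all()
        # anchors genuinely lie inside promoter windows
        promoters = [(g.chrom, g.tss - 500, g.tss + 500) for g in ann.genes]
        for lp in truth.loops:
            for anchor in lp.anchors():
                assert any(
                    c == anchor.chrom and s <= anchor.start and anchor.end <= e
                    for c, s, e in promoters
                )

    def test_decoy_q_values_straddle_threshold(self, default_spec, loop_truth):
        qs = np.array([lp.q_value for lp in loop_truth.loops])
        decoy = loop_truth.table.is_decoy.values
        assert (qs[decoy] > default_spec.q_threshold).all()
        assert (qs[~decoy] <= default_spec.q_threshold).all()

    def test_class_fractions_within_multinomial_3sigma(self):
        spec = SyntheticSpec(seed=14, n_loops=2000, n_decoys=0)
        ann = generate_annotations(spec)
        truth = generate_loops(spec, ann)
        n = len(truth.loops)
        pairs = list(zip(truth.table.class_a, truth.table.class_b))
        for (ca, cb), frac in spec.class_fractions.items():
            count = sum(1 for p in pairs if set(p) == {ca, cb} or p == (ca, cb))
            sigma = np.sqrt(n * frac * (1 - frac))
            assert abs(count - n * frac) < 3 * sigma, (ca, cb, count)

    def test_missing_track_for_requested_class_errors(self):
        spec = SyntheticSpec(
            seed=1, n_loops=5, n_decoys=0,
            class_fractions={("promoter", "LINE"): 1.0},
            n_genes=20, n_enhancers=2, n_false_enhancers=0,
            repeat_counts={"LINE": 0},
            gene_set_sizes={"all": 20, "down": 2, "up": 2},
            chrom_sizes={"chr1": 300_000},
        )
        ann = generate_annotations(spec)
        with pytest.raises(ValueError, match="LINE"):
            generate_loops(spec, ann)

    def test_determinism(self, default_spec, annotations):
        a = generate_loops(default_spec, annotations)
        b = generate_loops(default_spec, annotations)
        assert a.loops == b.loops
        assert a.table.equals(b.table)


@pytest.fixture(scope="module")
def read_dataset():
    spec = SyntheticSpec(
        seed=9, chrom_sizes={"chr1": 150_000}, n_reads=4000, spike_fraction=0.05
    )
    seqs, fm = generate_genome(spec)
    return spec, seqs, fm, generate_reads(spec, seqs, fm)


class TestGenerateReads:

    def test_spike_fraction_binomial(self, read_dataset):
        spec, _, _, reads = read_dataset
        n_spike = int(reads.table.is_spike.sum())
        n = spec.n_reads
        sigma = np.sqrt(n * 0.05 * 0.95)
        assert abs(n_spike - n * 0.05) < 3 * sigma

    def test_junction_reads_trim_to_planted_offset(self, read_dataset):
        _, _, _, reads = read_dataset
        offsets = reads.table.junction_offset.values
        checked = 0
        for (rid, seq), off in zip(reads.reads1, offsets):
            if off < 0:
                continue
            trimmed, found = trim_linker(seq)
            assert found and len(trimmed) == off + 4
            checked += 1
        assert checked > 100

    def test_prefix_matches_fragment_end(self, read_dataset):
        _, seqs, fm, reads = read_dataset
        row = reads.table[reads.table.junction_offset >= 0].iloc[0]
        rid_to_seq = dict(reads.reads1)
        seq = rid_to_seq[row.read_id]
        frag = fm.fragment(row.chrom_a, fm.assign(row.chrom_a, row.pos_a))
        off = int(row.junction_offset)
        assert seq[:off] == seqs[row.chrom_a][frag.end - off : frag.end]

    def test_zero_junction_fraction_means_no_linker(self):
        spec = SyntheticSpec(
            seed=10, chrom_sizes={"chr1": 100_000}, n_reads=500, junction_fraction=0.0
        )
        seqs, fm = generate_genome(spec)
        reads = generate_reads(spec, seqs, fm)
        for _, seq in reads.reads1:
            assert not any(site in seq for site in LIGATION_SITES)

    def test_short_read_length_rejected(self):
        spec = SyntheticSpec(seed=0, read_length=20)
        with pytest.raises(ValueError, match="linker"):
            spec.validate()
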