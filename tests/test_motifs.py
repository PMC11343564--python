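"""PWM scanning: exact p-values, priority labelling, pair tabulation."""
import itertools

import numpy as np
import pytest

from loophub import (
    MotifHit,
    PWM,
    default_pwms,
    dedup_and_prioritize,
    fit_background,
    pair_motif_table,
    scan,
    scan_anchors,
)
from loophub.motifs import (
    NO_MOTIF,
    ScoreDistribution,
    read_meme,
    write_meme,
)

RC = str.maketrans("ACGT", "TGCA")


def _brute_force_pvalues(pwm, background, bin_bits=0.001):
    """Enumerate all 4^w words; return {binned_total: P(word)} and the exact
    (unbinned) score per word for the discretisation-bound check."""
    log_odds = pwm.log_odds(background)
    iscores = np.rint(log_odds / bin_bits).astype(int)
    binned, exact = {}, []
    for word in itertools.product(range(4), repeat=pwm.width):
        p = float(np.prod([background[b] for b in word]))
        s = int(sum(iscores[i, b] for i, b in enumerate(word)))
        binned[s] = binned.get(s, 0.0) + p
        exact.append((float(sum(log_odds[i, b] for i, b in enumerate(word))), p))
    return binned, exact


class TestFitBackground:
    def test_all_a_without_symmetrization_is_nearly_one(self):
        bg = fit_background(["A" * 1000], symmetrize=False)
        assert bg[0] == pytest.approx(1001 / 1004)
        assert bg.sum() == pytest.approx(1.0)

    def test_symmetrized_background_pairs_at_and_cg(self):
        bg = fit_background(["ACGTACCCGGGT", "TTTAAACG"])
        assert bg[0] == pytest.approx(bg[3])
        assert bg[1] == pytest.approx(bg[2])

    def test_uniform_sequence_close_to_quarter(self):
        rng = np.random.default_rng(0)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 10_000)])
        bg = fit_background([seq])
        # binomial 3 sigma on n=10,000 draws at p=1/4
        sigma = np.sqrt(0.25 * 0.75 / 10_000)
        assert np.all(np.abs(bg - 0.25) < 3 * sigma + 1e-4)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            fit_background([])


@pytest.mark.parametrize(
    "consensus,bg",
    [
        ("CACGTG", np.array([0.25, 0.25, 0.25, 0.25])),
        ("CACGTG", np.array([0.3, 0.2, 0.2, 0.3])),
        ("GTTCGAAC", np.array([0.29, 0.21, 0.21, 0.29])),
    ],
)
class TestExactPValues:
    def test_dp_matches_enumeration(self, consensus, bg):
        pwm = PWM.from_consensus("m", consensus)
        dist = ScoreDistribution(pwm.log_odds(bg), bg)
        binned, exact = _brute_force_pvalues(pwm, bg)
        scores = sorted(binned)
        # same binning: agreement to numerical precision
        for s in scores:
            bf = sum(p for k, p in binned.items() if k >= s)
            assert dist.pvalue(s) == pytest.approx(bf, abs=1e-12)
        # vs exact (unbinned) scores: deviation bounded by the probability
        # mass within one discretisation half-width of the threshold
        w = pwm.width
        delta = w * dist.bin_bits
        for s in scores:
            thresh = s * dist.bin_bits
            bf_exact = sum(p for sc, p in exact if sc >= thresh - delta / 2)
            band = sum(p for sc, p in exact if abs(sc - thresh) <= delta)
            assert abs(dist.pvalue(s) - bf_exact) <= band + 1e-12

    def test_pvalue_monotone_in_score(self, consensus, bg):
        pwm = PWM.from_consensus("m", consensus)
        dist = ScoreDistribution(pwm.log_odds(bg), bg)
        lo, hi = dist.min_sum, dist.max_int_score()
        ps = [dist.pvalue(s) for s in range(lo, hi + 1)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        assert dist.pvalue(lo) == pytest.approx(1.0)


class TestScan:
    def test_consensus_attains_maximal_score(self):
        bg = np.array([0.3, 0.2, 0.2, 0.3])
        pwm = PWM.from_consensus("E-box", "CCACGTGG")
        seq = "TTATTT" + "CCACGTGG" + "TTAATT"
        hits = scan(seq, pwm, bg, p_threshold=1.0)
        best = min(hits, key=lambda h: h.p_value)
        assert best.offset == 6 and best.strand == "+"
        dist = ScoreDistribution(pwm.log_odds(bg), bg)
        assert round(best.score_bits / dist.bin_bits) == dist.max_int_score()

    def test_planted_consensus_passes_default_threshold(self):
        bg = fit_background(["ACGT" * 500])
        for pwm in default_pwms():
            seq = "TATATATT" + pwm.consensus() + "ATTATAAT"
            hits = scan(seq, pwm, bg, p_threshold=1e-4)
            assert any(h.p_value <= 1e-4 for h in hits), pwm.name

    def test_reverse_complement_hit_on_minus_strand(self):
        bg = np.array([0.25, 0.25, 0.25, 0.25])
        pwm = PWM.from_consensus("m", "GTTCGAAG")
        fwd = "TTTTAT" + "GTTCGAAG" + "TATTTT"
        rev = fwd.translate(RC)[::-1]
        plus = min(scan(fwd, pwm, bg, 1.0), key=lambda h: h.p_value)
        minus = min(scan(rev, pwm, bg, 1.0), key=lambda h: h.p_value)
        assert plus.strand == "+" and minus.strand == "-"
        assert minus.score_bits == pytest.approx(plus.score_bits)
        assert minus.p_value == pytest.approx(plus.p_value)

    def test_sequence_shorter_than_motif_yields_empty(self):
        bg = np.full(4, 0.25)
        assert scan("ACG", PWM.from_consensus("m", "CACGTG"), bg) == []


class TestDedupAndPrioritize:
    def _hit(self, anchor, motif, p):
        return MotifHit(motif, 0, "+", 10.0, p, anchor)

    def test_priority_beats_pvalue(self):
        hits = [self._hit("a1", "E-box", 1e-5), self._hit("a1", "A-box", 1e-9)]
        _, labels = dedup_and_prioritize(hits)
        assert labels["a1"] == "E-box"

    def test_lowest_p_kept_per_motif(self):
        hits = [self._hit("a1", "E-box", 1e-5), self._hit("a1", "E-box", 1e-6)]
        best, _ = dedup_and_prioritize(hits)
        assert best["a1"]["E-box"].p_value == 1e-6

    def test_anchor_without_hits_labelled_no_motif_in_table(self):
        _, labels = dedup_and_prioritize([self._hit("a1", "B-box", 1e-5)])
        table = pair_motif_table([("a1", "a2")], labels)
        # one loop: B-box in one anchor, nothing in the other
        assert table.sum() == pytest.approx(1.0)
        i_b = list(("E-box", "B-box", "A-box", NO_MOTIF)).index("B-box")
        i_n = list(("E-box", "B-box", "A-box", NO_MOTIF)).index(NO_MOTIF)
        assert table[i_b, i_n] == pytest.approx(0.5)
        assert table[i_n, i_b] == pytest.approx(0.5)


class TestPairMotifTable:
    def test_planted_ebox_bbox_loops_fill_single_unordered_cell(self):
        labels = {"p1": "E-box", "p2": "B-box", "p3": "E-box", "p4": "B-box"}
        table = pair_motif_table([("p1", "p2"), ("p4", "p3")], labels)
        assert table.sum() == pytest.approx(2.0)
        assert table[0, 1] + table[1, 0] == pytest.approx(2.0)

    def test_symmetry_and_total(self):
        rng = np.random.default_rng(5)
        cats = ["E-box", "B-box", "A-box", NO_MOTIF]
        labels = {f"a{i}": cats[rng.integers(0, 4)] for i in range(40)}
        pairs = [(f"a{rng.integers(0, 40)}", f"a{rng.integers(0, 40)}") for _ in range(30)]
        table = pair_motif_table(pairs, labels)
        assert np.allclose(table, table.T)
        assert table.sum() == pytest.approx(30.0)


class TestMemeFormat:
    def test_round_trip(self, tmp_path):
        pwms = default_pwms()
        path = tmp_path / "m.meme"
        write_meme(pwms, path)
        back = read_meme(path)
        assert [p.name for p in back] == [p.name for p in pwms]
        for a, b in zip(pwms, back):
            assert np.allclose(a.matrix, b.matrix, atol=1e-4)

    def test_scan_anchors_with_packaged_motifs(self):
        from importlib.resources import files

        path = files("loophub").joinpath("data/motifs/synthetic_motifs.meme")
        pwms = read_meme(str(path))
        seqs = {
            "a1": "ATATTATA" + "CCACGTGG" + "TATATAAT" + "ATTA" * 6,
            "a2": "ATTATATA" * 5,
        }
        hits = scan_anchors(seqs, pwms, background=np.full(4, 0.25))
        _, labels = dedup_and_prioritize(hits)
        assert labels.get("a1") == "E-box"
        assert "a2" not in labels
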