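"""Sequence-feature statistics vs direct-counting oracles."""

import numpy as np
import pytest

from ptetools import seqfeat
from ptetools.io import CoverageTrack, GenomicInterval
from ptetools.seqfeat import (
    DINUCLEOTIDES,
    PWM,
    cpg_window_track,
    dinucleotide_map,
    metaprofile,
    motif_centrality,
    polytract_profile,
    polytract_window_counts,
)

COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s):
    return s.translate(COMP)[::-1]


def random_seq(rng, n, letters="ACGT"):
    return "".join(rng.choice(list(letters), size=n))


# ---------------------------------------------------------------------------
# oracles


def brute_dinuc_freqs(seq, window):
    """Per-window di-nucleotide frequencies by direct substring counting."""
    n_win = len(seq) - window + 1
    out = np.full((16, n_win), np.nan)
    for s in range(n_win):
        win = seq[s : s + window]
        pairs = [win[i : i + 2] for i in range(len(win) - 1)]
        valid = [p for p in pairs if "N" not in p]
        if not valid:
            continue
        for d, name in enumerate(DINUCLEOTIDES):
            out[d, s] = sum(p == name for p in valid) / len(valid)
    return out


class TestDinucleotideMap:
    def test_self_subtraction_is_zero(self, rng):
        seqs = [random_seq(rng, 300) for _ in range(5)]
        dmap = dinucleotide_map(seqs, list(seqs), window=50)
        np.testing.assert_allclose(dmap.diff, 0.0, atol=1e-12)

    def test_window_frequencies_sum_to_one(self, rng):
        seq = random_seq(rng, 400)
        freqs = seqfeat._dinuc_window_freqs(seq, 100)
        np.testing.assert_allclose(freqs.sum(axis=0), 1.0, atol=1e-9)

    def test_polya_against_random_controls(self, rng):
        polya = ["A" * 200] * 4
        ctrl = [random_seq(rng, 200) for _ in range(50)]
        dmap = dinucleotide_map(polya, ctrl, window=50)
        ctrl_aa = np.mean(
            [brute_dinuc_freqs(s, 50)[0] for s in ctrl], axis=0
        )
        np.testing.assert_allclose(dmap.row("AA"), 1.0 - ctrl_aa, atol=1e-9)

    def test_matches_brute_force_oracle(self, rng):
        seqs = [random_seq(rng, 500, "ACGTN") for _ in range(10)]
        ctrl = [random_seq(rng, 500) for _ in range(10)]
        dmap = dinucleotide_map(seqs, ctrl, window=50)
        exp = np.nanmean(
            [brute_dinuc_freqs(s, 50) for s in seqs], axis=0
        ) - np.nanmean([brute_dinuc_freqs(s, 50) for s in ctrl], axis=0)
        np.testing.assert_allclose(dmap.diff, exp, atol=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dinucleotide_map(["ACGT" * 10], ["ACGT" * 20])


class TestPolytract:
    def test_overlapping_matches_counted(self):
        seq = "C" * 40 + "AAAAAA" + "C" * 54  # A6 contains two A5 starts
        _, counts = polytract_window_counts([seq], None, "AAAAA", window=100)
        assert counts[0, 0] == 2.0

    def test_orientation_symmetry(self, rng):
        seq = random_seq(rng, 200)
        _, fwd = polytract_window_counts([seq], ["R"], "AAAAA", window=40)
        _, rev = polytract_window_counts([revcomp(seq)], ["L"], "AAAAA", window=40)
        np.testing.assert_allclose(fwd, rev)

    def test_a5_equals_t5_under_global_flip(self, rng):
        seqs = [random_seq(rng, 200) for _ in range(8)]
        sides = [s for s in np.where(np.arange(8) % 2, "L", "R")]
        flipped = [{"L": "R", "R": "L"}[s] for s in sides]
        _, a5 = polytract_window_counts(seqs, sides, "AAAAA", window=40)
        _, t5 = polytract_window_counts(seqs, flipped, "TTTTT", window=40)
        # flipping every orientation turns A5 tracts into T5 tracts at the
        # mirrored offset, so the windowed count matrices are mirror images
        np.testing.assert_allclose(a5[:, ::-1], t5)

    def test_unknown_side_rejected(self):
        with pytest.raises(ValueError):
            polytract_window_counts(["ACGT" * 50], ["X"], "AAAAA")

    def test_profile_means_over_sequences(self, rng):
        seqs = [random_seq(rng, 150) for _ in range(6)]
        prof, ctrl = polytract_profile(
            seqs, ["R"] * 6, "AAAAA", window=30,
            control_sequences=[random_seq(rng, 150) for _ in range(6)],
        )
        _, counts = polytract_window_counts(seqs, ["R"] * 6, "AAAAA", window=30)
        np.testing.assert_allclose(prof.values, counts.mean(axis=0))
        assert ctrl is not None and len(ctrl.values) == len(prof.values)


class TestCpG:
    def test_simple_example(self):
        prof = cpg_window_track("CGCGCG", window=6)
        assert prof.values.tolist() == [3.0]

    def test_a_only_is_zero(self):
        prof = cpg_window_track("A" * 50, window=10)
        assert prof.values.sum() == 0.0

    def test_matches_brute_force(self, rng):
        seq = random_seq(rng, 300)
        prof = cpg_window_track(seq, window=25)
        for s in range(0, len(seq) - 25 + 1, 7):
            win = seq[s : s + 25]
            exp = sum(
                win[i : i + 2] == "CG" for i in range(len(win) - 1)
            )
            assert prof.values[s] == exp


class TestPWM:
    def test_from_consensus_scores_exact_match_highest(self):
        pwm = PWM.from_consensus("AAACGAAA")
        codes = seqfeat.encode("TTTTAAACGAAATTTT")
        scores = pwm.scan(codes)
        assert int(np.argmax(scores)) == 4

    def test_best_match_finds_minus_strand(self):
        pwm = PWM.from_consensus("AAACGAAA")
        seq = "GGGGGG" + revcomp("AAACGAAA") + "GGGGGG"
        hit = pwm.best_match(seqfeat.encode(seq))
        assert hit is not None
        start, score, strand = hit
        assert strand == "-" and start == 6

    def test_n_windows_are_excluded(self):
        pwm = PWM.from_consensus("AAAA")
        scores = pwm.scan(seqfeat.encode("AANAAAAA"))
        assert np.isneginf(scores[0])
        assert np.isfinite(scores[4])

    def test_meme_round_trip(self, tmp_path):
        pwm = PWM.from_consensus("AAACGAAA")
        p = tmp_path / "m.meme"
        pwm.to_meme(p)
        back = PWM.from_meme(p)
        np.testing.assert_allclose(back.matrix, pwm.matrix, atol=1e-6)
        np.testing.assert_allclose(back.background, pwm.background)

    def test_swap_positions_builds_control(self):
        pwm = PWM.from_consensus("AAACGAAA")
        sw = pwm.swap_positions(3, 4)
        np.testing.assert_allclose(sw.matrix[3], pwm.matrix[4])
        np.testing.assert_allclose(sw.matrix[4], pwm.matrix[3])


class TestMotifCentrality:
    def _planted(self, rng, n=60, length=1_000, motif="AAACGAAA", sd=30):
        seqs, qs = [], []
        for i in range(n):
            s = list(random_seq(rng, length))
            pos = int(np.clip(length // 2 + rng.normal(0, sd), 0, length - 9))
            s[pos : pos + len(motif)] = motif
            seqs.append("".join(s))
            qs.append("Q4")
        return seqs, qs

    def test_planted_motif_peaks_at_center(self, rng):
        seqs, qs = self._planted(rng)
        prof = motif_centrality(seqs, PWM.from_consensus("AAACGAAA"), qs, rolling=100)
        v, off = prof["Q4"].values, prof["Q4"].offsets
        assert abs(off[int(np.argmax(v))]) <= 100

    def test_per_quartile_normalization_sums_to_one(self, rng):
        seqs, _ = self._planted(rng, n=40)
        qs = ["Q4"] * 20 + ["Q3"] * 20
        prof = motif_centrality(seqs, PWM.from_consensus("AAACGAAA"), qs)
        for q in ("Q3", "Q4"):
            assert prof[q].raw.sum() == pytest.approx(1.0, abs=1e-9)
            assert (prof[q].values >= 0).all()

    def test_global_normalization_sums_to_share(self, rng):
        seqs, _ = self._planted(rng, n=40)
        qs = ["Q4"] * 30 + ["Q3"] * 10
        prof = motif_centrality(
            seqs, PWM.from_consensus("AAACGAAA"), qs, normalize="global"
        )
        total = prof["Q4"].raw.sum() + prof["Q3"].raw.sum()
        assert total == pytest.approx(1.0, abs=1e-9)
        assert prof["Q4"].raw.sum() > prof["Q3"].raw.sum()

    def test_no_match_quartile_is_flat_zero(self, rng):
        seqs = [random_seq(rng, 500, "C") for _ in range(5)]
        prof = motif_centrality(seqs, PWM.from_consensus("AAAAAAAA"), ["Q1"] * 5)
        assert prof["Q1"].values.sum() == 0.0


class TestMetaprofile:
    def test_constant_track_flat(self):
        t = CoverageTrack({"c": np.full(10_000, 2.5)})
        regs = [GenomicInterval("c", 4_000, 4_002), GenomicInterval("c", 6_000, 6_002)]
        prof = metaprofile(t, regs, 500)
        np.testing.assert_allclose(prof.values, 2.5)

    def test_single_region_equals_raw_window(self, rng):
        arr = rng.gamma(1, 1, 5_000)
        t = CoverageTrack({"c": arr})
        prof = metaprofile(t, [GenomicInterval("c", 2_000, 2_002)], 300)
        np.testing.assert_allclose(prof.values, arr[2_001 - 300 : 2_001 + 300])

    def test_edge_regions_excluded(self):
        t = CoverageTrack({"c": np.ones(1_000)})
        prof = metaprofile(
            t,
            [GenomicInterval("c", 0, 10), GenomicInterval("c", 500, 510)],
            300,
        )
        assert prof.n_regions == 1

    def test_matches_windowed_mean_oracle(self, rng):
        arr = rng.gamma(1, 1, 20_000)
        t = CoverageTrack({"c": arr})
        regs = [
            GenomicInterval("c", int(s), int(s) + 100)
            for s in rng.integers(1_000, 18_000, size=15)
        ]
        hw = 400
        prof = metaprofile(t, regs, hw)
        exp = np.mean(
            [arr[r.center - hw : r.center + hw] for r in regs], axis=0
        )
        np.testing.assert_allclose(prof.values, exp)

    def test_strand_aware_flipping(self):
        arr = np.arange(2_000, dtype=float)
        t = CoverageTrack({"c": arr})
        plus = GenomicInterval("c", 1_000, 1_002, "+")
        minus = GenomicInterval("c", 1_000, 1_002, "-")
        p = metaprofile(t, [plus], 100, strand_aware=True)
        m = metaprofile(t, [minus], 100, strand_aware=True)
        np.testing.assert_allclose(p.values, m.values[::-1])


class TestControlSampling:
    def test_excludes_and_is_deterministic(self):
        sizes = {"chr1": 100_000}
        excl = [GenomicInterval("chr1", 0, 60_000)]
        a = seqfeat.sample_control_windows(sizes, 10, 1_000, excl, seed=3)
        b = seqfeat.sample_control_windows(sizes, 10, 1_000, excl, seed=3)
        assert a == b
        assert all(not w.overlaps(excl[0]) for w in a)
        for i, w in enumerate(a):
            assert all(not w.overlaps(o) for j, o in enumerate(a) if i != j)
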