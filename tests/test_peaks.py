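"""Peak refinement: smoothing, extrema, filtering, pairing — vs oracles."""

import numpy as np
import pytest

from ptetools.io import CoverageTrack
from ptetools.peaks import (
    ConsensusPeak,
    Extremum,
    FilterParams,
    SmoothParams,
    assign_quartiles,
    consensus_over_grid,
    filter_peaks,
    find_extrema,
    loess_smooth,
    pair_replicates,
    score_and_quartile,
)

# ---------------------------------------------------------------------------
# oracles


def brute_extrema(y):
    """Neighbour-comparison oracle with plateau collapse to the midpoint."""
    out = []
    i = 1
    # compress runs
    runs = []
    s = 0
    for j in range(1, len(y) + 1):
        if j == len(y) or y[j] != y[s]:
            runs.append((s, j - 1, y[s]))
            s = j
    for r in range(1, len(runs) - 1):
        lo, hi, v = runs[r]
        mid = (lo + hi) // 2
        if v > runs[r - 1][2] and v > runs[r + 1][2]:
            out.append((mid, "peak"))
        elif v < runs[r - 1][2] and v < runs[r + 1][2]:
            out.append((mid, "valley"))
    return out


def brute_filter(extrema, peak_fraction, valley_depth, ref=None):
    """Sequential re-derivation of the keep-and-merge rule."""
    peaks = [e for e in extrema if e.kind == "peak"]
    valleys = [e for e in extrema if e.kind == "valley"]
    if not peaks:
        return []
    if ref is None:
        ref = max(p.score for p in peaks)
    kept = [p for p in peaks if p.score >= peak_fraction * ref]
    if not kept:
        return []
    result = [kept[0]]
    for p in kept[1:]:
        last = result[-1]
        vs = [v.score for v in valleys if last.position < v.position < p.position]
        if not vs or min(vs) <= (1 - valley_depth) * min(last.score, p.score):
            result.append(p)
        elif p.score > last.score:
            result[-1] = p
    return result


def brute_mutual_nn(p1, p2):
    """All-pairs mutual-nearest-neighbour matching."""
    p1, p2 = sorted(p1), sorted(p2)
    if not p1 or not p2:
        return []
    n1 = [min(range(len(p2)), key=lambda j: (abs(p2[j] - x), j)) for x in p1]
    n2 = [min(range(len(p1)), key=lambda i: (abs(p1[i] - x), i)) for x in p2]
    return [
        (p1[i], p2[j]) for i, j in enumerate(n1) if n2[j] == i
    ]


# ---------------------------------------------------------------------------
# smoothing


class TestLoess:
    def test_reproduces_constants(self):
        y = np.full(200, 3.7)
        np.testing.assert_allclose(loess_smooth(y), y, atol=1e-9)

    def test_reproduces_linear_ramp(self):
        y = np.linspace(0.0, 10.0, 300)
        for degree in (1, 2):
            sm = loess_smooth(y, SmoothParams(degree=degree))
            np.testing.assert_allclose(sm, y, atol=1e-8)

    def test_noisy_gaussian_bump_argmax(self, rng):
        n = 6_000
        x = np.arange(n)
        center = 3_111
        y = 40 * np.exp(-0.5 * ((x - center) / 250) ** 2) + rng.normal(0, 2, n)
        sm = loess_smooth(y)
        assert abs(int(np.argmax(sm)) - center) <= 25

    def test_matches_statsmodels_lowess_degree_one(self, rng):
        sm_api = pytest.importorskip("statsmodels.api")
        n = 400
        y = np.sin(np.arange(n) / 40.0) + rng.normal(0, 0.1, n)
        ours = loess_smooth(y, SmoothParams(span=0.3, degree=1))
        theirs = sm_api.nonparametric.lowess(
            y, np.arange(n, dtype=float), frac=0.3, it=0, return_sorted=False
        )
        # same estimator family; implementations differ in neighbourhood
        # rounding, so compare interior values loosely
        np.testing.assert_allclose(ours[40:-40], theirs[40:-40], atol=0.02)

    def test_binned_smoothing_tracks_unbinned(self, rng):
        n = 4_000
        x = np.arange(n)
        y = 30 * np.exp(-0.5 * ((x - 2_000) / 300.0) ** 2) + rng.normal(0, 1, n)
        fine = loess_smooth(y, SmoothParams())
        coarse = loess_smooth(y, SmoothParams(bin_size=10))
        assert abs(int(np.argmax(fine)) - int(np.argmax(coarse))) <= 30

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            loess_smooth(np.ones(5))


class TestFindExtrema:
    def test_monotone_has_no_extrema(self):
        assert find_extrema(np.arange(50.0)) == []

    def test_alternating_example(self):
        ext = find_extrema(np.array([0.0, 1.0, 0.0, 2.0, 0.0]))
        assert [(e.position, e.kind) for e in ext] == [
            (1, "peak"), (2, "valley"), (3, "peak")
        ]

    def test_plateau_collapses_to_midpoint(self):
        y = np.array([0.0, 5.0, 5.0, 5.0, 0.0])
        ext = find_extrema(y)
        assert [(e.position, e.kind) for e in ext] == [(2, "peak")]

    def test_kinds_alternate(self, rng):
        for _ in range(50):
            y = np.cumsum(rng.normal(0, 1, 200))
            kinds = [e.kind for e in find_extrema(y)]
            for a, b in zip(kinds, kinds[1:]):
                assert a != b

    def test_matches_neighbour_oracle(self, rng):
        for _ in range(100):
            y = np.round(np.cumsum(rng.normal(0, 1, int(rng.integers(10, 300)))), 1)
            got = [(e.position, e.kind) for e in find_extrema(y)]
            assert got == brute_extrema(list(y))

    def test_nine_position_scores_truncated_at_edges(self):
        y = np.array([0.0, 9.0, 0.0, 0, 0, 0, 0, 0, 0])
        ext = find_extrema(y)
        peak = ext[0]
        # window is indices 0..5 (truncated left): mean of 6 values
        assert peak.score == pytest.approx(9.0 / 6.0)


class TestFilterPeaks:
    def _ext(self, *pairs):
        out = []
        for i, (kind, score) in enumerate(pairs):
            out.append(Extremum(position=100 * i, kind=kind, score=score))
        return out

    def test_single_peak_always_kept(self):
        ext = self._ext(("peak", 10.0))
        for pf in (0.5, 0.6):
            assert len(filter_peaks(ext, pf, 0.3)) == 1

    def test_shallow_valley_merges_equal_peaks(self):
        ext = self._ext(("peak", 100.0), ("valley", 80.0), ("peak", 100.0))
        kept = filter_peaks(ext, 0.5, 0.30)
        assert len(kept) == 1  # 80 > (1-0.3)*100: valley too shallow

    def test_deep_valley_separates(self):
        ext = self._ext(("peak", 100.0), ("valley", 60.0), ("peak", 100.0))
        kept = filter_peaks(ext, 0.5, 0.30)
        assert len(kept) == 2  # 60 <= 70

    def test_low_peak_dropped(self):
        ext = self._ext(("peak", 100.0), ("valley", 10.0), ("peak", 40.0))
        kept = filter_peaks(ext, 0.5, 0.30)
        assert [e.score for e in kept] == [100.0]

    def test_matches_sequential_merge_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 15))
            pairs = []
            kind = "peak"
            for _i in range(2 * n - 1):
                pairs.append((kind, float(np.round(rng.uniform(1, 100), 1))))
                kind = "valley" if kind == "peak" else "peak"
            ext = self._ext(*pairs)
            pf = float(rng.choice([0.5, 0.55, 0.6]))
            vd = float(rng.choice([0.3, 0.35]))
            got = filter_peaks(ext, pf, vd)
            assert got == brute_filter(ext, pf, vd)


class TestConsensusOverGrid:
    def _random_extrema(self, rng):
        n = int(rng.integers(1, 10))
        out = []
        pos = 0
        kind = "peak"
        for _ in range(2 * n - 1):
            pos += int(rng.integers(30, 400))
            out.append(Extremum(pos, kind, float(rng.uniform(1, 100))))
            kind = "valley" if kind == "peak" else "peak"
        return out

    def test_subset_of_every_combination(self, rng):
        filt = FilterParams()
        for _ in range(100):
            ext = self._random_extrema(rng)
            cons = consensus_over_grid(ext, filt)
            for pf in filt.peak_fraction_grid:
                for vd in filt.valley_depth_grid:
                    single = filter_peaks(ext, pf, vd)
                    for c in cons:
                        assert any(
                            abs(p.position - c.position) <= filt.match_radius_bp
                            for p in single
                        )

    def test_enlarging_grid_never_grows_output(self, rng):
        small = FilterParams((0.55,), (0.30,))
        large = FilterParams((0.50, 0.55, 0.60), (0.30, 0.35))
        grew = 0
        for _ in range(100):
            ext = self._random_extrema(rng)
            if len(consensus_over_grid(ext, large)) > len(
                consensus_over_grid(ext, small)
            ):
                grew += 1
        assert grew == 0


class TestPairing:
    def test_identical_lists(self):
        pairs, u1, u2 = pair_replicates([100, 900], [100, 900], "c")
        assert [(p.position, p.accuracy) for p in pairs] == [(100, 0.0), (900, 0.0)]
        assert u1 == u2 == []

    def test_worked_example_194bp_apart(self):
        # peaks 194 bp apart: centre at the median position, accuracy 97 bp
        pairs, _, _ = pair_replicates([1_000], [1_194], "c")
        assert len(pairs) == 1
        assert pairs[0].position == 1_097
        assert pairs[0].accuracy == 97.0

    def test_unmatched_reported(self):
        pairs, u1, u2 = pair_replicates([100, 5_000], [110], "c")
        assert [(p.position) for p in pairs] == [105]
        assert u1 == [5_000] and u2 == []

    def test_max_distance_rejects(self):
        pairs, u1, u2 = pair_replicates([0], [10_000], "c", max_distance=500)
        assert pairs == [] and u1 == [0] and u2 == [10_000]

    def test_matches_brute_force_mutual_nn(self, rng):
        for _ in range(100):
            p1 = sorted(rng.choice(100_000, size=int(rng.integers(1, 20)),
                                   replace=False).tolist())
            p2 = sorted(
                int(x + rng.normal(0, 300)) for x in p1 if rng.random() < 0.8
            )
            if not p2:
                continue
            pairs, u1, u2 = pair_replicates(p1, p2, "c")
            oracle = brute_mutual_nn(p1, p2)
            assert [(2 * p.position // 2) for p in pairs] == [
                (a + b) // 2 for a, b in oracle
            ]
            # one-to-one: no peak used twice, conservation of peaks
            assert len(pairs) + len(u1) == len(p1)
            assert len(pairs) + len(u2) == len(p2)


class TestScoreAndQuartile:
    def _peaks(self, positions):
        return [ConsensusPeak("c", p, 0.0) for p in positions]

    def test_eight_distinct_scores_two_per_quartile(self):
        arr = np.zeros(10_000)
        positions = [200 * (i + 1) for i in range(8)]
        for i, p in enumerate(positions):
            arr[p] = (i + 1) * 10.0
        track = CoverageTrack({"c": arr})
        peaks = score_and_quartile(self._peaks(positions), track, track)
        quart = [p.quartile for p in peaks]
        assert quart == ["Q1", "Q1", "Q2", "Q2", "Q3", "Q3", "Q4", "Q4"]

    def test_all_equal_scores_stay_balanced(self):
        track = CoverageTrack({"c": np.ones(5_000)})
        peaks = score_and_quartile(self._peaks([500, 1_500, 2_500, 3_500]), track, track)
        assert [p.quartile for p in peaks] == ["Q1", "Q2", "Q3", "Q4"]

    def test_nine_bp_window_sum_per_replicate(self):
        a1 = np.zeros(100)
        a1[50 - 4 : 50 + 5] = 2.0
        a2 = np.zeros(100)
        a2[50] = 9.0
        t1, t2 = CoverageTrack({"c": a1}), CoverageTrack({"c": a2})
        (pk,) = score_and_quartile(self._peaks([50]), t1, t2)
        assert pk.score_rep1 == pytest.approx(18.0)
        assert pk.score_rep2 == pytest.approx(9.0)
        assert pk.score_mean == pytest.approx(13.5)

    def test_edge_window_truncated_and_flagged(self):
        track = CoverageTrack({"c": np.ones(100)})
        (pk,) = score_and_quartile(self._peaks([2]), track, track)
        assert pk.truncated
        assert pk.score_rep1 == pytest.approx(7.0)  # positions 0..6

    def test_quartile_sizes_balanced_within_one(self, rng):
        for n in (5, 9, 13, 101):
            labels = assign_quartiles(list(rng.normal(size=n)))
            counts = [labels.count(f"Q{i}") for i in (1, 2, 3, 4)]
            assert max(counts) - min(counts) <= 1


@pytest.fixture(scope="module")
def pairing(many_peak_fixture):
    """Pair distances from the full refinement on a >=50-peak study with
    120-bp per-replicate position jitter."""
    import ptetools as pt

    sim = many_peak_fixture["sim"]
    m1, m2 = sim.tracks["MEL18"]
    conc = pt.concordant_regions(
        sim.regions["MEL18"][0], sim.regions["MEL18"][1], m1, m2
    )
    peaks, _ = pt.refine_peaks(conc, m1, m2)
    return np.array([2.0 * p.accuracy for p in peaks])


class TestPairingGeometryOnFixtures:

    def test_median_pairing_distance(self, pairing):
        assert len(pairing) >= 50
        assert 100 <= np.median(pairing) <= 400

    def test_distance_fraction_ordering(self, pairing):
        f500 = np.mean(pairing < 500)
        f250 = np.mean(pairing < 250)
        f100 = np.mean(pairing < 100)
        assert f500 > f250 > f100
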