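"""Gamma shape MLE, CoC construction, interference distance, E-distribution."""

import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

from cocount.errors import (
    DegenerateSampleError,
    InsufficientDataError,
    ParameterError,
)
from cocount.interference import (
    NOT_REACHED,
    CoCCurve,
    CoCPoint,
    adjacent_distances,
    coc_curve,
    e_distribution,
    fit_gamma_shape,
    interference_distance,
    occupancy_matrix,
    pooled_distances,
    relative_distances,
)
from cocount.model import FocusTrack
from cocount.synthetic import SimConfig, simulate_cohort


def track(length, foci, segments=(), rank=1):
    return FocusTrack("n", "g", rank, length, segments=segments,
                      focus_positions=tuple(foci))


class TestAdjacentDistances:
    def test_successive_differences(self):
        assert adjacent_distances(track(10.0, [2.0, 7.5])) == [5.5]

    def test_single_focus_gives_empty(self):
        assert adjacent_distances(track(10.0, [3.0])) == []

    def test_pair_spanning_segment_gap_is_dropped(self):
        t = track(10.0, [1.0, 3.0, 7.0], segments=((0.0, 4.0), (6.0, 10.0)))
        assert adjacent_distances(t, within_segments=True) == [2.0]
        assert adjacent_distances(t, within_segments=False) == [2.0, 4.0]


class TestRelativeDistances:
    @pytest.mark.parametrize("dists,length,expected", [
        ([5.5], 10.0, [55.0]),
        ([], 10.0, []),
        ([10.0], 10.0, [100.0]),
    ])
    def test_percent_of_axis(self, dists, length, expected):
        assert relative_distances(dists, length) == expected

    def test_non_positive_axis_raises(self):
        with pytest.raises(ParameterError):
            relative_distances([1.0], 0.0)


class TestFitGammaShape:
    def test_matches_grid_search_profile_likelihood_oracle(self):
        # Oracle: 10,000-point log-spaced grid over shape in [0.01, 1000] on
        # the profile log-likelihood, refined locally; frozen value 4.26543.
        fit = fit_gamma_shape([0.5, 1.0, 1.5, 2.0])
        assert fit.shape == pytest.approx(4.26543, rel=1e-3)
        assert fit.scale == pytest.approx(1.25 / fit.shape, rel=1e-12)
        assert fit.n_spacings == 4

    def test_agrees_with_scipy_mle(self, rng):
        # independent route: scipy's generic gamma MLE with location fixed at 0
        x = rng.gamma(3.0, 2.0, size=400)
        fit = fit_gamma_shape(x)
        a, _, scale = scipy.stats.gamma.fit(x, floc=0)
        assert fit.shape == pytest.approx(a, rel=1e-4)
        assert fit.scale == pytest.approx(scale, rel=1e-4)

    def test_all_equal_sample_is_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            fit_gamma_shape([1.0, 1.0, 1.0, 1.0])

    def test_too_few_positive_spacings(self):
        with pytest.raises(InsufficientDataError):
            fit_gamma_shape([1.0])
        with pytest.raises(InsufficientDataError):
            fit_gamma_shape([0.0, -1.0, 2.0])

    def test_zero_spacings_dropped(self):
        fit = fit_gamma_shape([0.0, 0.5, 1.0, 1.5, 2.0])
        assert fit.n_spacings == 4

    def test_recovers_simulated_shape(self):
        cohort = simulate_cohort(SimConfig(n_nuclei=150, shape=5.0, seed=21))
        spacings = pooled_distances(cohort.tracks())
        assert len(spacings) >= 600
        fit = fit_gamma_shape(spacings)
        assert abs(fit.shape - 5.0) / 5.0 < 0.10

    def test_scale_invariance_of_shape(self, rng):
        # same distances in microns and percent of one shared axis length:
        # the shape is unchanged to 6 significant digits, the scale rescales
        x = rng.gamma(4.0, 1.5, size=300)
        microns = fit_gamma_shape(x)
        percent = fit_gamma_shape(relative_distances(x, 12.0),
                                  units_flag="percent_of_axis")
        assert percent.shape == pytest.approx(microns.shape, rel=1e-6)
        assert percent.scale == pytest.approx(microns.scale * 100.0 / 12.0, rel=1e-6)

    def test_bootstrap_uncertainty_is_seeded(self, rng):
        x = rng.gamma(5.0, 0.5, size=200)
        a = fit_gamma_shape(x, n_bootstrap=100, seed=1)
        b = fit_gamma_shape(x, n_bootstrap=100, seed=1)
        c = fit_gamma_shape(x, n_bootstrap=100, seed=2)
        assert a.shape_uncertainty == b.shape_uncertainty > 0
        assert a.shape_uncertainty != c.shape_uncertainty


def occupancy_track(occupied, n_intervals=2, length=10.0):
    """A track with one focus at the centre of each listed interval (1-based)."""
    size = length / n_intervals
    foci = [(k - 0.5) * size for k in occupied]
    return track(length, sorted(foci))


def brute_force_coc(tracks, n_intervals):
    """Independent exhaustive pairwise enumeration (direct double loop)."""
    n_biv = len(tracks)
    occ = []
    for t in tracks:
        size = t.axis_length / n_intervals
        row = set()
        for p in t.focus_positions:
            idx = 0 if p <= 0 else math.ceil(p / size) - 1
            row.add(min(max(idx, 0), n_intervals - 1))
        occ.append(row)
    mean_len = sum(t.axis_length for t in tracks) / n_biv / n_intervals
    freq = [sum(1 for row in occ if i in row) / n_biv for i in range(n_intervals)]
    by_class = {}
    for i in range(n_intervals):
        for j in range(i + 1, n_intervals):
            obs = sum(1 for row in occ if i in row and j in row) / n_biv
            exp = freq[i] * freq[j]
            entry = by_class.setdefault(j - i, {"obs": 0.0, "exp": 0.0,
                                                "pairs": 0, "skipped": 0})
            if exp == 0.0:
                entry["skipped"] += 1
            else:
                entry["obs"] += obs
                entry["exp"] += exp
                entry["pairs"] += 1
    points = []
    for d in sorted(by_class):
        e = by_class[d]
        if e["pairs"]:
            points.append((d * mean_len, e["obs"] / e["exp"], e["pairs"], e["skipped"]))
    return points


class TestCocCurve:
    def test_independent_occupancy_gives_coc_one(self):
        tracks = [occupancy_track(o) for o in [{1, 2}, {1}, {2}, set()]]
        curve = coc_curve(tracks, n_intervals=2)
        (point,) = curve.points
        assert point.coc == pytest.approx(1.0)

    def test_perfect_interference_gives_coc_zero(self):
        tracks = [occupancy_track(o) for o in [{1}, {1}, {2}, {2}]]
        curve = coc_curve(tracks, n_intervals=2)
        (point,) = curve.points
        assert point.coc == 0.0

    def test_matches_bruteforce_enumeration_exactly(self):
        occupancies = [{1, 3}, {1}, {2, 4}, {1, 4}, {3}, {2, 3}]
        tracks = [occupancy_track(o, n_intervals=4) for o in occupancies]
        curve = coc_curve(tracks, n_intervals=4)
        oracle = brute_force_coc(tracks, 4)
        assert len(curve.points) == len(oracle)
        for point, (dist, coc, n_pairs, n_skipped) in zip(curve.points, oracle):
            assert point.distance == dist
            assert point.coc == coc
            assert point.n_pairs == n_pairs
            assert point.n_skipped == n_skipped

    def test_expected_zero_pairs_are_skipped(self):
        # interval 2 never occupied: its pairs are skipped, not zero-divided
        tracks = [occupancy_track(o, n_intervals=3) for o in [{1}, {1, 3}, {3}]]
        curve = coc_curve(tracks, n_intervals=3)
        # adjacent classes (1,2) and (2,3) are entirely skipped: no point at d=1
        (point,) = curve.points
        assert point.distance == pytest.approx(20 / 3)  # the (1,3) pair
        assert point.n_pairs == 1 and point.n_skipped == 0

    def test_boundary_focus_goes_to_lower_interval(self):
        occ = occupancy_matrix([track(10.0, [5.0])], 2)
        assert occ[0].tolist() == [True, False]

    def test_auto_interval_count_rounds_half_up(self):
        # mean focus count 1.5 -> 5 * 1.5 = 7.5 -> 8 intervals
        tracks = [track(10.0, [1.0]), track(10.0, [2.0, 6.0])]
        assert coc_curve(tracks, n_intervals="auto").n_intervals == 8

    def test_errors(self):
        with pytest.raises(InsufficientDataError):
            coc_curve([])
        with pytest.raises(ParameterError):
            coc_curve([track(10.0, [1.0])], n_intervals=1)


class TestInterferenceDistance:
    def curve(self, pts):
        return CoCCurve("g", 2, 0.5,
                        tuple(CoCPoint(d, c, 1, 0) for d, c in pts), NOT_REACHED)

    def test_linear_interpolation(self):
        curve = self.curve([(0.5, 0.2), (1.0, 0.4), (1.5, 0.6)])
        assert interference_distance(curve) == pytest.approx(1.25)

    def test_zero_when_first_point_above_threshold(self):
        assert interference_distance(self.curve([(0.5, 0.7), (1.0, 0.9)])) == 0.0

    def test_not_reached(self):
        assert interference_distance(self.curve([(0.5, 0.1), (1.0, 0.3)])) == NOT_REACHED

    def test_empty_curve_raises(self):
        with pytest.raises(InsufficientDataError):
            interference_distance(CoCCurve("g", 2, 0.5, (), NOT_REACHED))

    def test_threshold_is_adjustable(self):
        curve = self.curve([(0.5, 0.2), (1.0, 0.4), (1.5, 0.6)])
        assert interference_distance(curve, threshold=0.3) == pytest.approx(0.75)


class TestEDistribution:
    def test_direct_tally(self):
        ed = e_distribution([0, 1, 1, 2])
        assert ed.proportions == (0.25, 0.5, 0.25)
        assert ed.n_units == 4

    def test_all_units_with_focus_means_e0_zero(self):
        assert e_distribution([1, 2, 1, 3]).e0 == 0.0

    def test_empty_raises(self):
        with pytest.raises(InsufficientDataError):
            e_distribution([])

    @given(st.lists(st.integers(0, 6), min_size=1, max_size=60))
    def test_proportions_sum_to_one(self, counts):
        assert abs(sum(e_distribution(counts).proportions) - 1.0) < 1e-12
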