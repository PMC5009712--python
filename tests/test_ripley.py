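"""Finite-location K estimator against brute-force oracles."""

import math

import numpy as np
import pytest

from finitek.geometry import Metric, rotate_points
from finitek.ripley import (CaseSet, MarkedLocationSet, as_thresholds,
                            cumulative_pair_counts, estimate_intensity,
                            max_pairwise_distance, ripley_k)


def _universe(coords, marks=None):
    coords = np.asarray(coords, dtype=float)
    if marks is None:
        marks = np.ones(len(coords), dtype=int)
    return MarkedLocationSet(coords=coords, marks=marks)


def brute_counts(coords, thresholds, metric=Metric("l2")):
    """Naive double-loop ordered-pair counter (the independent oracle)."""
    coords = np.asarray(coords, dtype=float)
    out = []
    for r in thresholds:
        c = 0
        for j in range(len(coords)):
            for k in range(len(coords)):
                if j != k and metric.distance(coords[j], coords[k]) <= r:
                    c += 1
        out.append(c)
    return np.array(out)


class TestContainers:
    def test_marks_and_coords_validated(self):
        with pytest.raises(ValueError):
            _universe([(0, np.nan)])
        with pytest.raises(ValueError):
            MarkedLocationSet(coords=[(0, 0), (1, 1)], marks=[1])
        with pytest.raises(ValueError):
            MarkedLocationSet(coords=[(0, 0)], marks=[1.5])

    def test_case_indices_must_be_distinct(self):
        with pytest.raises(ValueError):
            CaseSet(indices=[0, 1, 1])

    def test_thresholds_strictly_increasing_positive(self):
        for bad in ([], [0.0, 10.0], [10.0, 10.0], [10.0, 5.0]):
            with pytest.raises(ValueError):
                as_thresholds(bad)


class TestIntensity:
    def test_two_cases_100m_apart(self):
        loc = _universe([(0, 0), (100, 0)])
        lam = estimate_intensity(CaseSet([0, 1]), loc)
        assert lam == pytest.approx(2 / 100)

    def test_matches_exhaustive_pair_scan(self, rng):
        coords = rng.random((50, 2))
        loc = _universe(coords)
        brute = max(math.dist(coords[i], coords[j])
                    for i in range(50) for j in range(i + 1, 50))
        lam = estimate_intensity(CaseSet(np.arange(50)), loc)
        assert lam == pytest.approx(50 / brute)

    def test_convex_hull_shortcut_agrees_with_pair_scan(self, rng):
        coords = rng.normal(size=(600, 2)) * 100  # > 500 triggers the hull path
        exhaustive = max(np.hypot(*(coords - c).T).max() for c in coords)
        assert max_pairwise_distance(coords) == pytest.approx(exhaustive, rel=1e-12)

    def test_scaling_coordinates_halves_lambda(self, rng):
        coords = rng.random((10, 2)) * 100
        lam1 = estimate_intensity(CaseSet(np.arange(10)), _universe(coords))
        lam2 = estimate_intensity(CaseSet(np.arange(10)), _universe(coords * 2))
        assert lam2 == pytest.approx(lam1 / 2)

    def test_degenerate_inputs_raise(self):
        loc = _universe([(0, 0), (0, 0)])
        with pytest.raises(ValueError):
            estimate_intensity(CaseSet([0]), loc)
        with pytest.raises(ValueError):
            estimate_intensity(CaseSet([0, 1]), loc)


class TestPairCounts:
    def test_collinear_fixture(self):
        pts = [(0, 0), (100, 0), (250, 0)]
        counts = cumulative_pair_counts(pts, [50, 150, 300])
        assert counts.tolist() == [0, 4, 6]

    def test_empty_ball_and_saturation(self, rng):
        pts = rng.random((12, 2)) * 100
        d = Metric("l2").pairwise(pts)
        below = cumulative_pair_counts(pts, [d.min() * 0.99])
        above = cumulative_pair_counts(pts, [d.max() * 1.01])
        assert below[0] == 0
        assert above[0] == 12 * 11

    def test_counts_are_even_and_monotone(self, rng):
        pts = rng.random((20, 2)) * 500
        counts = cumulative_pair_counts(pts, np.arange(25, 800, 25))
        assert (counts % 2 == 0).all()
        assert (np.diff(counts) >= 0).all()

    @pytest.mark.parametrize("metric", [Metric("l2"), Metric("l1", 0.0),
                                        Metric("l1", 33.0)])
    def test_matches_double_loop_oracle(self, metric, rng):
        for _ in range(20):
            n = int(rng.integers(2, 51))
            pts = rng.random((n, 2)) * 1000
            thresholds = np.sort(rng.random(5)) * 1500 + 1
            fast = cumulative_pair_counts(pts, thresholds, metric)
            assert np.array_equal(fast, brute_counts(pts, thresholds, metric))


class TestRipleyK:
    def test_hand_computed_chain(self):
        loc = _universe([(0, 0), (100, 0)])
        est = ripley_k(CaseSet([0, 1]), loc, [50, 150])
        assert est.lam == pytest.approx(0.02)
        assert est.k_values == pytest.approx([0.0, 2 / (2 * 0.02)])
        assert est.k_values[1] == pytest.approx(50.0)
        assert est.scaled_values == pytest.approx([0.0, 0.02 ** 2 * 50.0])

    def test_l2_k_invariant_under_rotation(self, rng):
        coords = rng.random((30, 2)) * 1000
        thresholds = np.arange(50, 1500, 50)
        k1 = ripley_k(CaseSet(np.arange(30)), _universe(coords), thresholds)
        k2 = ripley_k(CaseSet(np.arange(30)), _universe(rotate_points(coords, 37.0)),
                      thresholds)
        assert np.allclose(k1.k_values, k2.k_values, rtol=1e-9)

    def test_axis_aligned_pair_under_rotated_l1(self):
        loc = _universe([(0, 0), (100, 0)])
        cases = CaseSet([0, 1])
        m = Metric("l1", 45.0)
        just_below = ripley_k(cases, loc, [100 * math.sqrt(2) - 1e-6], m)
        at = ripley_k(cases, loc, [100 * math.sqrt(2) + 1e-9], m)
        assert just_below.pair_counts[0] == 0
        assert at.pair_counts[0] == 2

    def test_k_nondecreasing_any_metric(self, small_universe):
        _, loc, cases, _ = small_universe
        for metric in (Metric("l2"), Metric("l1", 22.5)):
            est = ripley_k(cases, loc, np.arange(25, 2000, 25), metric)
            assert (np.diff(est.k_values) >= 0).all()

    def test_rank_against_simulations_invariant_to_lambda(self, rng):
        # lambda is a shared positive constant, so the rank of the observed K
        # among simulated Ks cannot depend on it — the property that makes the
        # envelope test robust to the unusual 1/length intensity definition
        coords = rng.random((40, 2)) * 1000
        loc = _universe(coords)
        thresholds = [300.0]
        sims = [CaseSet(rng.choice(40, 10, replace=False)) for _ in range(25)]
        obs = CaseSet(rng.choice(40, 10, replace=False))
        for lam in (0.001, 1.0, 123.4):
            ks = [ripley_k(c, loc, thresholds, lam=lam).k_values[0] for c in sims]
            rank = sum(k < ripley_k(obs, loc, thresholds, lam=lam).k_values[0]
                       for k in ks)
            if lam == 0.001:
                first = rank
            assert rank == first
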