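"""Null sampler, envelope construction, and one-sided significance."""

import numpy as np
import pytest

import finitek as fk
from finitek.envelope import (CapacityError, MarkCDF, UnsatisfiableMarkError,
                              build_envelope, build_mark_cdf, envelope_rank,
                              rotated_k_analysis, sample_null_pattern,
                              significance_trace)
from finitek.ripley import CaseSet, MarkedLocationSet, ripley_k


def _universe(coords, marks):
    return MarkedLocationSet(coords=np.asarray(coords, dtype=float),
                             marks=np.asarray(marks))


@pytest.fixture
def four_mark_universe(rng):
    coords = rng.random((200, 2)) * 1000
    marks = np.repeat([7, 9, 10, 3], 50)
    return _universe(coords, marks)


class TestMarkCDF:
    def test_counting_fixture(self):
        cdf = MarkCDF.from_marks([7, 7, 9, 10])
        assert cdf.mark_values.tolist() == [7, 9, 10]
        assert cdf.probs == pytest.approx([0.5, 0.25, 0.25])
        assert cdf.cum_probs.tolist() == [0.5, 0.75, 1.0]
        assert cdf.cum_probs[-1] == 1.0  # exactly

    def test_single_atom(self):
        cdf = MarkCDF.from_marks([4, 4, 4])
        assert (cdf.lookup(np.linspace(0, 0.999, 50)) == 4).all()

    def test_inverse_cdf_frequencies_within_3_sigma(self, rng):
        cdf = MarkCDF.from_marks([7, 7, 9, 10])
        n = 100_000
        draws = cdf.lookup(rng.random(n))
        for mark, p in zip([7, 9, 10], [0.5, 0.25, 0.25]):
            freq = (draws == mark).mean()
            sigma = np.sqrt(p * (1 - p) / n)
            assert abs(freq - p) < 3 * sigma

    def test_built_only_from_case_marks(self, four_mark_universe):
        cases = CaseSet(np.flatnonzero(four_mark_universe.marks == 7)[:5])
        cdf = build_mark_cdf(cases, four_mark_universe)
        assert cdf.mark_values.tolist() == [7]


class TestNullSampler:
    def test_forced_outcome_when_capacity_equals_q(self, rng):
        coords = rng.random((10, 2))
        marks = np.array([5] * 4 + [1] * 6)
        loc = _universe(coords, marks)
        cdf = MarkCDF.from_marks([5, 5, 5, 5])
        pattern = sample_null_pattern(loc, cdf, 4, rng)
        assert sorted(pattern.indices) == [0, 1, 2, 3]

    def test_two_candidates_chosen_equally_often(self, rng):
        loc = _universe([(0, 0), (1, 1), (2, 2)], [5, 5, 1])
        cdf = MarkCDF.from_marks([5])
        n = 10_000
        hits = sum(sample_null_pattern(loc, cdf, 1, rng).indices[0] == 0
                   for _ in range(n))
        sigma = np.sqrt(0.25 / n)
        assert abs(hits / n - 0.5) < 3 * sigma

    def test_pooled_mark_frequencies_match_cdf(self, rng):
        coords = rng.random((400, 2)) * 1000
        loc = _universe(coords, np.repeat([7, 9], 200))
        cdf = MarkCDF.from_marks([7, 9])
        counts = {7: 0, 9: 0}
        n_pat, q = 2000, 10
        for _ in range(n_pat):
            pat = sample_null_pattern(loc, cdf, q, rng)
            marks = pat.marks(loc)
            counts[7] += int((marks == 7).sum())
            counts[9] += int((marks == 9).sum())
        total = n_pat * q
        sigma = np.sqrt(0.25 / total)
        assert abs(counts[7] / total - 0.5) < 3 * sigma

    def test_distinct_indices_always(self, four_mark_universe, rng):
        cdf = MarkCDF.from_marks([7, 9, 10])
        for _ in range(50):
            pat = sample_null_pattern(four_mark_universe, cdf, 60, rng)
            assert len(np.unique(pat.indices)) == 60
            assert set(pat.marks(four_mark_universe)) <= {7, 9, 10}

    def test_unsatisfiable_mark_raises(self, rng):
        loc = _universe([(0, 0), (1, 1)], [1, 2])
        with pytest.raises(UnsatisfiableMarkError):
            sample_null_pattern(loc, MarkCDF.from_marks([3]), 1, rng)

    def test_capacity_error(self, rng):
        loc = _universe([(0, 0), (1, 1), (2, 2)], [5, 5, 1])
        with pytest.raises(CapacityError):
            sample_null_pattern(loc, MarkCDF.from_marks([5]), 3, rng)


class TestEnvelope:
    def test_rank_rule(self):
        assert envelope_rank(1000, 0.05) == 951
        assert envelope_rank(199, 0.05) == 191
        with pytest.raises(ValueError):
            envelope_rank(10, 0.05)  # alpha * n_sim < 1

    def test_envelope_columns_sorted_and_critical_monotone(self, small_universe):
        _, loc, cases, _ = small_universe
        env = build_envelope(loc, cases, np.arange(50, 800, 50), n_sim=99, rng=5)
        assert (np.diff(env.reference, axis=0) >= 0).all()
        assert (np.diff(env.critical_values) >= 0).all()
        assert (np.diff(env.median_values) >= 0).all()

    def test_seed_reproduces_envelope_bit_identically(self, small_universe):
        _, loc, cases, _ = small_universe
        r = np.arange(100, 600, 100)
        e1 = build_envelope(loc, cases, r, n_sim=49, rng=7)
        e2 = build_envelope(loc, cases, r, n_sim=49, rng=7)
        assert np.array_equal(e1.reference, e2.reference)
        assert e1.threshold_rank == e2.threshold_rank == envelope_rank(49, 0.05)

    def test_observed_included_as_top_draw_is_significant(self, small_universe):
        # ordering sanity: an observed K above every reference value must be
        # flagged wherever it strictly exceeds the critical value
        _, loc, cases, _ = small_universe
        r = np.arange(100, 600, 100)
        env = build_envelope(loc, cases, r, n_sim=49, rng=3)
        obs = ripley_k(cases, loc, r, lam=env.lam)
        boosted = fk.KEstimate(thresholds=obs.thresholds,
                               k_values=env.reference.max(axis=0) * 1.01 + 1.0,
                               lam=obs.lam, metric=obs.metric,
                               pair_counts=obs.pair_counts)
        assert significance_trace(boosted, env).significant.all()

    def test_tie_with_critical_value_is_not_significant(self, small_universe):
        _, loc, cases, _ = small_universe
        r = np.arange(100, 600, 100)
        env = build_envelope(loc, cases, r, n_sim=49, rng=3)
        obs = ripley_k(cases, loc, r, lam=env.lam)
        tied = fk.KEstimate(thresholds=obs.thresholds,
                            k_values=env.critical_values.copy(), lam=obs.lam,
                            metric=obs.metric, pair_counts=obs.pair_counts)
        assert not significance_trace(tied, env).significant.any()

    def test_threshold_mismatch_rejected(self, small_universe):
        _, loc, cases, _ = small_universe
        env = build_envelope(loc, cases, [100.0, 200.0], n_sim=49, rng=3)
        obs = ripley_k(cases, loc, [100.0, 300.0], lam=env.lam)
        with pytest.raises(ValueError):
            significance_trace(obs, env)


class TestRotatedAnalysis:
    def test_theta_zero_equals_plain_l1(self, small_universe):
        _, loc, cases, _ = small_universe
        r = np.arange(100, 800, 100)
        traces = rotated_k_analysis(loc, cases, r, [0.0], n_sim=49, rng=11)
        plain_env = build_envelope(loc, cases, r, metric=fk.Metric("l1", 0.0),
                                   n_sim=49, rng=11)
        plain_obs = ripley_k(cases, loc, r, fk.Metric("l1", 0.0), lam=plain_env.lam)
        trace = traces[0.0]
        assert np.array_equal(trace.observed.k_values, plain_obs.k_values)
        assert np.array_equal(trace.envelope.reference, plain_env.reference)

    def test_theta_0_and_90_produce_identical_traces(self, small_universe):
        _, loc, cases, _ = small_universe
        r = np.arange(100, 800, 100)
        traces = rotated_k_analysis(loc, cases, r, [0.0, 90.0], n_sim=49, rng=11)
        assert np.allclose(traces[0.0].observed.k_values,
                           traces[90.0].observed.k_values, rtol=1e-9)
        assert np.allclose(traces[0.0].envelope.reference,
                           traces[90.0].envelope.reference, rtol=1e-9)

    def test_axis_aligned_grid_distances_maximal_at_45(self):
        # an axis-aligned pair of length d measures d under L1 at 0 deg and
        # d*sqrt(2) at 45 deg, so cluster detection is latest at 45 deg
        loc = _universe([(0, 0), (100, 0), (0, 2000), (2000, 0)], [1, 1, 1, 1])
        cases = CaseSet([0, 1])
        d0 = fk.Metric("l1", 0.0).pairwise(cases.coords(loc))[0]
        d45 = fk.Metric("l1", 45.0).pairwise(cases.coords(loc))[0]
        d225 = fk.Metric("l1", 22.5).pairwise(cases.coords(loc))[0]
        assert d0 < d225 < d45
        assert d45 == pytest.approx(100 * np.sqrt(2))

    def test_rotation_range_validated(self, small_universe):
        _, loc, cases, _ = small_universe
        with pytest.raises(ValueError):
            rotated_k_analysis(loc, cases, [100.0], [-5.0], n_sim=25, rng=1)

    def test_contagion_detected_at_small_scales_only(self):
        cfg = fk.SyntheticConfig(grid_nx=30, grid_ny=30, q=80,
                                 contagion_prob=0.7, contagion_radius=200.0,
                                 seed=29)
        loc, cases, flags = fk.generate_dataset(cfg)
        assert flags.any()
        # K is cumulative, so the small-scale excess persists to intermediate
        # r; the grid extends toward the pattern diameter where it must fade
        model = fk.FiniteRipleyK(loc, cases, thresholds=np.arange(50, 2400, 50))
        res = model.fit(n_sim=199, seed=29)
        sig_r = res.trace.thresholds[res.significant]
        assert len(sig_r) > 0
        assert sig_r.min() <= 300.0          # detected at the injected scale
        assert not res.significant[-1]       # fades by the largest scale
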