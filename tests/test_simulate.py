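"""Statistical correctness of the synthetic stream generators."""

import json

import numpy as np
import pytest
from scipy import stats

from ctc_sampling import (
    EventSeries,
    IntervalSpec,
    SimSpec,
    count_in_windows,
    generate_fixture_suite,
    read_event_series,
    simulate_changepoint_poisson,
    simulate_diurnal_session,
    simulate_homogeneous_poisson,
    simulate_merged_poisson,
    simulate_switching_shedding,
    validate_event_series,
)


def pooled_nonoverlapping_counts(series_list, window=60.0):
    spec = IntervalSpec(window=window, mode="nonoverlapping")
    return np.concatenate([count_in_windows(s, spec).counts for s in series_list])


def mixture_moments(lam1, lam2, k_max=200):
    """Brute-force moments of the 50/50 Poisson mixture by pmf mixing."""
    k = np.arange(k_max + 1)
    pmf = 0.5 * stats.poisson.pmf(k, lam1) + 0.5 * stats.poisson.pmf(k, lam2)
    mean = float(np.sum(k * pmf))
    var = float(np.sum((k - mean) ** 2 * pmf))
    m4 = float(np.sum((k - mean) ** 4 * pmf))
    return mean, var, m4


class TestDeterminism:
    @pytest.mark.parametrize(
        "make",
        [
            lambda seed: simulate_homogeneous_poisson(5.0, 2100.0, seed),
            lambda seed: simulate_changepoint_poisson(4.0, 8.0, 1050.0, 2100.0, seed),
            lambda seed: simulate_merged_poisson(3.0, 6.0, 2100.0, seed),
            lambda seed: simulate_switching_shedding(1.0, 10.0, 5.0, 5.0, 2100.0, seed),
        ],
    )
    def test_same_seed_same_stream(self, make):
        a, b = make(123), make(123)
        np.testing.assert_array_equal(a.times, b.times)
        c = make(124)
        assert a.n_events != c.n_events or not np.array_equal(a.times, c.times)

    def test_diurnal_session_reproducible(self):
        a = simulate_diurnal_session(5.0, seed=7)
        b = simulate_diurnal_session(5.0, seed=7)
        for sa, sb in zip(a.scans, b.scans):
            np.testing.assert_array_equal(sa.times, sb.times)


class TestHomogeneous:
    def test_zero_rate_is_empty(self):
        assert simulate_homogeneous_poisson(0.0, 2100.0, 1).n_events == 0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_homogeneous_poisson(-1.0, 60.0, 1)

    def test_mean_count_matches_rate_times_duration(self):
        rate, dur, reps = 5.0, 2100.0, 400
        expected = rate / 60.0 * dur
        ss = np.random.SeedSequence(11).spawn(reps)
        counts = [simulate_homogeneous_poisson(rate, dur, np.random.default_rng(s)).n_events
                  for s in ss]
        se = np.sqrt(expected / reps)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_counts_pass_poisson_goodness_of_fit(self):
        """Pooled window counts fit the Poisson pmf (alpha=0.01) in >=95% of suites."""
        n_suites, passed = 20, 0
        for suite_seed in np.random.SeedSequence(42).spawn(n_suites):
            streams = [
                simulate_homogeneous_poisson(5.0, 2100.0, np.random.default_rng(s))
                for s in suite_seed.spawn(10)
            ]
            counts = pooled_nonoverlapping_counts(streams, 60.0)
            lam = counts.mean()
            # bin tails so every expected frequency is >= 5
            kmax = int(stats.poisson.isf(5.0 / len(counts), lam))
            edges = np.arange(kmax + 1)
            obs = np.array([np.sum(counts == k) for k in edges[:-1]])
            obs = np.append(obs, np.sum(counts >= kmax))
            exp = stats.poisson.pmf(edges[:-1], lam) * len(counts)
            exp = np.append(exp, stats.poisson.sf(kmax - 1, lam) * len(counts))
            keep = exp >= 5
            obs = np.append(obs[keep], obs[~keep].sum())
            exp = np.append(exp[keep], exp[~keep].sum())
            _, p = stats.chisquare(obs, exp * obs.sum() / exp.sum(), ddof=1)
            passed += p > 0.01
        assert passed >= 0.95 * n_suites


class TestChangepoint:
    def test_change_time_domain(self):
        for bad in (0.0, 2100.0, -5.0):
            with pytest.raises(ValueError):
                simulate_changepoint_poisson(4.0, 8.0, bad, 2100.0, 1)

    def test_equal_rates_reduce_to_homogeneous(self):
        streams = [
            simulate_changepoint_poisson(5.0, 5.0, 1050.0, 2100.0, np.random.default_rng(s))
            for s in np.random.SeedSequence(5).spawn(40)
        ]
        ref = [simulate_homogeneous_poisson(5.0, 2100.0, np.random.default_rng(s))
               for s in np.random.SeedSequence(6).spawn(40)]
        _, p = stats.ks_2samp(pooled_nonoverlapping_counts(streams),
                              pooled_nonoverlapping_counts(ref))
        assert p > 0.01

    def test_each_half_is_homogeneous_at_its_rate(self):
        reps = 200
        firsts, seconds = [], []
        for s in np.random.SeedSequence(9).spawn(reps):
            st_ = simulate_changepoint_poisson(4.0, 8.0, 1050.0, 2100.0, np.random.default_rng(s))
            firsts.append(np.sum(st_.times < 1050.0))
            seconds.append(np.sum(st_.times >= 1050.0))
        for got, lam in ((np.mean(firsts), 4.0 / 60 * 1050), (np.mean(seconds), 8.0 / 60 * 1050)):
            assert abs(got - lam) < 3 * np.sqrt(lam / reps)

    def test_mixture_variance_matches_closed_form(self):
        """Pooled window counts follow the 50/50 Poisson mixture: the
        closed-form variance-to-mean ratio 1 + (mu2-mu1)^2/(2(mu1+mu2))."""
        lam1, lam2 = 4.0, 8.0  # events per 1-min window
        mean, var, m4 = mixture_moments(lam1, lam2)
        closed_vmr = 1 + (lam2 - lam1) ** 2 / (2 * (lam1 + lam2))
        assert var / mean == pytest.approx(closed_vmr, rel=1e-9)

        streams = [
            simulate_changepoint_poisson(lam1, lam2, 1050.0, 2100.0, np.random.default_rng(s))
            for s in np.random.SeedSequence(21).spawn(300)
        ]
        counts = pooled_nonoverlapping_counts(streams, 60.0)
        se_var = np.sqrt((m4 - var**2) / counts.size)
        assert abs(np.var(counts, ddof=1) - var) < 4 * se_var
        assert abs(np.mean(counts) - mean) < 4 * np.sqrt(var / counts.size)


class TestMerged:
    def test_zero_first_rate_reduces_to_homogeneous(self):
        a = simulate_merged_poisson(0.0, 6.0, 2100.0, 3)
        assert a.n_events > 0  # only the second component contributes

    def test_superposition_matches_summed_rate(self):
        """merged(3,6) window counts are indistinguishable from Poisson rate 9."""
        n_pairs, passed = 40, 0
        for s in np.random.SeedSequence(33).spawn(n_pairs):
            r1, r2 = s.spawn(2)
            merged = [simulate_merged_poisson(3.0, 6.0, 2100.0, np.random.default_rng(c))
                      for c in r1.spawn(5)]
            hom = [simulate_homogeneous_poisson(9.0, 2100.0, np.random.default_rng(c))
                   for c in r2.spawn(5)]
            _, p = stats.ks_2samp(pooled_nonoverlapping_counts(merged, 24.0),
                                  pooled_nonoverlapping_counts(hom, 24.0))
            passed += p > 0.01
        assert passed >= 0.95 * n_pairs


class TestSwitching:
    def test_dwell_must_be_positive(self):
        with pytest.raises(ValueError):
            simulate_switching_shedding(1.0, 5.0, 0.0, 10.0, 600.0, 1)

    def test_equal_rates_look_homogeneous(self):
        sw = [simulate_switching_shedding(5.0, 5.0, 5.0, 5.0, 2100.0, np.random.default_rng(s))
              for s in np.random.SeedSequence(3).spawn(40)]
        hom = [simulate_homogeneous_poisson(5.0, 2100.0, np.random.default_rng(s))
               for s in np.random.SeedSequence(4).spawn(40)]
        _, p = stats.ks_2samp(pooled_nonoverlapping_counts(sw), pooled_nonoverlapping_counts(hom))
        assert p > 0.01

    def test_long_run_rate_is_dwell_weighted_average(self):
        r_lo, r_hi, d_lo, d_hi = 2.0, 10.0, 5.0, 10.0
        expected = (r_lo * d_lo + r_hi * d_hi) / (d_lo + d_hi)  # events/min
        reps = 200
        rates = [
            simulate_switching_shedding(r_lo, r_hi, d_lo, d_hi, 2100.0,
                                        np.random.default_rng(s)).rate_per_min
            for s in np.random.SeedSequence(17).spawn(reps)
        ]
        se = np.std(rates, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(rates) - expected) < 3 * se

    def test_slow_switching_is_overdispersed(self):
        s = simulate_switching_shedding(2.0, 10.0, 20.0, 20.0, 8 * 3600.0, 77)
        counts = pooled_nonoverlapping_counts([s], 60.0)
        assert np.var(counts, ddof=1) / np.mean(counts) > 1.5


class TestDiurnal:
    def test_fixed_multipliers_give_expected_ratio(self):
        session = simulate_diurnal_session(20.0, (0.2, 1.0, 2.0, 5.0), seed=2)
        rates = session.scan_rates_per_min
        assert 18 < rates.max() / rates.min() < 34  # expectation 25 +/- counting noise

    def test_nonpositive_multiplier_rejected(self):
        with pytest.raises(ValueError):
            simulate_diurnal_session(5.0, (1.0, 0.0, 1.0, 1.0), seed=1)

    def test_loguniform_sessions_far_more_variable_than_homogeneous(self):
        seeds = np.random.SeedSequence(8).spawn(30)
        diurnal = [simulate_diurnal_session(5.0, "loguniform", seed=np.random.default_rng(s))
                   for s in seeds]
        flat = [simulate_diurnal_session(5.0, (1.0, 1.0, 1.0, 1.0),
                                         seed=np.random.default_rng(s)) for s in seeds]
        ratio = lambda sess: sess.scan_rates_per_min.max() / sess.scan_rates_per_min.min()
        assert np.median([ratio(s) for s in diurnal]) > 3 * np.median([ratio(s) for s in flat])

    def test_pooled_rate_is_events_over_time(self):
        session = simulate_diurnal_session(5.0, (1.0, 1.0, 2.0, 2.0), seed=3)
        total = sum(s.n_events for s in session.scans)
        assert session.pooled_rate_per_min == pytest.approx(total / (4 * 50.0))


class TestSimSpec:
    def test_invariants(self):
        with pytest.raises(ValueError):
            SimSpec("bogus", 1.0)
        with pytest.raises(ValueError):
            SimSpec("homogeneous", -1.0)
        with pytest.raises(ValueError):
            SimSpec("changepoint", 1.0, 2.0, change_time=0.0)


class TestFixtureSuite:
    def test_small_suite_complete_and_deterministic(self, tmp_path):
        m1 = generate_fixture_suite(tmp_path / "a", 99, n_each=4, n_sessions=2)
        m2 = generate_fixture_suite(tmp_path / "b", 99, n_each=4, n_sessions=2)
        assert len(m1["entries"]) == 3 * 4 + 2
        assert json.dumps(m1["entries"]) == json.dumps(m2["entries"])
        for f in sorted((tmp_path / "a").glob("*.csv")):
            assert (tmp_path / "b" / f.name).read_bytes() == f.read_bytes()

    def test_all_files_validate(self, tmp_path):
        m = generate_fixture_suite(tmp_path, 5, n_each=3, n_sessions=1)
        for entry in m["entries"]:
            for p in entry["paths"]:
                series = validate_event_series(read_event_series(tmp_path / p))
                assert isinstance(series, EventSeries)
        counts = [e["n_events"] for e in m["entries"] if e["kind"] != "diurnal_session"]
        assert all(isinstance(c, int) for c in counts)
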