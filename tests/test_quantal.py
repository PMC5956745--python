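from itertools import combinations

import numpy as np
import pytest

import epsckit as ek
from conftest import detect_screen_align


def brute_force_rank_sum(x, y):
    """Independent oracle: exact two-sided p by full enumeration of the
    permutation distribution of the Mann-Whitney pair count (no ties)."""
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    n_x = len(x)
    u_obs = sum(xi > yj for xi in x for yj in y)
    us = []
    for idx in combinations(range(len(pooled)), n_x):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(sum(a > b for a in xs for b in ys))
    us = np.array(us)
    p_lo = np.mean(us <= u_obs)
    p_hi = np.mean(us >= u_obs)
    return u_obs, min(1.0, 2.0 * min(p_lo, p_hi))


class TestWilcoxonRankSum:
    def test_separated_samples_exact_p(self):
        w, p = ek.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert w == 0
        assert p == pytest.approx(0.10, abs=1e-12)

    def test_mirror_symmetry(self):
        w, p = ek.wilcoxon_rank_sum([4, 5, 6], [1, 2, 3])
        assert w == 9
        assert p == pytest.approx(0.10, abs=1e-12)

    def test_identical_sets_with_midranks(self):
        w, _ = ek.wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert w == pytest.approx(9 / 2)

    def test_statistic_complementarity(self, rng):
        for _ in range(10):
            x = rng.normal(size=rng.integers(2, 8))
            y = rng.normal(size=rng.integers(2, 8))
            wxy, _ = ek.wilcoxon_rank_sum(x, y)
            wyx, _ = ek.wilcoxon_rank_sum(y, x)
            assert wxy + wyx == pytest.approx(x.size * y.size)

    def test_exact_p_matches_enumeration_all_small_sizes(self, rng):
        """Exact p-values agree with full enumeration for all n_x, n_y <= 6."""
        for n_x in range(1, 7):
            for n_y in range(1, 7):
                x = rng.normal(size=n_x)
                y = rng.normal(size=n_y) + rng.uniform(-1, 1)
                w, p = ek.wilcoxon_rank_sum(x, y)
                w_ref, p_ref = brute_force_rank_sum(x, y)
                assert w == pytest.approx(w_ref)
                assert p == pytest.approx(p_ref, abs=1e-12), (n_x, n_y)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ek.wilcoxon_rank_sum([], [1.0])


def _sr2_session(seed=0, n_sweeps=30, fail=0.1, async_rate=40.0):
    return ek.SessionModel(
        noise_sd=1.0, sweep_duration=400.0, n_sweeps=n_sweeps, seed=seed,
        sr2_release=ek.Sr2Release(sync_amplitude=-60.0, async_rate=async_rate,
                                  async_tau=60.0, failure_prob=fail))


class TestAnalyzeSr2Session:
    def test_failure_rate_from_constructed_sweeps(self, quantal_model):
        """30 sweeps of which 3 silent give a failure rate of 0.10."""
        session = _sr2_session(seed=1, n_sweeps=30, fail=0.0)
        rec, _ = ek.simulate_sr2_session(quantal_model, session)
        # silence sweeps 4, 11 and 20 entirely
        rng = np.random.default_rng(2)
        for s in (4, 11, 20):
            rec.sweeps[s] = rng.normal(0, 1.0, rec.n_samples)
        _, events, sd = detect_screen_align(rec)
        summary = ek.analyze_sr2_session(rec, events)
        assert summary.failure_rate == pytest.approx(3 / 30)

    def test_exclusion_window_zeroes_counts(self, quantal_model):
        """Only the synchronous response inside 10 ms: all counts zero."""
        session = _sr2_session(seed=3, async_rate=0.0, fail=0.0)
        rec, _ = ek.simulate_sr2_session(quantal_model, session)
        _, events, _ = detect_screen_align(rec)
        summary = ek.analyze_sr2_session(rec, events)
        assert summary.per_sweep_counts.sum() == 0
        assert summary.failure_rate == 0.0
        assert summary.initial_epsc_amplitude < -30.0

    def test_mean_count_recovery(self, quantal_model):
        """Mean asynchronous quantal count per sweep recovered within 15%."""
        session = _sr2_session(seed=4, n_sweeps=50, fail=0.0, async_rate=40.0)
        rec, truth = ek.simulate_sr2_session(quantal_model, session)
        _, events, _ = detect_screen_align(rec)
        summary = ek.analyze_sr2_session(rec, events)
        countable = truth[(truth.kind == "async")
                          & (truth.time_ms > 20.0 + 10.0)]  # past exclusion
        true_mean = (countable.groupby("sweep").size()
                     .reindex(range(50), fill_value=0).mean())
        assert summary.per_sweep_counts.mean() == pytest.approx(true_mean,
                                                                rel=0.15)

    def test_failure_rate_unbiased(self, quantal_model):
        """Estimated failure rate is unbiased for the generator's q."""
        q = 0.2
        rates = []
        for seed in range(25):
            session = _sr2_session(seed=seed, n_sweeps=24, fail=q,
                                   async_rate=30.0)
            rec, _ = ek.simulate_sr2_session(quantal_model, session)
            _, events, _ = detect_screen_align(rec)
            rates.append(ek.analyze_sr2_session(rec, events).failure_rate)
        se = np.sqrt(q * (1 - q) / (24 * len(rates)))
        assert abs(np.mean(rates) - q) < 2 * se + 0.01

    def test_missing_stimuli_rejected(self, mepsc_recording):
        rec, _ = mepsc_recording
        with pytest.raises(ValueError):
            ek.analyze_sr2_session(rec, [])


class TestAnalyzeTrain:
    def _recordings(self, f=0.59, tau_rec=1e9, noise=0.5, n_sweeps=12,
                    seed=0, first_amp=-100.0):
        truth, rec = ek.simulate_train(
            ek.QuantalModel(), depletion=ek.Depletion(f, tau_rec),
            n_sweeps=n_sweeps, noise_sd=noise, first_amplitude=first_amp,
            seed=seed)
        return truth, rec

    def test_hand_computed_ppr(self):
        """Pulse amplitudes (100, 41, ...) give PPR 0.41."""
        truth, rec = self._recordings(f=0.59, noise=0.0)
        res = ek.analyze_train({"ctrl": rec}, reference="ctrl")["ctrl"]
        assert res.ppr_2_1 == pytest.approx(0.41, abs=0.02)
        assert res.normalized_amplitudes[0] == pytest.approx(1.0)

    def test_identical_responses_give_unity(self):
        truth, rec = self._recordings(f=1e-9, noise=0.0)
        res = ek.analyze_train({"ctrl": rec}, reference="ctrl")["ctrl"]
        np.testing.assert_allclose(res.normalized_amplitudes,
                                   np.ones(5), atol=0.02)
        assert res.ppr_2_1 == pytest.approx(1.0, abs=0.02)

    def test_depletion_recovery_with_noise(self):
        """Ground-truth PPR 0.30 recovered within 10% from noisy sweeps."""
        truth, rec = self._recordings(f=0.70, noise=1.0, n_sweeps=100, seed=5)
        assert truth.attrs["ppr_2_1"] == pytest.approx(0.30, abs=1e-6)
        res = ek.analyze_train({"ctrl": rec}, reference="ctrl")["ctrl"]
        assert res.ppr_2_1 == pytest.approx(0.30, rel=0.10)

    def test_cross_condition_normalization(self):
        _, high = self._recordings(f=0.59, noise=0.0)
        _, low = self._recordings(f=0.59, noise=0.0, first_amp=-40.0)
        res = ek.analyze_train({"high": high, "low": low}, reference="high")
        assert res["high"].normalized_amplitudes[0] == pytest.approx(1.0)
        assert res["low"].normalized_amplitudes[0] == pytest.approx(0.4,
                                                                    abs=0.02)

    def test_reference_condition_required(self):
        _, rec = self._recordings(noise=0.0)
        with pytest.raises(ValueError):
            ek.analyze_train({"ctrl": rec}, reference="nope")

    def test_minimum_sweep_count_enforced(self):
        _, rec = self._recordings(noise=0.0, n_sweeps=3)
        with pytest.raises(ValueError):
            ek.analyze_train({"ctrl": rec}, reference="ctrl")


class TestMinimalStimulation:
    def test_accepts_nominal_profile(self, rng):
        lat = rng.normal(1.0, 0.05, size=20)
        amp = rng.normal(-60.0, 5.0, size=20)
        assert ek.minimal_stimulation_ok(0.3, lat, amp)

    def test_rejects_wrong_failure_rate(self, rng):
        lat = rng.normal(1.0, 0.05, size=20)
        amp = rng.normal(-60.0, 5.0, size=20)
        assert not ek.minimal_stimulation_ok(0.8, lat, amp)

    def test_rejects_variable_latency(self, rng):
        lat = rng.uniform(0.5, 5.0, size=20)
        amp = rng.normal(-60.0, 5.0, size=20)
        assert not ek.minimal_stimulation_ok(0.3, lat, amp)


from hypothesis import given, settings
from hypothesis import strategies as st


class TestRankSumProperties:
    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=8,
                    unique=True),
           st.lists(st.floats(-50, 50), min_size=2, max_size=8,
                    unique=True))
    def test_complementarity_and_p_symmetry(self, x, y):
        wxy, pxy = ek.wilcoxon_rank_sum(x, y)
        wyx, pyx = ek.wilcoxon_rank_sum(y, x)
        assert wxy + wyx == pytest.approx(len(x) * len(y))
        assert pxy == pytest.approx(pyx, abs=1e-12)
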