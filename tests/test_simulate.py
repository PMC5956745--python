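import numpy as np
import pytest
from scipy import stats as sps

import epsckit as ek


class TestQuantalEvent:
    def test_single_channel_is_a_step_of_unitary_amplitude(self, rng):
        model = ek.QuantalModel(n_channels=1, unitary_current=-0.69,
                                tau_rise=1e-4, tau_decay=1.3)
        wave = ek.simulate_quantal_event(model, 0.05, rng)
        levels = np.unique(np.round(wave / model.unitary_current, 3))
        assert set(levels).issubset({0.0, 1.0})

    def test_variance_mean_parabola_at_half_open(self, sharp_rise_model):
        """At the decay time where half the channels remain open the
        across-event variance equals the binomial value i^2 * N_p / 4."""
        rng = np.random.default_rng(42)
        model = sharp_rise_model
        dt = 0.05
        waves = np.vstack([ek.simulate_quantal_event(model, dt, rng)
                           for _ in range(10_000)])
        t = np.arange(waves.shape[1]) * dt
        t_half = model.tau_decay * np.log(2.0)
        j = int(round(t_half / dt))
        i, n_p = model.unitary_current, model.n_channels
        expected_var = i**2 * n_p / 4.0
        observed = waves[:, j].var(ddof=1)
        # chi-square CI for a sample variance at n=10,000
        n = waves.shape[0]
        lo = expected_var * sps.chi2.ppf(0.0005, n - 1) / (n - 1)
        hi = expected_var * sps.chi2.ppf(0.9995, n - 1) / (n - 1)
        assert lo < observed < hi

    def test_variance_mean_parabola_pointwise_chi2(self, sharp_rise_model):
        """The full variance-mean relation sigma^2 = i*I - I^2/N_p holds
        pointwise across the decay (chi-square goodness at 10,000 events)."""
        rng = np.random.default_rng(99)
        model = sharp_rise_model
        dt = 0.05
        waves = np.vstack([ek.simulate_quantal_event(model, dt, rng)
                           for _ in range(10_000)])
        t = np.arange(waves.shape[1]) * dt
        sel = (t > 5 * model.tau_rise) & (t < 3 * model.tau_decay)
        mean = waves[:, sel].mean(axis=0)
        var = waves[:, sel].var(axis=0, ddof=1)
        expected = model.unitary_current * mean - mean**2 / model.n_channels
        n = waves.shape[0]
        # (n-1) s^2 / sigma^2 ~ chi2(n-1) at each time point; sum over points
        stat = ((n - 1) * var / expected).sum()
        dof = (n - 1) * sel.sum()
        z = (stat - dof) / np.sqrt(2 * dof)
        assert abs(z) < 4.0

    def test_variance_vanishes_at_the_peak_current(self, sharp_rise_model):
        """All channels open at onset: current there is exactly i*N_p."""
        rng = np.random.default_rng(0)
        model = sharp_rise_model
        dt = 0.001
        waves = np.vstack([ek.simulate_quantal_event(model, dt, rng,
                                                     duration=0.05)
                           for _ in range(200)])
        j = 10  # well past the 0.01 ms rise, essentially no closures yet
        assert waves[:, j].var() < (0.05 * model.peak_current) ** 2

    def test_ensemble_mean_decay(self, quantal_model):
        rng = np.random.default_rng(5)
        dt = 0.05
        waves = np.vstack([ek.simulate_quantal_event(quantal_model, dt, rng)
                           for _ in range(5000)])
        mean = waves.mean(axis=0)
        expected = ek.simulate.mean_event_waveform(quantal_model, dt)
        scale = abs(quantal_model.peak_current)
        assert np.max(np.abs(mean - expected)) / scale < 0.05


class TestMepscRecording:
    def test_zero_rate_gives_pure_noise(self, quantal_model):
        session = ek.SessionModel(event_rate=0.0, noise_sd=2.0,
                                  sweep_duration=500.0, n_sweeps=4, seed=1)
        rec, truth = ek.simulate_mepsc_recording(quantal_model, session)
        assert len(truth) == 0
        assert rec.sweeps.std() == pytest.approx(2.0, rel=0.05)

    def test_event_count_is_poisson_with_expected_mean(self, quantal_model):
        session = ek.SessionModel(event_rate=3.0, noise_sd=1.0,
                                  sweep_duration=1000.0, n_sweeps=60, seed=2)
        _, truth = ek.simulate_mepsc_recording(quantal_model, session)
        expected = 3.0 * 60  # 3 Hz for 60 s
        assert abs(len(truth) - expected) < 4 * np.sqrt(expected)

    def test_seed_determinism(self, quantal_model):
        session = ek.SessionModel(event_rate=3.0, noise_sd=1.0,
                                  sweep_duration=200.0, n_sweeps=3, seed=11)
        rec1, truth1 = ek.simulate_mepsc_recording(quantal_model, session)
        rec2, truth2 = ek.simulate_mepsc_recording(quantal_model, session)
        np.testing.assert_array_equal(rec1.sweeps, rec2.sweeps)
        assert truth1.equals(truth2)

    def test_sign_check_rejects_outward_unitary_at_negative_potential(self):
        model = ek.QuantalModel(unitary_current=0.69)
        session = ek.SessionModel(n_sweeps=1, sweep_duration=100.0)
        with pytest.raises(ValueError):
            ek.simulate_mepsc_recording(model, session,
                                        holding_potential=-60.0)


class TestIVRamp:
    def test_linear_iv_recovers_unity_ri(self):
        ramp = ek.simulate_iv_ramp(1.0, 1.0, noise_sd=0.0)
        assert ek.ri_slope(ramp) == pytest.approx(1.0, abs=1e-9)

    def test_rectifying_ramp_truth(self):
        ramp = ek.simulate_iv_ramp(1.0, 0.3, noise_sd=0.0)
        assert ek.ri_slope(ramp) == pytest.approx(0.3, abs=1e-9)

    def test_noisy_ramp_mean_recovery_within_5pct(self):
        ris = [ek.ri_slope(ek.simulate_iv_ramp(1.0, 0.3, noise_sd=2.0,
                                               seed=s))
               for s in range(10)]
        assert np.mean(ris) == pytest.approx(0.3, rel=0.05)


class TestSr2Session:
    def _session(self, seed=0, n_sweeps=30, fail=0.1):
        return ek.SessionModel(
            noise_sd=1.0, sweep_duration=400.0, n_sweeps=n_sweeps, seed=seed,
            sr2_release=ek.Sr2Release(sync_amplitude=-50.0, async_rate=40.0,
                                      async_tau=60.0, failure_prob=fail))

    def test_failure_sweep_count_matches_binomial_mean(self, quantal_model):
        fails = []
        for seed in range(10):
            _, truth = ek.simulate_sr2_session(quantal_model,
                                               self._session(seed))
            fails.append(truth["failure"].sum())
        assert np.mean(fails) == pytest.approx(3.0, abs=1.5)

    def test_zero_async_rate_gives_only_synchronous(self, quantal_model):
        session = self._session()
        session.sr2_release.async_rate = 0.0
        _, truth = ek.simulate_sr2_session(quantal_model, session)
        assert set(truth["kind"]) <= {"sync", "none"}

    def test_mean_async_count_matches_rate_integral(self, quantal_model):
        counts = []
        for seed in range(8):
            session = self._session(seed, n_sweeps=40, fail=0.0)
            _, truth = ek.simulate_sr2_session(quantal_model, session)
            per_sweep = truth[truth["kind"] == "async"].groupby("sweep").size()
            counts.append(per_sweep.reindex(range(40), fill_value=0).mean())
        sr2 = self._session().sr2_release
        expected = sr2.expected_async_count(400.0 - sr2.stim_time)
        assert np.mean(counts) == pytest.approx(expected, rel=0.1)


class TestTrainDepletion:
    def test_ppr_limit_without_recovery(self, quantal_model):
        truth, _ = ek.simulate_train(
            quantal_model, depletion=ek.Depletion(0.59, 1e9), noise_sd=0.0,
            n_sweeps=2)
        assert truth.attrs["ppr_2_1"] == pytest.approx(0.41, abs=1e-6)

    def test_no_depletion_means_flat_train(self, quantal_model):
        truth, _ = ek.simulate_train(
            quantal_model, depletion=ek.Depletion(1e-9, 1e9), noise_sd=0.0,
            n_sweeps=2)
        amps = truth["amplitude_pA"].to_numpy()
        np.testing.assert_allclose(amps, amps[0], rtol=1e-6)

    def test_instant_recovery_means_ppr_one(self, quantal_model):
        truth, _ = ek.simulate_train(
            quantal_model, depletion=ek.Depletion(0.59, 1e-9), noise_sd=0.0,
            n_sweeps=2)
        assert truth.attrs["ppr_2_1"] == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("f,tau_rec,dt", [
        (0.05, 50.0, 10.0), (0.5, 200.0, 10.0), (0.99, 5.0, 3.0),
        (1.0, 1000.0, 10.0)])
    def test_resources_stay_in_unit_interval(self, f, tau_rec, dt):
        r = ek.depletion_resources(40, f, tau_rec, dt)
        assert np.all(r > 0) and np.all(r <= 1.0)
        assert r[0] == 1.0


class TestTerminal:
    def test_zero_density_means_no_vesicles(self):
        ann = ek.simulate_terminal(density_per_um2=0.0, seed=0)
        assert ann.n_vesicles == 0

    def test_poisson_mean_count(self):
        counts = [ek.simulate_terminal(density_per_um2=130.0, seed=s).n_vesicles
                  for s in range(5)]
        assert np.mean(counts) == pytest.approx(1300, rel=0.05)

    def test_diameters_respect_hard_floor(self):
        ann = ek.simulate_terminal(density_per_um2=100.0,
                                   diameter_mean_nm=12.0, diameter_sd_nm=5.0,
                                   seed=1)
        assert (ann.vesicles["diameter_nm"] > 10.0).all()

    def test_determinism_under_seed(self):
        a = ek.simulate_terminal(density_per_um2=50.0, seed=42)
        b = ek.simulate_terminal(density_per_um2=50.0, seed=42)
        assert a.vesicles.equals(b.vesicles)

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError):
            ek.simulate_terminal(terminal_polygon=[(0, 0), (1, 1), (2, 2)])


from hypothesis import given, settings
from hypothesis import strategies as st


class TestDepletionProperties:
    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(f=st.floats(1e-6, 1.0), tau=st.floats(1e-3, 1e4),
           dt=st.floats(0.1, 1e3), n=st.integers(2, 60))
    def test_resources_bounded_for_any_parameters(self, f, tau, dt, n):
        r = ek.depletion_resources(n, f, tau, dt)
        assert np.all((r > 0) & (r <= 1.0))

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(f=st.floats(0.05, 0.95), dt=st.floats(1.0, 100.0))
    def test_ppr_equals_one_minus_f_without_recovery(self, f, dt):
        r = ek.depletion_resources(2, f, 1e12, dt)
        assert r[1] == pytest.approx(1.0 - f, rel=1e-6)
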