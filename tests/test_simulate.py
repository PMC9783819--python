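"""Synthetic generator: determinism, ground truth, statistical contracts."""

import numpy as np
import pytest
import scipy.stats

import chronovoc as cv
from chronovoc.errors import ConfigurationError
from chronovoc.simulate import circadian_factor, emission_window


def mean_chronogram(cond, seed, **over):
    rset, _ = cv.simulate_replicate_set(cv.default_config(cond, seed=seed, **over))
    return rset.mean


class TestConfig:
    def test_unknown_condition_rejected(self):
        with pytest.raises(ConfigurationError):
            cv.default_config("bacteria")

    @pytest.mark.parametrize(
        "overrides",
        [
            dict(ar1_coeff=1.0),
            dict(noise_sd=-0.1),
            dict(burst_shape=0.0),
            dict(baseline=float("nan")),
            dict(circadian_peak_hour=25.0),
        ],
    )
    def test_invalid_parameters_rejected(self, overrides):
        with pytest.raises(ConfigurationError):
            cv.default_config("plant", **overrides)

    def test_emission_window_ordering_enforced(self):
        with pytest.raises(ConfigurationError):
            cv.default_config("fungus", emission_onset_day=5.0, emission_offset_day=4.0)
        with pytest.raises(ConfigurationError):
            cv.default_config("interaction", emission_offset_day=9.0)  # > duration

    def test_background_conditions_have_no_emission(self):
        for cond in ("plant", "medium"):
            cfg = cv.default_config(cond)
            assert cfg.burst_rate == 0.0
            assert cfg.circadian_amplitude == 0.0

    def test_fungus_window_shorter_than_interaction(self):
        f, i = cv.default_config("fungus"), cv.default_config("interaction")
        f_days = f.emission_offset_day - f.emission_onset_day
        i_days = i.emission_offset_day - i.emission_onset_day
        assert f.emission_offset_day == i.emission_offset_day - 2
        assert f_days < i_days


class TestDeterminism:
    def test_identical_config_and_seed_bit_identical(self):
        a, ta = cv.simulate_replicate_set(cv.default_config("interaction", seed=11))
        b, tb = cv.simulate_replicate_set(cv.default_config("interaction", seed=11))
        for key in a.chronograms:
            np.testing.assert_array_equal(
                a.chronograms[key].intensities, b.chronograms[key].intensities
            )
        np.testing.assert_array_equal(a.mean.intensities, b.mean.intensities)
        for k in ta.per_replicate_noiseless_signal:
            np.testing.assert_array_equal(
                ta.per_replicate_noiseless_signal[k], tb.per_replicate_noiseless_signal[k]
            )

    def test_different_seeds_differ(self):
        a, _ = cv.simulate_replicate_set(cv.default_config("fungus", seed=1))
        b, _ = cv.simulate_replicate_set(cv.default_config("fungus", seed=2))
        assert not np.array_equal(a.mean.intensities, b.mean.intensities)

    def test_technical_count_does_not_perturb_biological_draws(self):
        _, t3 = cv.simulate_replicate_set(cv.default_config("fungus", seed=5))
        _, t1 = cv.simulate_replicate_set(cv.default_config("fungus", seed=5, n_technical=1))
        for b in t3.per_replicate_noiseless_signal:
            np.testing.assert_array_equal(
                t3.per_replicate_noiseless_signal[b],
                t1.per_replicate_noiseless_signal[b],
            )


class TestGroundTruth:
    def test_shapes_and_replicate_structure(self):
        cfg = cv.default_config("fungus", seed=3)
        rset, truth = cv.simulate_replicate_set(cfg)
        assert rset.n_replicates == cfg.n_biological * cfg.n_technical
        assert all(c.n == cfg.n_points for c in rset.chronograms.values())
        assert rset.mean.n == cfg.n_points
        assert set(truth.per_replicate_noiseless_signal) == {1, 2, 3}

    def test_noiseless_zero_outside_emission_window(self):
        cfg = cv.default_config("interaction", seed=9)
        _, truth = cv.simulate_replicate_set(cfg)
        t = truth.times_h
        t_on = (cfg.emission_onset_day - 1) * 24.0
        t_off = cfg.emission_offset_day * 24.0
        outside = (t < t_on) | (t > t_off)
        for sig in truth.per_replicate_noiseless_signal.values():
            assert np.all(sig[outside] == 0.0)
            assert np.any(sig[~outside] > 0.0)

    def test_background_truth_identically_zero(self):
        for cond in ("plant", "medium"):
            _, truth = cv.simulate_replicate_set(cv.default_config(cond, seed=4))
            for sig in truth.per_replicate_noiseless_signal.values():
                assert np.all(sig == 0.0)

    def test_intensities_clipped_at_zero(self):
        rset, _ = cv.simulate_replicate_set(
            cv.default_config("plant", seed=2, baseline=0.0, noise_sd=0.5)
        )
        assert all(np.all(c.intensities >= 0.0) for c in rset.chronograms.values())


class TestStatisticalContracts:
    def test_background_is_gaussian_shaped(self):
        """Plant-alone mean chronograms: moment statistics centred on the
        Gaussian values, averaged over 50 seeds (within 4 standard errors)."""
        skews, kurts = [], []
        for seed in range(1, 51):
            x = mean_chronogram("plant", seed).intensities
            skews.append(cv.skewness(x))
            kurts.append(cv.excess_kurtosis(x))
        n = 192
        se_skew = np.sqrt(6.0 / n) / np.sqrt(50)
        se_kurt = np.sqrt(24.0 / n) / np.sqrt(50)
        assert abs(np.mean(skews)) < 4 * se_skew
        assert abs(np.mean(kurts)) < 4 * se_kurt

    def test_degenerate_config_is_iid_gaussian(self):
        """burst_rate=0, circadian=0, ar1=0: raw technical-replicate series are
        i.i.d. Gaussian around the baseline (Kolmogorov-Smirnov at alpha=0.01)."""
        passed = 0
        for seed in range(5):
            cfg = cv.default_config(
                "plant", seed=seed, ar1_coeff=0.0, baseline=10.0, noise_sd=0.01
            )
            rset, _ = cv.simulate_replicate_set(cfg)
            x = rset.chronograms[(1, 1)].intensities
            p = scipy.stats.kstest(x, "norm", args=(10.0, 0.01)).pvalue
            passed += p > 0.01
        assert passed >= 4

    def test_ar1_coefficient_recovery(self):
        """Lag-1 ACF of burst-free simulations recovers ar1_coeff within 0.05
        (n = 192 points, 100 seeds)."""
        est = [
            cv.acf(mean_chronogram("plant", seed).intensities, max_lag=1)[1]
            for seed in range(1, 101)
        ]
        assert np.mean(est) == pytest.approx(0.25, abs=0.05)

    def test_moments_monotone_in_burst_scale(self):
        """Seed-averaged skewness / kurtosis of the fungus condition do not
        decrease when the burst amplitude scale doubles (3-point grid)."""
        default = cv.default_config("fungus").burst_scale
        means = []
        for scale in (default / 2, default, default * 2):
            sk, ku = [], []
            for seed in range(1, 51):
                x = mean_chronogram("fungus", seed, burst_scale=scale).intensities
                sk.append(cv.skewness(x))
                ku.append(cv.excess_kurtosis(x))
            means.append((np.mean(sk), np.mean(ku)))
        assert means[0][0] <= means[1][0] <= means[2][0]
        assert means[0][1] <= means[1][1] <= means[2][1]

    def test_white_noise_acf_band_without_autocorrelation(self):
        """ar1=0 and no bursts: sample ACF at lags >= 1 stays inside the
        2/sqrt(n) white-noise band for >= 93% of lags across seeds."""
        hits = total = 0
        for seed in range(1, 31):
            x = mean_chronogram("plant", seed, ar1_coeff=0.0).intensities
            rho = cv.acf(x, max_lag=20)
            hits += int(np.sum(np.abs(rho[1:]) < 2 / np.sqrt(x.size)))
            total += 20
        assert hits / total >= 0.93

    def test_circadian_peak_hour_exact_on_noiseless_signal(self):
        """The hour-of-day profile of the noiseless fungus envelope attains its
        maximum exactly at the configured peak hour."""
        cfg = cv.default_config("fungus")
        t = cfg.times_h()
        env = cv.emission_envelope(t, cfg)
        clock = np.floor((cfg.inoculation_clock_hour + t) % 24).astype(int)
        profile = [env[clock == h].mean() for h in range(24)]
        assert int(np.argmax(profile)) == int(cfg.circadian_peak_hour)

    def test_circadian_factor_elevated_in_dark_phase(self):
        cfg = cv.default_config("fungus")
        t = np.arange(0.0, 24.0, 0.25)
        circ = circadian_factor(t, cfg)
        clock = (cfg.inoculation_clock_hour + t) % 24
        dark = (clock >= cfg.lights_off_hour) | (clock < cfg.lights_on_hour)
        assert circ[dark].mean() > circ[~dark].mean()

    def test_window_smooth_peak_at_peak_day(self):
        cfg = cv.default_config("interaction")
        t = np.linspace(0, cfg.duration_days * 24.0, 4001)
        w = emission_window(t, cfg)
        assert w.max() == pytest.approx(1.0, abs=1e-9)
        peak_t = t[np.argmax(w)]
        assert peak_t == pytest.approx((cfg.emission_peak_day - 0.5) * 24.0, abs=0.2)
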