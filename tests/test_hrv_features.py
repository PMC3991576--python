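import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrvscreen import (
    EntropyConfig,
    FeatureError,
    RRSeries,
    SpectralConfig,
    apen,
    band_powers,
    featurize,
    power_spectrum,
    sampen,
    simulate_rr,
    healthy_params,
    time_domain,
)
from _oracles import apen_bruteforce, sampen_bruteforce, time_domain_bruteforce


def _series(values):
    return RRSeries(np.asarray(values, dtype=float))


class TestTimeDomain:
    def test_constant_series_has_zero_variability(self):
        td = time_domain(_series(np.full(100, 800.0)))
        assert td == (0.0, 0.0, 0.0, 0.0)

    def test_against_formula_oracle(self):
        td = time_domain(_series([800.0, 860, 790, 850]))
        exp = time_domain_bruteforce([800.0, 860, 790, 850])
        assert td == pytest.approx(exp, abs=1e-12)
        assert td.pnn50 == pytest.approx(100.0)  # |d| = 60, 70, 60 all > 50

    def test_pnn50_uses_strict_inequality_at_50ms(self):
        x = np.empty(300)
        x[::2], x[1::2] = 900.0, 950.0
        assert time_domain(_series(x)).pnn50 == 0.0

    def test_random_series_against_oracle(self, rng):
        x = rng.uniform(600, 1200, size=240)
        assert time_domain(_series(x)) == pytest.approx(time_domain_bruteforce(x), rel=1e-12)

    def test_requires_two_intervals(self):
        with pytest.raises(ValueError):
            time_domain(_series([800.0]))

    @given(k=st.floats(min_value=0.5, max_value=3.0))
    @settings(derandomize=True, max_examples=25)
    def test_scaling_all_intervals_scales_sdnn_rmssd_not_cvrr(self, k):
        x = np.array([810.0, 930, 760, 880, 905, 840])
        a, b = time_domain(_series(x)), time_domain(_series(k * x))
        assert b.sdnn == pytest.approx(k * a.sdnn)
        assert b.rmssd == pytest.approx(k * a.rmssd)
        assert b.cvrr == pytest.approx(a.cvrr)  # scale-free by construction


class TestSpectrum:
    def test_constant_series_has_zero_psd(self):
        f, psd = power_spectrum(_series(np.full(300, 1000.0)))
        assert np.allclose(psd, 0.0)

    def test_pure_lf_sinusoid_power_and_band(self):
        # 0.10 Hz sinusoid of amplitude A ms on a constant mean: total power
        # should approach A^2/2 and land almost entirely in the LF band.
        A = 40.0
        t, vals = 0.0, []
        while t < 300.0:
            v = 1000.0 + A * math.sin(2 * math.pi * 0.10 * t)
            vals.append(v)
            t += v / 1000.0
        cfg = SpectralConfig(log_scale=False)
        f, psd = power_spectrum(_series(vals), cfg)
        total = np.trapezoid(psd, f)
        assert total == pytest.approx(A**2 / 2, rel=0.05)
        bp = band_powers((f, psd), cfg)
        assert bp.lf / bp.tp > 0.95
        assert bp.lf > 100 * bp.hf

    def test_parseval_integral_matches_resampled_variance(self, rng):
        # independent resampling path: cubic interpolation onto a 4 Hz grid
        from scipy.interpolate import CubicSpline
        from scipy.signal import detrend

        x = 900.0 + rng.normal(0, 30, size=330)
        rr = _series(x)
        f, psd = power_spectrum(rr, SpectralConfig())
        t = np.cumsum(x) / 1000.0
        grid = np.arange(t[0], t[-1], 0.25)
        resampled = detrend(CubicSpline(t, x)(grid))
        assert np.trapezoid(psd, f) == pytest.approx(np.var(resampled), rel=0.01)

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValueError, match="60 s"):
            power_spectrum(_series(np.full(30, 1000.0)))

    def test_nyquist_must_cover_vhf_band(self):
        with pytest.raises(ValueError):
            SpectralConfig(resample_hz=1.5)


class TestBandPowers:
    def test_constant_psd_rectangle_areas(self):
        f = np.linspace(0, 2.0, 2001)
        psd = np.where(f <= 1.0, 3.0, 0.0)
        cfg = SpectralConfig(log_scale=False)
        bp = band_powers((f, psd), cfg)
        assert bp.vlf == pytest.approx(0.04 * 3.0, rel=1e-3)
        assert bp.lf == pytest.approx(0.11 * 3.0, rel=1e-3)
        assert bp.hf == pytest.approx(0.25 * 3.0, rel=1e-3)
        assert bp.vhf == pytest.approx(0.60 * 3.0, rel=1e-3)
        assert bp.tp == pytest.approx(0.40 * 3.0, rel=1e-3)

    def test_raw_scale_additivity_tp_equals_vlf_lf_hf(self, rng):
        rr = simulate_rr(healthy_params(), rng.integers(2**31))
        cfg = SpectralConfig(log_scale=False)
        bp = band_powers(power_spectrum(rr, cfg), cfg)
        assert bp.tp == pytest.approx(bp.vlf + bp.lf + bp.hf, rel=1e-9)
        assert min(bp.vlf, bp.lf, bp.hf, bp.vhf, bp.tp) >= 0

    def test_zero_hf_makes_ratio_undefined(self):
        f = np.linspace(0, 2.0, 201)
        psd = np.where(f < 0.04, 1.0, 0.0)
        bp = band_powers((f, psd), SpectralConfig(log_scale=False))
        assert math.isnan(bp.lf_hf)

    def test_spectrum_must_cover_vhf(self):
        f = np.linspace(0, 0.5, 100)
        with pytest.raises(ValueError, match="1.0 Hz"):
            band_powers((f, np.ones_like(f)), SpectralConfig())


class TestEntropies:
    @pytest.mark.parametrize("n", [60, 150, 400])
    def test_apen_matches_bruteforce_oracle(self, n, rng):
        x = rng.uniform(0, 1, size=n)
        cfg = EntropyConfig()
        r = cfg.r_coeff * float(np.std(x))
        assert apen(x, cfg) == pytest.approx(apen_bruteforce(x, cfg.m, r), abs=1e-10)

    @pytest.mark.parametrize("n", [60, 150, 400])
    def test_sampen_matches_bruteforce_oracle(self, n, rng):
        # smooth RR-like series keep SampEn defined even at small n
        t = np.arange(n)
        x = 900 + 40 * np.sin(2 * np.pi * 0.1 * t) + rng.normal(0, 15, size=n)
        cfg = EntropyConfig()
        r = cfg.r_coeff * float(np.std(x))
        result = sampen(x, cfg)
        assert math.isfinite(result)
        assert result == pytest.approx(sampen_bruteforce(x, cfg.m, r), abs=1e-10)

    def test_entropies_with_delay_two_match_oracle(self, rng):
        x = rng.normal(0, 1, size=120)
        cfg = EntropyConfig(tau=2)
        r = cfg.r_coeff * float(np.std(x))
        assert apen(x, cfg) == pytest.approx(apen_bruteforce(x, 2, r, tau=2), abs=1e-10)
        assert sampen(x, cfg) == pytest.approx(sampen_bruteforce(x, 2, r, tau=2), abs=1e-10)

    def test_period_two_sequence_is_maximally_regular(self):
        x = np.tile([1.0, 2.0], 50)
        cfg = EntropyConfig()
        assert sampen(x, cfg) == 0.0  # A/B = 1 for a perfectly self-similar signal
        r = cfg.r_coeff * float(np.std(x))
        assert apen(x, cfg) == pytest.approx(apen_bruteforce(x, 2, r), abs=1e-10)
        assert apen(x, cfg) < 0.1

    def test_white_noise_is_more_irregular_than_periodic(self, rng):
        cfg = EntropyConfig()
        noise = rng.uniform(0, 1, size=300)
        periodic = np.tile([1.0, 2.0], 150)
        assert apen(noise, cfg) > apen(periodic, cfg)
        assert sampen(rng.normal(0, 1, 300), cfg) > 1.0

    def test_sampen_decreases_as_tolerance_grows(self, rng):
        x = rng.normal(0, 1, size=250)
        vals = [sampen(x, EntropyConfig(r_coeff=rc)) for rc in (0.1, 0.2, 0.35, 0.5)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_zero_variance_input_is_an_error(self):
        with pytest.raises(ValueError, match="zero-variance"):
            apen(np.full(100, 5.0))
        with pytest.raises(ValueError, match="zero-variance"):
            sampen(np.full(100, 5.0))

    def test_sampen_undefined_when_no_long_matches(self):
        # (0, 0) pairs match at length m=2, but every length-3 template
        # contains a distinct large spike: A = 0 -> undefined marker
        x = np.zeros(30)
        x[2::3] = 1000.0 * (1 + np.arange(10))
        assert math.isnan(sampen(x))


class TestFeaturize:
    def test_constant_series_fails_in_entropy_stage(self):
        with pytest.raises(FeatureError, match="entropy"):
            featurize(_series(np.full(350, 900.0)))

    def test_synthetic_series_yields_finite_features(self):
        rr = simulate_rr(healthy_params(), 7)
        f = featurize(rr)
        vals = list(f.as_dict().values())
        assert all(math.isfinite(v) for v in vals)
        assert f.sdnn > 0 and 0 <= f.pnn50 <= 100

    def test_feature_vector_is_order_sensitive(self, rng):
        rr = simulate_rr(healthy_params(), 8)
        shuffled = RRSeries(rng.permutation(rr.intervals))
        a, b = featurize(rr), featurize(shuffled)
        assert a.sdnn == pytest.approx(b.sdnn)  # order-free statistic
        assert a.rmssd != pytest.approx(b.rmssd, rel=1e-3)

    def test_featurize_is_deterministic(self):
        rr = simulate_rr(healthy_params(), 9)
        assert featurize(rr) == featurize(rr)
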