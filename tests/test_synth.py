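import numpy as np
import pytest
from scipy import stats

import tonomap as tm
from tonomap.errors import ValidationError
from tonomap.synth import SHAPE_SINGLE, SiteTruth


def truth_single(cf=8000.0, thr=30.0, bw=1.0, lat=15.0):
    return SiteTruth(true_cf_hz=cf, true_thr_db=thr, true_bw10_oct=bw,
                     true_latency_ms=lat, true_shape=SHAPE_SINGLE,
                     is_ai=True, is_responsive=True)


class TestPresets:
    def test_shipped_presets_encode_group_means(self):
        c, v = tm.CONTROL_PRESET, tm.VPA_PRESET
        assert c.bw10_mean_oct == 1.24 and v.bw10_mean_oct == 3.02
        assert c.latency_mean_ms == 14.97 and v.latency_mean_ms == 10.27
        assert c.p_single == 0.9347 and v.p_single == 0.7625
        assert v.p_thr_above50 == pytest.approx(0.3758)

    def test_threshold_normal_matches_target_fraction(self):
        # P(N(mean, sd) > 55) is the fraction rounding above 50 dB on the grid
        for p in (tm.CONTROL_PRESET, tm.VPA_PRESET):
            frac = stats.norm.sf(55.0, loc=p.thr_mean_db, scale=p.thr_sd_db)
            assert frac == pytest.approx(p.p_thr_above50, abs=2e-3)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValidationError):
            tm.ConditionPreset(name="x", cf_jitter_oct_sd=0, bw10_mean_oct=1,
                               bw10_sd_oct=0, thr_mean_db=30, thr_sd_db=0,
                               p_thr_above50=0, latency_mean_ms=10,
                               latency_sd_ms=0, p_single=0.5, p_multi=0.5,
                               p_flat=0.5)


class TestSampleMap:
    def test_one_animal_has_128_sites(self, protocol):
        sites = tm.sample_map(tm.CONTROL_PRESET,
                              np.random.default_rng(0), protocol)
        assert len(sites) == 128
        pens = {g.penetration_id for g, _ in sites}
        assert pens == {0, 1}
        # 8x8 grid at 375 x 500 um pitch per penetration
        xs = sorted({g.x_um for g, _ in sites if g.penetration_id == 0})
        ys = sorted({g.y_um for g, _ in sites if g.penetration_id == 0})
        assert np.allclose(np.diff(xs), 375.0) and len(xs) == 8
        assert np.allclose(np.diff(ys), 500.0) and len(ys) == 8

    def test_noiseless_gradient_is_monotone_in_x(self, protocol):
        from dataclasses import replace
        preset = replace(tm.CONTROL_PRESET, cf_jitter_oct_sd=0.0,
                         hi_freq_bias=0.0)
        sites = tm.sample_map(preset, np.random.default_rng(1), protocol,
                              ai_border_frac=0.0)
        by_x = sorted(sites, key=lambda st: st[0].x_um)
        cfs = [t.true_cf_hz for g, t in by_x]
        xs = [g.x_um for g, _ in by_x]
        for (x1, c1), (x2, c2) in zip(zip(xs, cfs), zip(xs[1:], cfs[1:])):
            if x2 > x1:
                assert c2 > c1

    def test_same_seed_identical_truth(self, protocol):
        a = tm.sample_map(tm.VPA_PRESET, np.random.default_rng(3), protocol)
        b = tm.sample_map(tm.VPA_PRESET, np.random.default_rng(3), protocol)
        assert [(g, t) for g, t in a] == [(g, t) for g, t in b]

    def test_truth_respects_protocol_ranges(self, protocol):
        sites = tm.sample_map(tm.VPA_PRESET, np.random.default_rng(4), protocol)
        for _, t in sites:
            if t.is_responsive:
                assert protocol.frequencies_hz[0] <= t.true_cf_hz \
                    <= protocol.frequencies_hz[-1]
                assert t.true_thr_db in protocol.intensities_db
                assert t.true_bw10_oct > 0

    def test_border_fraction_marks_non_ai_sites(self, protocol):
        sites = tm.sample_map(tm.CONTROL_PRESET, np.random.default_rng(5),
                              protocol, ai_border_frac=0.15)
        non_ai = [t for _, t in sites if not t.is_ai]
        assert len(non_ai) == 20  # 2 penetrations x round(0.15 * 64)
        kinds = {(t.is_responsive) for t in non_ai}
        assert kinds == {True, False}  # high-threshold-only and unresponsive

    def test_shape_frequencies_match_preset(self, protocol):
        # binomial 99% CI check on single_v frequency in a large cohort
        rng = np.random.default_rng(6)
        n_single = n_resp = 0
        for _ in range(20):
            for _, t in tm.sample_map(tm.VPA_PRESET, rng, protocol,
                                      ai_border_frac=0.0):
                n_resp += 1
                n_single += t.true_shape == SHAPE_SINGLE
        p = tm.VPA_PRESET.p_single
        half = 2.576 * np.sqrt(p * (1 - p) / n_resp)
        assert abs(n_single / n_resp - p) < half

    def test_high_threshold_fraction_matches_preset(self, protocol):
        rng = np.random.default_rng(7)
        n_hi = n_resp = 0
        for _ in range(20):
            for _, t in tm.sample_map(tm.VPA_PRESET, rng, protocol,
                                      ai_border_frac=0.0):
                n_resp += 1
                n_hi += t.true_thr_db > 50.0
        p = tm.VPA_PRESET.p_thr_above50
        half = 2.576 * np.sqrt(p * (1 - p) / n_resp)
        assert abs(n_hi / n_resp - p) < half


class TestExpectedRateSurface:
    def test_supra_threshold_span_equals_bw10(self, protocol):
        cf = protocol.nearest_frequency(8000.0)
        t = truth_single(cf=cf, thr=30.0, bw=1.0)
        rate = tm.expected_rate_surface(t, protocol, tm.CONTROL_PRESET)
        i40 = protocol.intensity_index(40.0)
        evoked_cols = np.flatnonzero(
            rate[:, i40, :].max(axis=1) > tm.CONTROL_PRESET.baseline_rate_hz)
        freqs = protocol.freq_array
        span = np.log2(freqs[evoked_cols[-1]] / freqs[evoked_cols[0]])
        assert span == pytest.approx(1.0, abs=2 * protocol.freq_step_oct)

    def test_below_threshold_is_baseline(self, protocol):
        t = truth_single(thr=70.0, bw=1.0)
        rate = tm.expected_rate_surface(t, protocol, tm.CONTROL_PRESET)
        below = rate[:, :-1, :]
        # only the tip column responds at 70 dB; everything below is baseline
        assert np.allclose(below[np.abs(np.log2(protocol.freq_array / t.true_cf_hz)) > 1e-9],
                           tm.CONTROL_PRESET.baseline_rate_hz)

    def test_tip_is_at_true_cf(self, protocol):
        cf = protocol.nearest_frequency(4000.0)
        t = truth_single(cf=cf, thr=30.0, bw=1.0)
        rate = tm.expected_rate_surface(t, protocol, tm.CONTROL_PRESET)
        i30 = protocol.intensity_index(30.0)
        col = int(np.argmax(rate[:, i30, :].max(axis=1)))
        assert protocol.frequencies_hz[col] == cf

    def test_unresponsive_truth_is_all_baseline(self, protocol):
        t = SiteTruth(None, None, None, None, None, is_ai=False,
                      is_responsive=False)
        rate = tm.expected_rate_surface(t, protocol, tm.CONTROL_PRESET)
        assert np.allclose(rate, tm.CONTROL_PRESET.baseline_rate_hz)


class TestSimulateSite:
    def test_zero_baseline_unresponsive_site_is_silent(self, protocol):
        from dataclasses import replace
        preset = replace(tm.CONTROL_PRESET, baseline_rate_hz=0.0)
        t = SiteTruth(None, None, None, None, None, False, False)
        rec = tm.simulate_site(t, protocol, preset, np.random.default_rng(0))
        assert rec.counts.sum() == 0

    def test_counts_mean_matches_rate_surface(self, half_octave_protocol):
        # Monte Carlo vs the analytic mean, within 3 standard errors
        p = tm.make_protocol(
            frequencies_hz=half_octave_protocol.frequencies_hz,
            intensities_db=half_octave_protocol.intensities_db, n_trials=200)
        cf = p.nearest_frequency(4000.0)
        t = truth_single(cf=cf, thr=10.0, bw=1.0)
        rate = tm.expected_rate_surface(t, p, tm.CONTROL_PRESET)
        lam = rate * p.bin_ms / 1000.0
        rec = tm.simulate_site(t, p, tm.CONTROL_PRESET,
                               np.random.default_rng(11))
        # compare per-cell totals over the response window
        got = rec.counts.sum(axis=(2, 3)) / p.n_trials
        want = lam.sum(axis=-1)
        se = np.sqrt(lam.sum(axis=-1) / p.n_trials)
        assert np.all(np.abs(got - want) <= 3 * se + 1e-9)

    def test_same_seed_identical_counts(self, protocol):
        t = truth_single(cf=protocol.nearest_frequency(8000.0))
        a = tm.simulate_site(t, protocol, tm.CONTROL_PRESET,
                             np.random.default_rng(5))
        b = tm.simulate_site(t, protocol, tm.CONTROL_PRESET,
                             np.random.default_rng(5))
        assert np.array_equal(a.counts, b.counts)


class TestGenerativeConsistency:
    def test_estimators_recover_truth_on_noise_free_surfaces(self, protocol):
        """CF exact, threshold exact, BW10 within two grid steps, over a sweep."""
        from dataclasses import replace
        rng = np.random.default_rng(42)
        preset = replace(tm.CONTROL_PRESET, baseline_rate_hz=0.5,
                         evoked_gain=8.0)
        step = protocol.freq_step_oct
        n_checked = 0
        while n_checked < 100:
            cf = protocol.nearest_frequency(
                float(rng.uniform(3000.0, 20000.0)))
            thr = float(rng.choice([0., 10., 20., 30., 40., 50.]))
            bw = float(rng.uniform(0.5, 3.5))
            t = truth_single(cf=cf, thr=thr, bw=bw)
            rate = tm.expected_rate_surface(t, protocol, preset)
            lam = rate * protocol.bin_ms / 1000.0
            counts = np.repeat(lam[:, :, None, :], protocol.n_trials, axis=2)
            rec = tm.SiteRecording("nf", 0, 0, counts)
            fra = tm.build_fra(rec, protocol)
            cf_est, thr_est = tm.extract_cf_threshold(fra, protocol)
            assert cf_est == cf
            assert thr_est == thr
            bw_est = tm.compute_bw10(fra, thr_est, protocol)
            if bw_est is not None:
                assert bw_est <= bw + 1e-9
                assert bw - bw_est < 2 * step + 1e-9
            n_checked += 1
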