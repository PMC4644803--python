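import numpy as np
import pytest
from hypothesis import given, strategies as st

import tonomap as tm
from tonomap.synth import SHAPE_SINGLE, SiteTruth

from conftest import make_recording


def blank_counts(protocol, pre_ms=50.0, post_ms=100.0):
    n_bins = int(round((pre_ms + post_ms) / protocol.bin_ms))
    return np.zeros((protocol.n_freqs, protocol.n_intensities,
                     protocol.n_trials, n_bins))


def fra_from_mask(mask, baseline=0.0):
    m = np.asarray(mask, dtype=bool)
    return tm.FRA(evoked=m.astype(float), sig_mask=m, baseline_mean=baseline,
                  baseline_sd=0.0)


class TestBuildFRA:
    def test_cluster_rule_keeps_triples_drops_singletons(self, half_octave_protocol):
        p = half_octave_protocol
        counts = blank_counts(p)
        # 5 evoked spikes per trial at one cell and its two vertical neighbors
        f0 = p.freq_index(4000.0)
        for i in (1, 2, 3):
            counts[f0, i, :, 60:65] = 1  # 5 spikes in the response window
        # one isolated noisy cell far away
        counts[0, 4, 0, 70] = 1
        fra = tm.build_fra(make_recording(counts), p)
        assert fra.sig_mask[f0, 1] and fra.sig_mask[f0, 2] and fra.sig_mask[f0, 3]
        assert not fra.sig_mask[0, 4]
        assert fra.sig_mask.sum() == 3

    def test_uniform_baseline_gives_empty_mask(self, half_octave_protocol):
        p = half_octave_protocol
        rng = np.random.default_rng(0)
        counts = rng.poisson(0.005, size=blank_counts(p).shape)
        fra = tm.build_fra(make_recording(counts), p)
        assert not fra.sig_mask.any()
        assert fra.baseline_mean > 0

    def test_noise_free_single_v_mask_is_contiguous_v(self, protocol):
        t = SiteTruth(protocol.nearest_frequency(8000.0), 30.0, 1.0, 15.0,
                      SHAPE_SINGLE, True, True)
        rate = tm.expected_rate_surface(t, protocol, tm.CONTROL_PRESET)
        lam = rate * protocol.bin_ms / 1000.0
        counts = np.repeat(lam[:, :, None, :], protocol.n_trials, axis=2)
        fra = tm.build_fra(tm.SiteRecording("v", 0, 0, counts), protocol)
        # each intensity row at/above threshold is one contiguous run that
        # widens with intensity
        i_thr = protocol.intensity_index(30.0)
        prev = 0
        for i in range(i_thr, protocol.n_intensities):
            cols = np.flatnonzero(fra.sig_mask[:, i])
            assert cols.size >= max(prev, 1)
            assert np.all(np.diff(cols) == 1)
            prev = cols.size
        assert not fra.sig_mask[:, :i_thr].any()

    def test_all_zero_recording_is_valid_and_unresponsive(self, half_octave_protocol):
        fra = tm.build_fra(make_recording(blank_counts(half_octave_protocol)),
                           half_octave_protocol)
        assert not fra.responsive


class TestCFThreshold:
    def test_single_cell_tip(self, half_octave_protocol):
        p = half_octave_protocol
        mask = np.zeros((p.n_freqs, p.n_intensities), dtype=bool)
        f4, i20 = p.freq_index(4000.0), p.intensity_index(20.0)
        mask[f4, i20] = True
        mask[f4 - 1: f4 + 2, i20 + 1] = True
        cf, thr = tm.extract_cf_threshold(fra_from_mask(mask), p)
        assert cf == 4000.0 and thr == 20.0

    def test_flat_tip_takes_median_frequency(self, half_octave_protocol):
        # five significant bins 4-16 kHz at the minimal intensity -> 8 kHz
        p = half_octave_protocol
        mask = np.zeros((p.n_freqs, p.n_intensities), dtype=bool)
        lo, hi = p.freq_index(4000.0), p.freq_index(16000.0)
        mask[lo:hi + 1, 3] = True
        mask[lo:hi + 1, 4] = True
        cf, thr = tm.extract_cf_threshold(fra_from_mask(mask), p)
        assert thr == 30.0
        assert cf == pytest.approx(8000.0)

    def test_multi_peak_apex_with_lowest_threshold_wins(self, protocol):
        # apexes (4 kHz, 30 dB) and (32 kHz, 20 dB) -> CF 32 kHz, thr 20 dB
        p = protocol
        mask = np.zeros((p.n_freqs, p.n_intensities), dtype=bool)
        f4 = p.freq_array.searchsorted(4000.0)
        f32 = p.freq_array.searchsorted(32000.0)
        mask[f4 - 1: f4 + 2, 3:] = True
        mask[f32 - 1: f32 + 2, 2:] = True
        cf, thr = tm.extract_cf_threshold(fra_from_mask(mask), p)
        assert thr == 20.0
        assert abs(np.log2(cf / 32000.0)) < 0.1

    def test_empty_mask_undefined(self, half_octave_protocol):
        fra = fra_from_mask(np.zeros((half_octave_protocol.n_freqs,
                                      half_octave_protocol.n_intensities)))
        assert tm.extract_cf_threshold(fra, half_octave_protocol) == (None, None)


class TestBW10:
    def test_one_octave_span(self, half_octave_protocol):
        p = half_octave_protocol
        mask = np.zeros((p.n_freqs, p.n_intensities), dtype=bool)
        mask[p.freq_index(4000.0), 2] = True
        lo = p.freq_index(1000.0 * 2 ** 2.5)   # 5656.9 Hz
        hi = p.freq_index(1000.0 * 2 ** 3.5)   # 11313.7 Hz
        mask[lo:hi + 1, 3] = True
        assert tm.compute_bw10(fra_from_mask(mask), 20.0, p) == pytest.approx(1.0)

    def test_full_row_is_whole_tested_range(self, protocol):
        mask = np.zeros((protocol.n_freqs, protocol.n_intensities), dtype=bool)
        mask[:, 1] = True
        bw = tm.compute_bw10(fra_from_mask(mask), 0.0, protocol)
        assert bw == pytest.approx(np.log2(70.0), abs=1e-9)

    def test_single_cell_row_is_zero(self, half_octave_protocol):
        p = half_octave_protocol
        mask = np.zeros((p.n_freqs, p.n_intensities), dtype=bool)
        mask[3, 2], mask[3, 3] = True, True
        assert tm.compute_bw10(fra_from_mask(mask), 20.0, p) == 0.0

    def test_threshold_at_top_intensity_undefined(self, half_octave_protocol):
        p = half_octave_protocol
        mask = np.zeros((p.n_freqs, p.n_intensities), dtype=bool)
        mask[3, -1] = True
        assert tm.compute_bw10(fra_from_mask(mask), 40.0, p) is None


class TestLatency:
    def _psth_recording(self, psth, protocol):
        counts = np.asarray(psth, dtype=float)[None, None, None, :]
        return tm.SiteRecording("L", 0, 0, counts, pre_ms=50.0, post_ms=100.0)

    def test_four_sd_rule_hand_case(self):
        # baseline mean 0.5, SD 0.25 -> criterion 1.5; bins 15,16 at 1.5 -> 15 ms
        p = tm.make_protocol(frequencies_hz=(1000.0,), intensities_db=(70.0,),
                             n_trials=1)
        psth = np.zeros(150)
        psth[:50] = np.tile([0.25, 0.75], 25)
        psth[50 + 15] = psth[50 + 16] = 1.5
        rec = self._psth_recording(psth, p)
        assert tm.estimate_latency(rec, p, 70.0) == pytest.approx(15.0)

    def test_flat_psth_undefined(self):
        p = tm.make_protocol(frequencies_hz=(1000.0,), intensities_db=(70.0,),
                             n_trials=1)
        rec = self._psth_recording(np.full(150, 0.5), p)
        assert tm.estimate_latency(rec, p, 70.0) is None

    def test_translation_equivariance_noise_free(self, protocol):
        # shifting the evoked mass by +k ms shifts the estimate by +k ms
        ests = []
        for lat in (10.0, 14.0):
            t = SiteTruth(protocol.nearest_frequency(8000.0), 20.0, 1.5, lat,
                          SHAPE_SINGLE, True, True)
            rate = tm.expected_rate_surface(t, protocol, tm.CONTROL_PRESET)
            lam = rate * protocol.bin_ms / 1000.0
            counts = np.repeat(lam[:, :, None, :], protocol.n_trials, axis=2)
            rec = tm.SiteRecording("t", 0, 0, counts)
            ests.append(tm.estimate_latency(rec, protocol, 20.0))
        assert ests[1] - ests[0] == pytest.approx(4.0)

    def test_parameter_recovery_high_gain(self, protocol):
        from tonomap.validation import latency_recovery
        mean_est, n = latency_recovery(n_sites=40, seed=3,
                                       true_latency_ms=12.0)
        assert n >= 30
        assert abs(mean_est - 12.0) < 1.0


class TestIrregularityIndex:
    @pytest.mark.parametrize("mask, expected", [
        (np.ones((1, 1)), -2.0),                      # 1/1 - 3
        (np.ones((2, 2)), -2.0),                      # (4 - 2)/2 - 3
        (np.eye(2), 2.0 / np.sqrt(2.0) - 3.0),        # scattered > compact
    ])
    def test_hand_values(self, mask, expected):
        _, idx = tm.irregularity_index(mask.astype(bool))
        assert idx == pytest.approx(expected)

    @given(st.integers(min_value=1, max_value=8),
           st.integers(min_value=1, max_value=66))
    def test_rectangular_closed_form(self, a, b):
        mask = np.ones((b, a), dtype=bool)
        terms, idx = tm.irregularity_index(mask)
        assert idx == pytest.approx((a + b) / (2.0 * np.sqrt(a * b)) - 3.0)
        assert terms.c00 >= terms.c10 >= 0
        assert terms.c00 >= terms.c01 >= 0

    def test_invariant_to_padding_outside_mask(self):
        mask = np.zeros((6, 5), dtype=bool)
        mask[2:4, 1:4] = True
        _, idx = tm.irregularity_index(mask)
        padded = np.pad(mask, ((3, 7), (2, 4)))
        _, idx_padded = tm.irregularity_index(padded)
        assert idx == pytest.approx(idx_padded)

    def test_empty_mask_undefined(self):
        terms, idx = tm.irregularity_index(np.zeros((3, 3), dtype=bool))
        assert terms is None and idx is None


class TestClassifyShape:
    def _noise_free_fra(self, truth, protocol, preset=None):
        preset = preset or tm.CONTROL_PRESET
        rate = tm.expected_rate_surface(truth, protocol, preset)
        lam = rate * protocol.bin_ms / 1000.0
        counts = np.repeat(lam[:, :, None, :], protocol.n_trials, axis=2)
        return tm.build_fra(tm.SiteRecording("c", 0, 0, counts), protocol)

    def test_single_v_truth(self, protocol):
        t = SiteTruth(protocol.nearest_frequency(8000.0), 30.0, 2.0, 15.0,
                      SHAPE_SINGLE, True, True)
        fra = self._noise_free_fra(t, protocol)
        assert tm.classify_shape(fra, protocol) == "single_v"

    def test_two_deep_peaks_are_multi(self, protocol):
        t = SiteTruth(protocol.nearest_frequency(4000.0), 30.0, 1.0, 15.0,
                      "multi", True, True,
                      true_cf2_hz=protocol.nearest_frequency(16000.0),
                      true_thr2_db=40.0)
        fra = self._noise_free_fra(t, protocol)
        assert tm.classify_shape(fra, protocol) == "multi"

    def test_constant_threshold_across_two_octaves_is_flat(self, protocol):
        t = SiteTruth(protocol.nearest_frequency(8000.0), 30.0, 1.0, 15.0,
                      "flat", True, True, true_flat_span_oct=2.0)
        fra = self._noise_free_fra(t, protocol)
        assert tm.classify_shape(fra, protocol) == "flat"

    def test_classifier_accuracy_on_seeded_cohort(self, protocol):
        # v-shaped vs multi/flat dichotomy (the grouping the summaries use)
        from tonomap.config import RunConfig
        from tonomap.validation import _run_sites
        correct = total = 0
        for truth, m in _run_sites(tm.CONTROL_PRESET, 256,
                                   np.random.SeedSequence(123), protocol,
                                   RunConfig(), ai_border_frac=0.0):
            if m.shape is None:
                continue
            total += 1
            correct += (m.shape == "single_v") == (truth.true_shape == "single_v")
        assert total > 200
        assert correct / total >= 0.90
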