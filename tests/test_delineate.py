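import numpy as np
import pytest

from fecgkit import (DelineateConfig, InsufficientBeatsError, LengthError,
                     delineate, detect_r_peaks, find_mod_max_pairs,
                     match_peaks, se_ppv_f1, swt_quadratic_spline)
from fecgkit.delineate import _r_pairs, detect_p_t, detect_qrs_bounds, detect_qs
from fecgkit.simulate import fetal_waves, synth_ecg

FS = 1000.0


def _match_truth(fid, truths, key, fid_attr=None, tol=20):
    """Pair detected beats with analytic truth by R proximity; return errors."""
    errs = []
    by_r = {t["R"]: t for t in truths}
    for b in fid.beats:
        r_true = min(by_r, key=lambda k: abs(k - b.R))
        if abs(r_true - b.R) > tol:
            continue
        v = getattr(b, fid_attr or key)
        if v is not None and key in by_r[r_true]:
            errs.append(v - by_r[r_true][key])
    return np.asarray(errs, dtype=float)


class TestTransform:
    def test_constant_signal_zero_coefficients(self):
        w = swt_quadratic_spline(np.full(256, 2.5), FS)
        np.testing.assert_allclose(w.coeffs, 0.0, atol=1e-10)

    def test_ramp_gives_constant_scale1(self):
        w = swt_quadratic_spline(np.arange(256, dtype=float), FS)
        interior = w.coeffs[0][8:-8]
        assert np.ptp(interior) < 1e-10 and abs(interior[0]) > 0

    @pytest.mark.parametrize("scale", [1, 2, 3, 4])
    def test_step_modulus_maximum_near_edge(self, scale):
        x = np.zeros(1024)
        x[500:] = 1.0
        w = swt_quadratic_spline(x, FS)
        c = w.aligned(scale)
        peak = int(np.argmax(np.abs(c)))
        assert abs(peak - 500) <= 2 ** scale

    def test_too_short(self):
        with pytest.raises(LengthError):
            swt_quadratic_spline(np.zeros(32), FS)


class TestModMaxPairs:
    def test_zero_coefficients_empty(self):
        w = swt_quadratic_spline(np.zeros(256), FS)
        assert find_mod_max_pairs(w, 4, 0.1, -0.1) == []

    def test_single_lobe_pair(self):
        # a negative then a positive lobe -> one pair, zero crossing between
        t = np.arange(400)
        sig = -np.exp(-0.5 * ((t - 100) / 3.0) ** 2) \
            + np.exp(-0.5 * ((t - 110) / 3.0) ** 2)
        w = swt_quadratic_spline(np.zeros(400), FS)
        w.coeffs[3] = sig
        w.delays[3] = 0.0
        pairs = find_mod_max_pairs(w, 4, 0.1, -0.1)
        assert len(pairs) == 1
        p = pairs[0]
        assert p.neg_idx == 100 and p.pos_idx == 110
        assert 100 < p.zero_idx < 110

    def test_orphan_negative_dropped(self):
        t = np.arange(600)
        sig = (-np.exp(-0.5 * ((t - 100) / 3.0) ** 2)
               - np.exp(-0.5 * ((t - 160) / 3.0) ** 2)
               + np.exp(-0.5 * ((t - 170) / 3.0) ** 2))
        w = swt_quadratic_spline(np.zeros(600), FS)
        w.coeffs[3] = sig
        w.delays[3] = 0.0
        pairs = find_mod_max_pairs(w, 4, 0.1, -0.1)
        assert len(pairs) == 1
        assert pairs[0].neg_idx == 160  # nearest negative wins


class TestRDetection:
    def test_clean_signal_perfect(self, clean_fetal):
        x, r, _ = clean_fetal
        det = detect_r_peaks(x, FS)
        se, ppv, _ = se_ppv_f1(match_peaks(det, r, tol_s=0.02, fs=FS))
        assert se == 100.0 and ppv == 100.0

    def test_attenuated_beat_recovered_by_gap_rule(self, clean_fetal):
        x, r, _ = clean_fetal
        x = x.copy()
        k = r[10]
        x[k - 150:k + 250] *= 0.5  # halve one beat's amplitude
        det = detect_r_peaks(x, FS)
        assert np.min(np.abs(det - k)) <= 20

    def test_spurious_spike_rejected(self, clean_fetal):
        x, r, _ = clean_fetal
        x = x.copy()
        k = r[12] + 60  # 60 ms after a true R: violates 0.4 * mean RR
        x[k - 3:k + 4] += np.exp(-0.5 * ((np.arange(-3, 4)) / 1.5) ** 2)
        det = detect_r_peaks(x, FS)
        se, ppv, _ = se_ppv_f1(match_peaks(det, r, tol_s=0.02, fs=FS))
        assert ppv == 100.0 and se == 100.0

    def test_too_short(self):
        with pytest.raises(LengthError):
            detect_r_peaks(np.zeros(500), FS)

    def test_flat_signal_warns_empty(self):
        with pytest.warns(RuntimeWarning):
            det = detect_r_peaks(np.zeros(4000), FS)
        assert det.size == 0


class TestQSAndBounds:
    def test_qs_within_10ms(self, clean_fetal):
        x, _, truths = clean_fetal
        fid = delineate(x, FS)
        for key in ("Q", "S"):
            errs = _match_truth(fid, truths, key)
            assert errs.size > 0.9 * len(truths)
            assert np.abs(errs).max() <= 10

    def test_small_q_reported_absent(self):
        waves = [w for w in fetal_waves() if w.name != "Q"]
        waves.append(type(waves[0])("Q", -0.012, 0.004, -0.01))
        x, r, _ = synth_ecg(duration_s=30, seed=1, waves=waves)
        fid = delineate(x, FS)
        q_found = sum(b.Q is not None for b in fid.beats)
        assert q_found <= 0.1 * len(fid.beats)

    def test_early_peak_windows_clipped(self):
        x, r, _ = synth_ecg(duration_s=10, seed=2)
        w = swt_quadratic_spline(x, FS)
        pairs, _ = _r_pairs(x, FS, DelineateConfig(), w)
        pairs[0].neg_idx = 3  # simulate a pair at the very signal start
        out = detect_qs(x, w, pairs[:1], FS)  # must not crash
        assert len(out) == 1

    def test_qrs_duration_within_10ms(self, clean_fetal):
        x, _, truths = clean_fetal
        fid = delineate(x, FS)
        true_dur = truths[0]["qrs_duration_s"]
        durs = np.asarray(fid.qrs_durations_s, dtype=float)
        assert abs(np.mean(durs) - true_dur) <= 0.010
        assert true_dur == pytest.approx(0.040, abs=1e-12)

    def test_duration_in_normal_fetal_range(self, clean_fetal):
        x, _, _ = clean_fetal
        fid = delineate(x, FS)
        assert 0.02 <= np.mean(fid.qrs_durations_s) <= 0.05

    def test_fallback_bounds_without_qs(self):
        x, r, _ = synth_ecg(duration_s=10, seed=3)
        w = swt_quadratic_spline(x, FS)
        pairs, _ = _r_pairs(x, FS, DelineateConfig(), w)
        bounds = detect_qrs_bounds(w, [(None, None)] * len(pairs), pairs, FS)
        for (on, off, fb), p in zip(bounds, pairs):
            assert fb
            assert on == max(0, p.zero_idx - 25)
            assert off == p.zero_idx + 25


class TestPT:
    def test_t_peak_within_25ms(self, clean_fetal):
        x, _, truths = clean_fetal
        fid = delineate(x, FS)
        errs = _match_truth(fid, truths, "T_peak")
        assert errs.size > 0.9 * len(truths)
        assert np.abs(errs).max() <= 25

    def test_removed_t_stays_absent(self):
        x, r, _ = synth_ecg(duration_s=30, seed=4,
                            waves=fetal_waves(t_amp=0.0))
        fid = delineate(x, FS)
        t_found = sum(b.T_peak is not None for b in fid.beats)
        assert t_found <= 0.1 * len(fid.beats)

    def test_last_beat_clipped_no_crash(self, clean_fetal):
        x, r, _ = clean_fetal
        end = r[-1] + 80  # truncate right after the last QRS
        fid = delineate(x[:end], FS)
        assert len(fid) >= 2


class TestDelineate:
    def test_ordering_invariant(self, clean_fetal):
        x, _, _ = clean_fetal
        assert delineate(x, FS).ordering_ok()

    def test_st_elevation_recovered(self):
        x, r, truths = synth_ecg(duration_s=30, seed=5)
        x = x.copy()
        for t in truths:
            # pedestal from QRS offset to well past the T wave, so the whole
            # ST stretch (and the T wave riding on it) is shifted by +0.1 mV
            a, b = t["QRS_off"], t["T_peak"] + 80
            ramp = np.ones(b - a)
            edge = 5
            taper = 0.5 * (1 - np.cos(np.linspace(0, np.pi, edge)))
            ramp[:edge] = taper
            ramp[-edge:] = taper[::-1]
            x[a:b] += 0.1 * ramp
        def median_dev(sig):
            fid = delineate(sig, FS)
            devs = [b.st_deviation_mv for b in fid.beats
                    if b.st_deviation_mv is not None]
            assert len(devs) > 0.5 * len(fid.beats)
            return float(np.median(devs))

        # the T-wave onset tail contributes a small positive deviation even
        # for a clean trace; the pedestal must add 0.1 mV on top of it
        x0, _, _ = synth_ecg(duration_s=30, seed=5)
        elevation = median_dev(x) - median_dev(x0)
        assert 0.08 <= elevation <= 0.12

    def test_zero_signal_insufficient_beats(self):
        with pytest.raises((InsufficientBeatsError, LengthError)):
            with pytest.warns(RuntimeWarning):
                delineate(np.zeros(5000), FS)

    def test_shift_equivariance(self, clean_fetal):
        x, _, _ = clean_fetal
        d = 37
        fid0 = delineate(x[: 20000], FS)
        fid1 = delineate(np.r_[np.zeros(d), x[: 20000 - d]], FS)
        r0 = [b.R for b in fid0.beats]
        r1 = [b.R - d for b in fid1.beats]
        # interior beats shift exactly
        common = min(len(r0), len(r1)) - 1
        assert r0[1:common] == r1[1:common]

    def test_amplitude_scale_invariance(self, clean_fetal):
        x, _, _ = clean_fetal
        f0 = delineate(x[:20000], FS)
        f1 = delineate(7.3 * x[:20000], FS)
        assert [b.as_dict() for b in f0.beats] == [b.as_dict() for b in f1.beats]

    def test_non_1khz_input_resampled(self, clean_fetal):
        x, r, _ = clean_fetal
        x500 = x[::2]
        fid = delineate(x500, 500.0)
        det = np.array([b.R for b in fid.beats])
        se, ppv, _ = se_ppv_f1(match_peaks(det, (r / 2).astype(int),
                                           tol_s=0.02, fs=500.0))
        assert se == 100.0 and ppv == 100.0
        assert fid.fs == 500.0

    def test_multi_seed_perfect_r(self):
        for seed in range(5):
            x, r, _ = synth_ecg(duration_s=30, seed=seed)
            fid = delineate(x, FS)
            det = np.array([b.R for b in fid.beats])
            se, ppv, _ = se_ppv_f1(match_peaks(det, r, tol_s=0.02, fs=FS))
            assert se == 100.0 and ppv == 100.0
            assert fid.ordering_ok()


class TestPTDetectorDirect:
    def test_detect_p_t_returns_per_beat(self, clean_fetal):
        x, _, _ = clean_fetal
        w = swt_quadratic_spline(x, FS)
        pairs, _ = _r_pairs(x, FS, DelineateConfig(), w)
        out = detect_p_t(x, w, pairs, FS)
        assert len(out) == len(pairs)
        found = sum("T_peak" in d for d in out)
        assert found >= 0.9 * len(out)
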