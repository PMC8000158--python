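"""The 49-variant processing bank: census, nulls, gains, linearity,
operator form and signal averaging."""

import numpy as np
import pytest

import ecgi_bench as eb
from ecgi_bench.filters import (
    BDR_METHODS,
    HFR_METHODS,
    RTF_KERNEL,
    UnsupportedOperatorError,
)
from ecgi_bench.recording import BeatSegmentation, PotentialRecording

ALL_SINGLE = list(HFR_METHODS) + list(BDR_METHODS)


def make_recording(values, fs=1000.0, seg=True, line=50.0):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    segmentation = None
    if seg:
        n = values.shape[1]
        onsets = np.arange(200, n - 700, 600)
        segmentation = BeatSegmentation(onsets, onsets + 250, onsets - 30, 20, onsets + 500)
    return PotentialRecording(values, fs, segmentation=segmentation, line_freq_hz=line)


@pytest.fixture(scope="module")
def noisy_rec(noisy_dataset):
    return noisy_dataset.torso_rec


class TestCensus:
    def test_bank_has_49_variants(self):
        assert len(eb.enumerate_methods()) == 49

    def test_35_hfr_bdr_combinations(self):
        combos = [s for s in eb.enumerate_methods() if s.category == "HFR+BDR"]
        assert len(combos) == 35

    def test_ids_unique_and_stable(self):
        ids = [s.fid for s in eb.enumerate_methods()]
        assert len(set(ids)) == 49
        assert ids[0] == "RAW" and ids[-1] == "SA"
        assert eb.FilterSpec.from_id("HFR3+BDR2").hfr == "HFR3"

    def test_unknown_id_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            eb.FilterSpec.from_id("HFR9")


class TestHighFrequencyRemoval:
    def test_moving_average_annihilates_full_cycle_line(self):
        # exact null in the steady-state interior; the reflection-padded
        # edges (one window length) carry the usual FIR transient
        t = np.arange(4000) / 1000.0
        rec = make_recording(np.sin(2 * np.pi * 50 * t), seg=False)
        out = eb.apply_hfr(rec, "HFR1")
        assert np.abs(out.values[:, 20:-20]).max() < 1e-10 * np.abs(rec.values).max()

    def test_pipberger_annihilates_line_when_two_cycles_fit(self):
        t = np.arange(4000) / 1000.0
        rec = make_recording(np.cos(2 * np.pi * 50 * t + 0.3), seg=False)
        out = eb.apply_hfr(rec, "HFR2")
        assert np.abs(out.values[:, 40:-40]).max() < 1e-10

    def test_notch_removes_line_keeps_signal(self):
        t = np.arange(8000) / 1000.0
        low = np.sin(2 * np.pi * 10 * t)
        rec = make_recording(low + 0.5 * np.sin(2 * np.pi * 50 * t), seg=False)
        out = eb.apply_hfr(rec, "HFR3").values[0]
        spec = np.fft.rfft(out)
        freqs = np.fft.rfftfreq(len(out), 1e-3)
        assert np.abs(spec[np.argmin(np.abs(freqs - 50))]) < 1e-6 * len(t)
        # 10 Hz component preserved within 1%
        amp10 = 2 * np.abs(spec[np.argmin(np.abs(freqs - 10))]) / len(t)
        assert amp10 == pytest.approx(1.0, rel=0.01)

    def test_lowpass_attenuates_above_cutoff(self, rng):
        rec = make_recording(rng.normal(size=32768), seg=False)
        out = eb.apply_hfr(rec, "HFR6")
        freqs = np.fft.rfftfreq(rec.n_samples, 1e-3)
        p_in = np.abs(np.fft.rfft(rec.values[0])) ** 2
        p_out = np.abs(np.fft.rfft(out.values[0])) ** 2
        band = freqs > 60
        assert 10 * np.log10(p_out[band].sum() / p_in[band].sum()) < -40

    @pytest.mark.parametrize("method", HFR_METHODS)
    def test_unit_dc_gain(self, method):
        rec = make_recording(np.full(4000, 2.5), seg=False)
        out = eb.apply_hfr(rec, method)
        np.testing.assert_allclose(out.values, 2.5, atol=1e-9)

    @pytest.mark.parametrize("method", ["HFR4", "HFR5", "HFR6", "HFR7"])
    def test_zero_group_delay_on_symmetric_pulse(self, method):
        x = np.zeros(2001)
        x[800:1201] = np.hanning(401)
        out = eb.apply_hfr(make_recording(x, seg=False), method)
        assert np.argmax(out.values[0]) == np.argmax(x)

    def test_frame_longer_than_record_rejected(self):
        rec = make_recording(np.zeros(8), seg=False)
        with pytest.raises(ValueError, match="longer than"):
            eb.apply_hfr(rec, "HFR2")

    def test_unknown_method_rejected(self, noisy_rec):
        with pytest.raises(ValueError, match="unknown"):
            eb.apply_hfr(noisy_rec, "HFR8")

    def test_rtf_kernel_is_11_tap_normalized(self):
        assert len(RTF_KERNEL) == 11
        assert RTF_KERNEL.sum() == pytest.approx(1.0)


class TestBaselineDriftRemoval:
    def test_simple_correction_zeroes_isoelectric_means(self, noisy_rec):
        out = eb.apply_bdr(noisy_rec, "BDR1")
        seg = out.segmentation
        for b in range(seg.n_beats):
            np.testing.assert_allclose(
                out.values[:, seg.iso_window(b)].mean(axis=-1), 0.0, atol=1e-12
            )

    def test_highpass_removes_drift_keeps_signal(self):
        # steady state only: the zero-phase IIR transient (seconds at a
        # 0.5 Hz cutoff) is excluded before projecting on each frequency
        t = np.arange(60000) / 1000.0
        drift = np.sin(2 * np.pi * 0.05 * t + 0.4)
        sig = np.sin(2 * np.pi * 20 * t)
        out = eb.apply_bdr(make_recording(drift + sig, seg=False), "BDR5").values[0]
        mid = slice(20000, 40000)

        def amp(x, f):
            c = np.exp(-2j * np.pi * f * t[mid])
            return 2 * np.abs(np.mean(x[mid] * c))

        assert amp(out, 0.05) < 1e-3 * amp(drift + sig, 0.05)  # >= 60 dB down
        assert amp(out, 20.0) == pytest.approx(1.0, rel=0.01)

    def test_savgol_baseline_removes_slow_cubic_drift(self):
        # QRS train plus a slow cubic drift: inter-beat isoelectric spread
        # collapses by far more than 10x
        n = 8000
        t = np.arange(n) / 1000.0
        drift = 0.5 * (t - 4) ** 3 / 16 + 0.3 * (t - 4)
        spikes = np.zeros(n)
        for on in range(400, n - 400, 600):
            spikes[on : on + 80] += np.hanning(80)
        rec = make_recording(drift + spikes, seg=True)
        out = eb.apply_bdr(rec, "BDR3")
        seg = rec.segmentation
        iso = lambda v: np.array([v[0, seg.iso_window(b)].mean() for b in range(seg.n_beats)])
        assert iso(out.values).std() < iso(rec.values).std() / 10

    def test_spline_removes_cubic_drift_exactly(self):
        n = 5000
        t = np.arange(n) / 1000.0
        drift = 0.8 * t**3 - 2.0 * t**2 + 0.5 * t + 1.0
        rec = make_recording(drift, seg=True)
        out = eb.apply_bdr(rec, "BDR4")
        assert np.abs(out.values).max() < 1e-6

    def test_record_shorter_than_savgol_frame_rejected(self):
        rec = make_recording(np.zeros((2, 2000)), seg=False)
        with pytest.raises(ValueError, match="3000 ms"):
            eb.apply_bdr(rec, "BDR3")

    def test_segmentation_required_for_iso_based_methods(self):
        rec = make_recording(np.zeros(4000), seg=False)
        for m in ("BDR1", "BDR4"):
            with pytest.raises(ValueError, match="segmentation"):
                eb.apply_bdr(rec, m)

    @pytest.mark.parametrize("method", BDR_METHODS)
    def test_zero_dc_gain(self, method):
        rec = make_recording(np.full(4000, 3.0), seg=True)
        out = eb.apply_bdr(rec, method)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-7)

    def test_wavelet_removes_sub_half_hz_energy(self):
        t = np.arange(16384) / 1000.0
        drift = np.sin(2 * np.pi * 0.2 * t)
        keep = np.sin(2 * np.pi * 15 * t)
        out = eb.apply_bdr(make_recording(drift + keep, seg=False), "BDR2").values[0]
        spec = np.abs(np.fft.rfft(out)) ** 2
        freqs = np.fft.rfftfreq(len(t), 1e-3)
        assert spec[freqs < 0.5].sum() < 0.02 * spec.sum()
        # passband preserved in the interior (record edges carry the
        # symmetric-extension boundary distortion of the deep decomposition)
        mid = slice(2000, -2000)
        assert out[mid].std() == pytest.approx(keep[mid].std(), rel=0.01)


class TestLinearityAndComposition:
    @pytest.mark.parametrize("method", ALL_SINGLE)
    def test_linearity(self, method, rng):
        n = 4096
        s1, s2 = rng.normal(size=(2, 3, n))
        a, b = 1.7, -0.6
        f = lambda v: eb.apply_filter(make_recording(v), method).values
        lhs = f(a * s1 + b * s2)
        rhs = a * f(s1) + b * f(s2)
        np.testing.assert_allclose(lhs, rhs, atol=1e-8 * np.abs(rhs).max())

    def test_combined_equals_composition_bitwise(self, noisy_rec):
        via_combo = eb.apply_combined(noisy_rec, "HFR1", "BDR1")
        via_two = eb.apply_bdr(eb.apply_hfr(noisy_rec, "HFR1"), "BDR1")
        np.testing.assert_array_equal(via_combo.values, via_two.values)

    def test_all_35_combinations_distinct(self, noisy_rec):
        outputs = {}
        for spec in eb.enumerate_methods():
            if spec.category != "HFR+BDR":
                continue
            outputs[spec.fid] = eb.apply_filter(noisy_rec, spec).values
        ids = list(outputs)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                assert np.abs(outputs[ids[i]] - outputs[ids[j]]).max() > 0

    def test_notch_plus_wavelet_suppresses_both_noise_classes(self, noisy_rec):
        out = eb.apply_filter(noisy_rec, "HFR3+BDR2")
        freqs = np.fft.rfftfreq(noisy_rec.n_samples, 1 / noisy_rec.fs_hz)
        p_in = (np.abs(np.fft.rfft(noisy_rec.values, axis=-1)) ** 2).mean(axis=0)
        p_out = (np.abs(np.fft.rfft(out.values, axis=-1)) ** 2).mean(axis=0)
        line_bin = np.argmin(np.abs(freqs - 50))
        # the wavelet pass after the notch redistributes a trace of energy
        # back into the notched bins; joint suppression is still > 20 dB
        assert p_out[line_bin] < 1e-2 * p_in[line_bin]
        low = freqs < 0.5
        assert p_out[low].sum() < 0.05 * p_in[low].sum()


@pytest.fixture(scope="module")
def aligned_clean():
    """Clean dataset with zero beat jitter: beats repeat exactly."""
    cfg = eb.StudyConfig(
        seed=7, jitter_ms=0.0,
        noise=eb.NoiseSpec(line_amp_mV=0.0, white_sd_mV=0.0, drift_amp_mV=0.0),
    )
    return eb.build_dataset(cfg)


class TestSignalAveraging:
    def test_identical_beats_zero_noise_average_is_single_beat(self, aligned_clean):
        rec = aligned_clean.torso_rec
        filt = eb.apply_bdr(rec, "BDR2")  # SA's internal pre-filter
        sa, info = eb.signal_average(rec, return_info=True)
        assert info["n_beats_averaged"] == rec.segmentation.n_beats
        assert all(s == 0 for s in info["shifts"])
        seg = rec.segmentation
        pre = int(seg.qrs_onset[0] - (seg.iso_start[0] - seg.iso_len))
        windows = np.stack(
            [
                filt.values[:, int(on) - pre : int(on) - pre + sa.n_samples]
                for on in seg.qrs_onset
            ]
        )
        # definitional oracle: mean of the aligned wavelet-filtered windows
        np.testing.assert_allclose(sa.values, windows.mean(axis=0), atol=1e-9)
        # each window equals any other up to the wavelet's (time-variant)
        # beat-to-beat variation, so SA stays close to a single beat
        rel_l2 = np.linalg.norm(sa.values - windows[1]) / np.linalg.norm(windows[1])
        assert rel_l2 < 0.10

    def test_known_shift_recovered_exactly(self, aligned_clean):
        rec = aligned_clean.torso_rec.copy()
        seg = rec.segmentation
        # delay the whole record tail by +10 samples from beat k onward
        k = 2
        cut = seg.beat_regions(rec.n_samples)[k].start
        shifted = np.concatenate(
            [rec.values[:, :cut], rec.values[:, cut - 10 : rec.n_samples - 10]], axis=1
        )
        rec2 = PotentialRecording(shifted, rec.fs_hz, segmentation=seg, line_freq_hz=50.0)
        _, info = eb.signal_average(rec2, return_info=True)
        assert info["shifts"][k:] == [10] * (seg.n_beats - k)
        assert info["shifts"][0] == 0
        # the splice discontinuity sits inside beat k-1's T tail and may
        # nudge its alignment by at most one sample
        assert abs(info["shifts"][1]) <= 1

    def test_white_noise_reduced_by_sqrt_n(self):
        cfg = eb.StudyConfig(
            seed=3, n_beats=10, jitter_ms=0.0,
            noise=eb.NoiseSpec(line_amp_mV=0, drift_amp_mV=0, white_sd_mV=0.05, seed=3),
        )
        ds = eb.build_dataset(cfg)
        clean = eb.generate_torso_recording(ds.forward, ds.epi_rec, cfg.noise.silent())
        sa_noisy, info = eb.signal_average(ds.torso_rec, return_info=True)
        sa_clean = eb.signal_average(clean)
        resid_sa = (sa_noisy.values - sa_clean.values).std()
        resid_single = (
            eb.apply_bdr(ds.torso_rec, "BDR2").values - eb.apply_bdr(clean, "BDR2").values
        ).std()
        n = info["n_beats_averaged"]
        assert resid_sa / resid_single == pytest.approx(1 / np.sqrt(n), rel=0.2)

    def test_fewer_than_two_beats_rejected(self):
        rec = make_recording(np.zeros((2, 1200)), seg=False)
        onsets = np.array([300])
        rec = PotentialRecording(
            rec.values, 1000.0,
            segmentation=BeatSegmentation(onsets, onsets + 200, onsets - 30, 20),
        )
        with pytest.raises(ValueError, match="at least 2"):
            eb.signal_average(rec)


class TestOperatorForm:
    def test_moving_average_rows_are_boxcars(self):
        M = eb.as_operator("HFR1", 200, 1000.0, 50.0)
        # interior row: 20 nonzero entries of 1/20 summing to one
        row = M[100]
        assert np.count_nonzero(np.abs(row) > 1e-15) == 20
        np.testing.assert_allclose(row[row != 0], 1 / 20)
        np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-12)

    def test_impulse_column_reproduces_impulse_response(self):
        n = 300
        M = eb.as_operator("HFR5", n, 1000.0, 50.0)
        imp = np.zeros(n)
        imp[150] = 1.0
        direct = eb.apply_hfr(make_recording(imp, seg=False), "HFR5").values[0]
        np.testing.assert_allclose(M @ imp, direct, atol=1e-12)

    @pytest.mark.parametrize("fid", ["HFR1", "HFR3", "HFR6", "BDR2", "BDR5", "HFR2+BDR5"])
    def test_operator_matches_direct_application(self, fid, rng):
        n = 3100
        vals = rng.normal(size=(4, n))
        rec = make_recording(vals)
        M = eb.as_operator(fid, n, 1000.0, 50.0)
        direct = eb.apply_filter(rec, fid).values
        np.testing.assert_allclose(vals @ M.T, direct, atol=1e-8 * max(1.0, np.abs(direct).max()))

    @pytest.mark.parametrize("fid", ["BDR1", "BDR4", "SA", "HFR1+BDR1"])
    def test_segmentation_dependent_methods_unsupported(self, fid):
        with pytest.raises(UnsupportedOperatorError):
            eb.as_operator(fid, 100, 1000.0, 50.0)
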