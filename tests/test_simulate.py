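"""The synthetic thermal-breathing generator: signal content, persistence, cohorts."""

import numpy as np
import pytest
import tifffile
from scipy.signal import find_peaks

from thermoresp.simulate import (
    MAX_COUNT, BreathingProfile, FormatError, ThermalSequence, make_cohort,
    read_sequence, simulate_sequence, write_sequence,
)


def _dominant_bin_hz(signal, fps):
    spec = np.abs(np.fft.rfft(signal - signal.mean()))
    spec[0] = 0.0
    return np.fft.rfftfreq(len(signal), d=1.0 / fps)[np.argmax(spec)]


class TestBreathingSignal:
    def test_breath_count_and_zero_crossings(self, clean_sequence):
        # 12 bpm for 15 s is 3 full cycles: the mean-subtracted nostril
        # trace crosses zero six times.
        assert clean_sequence.gt_breaths == pytest.approx(3.0)
        trace = clean_sequence.roi_mean()
        centred = trace - trace.mean()
        signs = np.sign(centred[centred != 0])
        crossings = int(np.sum(signs[1:] * signs[:-1] < 0))
        assert crossings == 6

    def test_zero_amplitude_gives_static_frames(self):
        prof = BreathingProfile(rr_bpm=12.0, amplitude=0.0, noise_sd=0.0,
                                drift_per_s=0.0, seed=0)
        seq = simulate_sequence(prof, duration_s=5.0, fps=8.0)
        assert (seq.frames == seq.frames[0]).all()
        assert seq.gt_breaths == 0.0

    def test_fft_peak_lands_in_nearest_bin(self):
        # 20 bpm = 1/3 Hz; with a 60 s window at 8 fps the dominant DFT bin
        # of the nostril trace must be the bin nearest 0.3333 Hz.
        prof = BreathingProfile(rr_bpm=20.0, amplitude=600.0, noise_sd=0.0, seed=3)
        seq = simulate_sequence(prof, duration_s=60.0, fps=8.0)
        trace = seq.roi_mean()
        freqs = np.fft.rfftfreq(len(trace), d=1.0 / 8.0)
        expected = freqs[np.argmin(np.abs(freqs - 20.0 / 60.0))]
        assert _dominant_bin_hz(trace, 8.0) == pytest.approx(expected)

    def test_peak_count_matches_breath_count(self):
        for rr in (8.0, 14.0, 22.0):
            prof = BreathingProfile(rr_bpm=rr, amplitude=600.0, noise_sd=0.0, seed=1)
            seq = simulate_sequence(prof, duration_s=30.0, fps=8.7)
            peaks, _ = find_peaks(seq.roi_mean())
            gt = rr * 30.0 / 60.0
            assert np.floor(gt) - 1 <= len(peaks) <= np.ceil(gt) + 1

    def test_asymmetric_waveform_keeps_fundamental(self):
        prof = BreathingProfile(rr_bpm=15.0, amplitude=600.0, noise_sd=0.0,
                                waveform="asymmetric-exhale", seed=2)
        seq = simulate_sequence(prof, duration_s=60.0, fps=8.0)
        assert _dominant_bin_hz(seq.roi_mean(), 8.0) == pytest.approx(0.25, abs=0.01)


class TestDeterminismAndRange:
    def test_fixed_seed_bit_identical(self):
        prof = BreathingProfile(rr_bpm=17.0, amplitude=500.0, noise_sd=40.0,
                                drift_per_s=3.0, seed=42)
        a = simulate_sequence(prof, 10.0, 8.7)
        b = simulate_sequence(prof, 10.0, 8.7)
        assert (a.frames == b.frames).all()
        assert a.gt_breaths == b.gt_breaths

    @pytest.mark.parametrize("amplitude,noise_sd,drift", [
        (8000.0, 0.0, 0.0),
        (600.0, 5000.0, 0.0),
        (600.0, 20.0, 800.0),
        (600.0, 20.0, -800.0),
    ])
    def test_pixels_never_leave_14bit_range(self, amplitude, noise_sd, drift):
        prof = BreathingProfile(rr_bpm=12.0, amplitude=amplitude,
                                noise_sd=noise_sd, drift_per_s=drift, seed=9)
        seq = simulate_sequence(prof, 20.0, 8.7)
        assert seq.frames.min() >= 0
        assert seq.frames.max() <= MAX_COUNT

    def test_spectral_snr_nonincreasing_in_noise(self):
        # At fixed seed, the share of in-band spectral energy at the true
        # breathing frequency can only degrade as sensor noise grows.
        def snr(noise_sd):
            prof = BreathingProfile(rr_bpm=15.0, amplitude=600.0,
                                    noise_sd=noise_sd, seed=6)
            seq = simulate_sequence(prof, 30.0, 8.7)
            trace = seq.roi_mean()
            spec = np.abs(np.fft.rfft(trace - trace.mean()))
            freqs = np.fft.rfftfreq(len(trace), d=1.0 / 8.7)
            peak = spec[np.argmin(np.abs(freqs - 0.25))]
            return peak / spec[1:].sum()

        values = [snr(sd) for sd in (0.0, 50.0, 150.0, 400.0, 1000.0)]
        assert all(a >= b * 0.98 for a, b in zip(values, values[1:]))

    def test_invalid_arguments_rejected(self):
        prof = BreathingProfile()
        with pytest.raises(ValueError):
            simulate_sequence(prof, -1.0, 8.7)
        with pytest.raises(ValueError):
            simulate_sequence(prof, 10.0, 0.0)
        with pytest.raises(ValueError):
            simulate_sequence(prof, 10.0, 8.7, resolution=(3, 3))
        with pytest.raises(ValueError):
            BreathingProfile(rr_bpm=-2.0)
        with pytest.raises(ValueError):
            BreathingProfile(noise_sd=-1.0)


class TestPersistence:
    def test_round_trip_lossless(self, tmp_path):
        prof = BreathingProfile(rr_bpm=13.0, amplitude=600.0, noise_sd=30.0, seed=5)
        seq = simulate_sequence(prof, 15.0, 8.7, subject_id="S007")
        path = tmp_path / "seq.tif"
        write_sequence(seq, path)
        back = read_sequence(path)
        assert (back.frames == seq.frames).all()
        assert back.n_frames == 131  # 15 s at 8.7 Hz
        assert back.fps == seq.fps
        assert back.roi == seq.roi
        assert back.subject_id == "S007"
        assert back.gt_breaths == pytest.approx(seq.gt_breaths)
        assert back.profile == prof

    def test_out_of_range_pixel_rejected(self, tmp_path, clean_sequence):
        path = tmp_path / "bad.tif"
        write_sequence(clean_sequence, path)
        frames = clean_sequence.frames.copy()
        frames[0, 0, 0] = 2**14  # one past the 14-bit maximum
        tifffile.imwrite(path, frames)
        with pytest.raises(FormatError, match="14-bit"):
            read_sequence(path)

    def test_missing_metadata_field_named(self, tmp_path, clean_sequence):
        import json

        path = tmp_path / "seq.tif"
        write_sequence(clean_sequence, path)
        sidecar = path.with_suffix(".json")
        meta = json.loads(sidecar.read_text())
        del meta["fps"]
        sidecar.write_text(json.dumps(meta))
        with pytest.raises(FormatError, match="fps"):
            read_sequence(path)


class TestCohort:
    def test_counts_and_distinct_subjects(self):
        cohort = make_cohort(8, 1, (6.0, 30.0), duration_s=2.0,
                             resolution=(32, 32), seed=1)
        assert len(cohort) == 8
        assert len({s.subject_id for s in cohort}) == 8

    def test_seed_determinism(self):
        a = make_cohort(4, 2, (6.0, 30.0), duration_s=2.0, resolution=(32, 32), seed=3)
        b = make_cohort(4, 2, (6.0, 30.0), duration_s=2.0, resolution=(32, 32), seed=3)
        assert [s.gt_breaths for s in a] == [s.gt_breaths for s in b]

    def test_rr_sample_mean_matches_uniform_moments(self):
        # 1000 recordings with RR ~ U(6, 30): the sample mean must sit
        # within 3 standard errors of 18 bpm.
        cohort = make_cohort(50, 20, (6.0, 30.0), duration_s=1.0, fps=8.0,
                             resolution=(32, 32), seed=12, noise_sd=0.0)
        rates = np.array([s.rr_bpm for s in cohort])
        assert len(rates) == 1000
        se = (30.0 - 6.0) / np.sqrt(12.0 * 1000.0)
        assert abs(rates.mean() - 18.0) < 3.0 * se

    def test_empty_rr_range_rejected(self):
        with pytest.raises(ValueError):
            make_cohort(2, 1, (20.0, 20.0))
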