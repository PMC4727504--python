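"""Synthetic cohort generator: spectra, seizure morphology, artefacts."""

import numpy as np
import pytest
from scipy import signal as sps

from neoseiz.io import read_annotation_file
from neoseiz.synthetic import (
    SimConfig,
    simulate_background,
    simulate_cohort,
    simulate_record,
    simulate_seizure,
)


@pytest.fixture(scope="module")
def background():
    cfg = SimConfig(duration_s=600.0, sleep_cycle_s=120.0)
    return cfg, simulate_background(cfg, np.random.default_rng(5))


class TestBackground:
    def test_deterministic_per_seed(self):
        cfg = SimConfig(duration_s=60.0)
        a = simulate_background(cfg, np.random.default_rng(5))
        b = simulate_background(cfg, np.random.default_rng(5))
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(a.aux["Resp"], b.aux["Resp"])

    def test_powerlaw_psd_slope(self, background):
        cfg, rec = background
        f, p = sps.welch(rec.data, fs=cfg.sampling_rate, nperseg=4096, axis=-1)
        m = (f >= 1) & (f <= 10)
        for ch in range(3):
            slope = np.polyfit(np.log(f[m]), np.log(p[ch][m]), 1)[0]
            assert slope == pytest.approx(-cfg.noise_exponent, abs=0.4)

    def test_delta_power_varies_with_sleep_cycle(self, background):
        cfg, rec = background
        fs = cfg.sampling_rate
        sos = sps.butter(4, [0.5, 3.0], btype="bandpass", fs=fs, output="sos")
        delta = sps.sosfiltfilt(sos, rec.data[0])
        env = sps.savgol_filter(delta**2, int(fs) * 10 + 1, 1)
        env = env - env.mean()
        ac = np.correlate(env, env, "full")[len(env) - 1:]
        skip = int(fs) * 30  # skip the zero-lag peak region
        peaks, _ = sps.find_peaks(ac[skip:])
        assert len(peaks) > 0
        period = (peaks[0] + skip) / fs
        assert period == pytest.approx(cfg.sleep_cycle_s, rel=0.10)

    def test_rms_near_configured_level(self, background):
        cfg, rec = background
        assert np.allclose(rec.data.std(axis=-1), cfg.background_rms_uv, rtol=0.01)


class TestSeizureWaveform:
    @staticmethod
    def zc_freq(x, fs):
        s = np.sign(x)
        s[s == 0] = 1
        return np.sum(s[:-1] * s[1:] < 0) / 2 / (len(x) / fs)

    def test_frequency_evolution(self):
        w = simulate_seizure(120.0, 3.0, 1.5, 100.0, 32.0)
        q = len(w) // 4
        assert self.zc_freq(w[:q], 32.0) == pytest.approx(3.0, rel=0.15)
        assert self.zc_freq(w[-q:], 32.0) == pytest.approx(1.5, rel=0.15)

    def test_envelope_zero_at_ends(self):
        w = simulate_seizure(60.0, 2.0, 1.0, 100.0, 256.0)
        peak = np.abs(w).max()
        assert abs(w[0]) <= 0.01 * peak and abs(w[-1]) <= 0.01 * peak
        assert peak == pytest.approx(100.0, rel=0.01)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="10"):
            simulate_seizure(8.0, 3.0, 1.5, 100.0, 32.0)

    def test_frequency_bounds_enforced(self):
        with pytest.raises(ValueError, match="Hz"):
            simulate_seizure(60.0, 2.0, 0.2, 100.0, 32.0)


class TestRecordAndArtefacts:
    @pytest.fixture(scope="class")
    def record(self):
        cfg = SimConfig(duration_s=900.0, respiration_rate_per_h=8.0,
                        pulse_rate_per_h=8.0, sweat_rate_per_h=6.0)
        rec, truth = simulate_record(cfg, np.random.default_rng(9))
        return cfg, rec, truth

    def test_seizure_events_respect_minimum(self, record):
        _, _, truth = record
        assert len(truth.events) >= 1
        for ev in truth.events:
            assert ev.duration >= 10.0

    def test_seizure_intervals_have_raised_amplitude(self, record):
        cfg, rec, truth = record
        fs = cfg.sampling_rate
        # seizure-free, artefact-free background level
        mask = np.ones(rec.n_samples, dtype=bool)
        for ev in truth.events:
            mask[int(ev.onset * fs):int(ev.offset * fs)] = False
        for spans in truth.artefacts.values():
            for a, b in spans:
                mask[int(a * fs):int(b * fs)] = False
        bg_rms = np.median(rec.data[:, mask].std(axis=-1))
        for ev in truth.events:
            i, j = int(ev.onset * fs), int(ev.offset * fs)
            assert rec.data[:, i:j].std(axis=-1).max() > 1.4 * bg_rms

    def test_respiration_artefact_coherence(self, record):
        cfg, rec, truth = record
        fs = cfg.sampling_rate
        assert truth.artefacts["respiration"]
        found = 0
        for a, b in truth.artefacts["respiration"]:
            i, j = int(a * fs), int(b * fs)
            best = 0.0
            for ch in range(rec.n_channels):
                f, coh = sps.coherence(rec.data[ch, i:j], rec.aux["Resp"][i:j],
                                       fs=fs, nperseg=min(1024, j - i))
                m = (f > 0.3) & (f < 1.2)
                best = max(best, coh[m].max())
            if best > 0.8:
                found += 1
        assert found >= len(truth.artefacts["respiration"]) * 0.8

    def test_pulse_artefact_locked_to_r_peaks(self, record):
        # the artefact is a spike train at the R-peak times: a template
        # built from the ECG R-peaks must correlate with some channel
        cfg, rec, truth = record
        fs = cfg.sampling_rate
        assert truth.artefacts["pulse"]
        ecg = rec.aux["ECG"]
        r_peaks, _ = sps.find_peaks(ecg, height=0.5 * ecg.max(),
                                    distance=int(0.25 * fs))
        width = int(0.05 * fs)
        kern = np.exp(-0.5 * (np.arange(-3 * width, 3 * width + 1) / width) ** 2)
        for a, b in truth.artefacts["pulse"]:
            i, j = int(a * fs), int(b * fs)
            train = np.zeros(j - i)
            for pk in r_peaks[(r_peaks >= i) & (r_peaks < j)]:
                lo = max(0, pk - i - 3 * width)
                hi = min(j - i, pk - i + 3 * width + 1)
                train[lo:hi] += kern[(lo - (pk - i) + 3 * width):
                                     (hi - (pk - i) + 3 * width)]
            best = max(
                np.corrcoef(rec.data[ch, i:j], train)[0, 1]
                for ch in range(rec.n_channels)
            )
            assert best >= 0.4

    def test_sweat_artefact_slow_and_high_amplitude(self, record):
        cfg, rec, truth = record
        fs = cfg.sampling_rate
        assert truth.artefacts["sweat"]
        sos = sps.butter(4, 0.5, fs=fs, output="sos")
        for a, b in truth.artefacts["sweat"]:
            i, j = int(a * fs), int(b * fs)
            fracs, slow_amp = [], []
            for ch in range(rec.n_channels):
                f, p = sps.periodogram(rec.data[ch, i:j], fs=fs)
                fracs.append(p[f < 0.5].sum() / p.sum())
                slow_amp.append(
                    np.abs(sps.sosfiltfilt(sos, rec.data[ch, i:j])).max()
                )
            # on an affected channel, >= 90 % of power below 0.5 Hz and
            # a high-amplitude slow wave (well above the ~30 uV background)
            assert max(fracs) >= 0.9
            assert max(slow_amp) >= 150.0

    def test_nonseizure_record_has_no_events(self):
        cfg = SimConfig(duration_s=600.0, seizure_baby=False)
        _, truth = simulate_record(cfg, np.random.default_rng(3))
        assert len(truth.events) == 0


class TestCohort:
    def test_files_and_determinism(self, tmp_path):
        cfg = SimConfig(duration_s=60.0)
        m1 = simulate_cohort(2, 1, cfg, seed=7, outdir=tmp_path / "a")
        assert sorted(p.name for p in (tmp_path / "a").glob("*.edf")) == [
            "ns00.edf", "sz00.edf", "sz01.edf"
        ]
        assert (tmp_path / "a" / "ns00.txt").read_text() == ""
        simulate_cohort(2, 1, cfg, seed=7, outdir=tmp_path / "b")
        for name in ("sz00.txt", "sz01.txt", "ns00.txt", "manifest.csv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes()

    def test_annotations_roundtrip_ground_truth(self, tmp_path):
        cfg = SimConfig(duration_s=120.0)
        manifest = simulate_cohort(1, 0, cfg, seed=3, outdir=tmp_path)
        entry = manifest[0]
        loaded = read_annotation_file(
            tmp_path / "sz00.txt", entry["record"].duration
        )
        for got, truth in zip(loaded, entry["truth"].events):
            assert got.onset == pytest.approx(truth.onset, abs=1e-3)
            assert got.offset == pytest.approx(truth.offset, abs=1e-3)

    def test_overwrite_refused(self, tmp_path):
        cfg = SimConfig(duration_s=120.0)
        simulate_cohort(1, 0, cfg, seed=3, outdir=tmp_path)
        with pytest.raises(FileExistsError):
            simulate_cohort(1, 0, cfg, seed=3, outdir=tmp_path)

    def test_median_duration_matches_lognormal_target(self):
        from neoseiz.synthetic import _sample_seizure_events

        cfg = SimConfig(duration_s=36000.0, mean_seizures_per_record=1.0)
        rng = np.random.default_rng(77)
        durations = []
        while len(durations) < 200:
            for ev in _sample_seizure_events(cfg, rng):
                durations.append(ev.duration)
        med = float(np.median(durations[:200]))
        assert 95.0 <= med <= 135.0
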