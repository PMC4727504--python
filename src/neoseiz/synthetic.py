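"""Seeded synthetic neonatal EEG cohorts with ground-truth annotations.

The simulator produces multi-channel records that carry the statistical
signatures the detector relies on, without claiming physiological realism:

* background — spatially correlated 1/f^alpha noise (alpha = 1.5, RMS
  ~30 µV) plus a 0.5–3 Hz rhythmic delta component whose amplitude is
  modulated with the sleep-cycle period, emulating the raised delta
  rhythmicity of intermediate/quiet sleep;
* seizures — focal, evolving spike-wave discharges: a harmonic-rich carrier
  whose instantaneous frequency moves linearly from ``f_start`` to
  ``f_end`` under a ramp–plateau–ramp envelope, 2–4 x background amplitude,
  with log-normal durations whose median defaults to 115 s (a typical
  neonatal cohort median) truncated at the 10 s electrographic minimum;
* artefacts — respiration-locked rhythmic waves (phase-locked to the
  simulated respiration trace), pulse spikes aligned to simulated ECG
  R-peaks, and high-amplitude (< 0.5 Hz, > 200 µV) semi-rhythmic sweat
  waves; every artefact interval is logged as ground truth.

All randomness flows from a single ``numpy`` seed; regenerating a cohort
with the same seed reproduces every file byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as sp_signal

from .io import (
    EEGRecord,
    REQUIRED_CHANNELS,
    SeizureEvent,
    SeizureEventList,
    write_annotation_file,
    write_edf,
    write_sidecar,
)

MIN_SEIZURE_S = 10.0


@dataclass
class SimConfig:
    """Study conditions for one simulated record."""

    duration_s: float = 3600.0
    sampling_rate: float = 256.0
    channel_labels: tuple[str, ...] = REQUIRED_CHANNELS
    seizure_baby: bool = True
    # seizure process
    mean_seizures_per_record: float = 4.0      # Poisson mean, min 1 enforced
    seizure_median_duration_s: float = 115.0   # log-normal median
    seizure_duration_sigma: float = 0.7        # log-normal shape
    seizure_freq_start_hz: tuple[float, float] = (1.5, 3.5)  # sampled uniform
    seizure_freq_decay: tuple[float, float] = (0.4, 0.7)     # f_end/f_start
    seizure_amplitude_factor: tuple[float, float] = (2.0, 4.0)  # x background
    # background
    background_rms_uv: float = 30.0
    noise_exponent: float = 1.5                # 1/f^alpha
    interchannel_corr: float = 0.5
    sleep_cycle_s: float = 3000.0
    delta_mod_depth: float = 0.8
    delta_rhythm_factor: float = 0.3   # extra narrowband delta / intrinsic delta RMS
    # artefacts (events per hour; None disables a class)
    respiration_rate_per_h: float = 2.0
    pulse_rate_per_h: float = 2.0
    sweat_rate_per_h: float = 1.0
    respiration_freq_hz: float = 0.65
    heart_rate_hz: float = 2.3                 # ~138 bpm
    # metadata
    start_age_h: float = 12.0


@dataclass
class GroundTruth:
    """Everything the simulator knows about a generated record."""

    events: SeizureEventList
    artefacts: dict[str, list[tuple[float, float]]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Background
# ---------------------------------------------------------------------------

def _powerlaw_noise(rng: np.random.Generator, shape: tuple[int, int],
                    alpha: float, fs: float) -> np.ndarray:
    """Gaussian noise with a 1/f^alpha power spectrum, unit RMS per row."""
    n_rows, n = shape
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-alpha / 2.0)
    spec = (
        rng.normal(size=(n_rows, len(freqs)))
        + 1j * rng.normal(size=(n_rows, len(freqs)))
    ) * scale
    x = np.fft.irfft(spec, n=n, axis=-1)
    rms = x.std(axis=-1, keepdims=True)
    return x / np.where(rms > 0, rms, 1.0)


def _respiration_trace(rng, n, fs, freq_hz) -> np.ndarray:
    # slow sinusoid with gentle frequency wander
    drift = sp_signal.sosfiltfilt(
        sp_signal.butter(2, 0.01, fs=fs, output="sos"),
        rng.normal(0, 1, n),
    )
    drift = 0.1 * drift / max(drift.std(), 1e-12)
    inst = np.clip(freq_hz * (1 + drift), 0.3, 1.2)
    phase = 2 * np.pi * np.cumsum(inst) / fs
    return np.sin(phase)


def _ecg_trace(rng, n, fs, heart_rate_hz) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic ECG-like trace plus the R-peak sample times (seconds)."""
    t, peaks = 0.0, []
    while t < n / fs:
        peaks.append(t)
        rr = 1.0 / heart_rate_hz * (1 + rng.normal(0, 0.04))
        t += max(rr, 0.25)
    trace = np.zeros(n)
    width = int(0.03 * fs)
    kernel = np.exp(-0.5 * (np.arange(-3 * width, 3 * width + 1) / width) ** 2)
    for pk in peaks:
        i = int(pk * fs)
        a, b = max(0, i - 3 * width), min(n, i + 3 * width + 1)
        trace[a:b] += kernel[(a - i + 3 * width):(b - i + 3 * width)]
    return trace, np.asarray(peaks)


def simulate_background(config: SimConfig, rng: np.random.Generator) -> EEGRecord:
    """Background EEG: correlated 1/f^alpha noise whose delta band (0.5-3 Hz,
    augmented by a narrowband rhythmic component) is amplitude-modulated
    with the sleep-cycle period; respiration and ECG auxiliaries attached.

    The modulation has unit mean, so the time-averaged spectrum stays close
    to the configured power law."""
    fs = config.sampling_rate
    n = int(round(config.duration_s * fs))
    n_ch = len(config.channel_labels)

    common = _powerlaw_noise(rng, (1, n), config.noise_exponent, fs)
    indiv = _powerlaw_noise(rng, (n_ch, n), config.noise_exponent, fs)
    rho = config.interchannel_corr
    broadband = np.sqrt(rho) * common + np.sqrt(1 - rho) * indiv

    # split off the intrinsic delta band and add extra rhythmic delta
    sos = sp_signal.butter(4, [0.5, 3.0], btype="bandpass", fs=fs, output="sos")
    delta = sp_signal.sosfiltfilt(sos, broadband, axis=-1)
    rest = broadband - delta
    narrow = sp_signal.sosfiltfilt(
        sp_signal.butter(4, [1.0, 3.0], btype="bandpass", fs=fs, output="sos"),
        rng.normal(0, 1, (n_ch, n)),
        axis=-1,
    )
    narrow /= np.maximum(narrow.std(axis=-1, keepdims=True), 1e-12)
    narrow *= config.delta_rhythm_factor * delta.std(axis=-1, keepdims=True)

    t = np.arange(n) / fs
    phase0 = rng.uniform(0, 2 * np.pi)
    mod = 1.0 + config.delta_mod_depth * np.sin(
        2 * np.pi * t / config.sleep_cycle_s + phase0
    )
    data = rest + mod[None, :] * (delta + narrow)
    data *= config.background_rms_uv / data.std(axis=-1, keepdims=True)

    resp = _respiration_trace(rng, n, fs, config.respiration_freq_hz)
    ecg, _ = _ecg_trace(rng, n, fs, config.heart_rate_hz)
    return EEGRecord(
        channel_labels=list(config.channel_labels),
        sampling_rate=fs,
        data=data,
        aux={"Resp": resp * 100.0, "ECG": ecg * 100.0},
        start_age=config.start_age_h,
    )


# ---------------------------------------------------------------------------
# Seizures
# ---------------------------------------------------------------------------

_CARRIER_HARMONICS = (1.0, 0.4, 0.2)
_RAMP_FRACTION = 0.15


def simulate_seizure(
    duration_s: float,
    f_start_hz: float,
    f_end_hz: float,
    amplitude_uv: float,
    fs: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One evolving rhythmic discharge as a waveform of ``duration * fs``
    samples: harmonic spike-wave carrier with linearly falling instantaneous
    frequency under a ramp-plateau-ramp envelope (zero at both ends)."""
    if duration_s < MIN_SEIZURE_S:
        raise ValueError(f"seizure duration must be >= {MIN_SEIZURE_S} s")
    if not (0.5 <= f_end_hz <= f_start_hz <= 13.0):
        raise ValueError("need 0.5 <= f_end <= f_start <= 13 Hz")
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    inst = f_start_hz + (f_end_hz - f_start_hz) * t / duration_s
    phase = 2 * np.pi * np.cumsum(inst) / fs
    if rng is not None:
        phase += rng.uniform(0, 2 * np.pi)
    carrier = sum(a * np.sin((k + 1) * phase)
                  for k, a in enumerate(_CARRIER_HARMONICS))
    carrier /= np.max(np.abs(carrier))

    ramp = max(int(_RAMP_FRACTION * n), 1)
    env = np.ones(n)
    env[:ramp] = np.linspace(0.0, 1.0, ramp, endpoint=False)
    env[n - ramp:] = np.linspace(1.0, 0.0, ramp)
    return amplitude_uv * env * carrier


def _sample_seizure_events(config: SimConfig, rng) -> list[SeizureEvent]:
    if config.duration_s < 3 * MIN_SEIZURE_S:
        raise ValueError("seizure records must last at least 30 s")
    n_seiz = max(1, int(rng.poisson(config.mean_seizures_per_record)))
    mu = np.log(config.seizure_median_duration_s)
    durations = []
    while len(durations) < n_seiz:
        d = float(np.exp(rng.normal(mu, config.seizure_duration_sigma)))
        if MIN_SEIZURE_S <= d <= config.duration_s / 3:
            durations.append(d)
    # random non-overlapping placement with >= 30 s gaps
    events: list[SeizureEvent] = []
    for d in sorted(durations, reverse=True):
        for _ in range(200):
            onset = float(rng.uniform(10.0, config.duration_s - d - 10.0))
            if all(
                onset + d + 30.0 < ev.onset or ev.offset + 30.0 < onset
                for ev in events
            ):
                events.append(SeizureEvent(onset, onset + d))
                break
    return sorted(events, key=lambda e: e.onset)


def _channel_weights(n_ch: int, rng) -> np.ndarray:
    focus = rng.integers(n_ch)
    dist = np.abs(np.arange(n_ch) - focus)
    return np.clip(np.exp(-dist / 2.5), 0.3, 1.0)


def inject_seizures(
    rec: EEGRecord, config: SimConfig, rng: np.random.Generator
) -> SeizureEventList:
    """Add evolving focal discharges on top of the background, in place."""
    fs = rec.sampling_rate
    bg_rms = float(np.median(rec.data.std(axis=-1)))
    events = _sample_seizure_events(config, rng)
    for ev in events:
        f_start = rng.uniform(*config.seizure_freq_start_hz)
        f_end = max(0.5, f_start * rng.uniform(*config.seizure_freq_decay))
        amp = bg_rms * rng.uniform(*config.seizure_amplitude_factor)
        wave = simulate_seizure(ev.duration, f_start, f_end, amp, fs, rng)
        weights = _channel_weights(rec.n_channels, rng)
        a = int(round(ev.onset * fs))
        b = a + len(wave)
        rec.data[:, a:b] += weights[:, None] * wave[None, :]
    return SeizureEventList(events, rec.duration)


# ---------------------------------------------------------------------------
# Artefacts
# ---------------------------------------------------------------------------

def _artefact_intervals(rate_per_h, dur_range, config, rng, forbidden):
    n_art = int(rng.poisson(rate_per_h * config.duration_s / 3600.0))
    out = []
    for _ in range(n_art):
        d = float(rng.uniform(*dur_range))
        for _ in range(100):
            onset = float(rng.uniform(0.0, config.duration_s - d))
            if all(onset + d < a or b < onset for a, b in forbidden):
                out.append((onset, onset + d))
                break
    return sorted(out)


def _taper(n: int) -> np.ndarray:
    return sp_signal.windows.tukey(n, alpha=0.2)


def inject_artefacts(
    rec: EEGRecord, config: SimConfig, rng: np.random.Generator,
    avoid: SeizureEventList | None = None,
) -> dict[str, list[tuple[float, float]]]:
    """Add respiration, pulse and sweat artefacts in place; returns the
    logged intervals per class.  Requires the aux respiration/ECG traces.

    Artefact placement avoids ground-truth seizure intervals so artefact
    epochs carry unambiguous non-seizure labels.
    """
    for name in ("Resp", "ECG"):
        if name not in rec.aux:
            raise ValueError(f"auxiliary trace {name!r} missing")
    fs = rec.sampling_rate
    bg_rms = float(np.median(rec.data.std(axis=-1)))
    forbidden = [(ev.onset, ev.offset) for ev in (avoid or [])]
    log: dict[str, list[tuple[float, float]]] = {}

    # respiration: rhythmic wave phase-locked to the respiration trace
    resp_sig = rec.aux["Resp"] / max(np.abs(rec.aux["Resp"]).max(), 1e-12)
    intervals = _artefact_intervals(
        config.respiration_rate_per_h, (20.0, 60.0), config, rng, forbidden
    )
    channels = rng.choice(rec.n_channels, size=min(3, rec.n_channels),
                          replace=False)
    for a, b in intervals:
        i, j = int(a * fs), int(b * fs)
        seg = resp_sig[i:j] * _taper(j - i) * 1.8 * bg_rms
        rec.data[channels, i:j] += seg[None, :]
    log["respiration"] = intervals

    # pulse: spikes aligned to ECG R-peaks
    ecg = rec.aux["ECG"]
    peak_idx, _ = sp_signal.find_peaks(ecg, height=0.5 * ecg.max(),
                                       distance=int(0.25 * fs))
    intervals = _artefact_intervals(
        config.pulse_rate_per_h, (20.0, 60.0), config, rng, forbidden
    )
    width = int(0.05 * fs)
    kernel = np.exp(-0.5 * (np.arange(-3 * width, 3 * width + 1) / width) ** 2)
    ch = int(rng.integers(rec.n_channels))
    for a, b in intervals:
        i, j = int(a * fs), int(b * fs)
        spike_train = np.zeros(j - i)
        for pk in peak_idx[(peak_idx >= i) & (peak_idx < j)]:
            lo, hi = max(0, pk - i - 3 * width), min(j - i, pk - i + 3 * width + 1)
            spike_train[lo:hi] += kernel[(lo - (pk - i) + 3 * width):
                                         (hi - (pk - i) + 3 * width)]
        rec.data[ch, i:j] += spike_train * _taper(j - i) * 2.0 * bg_rms
    log["pulse"] = intervals

    # sweat: high-amplitude semi-rhythmic < 0.5 Hz waves
    intervals = _artefact_intervals(
        config.sweat_rate_per_h, (30.0, 90.0), config, rng, forbidden
    )
    sos = sp_signal.butter(4, 0.45, fs=fs, output="sos")
    channels = rng.choice(rec.n_channels, size=min(4, rec.n_channels),
                          replace=False)
    for a, b in intervals:
        i, j = int(a * fs), int(b * fs)
        slow = sp_signal.sosfiltfilt(sos, rng.normal(0, 1, (len(channels), j - i)),
                                     axis=-1)
        slow /= np.maximum(np.abs(slow).max(axis=-1, keepdims=True), 1e-12)
        rec.data[channels, i:j] += slow * _taper(j - i)[None, :] * 250.0
    log["sweat"] = intervals

    return log


# ---------------------------------------------------------------------------
# Records and cohorts
# ---------------------------------------------------------------------------

def simulate_record(
    config: SimConfig, rng: np.random.Generator
) -> tuple[EEGRecord, GroundTruth]:
    """One complete record: background, seizures (if a seizure baby) and
    artefacts, with full ground truth."""
    rec = simulate_background(config, rng)
    if config.seizure_baby:
        events = inject_seizures(rec, config, rng)
    else:
        events = SeizureEventList([], rec.duration)
    artefacts = inject_artefacts(rec, config, rng, avoid=events)
    return rec, GroundTruth(events, artefacts)


def simulate_cohort(
    n_seizure: int,
    n_nonseizure: int,
    config: SimConfig,
    seed: int,
    outdir: str | Path | None = None,
) -> list[dict]:
    """Generate a cohort of seizure and non-seizure babies.

    Returns one manifest entry per record (id, paths, ground truth).  When
    ``outdir`` is given, writes per record: EDF, annotation text file, YAML
    sidecar (postnatal age, AED times) and a cohort ``manifest.csv``;
    existing files raise rather than being overwritten.
    """
    if n_seizure < 0 or n_nonseizure < 0 or n_seizure + n_nonseizure < 1:
        raise ValueError("need at least one record")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_seizure + n_nonseizure)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)

    manifest = []
    for i, child in enumerate(children):
        is_seizure = i < n_seizure
        rec_id = f"sz{i:02d}" if is_seizure else f"ns{i - n_seizure:02d}"
        rng = np.random.default_rng(child)
        cfg = replace(
            config,
            seizure_baby=is_seizure,
            start_age_h=float(np.round(rng.uniform(8.0, 24.0), 2)),
        )
        rec, truth = simulate_record(cfg, rng)

        # simulated dosing: one dose shortly after a seizure (concurrent)
        # and possibly one far from any seizure (non-concurrent)
        aed_times = []
        if is_seizure and len(truth.events) > 0:
            first = truth.events.events[0]
            aed_times.append(cfg.start_age_h + (first.offset + 600.0) / 3600.0)

        entry = {
            "record_id": rec_id,
            "seizure_baby": is_seizure,
            "start_age_h": cfg.start_age_h,
            "duration_s": rec.duration,
            "n_seizures": len(truth.events),
            "record": rec,
            "truth": truth,
            "aed_times_h": aed_times,
        }
        if outdir is not None:
            edf_path = outdir / f"{rec_id}.edf"
            if edf_path.exists():
                raise FileExistsError(f"refusing to overwrite {edf_path}")
            write_edf(rec, edf_path)
            write_annotation_file(truth.events, outdir / f"{rec_id}.txt")
            write_sidecar(
                outdir / f"{rec_id}.yaml",
                start_age_h=cfg.start_age_h,
                aed_times_h=aed_times,
                seizure_baby=is_seizure,
            )
            entry["edf_path"] = str(edf_path)
            entry["annotation_path"] = str(outdir / f"{rec_id}.txt")
        manifest.append(entry)

    if outdir is not None:
        import csv

        with open(outdir / "manifest.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["record_id", "seizure_baby", "start_age_h",
                        "duration_s", "n_seizures", "edf", "annotation"])
            for e in manifest:
                w.writerow([e["record_id"], int(e["seizure_baby"]),
                            e["start_age_h"], e["duration_s"], e["n_seizures"],
                            f"{e['record_id']}.edf", f"{e['record_id']}.txt"])
    return manifest
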