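"""EEG recording and annotation I/O, preprocessing and epoching.

The detection pipeline works on multi-channel scalp EEG from term neonates,
recorded from the nine-electrode reduced 10:20 montage (F4, F3, T4, T3, C4,
C3, CZ, O2, O1) at 250 or 256 Hz.  Before feature extraction the EEG is
down-sampled to 32 Hz behind a 12.8 Hz anti-aliasing filter and cut into
8 s epochs with 50 % overlap.

Seizure annotations (expert or algorithmic) are stored as plain-text event
files: one ``onset<TAB>offset`` pair of seconds per line, ``#`` comments
allowed.  Intervals are half-open ``[onset, offset)``, 0-based from record
start, so 1 Hz binarisation is exact.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import signal as sp_signal

#: Canonical neonatal reduced-montage electrode labels, in detection order.
REQUIRED_CHANNELS = ("F4", "F3", "T4", "T3", "C4", "C3", "CZ", "O2", "O1")

#: Auxiliary (non-EEG) trace labels recognised on load.
AUX_CHANNELS = ("Resp", "ECG")

#: Working sampling rate of the detector, Hz.
WORKING_RATE = 32.0

#: Anti-aliasing cutoff, Hz (0.4 x working Nyquist band of 32 Hz).
ANTIALIAS_CUTOFF = 12.8

EPOCH_LENGTH_S = 8.0
EPOCH_HOP_S = 4.0


class ChannelError(ValueError):
    """A required channel is absent or channels are mutually inconsistent."""


class AnnotationError(ValueError):
    """A seizure annotation file violates the onset/offset contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class EEGRecord:
    """A multi-channel EEG recording with optional auxiliary traces.

    Parameters
    ----------
    channel_labels
        Electrode names, one per row of ``data``.
    sampling_rate
        Sampling rate in Hz (identical for all channels).
    data
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    aux
        Optional auxiliary traces (respiration, ECG) time-aligned with the
        EEG and sampled at the same rate.
    start_age
        Postnatal age at record start, hours.
    """

    channel_labels: list[str]
    sampling_rate: float
    data: np.ndarray
    aux: dict[str, np.ndarray] = field(default_factory=dict)
    start_age: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must match data rows")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        for name, trace in self.aux.items():
            if len(trace) != self.n_samples:
                raise ValueError(f"aux trace {name!r} not aligned with EEG")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return self.n_samples / self.sampling_rate


@dataclass(frozen=True)
class SeizureEvent:
    """Half-open seizure interval ``[onset, offset)`` in seconds."""

    onset: float
    offset: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise ValueError(
                f"event offset ({self.offset}) must exceed onset ({self.onset})"
            )

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    def intersects(self, other: "SeizureEvent") -> bool:
        return self.onset < other.offset and other.onset < self.offset


@dataclass
class SeizureEventList:
    """Ordered, non-overlapping seizure events for one recording.

    Events are sorted by onset and overlapping/abutting raw intervals are
    merged on construction, because the downstream binary agreement model is
    insensitive to sub-event structure.
    """

    events: list[SeizureEvent]
    record_duration: float

    def __post_init__(self) -> None:
        if self.record_duration <= 0:
            raise ValueError("record_duration must be positive")
        self.events = self._normalise(self.events)

    def _normalise(self, events: list[SeizureEvent]) -> list[SeizureEvent]:
        clipped = []
        for ev in sorted(events, key=lambda e: (e.onset, e.offset)):
            onset = max(0.0, ev.onset)
            offset = min(float(self.record_duration), ev.offset)
            if offset > onset:
                clipped.append(SeizureEvent(onset, offset, ev.label))
        merged: list[SeizureEvent] = []
        for ev in clipped:
            if merged and ev.onset <= merged[-1].offset:
                prev = merged.pop()
                merged.append(
                    SeizureEvent(prev.onset, max(prev.offset, ev.offset), prev.label)
                )
            else:
                merged.append(ev)
        return merged

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SeizureEventList):
            return NotImplemented
        return (
            self.record_duration == other.record_duration
            and [(e.onset, e.offset) for e in self.events]
            == [(e.onset, e.offset) for e in other.events]
        )

    @property
    def total_duration(self) -> float:
        """Total seconds spent in seizure."""
        return sum(e.duration for e in self.events)


@dataclass(frozen=True)
class EpochGrid:
    """Placement of overlapping analysis epochs on a record."""

    epoch_length: float
    hop: float
    epoch_starts: np.ndarray
    samples_per_epoch: int

    @property
    def n_epochs(self) -> int:
        return len(self.epoch_starts)


# ---------------------------------------------------------------------------
# EDF writing (minimal EDF, identical-rate channels, 1 s data records)
# ---------------------------------------------------------------------------

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def _fmt8(x: float) -> str:
    """Format a float into at most 8 ASCII characters without truncation."""
    for prec in range(6, 0, -1):
        s = f"{x:.{prec}g}"
        if len(s) <= 8:
            return s
    return f"{x:.0e}"[:8]


def write_edf(rec: EEGRecord, path: str | Path) -> None:
    """Write an :class:`EEGRecord` (plus aux traces) as a minimal EDF file.

    All signals are stored at the EEG sampling rate with 1 s data records
    and per-channel physical scaling; the record is truncated to a whole
    number of seconds (EDF data records are fixed-duration).
    """
    path = Path(path)
    fs = rec.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    labels = list(rec.channel_labels) + list(rec.aux.keys())
    traces = [np.asarray(rec.data[i], dtype=float) for i in range(rec.n_channels)]
    traces += [np.asarray(rec.aux[k], dtype=float) for k in rec.aux]
    n_records = min(len(t) for t in traces) // fs
    if n_records < 1:
        raise ValueError("record shorter than one EDF data record (1 s)")
    ns = len(labels)

    phys_min, phys_max, scaled = [], [], []
    for t in traces:
        t = t[: n_records * fs]
        amax = float(np.max(np.abs(t))) if t.size else 0.0
        amax = amax * 1.0001 if amax > 0 else 1.0
        amax = float(_fmt8(amax))  # scale with the value the header stores
        phys_min.append(-amax)
        phys_max.append(amax)
        dig = np.clip(np.round(t / amax * 32767.0), -32768, 32767).astype("<i2")
        scaled.append(dig)

    header = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),  # patient id (anonymised)
            _pad("Startdate X X X X", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(256 + ns * 256), 8),
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad("1", 8),
            _pad(str(ns), 4),
        ]
    )
    sig_header = b"".join(
        [
            b"".join(_pad(lb, 16) for lb in labels),
            b"".join(_pad("", 80) for _ in labels),
            b"".join(_pad("uV", 8) for _ in labels),
            b"".join(_pad(_fmt8(phys_min[i]), 8) for i in range(ns)),
            b"".join(_pad(_fmt8(phys_max[i]), 8) for i in range(ns)),
            b"".join(_pad("-32768", 8) for _ in labels),
            b"".join(_pad("32767", 8) for _ in labels),
            b"".join(_pad("", 80) for _ in labels),
            b"".join(_pad(str(fs), 8) for _ in labels),
            b"".join(_pad("", 32) for _ in labels),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_records):
            for dig in scaled:
                fh.write(dig[r * fs : (r + 1) * fs].tobytes())


def _edf_samples_per_record(path: Path) -> dict[str, int]:
    """Peek the EDF header for each signal's samples-per-record field."""
    with open(path, "rb") as fh:
        hdr = fh.read(256)
        ns = int(hdr[252:256].decode("ascii").strip())
        sig = fh.read(ns * 256)
    labels = [
        sig[i * 16 : (i + 1) * 16].decode("ascii", "replace").strip()
        for i in range(ns)
    ]
    off = ns * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
    nsamp = [
        int(sig[off + i * 8 : off + (i + 1) * 8].decode("ascii").strip())
        for i in range(ns)
    ]
    return dict(zip(labels, nsamp))


def read_recording(
    path: str | Path,
    required_channels: tuple[str, ...] | list[str] = REQUIRED_CHANNELS,
) -> EEGRecord:
    """Read an EDF recording, returning required channels in canonical order.

    Extra EEG channels are retained after the required set; auxiliary
    respiration/ECG traces are attached as ``aux``.  Metadata (postnatal age
    at record start) is read from a ``<stem>.yaml`` sidecar when present.

    Raises
    ------
    ChannelError
        If a required channel is missing (the error names the absent
        labels) or if channels are stored at unequal sampling rates.
    """
    import mne

    path = Path(path)
    per_signal = _edf_samples_per_record(path)
    eeg_rates = {
        n for lb, n in per_signal.items() if lb not in AUX_CHANNELS
    }
    if len(eeg_rates) > 1:
        raise ChannelError(
            f"unequal channel sampling rates in {path.name}: "
            f"{sorted(per_signal.items())}"
        )

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    available = list(raw.ch_names)
    missing = [ch for ch in required_channels if ch not in available]
    if missing:
        raise ChannelError(f"missing required channels: {', '.join(missing)}")

    aux = {}
    for name in AUX_CHANNELS:
        if name in available:
            aux[name] = raw.get_data(picks=[name])[0] * 1e6

    eeg_labels = [ch for ch in required_channels if ch in available]
    eeg_labels += [
        ch for ch in available if ch not in eeg_labels and ch not in AUX_CHANNELS
    ]
    data = raw.get_data(picks=eeg_labels) * 1e6  # mne returns volts

    start_age = 0.0
    sidecar = path.with_suffix(".yaml")
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
        start_age = float(meta.get("start_age_h", 0.0))

    return EEGRecord(
        channel_labels=list(eeg_labels),
        sampling_rate=float(raw.info["sfreq"]),
        data=data,
        aux=aux,
        start_age=start_age,
    )


def write_sidecar(
    path: str | Path,
    start_age_h: float,
    aed_times_h: list[float] | None = None,
    **extra,
) -> None:
    """Write the per-record YAML metadata sidecar."""
    meta = {"start_age_h": float(start_age_h)}
    if aed_times_h is not None:
        meta["aed_times_h"] = [float(t) for t in aed_times_h]
    meta.update(extra)
    Path(path).write_text(yaml.safe_dump(meta, sort_keys=True))


def read_sidecar(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}


# ---------------------------------------------------------------------------
# Annotation text files
# ---------------------------------------------------------------------------

def read_annotation_file(path: str | Path, record_duration: float) -> SeizureEventList:
    """Parse a seizure annotation text file.

    Each non-comment line is ``onset_s<TAB>offset_s``; events are sorted,
    overlaps merged and intervals clipped to ``[0, record_duration]``.
    """
    events = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise AnnotationError(
                f"{path}:{lineno}: expected 'onset<TAB>offset', got {line!r}"
            )
        try:
            onset, offset = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise AnnotationError(f"{path}:{lineno}: non-numeric field") from exc
        if offset <= onset:
            raise AnnotationError(
                f"{path}:{lineno}: offset ({offset}) must exceed onset ({onset})"
            )
        events.append(SeizureEvent(onset, offset))
    return SeizureEventList(events, record_duration)


def write_annotation_file(events: SeizureEventList, path: str | Path) -> None:
    """Write events as onset/offset text, millisecond precision; round-trips
    exactly through :func:`read_annotation_file`."""
    lines = [f"{ev.onset:.3f}\t{ev.offset:.3f}" for ev in events]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Preprocessing and epoching
# ---------------------------------------------------------------------------

def _antialias_sos(input_rate: float):
    # Zero-phase order-8 Butterworth low-pass at 12.8 Hz: squared magnitude
    # keeps <10 Hz within 2 % and attenuates >=15 Hz by >20 dB.
    return sp_signal.butter(8, ANTIALIAS_CUTOFF, fs=input_rate, output="sos")


def preprocess(rec: EEGRecord) -> EEGRecord:
    """Down-sample an EEG record to the 32 Hz working rate.

    Applies a zero-phase (forward-backward) order-8 Butterworth low-pass at
    12.8 Hz, then decimates.  256 Hz input is decimated by stride 8; other
    rates (e.g. 250 Hz) go through polyphase rational resampling.  Auxiliary
    traces are resampled the same way so they stay time-aligned.

    Raises
    ------
    ValueError
        If the input rate is below 64 Hz.
    """
    fs = rec.sampling_rate
    if fs != WORKING_RATE and fs < 64:
        raise ValueError(f"input rate {fs} Hz too low; need >= 64 Hz")
    if fs == WORKING_RATE:
        # Working-rate input: just re-apply the zero-phase anti-alias filter
        # (idempotent in practice because the band above 12.8 Hz is empty).
        sos = _antialias_sos(fs)
        data = sp_signal.sosfiltfilt(sos, rec.data, axis=1)
        aux = {k: sp_signal.sosfiltfilt(sos, v) for k, v in rec.aux.items()}
        return EEGRecord(list(rec.channel_labels), WORKING_RATE, data, aux,
                         rec.start_age)

    sos = _antialias_sos(fs)
    filtered = sp_signal.sosfiltfilt(sos, rec.data, axis=1)
    aux_filtered = {k: sp_signal.sosfiltfilt(sos, v) for k, v in rec.aux.items()}

    ratio = fs / WORKING_RATE
    if abs(ratio - round(ratio)) < 1e-9:
        step = int(round(ratio))
        data = filtered[:, ::step]
        aux = {k: v[::step] for k, v in aux_filtered.items()}
    else:
        from fractions import Fraction

        frac = Fraction(int(round(WORKING_RATE * 1000)), int(round(fs * 1000)))
        up, down = frac.numerator, frac.denominator
        data = sp_signal.resample_poly(filtered, up, down, axis=1)
        aux = {k: sp_signal.resample_poly(v, up, down) for k, v in aux_filtered.items()}

    return EEGRecord(list(rec.channel_labels), WORKING_RATE, data, aux,
                     rec.start_age)


def make_epochs(rec: EEGRecord) -> tuple[EpochGrid, np.ndarray]:
    """Cut a 32 Hz record into 8 s epochs with 50 % overlap.

    Returns the :class:`EpochGrid` and a block array of shape
    ``(n_epochs, n_channels, 256)``.  Epoch ``k`` starts at ``4 k`` seconds;
    the last epoch must fit entirely inside the record.
    """
    if rec.sampling_rate != WORKING_RATE:
        raise ValueError("make_epochs expects a 32 Hz (preprocessed) record")
    samples_per_epoch = int(EPOCH_LENGTH_S * WORKING_RATE)
    hop_samples = int(EPOCH_HOP_S * WORKING_RATE)
    if rec.n_samples < samples_per_epoch:
        raise ValueError(
            f"record too short: {rec.duration:.2f} s < {EPOCH_LENGTH_S} s"
        )
    n_epochs = (rec.n_samples - samples_per_epoch) // hop_samples + 1
    starts = np.arange(n_epochs) * EPOCH_HOP_S
    idx = np.arange(n_epochs)[:, None] * hop_samples + np.arange(samples_per_epoch)
    blocks = rec.data[:, idx].transpose(1, 0, 2)  # epochs x channels x samples
    grid = EpochGrid(
        epoch_length=EPOCH_LENGTH_S,
        hop=EPOCH_HOP_S,
        epoch_starts=starts,
        samples_per_epoch=samples_per_epoch,
    )
    return grid, blocks
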