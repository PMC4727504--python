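"""The 55-feature epoch descriptor used by the seizure detector.

Every 8 s epoch (256 samples at 32 Hz) of every channel is summarised by 55
real features spanning three families:

* 28 frequency-domain features — total spectral power over 0–12 Hz, peak
  frequency, spectral edge frequencies (80/90/95 %), power in eleven
  overlapping 2 Hz sub-bands (0–2, 1–3, …, 10–12 Hz), the same sub-band
  powers normalised by total power, and the Daubechies-4 wavelet energy of
  the detail band spanning 1–2 Hz (the 5th of the 8 coefficient arrays of a
  level-7 decomposition).
* 23 time-domain features — curve length, number of local extrema, RMS
  amplitude, the three Hjorth parameters (activity, mobility, complexity),
  zero crossings of the raw epoch and its first and second differences,
  autoregressive modelling error for model orders 1–9 (Yule–Walker /
  Levinson–Durbin), skewness, kurtosis, nonlinear (Teager) energy, and the
  variances of the first and second differences.
* 4 information-theory features — Shannon entropy of a 10-bin amplitude
  histogram, singular-value-decomposition entropy and Fisher information of
  a delay embedding (m = 10, lag 1), and normalised spectral entropy.

Spectra are periodograms of the Hamming-windowed epoch.  Constant
(degenerate) epochs are flagged and ratio-based features are set to zero
instead of dividing by zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sp_signal

from .io import EEGRecord, EpochGrid, make_epochs

FS = 32.0
EPOCH_SAMPLES = 256
_SUBBAND_EDGES = [(lo, lo + 2) for lo in range(11)]  # 0-2, 1-3, ..., 10-12 Hz

FREQUENCY_FEATURES = (
    ["total_power", "peak_frequency", "sef80", "sef90", "sef95"]
    + [f"bandpower_{lo}_{hi}" for lo, hi in _SUBBAND_EDGES]
    + [f"norm_bandpower_{lo}_{hi}" for lo, hi in _SUBBAND_EDGES]
    + ["wavelet_energy"]
)
TIME_FEATURES = (
    ["curve_length", "n_extrema", "rms_amplitude",
     "hjorth_activity", "hjorth_mobility", "hjorth_complexity",
     "zero_crossings", "zero_crossings_d1", "zero_crossings_d2"]
    + [f"ar_error_{k}" for k in range(1, 10)]
    + ["skewness", "kurtosis", "nonlinear_energy", "var_d1", "var_d2"]
)
INFO_FEATURES = ["shannon_entropy", "svd_entropy", "fisher_information",
                 "spectral_entropy"]

#: Fixed, documented order of all 55 features.
FEATURE_NAMES: tuple[str, ...] = tuple(
    FREQUENCY_FEATURES + TIME_FEATURES + INFO_FEATURES
)
N_FEATURES = len(FEATURE_NAMES)
assert N_FEATURES == 55

_SVD_EMBED_DIM = 10
_SHANNON_BINS = 10
_AR_MAX_ORDER = 9


@dataclass
class FeatureMatrix:
    """Per-epoch, per-channel feature array of shape (epochs, channels, 55)."""

    values: np.ndarray
    epoch_starts: np.ndarray
    channel_labels: list[str]
    feature_names: tuple[str, ...] = FEATURE_NAMES
    degenerate: np.ndarray | None = None  # (epochs, channels) bool

    def __post_init__(self) -> None:
        if self.values.ndim != 3 or self.values.shape[2] != N_FEATURES:
            raise ValueError("values must have shape (epochs, channels, 55)")
        if self.degenerate is None:
            self.degenerate = np.zeros(self.values.shape[:2], dtype=bool)

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: epoch_start, channel, feature, value."""
        e, c, f = self.values.shape
        idx = pd.MultiIndex.from_product(
            [self.epoch_starts, self.channel_labels, self.feature_names],
            names=["epoch_start", "channel", "feature"],
        )
        return pd.DataFrame({"value": self.values.reshape(-1)}, index=idx).reset_index()


# ---------------------------------------------------------------------------
# Internal vectorised helpers (rows = epochs*channels)
# ---------------------------------------------------------------------------

def _periodogram(rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    freqs, psd = sp_signal.periodogram(rows, fs=FS, window="hamming", axis=-1)
    return freqs, psd


def _signed(rows: np.ndarray) -> np.ndarray:
    """Sign sequence with zeros attached to the preceding sign."""
    s = np.sign(rows)
    out = s.copy()
    for i in range(1, out.shape[-1]):
        col = out[..., i]
        prev = out[..., i - 1]
        np.copyto(col, prev, where=(col == 0))
    return out


def _count_sign_changes(rows: np.ndarray) -> np.ndarray:
    s = _signed(rows)
    return np.sum(s[..., :-1] * s[..., 1:] < 0, axis=-1).astype(float)


def _levinson_errors(rows: np.ndarray, max_order: int) -> np.ndarray:
    """Prediction-error variance of Yule-Walker AR fits of order 1..max_order.

    Biased autocovariances of the demeaned rows; the Levinson recursion is
    run batched across rows.  Rows with zero variance yield all-zero errors.
    """
    n = rows.shape[-1]
    z = rows - rows.mean(axis=-1, keepdims=True)
    r = np.empty(rows.shape[:-1] + (max_order + 1,))
    for k in range(max_order + 1):
        r[..., k] = np.sum(z[..., : n - k] * z[..., k:], axis=-1) / n
    err = r[..., 0].copy()
    ok = err > 0
    safe_err = np.where(ok, err, 1.0)
    a = np.zeros(rows.shape[:-1] + (0,))
    out = np.zeros(rows.shape[:-1] + (max_order,))
    for m in range(1, max_order + 1):
        if m == 1:
            acc = np.zeros_like(err)
        else:
            acc = np.sum(a * r[..., 1:m][..., ::-1], axis=-1)
        k = np.where(ok, (r[..., m] - acc) / safe_err, 0.0)
        a = np.concatenate([a - k[..., None] * a[..., ::-1], k[..., None]], axis=-1)
        err = err * (1.0 - k**2)
        safe_err = np.where(err > 0, err, 1.0)
        out[..., m - 1] = np.where(ok, err, 0.0)
    return out


def _entropy(p: np.ndarray, axis: int = -1) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(p > 0, p * np.log(p), 0.0)
    return -np.sum(t, axis=axis)


# ---------------------------------------------------------------------------
# Public per-family operations
# ---------------------------------------------------------------------------

def frequency_features(rows: np.ndarray) -> np.ndarray:
    """28 frequency-domain features per row of 256 samples at 32 Hz."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    freqs, psd = _periodogram(rows)
    df = freqs[1] - freqs[0]
    band = freqs <= 12.0
    fb = freqs[band]
    pb = psd[..., band]
    total = pb.sum(axis=-1) * df

    peak = fb[np.argmax(pb, axis=-1)]

    cum = np.cumsum(pb, axis=-1) * df
    sef = []
    for pct in (0.80, 0.90, 0.95):
        target = pct * total
        idx = np.argmax(cum >= target[..., None] - 1e-30, axis=-1)
        sef.append(fb[idx])

    bps = []
    for lo, hi in _SUBBAND_EDGES:
        m = (fb >= lo) & (fb < hi)
        bps.append(pb[..., m].sum(axis=-1) * df)
    bps = np.stack(bps, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        nbps = np.where(total[..., None] > 0, bps / total[..., None], 0.0)

    # db4 detail level 4 spans 1-2 Hz at 32 Hz; it is the 5th of the 8
    # coefficient arrays [cA7, cD7 ... cD1] of a full level-7 decomposition.
    coeffs = pywt.wavedec(rows, "db4", level=4, axis=-1)
    wav = np.sum(coeffs[1] ** 2, axis=-1)

    out = np.concatenate(
        [total[..., None], peak[..., None]]
        + [s[..., None] for s in sef]
        + [bps, nbps, wav[..., None]],
        axis=-1,
    )
    return out


def time_features(rows: np.ndarray) -> np.ndarray:
    """23 time-domain features per row of 256 samples."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    d1 = np.diff(rows, axis=-1)
    d2 = np.diff(rows, n=2, axis=-1)

    curve_length = np.sum(np.abs(d1), axis=-1)
    n_extrema = _count_sign_changes(d1)
    rms = np.sqrt(np.mean(rows**2, axis=-1))

    var = rows.var(axis=-1)
    var1 = d1.var(axis=-1)
    var2 = d2.var(axis=-1)
    ok = var > 0
    ok1 = ok & (var1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mobility = np.where(ok, np.sqrt(var1 / np.where(ok, var, 1.0)), 0.0)
        mob_d1 = np.where(ok1, np.sqrt(var2 / np.where(var1 > 0, var1, 1.0)), 0.0)
        complexity = np.where(
            ok1 & (mobility > 0), mob_d1 / np.where(mobility > 0, mobility, 1.0), 0.0
        )

    zc = _count_sign_changes(rows)
    zc1 = _count_sign_changes(d1)
    zc2 = _count_sign_changes(d2)

    ar_err = _levinson_errors(rows, _AR_MAX_ORDER)

    z = rows - rows.mean(axis=-1, keepdims=True)
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(ok, np.mean(z**3, axis=-1) / np.where(ok, sd**3, 1.0), 0.0)
        kurt = np.where(
            ok, np.mean(z**4, axis=-1) / np.where(ok, var**2, 1.0) - 3.0, 0.0
        )

    teager = np.mean(
        rows[..., 1:-1] ** 2 - rows[..., :-2] * rows[..., 2:], axis=-1
    )

    return np.concatenate(
        [
            np.stack(
                [curve_length, n_extrema, rms, var, mobility, complexity,
                 zc, zc1, zc2],
                axis=-1,
            ),
            ar_err,
            np.stack([skew, kurt, teager, var1, var2], axis=-1),
        ],
        axis=-1,
    )


def information_features(rows: np.ndarray) -> np.ndarray:
    """4 information-theory features per row of 256 samples."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    n_rows, n = rows.shape
    lo = rows.min(axis=-1, keepdims=True)
    hi = rows.max(axis=-1, keepdims=True)
    rng = hi - lo
    ok = (rng > 0).ravel()

    # Shannon entropy of a 10-equal-width amplitude histogram (per epoch).
    shannon = np.zeros(n_rows)
    if ok.any():
        safe_rng = np.where(rng > 0, rng, 1.0)
        idx = np.clip(
            ((rows - lo) / safe_rng * _SHANNON_BINS).astype(int), 0, _SHANNON_BINS - 1
        )
        flat = idx + np.arange(n_rows)[:, None] * _SHANNON_BINS
        counts = np.bincount(flat.ravel(), minlength=n_rows * _SHANNON_BINS)
        counts = counts.reshape(n_rows, _SHANNON_BINS).astype(float)
        shannon = np.where(ok, _entropy(counts / n), 0.0)

    # SVD entropy + Fisher information of the delay embedding (m=10, lag 1).
    emb = sliding_window_view(rows, _SVD_EMBED_DIM, axis=-1)
    s = np.linalg.svd(emb, compute_uv=False)
    ssum = s.sum(axis=-1, keepdims=True)
    p = np.where(ssum > 0, s / np.where(ssum > 0, ssum, 1.0), 0.0)
    svd_ent = np.where(ok, _entropy(p), 0.0)
    dp = p[..., 1:] - p[..., :-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p[..., :-1] > 0, dp**2 / np.where(p[..., :-1] > 0,
                                                           p[..., :-1], 1.0), 0.0)
    fisher = np.where(ok, terms.sum(axis=-1), 0.0)

    # Normalised spectral entropy over the 0-12 Hz periodogram bins.
    freqs, psd = _periodogram(rows)
    band = freqs <= 12.0
    pb = psd[..., band]
    tot = pb.sum(axis=-1, keepdims=True)
    q = np.where(tot > 0, pb / np.where(tot > 0, tot, 1.0), 0.0)
    spec_ent = np.where(ok, _entropy(q) / np.log(band.sum()), 0.0)

    return np.stack([shannon, svd_ent, fisher, spec_ent], axis=-1)


def feature_vector(epoch: np.ndarray) -> np.ndarray:
    """All 55 features, in :data:`FEATURE_NAMES` order, for one epoch."""
    epoch = np.asarray(epoch, dtype=float)
    if epoch.shape != (EPOCH_SAMPLES,):
        raise ValueError(f"epoch must have {EPOCH_SAMPLES} samples")
    row = epoch[None, :]
    return np.concatenate(
        [frequency_features(row), time_features(row), information_features(row)],
        axis=-1,
    )[0]


def extract_feature_matrix(rec: EEGRecord) -> FeatureMatrix:
    """Epoch a preprocessed (32 Hz) record and compute all 55 features.

    Returns a deterministic (epochs x channels x 55) matrix; channels that
    are constant within an epoch are flagged degenerate rather than fatal.
    """
    grid, blocks = make_epochs(rec)
    e, c, n = blocks.shape
    rows = blocks.reshape(e * c, n)
    vals = np.concatenate(
        [frequency_features(rows), time_features(rows), information_features(rows)],
        axis=-1,
    ).reshape(e, c, N_FEATURES)
    degenerate = (blocks.max(axis=-1) - blocks.min(axis=-1)) <= 0
    return FeatureMatrix(
        values=vals,
        epoch_starts=grid.epoch_starts.copy(),
        channel_labels=list(rec.channel_labels),
        degenerate=degenerate,
    )
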