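"""Probabilistic epoch classifier and threshold-based event detection.

Each 8 s epoch of each channel is scored by a support vector machine with a
radial-basis kernel, trained on pooled labelled epochs (one model applied to
every channel).  The SVM margin is mapped to a seizure probability through a
monotone logistic (Platt) calibration, the per-epoch probabilities are laid
out on a 1 Hz grid (mean over the epochs covering each second), per-channel
traces are fused by the per-second maximum — the seizure definition requires
only one channel — and a detection is declared wherever the (optionally
smoothed) fused trace stays at or above the chosen threshold for at least
10 s, after bridging sub-2 s dips.

The decision threshold is adjustable over 0.1 (most sensitive) … 0.9 (least
sensitive) in steps of 0.1.
"""

from __future__ import annotations

import hashlib
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import FEATURE_NAMES, FeatureMatrix, N_FEATURES, extract_feature_matrix
from .io import (
    EEGRecord,
    EPOCH_HOP_S,
    EPOCH_LENGTH_S,
    SeizureEvent,
    SeizureEventList,
)

#: The nine detector sensitivity thresholds.
THRESHOLDS: tuple[float, ...] = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1))

MIN_EVENT_DURATION_S = 10.0
GAP_BRIDGE_S = 2.0
SMOOTHING_WINDOW_S = 15

#: Fraction of an epoch that must overlap a reference seizure for the epoch
#: to be labelled seizure-positive during training.
EPOCH_LABEL_OVERLAP = 0.5


def _feature_checksum(names) -> str:
    return hashlib.sha256("|".join(names).encode()).hexdigest()[:16]


@dataclass
class TrainConfig:
    """Hyperparameter search and training-set handling."""

    c_grid: tuple[float, ...] = (1.0, 10.0)
    gamma_grid: tuple = ("scale",)
    cv_folds: int = 3
    max_train_rows: int = 5000  # balanced subsample cap for SVM tractability
    seed: int = 0


@dataclass
class SeizureModel:
    """Trained epoch classifier: normalisation, RBF-SVM and calibration."""

    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    svm: object
    feature_checksum: str = ""
    training_accuracy: float = 0.0
    best_params: dict = field(default_factory=dict)
    version: str = "neoseiz-model-1"

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "SeizureModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, SeizureModel):
            raise TypeError("not a SeizureModel file")
        return model

    def _check(self, feature_names) -> None:
        if _feature_checksum(feature_names) != self.feature_checksum:
            raise ValueError("feature-name checksum mismatch: model and "
                             "feature matrix disagree on the 55-feature layout")

    def predict_epoch_probabilities(self, x: np.ndarray) -> np.ndarray:
        """Seizure probability for rows of 55 features; non-finite rows 0."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != N_FEATURES:
            raise ValueError(f"expected {N_FEATURES} features, got {x.shape[1]}")
        bad = ~np.isfinite(x).all(axis=1)
        z = (np.where(np.isfinite(x), x, 0.0) - self.scaler_mean) / self.scaler_scale
        pos = list(self.svm.classes_).index(1)
        p = self.svm.predict_proba(z)[:, pos]
        p[bad] = 0.0
        return p


def label_epochs(
    epoch_starts: np.ndarray,
    events: SeizureEventList,
    epoch_length: float = EPOCH_LENGTH_S,
    min_overlap: float = EPOCH_LABEL_OVERLAP,
) -> np.ndarray:
    """Label an epoch seizure-positive when at least ``min_overlap`` of it
    overlaps a reference seizure event."""
    labels = np.zeros(len(epoch_starts), dtype=int)
    for i, start in enumerate(epoch_starts):
        end = start + epoch_length
        overlap = sum(
            max(0.0, min(end, ev.offset) - max(start, ev.onset)) for ev in events
        )
        if overlap >= min_overlap * epoch_length:
            labels[i] = 1
    return labels


def train_model(
    features: np.ndarray,
    labels: np.ndarray,
    config: TrainConfig | None = None,
    feature_names=FEATURE_NAMES,
) -> SeizureModel:
    """Train the pooled-epoch RBF-SVM with Platt-calibrated probabilities.

    ``features`` is (n_epochs, 55) pooled over channels and records;
    ``labels`` is 0/1.  Hyperparameters are chosen by cross-validated grid
    search; a balanced subsample caps the SVM problem size.  Deterministic
    for a fixed seed.
    """
    from sklearn.calibration import CalibratedClassifierCV
    from sklearn.model_selection import GridSearchCV, StratifiedKFold
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    config = config or TrainConfig()
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if x.ndim != 2 or x.shape[1] != N_FEATURES:
        raise ValueError(f"expected (n, {N_FEATURES}) feature table")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training data must contain both classes")

    finite = np.isfinite(x).all(axis=1)
    x, y = x[finite], y[finite]

    rng = np.random.default_rng(config.seed)
    if len(y) > config.max_train_rows:
        per_class = config.max_train_rows // 2
        keep = []
        for cls in (0, 1):
            idx = np.flatnonzero(y == cls)
            if len(idx) > per_class:
                idx = rng.choice(idx, size=per_class, replace=False)
            keep.append(idx)
        keep = np.sort(np.concatenate(keep))
        x, y = x[keep], y[keep]

    scaler = StandardScaler().fit(x)
    z = scaler.transform(x)

    base = SVC(kernel="rbf", class_weight="balanced")
    grid = {"C": list(config.c_grid), "gamma": list(config.gamma_grid)}
    cv = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                         random_state=config.seed)
    if len(config.c_grid) * len(config.gamma_grid) > 1:
        search = GridSearchCV(base, grid, cv=cv, scoring="roc_auc", n_jobs=1)
        search.fit(z, y)
        best = dict(search.best_params_)
    else:
        best = {"C": config.c_grid[0], "gamma": config.gamma_grid[0]}
    # monotone logistic (Platt) map from SVM margin to probability
    svm = CalibratedClassifierCV(
        base.set_params(**best), method="sigmoid", cv=cv, ensemble=False
    )
    svm.fit(z, y)

    return SeizureModel(
        scaler_mean=scaler.mean_.copy(),
        scaler_scale=scaler.scale_.copy(),
        svm=svm,
        feature_checksum=_feature_checksum(feature_names),
        training_accuracy=float((svm.predict(z) == y).mean()),
        best_params=best,
    )


# ---------------------------------------------------------------------------
# Probability traces
# ---------------------------------------------------------------------------

@dataclass
class ProbabilityTrace:
    """Per-second (1 Hz) seizure probabilities, per channel plus fused."""

    per_channel: np.ndarray          # (n_channels, n_seconds)
    fused: np.ndarray                # (n_seconds,)
    channel_labels: list[str]

    def __post_init__(self) -> None:
        if self.per_channel.shape[1] != len(self.fused):
            raise ValueError("fused length must equal per-channel length")
        for arr in (self.per_channel, self.fused):
            if arr.size and (arr.min() < 0 or arr.max() > 1):
                raise ValueError("probabilities must lie in [0, 1]")

    @property
    def n_seconds(self) -> int:
        return len(self.fused)


def _epochs_to_seconds(
    epoch_probs: np.ndarray, epoch_starts: np.ndarray, n_seconds: int
) -> np.ndarray:
    """Second ``t`` takes the mean probability of all epochs covering it;
    uncovered seconds take the nearest epoch's probability."""
    acc = np.zeros(n_seconds)
    cnt = np.zeros(n_seconds)
    for p, start in zip(epoch_probs, epoch_starts):
        a = int(np.floor(start))
        b = min(n_seconds, int(np.ceil(start + EPOCH_LENGTH_S)))
        acc[a:b] += p
        cnt[a:b] += 1
    out = np.zeros(n_seconds)
    covered = cnt > 0
    out[covered] = acc[covered] / cnt[covered]
    if not covered.all():
        if not covered.any():
            raise ValueError("no epochs cover the record")
        centres = epoch_starts + EPOCH_LENGTH_S / 2
        for t in np.flatnonzero(~covered):
            out[t] = epoch_probs[np.argmin(np.abs(centres - (t + 0.5)))]
    return np.clip(out, 0.0, 1.0)


def predict_probability(model: SeizureModel, fm: FeatureMatrix,
                        record_duration: float | None = None) -> ProbabilityTrace:
    """Per-channel 1 Hz probability traces for a feature matrix."""
    model._check(fm.feature_names)
    if record_duration is None:
        record_duration = float(fm.epoch_starts[-1] + EPOCH_LENGTH_S)
    n_seconds = int(np.floor(record_duration))
    e, c, _ = fm.values.shape
    flat = fm.values.reshape(e * c, N_FEATURES)
    probs = model.predict_epoch_probabilities(flat).reshape(e, c)
    per_channel = np.stack(
        [_epochs_to_seconds(probs[:, ch], fm.epoch_starts, n_seconds)
         for ch in range(c)]
    )
    fused = fuse_channels(per_channel)
    return ProbabilityTrace(per_channel, fused, list(fm.channel_labels))


def fuse_channels(per_channel: np.ndarray) -> np.ndarray:
    """Fuse per-channel traces by the per-second maximum: a seizure on any
    single channel must be able to trigger a detection."""
    per_channel = np.atleast_2d(np.asarray(per_channel, dtype=float))
    if per_channel.shape[0] == 0:
        raise ValueError("need at least one channel")
    return per_channel.max(axis=0)


def smooth_trace(trace: np.ndarray, window_s: int = SMOOTHING_WINDOW_S) -> np.ndarray:
    """Centred moving average over ``window_s`` seconds (edges shrink)."""
    trace = np.asarray(trace, dtype=float)
    if window_s <= 1 or len(trace) == 0:
        return trace.copy()
    half = window_s // 2
    c = np.concatenate([[0.0], np.cumsum(trace)])
    idx = np.arange(len(trace))
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, len(trace))
    return (c[hi] - c[lo]) / (hi - lo)


def events_from_trace(
    trace: np.ndarray,
    threshold: float,
    record_duration: float | None = None,
    min_duration_s: float = MIN_EVENT_DURATION_S,
    gap_bridge_s: float = GAP_BRIDGE_S,
) -> SeizureEventList:
    """Threshold the 1 Hz trace into detected seizure events.

    Maximal runs of seconds at or above the threshold become events; gaps
    shorter than ``gap_bridge_s`` are bridged first, then runs shorter than
    ``min_duration_s`` are discarded (mirroring the >= 10 s electrographic
    seizure definition).
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    trace = np.asarray(trace, dtype=float)
    if record_duration is None:
        record_duration = float(len(trace))
    mask = trace >= threshold

    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(int))
    onsets = np.flatnonzero(d == 1)
    offsets = np.flatnonzero(d == -1)

    bridged: list[list[float]] = []
    for a, b in zip(onsets, offsets):
        if bridged and a - bridged[-1][1] < gap_bridge_s:
            bridged[-1][1] = b
        else:
            bridged.append([float(a), float(b)])

    events = [
        SeizureEvent(a, b) for a, b in bridged if b - a >= min_duration_s
    ]
    return SeizureEventList(events, record_duration)


def detect(
    model: SeizureModel,
    rec: EEGRecord,
    thresholds=THRESHOLDS,
    smoothing: bool = True,
    min_duration_s: float = MIN_EVENT_DURATION_S,
    gap_bridge_s: float = GAP_BRIDGE_S,
) -> tuple[ProbabilityTrace, np.ndarray, dict[float, SeizureEventList]]:
    """Full detection on a preprocessed (32 Hz) record.

    Returns the raw probability trace, the (optionally smoothed) fused
    trace actually thresholded, and per-threshold event lists.
    """
    for th in thresholds:
        if not any(abs(th - t) < 1e-9 for t in THRESHOLDS):
            raise ValueError(f"threshold {th} is not one of the nine "
                             f"detector thresholds {THRESHOLDS}")
    fm = extract_feature_matrix(rec)
    trace = predict_probability(model, fm, rec.duration)
    fused = smooth_trace(trace.fused) if smoothing else trace.fused.copy()
    events = {
        float(th): events_from_trace(
            fused, float(th), rec.duration,
            min_duration_s=min_duration_s, gap_bridge_s=gap_bridge_s,
        )
        for th in thresholds
    }
    return trace, fused, events
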