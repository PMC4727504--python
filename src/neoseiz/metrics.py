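"""Agreement and validation metrics for seizure annotations.

Two annotations of the same recording (an expert reference and a detector
output) are compared on a 1 Hz grid.  Time-based ("overlap integral")
metrics count per-second true/false positives/negatives; event-based
("any overlap") metrics count a reference seizure as detected when at least
one detection shares at least one second with it, and report false
detections per hour instead of specificity.  Cohen's kappa is reported with
the Byrt–Bishop–Carlin prevalence (|TP−TN|/N) and bias (|FP−FN|/N) indices.

Clinically oriented summaries — seizure burden, number, mean/median
duration, onset (postnatal hours) and period — are compared between raters
with the intra-class correlation coefficient (two-way, absolute agreement,
average measures), and the framework also scores baby-level seizure
identification and whether detector output would have supported
antiepileptic drug (AED) decisions in the 90 min before each dose.

Quantities whose denominator is empty (e.g. sensitivity on a seizure-free
record) are reported as ``None`` rather than an arbitrary number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SeizureEvent, SeizureEventList

AED_WINDOW_S = 90 * 60.0
DEFAULT_DURATION_BINS_MIN = tuple(float(x) for x in range(11)) + (math.inf,)


@dataclass
class BinaryTrack:
    """Per-second 0/1 seizure indicator at 1 Hz."""

    values: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 1:
            raise ValueError("BinaryTrack values must be 1-D")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("BinaryTrack values must be 0/1")
        if len(self.values) != int(math.floor(self.duration)):
            raise ValueError("track length must equal floor(duration)")


@dataclass(frozen=True)
class ContingencyCounts:
    """Per-second agreement counts (seconds)."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class TemporalMetrics:
    sensitivity: float | None  # %, None when the reference has no seizure
    specificity: float | None  # %, None when the reference is all seizure


@dataclass(frozen=True)
class EventMetrics:
    sdr: float | None  # seizure detection rate %, None when no ref events
    fd_per_h: float
    n_ref_events: int
    n_detected: int
    n_false_detections: int


@dataclass(frozen=True)
class KappaResult:
    kappa: float | None
    prevalence_index: float
    bias_index: float


@dataclass(frozen=True)
class SummaryStats:
    """Per-recording clinical seizure summary."""

    seizure_number: int
    seizure_burden_min: float
    seizure_onset_h: float | None      # postnatal age of first seizure
    seizure_period_h: float | None     # first onset to last offset
    mean_duration_s: float | None
    median_duration_s: float | None


@dataclass
class AEDRecord:
    """Antiepileptic drug doses for one baby (postnatal hours)."""

    times_h: list[float]
    drug: str = ""
    window_s: float = AED_WINDOW_S


# ---------------------------------------------------------------------------
# Time-based (overlap integral) agreement
# ---------------------------------------------------------------------------

def binarize(events: SeizureEventList) -> BinaryTrack:
    """1 Hz binary track: second ``t`` is 1 iff ``[t, t+1)`` meets an event."""
    n = int(math.floor(events.record_duration))
    values = np.zeros(n, dtype=np.int8)
    for ev in events:
        a = max(0, int(math.floor(ev.onset)))
        b = min(n, int(math.ceil(ev.offset)))
        values[a:b] = 1
    return BinaryTrack(values, float(events.record_duration))


def events_from_track(track: BinaryTrack) -> SeizureEventList:
    """Maximal runs of ones as events (inverse of :func:`binarize` on the grid)."""
    v = np.concatenate([[0], track.values, [0]])
    d = np.diff(v)
    onsets = np.flatnonzero(d == 1)
    offsets = np.flatnonzero(d == -1)
    events = [SeizureEvent(float(a), float(b)) for a, b in zip(onsets, offsets)]
    return SeizureEventList(events, track.duration)


def temporal_agreement(
    ref: BinaryTrack, test: BinaryTrack
) -> tuple[ContingencyCounts, TemporalMetrics]:
    """Per-second sensitivity/specificity between reference and test tracks."""
    if len(ref.values) != len(test.values):
        raise ValueError(
            f"track length mismatch: {len(ref.values)} vs {len(test.values)}"
        )
    r = ref.values.astype(bool)
    t = test.values.astype(bool)
    tp = int(np.sum(r & t))
    tn = int(np.sum(~r & ~t))
    fp = int(np.sum(~r & t))
    fn = int(np.sum(r & ~t))
    counts = ContingencyCounts(tp, tn, fp, fn)
    sens = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else None
    spec = 100.0 * tn / (tn + fp) if (tn + fp) > 0 else None
    return counts, TemporalMetrics(sens, spec)


def kappa_indices(counts: ContingencyCounts) -> KappaResult:
    """Cohen's kappa with prevalence and bias indices from second counts."""
    n = counts.n
    if n <= 0:
        raise ValueError("empty contingency table")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
    kappa = (po - pe) / (1.0 - pe) if pe < 1.0 else None
    return KappaResult(kappa, abs(tp - tn) / n, abs(fp - fn) / n)


# ---------------------------------------------------------------------------
# Event-based (any overlap) agreement
# ---------------------------------------------------------------------------

def _event_hits_track(ev: SeizureEvent, track: BinaryTrack) -> bool:
    a = max(0, int(math.floor(ev.onset)))
    b = min(len(track.values), int(math.ceil(ev.offset)))
    return bool(track.values[a:b].any())


def event_agreement(ref: SeizureEventList, test: SeizureEventList) -> EventMetrics:
    """Any-overlap seizure detection rate and false detections per hour.

    Overlap requires at least one shared second on the 1 Hz analysis grid.
    """
    if ref.record_duration != test.record_duration:
        raise ValueError("event lists must share the record duration")
    ref_track = binarize(ref)
    test_track = binarize(test)
    detected = sum(_event_hits_track(ev, test_track) for ev in ref)
    false_det = sum(not _event_hits_track(ev, ref_track) for ev in test)
    hours = ref.record_duration / 3600.0
    sdr = 100.0 * detected / len(ref) if len(ref) > 0 else None
    return EventMetrics(sdr, false_det / hours, len(ref), detected, false_det)


def detection_by_duration(
    ref: SeizureEventList,
    test: SeizureEventList,
    bin_edges_min: tuple[float, ...] = DEFAULT_DURATION_BINS_MIN,
) -> pd.DataFrame:
    """Any-overlap detection rate per reference-seizure-duration bin.

    Returns a frame with one row per bin: the event count (duration
    histogram), the number detected and the per-bin SDR (``None`` for empty
    bins).  Default bins are 1 min wide up to 10 min, then open-ended.
    """
    edges = np.asarray(bin_edges_min, dtype=float) * 60.0
    if edges[0] != 0 or not np.isinf(edges[-1]):
        raise ValueError("bins must cover (0, inf)")
    test_track = binarize(test)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = [ev for ev in ref if lo <= ev.duration < hi]
        det = sum(_event_hits_track(ev, test_track) for ev in in_bin)
        rows.append(
            {
                "bin_lo_min": lo / 60.0,
                "bin_hi_min": hi / 60.0,
                "n_events": len(in_bin),
                "n_detected": det,
                "sdr": 100.0 * det / len(in_bin) if in_bin else math.nan,
            }
        )
    return pd.DataFrame(rows).astype({"sdr": float})


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(
    trace: np.ndarray,
    ref: BinaryTrack,
    thresholds: tuple[float, ...] = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1)),
) -> tuple[float | None, pd.DataFrame]:
    """AUC of the per-second probability trace against the reference track.

    The headline AUC is the rank statistic over all seconds; a nine-point
    (sensitivity, specificity) curve over the standard detector thresholds,
    anchored at (0, 100) and (100, 0), is returned alongside with its own
    trapezoidal area for comparison.
    """
    from sklearn.metrics import roc_auc_score

    trace = np.asarray(trace, dtype=float)
    if len(trace) != len(ref.values):
        raise ValueError("trace/track length mismatch")
    y = ref.values
    if y.min() == y.max():
        return None, pd.DataFrame(columns=["threshold", "sensitivity", "specificity"])
    auc = float(roc_auc_score(y, trace))

    rows = []
    for th in thresholds:
        mask = BinaryTrack((trace >= th).astype(np.int8), ref.duration)
        _, tm = temporal_agreement(ref, mask)
        rows.append(
            {"threshold": float(th), "sensitivity": tm.sensitivity,
             "specificity": tm.specificity}
        )
    curve = pd.DataFrame(rows)

    pts = [(0.0, 100.0)] + [
        (r["sensitivity"], r["specificity"]) for _, r in curve.iterrows()
    ] + [(100.0, 0.0)]
    fpr = np.array([100.0 - spec for _, spec in pts])
    sens = np.array([s for s, _ in pts])
    order = np.argsort(fpr, kind="stable")
    curve.attrs["trapezoid_auc"] = float(
        np.trapezoid(sens[order], fpr[order]) / 1e4
    )
    return auc, curve


# ---------------------------------------------------------------------------
# Application-specific measures
# ---------------------------------------------------------------------------

def summary_stats(events: SeizureEventList, start_age_h: float = 0.0) -> SummaryStats:
    """Clinical seizure summary of one recording.

    Onset is the postnatal age (hours) at the first seizure; period spans
    first onset to last offset, in hours; burden is total seizure minutes.
    """
    durations = [ev.duration for ev in events]
    if not durations:
        return SummaryStats(0, 0.0, None, None, None, None)
    first = events.events[0]
    last = events.events[-1]
    return SummaryStats(
        seizure_number=len(durations),
        seizure_burden_min=sum(durations) / 60.0,
        seizure_onset_h=start_age_h + first.onset / 3600.0,
        seizure_period_h=(last.offset - first.onset) / 3600.0,
        mean_duration_s=float(np.mean(durations)),
        median_duration_s=float(np.median(durations)),
    )


def icc(expert_values, sda_values) -> float:
    """Two-way mixed-effects, absolute-agreement, average-measures ICC.

    Pairs with an undefined entry on either side are dropped; at least three
    complete pairs are required.
    """
    import pingouin as pg

    pairs = [
        (float(a), float(b))
        for a, b in zip(expert_values, sda_values)
        if a is not None and b is not None
        and np.isfinite(a) and np.isfinite(b)
    ]
    if len(pairs) < 3:
        raise ValueError(f"ICC needs >= 3 complete pairs, got {len(pairs)}")
    df = pd.DataFrame(
        {
            "target": list(range(len(pairs))) * 2,
            "rater": ["expert"] * len(pairs) + ["sda"] * len(pairs),
            "rating": [p[0] for p in pairs] + [p[1] for p in pairs],
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        table = pg.intraclass_corr(
            data=df, targets="target", raters="rater", ratings="rating"
        )
    return float(table.loc[table["Type"] == "ICC(A,k)", "ICC"].iloc[0])


def classify_babies(
    cohort: dict[str, tuple[SeizureEventList, SeizureEventList]]
) -> pd.DataFrame:
    """Baby-level identification: any detection in seizure babies, none in
    non-seizure babies.

    ``cohort`` maps record id to (expert events, detector events).
    """
    rows = []
    for rec_id, (ref, test) in cohort.items():
        is_seizure = len(ref) > 0
        identified = (len(test) > 0) if is_seizure else (len(test) == 0)
        rows.append(
            {"record": rec_id, "seizure_baby": is_seizure, "identified": identified,
             "n_detections": len(test)}
        )
    return pd.DataFrame(rows)


def aed_support(
    aed: AEDRecord,
    ref: SeizureEventList,
    test: SeizureEventList,
    start_age_h: float = 0.0,
) -> pd.DataFrame:
    """Per-dose table of EEG-concurrent vs detector-supported AED decisions.

    A dose at postnatal time ``t`` is *concurrent* when a reference seizure
    touches the closed window ``[t - 90 min, t]``, and *supported* when a
    detector event touches the same window.  Doses outside the recording
    are excluded (with a warning flag in the returned frame attrs).
    """
    duration = ref.record_duration
    rows, excluded = [], []
    for t_h in aed.times_h:
        t = (t_h - start_age_h) * 3600.0
        if not (0.0 <= t <= duration):
            excluded.append(t_h)
            continue
        a, b = t - aed.window_s, t
        touches = lambda evs: any(
            ev.onset <= b and ev.offset >= a for ev in evs
        )
        rows.append(
            {
                "dose_time_h": t_h,
                "concurrent": touches(ref),
                "supported": touches(test),
            }
        )
    out = pd.DataFrame(rows, columns=["dose_time_h", "concurrent", "supported"])
    out["concurrent"] = out["concurrent"].astype(bool)
    out["supported"] = out["supported"].astype(bool)
    out.attrs["excluded_doses_h"] = excluded
    return out


# ---------------------------------------------------------------------------
# Record- and cohort-level reports
# ---------------------------------------------------------------------------

@dataclass
class RecordEvaluation:
    """All agreement measures for one recording at each threshold."""

    record_id: str
    duration: float
    per_threshold: dict[float, dict] = field(default_factory=dict)
    auc: float | None = None
    roc_curve: pd.DataFrame | None = None
    expert_summary: SummaryStats | None = None
    sda_summary: dict[float, SummaryStats] = field(default_factory=dict)


def evaluate_record(
    record_id: str,
    ref: SeizureEventList,
    per_threshold_events: dict[float, SeizureEventList],
    trace: np.ndarray | None = None,
    start_age_h: float = 0.0,
) -> RecordEvaluation:
    """Compare one expert annotation against detector annotations."""
    ref_track = binarize(ref)
    ev = RecordEvaluation(record_id, ref.record_duration)
    ev.expert_summary = summary_stats(ref, start_age_h)
    for th, test in sorted(per_threshold_events.items()):
        counts, temporal = temporal_agreement(ref_track, binarize(test))
        ev.per_threshold[th] = {
            "counts": counts,
            "temporal": temporal,
            "kappa": kappa_indices(counts),
            "event": event_agreement(ref, test),
        }
        ev.sda_summary[th] = summary_stats(test, start_age_h)
    if trace is not None and len(ref_track.values) > 0:
        ev.auc, ev.roc_curve = roc_auc(trace, ref_track)
    return ev


def _median_iqr(values: list[float]) -> dict:
    vals = [v for v in values if v is not None and np.isfinite(v)]
    if not vals:
        return {"median": None, "iqr_lo": None, "iqr_hi": None, "n": 0}
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return {"median": float(med), "iqr_lo": float(q1), "iqr_hi": float(q3),
            "n": len(vals)}


def threshold_table(evaluations: list[RecordEvaluation]) -> pd.DataFrame:
    """Cohort per-threshold grid: kappa triplet plus temporal and event
    metrics, summarised across records as median (IQR)."""
    thresholds = sorted({th for ev in evaluations for th in ev.per_threshold})
    rows = []
    for th in thresholds:
        cells = {"threshold": th}
        pulls = {
            "kappa": lambda d: d["kappa"].kappa,
            "prevalence_index": lambda d: d["kappa"].prevalence_index,
            "bias_index": lambda d: d["kappa"].bias_index,
            "sensitivity": lambda d: d["temporal"].sensitivity,
            "specificity": lambda d: d["temporal"].specificity,
            "sdr": lambda d: d["event"].sdr,
            "fd_per_h": lambda d: d["event"].fd_per_h,
        }
        for name, pull in pulls.items():
            stats = _median_iqr(
                [pull(ev.per_threshold[th]) for ev in evaluations
                 if th in ev.per_threshold]
            )
            cells[name] = stats["median"]
            cells[f"{name}_iqr_lo"] = stats["iqr_lo"]
            cells[f"{name}_iqr_hi"] = stats["iqr_hi"]
        rows.append(cells)
    return pd.DataFrame(rows)


_SUMMARY_FIELDS = (
    "seizure_onset_h", "seizure_period_h", "seizure_burden_min",
    "seizure_number", "mean_duration_s", "median_duration_s",
)


def icc_table(evaluations: list[RecordEvaluation]) -> pd.DataFrame:
    """ICC between expert and detector seizure summaries, per threshold.

    Only babies in whom the expert marked seizures and the detector found at
    least one event contribute pairs; thresholds with fewer than three such
    pairs are reported as ``None``.
    """
    thresholds = sorted(
        {th for ev in evaluations for th in ev.sda_summary}
    )
    rows = []
    for stat in _SUMMARY_FIELDS:
        for th in thresholds:
            expert, sda = [], []
            for ev in evaluations:
                if ev.expert_summary is None or ev.expert_summary.seizure_number == 0:
                    continue
                s = ev.sda_summary.get(th)
                if s is None or s.seizure_number == 0:
                    continue
                expert.append(getattr(ev.expert_summary, stat))
                sda.append(getattr(s, stat))
            try:
                value = icc(expert, sda)
            except ValueError:
                value = None
            rows.append(
                {"statistic": stat, "threshold": th, "icc": value,
                 "n_pairs": len(expert)}
            )
    return pd.DataFrame(rows)
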