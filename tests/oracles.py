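"""Independent direct-definition oracles used to cross-check the package.

Everything here is written from the definitions, with plain loops and no
reuse of the package's vectorised code paths.
"""

from __future__ import annotations

import math

import numpy as np
import pywt
from scipy.signal import get_window

FS = 32.0
N = 256


def _psd(x):
    """One-sided Hamming periodogram (constant detrend), density scaling."""
    w = get_window("hamming", N)
    xd = x - np.mean(x)
    X = np.fft.rfft(xd * w)
    scale = 1.0 / (FS * np.sum(w * w))
    p = (np.abs(X) ** 2) * scale
    p[1:-1] *= 2.0  # one-sided, interior bins
    f = np.fft.rfftfreq(N, d=1.0 / FS)
    return f, p


def oracle_features(x: np.ndarray) -> dict[str, float]:
    """All 55 features of one epoch, computed naively; keyed by name."""
    x = np.asarray(x, dtype=float)
    out: dict[str, float] = {}
    degenerate = np.max(x) - np.min(x) <= 0

    # ---- frequency domain -------------------------------------------------
    f, p = _psd(x)
    df = f[1] - f[0]
    band = [k for k in range(len(f)) if f[k] <= 12.0]
    total = sum(p[k] for k in band) * df
    out["total_power"] = total
    peak_k = band[0]
    for k in band:
        if p[k] > p[peak_k]:
            peak_k = k
    out["peak_frequency"] = f[peak_k]
    for pct, name in ((0.80, "sef80"), (0.90, "sef90"), (0.95, "sef95")):
        cum = 0.0
        sef = f[band[-1]]
        for k in band:
            cum += p[k] * df
            if cum >= pct * total - 1e-30:
                sef = f[k]
                break
        out[name] = sef
    for lo in range(11):
        hi = lo + 2
        bp = sum(p[k] for k in band if lo <= f[k] < hi) * df
        out[f"bandpower_{lo}_{hi}"] = bp
        out[f"norm_bandpower_{lo}_{hi}"] = bp / total if total > 0 else 0.0
    coeffs = pywt.wavedec(x, "db4", level=7)  # [cA7, cD7, ..., cD1]
    out["wavelet_energy"] = float(sum(c * c for c in coeffs[4]))  # cD4: 1-2 Hz

    # ---- time domain ------------------------------------------------------
    d1 = [x[i + 1] - x[i] for i in range(len(x) - 1)]
    d2 = [d1[i + 1] - d1[i] for i in range(len(d1) - 1)]
    out["curve_length"] = sum(abs(v) for v in d1)

    def signs(seq):
        s, prev = [], 0
        for v in seq:
            cur = int(v > 0) - int(v < 0)
            if cur == 0:
                cur = prev
            s.append(cur)
            prev = cur
        return s

    def crossings(seq):
        s = signs(seq)
        return float(sum(1 for a, b in zip(s[:-1], s[1:]) if a * b < 0))

    out["n_extrema"] = crossings(d1)
    out["rms_amplitude"] = math.sqrt(sum(v * v for v in x) / len(x))

    def var(seq):
        m = sum(seq) / len(seq)
        return sum((v - m) ** 2 for v in seq) / len(seq)

    v0, v1, v2 = var(x), var(d1), var(d2)
    out["hjorth_activity"] = v0
    mob = math.sqrt(v1 / v0) if v0 > 0 else 0.0
    out["hjorth_mobility"] = mob
    mob1 = math.sqrt(v2 / v1) if v1 > 0 else 0.0
    out["hjorth_complexity"] = mob1 / mob if (mob > 0 and v1 > 0) else 0.0
    out["zero_crossings"] = crossings(x)
    out["zero_crossings_d1"] = crossings(d1)
    out["zero_crossings_d2"] = crossings(d2)

    if v0 > 0:
        from statsmodels.tsa.stattools import levinson_durbin

        sigma = levinson_durbin(x - x.mean(), nlags=9, isacov=False)[3]
        for k in range(1, 10):
            out[f"ar_error_{k}"] = float(sigma[k])
    else:
        for k in range(1, 10):
            out[f"ar_error_{k}"] = 0.0

    m = sum(x) / len(x)
    sd = math.sqrt(v0)
    out["skewness"] = (
        sum((v - m) ** 3 for v in x) / len(x) / sd**3 if sd > 0 else 0.0
    )
    out["kurtosis"] = (
        sum((v - m) ** 4 for v in x) / len(x) / v0**2 - 3.0 if v0 > 0 else 0.0
    )
    out["nonlinear_energy"] = sum(
        x[i] ** 2 - x[i - 1] * x[i + 1] for i in range(1, len(x) - 1)
    ) / (len(x) - 2)
    out["var_d1"] = v1
    out["var_d2"] = v2

    # ---- information theory -----------------------------------------------
    if degenerate:
        out["shannon_entropy"] = 0.0
        out["svd_entropy"] = 0.0
        out["fisher_information"] = 0.0
        out["spectral_entropy"] = 0.0
        return out

    # 10 equal-width bins; index floor((v-lo)/range*10), top edge closed
    lo, hi = np.min(x), np.max(x)
    counts = [0] * 10
    for v in x:
        counts[min(int((v - lo) / (hi - lo) * 10), 9)] += 1
    probs = [c / len(x) for c in counts]
    out["shannon_entropy"] = -sum(
        q * math.log(q) for q in probs if q > 0
    )

    emb = np.array([x[i : i + 10] for i in range(len(x) - 9)])
    s = np.linalg.svd(emb, compute_uv=False)
    ps = s / s.sum()
    out["svd_entropy"] = -sum(q * math.log(q) for q in ps if q > 0)
    out["fisher_information"] = sum(
        (ps[i + 1] - ps[i]) ** 2 / ps[i] for i in range(len(ps) - 1) if ps[i] > 0
    )

    q = [p[k] for k in band]
    tot = sum(q)
    q = [v / tot for v in q]
    out["spectral_entropy"] = -sum(
        v * math.log(v) for v in q if v > 0
    ) / math.log(len(band))
    return out


# ---------------------------------------------------------------------------
# Brute-force agreement metrics
# ---------------------------------------------------------------------------

def brute_second_labels(events, duration) -> list[bool]:
    n = int(math.floor(duration))
    return [
        any(ev.onset < t + 1 and t < ev.offset for ev in events)
        for t in range(n)
    ]


def brute_temporal(ref, test, duration):
    r = brute_second_labels(ref, duration)
    s = brute_second_labels(test, duration)
    tp = sum(1 for a, b in zip(r, s) if a and b)
    tn = sum(1 for a, b in zip(r, s) if not a and not b)
    fp = sum(1 for a, b in zip(r, s) if not a and b)
    fn = sum(1 for a, b in zip(r, s) if a and not b)
    return tp, tn, fp, fn


def brute_event(ref, test, duration):
    """Any-overlap SDR numerator and false-detection count, on the 1 Hz grid."""
    r = brute_second_labels(ref, duration)
    s = brute_second_labels(test, duration)

    def covered_seconds(ev):
        return [
            t for t in range(int(math.floor(duration)))
            if ev.onset < t + 1 and t < ev.offset
        ]

    detected = sum(
        1 for ev in ref if any(s[t] for t in covered_seconds(ev))
    )
    false_det = sum(
        1 for ev in test if not any(r[t] for t in covered_seconds(ev))
    )
    return detected, false_det
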