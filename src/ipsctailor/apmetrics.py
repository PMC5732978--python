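"""Action-potential normalization and APD metrics.

The same normalization serves optical-mapping-style fluorescence traces
(arbitrary units, baseline drift, photon noise) and simulated membrane
potential: heuristics locate the upstroke, the region just before the
upstroke sets the normalized baseline (0), and the 95th percentile of the
in-AP samples sets normalized amplitude 1. APD90/APD50 are then read from
the normalized signal with linear interpolation at the repolarization
crossings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .model import APTrace

__all__ = [
    "NormalizedAP",
    "APDResult",
    "normalize_ap",
    "compute_apd",
    "detect_alternans",
    "summarize_population",
    "apd_from_trace",
]

SMOOTH_WINDOW_MS = 5.0
BASELINE_WINDOW_MS = 20.0
UPSTROKE_FRACTION = 0.10  # derivative fraction defining AP start
END_FRACTION = 0.10  # return-to-baseline fraction defining AP end
MIN_UPSTROKE_SLOPE = 1e-3  # in amplitude units per ms, after rescaling


class DetectionError(ValueError):
    """No usable upstroke in the trace."""


@dataclass
class NormalizedAP:
    """An AP trace rescaled so baseline = 0 and in-AP 95th percentile = 1."""

    time_ms: np.ndarray
    signal: np.ndarray
    baseline: float
    amplitude: float
    ap_start_ms: float
    ap_end_ms: float
    activation_time_ms: float  # maximum-upstroke-velocity time


@dataclass
class APDResult:
    apd90: float | None  # ms; None when repolarization failed
    apd50: float | None
    activation_time: float
    alternans_flag: bool = False
    failure_flag: bool = False


def _smooth(signal: np.ndarray, dt_ms: float) -> np.ndarray:
    win = max(5, int(round(SMOOTH_WINDOW_MS / dt_ms)) | 1)
    if win >= signal.size:
        win = (signal.size - 1) | 1
    if win < 5:
        return signal.astype(float)
    return savgol_filter(signal, win, polyorder=3)


def _baseline_noise(norm: NormalizedAP) -> float:
    """Noise level (normalized units) of the recording.

    Uses the detrended pre-AP baseline when one exists; paced recordings
    start at the stimulus, so the fall-back reads the high-frequency
    (first-difference) residual of the final tenth of the trace, which is
    diastolic for any repolarized beat.
    """
    pre = norm.signal[norm.time_ms < norm.ap_start_ms - 1.0]
    if pre.size >= 8:
        x = np.arange(pre.size, dtype=float)
        coef = np.polyfit(x, pre, 1)
        return float(np.std(pre - np.polyval(coef, x)))
    tail = norm.signal[-max(8, norm.signal.size // 10):]
    return float(np.std(np.diff(tail)) / np.sqrt(2.0))


def normalize_ap(trace: APTrace) -> NormalizedAP:
    """Normalize one AP so that baseline maps to 0 and amplitude to 1.

    The upstroke is the maximum first derivative of the smoothed signal;
    the AP start is the last pre-upstroke sample where the derivative is
    below 10% of the maximum; the baseline is the mean of the 20 ms window
    ending there. The AP end is the first return below 10% of the rough
    amplitude (or the trace end), and the amplitude is the 95th percentile
    of the in-AP samples minus the baseline. Affine-invariant by
    construction.
    """
    t = trace.time_ms
    y = np.asarray(trace.signal, dtype=float)
    dt = float(np.median(np.diff(t)))
    smoothed = _smooth(y, dt)
    dv = np.gradient(smoothed, t)

    k_up = int(np.argmax(dv))
    span = float(np.max(smoothed) - np.min(smoothed))
    if span <= 0 or dv[k_up] <= MIN_UPSTROKE_SLOPE * span:
        raise DetectionError("no detectable upstroke")

    # AP start: last pre-upstroke sample with slow derivative
    thresh = UPSTROKE_FRACTION * dv[k_up]
    pre = np.nonzero(dv[: k_up + 1] < thresh)[0]
    k_start = int(pre[-1]) if pre.size else 0

    n_base = max(1, int(round(BASELINE_WINDOW_MS / dt)))
    baseline = float(np.mean(y[max(0, k_start - n_base): k_start + 1]))

    rough_amp = float(np.max(smoothed) - baseline)
    k_peak = int(np.argmax(smoothed))
    below = np.nonzero(
        smoothed[k_peak:] < baseline + END_FRACTION * rough_amp
    )[0]
    k_end = int(k_peak + below[0]) if below.size else y.size - 1

    in_ap = y[k_start: k_end + 1]
    amplitude = float(np.percentile(in_ap, 95)) - baseline
    if amplitude <= 0:
        raise DetectionError("degenerate trace: zero amplitude")

    return NormalizedAP(
        time_ms=t,
        signal=(y - baseline) / amplitude,
        baseline=baseline,
        amplitude=amplitude,
        ap_start_ms=float(t[k_start]),
        ap_end_ms=float(t[k_end]),
        activation_time_ms=float(t[k_up]),
    )


def compute_apd(norm: NormalizedAP, repolarization_fraction: float) -> float | None:
    """APD at a repolarization fraction (0.9 -> APD90), in ms.

    Duration from the activation (maximum-upstroke) time to the first
    sustained downward crossing of 1 - fraction in normalized units after
    the peak, linearly interpolated between samples. "Sustained" means the
    mean over the following ~2 ms also sits below the threshold, which
    makes the crossing robust to sample noise (a single noisy sample
    dipping below the level would otherwise bias high-rate recordings
    early); on noise-free monotone repolarization it is the plain first
    crossing. Returns None when the signal never recovers below the
    threshold (repolarization failure).
    """
    if not 0.0 < repolarization_fraction < 1.0:
        raise ValueError("repolarization fraction must be in (0, 1)")
    level = 1.0 - repolarization_fraction
    t, y = norm.time_ms, norm.signal
    dt = float(np.median(np.diff(t)))
    # noise-adaptive filtering: on noisy (optical-style) recordings the
    # crossings are read from the polynomial-smoothed signal, as in
    # semi-automatic optical-mapping pipelines; clean traces are untouched
    if _baseline_noise(norm) > 0.005:
        y = _smooth(y, dt)
    k0 = int(np.searchsorted(t, norm.activation_time_ms))
    k_peak = k0 + int(np.argmax(y[k0:]))
    seg = y[k_peak:]
    win = max(1, int(round(2.0 / dt)))
    csum = np.cumsum(np.concatenate([[0.0], seg]))
    n_tail = np.minimum(win, seg.size - np.arange(seg.size))
    tail_mean = (csum[np.arange(seg.size) + n_tail] - csum[:-1][: seg.size]) / n_tail
    below = np.nonzero((seg < level) & (tail_mean < level))[0]
    if below.size == 0:
        return None
    k = k_peak + int(below[0])
    if k == 0:
        return 0.0
    # linear interpolation of the crossing
    t_cross = t[k - 1] + (t[k] - t[k - 1]) * (y[k - 1] - level) / (y[k - 1] - y[k])
    return float(t_cross - norm.activation_time_ms)


def apd_from_trace(trace: APTrace) -> APDResult:
    """Normalize a single-beat trace and compute APD90/APD50."""
    try:
        norm = normalize_ap(trace)
    except DetectionError:
        return APDResult(apd90=None, apd50=None, activation_time=np.nan,
                         failure_flag=True)
    apd90 = compute_apd(norm, 0.9)
    apd50 = compute_apd(norm, 0.5)
    return APDResult(
        apd90=apd90,
        apd50=apd50,
        activation_time=norm.activation_time_ms,
        failure_flag=apd90 is None,
    )


def detect_alternans(apds, threshold: float = 0.05):
    """Beat-to-beat APD alternation flag plus the selected APD.

    ``apds`` are consecutive-beat APD90 values (ms). Flags when any
    consecutive relative difference exceeds ``threshold``; the selected APD
    is the longer of the final two beats when flagged, the final beat
    otherwise.
    """
    apds = [a for a in apds]
    if len(apds) < 2:
        raise ValueError("need at least two beats")
    if any(a is None or not np.isfinite(a) for a in apds):
        return True, None
    arr = np.asarray(apds, dtype=float)
    rel = np.abs(np.diff(arr)) / np.maximum(arr[:-1], 1e-12)
    flagged = bool(np.any(rel > threshold))
    selected = float(max(arr[-2], arr[-1])) if flagged else float(arr[-1])
    return flagged, selected


def summarize_population(values, bin_edges=None):
    """Median and quartiles (linear-interpolation percentiles) + histogram."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("empty population")
    q25, med, q75 = np.percentile(arr, [25, 50, 75])
    if bin_edges is None:
        bin_edges = np.histogram_bin_edges(arr, bins=10)
    counts, edges = np.histogram(arr, bins=bin_edges)
    return {
        "median": float(med),
        "q25": float(q25),
        "q75": float(q75),
        "histogram_counts": counts,
        "histogram_edges": edges,
        "n": int(arr.size),
    }
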