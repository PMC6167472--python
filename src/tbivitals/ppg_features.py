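"""PPG pulse variability, morphology, and dicrotic-notch dynamics.

The PPG peak-to-peak interval is the pulse analogue of the ECG NN interval,
so the variability metric set and the window summaries are shared with
:mod:`tbivitals.ecg_features`. What is PPG-specific here is the pulse
geometry (rise/fall times and amplitudes between foot, systolic peak, and
next foot) and the dicrotic notch, localized on the diastolic downslope via
three-point central-difference first and second derivatives: the notch is
the prominent local maximum of the second derivative (the point of sharpest
deceleration-to-reacceleration) between the systolic peak and the next
pulse foot.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from tbivitals.ecg_features import (
    apply_interval_quality,
    hrv_nonlinear,
    hrv_time_domain,
    nn_intervals,
    summarize,
)
from tbivitals.types import (
    AnalysisWindow,
    BeatAnnotations,
    InputError,
    WaveformRecord,
)

__all__ = [
    "central_difference",
    "ppg_variability",
    "pulse_morphology",
    "detect_dicrotic_notch",
    "summarize",
    "extract_ppg_features",
]

# fraction of the within-pulse 2nd-derivative range a notch candidate must
# exceed in prominence, and the neighborhood for decel/accel extrema
NOTCH_PROMINENCE_FRAC = 0.05
NOTCH_NEIGHBORHOOD_S = 0.050


def central_difference(signal: np.ndarray, fs: float, order: int = 1) -> np.ndarray:
    """Three-point central-difference derivative.

    Interior points: order 1 is ``(x[i+1] - x[i-1]) * fs / 2`` (units/s),
    order 2 is ``(x[i+1] - 2*x[i] + x[i-1]) * fs**2`` (units/s^2).
    Endpoints use the one-sided difference. Exact for quadratics (order 1)
    and linear ramps (order 2).
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 3:
        raise InputError("central difference requires at least 3 samples")
    if order not in (1, 2):
        raise InputError("order must be 1 or 2")
    d = np.empty_like(x)
    if order == 1:
        d[1:-1] = (x[2:] - x[:-2]) * fs / 2.0
        d[0] = (x[1] - x[0]) * fs
        d[-1] = (x[-1] - x[-2]) * fs
    else:
        d[1:-1] = (x[2:] - 2 * x[1:-1] + x[:-2]) * fs**2
        d[0] = d[1]
        d[-1] = d[-2]
    return d


def ppg_variability(
    annotations: BeatAnnotations,
    window: AnalysisWindow,
    prefix: str = "ppg_pp",
) -> dict[str, float]:
    """Variability of peak-to-peak intervals, same formulas as ECG HRV.

    Returns the time-domain and nonlinear metric set with feature ids
    prefixed ``ppg_`` (e.g. ``ppg_pp_sdnn``).
    """
    pp = nn_intervals(annotations, window)
    out = {f"{prefix}_{k}": v for k, v in hrv_time_domain(pp).items()}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out.update({f"{prefix}_{k}": v for k, v in hrv_nonlinear(pp).items()})
    return out


def pulse_morphology(
    record: WaveformRecord,
    annotations: BeatAnnotations,
    window: AnalysisWindow,
) -> pd.DataFrame:
    """Per-pulse geometry: peak-to-peak interval, rise and fall time/amplitude.

    Rise is foot -> systolic peak; fall is peak -> next pulse foot. Times in
    ms, amplitudes in signal units. Malformed pulses (peak not after its
    foot, or non-positive fall) are dropped and counted in
    ``frame.attrs['n_dropped']``.
    """
    fs = record.fs
    x = record.samples
    feet = annotations.fiducials["foot"]
    peaks = annotations.fiducials["peak"]
    times = annotations.anchor_times
    keep = annotations.quality & window.contains(times)
    rows = []
    n_dropped = 0
    for i in np.flatnonzero(keep):
        if i + 1 >= peaks.size:
            continue  # last pulse has no closing foot
        foot, peak, next_foot = feet[i], peaks[i], feet[i + 1]
        if not foot < peak < next_foot:
            n_dropped += 1
            continue
        rows.append(
            {
                "pulse_time": times[i],
                "pp_interval": (peaks[i + 1] - peak) * 1000.0 / fs,
                "rise_time": (peak - foot) * 1000.0 / fs,
                "fall_time": (next_foot - peak) * 1000.0 / fs,
                "rise_amp": x[peak] - x[foot],
                "fall_amp": x[peak] - x[next_foot],
            }
        )
    frame = pd.DataFrame(rows, columns=["pulse_time", "pp_interval", "rise_time", "fall_time", "rise_amp", "fall_amp"])
    frame.attrs["n_dropped"] = n_dropped
    return frame


def detect_dicrotic_notch(
    record: WaveformRecord,
    annotations: BeatAnnotations,
) -> pd.DataFrame:
    """Locate the dicrotic notch on each pulse via the second derivative.

    For each pulse the search region is the diastolic downslope between the
    systolic peak and the next pulse foot (with a small margin at both
    ends). The notch is the largest local maximum of the (lightly smoothed)
    second derivative whose prominence exceeds 5% of the within-pulse
    second-derivative range; absence is a value, not an error
    (``notch_index = -1``). ``notch_decel`` / ``notch_accel`` are the
    maximum / minimum of the second derivative within +/-50 ms of the notch.
    """
    fs = record.fs
    x = record.samples
    d2 = central_difference(x, fs, order=2)
    # light symmetric smoothing suppresses discretization jitter without
    # shifting the curvature maximum
    d2s = uniform_filter1d(d2, size=max(3, int(round(0.015 * fs)) | 1))
    feet = annotations.fiducials["foot"]
    peaks = annotations.fiducials["peak"]
    margin = max(2, int(round(0.03 * fs)))
    nbh = int(round(NOTCH_NEIGHBORHOOD_S * fs))
    rows = []
    for i in range(peaks.size):
        if i + 1 >= feet.size:
            break
        peak, next_foot = peaks[i], feet[i + 1]
        lo, hi = peak + margin, next_foot - margin
        row = {"pulse": i, "notch_index": -1, "notch_decel": np.nan, "notch_accel": np.nan}
        if hi - lo > 3:
            region = d2s[lo:hi]
            pulse_range = float(np.ptp(d2s[feet[i] : next_foot])) if next_foot > feet[i] else 0.0
            cand, props = find_peaks(region, prominence=NOTCH_PROMINENCE_FRAC * pulse_range)
            if cand.size:
                best = cand[int(np.argmax(region[cand]))]
                notch = lo + int(best)
                w0, w1 = max(0, notch - nbh), min(d2.size, notch + nbh + 1)
                row.update(
                    notch_index=notch,
                    notch_decel=float(d2[w0:w1].max()),
                    notch_accel=float(d2[w0:w1].min()),
                )
        rows.append(row)
    return pd.DataFrame(rows, columns=["pulse", "notch_index", "notch_decel", "notch_accel"])


def extract_ppg_features(
    record: WaveformRecord,
    window: AnalysisWindow,
    z_threshold: float = 3.0,
    prefix: str = "ppg",
) -> dict[str, float]:
    """Full PPG feature vector for one window.

    Pulse delineation, interval-quality masking, variability metrics,
    summarized pulse-geometry series, notch dynamics summaries, and a
    notch-presence fraction. Pulses lacking a notch contribute no values
    (not zeros) to the notch summaries; if no pulse has a notch the notch
    summaries are omitted and only the presence fraction (0.0) is emitted.
    """
    from tbivitals.signal_processing import detect_ppg_pulses

    ann = detect_ppg_pulses(record)
    ann = apply_interval_quality(ann, z_threshold=z_threshold)
    features = ppg_variability(ann, window, prefix=f"{prefix}_pp")
    pp = nn_intervals(ann, window)
    for name, value in summarize(pp).items():
        features[f"{prefix}_pp_{name}"] = value
    morph = pulse_morphology(record, ann, window)
    if len(morph):
        for col in ("rise_time", "fall_time", "rise_amp", "fall_amp"):
            for name, value in summarize(morph[col].to_numpy()).items():
                features[f"{prefix}_{col}_{name}"] = value
    notch = detect_dicrotic_notch(record, ann)
    in_win = annotations_in_window_mask(ann, window)
    notch = notch[in_win[notch["pulse"].to_numpy()]]
    present = notch["notch_index"].to_numpy() >= 0
    features[f"{prefix}_notch_presence"] = float(present.mean()) if len(notch) else 0.0
    if present.any():
        for col in ("notch_decel", "notch_accel"):
            vals = notch.loc[present, col].to_numpy(dtype=float)
            for name, value in summarize(vals).items():
                features[f"{prefix}_{col}_{name}"] = value
    return features


def annotations_in_window_mask(annotations: BeatAnnotations, window: AnalysisWindow) -> np.ndarray:
    """Boolean per-beat mask: good beats whose anchor lies inside the window."""
    return annotations.quality & window.contains(annotations.anchor_times)
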