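"""Beat detection, delineation, and Z-test beat-quality masking.

The R-peak detector is a Pan-Tompkins-style energy detector: band-pass,
differentiate, square, moving-window integrate, adaptive threshold with a
refractory period, then refine each detection to the local maximum of the
raw signal. PPG pulses are delineated as prominent systolic peaks with the
pulse foot at the minimum between consecutive peaks.

Quality masking follows the Z-test idea — under good signal quality the RR
intervals in a short segment are approximately normal, so beats whose
interval sits far in the tail are flagged — but uses median/MAD scaling by
default so the very outliers being hunted do not corrupt the test statistic.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.signal import butter, find_peaks, sosfiltfilt
from scipy.ndimage import uniform_filter1d

from tbivitals.types import BeatAnnotations, InputError, WaveformRecord

__all__ = [
    "detect_r_peaks",
    "delineate_pqrst",
    "detect_ppg_pulses",
    "zscore_quality_mask",
]

# delineation search windows around R, seconds; cover a normal QRS at 240 Hz
_Q_WIN = 0.080
_S_WIN = 0.100
_P_WIN = (0.250, 0.080)  # before R: [R-250 ms, R-80 ms)
_T_WIN = (0.100, 0.400)  # after R: (R+100 ms, R+400 ms]
_REFRACTORY = 0.250  # s, minimum R-R spacing enforced by the detector


def detect_r_peaks(record: WaveformRecord) -> np.ndarray:
    """Detect R-peak sample indices on an ECG record.

    Returns a strictly increasing index array; a flat (zero-range) record
    yields no peaks. Raises :class:`InputError` for non-ECG input or records
    shorter than 2 s.
    """
    if record.channel != "ECG":
        raise InputError(f"expected an ECG record, got {record.channel}")
    if record.duration < 2.0:
        raise InputError("record too short for R-peak detection (< 2 s)")
    x = record.samples
    fs = record.fs
    if np.ptp(x) == 0:
        return np.empty(0, dtype=int)

    sos = butter(2, [5.0, 25.0], btype="bandpass", fs=fs, output="sos")
    bp = sosfiltfilt(sos, x)
    energy = np.gradient(bp) ** 2
    win = max(3, int(round(0.150 * fs)))
    env = uniform_filter1d(energy, size=win)

    thr = 0.15 * np.percentile(env, 99)
    if thr <= 0:
        return np.empty(0, dtype=int)
    cand, _ = find_peaks(env, height=thr, distance=max(1, int(_REFRACTORY * fs)))

    # refine each energy peak to the raw-signal maximum nearby
    half = int(round(0.060 * fs))
    peaks = []
    for c in cand:
        lo, hi = max(0, c - half), min(x.size, c + half + 1)
        peaks.append(lo + int(np.argmax(x[lo:hi])))
    peaks = np.unique(peaks)
    if peaks.size > 1:
        # refinement can merge neighbours; enforce the refractory period,
        # keeping the taller peak of any violating pair
        keep = [0]
        for i in range(1, peaks.size):
            if peaks[i] - peaks[keep[-1]] >= _REFRACTORY * fs:
                keep.append(i)
            elif x[peaks[i]] > x[peaks[keep[-1]]]:
                keep[-1] = i
        peaks = peaks[keep]
    return peaks.astype(int)


def delineate_pqrst(record: WaveformRecord, r_peaks: np.ndarray) -> BeatAnnotations:
    """Locate P, Q, S, T around each detected R peak.

    Q is the signal minimum in the 80 ms before R, S the minimum in the
    100 ms after; P and T are the maxima in fixed windows further out. Beats
    whose windows fall outside the record are dropped. A beat whose Q or S
    lands on its search-window boundary (no real deflection) is kept but
    flagged low-confidence via ``quality=False``.
    """
    r_peaks = np.asarray(r_peaks, dtype=int)
    fs = record.fs
    x = record.samples
    fid = {k: [] for k in ("p", "q", "r", "s", "t")}
    quality = []
    n_dropped = 0
    for r in r_peaks:
        p_lo, p_hi = r - int(_P_WIN[0] * fs), r - int(_P_WIN[1] * fs)
        q_lo = r - int(_Q_WIN * fs)
        s_hi = r + int(_S_WIN * fs) + 1
        t_lo, t_hi = r + int(_T_WIN[0] * fs), r + int(_T_WIN[1] * fs) + 1
        if p_lo < 0 or t_hi > x.size:
            n_dropped += 1
            continue
        q = q_lo + int(np.argmin(x[q_lo:r]))
        s = r + 1 + int(np.argmin(x[r + 1 : s_hi]))
        p = p_lo + int(np.argmax(x[p_lo:p_hi]))
        t = t_lo + int(np.argmax(x[t_lo:t_hi]))
        confident = q > q_lo and s < s_hi - 1
        fid["p"].append(p)
        fid["q"].append(q)
        fid["r"].append(int(r))
        fid["s"].append(s)
        fid["t"].append(t)
        quality.append(confident)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} edge beats with incomplete delineation windows")
    return BeatAnnotations(
        {k: np.array(v, dtype=int) for k, v in fid.items()},
        np.array(quality, dtype=bool),
        "ECG",
        fs,
        record.t0,
    )


def detect_ppg_pulses(record: WaveformRecord) -> BeatAnnotations:
    """Delineate PPG pulses: one systolic peak and one foot per pulse.

    Systolic peaks are found by prominence (40% of the robust signal range),
    which keeps secondary dicrotic waves from being counted as pulses; each
    pulse foot is the signal minimum between the previous peak and the peak
    (for the first pulse, within 1.5 median periods before it).
    """
    if record.channel != "PPG":
        raise InputError(f"expected a PPG record, got {record.channel}")
    if record.duration < 2.0:
        raise InputError("record too short for pulse detection (< 2 s)")
    x = record.samples
    fs = record.fs
    lo_p, hi_p = np.percentile(x, [0.5, 99.5])
    if hi_p - lo_p == 0:
        empty = np.empty(0, dtype=int)
        return BeatAnnotations(
            {"foot": empty, "peak": empty.copy()}, np.empty(0, bool), "PPG", fs, record.t0
        )
    peaks, _ = find_peaks(x, prominence=0.4 * (hi_p - lo_p), distance=max(1, int(0.2 * fs)))
    if peaks.size == 0:
        empty = np.empty(0, dtype=int)
        return BeatAnnotations(
            {"foot": empty, "peak": empty.copy()}, np.empty(0, bool), "PPG", fs, record.t0
        )
    median_pp = float(np.median(np.diff(peaks))) if peaks.size > 1 else 0.8 * fs
    feet = np.empty(peaks.size, dtype=int)
    first_lo = max(0, peaks[0] - int(1.5 * median_pp))
    feet[0] = first_lo + int(np.argmin(x[first_lo : peaks[0] + 1]))
    for i in range(1, peaks.size):
        lo = peaks[i - 1]
        feet[i] = lo + int(np.argmin(x[lo : peaks[i] + 1]))
    return BeatAnnotations(
        {"foot": feet, "peak": peaks.astype(int)},
        np.ones(peaks.size, dtype=bool),
        "PPG",
        fs,
        record.t0,
    )


def zscore_quality_mask(
    rr_intervals: np.ndarray,
    z_threshold: float = 3.0,
    robust: bool = True,
    segment_len: int = 300,
) -> tuple[np.ndarray, float]:
    """Flag outlying RR (or peak-to-peak) intervals by a per-segment Z-test.

    Good-quality signal yields approximately normal RR intervals, so an
    interval with \\|z\\| > ``z_threshold`` within its segment marks a
    low-quality beat. Segments are ``segment_len`` consecutive intervals
    (default 300, a few minutes at resting heart rate: long enough that the
    robust scale estimate is stable and the tail test calibrated, short
    enough that the test stays local; counting intervals rather than
    seconds keeps the mask invariant under affine rescaling of the series).
    With ``robust=True`` (default) the segment centre and
    scale are the median and 1.4826*MAD, so a gross outlier cannot mask
    itself by inflating the plain standard deviation; ``robust=False`` gives
    the textbook mean/SD Z-test. Segments with zero scale mask nothing.

    Returns ``(mask, bad_fraction)`` where ``mask[i]`` is True for a good
    interval. Fewer than 10 intervals are indeterminate: all flagged bad
    with a warning.
    """
    rr = np.asarray(rr_intervals, dtype=float)
    if rr.size < 10:
        warnings.warn("fewer than 10 intervals: quality indeterminate, all flagged bad")
        return np.zeros(rr.size, dtype=bool), 1.0 if rr.size else 0.0
    seg_ids = np.arange(rr.size) // max(10, segment_len)
    mask = np.ones(rr.size, dtype=bool)
    for seg in np.unique(seg_ids):
        sel = seg_ids == seg
        vals = rr[sel]
        if robust:
            center = np.median(vals)
            scale = 1.4826 * np.median(np.abs(vals - center))
        else:
            center = vals.mean()
            scale = vals.std(ddof=1) if vals.size > 1 else 0.0
        if scale == 0:
            continue
        mask[sel] = np.abs(vals - center) / scale <= z_threshold
    return mask, float(1.0 - mask.mean())
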