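"""HRV (time-domain and nonlinear) and QRS morphology features.

Per-beat quantities are computed inside an :class:`~tbivitals.types.AnalysisWindow`
(15 or 60 minutes from TRU arrival) and each per-beat series is summarized
by its quartiles, minimum, maximum, and Shannon entropy, mirroring how the
beat-level measurements enter the window-level feature vector.

Conventions: SDNN and RMSSD use the sample (n-1) standard deviation;
quartiles use linear interpolation between order statistics (the type-7
convention, numpy's default); Shannon entropy is in bits over 16 equal-width
histogram bins between the series minimum and maximum (a degenerate series
has entropy 0).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from tbivitals.signal_processing import zscore_quality_mask
from tbivitals.types import (
    AnalysisWindow,
    BeatAnnotations,
    InputError,
    WaveformRecord,
    WindowRejectedError,
)

__all__ = [
    "nn_intervals",
    "hrv_time_domain",
    "hrv_nonlinear",
    "sample_entropy",
    "qrs_morphology",
    "summarize",
    "apply_interval_quality",
    "extract_ecg_features",
]

N_ENTROPY_BINS = 16
SUMMARY_NAMES = ("q1", "median", "q3", "min", "max", "entropy")


def apply_interval_quality(
    annotations: BeatAnnotations,
    z_threshold: float = 3.0,
    robust: bool = True,
) -> BeatAnnotations:
    """Mark beats adjoining a Z-test-flagged interval as bad quality.

    The Z-test operates on inter-beat intervals; a flagged interval implies
    at least one of its two bounding beats is unreliable, so both are
    conservatively masked. Returns a new annotation object whose quality is
    the AND of the input quality and the interval-based mask.
    """
    times_ms = annotations.anchor_times * 1000.0
    if times_ms.size < 2:
        return annotations
    intervals = np.diff(times_ms)
    good_iv, _ = zscore_quality_mask(intervals, z_threshold=z_threshold, robust=robust)
    beat_good = np.ones(times_ms.size, dtype=bool)
    beat_good[:-1] &= good_iv
    beat_good[1:] &= good_iv
    return BeatAnnotations(
        dict(annotations.fiducials),
        annotations.quality & beat_good,
        annotations.channel,
        annotations.fs,
        annotations.t0,
    )


def nn_intervals(annotations: BeatAnnotations, window: AnalysisWindow) -> np.ndarray:
    """NN intervals (ms) between consecutive good beats inside a window.

    An interval is kept only if both bounding beats are good and lie inside
    the window, so no interval spans a masked beat. Raises
    :class:`WindowRejectedError` when fewer than ``window.min_good_beats``
    good beats fall in the window.
    """
    times = annotations.anchor_times
    in_win = window.contains(times)
    good = annotations.quality & in_win
    if good.sum() < window.min_good_beats:
        raise WindowRejectedError(
            f"window [{window.start}, {window.end}) s holds {int(good.sum())} good "
            f"beats, fewer than the required {window.min_good_beats}"
        )
    valid = good[:-1] & good[1:]
    return np.diff(times * 1000.0)[valid]


def hrv_time_domain(nn: np.ndarray) -> dict[str, float]:
    """Time-domain HRV: mean NN, SDNN, RMSSD, pNN50 (%), CV of NN."""
    nn = np.asarray(nn, dtype=float)
    if nn.size < 2:
        raise InputError("sdnn requires at least 2 NN intervals")
    if nn.size < 3:
        raise InputError("rmssd requires at least 3 NN intervals")
    diffs = np.diff(nn)
    mean_nn = float(nn.mean())
    sdnn = float(nn.std(ddof=1))
    return {
        "mean_nn": mean_nn,
        "sdnn": sdnn,
        "rmssd": float(np.sqrt(np.mean(diffs**2))),
        "pnn50": float(100.0 * np.mean(np.abs(diffs) > 50.0)),
        "cv_nn": sdnn / mean_nn,
    }


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy SampEn(m, r) with Chebyshev distance.

    ``r`` defaults to 0.2 times the sample SD. Self-matches are excluded;
    returns ``-ln(A/B)`` where B counts template matches of length ``m`` and
    A of length ``m+1``. Raises :class:`InputError` when no matches exist or
    ``r`` is zero (constant series).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < m + 2:
        raise InputError("series too short for sample entropy")
    if r is None:
        r = 0.2 * x.std(ddof=1)
    if r <= 0:
        raise InputError("sample entropy undefined for zero tolerance (constant series)")

    def _count(mm: int) -> int:
        templ = np.lib.stride_tricks.sliding_window_view(x, mm)
        total = 0
        # chunked pairwise Chebyshev comparison, O(n^2) memory-bounded
        step = max(1, 2_000_000 // max(1, templ.shape[0] * mm))
        for i0 in range(0, templ.shape[0], step):
            blk = templ[i0 : i0 + step]
            d = np.abs(blk[:, None, :] - templ[None, :, :]).max(axis=2)
            total += int((d <= r).sum()) - blk.shape[0]  # exclude self-matches
        return total

    b = _count(m)
    a = _count(m + 1)
    if b == 0 or a == 0:
        raise InputError("no template matches; sample entropy undefined at this tolerance")
    return float(-np.log(a / b))


def hrv_nonlinear(nn: np.ndarray) -> dict[str, float]:
    """Nonlinear HRV: Poincaré SD1/SD2 and sample entropy (m=2, r=0.2*SD).

    SD1 is the short-axis spread of the Poincaré cloud,
    ``sqrt(var(successive diffs)/2)``; SD2 the long axis,
    ``sqrt(2*var(NN) - SD1^2)``. Metrics whose preconditions fail (fewer
    than 10 intervals for Poincaré, 100 for sample entropy, or a constant
    series) are omitted from the result with a warning rather than
    NaN-filled.
    """
    nn = np.asarray(nn, dtype=float)
    out: dict[str, float] = {}
    if nn.size < 10:
        warnings.warn("fewer than 10 intervals: Poincaré SD1/SD2 omitted")
    else:
        # population-variance convention: SD1 is then exactly the spread of
        # the Poincaré cloud along the line of identity's normal
        sd1_sq = np.var(np.diff(nn)) / 2.0
        out["sd1"] = float(np.sqrt(sd1_sq))
        out["sd2"] = float(np.sqrt(max(2.0 * np.var(nn) - sd1_sq, 0.0)))
    if nn.size < 100:
        warnings.warn("fewer than 100 intervals: sample entropy omitted")
    else:
        try:
            out["sampen"] = sample_entropy(nn, m=2)
        except InputError as exc:
            warnings.warn(f"sample entropy omitted: {exc}")
    return out


def qrs_morphology(
    record: WaveformRecord,
    annotations: BeatAnnotations,
    window: AnalysisWindow,
) -> pd.DataFrame:
    """Per-beat QRS geometry: Q->R rise and R->S fall, in time and amplitude.

    Rise/fall times are fiducial time differences in ms; amplitudes are
    signal-value differences. Beats with non-positive time differences are
    dropped (count in ``frame.attrs['n_dropped']``); only good beats inside
    the window are measured.
    """
    fs = record.fs
    x = record.samples
    times = annotations.anchor_times
    keep = annotations.quality & window.contains(times)
    q = annotations.fiducials["q"][keep]
    r = annotations.fiducials["r"][keep]
    s = annotations.fiducials["s"][keep]
    rise_t = (r - q) * 1000.0 / fs
    fall_t = (s - r) * 1000.0 / fs
    ok = (rise_t > 0) & (fall_t > 0)
    frame = pd.DataFrame(
        {
            "beat_time": times[keep][ok],
            "qr_rise_time": rise_t[ok],
            "rs_fall_time": fall_t[ok],
            "qr_rise_amp": x[r[ok]] - x[q[ok]],
            "rs_fall_amp": x[r[ok]] - x[s[ok]],
        }
    )
    frame.attrs["n_dropped"] = int((~ok).sum())
    return frame


def summarize(series: np.ndarray, n_bins: int = N_ENTROPY_BINS) -> dict[str, float]:
    """Quartiles, extremes, and Shannon entropy of a per-beat series.

    Entropy is in bits, from a histogram of ``n_bins`` equal-width bins
    between the series min and max; a constant series has entropy 0.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise InputError("cannot summarize an empty series")
    q1, med, q3 = np.percentile(series, [25, 50, 75])
    lo, hi = float(series.min()), float(series.max())
    # ranges at float-noise level are degenerate, not informative spread
    if hi - lo <= 1e-9 * max(abs(hi), abs(lo), 1.0):
        entropy = 0.0
    else:
        counts, _ = np.histogram(series, bins=n_bins, range=(lo, hi))
        p = counts[counts > 0] / series.size
        entropy = float(-(p * np.log2(p)).sum())
    return {"q1": float(q1), "median": float(med), "q3": float(q3), "min": lo, "max": hi, "entropy": entropy}


def _summarize_into(features: dict, series: np.ndarray, base: str) -> None:
    for name, value in summarize(series).items():
        features[f"{base}_{name}"] = value


def extract_ecg_features(
    record: WaveformRecord,
    window: AnalysisWindow,
    z_threshold: float = 3.0,
    prefix: str = "ecg",
) -> dict[str, float]:
    """Full ECG feature vector for one window.

    Runs detection, delineation, and interval-quality masking, then emits
    HRV metrics plus the summarized NN-interval and QRS-morphology series as
    a flat ``{feature_id: value}`` map (ids like ``ecg_nn_sdnn``,
    ``ecg_qr_rise_time_q3``). No NaNs: metrics that cannot be computed are
    omitted.
    """
    from tbivitals.signal_processing import delineate_pqrst, detect_r_peaks

    r_peaks = detect_r_peaks(record)
    ann = delineate_pqrst(record, r_peaks)
    ann = apply_interval_quality(ann, z_threshold=z_threshold)
    nn = nn_intervals(ann, window)
    features: dict[str, float] = {}
    for name, value in hrv_time_domain(nn).items():
        features[f"{prefix}_nn_{name}"] = value
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, value in hrv_nonlinear(nn).items():
            features[f"{prefix}_nn_{name}"] = value
    _summarize_into(features, nn, f"{prefix}_nn")
    morph = qrs_morphology(record, ann, window)
    if len(morph):
        for col in ("qr_rise_time", "rs_fall_time", "qr_rise_amp", "rs_fall_amp"):
            _summarize_into(features, morph[col].to_numpy(), f"{prefix}_{col}")
    return features
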