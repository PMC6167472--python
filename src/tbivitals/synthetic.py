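"""Synthetic ECG/PPG waveforms and patient cohorts with known ground truth.

Every downstream stage (beat detection, delineation, feature extraction,
cohort assembly, modeling) is exercised against output of this module, so
each generator exposes its ground truth analytically: beat times, fiducial
geometry, notch position, and — for cohorts — the generating logistic
coefficients and the analytic AUROC of the generating score.

The generators are deliberately simple stand-ins, not physiological models:
the inter-beat process is sinusoidal modulation plus white noise, the ECG is
a sum of Gaussian bumps per fiducial, and the PPG pulse is a smooth
rise/decay template with an explicit Gaussian notch dip. See the methods
note for what these do and do not emulate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, ndtri
from scipy.stats import norm

from tbivitals.types import GenerationError, ParameterError, WaveformRecord

__all__ = [
    "RRGenParams",
    "MorphParams",
    "CohortGenParams",
    "simulate_rr_series",
    "synthesize_ecg",
    "synthesize_ppg",
    "ecg_fiducial_truth",
    "ppg_fiducial_truth",
    "inject_artifacts",
    "simulate_cohort",
    "simulate_binormal_scores",
    "simulate_mortality_outcome",
]


@dataclass(frozen=True)
class RRGenParams:
    """Parameters of the inter-beat (NN) interval generator.

    ``sdnn_target`` is hit exactly on the realized sample (the deviation
    series is rescaled); ``rmssd_target`` steers the split between white
    noise (fast variability) and slow sinusoidal modulation and is only
    approximate.
    """

    mean_rr: float = 800.0  # ms
    sdnn_target: float = 50.0  # ms
    rmssd_target: float = 35.0  # ms
    n_beats: int = 1000
    respiratory_mod_freq: float = 0.25  # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.mean_rr > 0:
            raise ParameterError("mean_rr must be > 0")
        if self.sdnn_target < 0 or self.rmssd_target < 0:
            raise ParameterError("variability targets must be >= 0")
        if self.n_beats < 2:
            raise ParameterError("n_beats must be >= 2")
        if not self.respiratory_mod_freq > 0:
            raise ParameterError("respiratory_mod_freq must be > 0")


@dataclass(frozen=True)
class MorphParams:
    """Waveform template geometry for both channels.

    ECG amplitudes are the depths/heights of the Gaussian fiducial bumps
    (signal units); PPG geometry is expressed as fractions of the pulse
    period so it scales with heart rate.
    """

    qrs_width: float = 80.0  # ms, Q-to-S support of the QRS complex
    q_depth: float = 0.15
    r_amp: float = 1.0
    s_depth: float = 0.25
    p_t_amplitudes: tuple[float, float] = (0.15, 0.3)
    ppg_rise_frac: float = 0.3
    notch_delay_frac: float = 0.45
    notch_depth_frac: float = 0.15
    amplitude_jitter_cv: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.ppg_rise_frac < 1:
            raise ParameterError("ppg_rise_frac must be in (0, 1)")
        if not 0 < self.notch_delay_frac < 1:
            raise ParameterError("notch_delay_frac must be in (0, 1)")
        if not 0 <= self.notch_depth_frac < 1:
            raise ParameterError("notch_depth_frac must be in [0, 1)")
        if self.notch_depth_frac > 0 and self.notch_delay_frac <= self.ppg_rise_frac:
            raise ParameterError(
                "a dicrotic notch must fall after the systolic peak: "
                "notch_delay_frac must exceed ppg_rise_frac"
            )
        if not self.qrs_width > 0:
            raise ParameterError("qrs_width must be > 0")
        if self.amplitude_jitter_cv < 0:
            raise ParameterError("amplitude_jitter_cv must be >= 0")


@dataclass(frozen=True)
class CohortGenParams:
    """Parameters of the synthetic patient cohort.

    ``true_coefficients`` maps feature name -> log-odds per unit of the
    (standard-normal) feature; the intercept is solved so the marginal ND
    prevalence equals ``nd_prevalence``.
    """

    n_patients: int = 200
    nd_prevalence: float = 0.17
    true_coefficients: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.nd_prevalence < 1:
            raise ParameterError("nd_prevalence must be in (0, 1)")
        if self.n_patients < 20:
            raise ParameterError("n_patients must be >= 20")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


def simulate_rr_series(params: RRGenParams) -> tuple[np.ndarray, np.ndarray]:
    """Simulate beat times and RR intervals.

    The deviation from ``mean_rr`` is a respiratory sinusoid (at
    ``respiratory_mod_freq``), a slow ~0.1 Hz sinusoid, and white noise,
    rescaled so the realized sample SDNN equals ``sdnn_target``.

    Returns
    -------
    beat_times : ndarray
        Beat times in seconds, starting at 0; length ``n_beats``.
    rr : ndarray
        The ``n_beats - 1`` inter-beat intervals in milliseconds.
    """
    n_int = params.n_beats - 1
    rng = np.random.default_rng(params.seed)
    if params.sdnn_target == 0:
        rr = np.full(n_int, params.mean_rr)
    else:
        # nominal beat times set the modulation phases; feedback of RR onto
        # the phase is a second-order effect we ignore
        t_nom = np.arange(n_int) * params.mean_rr / 1000.0
        resp = np.sin(2 * np.pi * params.respiratory_mod_freq * t_nom + rng.uniform(0, 2 * np.pi))
        slow = np.sin(2 * np.pi * 0.1 * t_nom + rng.uniform(0, 2 * np.pi))
        white = rng.standard_normal(n_int)
        # Allocate variance across components to approximate rmssd_target.
        # A component of variance v contributes g*v to the mean squared
        # successive difference: g = 2 for white noise, g = 4*sin^2(pi*f*dt)
        # for a sinusoid at frequency f sampled every dt.
        dt = params.mean_rr / 1000.0
        g_resp = 4 * math.sin(math.pi * params.respiratory_mod_freq * dt) ** 2
        g_slow = 4 * math.sin(math.pi * 0.1 * dt) ** 2
        ratio = (params.rmssd_target / params.sdnn_target) ** 2
        w_resp = 0.5
        w_white = (ratio - w_resp * g_resp - (1 - w_resp) * g_slow) / (2.0 - g_slow)
        if w_white >= 0:
            w_slow = max(0.0, 1.0 - w_resp - w_white)
            if w_slow == 0.0:  # very fast variability: trade resp for white
                w_white = min(1.0, (ratio - g_resp) / (2.0 - g_resp)) if g_resp < 2 else 1.0
                w_white = max(0.0, w_white)
                w_resp = 1.0 - w_white
        else:  # slow variability dominates: no white noise, shrink resp
            w_white = 0.0
            denom = g_resp - g_slow
            w_resp = min(1.0, max(0.0, (ratio - g_slow) / denom)) if denom else 0.0
            w_slow = 1.0 - w_resp
        dev = (
            math.sqrt(2 * w_resp) * resp
            + math.sqrt(2 * w_slow) * slow
            + math.sqrt(w_white) * white
        )
        dev = dev - dev.mean()
        sd = dev.std(ddof=1)
        if sd > 0:
            dev *= params.sdnn_target / sd
        rr = params.mean_rr + dev
        # keep intervals physiological; only triggered at extreme targets
        rr = np.clip(rr, 0.25 * params.mean_rr, None)
    beat_times = np.concatenate([[0.0], np.cumsum(rr) / 1000.0])
    return beat_times, rr


# ECG fiducial layout relative to the R wave: (offset, sigma, amplitude sign)
# offsets/sigmas of P and T are fixed in seconds; Q, R, S scale with qrs_width.
_P_OFFSET, _P_SIGMA = -0.16, 0.025
_T_OFFSET, _T_SIGMA = 0.25, 0.05


def _ecg_layout(morph: MorphParams) -> dict[str, tuple[float, float, float]]:
    qw = morph.qrs_width / 1000.0
    return {
        "p": (_P_OFFSET, _P_SIGMA, morph.p_t_amplitudes[0]),
        "q": (-0.375 * qw, qw / 7.0, -morph.q_depth),
        "r": (0.0, qw / 10.0, morph.r_amp),
        "s": (0.375 * qw, qw / 7.0, -morph.s_depth),
        "t": (_T_OFFSET, _T_SIGMA, morph.p_t_amplitudes[1]),
    }


def ecg_fiducial_truth(beat_times: np.ndarray, morph: MorphParams, fs: float) -> dict[str, np.ndarray]:
    """Ground-truth fiducial sample indices for :func:`synthesize_ecg`."""
    beat_times = np.asarray(beat_times, dtype=float)
    layout = _ecg_layout(morph)
    return {
        name: np.rint((beat_times + off) * fs).astype(int)
        for name, (off, _sig, _amp) in layout.items()
    }


def _check_beat_times(beat_times: np.ndarray, fs: float) -> np.ndarray:
    beat_times = np.asarray(beat_times, dtype=float)
    if fs < 100:
        raise ParameterError("fs must be >= 100 Hz")
    if beat_times.size > 1 and not np.all(np.diff(beat_times) > 0):
        raise ParameterError("beat_times must be strictly increasing")
    return beat_times


def synthesize_ecg(
    beat_times: np.ndarray,
    morph: MorphParams = MorphParams(),
    fs: float = 240.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    t0: float = 0.0,
) -> WaveformRecord:
    """Render one PQRST complex per beat time as a sum of Gaussian bumps.

    With ``noise_sd = 0`` the R-peak sample of every complex lies within one
    sample of its beat time, and the Q and S bump depths equal ``q_depth``
    and ``s_depth`` up to ~1% cross-talk between neighbouring bumps.
    """
    beat_times = _check_beat_times(beat_times, fs)
    if beat_times.size == 0:
        return WaveformRecord(np.empty(0), fs, "ECG", t0)
    if beat_times.size > 1:
        min_rr = float(np.min(np.diff(beat_times)))
        if min_rr < 1.5 * morph.qrs_width / 1000.0:
            raise GenerationError(
                f"beats {min_rr * 1000:.0f} ms apart overlap within the "
                f"{morph.qrs_width:.0f} ms QRS support"
            )
    rng = np.random.default_rng(seed)
    n = int(round((beat_times[-1] + 0.6) * fs)) + 1
    t = np.arange(n) / fs
    x = np.zeros(n)
    layout = _ecg_layout(morph)
    scales = 1.0 + morph.amplitude_jitter_cv * rng.standard_normal(beat_times.size)
    for bt, sc in zip(beat_times, scales):
        lo = max(0, int((bt - 0.4) * fs))
        hi = min(n, int((bt + 0.5) * fs) + 1)
        seg = t[lo:hi]
        for off, sig, amp in layout.values():
            x[lo:hi] += sc * amp * np.exp(-0.5 * ((seg - bt - off) / sig) ** 2)
    if noise_sd > 0:
        x += noise_sd * rng.standard_normal(n)
    return WaveformRecord(x, fs, "ECG", t0)


def _ppg_pulse(tau: np.ndarray, period: float, morph: MorphParams, amp: float) -> np.ndarray:
    """One PPG pulse on [0, period): sin^2 upstroke, cos^2 decay, Gaussian notch dip."""
    tr = morph.ppg_rise_frac * period
    y = np.where(
        tau < tr,
        np.sin(0.5 * np.pi * tau / tr) ** 2,
        np.cos(0.5 * np.pi * (tau - tr) / (period - tr)) ** 2,
    )
    if morph.notch_depth_frac > 0:
        t_notch = morph.notch_delay_frac * period
        sigma = 0.025 * period
        y = y - morph.notch_depth_frac * np.exp(-0.5 * ((tau - t_notch) / sigma) ** 2)
    return amp * y


def ppg_fiducial_truth(beat_times: np.ndarray, morph: MorphParams, fs: float) -> dict[str, np.ndarray]:
    """Ground-truth foot/peak/notch sample indices for :func:`synthesize_ppg`.

    ``notch`` entries are -1 when ``notch_depth_frac`` is 0.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size == 0:
        empty = np.empty(0, dtype=int)
        return {"foot": empty, "peak": empty.copy(), "notch": empty.copy()}
    periods = np.diff(beat_times)
    last = periods[-1] if periods.size else 0.8
    periods = np.concatenate([periods, [last]])
    foot = np.rint(beat_times * fs).astype(int)
    peak = np.rint((beat_times + morph.ppg_rise_frac * periods) * fs).astype(int)
    if morph.notch_depth_frac > 0:
        notch = np.rint((beat_times + morph.notch_delay_frac * periods) * fs).astype(int)
    else:
        notch = np.full(beat_times.size, -1, dtype=int)
    return {"foot": foot, "peak": peak, "notch": notch}


def synthesize_ppg(
    beat_times: np.ndarray,
    morph: MorphParams = MorphParams(),
    fs: float = 240.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    t0: float = 0.0,
) -> WaveformRecord:
    """Render one pulse per beat time.

    Each pulse starts at its beat time (the pulse foot, amplitude 0), peaks
    at ``ppg_rise_frac`` of the pulse period, decays smoothly back to 0, and
    carries a dicrotic notch at ``notch_delay_frac`` of the period with
    relative depth ``notch_depth_frac``.
    """
    beat_times = _check_beat_times(beat_times, fs)
    if beat_times.size == 0:
        return WaveformRecord(np.empty(0), fs, "PPG", t0)
    periods = np.diff(beat_times)
    if periods.size and np.min(periods) < 0.2:
        raise GenerationError("pulse periods below 200 ms are not supported")
    last = periods[-1] if periods.size else 0.8
    periods = np.concatenate([periods, [last]])
    rng = np.random.default_rng(seed)
    n = int(round((beat_times[-1] + periods[-1]) * fs)) + 1
    t = np.arange(n) / fs
    x = np.zeros(n)
    amps = 1.0 + morph.amplitude_jitter_cv * rng.standard_normal(beat_times.size)
    for bt, period, amp in zip(beat_times, periods, amps):
        lo = int(np.ceil(bt * fs))
        hi = min(n, int(np.ceil((bt + period) * fs)))
        if hi <= lo:
            continue
        x[lo:hi] = _ppg_pulse(t[lo:hi] - bt, period, morph, amp)
    if noise_sd > 0:
        x += noise_sd * rng.standard_normal(n)
    return WaveformRecord(x, fs, "PPG", t0)


_ARTIFACT_KINDS = ("dropout", "spike", "baseline_wander")


def inject_artifacts(
    record: WaveformRecord,
    kind: str,
    spec: dict,
    seed: int = 0,
) -> WaveformRecord:
    """Corrupt a copy of ``record`` inside a declared span.

    ``kind`` is one of ``dropout`` (flatline at the span's first value;
    ``spec = {"start": s, "duration": s}``), ``spike`` (one-sample
    deflection; ``spec = {"time": s, "amplitude": u}``), or
    ``baseline_wander`` (additive low-frequency sinusoid;
    ``spec = {"start", "duration", "freq", "amplitude"}``). Samples outside
    the span are bit-identical to the input.
    """
    if kind not in _ARTIFACT_KINDS:
        raise ParameterError(f"unknown artifact kind {kind!r}")
    x = record.samples.copy()
    n = x.size
    fs = record.fs

    def _span(start: float, duration: float) -> tuple[int, int]:
        i0 = int(round(start * fs))
        i1 = int(round((start + duration) * fs))
        if start < 0 or duration <= 0 or i1 > n:
            raise ParameterError("artifact span outside record")
        return i0, i1

    if kind == "dropout":
        i0, i1 = _span(spec["start"], spec["duration"])
        x[i0:i1] = x[i0]
    elif kind == "spike":
        i = int(round(spec["time"] * fs))
        if not 0 <= i < n:
            raise ParameterError("artifact span outside record")
        x[i] += spec["amplitude"]
    else:  # baseline_wander
        i0, i1 = _span(spec["start"], spec["duration"])
        tt = np.arange(i1 - i0) / fs
        x[i0:i1] += spec["amplitude"] * np.sin(2 * np.pi * spec["freq"] * tt)
    return WaveformRecord(x, fs, record.channel, record.t0)


def _solve_intercept(prevalence: float, score_sd: float) -> float:
    """Intercept b0 with E[expit(b0 + s)] = prevalence for s ~ N(0, score_sd^2)."""
    if score_sd == 0:
        return float(np.log(prevalence / (1 - prevalence)))
    nodes, weights = np.polynomial.hermite_e.hermegauss(80)

    def marginal(b0: float) -> float:
        return float(weights @ expit(b0 + score_sd * nodes) / weights.sum() - prevalence)

    return float(brentq(marginal, -30, 30))


def _analytic_auroc(intercept: float, score_sd: float) -> float:
    """AUROC of the generating score s ~ N(0, sd^2) against y ~ Bern(expit(b0+s)).

    Computed by numerical integration of P(s_case > s_control); the score is
    continuous so ties have probability zero.
    """
    if score_sd == 0:
        return 0.5
    s = np.linspace(-8 * score_sd, 8 * score_sd, 8001)
    phi = norm.pdf(s, scale=score_sd)
    p = expit(intercept + s)
    f1 = phi * p
    f0 = phi * (1 - p)
    f1 /= np.trapezoid(f1, s)
    f0 /= np.trapezoid(f0, s)
    from scipy.integrate import cumulative_trapezoid

    cdf0 = cumulative_trapezoid(f0, s, initial=0.0)
    return float(np.trapezoid(f1 * cdf0, s))


def simulate_cohort(
    params: CohortGenParams,
    feature_schema: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a feature table and cohort table with a known ND model.

    Features are i.i.d. standard normal; the ND label is drawn
    ``Bernoulli(expit(b0 + X @ beta))`` with ``beta`` from
    ``true_coefficients`` (zero for schema features not named) and ``b0``
    solved so the marginal prevalence equals ``nd_prevalence``. When
    ``noise_sd > 0`` the *stored* features carry additive measurement noise
    while the outcome is generated from the noise-free values.

    Returns
    -------
    features : DataFrame
        ``patient_id`` plus one column per schema feature. Its ``attrs``
        carry ``true_coefficients``, ``intercept``, ``analytic_auroc``
        (AUROC of the generating score, by numerical integration), and the
        generating score itself under ``true_score``.
    cohort : DataFrame
        ``patient_id``, ``nd`` (0/1), and ``nd_probability``.
    """
    if not feature_schema:
        raise ParameterError("feature_schema must not be empty")
    unknown = set(params.true_coefficients) - set(feature_schema)
    if unknown:
        raise ParameterError(f"true_coefficients name features outside the schema: {sorted(unknown)}")
    rng = np.random.default_rng(params.seed)
    n, p = params.n_patients, len(feature_schema)
    X = rng.standard_normal((n, p))
    beta = np.array([params.true_coefficients.get(f, 0.0) for f in feature_schema])
    score = X @ beta
    score_sd = float(np.linalg.norm(beta))
    b0 = _solve_intercept(params.nd_prevalence, score_sd)
    prob = expit(b0 + score)
    nd = (rng.uniform(size=n) < prob).astype(int)
    X_obs = X + params.noise_sd * rng.standard_normal((n, p)) if params.noise_sd else X
    ids = [f"P{i:05d}" for i in range(n)]
    features = pd.DataFrame(X_obs, columns=feature_schema)
    features.insert(0, "patient_id", ids)
    features.attrs.update(
        true_coefficients=dict(params.true_coefficients),
        intercept=b0,
        analytic_auroc=_analytic_auroc(b0, score_sd),
        true_score=score,
    )
    cohort = pd.DataFrame({"patient_id": ids, "nd": nd, "nd_probability": prob})
    return features, cohort


def simulate_binormal_scores(
    n: int,
    auroc: float = 0.8,
    prevalence: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Scores from the equal-variance binormal model with a given AUROC.

    Controls are N(0,1), cases are N(d', 1) with d' = sqrt(2) * Phi^{-1}(AUROC),
    so the analytic AUROC is exactly ``auroc``.
    """
    if not 0.5 <= auroc < 1:
        raise ParameterError("auroc must be in [0.5, 1)")
    rng = np.random.default_rng(seed)
    labels = (rng.uniform(size=n) < prevalence).astype(int)
    d_prime = math.sqrt(2) * ndtri(auroc)
    scores = rng.standard_normal(n) + d_prime * labels
    return scores, labels


def simulate_mortality_outcome(
    data: pd.DataFrame,
    coefficients: dict[str, float],
    prevalence: float,
    seed: int = 0,
) -> np.ndarray:
    """Draw a binary outcome from a logistic model over columns of ``data``.

    Covariates are used as stored (not standardized); the intercept is
    solved on the realized linear predictor so the expected prevalence
    matches ``prevalence``.
    """
    missing = set(coefficients) - set(data.columns)
    if missing:
        raise ParameterError(f"coefficients name absent columns: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    lp = np.zeros(len(data))
    for name, coef in coefficients.items():
        lp += coef * data[name].to_numpy(dtype=float)

    def marginal(b0: float) -> float:
        return float(expit(b0 + lp).mean() - prevalence)

    b0 = float(brentq(marginal, -40, 40))
    return (rng.uniform(size=len(data)) < expit(b0 + lp)).astype(int)
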