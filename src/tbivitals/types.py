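"""Shared containers and exceptions.

Conventions used throughout the package: time is seconds from arrival in
the trauma resuscitation unit (TRU), sample indices are 0-based, interval
units are milliseconds, and waveform amplitudes are arbitrary signal units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ParameterError(ValueError):
    """Invalid generator or algorithm parameters."""


class GenerationError(RuntimeError):
    """A simulator cannot produce a well-formed signal for these inputs."""


class InputError(ValueError):
    """Invalid data handed to a processing or modeling operation."""


class WindowRejectedError(InputError):
    """An analysis window holds too few good beats to yield features."""


@dataclass(frozen=True)
class WaveformRecord:
    """A uniformly sampled physiological signal.

    Parameters
    ----------
    samples : ndarray
        Signal values (arbitrary units); must be finite.
    fs : float
        Sampling rate in Hz, > 0.
    channel : str
        ``"ECG"`` or ``"PPG"``.
    t0 : float
        Record start, seconds from TRU admission.
    """

    samples: np.ndarray
    fs: float
    channel: str
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if not self.fs > 0:
            raise ParameterError(f"fs must be > 0, got {self.fs}")
        if self.channel not in ("ECG", "PPG"):
            raise ParameterError(f"channel must be ECG or PPG, got {self.channel!r}")
        if samples.size and not np.all(np.isfinite(samples)):
            raise ParameterError("samples must be finite")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Per-sample times, seconds from TRU admission."""
        return self.t0 + np.arange(self.samples.size) / self.fs


@dataclass
class BeatAnnotations:
    """Per-beat fiducial sample indices with a quality flag.

    ECG annotations carry fiducials ``p, q, r, s, t``; PPG annotations carry
    ``foot, peak`` (and optionally ``notch``, -1 where absent). All fiducial
    arrays have one entry per beat; within a beat the fiducials are strictly
    increasing, and the anchor fiducial (R or systolic peak) is strictly
    increasing across beats.
    """

    fiducials: dict[str, np.ndarray]
    quality: np.ndarray
    channel: str
    fs: float
    t0: float = 0.0

    _ORDER = {"ECG": ("p", "q", "r", "s", "t"), "PPG": ("foot", "peak", "notch")}

    def __post_init__(self) -> None:
        self.fiducials = {k: np.asarray(v, dtype=int) for k, v in self.fiducials.items()}
        self.quality = np.asarray(self.quality, dtype=bool)
        n = self.n_beats
        for name, idx in self.fiducials.items():
            if idx.size != n:
                raise InputError(f"fiducial {name!r} has {idx.size} entries, expected {n}")
        anchor = self.anchor_indices
        if anchor.size > 1 and not np.all(np.diff(anchor) > 0):
            raise InputError("anchor fiducials must be strictly increasing across beats")

    @property
    def n_beats(self) -> int:
        return self.quality.size

    @property
    def anchor_indices(self) -> np.ndarray:
        """R-peak (ECG) or systolic-peak (PPG) sample indices."""
        key = "r" if self.channel == "ECG" else "peak"
        return self.fiducials.get(key, np.empty(0, dtype=int))

    @property
    def anchor_times(self) -> np.ndarray:
        """Anchor fiducial times, seconds from TRU admission."""
        return self.t0 + self.anchor_indices / self.fs

    def to_frame(self) -> pd.DataFrame:
        """Annotations as a table (one row per beat), for CSV export."""
        data = {"beat": np.arange(self.n_beats)}
        for name in self._ORDER.get(self.channel, sorted(self.fiducials)):
            if name in self.fiducials:
                data[name] = self.fiducials[name]
        data["quality"] = self.quality.astype(int)
        return pd.DataFrame(data)


@dataclass(frozen=True)
class AnalysisWindow:
    """Analysis window over which per-beat series are summarized.

    The study windows are the first 15 and 60 minutes after TRU arrival
    (900 s and 3600 s starting at 0).
    """

    start: float = 0.0
    duration: float = 900.0
    min_good_beats: int = 30

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ParameterError("window start must be >= 0")
        if self.duration <= 0:
            raise ParameterError("window duration must be > 0")

    @property
    def end(self) -> float:
        return self.start + self.duration

    def contains(self, times: np.ndarray) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        return (times >= self.start) & (times < self.end)


WINDOW_15MIN = AnalysisWindow(0.0, 900.0)
WINDOW_60MIN = AnalysisWindow(0.0, 3600.0)
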