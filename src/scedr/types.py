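"""Core data containers for cardiorespiratory signal analysis.

Signals live in small dataclasses wrapping numpy arrays; tabular results
(epoch tables, band-power summaries) are plain pandas DataFrames produced
by the analysis functions.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Confidence labels for breathing-rate samples.
TRACKED = "tracked"
GAP_BRIDGED = "gap-bridged"

#: Hypnogram vocabulary: eyes-closed wake, NREM 1-3, REM and the putative REM0.
STAGE_LABELS = ("ECW", "N1", "N2", "N3", "REM", "REM0")


class NoBeatsError(ValueError):
    """Raised when no heart beats can be detected in an ECG segment."""


class NoRespiratoryComponentError(ValueError):
    """Raised when no spectral track can be attributed to breathing."""


@dataclass
class ECGSignal:
    """Single-lead ECG trace in millivolts."""

    samples: np.ndarray
    sample_rate_hz: float
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate_hz < 100.0:
            raise ValueError(
                f"ECG sample rate {self.sample_rate_hz} Hz too low for R detection (need >= 100 Hz)"
            )

    @property
    def times_s(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.samples.size) / self.sample_rate_hz


@dataclass
class FlowSignal:
    """Nasal-pressure airflow trace (arbitrary pressure units)."""

    samples: np.ndarray
    sample_rate_hz: float
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("flow signal contains non-finite samples")

    @property
    def times_s(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.samples.size) / self.sample_rate_hz


@dataclass
class HeartRateSeries:
    """Instantaneous heart rate (bpm) on a strictly uniform time grid.

    ``beat_times_s`` keeps the original R-peak times so the R-R sequence can
    be recovered; it is empty for directly simulated heart rate.
    """

    hr_bpm: np.ndarray
    times_s: np.ndarray
    grid_rate_hz: float
    beat_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.hr_bpm = np.asarray(self.hr_bpm, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        if self.hr_bpm.shape != self.times_s.shape:
            raise ValueError("hr_bpm and times_s must have the same shape")
        if self.times_s.size >= 2:
            dt = np.diff(self.times_s)
            if not np.allclose(dt, 1.0 / self.grid_rate_hz, rtol=1e-6, atol=1e-9):
                raise ValueError("times_s is not a uniform grid at grid_rate_hz")

    @property
    def duration_s(self) -> float:
        return float(self.times_s[-1] - self.times_s[0]) if self.times_s.size else 0.0


@dataclass
class BreathingRateSeries:
    """Breathing rate (bpm) on a uniform grid with per-sample provenance.

    ``source`` records which extractor produced the series (``pressure``,
    ``scedr`` or ``maxpower``); ``confidence`` flags samples backed by an
    actual spectral peak (``tracked``) versus bridged gaps.
    """

    br_bpm: np.ndarray
    times_s: np.ndarray
    source: str
    confidence: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.br_bpm = np.asarray(self.br_bpm, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.source not in ("pressure", "scedr", "maxpower"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.confidence is None:
            self.confidence = np.full(self.br_bpm.shape, TRACKED, dtype=object)
        else:
            self.confidence = np.asarray(self.confidence, dtype=object)

    @property
    def f_br_hz(self) -> np.ndarray:
        """Breathing frequency in Hz (br_bpm / 60)."""
        return self.br_bpm / 60.0


@dataclass
class Hypnogram:
    """Sequence of fixed-length sleep-stage epochs (30 s scoring convention)."""

    labels: Sequence[str]
    epoch_len_s: float = 30.0
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        bad = sorted({l for l in self.labels if l not in STAGE_LABELS})
        if bad:
            raise ValueError(f"unknown stage labels: {bad}; expected one of {STAGE_LABELS}")

    def __len__(self) -> int:
        return len(self.labels)

    def epoch_bounds(self, k: int) -> tuple[float, float]:
        """Half-open [start, stop) time bounds of epoch ``k`` in seconds."""
        t0 = self.start_time_s + k * self.epoch_len_s
        return t0, t0 + self.epoch_len_s

    def epoch_of_time(self, t: float) -> int:
        return int((t - self.start_time_s) // self.epoch_len_s)
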