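"""Synthetic cardiorespiratory records with known ground truth.

The signal model is the one the continuity-based extractor assumes: heart
rate carries a respiratory sinus arrhythmia (RSA) component — a smooth
sinusoidal modulation whose instantaneous frequency is the breathing rate,
present whenever the subject breathes — plus transient interfering
oscillations of comparable or greater power in the same band, slow
low-frequency drift, and apnea windows in which the RSA (and the airflow)
vanishes.  A matched flow signal has exactly one crest per breath, and a
stereotyped-QRS ECG lets R-peak detection be exercised end to end.

Everything is deterministic given the scenario's seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .types import ECGSignal, FlowSignal, HeartRateSeries, Hypnogram

#: physiological breathing band the extractor can represent, bpm
BR_BAND_BPM = (9.0, 27.0)

# A time-varying parameter may be a constant, a list of (time_s, value)
# knots (linearly interpolated, clamped at the ends), or a callable.
Trajectory = float | Sequence[tuple[float, float]] | Callable[[np.ndarray], np.ndarray]


def as_function(traj: Trajectory) -> Callable[[np.ndarray], np.ndarray]:
    if callable(traj):
        return traj
    if np.isscalar(traj):
        value = float(traj)  # type: ignore[arg-type]
        return lambda t: np.full_like(np.asarray(t, dtype=float), value)
    knots = np.asarray(traj, dtype=float)
    return lambda t: np.interp(np.asarray(t, dtype=float), knots[:, 0], knots[:, 1])


@dataclass
class Interferer:
    """A transient sinusoidal heart-rate component competing with RSA."""

    start_s: float
    stop_s: float
    freq_hz: float
    amplitude_bpm: float


@dataclass
class SimScenario:
    """Parameters of one simulated record.

    Defaults describe a resting healthy adult: HR 70 bpm with an RSA
    modulation depth of 2 bpm around a 15-bpm breathing rate.
    """

    duration_s: float = 600.0
    hr_baseline: float = 70.0
    rsa_amplitude: Trajectory = 2.0
    br_trajectory: Trajectory = 15.0
    interferers: list[Interferer] = field(default_factory=list)
    apnea_windows: list[tuple[float, float]] = field(default_factory=list)
    lf_noise_amp: Trajectory = 0.0
    lf_noise_freq_hz: float = 0.05
    hr_white_noise_bpm: float = 0.0
    sample_rate_hz: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate_hz < 2.0:
            raise ValueError("sample_rate_hz must be >= 2 Hz")
        windows = sorted(self.apnea_windows)
        for (a0, a1), (b0, b1) in zip(windows, windows[1:]):
            if b0 < a1:
                raise ValueError("apnea windows must be disjoint")
        t = self.times()
        br = as_function(self.br_trajectory)(t)
        if np.any(br < BR_BAND_BPM[0]) or np.any(br > BR_BAND_BPM[1]):
            raise ValueError(
                f"br_trajectory leaves the representable band {BR_BAND_BPM} bpm"
            )

    def times(self) -> np.ndarray:
        n = int(round(self.duration_s * self.sample_rate_hz))
        return np.arange(n) / self.sample_rate_hz

    def apnea_mask(self, t: np.ndarray) -> np.ndarray:
        mask = np.zeros(t.shape, dtype=bool)
        for a0, a1 in self.apnea_windows:
            mask |= (t >= a0) & (t < a1)
        return mask


@dataclass
class GroundTruth:
    """What the simulator knows that an extractor must recover."""

    times_s: np.ndarray
    br_true_bpm: np.ndarray
    breath_crest_times_s: np.ndarray
    rsa_component_bpm: np.ndarray
    rsa_phase_rad: np.ndarray
    ecg_beat_times_s: np.ndarray | None = None


def simulate_heart_rate(scenario: SimScenario) -> tuple[HeartRateSeries, GroundTruth]:
    """Build HR(t) = baseline + RSA + interferers + LF drift (+ white noise).

    The RSA term is ``a(t) * sin(phi(t))`` with ``phi = 2*pi * integral of
    f_BR`` so its instantaneous frequency equals the commanded breathing
    rate exactly; it is zeroed inside apnea windows.  Breath crest times are
    the upward crossings of ``sin(phi)`` through its maxima outside apnea.
    """
    rng = np.random.default_rng(scenario.seed)
    t = scenario.times()
    br_bpm = as_function(scenario.br_trajectory)(t)
    f_br = br_bpm / 60.0
    phase = 2.0 * np.pi * cumulative_trapezoid(f_br, t, initial=0.0)

    apnea = scenario.apnea_mask(t)
    rsa = as_function(scenario.rsa_amplitude)(t) * np.sin(phase)
    rsa[apnea] = 0.0

    hr = scenario.hr_baseline + rsa
    for itf in scenario.interferers:
        active = (t >= itf.start_s) & (t < itf.stop_s)
        hr = hr + np.where(
            active, itf.amplitude_bpm * np.sin(2.0 * np.pi * itf.freq_hz * (t - itf.start_s)), 0.0
        )
    lf_phase0 = 2.0 * np.pi * rng.random()
    hr = hr + as_function(scenario.lf_noise_amp)(t) * np.sin(
        2.0 * np.pi * scenario.lf_noise_freq_hz * t + lf_phase0
    )
    if scenario.hr_white_noise_bpm > 0:
        hr = hr + scenario.hr_white_noise_bpm * rng.standard_normal(t.size)

    # crest whenever the phase passes pi/2 + 2*pi*k (sin at its maximum)
    k_first = np.ceil((phase[0] - np.pi / 2) / (2 * np.pi))
    k_last = np.floor((phase[-1] - np.pi / 2) / (2 * np.pi))
    targets = np.pi / 2 + 2 * np.pi * np.arange(k_first, k_last + 1)
    crest_times = np.interp(targets, phase, t)
    crest_times = crest_times[~scenario.apnea_mask(crest_times)]

    series = HeartRateSeries(hr, t, scenario.sample_rate_hz)
    truth = GroundTruth(t, br_bpm, crest_times, rsa, phase)
    return series, truth


def simulate_flow(ground_truth: GroundTruth, scenario: SimScenario) -> FlowSignal:
    """Unit-amplitude sinusoidal airflow with one crest per breath.

    Inside apnea windows the flow is flat apart from a small sensor-noise
    floor, so no crest is detectable there.
    """
    rng = np.random.default_rng(scenario.seed + 1)
    flow = np.sin(ground_truth.rsa_phase_rad)
    apnea = scenario.apnea_mask(ground_truth.times_s)
    flow[apnea] = 0.0
    flow = flow + 0.01 * rng.standard_normal(flow.size)
    return FlowSignal(flow, scenario.sample_rate_hz)


def simulate_ecg(
    ground_truth: GroundTruth,
    scenario: SimScenario,
    ecg_rate_hz: float = 250.0,
) -> tuple[ECGSignal, np.ndarray]:
    """Place a stereotyped QRS at integrate-and-fire beat times.

    Beats fire when the integral of HR(t)/60 crosses successive integers,
    so the reciprocal R-R intervals encode HR(t) exactly.  The QRS template
    is an 80 ms raised-cosine spike of 1 mV; morphology beyond that (P/T
    waves, ectopy) is deliberately absent.  Returns the signal and the true
    beat times.
    """
    rng = np.random.default_rng(scenario.seed + 2)
    hr_series, _ = simulate_heart_rate(scenario)
    t = hr_series.times_s
    beats_integral = cumulative_trapezoid(hr_series.hr_bpm / 60.0, t, initial=0.0)
    n_beats = int(np.floor(beats_integral[-1]))
    beat_times = np.interp(np.arange(1, n_beats + 1), beats_integral, t)

    n = int(round(scenario.duration_s * ecg_rate_hz))
    ecg = 0.01 * rng.standard_normal(n)
    half_w = 0.04  # 80 ms wide template
    tpl_n = int(round(half_w * ecg_rate_hz))
    tpl_t = np.arange(-tpl_n, tpl_n + 1) / ecg_rate_hz
    template = 0.5 * (1.0 + np.cos(np.pi * tpl_t / half_w))
    for bt in beat_times:
        c = int(round(bt * ecg_rate_hz))
        lo, hi = c - tpl_n, c + tpl_n + 1
        s0, s1 = max(lo, 0), min(hi, n)
        ecg[s0:s1] += template[s0 - lo : s1 - lo]
    ground_truth.ecg_beat_times_s = beat_times
    return ECGSignal(ecg, ecg_rate_hz), beat_times


#: per-stage (rsa_amplitude_bpm, lf_amplitude_bpm) defaults for sleep records:
#: deep NREM has strong vagal RSA and weak LF; REM/REM0 the reverse.
STAGE_AUTONOMIC = {
    "ECW": (1.5, 1.5),
    "N1": (1.8, 1.2),
    "N2": (2.2, 0.8),
    "N3": (2.5, 0.5),
    "REM": (1.2, 2.5),
    "REM0": (1.2, 2.5),
}


def sleep_scenario(
    labels: Sequence[str],
    stage_autonomic: dict[str, tuple[float, float]] | None = None,
    interferer_stages: Sequence[str] = ("REM", "REM0"),
    interferers_per_epoch: float = 0.5,
    br_trajectory: Trajectory = 15.0,
    epoch_len_s: float = 30.0,
    seed: int = 0,
    **kwargs,
) -> tuple[SimScenario, Hypnogram]:
    """Build a stage-programmed whole-record scenario from a hypnogram.

    RSA and LF-drift amplitudes follow the stage of each 30-s epoch
    (piecewise constant), and transient interferers (2x the local RSA
    amplitude, 30 s, two bins away from the breathing frequency) are placed
    at random epochs of the requested stages — emulating the movement- and
    arousal-related components that crowd the high-frequency band in REM.
    """
    rng = np.random.default_rng(seed)
    stage_autonomic = stage_autonomic or STAGE_AUTONOMIC
    edges = np.arange(len(labels) + 1) * epoch_len_s
    rsa_steps = np.array([stage_autonomic[l][0] for l in labels])
    lf_steps = np.array([stage_autonomic[l][1] for l in labels])

    def step_traj(steps: np.ndarray) -> Callable[[np.ndarray], np.ndarray]:
        return lambda t: steps[
            np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(steps) - 1)
        ]

    br_fn = as_function(br_trajectory)
    interferers = []
    for k, label in enumerate(labels):
        if label in interferer_stages and rng.random() < interferers_per_epoch:
            t0 = edges[k]
            f_true = float(br_fn(np.array([t0 + epoch_len_s / 2]))[0]) / 60.0
            # at least two 0.02 Hz bins away, staying inside 0.15-0.45 Hz
            offset = rng.choice([-1, 1]) * (0.04 + 0.04 * rng.random())
            f_itf = float(np.clip(f_true + offset, 0.16, 0.44))
            if abs(f_itf - f_true) < 0.04:
                f_itf = f_true + 0.06
            interferers.append(Interferer(t0, t0 + epoch_len_s, f_itf, 2.0 * rsa_steps[k]))

    kwargs.setdefault("lf_noise_freq_hz", 0.09)  # mid-LF, clear of band edges
    scenario = SimScenario(
        duration_s=len(labels) * epoch_len_s,
        rsa_amplitude=step_traj(rsa_steps),
        lf_noise_amp=step_traj(lf_steps),
        br_trajectory=br_trajectory,
        interferers=interferers,
        seed=seed,
        **kwargs,
    )
    return scenario, Hypnogram(list(labels), epoch_len_s)
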