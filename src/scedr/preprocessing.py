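"""Raw-channel conditioning: R peaks -> heart rate, flow crests -> breathing rate.

Both outputs land on one uniform grid (20 Hz by default, one sample per
50 ms analysis slice) so downstream epoching aligns sample-for-sample.
The instantaneous series are step-wise by construction (one value per
R-R or crest-crest interval, placed at the interval midpoint); a modified
Akima piecewise cubic smooths them onto the grid.  That choice balances
two failure modes: an unconstrained spline overshoots around artifacts
(injecting spurious spectral content into the band the wavelet analysis
searches), while strictly monotone schemes clip every extremum of a
breathing-frequency oscillation sampled at ~1 Hz beat rate, attenuating
the very RSA component the extractor needs.
"""
from __future__ import annotations

import numpy as np
from scipy.interpolate import Akima1DInterpolator
from scipy.signal import butter, find_peaks, sosfiltfilt

from .config import PreprocessConfig
from .types import TRACKED, BreathingRateSeries, ECGSignal, FlowSignal, HeartRateSeries, NoBeatsError


def detect_r_peaks(ecg: ECGSignal, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Detect R-peak times with a band-pass + derivative-energy detector.

    Pan-Tompkins-style: 5-25 Hz band-pass isolates the QRS, the squared
    derivative is integrated over 150 ms, and peaks of that energy envelope
    above an adaptive threshold mark beats.  A 270 ms refractory distance
    enforces physiologic rates (< 222 bpm); each detection is then refined
    to the local extremum of the band-passed ECG.
    """
    cfg = cfg or PreprocessConfig()
    fs = ecg.sample_rate_hz
    x = ecg.samples
    if x.size == 0 or np.ptp(x) == 0:
        raise NoBeatsError("ECG signal is empty or flat: no beats detectable")

    sos = butter(3, [5.0, 25.0], btype="bandpass", fs=fs, output="sos")
    bp = sosfiltfilt(sos, x)
    energy = np.gradient(bp) ** 2
    win = max(int(round(0.150 * fs)), 1)
    envelope = np.convolve(energy, np.ones(win) / win, mode="same")

    height = 0.15 * np.percentile(envelope, 99)
    if height <= 0:
        raise NoBeatsError("ECG energy envelope is flat: no beats detectable")
    locs, _ = find_peaks(envelope, height=height, distance=int(round(cfg.rr_valid_s[0] * fs)))
    if locs.size == 0:
        raise NoBeatsError("no QRS complexes found above the energy threshold")

    # refine each beat to the nearby band-passed extremum (R apex)
    half = int(round(0.05 * fs))
    refined = np.empty(locs.size, dtype=int)
    for i, loc in enumerate(locs):
        lo, hi = max(loc - half, 0), min(loc + half + 1, x.size)
        refined[i] = lo + int(np.argmax(np.abs(bp[lo:hi])))
    beat_times = ecg.start_time_s + np.unique(refined) / fs
    return beat_times


def hr_from_beats(
    beat_times_s: np.ndarray,
    grid_rate_hz: float = 20.0,
    cfg: PreprocessConfig | None = None,
    times_s: np.ndarray | None = None,
) -> HeartRateSeries:
    """Instantaneous heart rate HR = 60 / (R-R interval) on a uniform grid.

    Each interval's rate sits at its midpoint; intervals outside the
    physiologic window are treated as artifacts and bridged by the
    interpolation of their neighbours rather than deleted, preserving the
    uniform grid.  Constant-interval input is reproduced exactly.
    """
    cfg = cfg or PreprocessConfig()
    beat_times_s = np.asarray(beat_times_s, dtype=float)
    if beat_times_s.size < 3:
        raise ValueError("need at least 3 beats to form a heart-rate series")
    rr = np.diff(beat_times_s)
    if np.any(rr <= 0):
        raise ValueError("beat times must be strictly increasing")

    mids = beat_times_s[:-1] + rr / 2.0
    hr_inst = 60.0 / rr
    ok = (rr >= cfg.rr_valid_s[0]) & (rr <= cfg.rr_valid_s[1])
    if not ok.any():
        raise ValueError("all R-R intervals flagged as artifacts")

    if times_s is None:
        n = int(np.floor((beat_times_s[-1] - beat_times_s[0]) * grid_rate_hz)) + 1
        times_s = beat_times_s[0] + np.arange(n) / grid_rate_hz
    hr = _interp_smooth(mids[ok], hr_inst[ok], times_s)
    return HeartRateSeries(hr, times_s, grid_rate_hz, beat_times_s)


def br_from_flow(
    flow: FlowSignal,
    grid_rate_hz: float = 20.0,
    cfg: PreprocessConfig | None = None,
    times_s: np.ndarray | None = None,
) -> BreathingRateSeries:
    """Gold-standard breathing rate from airflow crests: BR = 60 / (crest-crest).

    Crests are picked with a prominence of a quarter of the signal's
    interquartile range, which rides out baseline drift; during apnea the
    flat flow produces no crests, the pause-spanning interval is discarded
    as non-physiological, and the rate is bridged between the surrounding
    breaths.
    """
    cfg = cfg or PreprocessConfig()
    crest_times = detect_flow_crests(flow, cfg)
    if crest_times.size < 2:
        raise ValueError("fewer than 2 flow crests: cannot form a breathing rate")

    intervals = np.diff(crest_times)
    mids = crest_times[:-1] + intervals / 2.0
    br_inst = 60.0 / intervals
    # an interval spanning an apnea is a pause, not a slow breath: bridge it
    ok = intervals <= cfg.crest_interval_max_s
    if not ok.any():
        raise ValueError("no physiological crest-crest intervals found")
    mids, br_inst = mids[ok], br_inst[ok]
    if times_s is None:
        n = int(np.floor((crest_times[-1] - crest_times[0]) * grid_rate_hz)) + 1
        times_s = crest_times[0] + np.arange(n) / grid_rate_hz
    br = _interp_smooth(mids, br_inst, times_s)
    conf = np.full(times_s.shape, TRACKED, dtype=object)
    return BreathingRateSeries(br, times_s, "pressure", conf)


def detect_flow_crests(flow: FlowSignal, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Crest times of the airflow signal (one per breathing cycle).

    The flow is low-passed at 1 Hz (zero phase) first — a breathing crest is
    locally flat, so raw sensor noise otherwise jitters the detected crest
    sample by hundreds of milliseconds — and each crest is refined to
    sub-sample precision with a parabolic fit through the peak neighbourhood.
    """
    cfg = cfg or PreprocessConfig()
    fs = flow.sample_rate_hz
    x = flow.samples
    if fs > 2.5:
        sos = butter(3, 1.0, btype="lowpass", fs=fs, output="sos")
        x = sosfiltfilt(sos, x)
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    if iqr <= 0:
        return np.empty(0)
    # minimum crest spacing: fastest representable breathing (27 bpm -> 2.2 s);
    # prominence is evaluated within a 10-s window so a flat (apnea) stretch
    # cannot borrow prominence from distant deep troughs
    min_dist = max(int(round(2.0 * fs)), 1)
    wlen = max(int(round(10.0 * fs)), 3)
    locs, _ = find_peaks(
        x, prominence=cfg.crest_prominence_frac * iqr, distance=min_dist, wlen=wlen
    )
    times = locs.astype(float)
    inner = (locs > 0) & (locs < x.size - 1)
    y0, y1, y2 = x[locs[inner] - 1], x[locs[inner]], x[locs[inner] + 1]
    denom = y0 - 2.0 * y1 + y2
    shift = np.where(denom < 0, 0.5 * (y0 - y2) / denom, 0.0)
    times[inner] += np.clip(shift, -0.5, 0.5)
    return flow.start_time_s + times / fs


def _interp_smooth(x: np.ndarray, y: np.ndarray, xq: np.ndarray) -> np.ndarray:
    """Modified-Akima cubic interpolation, constant-extended beyond the data."""
    if x.size == 1:
        return np.full(xq.shape, y[0])
    if x.size < 4:
        return np.interp(xq, x, y)
    out = Akima1DInterpolator(x, y, method="makima", extrapolate=False)(xq)
    out[xq <= x[0]] = y[0]
    out[xq >= x[-1]] = y[-1]
    out[~np.isfinite(out)] = np.interp(xq[~np.isfinite(out)], x, y)
    return out
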