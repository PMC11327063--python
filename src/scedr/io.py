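"""File formats: EDF channels, hypnograms, event-time lists, series CSV.

Reading EDF goes through ``mne`` (an optional dependency).  Writing uses a
minimal plain-EDF (16-bit) encoder implemented here, since no required
dependency provides EDF export; it emits a standard single-record-per-
second header that any EDF reader (including mne) accepts.  Amplitude
scale on read-back follows the reader's unit conventions; the analysis is
scale-invariant (percentile/prominence thresholds), so this is benign.

Hypnograms are plain text — one stage label per line after a
``# epoch_len_s=30`` header — or a two-column CSV (epoch_start_s, label).
Event times (R peaks, flow crests) are one float (seconds) per line.
"""
from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .simulate import Interferer, SimScenario
from .types import BreathingRateSeries, HeartRateSeries, Hypnogram


def _pad(value, width: int) -> bytes:
    if isinstance(value, float):
        for precision in range(6, 0, -1):
            s = f"{value:.{precision}g}"
            if len(s) <= width:
                break
    else:
        s = str(value)
    return s[:width].ljust(width).encode("ascii")


def write_edf(path: str | Path, channels: Sequence[tuple[str, np.ndarray, float]]) -> None:
    """Write channels as plain EDF (one-second data records, int16).

    ``channels`` is a sequence of (label, samples, sample_rate_hz); rates
    must be whole numbers per second.  The last record is zero-padded.
    """
    path = Path(path)
    ns = len(channels)
    rates = [int(round(r)) for _, _, r in channels]
    for (_, _, r), ri in zip(channels, rates):
        if abs(r - ri) > 1e-9 or ri <= 0:
            raise ValueError("EDF writer needs integer samples per second")
    n_records = max(int(np.ceil(len(s) / r)) for (_, s, _), r in zip(channels, rates))

    header = b""
    header += _pad("0", 8)
    header += _pad("synthetic", 80)
    header += _pad("scedr", 80)
    header += _pad("01.01.00", 8)
    header += _pad("00.00.00", 8)
    header += _pad(256 * (ns + 1), 8)
    header += _pad("", 44)
    header += _pad(n_records, 8)
    header += _pad(1, 8)
    header += _pad(ns, 4)

    scaled = []
    pmins, pmaxs = [], []
    for _, samples, _ in channels:
        samples = np.asarray(samples, dtype=float)
        pmin, pmax = float(samples.min()), float(samples.max())
        if pmax <= pmin:
            pmin, pmax = pmin - 1.0, pmin + 1.0
        dig = np.round((samples - pmin) / (pmax - pmin) * 65535.0 - 32768.0)
        scaled.append(dig.astype("<i2"))
        pmins.append(pmin)
        pmaxs.append(pmax)

    for field_fn in (
        lambda i: _pad(channels[i][0], 16),
        lambda i: _pad("", 80),
        lambda i: _pad("", 8),
        lambda i: _pad(pmins[i], 8),
        lambda i: _pad(pmaxs[i], 8),
        lambda i: _pad(-32768, 8),
        lambda i: _pad(32767, 8),
        lambda i: _pad("", 80),
        lambda i: _pad(rates[i], 8),
        lambda i: _pad("", 32),
    ):
        for i in range(ns):
            header += field_fn(i)

    with path.open("wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            for dig, rate in zip(scaled, rates):
                chunk = dig[rec * rate : (rec + 1) * rate]
                if chunk.size < rate:
                    chunk = np.pad(chunk, (0, rate - chunk.size))
                fh.write(chunk.tobytes())


def read_edf(path: str | Path, labels: Sequence[str] | None = None) -> dict[str, tuple[np.ndarray, float]]:
    """Read EDF channels by label via mne; returns {label: (samples, rate)}."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    out = {}
    for label in labels or raw.ch_names:
        idx = raw.ch_names.index(label)
        out[label] = (raw.get_data(picks=[idx])[0], float(raw.info["sfreq"]))
    return out


def write_event_times(path: str | Path, times_s: np.ndarray) -> None:
    Path(path).write_text("".join(f"{t:.6f}\n" for t in np.asarray(times_s, dtype=float)))


def read_event_times(path: str | Path) -> np.ndarray:
    lines = [l.strip() for l in Path(path).read_text().splitlines()]
    return np.array([float(l) for l in lines if l and not l.startswith("#")])


def write_hypnogram(path: str | Path, hypnogram: Hypnogram) -> None:
    out = [f"# epoch_len_s={hypnogram.epoch_len_s:g}"]
    out.extend(hypnogram.labels)
    Path(path).write_text("\n".join(out) + "\n")


def read_hypnogram(path: str | Path) -> Hypnogram:
    """Read either the plain-text (header + label lines) or CSV variant."""
    text = Path(path).read_text()
    first = text.splitlines()[0] if text.splitlines() else ""
    if "," in first and "label" in first.lower():
        df = pd.read_csv(path)
        starts = df["epoch_start_s"].to_numpy(dtype=float)
        if len(starts) >= 2:
            epoch_len = float(starts[1] - starts[0])
        else:
            epoch_len = 30.0
        return Hypnogram(list(df["label"]), epoch_len, float(starts[0]) if len(starts) else 0.0)
    epoch_len = 30.0
    labels = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "epoch_len_s=" in line:
                epoch_len = float(line.split("epoch_len_s=")[1])
            continue
        labels.append(line)
    return Hypnogram(labels, epoch_len)


def write_hypnogram_csv(path: str | Path, hypnogram: Hypnogram) -> None:
    rows = [
        {"epoch_start_s": hypnogram.epoch_bounds(k)[0], "label": hypnogram.labels[k]}
        for k in range(len(hypnogram))
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_hr_series(path: str | Path, hr: HeartRateSeries) -> None:
    pd.DataFrame({"time_s": hr.times_s, "hr_bpm": hr.hr_bpm}).to_csv(
        path, index=False, float_format="%.6f"
    )


def read_hr_series(path: str | Path) -> HeartRateSeries:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    rate = 1.0 / float(np.median(np.diff(t)))
    return HeartRateSeries(df["hr_bpm"].to_numpy(dtype=float), t, round(rate, 6))


def write_br_series(path: str | Path, br: BreathingRateSeries) -> None:
    pd.DataFrame(
        {
            "time_s": br.times_s,
            "br_bpm": br.br_bpm,
            "source": br.source,
            "confidence": br.confidence,
        }
    ).to_csv(path, index=False, float_format="%.6f")


def read_br_series(path: str | Path) -> BreathingRateSeries:
    df = pd.read_csv(path)
    return BreathingRateSeries(
        df["br_bpm"].to_numpy(dtype=float),
        df["time_s"].to_numpy(dtype=float),
        str(df["source"].iloc[0]),
        df["confidence"].to_numpy(dtype=object),
    )


def load_scenario(path: str | Path) -> SimScenario:
    """Build a SimScenario from a YAML key-value file.

    Keys are the SimScenario field names; ``br_trajectory`` and the
    amplitude fields accept a number or a list of [time_s, value] knots;
    ``interferers`` is a list of [start_s, stop_s, freq_hz, amplitude_bpm];
    ``apnea_windows`` a list of [start_s, stop_s].
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "interferers" in raw:
        raw["interferers"] = [Interferer(*row) for row in raw["interferers"]]
    if "apnea_windows" in raw:
        raw["apnea_windows"] = [tuple(w) for w in raw["apnea_windows"]]
    for key in ("br_trajectory", "rsa_amplitude", "lf_noise_amp"):
        if isinstance(raw.get(key), list):
            raw[key] = [tuple(k) for k in raw[key]]
    return SimScenario(**raw)
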