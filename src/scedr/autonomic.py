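"""Heart-rate spectral band powers, variability metrics and REM0 restaging.

Band powers follow the standard HRV frequency bands — VLF 0.004-0.05 Hz,
LF 0.05-0.15 Hz, HF 0.15-0.40 Hz — integrated from the wavelet PSD over a
90-s window centered on each 30-s scored epoch.  The 90-s window is a
compromise: a 30-s epoch holds at most a fraction of a VLF cycle (periods
up to 250 s), so VLF summaries are partial-cycle estimates by nature, and
LF/HF and VLF/HF ratios are the quantities of interest.

REM0 restaging: epochs whose heart-rate variability exceeds a threshold
derived from the pre-sleep eyes-closed-wake (ECW) baseline are candidates
for reassignment; among those, high EEG global-field-power variability
marks REM0 (NREM-like cortex with REM-like autonomic surges), low GFP
variability marks REM.  All other epochs keep their expert label.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .morse import TimeFrequencyMap
from .types import Hypnogram

logger = logging.getLogger(__name__)


@dataclass
class BandDefinition:
    """HRV spectral bands in Hz (half-open [lo, hi) on the analysis grid)."""

    vlf: tuple[float, float] = (0.004, 0.05)
    lf: tuple[float, float] = (0.05, 0.15)
    hf: tuple[float, float] = (0.15, 0.40)

    def __post_init__(self) -> None:
        seq = [self.vlf, self.lf, self.hf]
        for (a0, a1), (b0, b1) in zip(seq, seq[1:]):
            if a1 > b0 or a0 >= a1:
                raise ValueError("bands must be increasing and non-overlapping")


@dataclass
class VariabilityThresholds:
    """Variability thresholds derived from the ECW (pre-sleep) baseline."""

    hr_var_threshold: float
    gfp_var_threshold: float | None
    baseline_epochs: list[int]

    def __post_init__(self) -> None:
        if self.hr_var_threshold <= 0:
            raise ValueError("hr_var_threshold must be positive")


def band_powers(
    tfmap: TimeFrequencyMap,
    hypnogram: Hypnogram,
    bands: BandDefinition | None = None,
    window_s: float = 90.0,
) -> pd.DataFrame:
    """Per-epoch band powers and ratios from the wavelet PSD.

    The map must cover the full VLF-HF range (0.004-0.45 Hz grid).  Epochs
    whose centered window leaves the record are flagged ``valid = False``
    and carry NaN powers.  Band integration is a Riemann sum over half-open
    frequency bins, so power is exactly additive across adjacent bands.
    """
    bands = bands or BandDefinition()
    if tfmap.freqs_hz[0] > bands.vlf[0] + 1e-9:
        raise ValueError(
            f"map starts at {tfmap.freqs_hz[0]} Hz; band powers need the extended "
            f"grid down to {bands.vlf[0]} Hz"
        )
    df_step = float(np.median(np.diff(tfmap.freqs_hz)))
    psd = tfmap.psd
    t = tfmap.slice_times_s
    rows = []
    for k in range(len(hypnogram)):
        e0, e1 = hypnogram.epoch_bounds(k)
        c = (e0 + e1) / 2.0
        w0, w1 = c - window_s / 2.0, c + window_s / 2.0
        valid = w0 >= t[0] - 1e-9 and w1 <= t[-1] + 1e-9
        if valid:
            sl = (t >= w0) & (t < w1)
            mean_psd = psd[sl].mean(axis=0)
            powers = {
                name: float(mean_psd[tfmap.band_indices(*band, half_open=True)].sum() * df_step)
                for name, band in (("vlf", bands.vlf), ("lf", bands.lf), ("hf", bands.hf))
            }
        else:
            powers = {"vlf": np.nan, "lf": np.nan, "hf": np.nan}
        hf = powers["hf"]
        rows.append(
            {
                "epoch_index": k,
                "stage": hypnogram.labels[k],
                "vlf_power": powers["vlf"],
                "lf_power": powers["lf"],
                "hf_power": hf,
                "lf_hf_ratio": powers["lf"] / hf if hf and hf > 0 else np.nan,
                "vlf_hf_ratio": powers["vlf"] / hf if hf and hf > 0 else np.nan,
                "valid": valid,
            }
        )
    n_bad = sum(not r["valid"] for r in rows)
    if n_bad:
        logger.info("band_powers: %d epochs excluded (90-s window exceeds record)", n_bad)
    return pd.DataFrame(rows)


def gfp(eeg_samples: np.ndarray) -> np.ndarray:
    """Global field power: across-channel SD at each sample.

    ``eeg_samples`` has shape (n_channels, n_samples).
    """
    return np.std(np.asarray(eeg_samples, dtype=float), axis=0, ddof=0)


def variability_per_epoch(
    values: np.ndarray,
    times_s: np.ndarray,
    hypnogram: Hypnogram,
    max_invalid_frac: float = 0.5,
) -> np.ndarray:
    """Within-epoch standard deviation of a uniformly sampled series.

    Epochs with more than ``max_invalid_frac`` non-finite samples (or no
    samples at all) are returned as NaN.
    """
    values = np.asarray(values, dtype=float)
    out = np.full(len(hypnogram), np.nan)
    for k in range(len(hypnogram)):
        e0, e1 = hypnogram.epoch_bounds(k)
        sl = (times_s >= e0) & (times_s < e1)
        seg = values[sl]
        if seg.size == 0:
            continue
        finite = np.isfinite(seg)
        if finite.mean() < 1.0 - max_invalid_frac:
            continue
        out[k] = np.std(seg[finite], ddof=0)
    return out


def derive_thresholds(
    hr_var: np.ndarray,
    hypnogram: Hypnogram,
    gfp_var: np.ndarray | None = None,
    percentile: float = 95.0,
    ecw_label: str = "ECW",
) -> VariabilityThresholds:
    """Variability thresholds as a percentile of the ECW-epoch distribution."""
    ecw = [k for k, l in enumerate(hypnogram.labels) if l == ecw_label]
    ecw = [k for k in ecw if np.isfinite(hr_var[k])]
    if not ecw:
        raise ValueError("no ECW epochs: variability thresholds cannot be defined")
    if len(ecw) < 4:
        logger.warning("only %d ECW epochs; thresholds will be unstable", len(ecw))
    hr_thr = float(np.percentile([hr_var[k] for k in ecw], percentile))
    gfp_thr = None
    if gfp_var is not None:
        vals = [gfp_var[k] for k in ecw if np.isfinite(gfp_var[k])]
        if vals:
            gfp_thr = float(np.percentile(vals, percentile))
    return VariabilityThresholds(hr_thr, gfp_thr, ecw)


def reassign_rem0(
    hypnogram: Hypnogram,
    hr_var: np.ndarray,
    gfp_var: np.ndarray | None,
    thresholds: VariabilityThresholds,
    return_table: bool = False,
):
    """Augment an expert hypnogram with the putative REM0 stage.

    Per-epoch rule: HR variability at or below its threshold keeps the
    expert label; above it, high GFP variability relabels the epoch REM0
    and low GFP variability relabels it REM.  Epochs needing a GFP verdict
    that lack one are left unchanged and flagged unresolved.
    """
    labels = list(hypnogram.labels)
    rows = []
    for k, old in enumerate(labels):
        new, branch = old, "keep"
        if np.isfinite(hr_var[k]) and hr_var[k] > thresholds.hr_var_threshold:
            g = gfp_var[k] if gfp_var is not None else np.nan
            if thresholds.gfp_var_threshold is None or not np.isfinite(g):
                branch = "unresolved"
            elif g > thresholds.gfp_var_threshold:
                new, branch = "REM0", "rem0"
            else:
                new, branch = "REM", "rem"
        labels[k] = new
        rows.append({"epoch_index": k, "old": old, "new": new, "branch": branch})
    out = Hypnogram(labels, hypnogram.epoch_len_s, hypnogram.start_time_s)
    if return_table:
        return out, pd.DataFrame(rows)
    return out


def stage_ratio_summary(power_table: pd.DataFrame) -> pd.DataFrame:
    """Median and quartiles of LF/HF and VLF/HF per sleep stage."""
    rows = []
    for stage, grp in power_table[power_table["valid"]].groupby("stage"):
        for metric in ("lf_hf_ratio", "vlf_hf_ratio", "vlf_power", "lf_power", "hf_power"):
            q1, med, q3 = np.nanpercentile(grp[metric], [25, 50, 75])
            rows.append(
                {"stage": stage, "metric": metric, "q1": q1, "median": med, "q3": q3,
                 "n_epochs": len(grp)}
            )
    return pd.DataFrame(rows)
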