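"""Epoch-wise accuracy of extracted breathing rate against the flow standard.

Both series are averaged over each 30-s scored epoch (half-open
[30k, 30k+30) windows aligned to the hypnogram); the absolute difference
of the two epoch means is the error in breaths per minute and, divided by
the flow-meter mean and scaled by 100, the percentage error.  Summaries
are broken down per sleep stage with one-SD spreads, and a four-panel
whole-record report mirrors the standard visual check: smoothed heart
rate, both breathing rates, the hypnogram with REM boundaries, and the
per-epoch percentage error against a 5 % reference line.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import BreathingRateSeries, HeartRateSeries, Hypnogram

logger = logging.getLogger(__name__)


def epoch_errors(
    br_edr: BreathingRateSeries,
    br_pressure: BreathingRateSeries,
    hypnogram: Hypnogram,
    include_bridged: bool = True,
) -> pd.DataFrame:
    """Per-epoch means, error (bpm) and %error of extractor vs flow meter.

    ``include_bridged=False`` drops gap-bridged (no spectral peak) samples
    from the extractor's epoch means; by default they stay in, so noisy
    stretches count against the method rather than silently vanishing.
    Epochs with no finite samples in either series are excluded and logged.
    """
    rows = []
    for k in range(len(hypnogram)):
        e0, e1 = hypnogram.epoch_bounds(k)
        edr_sel = (br_edr.times_s >= e0) & (br_edr.times_s < e1)
        if not include_bridged:
            edr_sel &= br_edr.confidence == "tracked"
        prs_sel = (br_pressure.times_s >= e0) & (br_pressure.times_s < e1)
        edr_vals = br_edr.br_bpm[edr_sel]
        prs_vals = br_pressure.br_bpm[prs_sel]
        edr_vals = edr_vals[np.isfinite(edr_vals)]
        prs_vals = prs_vals[np.isfinite(prs_vals)]
        if edr_vals.size == 0 or prs_vals.size == 0:
            logger.info("epoch %d excluded: no valid samples (stage %s)", k, hypnogram.labels[k])
            continue
        m_edr, m_prs = float(edr_vals.mean()), float(prs_vals.mean())
        err = abs(m_edr - m_prs)
        rows.append(
            {
                "epoch_index": k,
                "stage": hypnogram.labels[k],
                "br_edr_mean": m_edr,
                "br_pressure_mean": m_prs,
                "error_bpm": err,
                "pct_error": 100.0 * err / m_prs,
                "method": br_edr.source,
            }
        )
    return pd.DataFrame(rows)


def stage_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD of error and %error per sleep stage and whole record.

    SD is the sample standard deviation over contributing epochs (NaN for a
    single-epoch stage).
    """
    if table.empty:
        raise ValueError("empty epoch table")
    groups = [(stage, grp) for stage, grp in table.groupby("stage")]
    groups.append(("whole", table))
    rows = []
    for stage, grp in groups:
        if grp.empty:
            logger.info("stage %s: no epochs, omitted from summary", stage)
            continue
        rows.append(
            {
                "stage": stage,
                "mean_error_bpm": grp["error_bpm"].mean(),
                "sd_error_bpm": grp["error_bpm"].std(ddof=1),
                "mean_pct_error": grp["pct_error"].mean(),
                "sd_pct_error": grp["pct_error"].std(ddof=1),
                "n_epochs": len(grp),
            }
        )
    return pd.DataFrame(rows)


def moving_average(values: np.ndarray, rate_hz: float, window_s: float = 2.0) -> np.ndarray:
    """Centered moving average over ``window_s`` seconds."""
    n = max(int(round(window_s * rate_hz)), 1)
    kernel = np.ones(n) / n
    return np.convolve(values, kernel, mode="same")


def rem_boundaries(hypnogram: Hypnogram) -> tuple[list[float], list[float]]:
    """Onset and offset times (s) of expert-scored REM periods."""
    onsets, offsets = [], []
    prev = None
    for k, label in enumerate(hypnogram.labels):
        t0, _ = hypnogram.epoch_bounds(k)
        if label == "REM" and prev != "REM":
            onsets.append(t0)
        if label != "REM" and prev == "REM":
            offsets.append(t0)
        prev = label
    if prev == "REM":
        offsets.append(hypnogram.epoch_bounds(len(hypnogram) - 1)[1])
    return onsets, offsets


STAGE_Y = {"N3": 0, "N2": 1, "N1": 2, "REM0": 3, "REM": 4, "ECW": 5}


def whole_record_report(
    hr: HeartRateSeries,
    br_edr: BreathingRateSeries,
    br_pressure: BreathingRateSeries,
    hypnogram: Hypnogram,
    epoch_table: pd.DataFrame,
    out_image: str | Path,
    out_csv_prefix: str | Path | None = None,
) -> None:
    """Render the four-panel whole-record figure and its underlying CSVs.

    Panels (shared time axis): (A) 2-s moving-average heart rate; (B) both
    breathing-rate series, same smoothing; (C) hypnogram with REM onsets as
    solid and offsets as dotted vertical lines; (D) per-epoch %error with a
    dashed reference line at 5 %.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(4, 1, figsize=(12, 9), sharex=True)
    ax_hr, ax_br, ax_hyp, ax_err = axes

    ax_hr.plot(hr.times_s, moving_average(hr.hr_bpm, hr.grid_rate_hz), color="k", lw=0.7)
    ax_hr.set_ylabel("HR (bpm)")

    br_rate = 1.0 / float(np.median(np.diff(br_edr.times_s)))
    ax_br.plot(
        br_pressure.times_s,
        moving_average(br_pressure.br_bpm, br_rate),
        color="c", lw=0.9, label="flow meter",
    )
    ax_br.plot(
        br_edr.times_s,
        moving_average(br_edr.br_bpm, br_rate),
        color="r", lw=0.9, label=br_edr.source,
    )
    ax_br.set_ylabel("BR (bpm)")
    ax_br.legend(loc="upper right", fontsize=8)

    y = [STAGE_Y[l] for l in hypnogram.labels]
    t_epochs = [hypnogram.epoch_bounds(k)[0] for k in range(len(hypnogram))]
    ax_hyp.step(t_epochs, y, where="post", color="k", lw=0.9)
    ax_hyp.set_yticks(sorted(STAGE_Y.values()))
    ax_hyp.set_yticklabels([s for s, _ in sorted(STAGE_Y.items(), key=lambda kv: kv[1])])
    ax_hyp.set_ylabel("stage")

    onsets, offsets = rem_boundaries(hypnogram)
    for axis in axes:
        for t in onsets:
            axis.axvline(t, color="k", ls="-", lw=0.8)
        for t in offsets:
            axis.axvline(t, color="k", ls=":", lw=0.8)

    if not epoch_table.empty:
        centers = [hypnogram.epoch_bounds(int(k))[0] + hypnogram.epoch_len_s / 2
                   for k in epoch_table["epoch_index"]]
        ax_err.plot(centers, epoch_table["pct_error"], ".", color="0.3", ms=3)
    ax_err.axhline(5.0, color="k", ls="--", lw=0.8)
    ax_err.set_ylabel("%error")
    ax_err.set_xlabel("time (s)")

    fig.tight_layout()
    fig.savefig(out_image, dpi=120)
    plt.close(fig)

    if out_csv_prefix is not None:
        prefix = Path(out_csv_prefix)
        pd.DataFrame({"time_s": hr.times_s, "hr_bpm": hr.hr_bpm}).to_csv(
            prefix.with_name(prefix.name + "_hr.csv"), index=False
        )
        pd.DataFrame(
            {"time_s": br_edr.times_s, "br_edr_bpm": br_edr.br_bpm}
        ).to_csv(prefix.with_name(prefix.name + "_br_edr.csv"), index=False)
        pd.DataFrame(
            {"time_s": br_pressure.times_s, "br_pressure_bpm": br_pressure.br_bpm}
        ).to_csv(prefix.with_name(prefix.name + "_br_pressure.csv"), index=False)
        epoch_table.to_csv(prefix.with_name(prefix.name + "_epochs.csv"), index=False)
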