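"""Analysis configuration with the method's published defaults.

Every tolerance of the extraction pipeline lives here so a run can be
reproduced from a single YAML file.  Units: frequencies in Hz, the slice
step in milliseconds, windows in slices (one slice = ``slice_ms``).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class TFAConfig:
    """Morse-wavelet time-frequency analysis parameters.

    gamma=3 gives a Gaussian-like wavelet envelope; beta=90 sets the
    time-bandwidth product (gamma*beta = 270), trading time resolution for
    the frequency resolution needed to separate breathing from neighbouring
    heart-rate components.
    """

    gamma: float = 3.0
    beta: float = 90.0
    fmin_hz: float = 0.05
    fmax_hz: float = 0.45
    fstep_hz: float = 0.02
    slice_ms: float = 50.0
    #: edge-invalidation span in wavelet e-folding times (cone of influence)
    edge_efolds: float = 1.5


@dataclass
class EDRConfig:
    """Breathing-track extraction parameters."""

    #: band searched for breathing peaks (respiratory frequencies, 9-27 bpm)
    search_band_hz: tuple[float, float] = (0.15, 0.45)
    #: wider band over which the per-slice dynamic threshold maximum is taken
    threshold_band_hz: tuple[float, float] = (0.05, 0.45)
    #: significant peaks must exceed this fraction of the slice maximum
    threshold_frac: float = 0.20
    #: max frequency jump between linked peaks (one analysis bin)
    link_tolerance_hz: float = 0.02
    #: max run of peak-less slices inside one track (2 s at 50 ms slices)
    gap_tolerance_slices: int = 40
    #: how far ahead (slices) a candidate track may start to rejoin after an
    #: apnea or dropout of the breathing track (60 s)
    rejoin_window_slices: int = 1200
    #: half-width of the inverse-wavelet reconstruction window
    recon_halfwidth_hz: float = 0.015


@dataclass
class PreprocessConfig:
    """Raw-channel conditioning parameters."""

    #: uniform grid for instantaneous heart rate; 20 Hz = one sample per
    #: 50 ms analysis slice
    grid_rate_hz: float = 20.0
    #: R-R intervals outside this range (s) are treated as artifacts
    rr_valid_s: tuple[float, float] = (0.27, 3.0)
    #: crest-picking prominence as a fraction of the flow interquartile range
    crest_prominence_frac: float = 0.25
    #: crest-crest intervals longer than this (no breath for > 7.5 s, i.e.
    #: below 8 bpm) are treated as apnea and bridged, not read as a rate
    crest_interval_max_s: float = 7.5


@dataclass
class Config:
    tfa: TFAConfig = dataclasses.field(default_factory=TFAConfig)
    edr: EDRConfig = dataclasses.field(default_factory=EDRConfig)
    preprocess: PreprocessConfig = dataclasses.field(default_factory=PreprocessConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        """Load a config file; keys not present keep their defaults.

        Schema: three optional mappings ``tfa``, ``edr`` and ``preprocess``
        whose keys are the dataclass field names above.
        """
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for section_name in ("tfa", "edr", "preprocess"):
            section = raw.get(section_name, {})
            target = getattr(cfg, section_name)
            valid = {f.name for f in dataclasses.fields(target)}
            for key, value in section.items():
                if key not in valid:
                    raise KeyError(f"unknown config key {section_name}.{key}")
                if isinstance(value, list):
                    value = tuple(value)
                setattr(target, key, value)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        out = {
            name: dataclasses.asdict(getattr(self, name))
            for name in ("tfa", "edr", "preprocess")
        }
        Path(path).write_text(yaml.safe_dump(out, sort_keys=False))
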