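"""Peak extraction, track linking, breathing-track selection, both extractors."""
from __future__ import annotations

import numpy as np
import pytest

from scedr.edr import (
    FrequencyTrack,
    SpectralPeak,
    build_tracks,
    extract_slice_peaks,
    maxpower_edr,
    scedr,
    select_breathing_track,
)
from scedr.morse import MorseParams, TimeFrequencyMap
from scedr.types import GAP_BRIDGED, TRACKED, NoRespiratoryComponentError


def toy_map(power_rows: np.ndarray, freqs: np.ndarray) -> TimeFrequencyMap:
    """A TimeFrequencyMap with prescribed per-slice power (unit psd norm)."""
    power_rows = np.atleast_2d(np.asarray(power_rows, dtype=float))
    coeffs = np.sqrt(power_rows).astype(complex)
    times = 0.05 * np.arange(power_rows.shape[0])
    return TimeFrequencyMap(coeffs, freqs, times, MorseParams())


def dag_longest_path(peaks, link_tol: float, gap_tol: int) -> int:
    """Independent oracle: exhaustive longest-duration path in the linking DAG.

    O(n^2) relaxation over peaks ordered by slice; a link is legal when the
    frequency jump is within tolerance and at most ``gap_tol`` empty slices
    intervene.
    """
    order = sorted(range(len(peaks)), key=lambda i: peaks[i].slice_index)
    start: dict[int, int] = {}
    best = 0
    for i in order:
        pi = peaks[i]
        s = pi.slice_index
        for j in order:
            pj = peaks[j]
            if pj.slice_index >= pi.slice_index:
                break
            if (
                pi.slice_index - pj.slice_index - 1 <= gap_tol
                and abs(pi.freq_hz - pj.freq_hz) <= link_tol + 1e-9
            ):
                s = min(s, start[j])
        start[i] = s
        best = max(best, pi.slice_index - s + 1)
    return best


class TestExtractSlicePeaks:
    FREQS = np.array([0.15, 0.17, 0.19, 0.21, 0.23])

    def test_two_local_maxima_both_significant(self):
        peaks = extract_slice_peaks(
            toy_map([[1, 5, 2, 8, 3]], self.FREQS),
            search_band=(0.15, 0.23), threshold_band=(0.15, 0.23),
        )
        assert [p.freq_hz for p in peaks] == [0.17, 0.21]
        assert np.allclose([p.power for p in peaks], [5.0, 8.0])

    def test_sub_threshold_peak_dropped(self):
        peaks = extract_slice_peaks(
            toy_map([[1, 1.5, 1, 10, 1]], self.FREQS),
            search_band=(0.15, 0.23), threshold_band=(0.15, 0.23),
        )
        assert [p.freq_hz for p in peaks] == [0.21]
        assert np.allclose([p.power for p in peaks], [10.0])

    def test_all_zero_slice_yields_no_peaks(self):
        assert extract_slice_peaks(
            toy_map([[0, 0, 0, 0, 0]], self.FREQS),
            search_band=(0.15, 0.23), threshold_band=(0.15, 0.23),
        ) == []

    def test_wider_threshold_band_can_silence_search_band(self):
        """A strong out-of-search-band component raises the bar inside it."""
        freqs = np.array([0.05, 0.15, 0.17])
        # slice max over the wide band is 100 -> threshold 20 kills the 5
        peaks = extract_slice_peaks(
            toy_map([[100, 1, 5]], freqs), search_band=(0.15, 0.17),
            threshold_band=(0.05, 0.17),
        )
        assert peaks == []

    def test_single_tone_map_one_peak_per_interior_slice(self, tone_record):
        _, _, _, tfmap = tone_record
        peaks = extract_slice_peaks(tfmap)
        by_slice = {}
        for p in peaks:
            by_slice.setdefault(p.slice_index, []).append(p)
        interior = np.nonzero(tfmap.valid.all(axis=1))[0]
        for s in interior:
            assert len(by_slice[s]) == 1
            assert by_slice[s][0].freq_hz == 0.25


class TestBuildTracks:
    def test_persistent_ridge_is_one_track(self):
        peaks = [SpectralPeak(s, 0.25, 1.0) for s in range(100)]
        tracks = build_tracks(peaks)
        assert len(tracks) == 1
        assert tracks[0].duration_slices == 100

    def test_transient_forms_second_track(self):
        peaks = [SpectralPeak(s, 0.25, 1.0) for s in range(1, 101)]
        peaks += [SpectralPeak(s, 0.35, 2.0) for s in range(40, 61)]
        tracks = build_tracks(peaks)
        assert sorted(t.duration_slices for t in tracks) == [21, 100]

    def test_longest_track_matches_exhaustive_oracle(self):
        """On 100 random peak fields the longest track equals the DAG
        longest path; any discrepancy must coincide with a logged tie."""
        bins = np.round(np.arange(0.15, 0.4501, 0.02), 4)
        rng = np.random.default_rng(314159)
        n_agree, n_tied_disagreements = 0, 0
        for _ in range(100):
            n_slices = int(rng.integers(4, 13))
            peaks = []
            for s in range(n_slices):
                k = int(rng.integers(0, 6))
                for f in rng.choice(bins, size=k, replace=False):
                    peaks.append(SpectralPeak(int(s), float(f), float(rng.random())))
            tracks, stats = build_tracks(peaks, 0.02, 2, return_stats=True)
            got = max((t.duration_slices for t in tracks), default=0)
            want = dag_longest_path(peaks, 0.02, 2)
            if got == want:
                n_agree += 1
            elif stats.n_ties > 0:
                n_tied_disagreements += 1
            else:
                pytest.fail(f"untied disagreement: got {got}, oracle {want}")
        assert n_agree >= 95

    def test_gap_within_tolerance_bridged(self):
        peaks = [SpectralPeak(s, 0.25, 1.0) for s in list(range(10)) + list(range(12, 20))]
        tracks = build_tracks(peaks, gap_tolerance_slices=2)
        assert len(tracks) == 1
        assert tracks[0].duration_slices == 20

    def test_gap_beyond_tolerance_splits(self):
        peaks = [SpectralPeak(s, 0.25, 1.0) for s in list(range(10)) + list(range(15, 20))]
        tracks = build_tracks(peaks, gap_tolerance_slices=2)
        assert sorted(t.duration_slices for t in tracks) == [5, 10]


class TestSelectBreathingTrack:
    def track(self, slices, freq, power=1.0):
        return FrequencyTrack([SpectralPeak(s, freq, power) for s in slices])

    def test_longest_wins(self):
        tracks = [self.track(range(100), 0.25), self.track(range(40, 61), 0.35)]
        winner, freq, conf, _ = select_breathing_track(tracks, 100)
        assert winner is tracks[0]
        assert np.all(freq == 0.25)

    def test_equal_duration_tie_broken_by_power(self):
        tracks = [self.track(range(50), 0.20, power=1.2),
                  self.track(range(50), 0.30, power=3.0)]
        winner, _, _, _ = select_breathing_track(tracks, 50)
        assert winner is tracks[1]

    def test_apnea_rejoin_picks_nearest_frequency(self):
        """After the main track ends, the candidate closest in frequency is
        appended and the uncovered span is held at the last frequency."""
        main = self.track(range(0, 201), 0.26)
        near = self.track(range(240, 300), 0.27)
        far = self.track(range(240, 290), 0.40)
        winner, freq, conf, used = select_breathing_track([main, near, far], 300)
        assert winner is main
        assert np.all(freq[201:240] == 0.26)
        assert np.all(conf[201:240] == GAP_BRIDGED)
        assert np.all(freq[240:300] == 0.27)
        assert np.all(conf[240:300] == TRACKED)
        assert len(used) == 2

    def test_no_tracks_raises(self):
        with pytest.raises(NoRespiratoryComponentError):
            select_breathing_track([], 100)

    def test_no_tracks_with_previous_holds_frequency(self):
        prev = self.track(range(10), 0.24)
        winner, freq, conf, _ = select_breathing_track([], 50, previous_track=prev)
        assert winner is None
        assert np.all(freq == 0.24)
        assert np.all(conf == GAP_BRIDGED)


class TestExtractors:
    def test_scedr_constant_br_epoch_means(self, tone_record):
        _, _, _, tfmap = tone_record
        result = scedr(tfmap)
        from conftest import epoch_means

        idx, means = epoch_means(result.br.br_bpm, result.br.times_s)
        interior = (idx > 0) & (idx < idx.max())
        assert np.all(np.abs(means[interior] - 15.0) <= 0.6)

    def test_scedr_output_within_physiologic_band(self, interferer_record):
        _, _, _, tfmap = interferer_record
        result = scedr(tfmap)
        assert result.br.br_bpm.min() >= 9.0
        assert result.br.br_bpm.max() <= 27.0

    def test_scedr_continuity_on_tracked_slices(self, interferer_record):
        _, _, _, tfmap = interferer_record
        result = scedr(tfmap)
        tracked = result.br.confidence == TRACKED
        jumps = np.abs(np.diff(result.br.f_br_hz))
        both_tracked = tracked[1:] & tracked[:-1]
        assert jumps[both_tracked].max() <= 0.02 + 1e-9

    def test_maxpower_single_tone(self, tone_record):
        _, _, _, tfmap = tone_record
        result = maxpower_edr(tfmap)
        tracked = result.br.confidence == TRACKED
        assert np.all(result.br.br_bpm[tracked] == 15.0)

    def test_maxpower_follows_power_not_continuity(self):
        """Two persistent tones, the faster one stronger: Max-Power reports
        24 bpm everywhere even though 0.20 Hz is equally continuous."""
        from test_morse import make_series, tone
        from scedr.morse import cwt_morse

        x = 70 + tone(0.21, duration_s=400) + 2.5 * tone(0.41, duration_s=400)
        tfmap = cwt_morse(make_series(x))
        result = maxpower_edr(tfmap)
        tracked = result.br.confidence == TRACKED
        assert np.all(result.br.br_bpm[tracked] == pytest.approx(0.41 * 60, abs=1e-9))

    def test_interferer_diverts_maxpower_not_scedr(self, interferer_record):
        scenario, _, truth, tfmap = interferer_record
        res_sc = scedr(tfmap)
        res_mp = maxpower_edr(tfmap)
        window = (tfmap.slice_times_s >= 300.0) & (tfmap.slice_times_s < 330.0)
        err_sc = np.abs(res_sc.br.br_bpm[window] - 15.0).mean()
        err_mp = np.abs(res_mp.br.br_bpm[window] - 15.0).mean()
        assert err_mp > 3.0
        assert err_sc <= 1.2
        # Max-Power violates the continuity bound somewhere around the onset
        mp_jumps = np.abs(np.diff(res_mp.br.f_br_hz))
        assert mp_jumps.max() > 0.02

    def test_robustness_monotone_in_interferer_amplitude(self):
        """Whole-record error does not grow as the interferer weakens, and a
        clean record gives the same answer for both extractors."""
        from scedr.morse import cwt_morse
        from scedr.simulate import Interferer, SimScenario, simulate_heart_rate

        errors = []
        for amp in (4.0, 2.0, 0.0):
            itf = [Interferer(120.0, 150.0, 0.35, amp)] if amp else []
            scenario = SimScenario(duration_s=300.0, br_trajectory=15.0,
                                   interferers=itf, seed=21)
            hr, _ = simulate_heart_rate(scenario)
            tfmap = cwt_morse(hr)
            res = scedr(tfmap)
            errors.append(np.abs(res.br.br_bpm - 15.0).mean())
            if amp == 0.0:
                mp = maxpower_edr(tfmap)
                assert np.array_equal(res.br.br_bpm, mp.br.br_bpm)
        assert errors[0] >= errors[1] >= errors[2]

    def test_reconstruction_tracks_rsa_component(self, tone_record):
        _, _, truth, tfmap = tone_record
        result = scedr(tfmap, reconstruct=True)
        interior = tfmap.valid.all(axis=1)
        rsa = truth.rsa_component_bpm[: tfmap.n_slices]
        r = np.corrcoef(result.reconstructed_signal[interior], rsa[interior])[0, 1]
        assert r >= 0.9
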