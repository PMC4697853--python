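"""EEG metric suite: spectrogram, permutation entropy, bispectrum/SFS, correlation."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pknmm.eeg import EEGRecord
from pknmm.metrics import (
    InsufficientDataError,
    MetricSeries,
    bispectrum,
    compute_spectrogram,
    metric_over_windows,
    pearson_correlation,
    permutation_entropy,
    state_summary,
    synch_fast_slow,
)
from pknmm.pipeline import AnesthesiaTimeline


def brute_force_pe(x, m, tau):
    """Exhaustive ordinal-pattern counter (independent oracle).

    Ranks by stable sort: ties keep temporal order, matching the tie rule of
    the implementation under test but built from first principles.
    """
    x = list(x)
    n_vec = len(x) - (m - 1) * tau
    counts = {}
    for i in range(n_vec):
        window = [x[i + k * tau] for k in range(m)]
        order = tuple(sorted(range(m), key=lambda k: (window[k], k)))
        counts[order] = counts.get(order, 0) + 1
    h = -sum((c / n_vec) * math.log(c / n_vec) for c in counts.values())
    return h / math.log(math.factorial(m))


class TestPermutationEntropy:
    def test_monotone_series_has_zero_entropy(self):
        for m in (2, 3, 6):
            assert permutation_entropy(np.arange(30.0), m=m) == 0.0

    def test_seven_point_hand_count(self):
        # six ordinal pairs: four rising, two falling
        x = np.array([4, 7, 9, 10, 6, 11, 3], dtype=float)
        expected = -((2 / 3) * math.log(2 / 3) + (1 / 3) * math.log(1 / 3)) / math.log(2)
        assert permutation_entropy(x, m=2, tau=1) == pytest.approx(expected)
        assert expected == pytest.approx(0.918, abs=5e-4)

    def test_constant_series_single_pattern(self):
        assert permutation_entropy(np.zeros(40), m=3) == 0.0

    @given(
        x=st.lists(st.floats(min_value=-100, max_value=100, allow_nan=False),
                   min_size=10, max_size=50),
        m=st.integers(min_value=2, max_value=4),
        tau=st.integers(min_value=1, max_value=2),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_matches_exhaustive_counter(self, x, m, tau):
        if len(x) <= (m - 1) * tau + 1:
            return
        fast = permutation_entropy(np.array(x), m=m, tau=tau)
        assert fast == pytest.approx(brute_force_pe(x, m, tau), abs=1e-12)
        assert 0.0 <= fast <= 1.0

    def test_all_short_integer_series_exhaustively(self):
        # every ternary series of length 7 — exact oracle equivalence incl. ties
        for vals in itertools.product((0.0, 1.0, 2.0), repeat=7):
            x = np.array(vals)
            assert permutation_entropy(x, m=3, tau=1) == pytest.approx(
                brute_force_pe(x, 3, 1), abs=1e-12)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            permutation_entropy(np.arange(6.0), m=6, tau=1)


class TestSpectrogram:
    def test_pure_tone_peaks_in_its_bin(self):
        fs = 100.0
        t = np.arange(int(60 * fs)) / fs
        rec = EEGRecord(np.sin(2 * np.pi * 10.0 * t), fs=fs)
        f, tt, S = compute_spectrogram(rec)
        for col in range(S.shape[1]):
            assert abs(f[np.argmax(S[:, col])] - 10.0) < 0.2

    def test_zero_record_gives_zero_power(self):
        rec = EEGRecord(np.zeros(3000), fs=100.0)
        _, _, S = compute_spectrogram(rec)
        assert np.all(S == 0.0)

    def test_parseval_energy_identity(self, rng):
        fs = 100.0
        rec = EEGRecord(rng.standard_normal(4000), fs=fs)
        f, tt, S = compute_spectrogram(rec, window_s=5.0, overlap_s=0.0, window="boxcar")
        df = f[1] - f[0]
        nper = int(5.0 * fs)
        for k, _ in enumerate(tt):
            seg = rec.samples[k * nper:(k + 1) * nper]
            assert S[:, k].sum() * df == pytest.approx(np.mean(seg**2), rel=1e-10)

    def test_too_short_record(self):
        with pytest.raises(InsufficientDataError):
            compute_spectrogram(EEGRecord(np.zeros(100), fs=100.0), window_s=10.0)


class TestBispectrum:
    def test_phase_coupled_triplet_peak(self):
        fs, dur = 100.0, 20.0
        t = np.arange(int(fs * dur)) / fs
        x = sum(np.cos(2 * np.pi * f * t) for f in (5.0, 8.0, 13.0))
        freqs, B = bispectrum(x, fs)
        i5, i8 = np.searchsorted(freqs, [5.0, 8.0])
        peak = B[i5, i8]
        tri = np.triu(np.ones_like(B, dtype=bool))
        assert peak > 20 * np.median(B[tri & (B > 0)])

    def test_phase_randomization_destroys_coupling(self, rng):
        fs, dur = 100.0, 40.0
        t = np.arange(int(fs * dur)) / fs
        aligned = sum(np.cos(2 * np.pi * f * t) for f in (5.0, 8.0, 13.0))
        # re-randomize the 13 Hz phase every second so sub-epoch triple
        # products average out
        randomized = np.cos(2 * np.pi * 5 * t) + np.cos(2 * np.pi * 8 * t)
        phase = np.repeat(rng.uniform(0, 2 * np.pi, int(dur)), int(fs))
        randomized = randomized + np.cos(2 * np.pi * 13 * t + phase)
        freqs, Ba = bispectrum(aligned, fs)
        _, Br = bispectrum(randomized, fs)
        i5, i8 = np.searchsorted(freqs, [5.0, 8.0])
        assert Br[i5, i8] < 0.2 * Ba[i5, i8]

    def test_zero_signal_zero_matrix(self):
        _, B = bispectrum(np.zeros(1000), 100.0)
        assert np.all(B == 0.0)

    def test_triangular_domain_only(self, rng):
        freqs, B = bispectrum(rng.standard_normal(1000), 100.0)
        f1 = freqs[:, None]
        f2 = freqs[None, :]
        outside = (f2 < f1) | (f1 <= 0) | (f1 + f2 > 50.0)
        assert np.all(B[outside] == 0.0)

    def test_too_short_segment(self):
        with pytest.raises(InsufficientDataError):
            bispectrum(np.zeros(100), 100.0)


class TestSynchFastSlow:
    def test_nonnegative_by_subset_sum(self, rng):
        x = rng.standard_normal(3000)
        assert synch_fast_slow(x, 100.0) >= 0.0

    def test_lowpass_filtering_raises_sfs(self, rng):
        from scipy import signal as sg
        x = rng.standard_normal(4000)
        sos = sg.butter(4, 20.0, btype="lowpass", fs=100.0, output="sos")
        x_lp = sg.sosfiltfilt(sos, x)
        assert synch_fast_slow(x_lp, 100.0) > synch_fast_slow(x, 100.0)

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError):
            synch_fast_slow(np.zeros(500), 50.0)

    def test_degenerate_spectrum_rejected(self):
        with pytest.raises(ArithmeticError):
            synch_fast_slow(np.zeros(1000), 100.0)


class TestMetricOverWindows:
    def test_single_window_record(self, rng):
        rec = EEGRecord(rng.standard_normal(1000), fs=100.0)
        series = metric_over_windows(rec, "PE")
        assert series.values.size == 1
        assert series.window_centers[0] == pytest.approx(5.0)

    def test_window_grid_follows_overlap(self, rng):
        rec = EEGRecord(rng.standard_normal(4000), fs=100.0)
        series = metric_over_windows(rec, "PE")
        assert np.allclose(np.diff(series.window_centers), 2.5)  # 10 s minus 7.5 s

    def test_stationary_noise_pe_stabilizes_with_window_length(self, rng):
        x = rng.standard_normal(60000)
        rec = EEGRecord(x, fs=100.0)
        short = metric_over_windows(rec, "PE", window_s=5.0, overlap_s=0.0)
        long = metric_over_windows(rec, "PE", window_s=20.0, overlap_s=0.0)
        assert long.values.std() < short.values.std()
        assert 0.85 < np.median(long.values) <= 1.0

    def test_normalized_series_spans_unit_interval(self, rng):
        rec = EEGRecord(rng.standard_normal(4000), fs=100.0)
        series = metric_over_windows(rec, "SFS").normalized()
        assert series.metric == "SFS_normalized"
        assert series.values.min() == 0.0 and series.values.max() == 1.0


class TestPearsonCorrelation:
    def test_self_and_negated(self, rng):
        x = rng.standard_normal(50)
        assert pearson_correlation(x, x) == pytest.approx(1.0)
        assert pearson_correlation(x, -x) == pytest.approx(-1.0)

    def test_orthogonal_sinusoids(self):
        t = np.linspace(0, 4 * 2 * np.pi, 4000, endpoint=False)
        assert pearson_correlation(np.sin(t), np.cos(t)) == pytest.approx(0.0, abs=1e-10)

    def test_constant_input_rejected(self):
        with pytest.raises(ArithmeticError):
            pearson_correlation(np.ones(10), np.arange(10.0))

    @given(
        x=st.lists(st.floats(min_value=-50, max_value=50), min_size=5, max_size=30),
        a=st.floats(min_value=0.1, max_value=10),
        b=st.floats(min_value=-5, max_value=5),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_symmetry_and_affine_invariance(self, x, a, b):
        x = np.array(x)
        y = np.linspace(-1, 1, x.size) + 0.1 * x
        if np.ptp(x) < 1e-6 or np.ptp(y) < 1e-6:  # avoid numerically degenerate inputs
            return
        r = pearson_correlation(x, y)
        assert pearson_correlation(y, x) == pytest.approx(r, abs=1e-9)
        assert pearson_correlation(a * x + b, y) == pytest.approx(r, abs=1e-6)
        assert -1.0 <= r <= 1.0


class TestStateSummary:
    def _series(self, centers, values):
        return MetricSeries(window_centers=np.asarray(centers, float),
                            values=np.asarray(values, float),
                            metric="PE", window_s=10.0, overlap_s=7.5)

    def test_constant_metric_collapses_summaries(self, short_timeline):
        s = self._series(np.arange(5, 160, 2.5), np.full(62, 0.7))
        out = state_summary(s, short_timeline)
        for st_ in ("conscious", "unconscious", "recovery"):
            assert out[st_].median == out[st_].min == out[st_].max == 0.7

    def test_gap_windows_are_excluded(self, short_timeline):
        centers = [10.0, 45.0, 70.0, 90.0, 110.0]  # 45 and 90 fall in gaps
        out = state_summary(self._series(centers, [1, 2, 3, 4, 5]), short_timeline)
        assert out["conscious"].n_windows == 1
        assert out["unconscious"].n_windows == 1
        assert out["recovery"].n_windows == 1

    def test_missing_number_time_falls_back_to_command(self):
        tl = AnesthesiaTimeline(object_time=30, syringe_drop_time=60, command_time=100)
        assert tl.unconscious_end == 100
        out = state_summary(self._series([70.0, 95.0], [0.5, 0.6]), tl)
        assert out["unconscious"].n_windows == 2

    def test_empty_state_flagged_not_raised(self, short_timeline):
        out = state_summary(self._series([70.0], [0.5]), short_timeline)
        assert out["conscious"].empty
        assert math.isnan(out["conscious"].median)
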