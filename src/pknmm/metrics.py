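"""Depth-of-anesthesia EEG metrics: spectrogram, permutation entropy, bispectral
SynchFastSlow, Pearson correlation and per-state summaries.

Permutation entropy is the Shannon entropy of ordinal-pattern frequencies of
the embedded series, normalized by ln(m!) so that PE ∈ [0, 1].  SynchFastSlow
is log10 of the summed bispectral magnitude over the 0.5–47 Hz triplet region
over the sum restricted to triplets with f1+f2 ∈ [40, 47] Hz; because the
denominator region is a subset of the numerator region, SFS ≥ 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .eeg import EEGRecord

__all__ = [
    "MetricSeries",
    "StateSummary",
    "InsufficientDataError",
    "compute_spectrogram",
    "permutation_entropy",
    "metric_over_windows",
    "bispectrum",
    "synch_fast_slow",
    "pearson_correlation",
    "state_summary",
]


class InsufficientDataError(ValueError):
    """The record or segment is too short for the requested analysis."""


# --------------------------------------------------------------------- STFT

def compute_spectrogram(
    record: EEGRecord,
    window_s: float = 10.0,
    overlap_s: float = 7.5,
    window: str = "hann",
    mode: str = "psd",
):
    """Short-time Fourier power of a record.

    Returns ``(freqs, times, S)`` with one-sided frequency axis 0..fs/2;
    defaults match the metric windowing (10-s windows, 7.5-s overlap).
    """
    nperseg = int(round(window_s * record.fs))
    noverlap = int(round(overlap_s * record.fs))
    if nperseg < 2:
        raise ValueError("window must span at least two samples")
    if noverlap >= nperseg:
        raise ValueError("overlap must be shorter than the window")
    if record.samples.size < nperseg:
        raise InsufficientDataError("record is shorter than one analysis window")
    return signal.spectrogram(
        record.samples, fs=record.fs, window=window,
        nperseg=nperseg, noverlap=noverlap, detrend=False,
        scaling="density", mode=mode,
    )


# -------------------------------------------------------- permutation entropy

def _ordinal_codes(segment: np.ndarray, m: int, tau: int) -> np.ndarray:
    """Integer code of each embedded vector's ordinal pattern.

    Ranks come from a stable argsort, so tied samples keep their temporal
    order (earlier sample ranks lower) — a deterministic tie rule.
    """
    x = np.asarray(segment, dtype=float)
    n_vec = x.size - (m - 1) * tau
    emb = np.lib.stride_tricks.sliding_window_view(x, (m - 1) * tau + 1)[:, ::tau]
    order = np.argsort(emb[:n_vec], axis=1, kind="stable")
    # encode the permutation as an integer in factorial-free positional form
    codes = np.zeros(n_vec, dtype=np.int64)
    for k in range(m):
        codes = codes * m + order[:, k]
    return codes


def permutation_entropy(segment, m: int = 6, tau: int = 1) -> float:
    """Normalized permutation entropy of a segment (∈ [0, 1]).

    The ordinal-pattern distribution is estimated over the
    ``len(segment) − (m−1)·τ`` embedded vectors and the Shannon entropy is
    normalized by ln(m!).
    """
    x = np.asarray(segment, dtype=float)
    if m < 2:
        raise ValueError("embedding dimension m must be ≥ 2")
    if tau < 1:
        raise ValueError("lag τ must be ≥ 1")
    if x.size <= (m - 1) * tau + 1:
        raise InsufficientDataError(
            f"segment of {x.size} samples too short for m={m}, τ={tau}")
    codes = _ordinal_codes(x, m, tau)
    _, counts = np.unique(codes, return_counts=True)
    p = counts / codes.size
    hp = -np.sum(p * np.log(p))
    return float(hp / math.log(math.factorial(m)))


# ------------------------------------------------------------- windowed metrics

@dataclass
class MetricSeries:
    """A metric evaluated on sliding windows of a record."""

    window_centers: np.ndarray  # s
    values: np.ndarray
    metric: str  # {"PE", "SFS", "SFS_normalized"}
    window_s: float
    overlap_s: float
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.window_centers) <= 0):
            raise ValueError("window centers must be strictly increasing")

    def normalized(self) -> "MetricSeries":
        """Min–max normalization of the series to [0, 1] (plotting convention)."""
        v = self.values
        span = v.max() - v.min()
        if span == 0:
            raise ValueError("cannot min–max normalize a constant series")
        return MetricSeries(self.window_centers, (v - v.min()) / span,
                            metric=f"{self.metric}_normalized",
                            window_s=self.window_s, overlap_s=self.overlap_s,
                            params=dict(self.params))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"window_center_s": self.window_centers,
                             "metric": self.metric, "value": self.values})


def metric_over_windows(
    record: EEGRecord,
    metric: str = "PE",
    window_s: float = 10.0,
    overlap_s: float = 7.5,
    m: int = 6,
    tau: int = 1,
) -> MetricSeries:
    """Evaluate PE or SFS on sliding windows (defaults 10 s / 7.5 s overlap)."""
    if metric not in ("PE", "SFS"):
        raise ValueError("metric must be 'PE' or 'SFS'")
    nper = int(round(window_s * record.fs))
    hop = nper - int(round(overlap_s * record.fs))
    if hop < 1:
        raise ValueError("overlap must be shorter than the window")
    x = record.samples
    if x.size < nper:
        raise InsufficientDataError("record is shorter than one window")
    starts = np.arange(0, x.size - nper + 1, hop)
    values = np.empty(starts.size)
    for j, s in enumerate(starts):
        seg = x[s:s + nper]
        if metric == "PE":
            values[j] = permutation_entropy(seg, m=m, tau=tau)
        else:
            values[j] = synch_fast_slow(seg, record.fs)
    centers = (starts + nper / 2.0) / record.fs
    params = {"m": m, "tau": tau} if metric == "PE" else {}
    return MetricSeries(window_centers=centers, values=values, metric=metric,
                        window_s=window_s, overlap_s=overlap_s, params=params)


# ------------------------------------------------------------------ bispectrum

def bispectrum(
    segment,
    fs: float,
    subepoch_s: float = 2.0,
    overlap: float = 0.5,
    window: str = "hann",
):
    """Sub-epoch-averaged bispectrum B(f1, f2) = |⟨X(f1)X(f2)X*(f1+f2)⟩|.

    The segment is split into Hann-windowed sub-epochs (default 2 s, 50%
    overlap); the complex triple products are averaged across sub-epochs
    before taking the magnitude, so phase-random triplets cancel.  Returns
    ``(freqs, B)`` on the triangular principal domain f2 ≥ f1 > 0,
    f1 + f2 ≤ fs/2 (zero elsewhere).
    """
    x = np.asarray(segment, dtype=float)
    nsub = int(round(subepoch_s * fs))
    if x.size < nsub:
        raise InsufficientDataError(
            f"segment of {x.size} samples shorter than one {subepoch_s}-s sub-epoch")
    hop = max(int(round(nsub * (1.0 - overlap))), 1)
    win = signal.get_window(window, nsub)
    starts = np.arange(0, x.size - nsub + 1, hop)
    nf = nsub // 2 + 1
    freqs = np.fft.rfftfreq(nsub, d=1.0 / fs)
    acc = np.zeros((nf, nf), dtype=complex)
    i1 = np.arange(nf)[:, None]
    i2 = np.arange(nf)[None, :]
    isum = i1 + i2
    valid = (i2 >= i1) & (i1 > 0) & (isum < nf)
    isum_c = np.where(valid, isum, 0)
    for s in starts:
        X = np.fft.rfft(x[s:s + nsub] * win)
        acc += np.where(valid, X[i1] * X[i2] * np.conj(X[isum_c]), 0.0)
    B = np.abs(acc / starts.size)
    return freqs, B


def synch_fast_slow(
    segment,
    fs: float,
    full_band: tuple[float, float] = (0.5, 47.0),
    slow_sum_band: tuple[float, float] = (40.0, 47.0),
    **bispec_kw,
) -> float:
    """SynchFastSlow: log10 ratio of bispectral sums.

    Numerator: all triplets with f1 ≥ 0.5 Hz and f1+f2 ≤ 47 Hz.  Denominator:
    the subset with f1+f2 ∈ [40, 47] Hz.  Requires fs ≥ 100 Hz so 47 Hz is
    resolvable.
    """
    if fs < 2 * full_band[1] + 6:  # Nyquist must cover 47 Hz; 100 Hz in practice
        raise ValueError("sampling rate too low to resolve the 47 Hz band edge")
    freqs, B = bispectrum(segment, fs, **bispec_kw)
    f1 = freqs[:, None]
    f2 = freqs[None, :]
    fsum = f1 + f2
    tri = (f2 >= f1) & (f1 >= full_band[0]) & (fsum <= full_band[1])
    num = B[tri].sum()
    den = B[tri & (fsum >= slow_sum_band[0])].sum()
    if den <= 0:
        raise ArithmeticError("degenerate spectrum: no bispectral power in 40–47 Hz")
    return float(np.log10(num / den))


# ------------------------------------------------------------------ correlation

def pearson_correlation(x1, x2) -> float:
    """Pearson correlation coefficient (covariance over the product of SDs)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape or x1.size < 3:
        raise ValueError("series must have equal length ≥ 3")
    if np.ptp(x1) == 0 or np.ptp(x2) == 0:
        raise ArithmeticError("correlation undefined for a constant series")
    return float(np.corrcoef(x1, x2)[0, 1])


# ------------------------------------------------------------- state summaries

@dataclass(frozen=True)
class StateSummary:
    """Median/min/max of a metric within one behavioral state."""

    state: str  # {"conscious", "unconscious", "recovery"}
    median: float
    min: float
    max: float
    n_windows: int

    @property
    def empty(self) -> bool:
        return self.n_windows == 0


def state_summary(series: MetricSeries, timeline) -> dict[str, StateSummary]:
    """Assign metric windows to behavioral states and summarize each.

    Conscious: window centers before object time.  Unconscious: syringe-drop
    time (loss of consciousness) to number time, or to command time when no
    number was recalled.  Recovery: after command time.  Windows in the gaps
    are excluded.  Empty states yield a flagged (NaN) summary, not an error.
    """
    t = series.window_centers
    v = series.values
    bounds = {
        "conscious": (-np.inf, timeline.object_time),
        "unconscious": (timeline.syringe_drop_time, timeline.unconscious_end),
        "recovery": (timeline.command_time, np.inf),
    }
    out = {}
    for state, (lo, hi) in bounds.items():
        sel = v[(t >= lo) & (t < hi)]
        if sel.size == 0:
            out[state] = StateSummary(state, math.nan, math.nan, math.nan, 0)
        else:
            out[state] = StateSummary(state, float(np.median(sel)),
                                      float(sel.min()), float(sel.max()), int(sel.size))
    return out
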