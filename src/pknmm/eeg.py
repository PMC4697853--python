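"""Single-channel EEG container with CSV/EDF I/O and rational resampling."""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

__all__ = ["EEGRecord"]

_PROVENANCES = ("simulated", "surrogate", "external")


@dataclass
class EEGRecord:
    """Uniformly sampled single-channel signal.

    ``provenance`` records whether the signal came out of the cortical model
    (``simulated``), the surrogate generator (``surrogate``) or a file supplied
    by the user (``external``).
    """

    samples: np.ndarray
    fs: float  # Hz
    provenance: str = "external"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.ndim != 1:
            raise ValueError("expected a single-channel 1-D signal")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.provenance not in _PROVENANCES:
            raise ValueError(f"provenance must be one of {_PROVENANCES}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs

    def resample(self, fs_out: float) -> "EEGRecord":
        """Polyphase (anti-aliased) resampling to ``fs_out``."""
        if fs_out <= 0:
            raise ValueError("target rate must be positive")
        if np.isclose(fs_out, self.fs):
            return replace(self)
        frac = Fraction(fs_out / self.fs).limit_denominator(1000)
        out = signal.resample_poly(self.samples, frac.numerator, frac.denominator)
        return EEGRecord(out, fs=fs_out, provenance=self.provenance)

    def segment(self, t0: float, t1: float) -> np.ndarray:
        """Samples with t0 <= t < t1 (seconds)."""
        i0 = max(int(np.ceil(t0 * self.fs)), 0)
        i1 = min(int(np.ceil(t1 * self.fs)), self.samples.size)
        return self.samples[i0:i1]

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.times, "amplitude": self.samples}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, provenance: str = "external") -> "EEGRecord":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy()
        if t.size < 2:
            raise ValueError("need at least two samples to infer the rate")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("CSV time axis is not uniform")
        return cls(df["amplitude"].to_numpy(), fs=1.0 / dt[0], provenance=provenance)

    @classmethod
    def from_edf(cls, path, channel: int | str = 0) -> "EEGRecord":
        """Read one channel of an EDF file (requires the optional mne dependency)."""
        try:
            import mne
        except ImportError as exc:  # pragma: no cover
            raise ImportError("reading EDF requires the 'mne' package") from exc
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        if isinstance(channel, int):
            channel = raw.ch_names[channel]
        data = raw.get_data(picks=[channel])[0]
        return cls(data, fs=float(raw.info["sfreq"]), provenance="external")

    def to_edf(self, path) -> None:  # pragma: no cover - needs optional export backend
        """Write an EDF file via mne's exporter (requires its edfio backend)."""
        try:
            import mne
        except ImportError as exc:
            raise ImportError("writing EDF requires the 'mne' package") from exc
        info = mne.create_info(["EEG"], sfreq=self.fs, ch_types="eeg")
        raw = mne.io.RawArray(self.samples[np.newaxis, :] * 1e-3, info, verbose="error")
        raw.export(str(path), fmt="edf", overwrite=True)
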