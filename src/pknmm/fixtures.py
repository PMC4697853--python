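"""Synthetic inputs: surrogate "real" EEG and small hand-checkable series.

The clinical recordings behind the study protocol are not redistributable, so
the comparison pipeline is exercised against surrogate EEG built from
band-filtered Gaussian noise whose per-state band-power profile mimics
propofol phenomenology: broadband activity while conscious, delta/theta
dominance while unconscious, beta return during recovery.  Surrogates are
deliberately filtered noise — not autoregressive fits to clinical data — so
they cannot be mistaken for the unavailable recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .eeg import EEGRecord
from .pipeline import AnesthesiaTimeline

__all__ = ["SurrogateSpec", "generate_surrogate_reeg", "worked_example_series", "BANDS"]

#: canonical EEG bands (Hz)
BANDS = {"delta": (0.5, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 13.0), "beta": (13.0, 30.0)}

_DEFAULT_PROFILES = {
    # relative band power per state, summing to 1
    "conscious": {"delta": 0.15, "theta": 0.2, "alpha": 0.3, "beta": 0.35},
    "unconscious": {"delta": 0.6, "theta": 0.25, "alpha": 0.1, "beta": 0.05},
    "recovery": {"delta": 0.2, "theta": 0.2, "alpha": 0.25, "beta": 0.35},
}


@dataclass(frozen=True)
class SurrogateSpec:
    """Recipe for a surrogate EEG record with state-dependent spectra."""

    timeline: AnesthesiaTimeline
    profiles: dict = field(default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_PROFILES.items()})
    amplitude: float = 10.0  # µV-scale overall RMS
    seed: int = 0

    def __post_init__(self) -> None:
        for state, prof in self.profiles.items():
            total = sum(prof.values())
            if any(v < 0 for v in prof.values()):
                raise ValueError(f"negative band power in state {state!r}")
            if total <= 0:
                raise ValueError(f"all-zero band profile in state {state!r}")
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"band powers in state {state!r} must sum to 1")


def _band_noise(rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Unit-variance Gaussian noise confined exactly to ``band``.

    A brick-wall spectral mask (rather than an IIR filter) keeps the delivered
    band-power fractions on target: all of the component's power lies inside
    its nominal band.
    """
    x = rng.standard_normal(n)
    spectrum = np.fft.rfft(x)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spectrum[(f < band[0]) | (f >= band[1])] = 0.0  # brick-wall band limitation
    y = np.fft.irfft(spectrum, n)
    return y / y.std()


def _state_weights(times: np.ndarray, tl: AnesthesiaTimeline, fade_s: float = 10.0) -> dict:
    """Smooth mixing weight per state (cosine cross-fades at transitions).

    Conscious fades into unconscious across (object, syringe-drop); unconscious
    fades into recovery across ``fade_s`` after command time.
    """
    def ramp(t, t0, t1):
        z = np.clip((t - t0) / max(t1 - t0, 1e-9), 0.0, 1.0)
        return 0.5 - 0.5 * np.cos(np.pi * z)

    to_unconscious = ramp(times, tl.object_time, tl.syringe_drop_time)
    to_recovery = ramp(times, tl.command_time, tl.command_time + fade_s)
    w_rec = to_recovery
    w_unc = to_unconscious * (1.0 - to_recovery)
    w_con = (1.0 - to_unconscious) * (1.0 - to_recovery)
    return {"conscious": w_con, "unconscious": w_unc, "recovery": w_rec}


def generate_surrogate_reeg(spec: SurrogateSpec, fs: float = 100.0) -> EEGRecord:
    """Deterministic surrogate EEG for a session (provenance ``surrogate``).

    Each state's signal is a weighted sum of band-limited unit-variance noise
    components with weights √(relative band power); state signals are mixed
    with smooth amplitude envelopes so spectra cross-fade at the behavioral
    transitions.
    """
    n = int(round(spec.timeline.session_end * fs))
    times = np.arange(n) / fs
    rng = np.random.default_rng(spec.seed)
    weights = _state_weights(times, spec.timeline)
    out = np.zeros(n)
    for state in ("conscious", "unconscious", "recovery"):
        prof = spec.profiles[state]
        sig_state = np.zeros(n)
        for band, rel in prof.items():
            if rel > 0:
                sig_state += np.sqrt(rel) * _band_noise(rng, n, fs, BANDS[band])
        # envelope applies in amplitude; power mixes as the envelope squared
        out += np.sqrt(weights[state]) * sig_state
    out *= spec.amplitude / out.std()
    return EEGRecord(out, fs=fs, provenance="surrogate")


def worked_example_series() -> dict:
    """Small named fixtures reused across the test-suite's hand checks.

    * ``pe_series``: the 7-point series whose m=2 ordinal-pair distribution
      (4 rising, 2 falling) gives PE = −((2/3)ln(2/3)+(1/3)ln(1/3))/ln 2.
    * ``tone_freqs`` / ``tone_signal``: three phase-aligned cosines at 5, 8 and
      13 Hz — a quadratic phase-coupled triplet with a bispectral peak at (5, 8).
    * ``one_compartment``: Schnider parameters for subject-like demographics
      with the peripheral rate constants zeroed, for which the central
      compartment has the closed form C1(t) = u/(V1 k10) (1 − exp(−k10 t)).
    """
    from .pk import SubjectProfile, derive_schnider_params

    def tone_signal(fs: float = 100.0, duration: float = 20.0) -> np.ndarray:
        t = np.arange(int(fs * duration)) / fs
        return sum(np.cos(2 * np.pi * f * t) for f in (5.0, 8.0, 13.0))

    profile = SubjectProfile(id="fixture", sex="male", age=39, weight=98, height=191)
    one_compartment = derive_schnider_params(profile).zeroed("k12", "k13")
    return {
        "pe_series": np.array([4.0, 7.0, 9.0, 10.0, 6.0, 11.0, 3.0]),
        "tone_freqs": (5.0, 8.0, 13.0),
        "tone_signal": tone_signal,
        "one_compartment": one_compartment,
    }
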