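"""Stochastic neural mass model of a cortical macrocolumn under propofol.

The cortex is reduced to a single spatially homogeneous macrocolumn of
interacting excitatory (≈85%) and inhibitory (≈15%) populations, following the
Steyn-Ross/Liley mean-field formulation.  The state of the cortex is carried
by two variables, the population-mean soma potentials ``he`` and ``hi`` (mV).
Synaptic input arrives through postsynaptic-potential channels with the
alpha-type impulse response ``γ t exp(1 − γ t)`` (unit peak at t = 1/γ);
long-range cortico-cortical flux and subcortical input add to the local
firing-rate drive.  Propofol potentiates GABA_A inhibition by holding
postsynaptic chloride channels open longer, modeled by stretching the
inhibitory kernel, ``γi → γi / λ``, with the dimensionless anesthetic factor
λ ∈ [1, 1.49] driven by the rescaled effect-site concentration.  Lengthening
the IPSP leaves its peak amplitude unchanged, so the transferred charge — the
steady inhibitory gain — grows by the factor λ.

Model reduction used here.  The synaptic rate constants (γe = 300 1/s,
cortico-cortical flux ≈ 2800 1/s) are fast against the population response
times (τe = 94 ms, τi = 42 ms), so the deterministic synaptic feedback is
slaved to its quasi-steady value (adiabatic elimination), giving the planar
drift

    τe dhe/dt = (he_rest − he) + ψee(he)·Iee + ψie(he)·Iie
    τi dhi/dt = (hi_rest − hi) + ψei(hi)·Iei + ψii(hi)·Iii

    Iee = (e·Ge/γe)·[(Nee_beta + Nee_alpha)·Se(he) + pee] + ñee
    Iei = (e·Ge/γe)·[(Nei_beta + Nei_alpha)·Se(he) + pei] + ñei
    Iie = (e·Gi·λ/γi)·[Nie_beta·Si(hi) + pie] + ñie
    Iii = (e·Gi·λ/γi)·[Nii_beta·Si(hi) + pii] + ñii

with reversal-potential weights ψjk(h) = (hj_rev − h)/|hj_rev − hk_rest| and
sigmoid rates Sq(h) = Smax/(1 + exp(−gq (h − θq))).  The subcortical inputs
are stochastic; their zero-mean fluctuations ñjk are NOT slaved — each is
white noise filtered by its own PSP kernel, ``(d/dt + γ)² ñ = e G γ σ ξ(t)``,
so the anesthetic stretching of the inhibitory kernel also reddens the input
noise.  This reduction keeps the active equilibrium branch stable up to its
saddle-node (λc ≈ 1.50): the loss-of-consciousness transition is a
first-order phase transition approached from below, and fluctuations about
the steady state — the source of the simulated EEG — grow and slow as the
fold is approached (the biphasic surge).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import optimize

from ._kernels import em_chunk
from .eeg import EEGRecord

__all__ = [
    "NMMParameters",
    "AnestheticDrive",
    "SteadyState",
    "CorticalTrajectory",
    "DivergenceError",
    "BracketError",
    "psp_kernel",
    "compute_steady_states",
    "track_steady_states",
    "steady_state_vector",
    "simulate_cortex",
    "extract_seeg",
]

#: physiological soma-potential bounds (mV); leaving them aborts a simulation
H_BOUNDS = (-90.0, -10.0)


class DivergenceError(RuntimeError):
    """Cortical state escaped the physiological soma-potential bounds."""


class BracketError(RuntimeError):
    """No equilibrium found in the scanned physiological bracket."""


@dataclass(frozen=True)
class NMMParameters:
    """Macrocolumn constants (Steyn-Ross/Liley mean-field lineage).

    Units: potentials mV, rates 1/s, counts dimensionless.  The connectivity
    counts encode the ≈85:15 excitatory:inhibitory population split
    (``exc_fraction`` is descriptive and fixed).  ``sigma_jk`` are the white-
    noise amplitudes of the subcortical inputs (None for the excitatory
    channels means the shot-noise value √p̄); all are multiplied by
    ``noise_scale``.  ``axon_rate`` is the cortico-cortical flux rate vΛ; in
    the reduction used here that channel is slaved (it is the fastest rate in
    the system), so the value is retained for reference only.
    """

    he_rest: float = -70.0        # resting soma potential, excitatory (mV)
    hi_rest: float = -70.0        # resting soma potential, inhibitory (mV)
    he_rev: float = 45.0          # excitatory (AMPA) reversal potential (mV)
    hi_rev: float = -90.0         # inhibitory (GABA) reversal potential (mV)
    tau_e: float = 0.094          # population response time, excitatory (s)
    tau_i: float = 0.042          # population response time, inhibitory (s)
    gamma_e: float = 300.0        # EPSP rate constant (1/s)
    gamma_i: float = 65.0         # IPSP rate constant (1/s)
    Ge: float = 0.18              # EPSP peak amplitude (mV)
    Gi: float = 0.37              # IPSP peak amplitude (mV)
    Nee_beta: float = 3034.0      # local e→e connection count
    Nei_beta: float = 3034.0      # local e→i connection count
    Nie_beta: float = 536.0       # local i→e connection count
    Nii_beta: float = 536.0       # local i→i connection count
    Nee_alpha: float = 4000.0     # long-range e→e connection count
    Nei_alpha: float = 2000.0     # long-range e→i connection count
    smax_e: float = 100.0         # maximum firing rate, excitatory (1/s)
    smax_i: float = 100.0         # maximum firing rate, inhibitory (1/s)
    theta_e: float = -60.0        # sigmoid threshold (mV)
    theta_i: float = -60.0
    slope_e: float = 0.28         # sigmoid slope (1/mV)
    slope_i: float = 0.14
    p_ee: float = 1100.0          # mean subcortical input rates (1/s)
    p_ei: float = 1600.0
    p_ie: float = 0.0
    p_ii: float = 0.0
    sigma_ee: float | None = None  # subcortical noise amplitudes (1/s); None → √p̄
    sigma_ei: float | None = None
    sigma_ie: float = 2.0
    sigma_ii: float = 2.0
    noise_scale: float = 1.0      # global multiplier on all noise amplitudes
    axon_rate: float = 2800.0     # vΛ cortico-cortical flux rate (slaved; reference)
    exc_fraction: float = 0.85    # excitatory share of the macrocolumn population

    def __post_init__(self) -> None:
        if not (self.gamma_e > 0 and self.gamma_i > 0):
            raise ValueError("PSP rate constants must be positive")
        if self.noise_scale < 0:
            raise ValueError("noise amplitude must be non-negative")
        for name in ("sigma_ie", "sigma_ii"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.exc_fraction != 0.85:
            raise ValueError("the excitatory:inhibitory population ratio is fixed at 85:15")

    def noise_amplitudes(self) -> np.ndarray:
        """Per-channel amplitudes (ee, ei, ie, ii), scaled by ``noise_scale``."""
        s_ee = math.sqrt(self.p_ee) if self.sigma_ee is None else self.sigma_ee
        s_ei = math.sqrt(self.p_ei) if self.sigma_ei is None else self.sigma_ei
        return self.noise_scale * np.array([s_ee, s_ei, self.sigma_ie, self.sigma_ii])

    def replace(self, **kw) -> "NMMParameters":
        return replace(self, **kw)

    def sigmoid_e(self, h):
        return self.smax_e / (1.0 + np.exp(-self.slope_e * (np.asarray(h) - self.theta_e)))

    def sigmoid_i(self, h):
        return self.smax_i / (1.0 + np.exp(-self.slope_i * (np.asarray(h) - self.theta_i)))


def psp_kernel(gamma: float, t) -> np.ndarray:
    """Alpha-type postsynaptic-potential kernel γt·exp(1−γt); unit peak at t = 1/γ.

    Replacing γ by γ/λ (λ > 1) stretches the time-to-peak and duration by the
    factor λ while leaving the peak at 1 — the anesthetic action on the IPSP.
    """
    if gamma <= 0:
        raise ValueError("rate constant must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("kernel is defined for non-negative times only")
    return gamma * t * np.exp(1.0 - gamma * t)


# --------------------------------------------------------------------------
# steady states
# --------------------------------------------------------------------------

def _input_gains(p: NMMParameters, lam: float):
    ke = math.e * p.Ge / p.gamma_e          # steady EPSP input gain (mV·s)
    ki = math.e * p.Gi * lam / p.gamma_i    # steady IPSP input gain; λ deepens inhibition
    return ke, ki


def equilibrium_residuals(he, hi, p: NMMParameters, lam: float):
    """Residuals of the noise-free, derivative-zero soma equations (mV)."""
    ke, ki = _input_gains(p, lam)
    se = p.sigmoid_e(he)
    si = p.sigmoid_i(hi)
    iee0 = ke * (p.Nee_beta * se + p.Nee_alpha * se + p.p_ee)
    iei0 = ke * (p.Nei_beta * se + p.Nei_alpha * se + p.p_ei)
    iie0 = ki * (p.Nie_beta * si + p.p_ie)
    iii0 = ki * (p.Nii_beta * si + p.p_ii)
    psi_ee = (p.he_rev - he) / abs(p.he_rev - p.he_rest)
    psi_ie = (p.hi_rev - he) / abs(p.hi_rev - p.he_rest)
    psi_ei = (p.he_rev - hi) / abs(p.he_rev - p.hi_rest)
    psi_ii = (p.hi_rev - hi) / abs(p.hi_rev - p.hi_rest)
    fe = p.he_rest - he + psi_ee * iee0 + psi_ie * iie0
    fi = p.hi_rest - hi + psi_ei * iei0 + psi_ii * iii0
    return fe, fi


def _hi_roots(he: float, p: NMMParameters, lam: float, n_scan: int = 256) -> list[float]:
    lo, hi_b = H_BOUNDS[0] + 1e-6, H_BOUNDS[1] - 1e-6
    grid = np.linspace(lo, hi_b, n_scan)
    vals = equilibrium_residuals(he, grid, p, lam)[1]
    roots = []
    sign = np.sign(vals)
    idx = np.where(sign[:-1] * sign[1:] < 0)[0]
    for i in idx:
        r = optimize.brentq(lambda x: equilibrium_residuals(he, x, p, lam)[1],
                            grid[i], grid[i + 1], xtol=1e-12)
        roots.append(r)
    exact = np.where(vals == 0.0)[0]
    roots.extend(grid[exact].tolist())
    return sorted(roots)


@dataclass(frozen=True)
class SteadyState:
    """One equilibrium of the macrocolumn at a fixed anesthetic factor."""

    lam: float
    he0: float  # mV
    hi0: float  # mV
    branch: str  # {"bottom", "middle", "top"}
    residual: float  # ∞-norm of the equilibrium equations (mV)


def compute_steady_states(
    p: NMMParameters,
    lam: float,
    n_grid: int = 2001,
    tol: float = 1e-9,
) -> list[SteadyState]:
    """All equilibria at anesthetic factor ``lam``, sorted by he0.

    The excitatory potential axis is scanned densely inside the physiological
    bracket; each sign change of the reduced residual (with ``hi`` eliminated
    by an inner root solve) is polished with Brent's method.  Three coexisting
    roots are labeled bottom/middle/top; a lone root is labeled by its firing
    regime relative to the sigmoid threshold.
    """
    if lam < 1.0:
        raise ValueError("anesthetic factor λ must be ≥ 1")

    def reduced(he: float) -> float:
        r = _hi_roots(he, p, lam)
        if not r:
            raise BracketError(
                f"no inhibitory equilibrium for he={he:.2f} mV in bracket {H_BOUNDS}")
        return equilibrium_residuals(he, r[0], p, lam)[0]

    lo, hi_b = H_BOUNDS[0] + 1e-6, H_BOUNDS[1] - 1e-6
    grid = np.linspace(lo, hi_b, n_grid)
    vals = np.array([reduced(x) for x in grid])
    idx = np.where(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]
    if idx.size == 0 and not np.any(vals == 0.0):
        raise BracketError(
            f"no equilibrium found for λ={lam} scanning he in [{lo:.2f}, {hi_b:.2f}] mV")
    roots = []
    for i in idx:
        he0 = optimize.brentq(reduced, grid[i], grid[i + 1], xtol=1e-12)
        hi0 = _hi_roots(he0, p, lam)[0]
        res = max(abs(v) for v in equilibrium_residuals(he0, hi0, p, lam))
        if res < tol:
            roots.append((he0, hi0, res))
    roots.sort(key=lambda r: r[0])
    labels = _branch_labels(len(roots), [r[0] for r in roots], p)
    return [SteadyState(lam=lam, he0=he0, hi0=hi0, branch=lab, residual=res)
            for (he0, hi0, res), lab in zip(roots, labels)]


def _branch_labels(n: int, he0s: Sequence[float], p: NMMParameters) -> list[str]:
    if n == 3:
        return ["bottom", "middle", "top"]
    # lone equilibrium: classify by firing regime relative to the sigmoid midpoint
    return ["top" if he0 >= p.theta_e else "bottom" for he0 in he0s]


def _polish(p: NMMParameters, lam: float, guess: tuple[float, float]):
    sol = optimize.root(lambda x: equilibrium_residuals(x[0], x[1], p, lam),
                        x0=np.asarray(guess), method="hybr", tol=1e-13)
    he0, hi0 = sol.x
    res = max(abs(v) for v in equilibrium_residuals(he0, hi0, p, lam))
    ok = sol.success and res < 1e-8 and H_BOUNDS[0] < he0 < H_BOUNDS[1]
    return ok, he0, hi0, res


def track_steady_states(
    p: NMMParameters,
    lam_values: np.ndarray,
    start: SteadyState | None = None,
) -> np.ndarray:
    """Continuation of one equilibrium branch along a λ schedule.

    Starts on the top (active) branch at ``lam_values[0]`` unless ``start`` is
    given, then follows the branch by Newton polishing from the previous
    solution.  If the branch is lost at a fold, a single jump to the nearest
    surviving equilibrium is taken.  Returns an array (n, 2) of (he0, hi0).
    """
    lam_values = np.asarray(lam_values, dtype=float)
    if start is None:
        roots = compute_steady_states(p, float(lam_values[0]))
        start = roots[-1]  # top branch: largest he0
    out = np.empty((lam_values.size, 2))
    prev = (start.he0, start.hi0)
    for i, lam in enumerate(lam_values):
        ok, he0, hi0, _res = _polish(p, float(lam), prev)
        if not ok or abs(he0 - prev[0]) > 5.0:
            # fold crossing (or solver failure): fall back to a full scan and
            # jump to the equilibrium nearest the previous branch point
            roots = compute_steady_states(p, float(lam))
            he0, hi0 = min(((r.he0, r.hi0) for r in roots),
                           key=lambda r: abs(r[0] - prev[0]))
        out[i] = (he0, hi0)
        prev = (he0, hi0)
    return out


def steady_state_vector(p: NMMParameters, lam: float, he0: float, hi0: float) -> np.ndarray:
    """Full 10-component state vector at an equilibrium.

    The noise channels are zero-mean fluctuations, so the equilibrium state is
    simply (he0, hi0) with all channels at rest.
    """
    y = np.zeros(10)
    y[0], y[1] = he0, hi0
    return y


# --------------------------------------------------------------------------
# stochastic simulation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AnestheticDrive:
    """Anesthetic factor λ(t) on a uniform knot grid, held piecewise constant."""

    times: np.ndarray  # s, uniform from 0
    lam: np.ndarray    # dimensionless, ≥ 1

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        lam = np.asarray(self.lam, dtype=float)
        if t.size != lam.size or t.size < 1:
            raise ValueError("times and λ must be equal-length, non-empty")
        if t.size > 1:
            dt = np.diff(t)
            if not np.allclose(dt, dt[0]):
                raise ValueError("drive knots must be uniformly spaced")
        if np.any(lam < 1.0):
            raise ValueError("anesthetic factor λ must be ≥ 1 everywhere")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "lam", lam)

    @property
    def spacing(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else 1.0

    @property
    def duration(self) -> float:
        return float(self.times[-1])

    @classmethod
    def constant(cls, lam: float, duration: float, spacing: float = 1.0) -> "AnestheticDrive":
        t = np.arange(0.0, duration + spacing / 2, spacing)
        return cls(times=t, lam=np.full(t.size, float(lam)))

    @classmethod
    def from_pk(cls, traj, spacing: float = 1.0) -> "AnestheticDrive":
        """Zero-order sample of rCeff onto the drive grid (PK is far slower than the NMM)."""
        rc = traj.rCeff
        if rc is None:
            from .pk import rescale_ceff
            rc = rescale_ceff(traj.Ceff)
        t = np.arange(0.0, traj.times[-1] + spacing / 2, spacing)
        idx = np.searchsorted(traj.times, t, side="right") - 1
        return cls(times=t, lam=rc[np.clip(idx, 0, rc.size - 1)])


@dataclass
class CorticalTrajectory:
    """Recorded macrocolumn state on a uniform output grid.

    ``I_jk`` are the four synaptic input series (slaved mean part plus
    stochastic channel), ``phi_ee``/``phi_ei`` the slaved long-range flux, and
    ``steady_he`` the steady-state continuation track on the same grid.
    """

    times: np.ndarray
    he: np.ndarray
    hi: np.ndarray
    I_ee: np.ndarray
    I_ei: np.ndarray
    I_ie: np.ndarray
    I_ii: np.ndarray
    phi_ee: np.ndarray
    phi_ei: np.ndarray
    steady_he: np.ndarray
    seed: int
    fs: float

    def __post_init__(self) -> None:
        lo, hi_b = H_BOUNDS
        for name in ("he", "hi"):
            v = getattr(self, name)
            if np.any((v <= lo) | (v >= hi_b)):
                raise DivergenceError(f"{name} outside physiological bounds {H_BOUNDS}")


_CHUNK = 1_000_000


def simulate_cortex(
    params: NMMParameters,
    drive: AnestheticDrive,
    step: float = 1e-4,
    seed: int = 0,
    record_fs: float = 1000.0,
    initial: np.ndarray | None = None,
    track_spacing: float = 1.0,
) -> CorticalTrajectory:
    """Integrate the stochastic macrocolumn model under an anesthetic drive.

    Euler–Maruyama at fixed ``step``; noise enters only the four subcortical
    input channels, each fed by an independent substream spawned
    deterministically from ``seed``.  The run starts on the active (top)
    equilibrium branch at λ(0) unless ``initial`` is given; the steady-state
    track is obtained by continuation along λ(t) at ``track_spacing``
    resolution and linearly interpolated onto the output grid.  Raises
    :class:`DivergenceError` if (he, hi) leave the physiological bounds.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    stiffest = max(params.gamma_e, params.gamma_i / float(np.min(drive.lam)),
                   1.0 / params.tau_e, 1.0 / params.tau_i)
    if step * stiffest > 0.5:
        raise ValueError(f"step {step} too large for stiffest rate {stiffest:.0f}/s")
    rec_every = int(round(1.0 / (record_fs * step)))
    if rec_every < 1 or abs(rec_every * record_fs * step - 1.0) > 1e-9:
        raise ValueError("record_fs must divide the integration rate")

    duration = drive.duration
    nsteps = int(round(duration / step))
    nrec = nsteps // rec_every + 1

    # steady-state continuation along the drive
    knot_t = np.arange(0.0, duration + track_spacing / 2, track_spacing)
    idx = np.clip(np.searchsorted(drive.times, knot_t, side="right") - 1, 0, drive.lam.size - 1)
    lam_knots = drive.lam[idx]
    track = track_steady_states(params, lam_knots)

    if initial is None:
        initial = steady_state_vector(params, float(lam_knots[0]), track[0, 0], track[0, 1])
    y = np.array(initial, dtype=float).copy()
    if y.shape != (10,):
        raise ValueError("initial state must have 10 components")

    rec = np.empty((8, nrec))
    sig = params.noise_amplitudes()
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(4)]

    done = 0
    while done < nsteps:
        n = min(_CHUNK, nsteps - done)
        noise = np.empty((4, n))
        for c in range(4):
            noise[c] = streams[c].standard_normal(n)
        bad = em_chunk(
            y, step, done, n, drive.lam, drive.spacing,
            sig[0], sig[1], sig[2], sig[3], noise,
            params.he_rest, params.hi_rest, params.he_rev, params.hi_rev,
            params.tau_e, params.tau_i, params.gamma_e, params.gamma_i,
            params.Ge, params.Gi,
            params.Nee_beta, params.Nei_beta, params.Nie_beta, params.Nii_beta,
            params.Nee_alpha, params.Nei_alpha,
            params.smax_e, params.smax_i, params.theta_e, params.theta_i,
            params.slope_e, params.slope_i,
            params.p_ee, params.p_ei, params.p_ie, params.p_ii,
            H_BOUNDS[0], H_BOUNDS[1], rec, rec_every,
        )
        if bad >= 0:
            raise DivergenceError(
                f"soma potential left {H_BOUNDS} mV at t = {bad * step:.4f} s")
        done += n
    if nsteps % rec_every == 0:  # final grid point, recorded from the end state
        ke, ki = _input_gains(params, float(lam_knots[-1]))
        se = float(params.sigmoid_e(y[0]))
        si = float(params.sigmoid_i(y[1]))
        rec[0, -1], rec[1, -1] = y[0], y[1]
        rec[2, -1] = ke * ((params.Nee_beta + params.Nee_alpha) * se + params.p_ee) + y[2]
        rec[3, -1] = ke * ((params.Nei_beta + params.Nei_alpha) * se + params.p_ei) + y[4]
        rec[4, -1] = ki * (params.Nie_beta * si + params.p_ie) + y[6]
        rec[5, -1] = ki * (params.Nii_beta * si + params.p_ii) + y[8]
        rec[6, -1] = params.Nee_alpha * se
        rec[7, -1] = params.Nei_alpha * se

    times = np.arange(nrec) * (rec_every * step)
    steady_he = np.interp(times, knot_t, track[:, 0])
    return CorticalTrajectory(
        times=times, he=rec[0], hi=rec[1],
        I_ee=rec[2], I_ei=rec[3], I_ie=rec[4], I_ii=rec[5],
        phi_ee=rec[6], phi_ei=rec[7],
        steady_he=steady_he, seed=seed, fs=record_fs,
    )


def extract_seeg(traj: CorticalTrajectory, fs_out: float = 100.0) -> EEGRecord:
    """Simulated EEG: he fluctuation about its steady-state track, resampled.

    The record is anti-alias filtered and decimated to ``fs_out`` (default
    100 Hz, the rate used for all metric analyses).
    """
    if fs_out > traj.fs:
        raise ValueError("fs_out exceeds the trajectory sampling rate")
    seeg = traj.he - traj.steady_he
    rec = EEGRecord(seeg, fs=traj.fs, provenance="simulated")
    if np.isclose(fs_out, traj.fs):
        return rec
    return rec.resample(fs_out)
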