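"""Schnider three-compartment pharmacokinetics of propofol with an effect site.

The central compartment (plasma) exchanges drug with two peripheral
compartments by first-order kinetics; a hypothetical effect compartment
equilibrates with plasma at rate ``ke0``.  Compartment volumes and clearances
are demographic functions (age, weight, height, sex via lean body mass) per
the Schnider population model.  Concentrations are in µg/mL (= mg/L),
volumes in L, clearances in L/min, rate constants in 1/min; the public time
axis is in seconds.

The rescaled effect-site concentration

    rCeff(t) = 0.49 * Ceff(t) / max(Ceff) + 1

maps any session's effect-site trajectory onto [1, 1.49], the admissible
range of the anesthetic-effect factor λ of the cortical model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SubjectProfile",
    "PKParameters",
    "InfusionProtocol",
    "PKTrajectory",
    "PKDomainError",
    "derive_schnider_params",
    "simulate_pk",
    "rescale_ceff",
    "normalize_timeline",
]

#: published Schnider plasma–effect-site equilibration constant (1/min)
DEFAULT_KE0 = 0.456


class PKDomainError(ValueError):
    """A demographic profile yields a non-positive PK quantity."""


@dataclass(frozen=True)
class SubjectProfile:
    """Demographics parameterizing the Schnider model."""

    id: str
    sex: str  # "male" | "female"
    age: float  # years
    weight: float  # kg
    height: float  # cm

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        for name in ("age", "weight", "height"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class PKParameters:
    """Volumes (L), clearances (L/min) and rate constants (1/min)."""

    V1: float
    V2: float
    V3: float
    Cl1: float
    Cl2: float
    Cl3: float
    k10: float
    k12: float
    k13: float
    k21: float
    k31: float
    ke0: float
    lbm: float

    def zeroed(self, *names: str) -> "PKParameters":
        """Copy with the given rate constants set to zero (reduced-model limits)."""
        return replace(self, **{n: 0.0 for n in names})


def lean_body_mass(sex: str, weight: float, height: float) -> float:
    """James lean-body-mass formula used by the Schnider model (kg)."""
    if sex == "male":
        return 1.1 * weight - 128.0 * weight**2 / height**2
    return 1.07 * weight - 148.0 * weight**2 / height**2


def derive_schnider_params(profile: SubjectProfile, ke0: float = DEFAULT_KE0) -> PKParameters:
    """Evaluate the Schnider demographic formulas and the derived rate constants.

    Raises :class:`PKDomainError` naming the offending quantity if any derived
    volume or clearance is non-positive (e.g. V2 at very advanced age).
    """
    lbm = lean_body_mass(profile.sex, profile.weight, profile.height)
    V1 = 4.27
    V2 = 18.9 - 0.391 * (profile.age - 53.0)
    V3 = 238.0
    Cl1 = (
        1.89
        + 0.0456 * (profile.weight - 77.0)
        - 0.0681 * (lbm - 59.0)
        + 0.0264 * (profile.height - 177.0)
    )
    Cl2 = 1.29 - 0.024 * (profile.age - 53.0)
    Cl3 = 0.836
    for name, value in [("lbm", lbm), ("V1", V1), ("V2", V2), ("V3", V3),
                        ("Cl1", Cl1), ("Cl2", Cl2), ("Cl3", Cl3), ("ke0", ke0)]:
        if not value > 0:
            raise PKDomainError(
                f"derived PK quantity {name} = {value:.4g} is not strictly positive "
                f"for subject {profile.id!r}"
            )
    return PKParameters(
        V1=V1, V2=V2, V3=V3, Cl1=Cl1, Cl2=Cl2, Cl3=Cl3,
        k10=Cl1 / V1, k12=Cl2 / V1, k13=Cl3 / V1,
        k21=Cl2 / V2, k31=Cl3 / V3,
        ke0=ke0, lbm=lbm,
    )


@dataclass(frozen=True)
class InfusionProtocol:
    """Piecewise-constant infusion rate over a session.

    ``rates[i]`` (mg/min) applies on ``[breakpoints[i], breakpoints[i+1])``;
    the final segment extends to ``duration`` (seconds).
    """

    breakpoints: tuple  # seconds, strictly increasing, starting at 0
    rates: tuple  # mg/min, one per segment
    duration: float  # seconds

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        r = np.asarray(self.rates, dtype=float)
        if bp.size != r.size:
            raise ValueError("need one rate per breakpoint segment")
        if bp.size == 0 or bp[0] != 0.0:
            raise ValueError("breakpoints must start at time 0")
        if np.any(np.diff(bp) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if np.any(r < 0):
            raise ValueError("infusion rates must be non-negative")
        if self.duration <= bp[-1]:
            raise ValueError("duration must exceed the last breakpoint")
        object.__setattr__(self, "breakpoints", tuple(bp))
        object.__setattr__(self, "rates", tuple(r))

    @classmethod
    def constant(cls, rate_mg_min: float, stop_s: float, duration_s: float) -> "InfusionProtocol":
        """Constant rate from t=0 until ``stop_s``, zero afterwards."""
        return cls(breakpoints=(0.0, float(stop_s)), rates=(float(rate_mg_min), 0.0),
                   duration=float(duration_s))

    @classmethod
    def from_ml_per_h(cls, rate_ml_h: float, stop_s: float, duration_s: float,
                      drug_conc_mg_ml: float = 10.0) -> "InfusionProtocol":
        """Syringe-driver convention: ml/h of a propofol solution (default 10 mg/ml)."""
        return cls.constant(rate_ml_h * drug_conc_mg_ml / 60.0, stop_s, duration_s)

    def rate_at(self, t: float) -> float:
        """Infusion rate (mg/min) at time t (seconds); zero outside the session."""
        if t < 0 or t >= self.duration:
            return 0.0
        idx = np.searchsorted(np.asarray(self.breakpoints), t, side="right") - 1
        return self.rates[idx]


@dataclass
class PKTrajectory:
    """Uniformly sampled compartment/effect-site concentration time series."""

    times: np.ndarray  # s
    C1: np.ndarray  # µg/mL
    C2: np.ndarray
    C3: np.ndarray
    Ceff: np.ndarray
    rCeff: np.ndarray | None = None

    def with_rceff(self) -> "PKTrajectory":
        return replace_traj(self, rCeff=rescale_ceff(self.Ceff))

    def to_frame(self) -> pd.DataFrame:
        data = {"time_s": self.times, "C1": self.C1, "C2": self.C2,
                "C3": self.C3, "Ceff": self.Ceff}
        data["rCeff"] = self.rCeff if self.rCeff is not None else np.full_like(self.times, np.nan)
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PKTrajectory":
        df = pd.read_csv(path)
        rc = df["rCeff"].to_numpy() if "rCeff" in df else None
        if rc is not None and np.all(np.isnan(rc)):
            rc = None
        return cls(times=df["time_s"].to_numpy(), C1=df["C1"].to_numpy(),
                   C2=df["C2"].to_numpy(), C3=df["C3"].to_numpy(),
                   Ceff=df["Ceff"].to_numpy(), rCeff=rc)


def replace_traj(traj: PKTrajectory, **kw) -> PKTrajectory:
    d = dict(times=traj.times, C1=traj.C1, C2=traj.C2, C3=traj.C3,
             Ceff=traj.Ceff, rCeff=traj.rCeff)
    d.update(kw)
    return PKTrajectory(**d)


def _pk_rhs(y: np.ndarray, u_mg_min: float, p: PKParameters) -> np.ndarray:
    # concentration-form three-compartment system + effect site; rates per minute
    C1, C2, C3, Ce = y
    dC1 = (-(p.k10 + p.k12 + p.k13) * C1
           + p.k21 * (p.V2 / p.V1) * C2
           + p.k31 * (p.V3 / p.V1) * C3
           + u_mg_min / p.V1)
    dC2 = p.k12 * (p.V1 / p.V2) * C1 - p.k21 * C2
    dC3 = p.k13 * (p.V1 / p.V3) * C1 - p.k31 * C3
    dCe = p.ke0 * (C1 - Ce)
    return np.array([dC1, dC2, dC3, dCe]) / 60.0  # per second


def simulate_pk(
    params: PKParameters,
    protocol: InfusionProtocol,
    step: float = 0.1,
    duration: float | None = None,
    initial: Sequence[float] = (0.0, 0.0, 0.0, 0.0),
) -> PKTrajectory:
    """Integrate the compartment system with classical RK4 on a fixed grid.

    The infusion is piecewise constant and its breakpoints are snapped onto the
    integration grid, so each RK4 step sees a single exact rate and the scheme
    retains full order.  ``duration`` defaults to the protocol duration.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if duration is None:
        duration = protocol.duration
    if duration < protocol.duration - 1e-9:
        raise ValueError("duration must cover the infusion protocol")
    n = int(round(duration / step))
    times = np.arange(n + 1) * step
    # snap breakpoints to grid indices; rate within a step = rate at its left edge
    y = np.zeros((n + 1, 4))
    y[0] = np.asarray(initial, dtype=float)
    for i in range(n):
        t = times[i]
        u = protocol.rate_at(round(t / step) * step)
        k1 = _pk_rhs(y[i], u, params)
        k2 = _pk_rhs(y[i] + 0.5 * step * k1, u, params)
        k3 = _pk_rhs(y[i] + 0.5 * step * k2, u, params)
        k4 = _pk_rhs(y[i] + step * k3, u, params)
        y[i + 1] = y[i] + (step / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    if np.any(y < -1e-9):
        t_bad = times[np.where(np.any(y < -1e-9, axis=1))[0][0]]
        raise ArithmeticError(f"negative concentration at t = {t_bad:.3f} s; integration failed")
    y = np.clip(y, 0.0, None)
    return PKTrajectory(times=times, C1=y[:, 0], C2=y[:, 1], C3=y[:, 2], Ceff=y[:, 3])


def rescale_ceff(ceff: np.ndarray) -> np.ndarray:
    """Map an effect-site concentration series onto [1, 1.49].

    ``rCeff = 0.49 * Ceff / max(Ceff) + 1``.  The maximum is taken over the
    *provided* series, so callers must pass the complete session trajectory.
    """
    ceff = np.asarray(ceff, dtype=float)
    if np.any(ceff < 0):
        raise ValueError("effect-site concentrations must be non-negative")
    peak = ceff.max() if ceff.size else 0.0
    if peak <= 0:
        raise ValueError("all-zero effect-site series: rescaling maximum undefined")
    return 0.49 * ceff / peak + 1.0


def normalize_timeline(traj: PKTrajectory, syringe_drop_time: float) -> PKTrajectory:
    """Express the time axis in units of the syringe-drop (loss-of-consciousness) time.

    Normalized time 1 marks loss of consciousness, letting sessions of
    different lengths be overlaid.
    """
    if not (syringe_drop_time > 0):
        raise ValueError("syringe_drop_time must be positive")
    if syringe_drop_time > traj.times[-1] + 1e-9:
        raise ValueError("syringe_drop_time lies outside the trajectory span")
    return replace_traj(traj, times=traj.times / syringe_drop_time)
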