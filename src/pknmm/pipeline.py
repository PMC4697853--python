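"""End-to-end anesthesia session pipeline: PK → cortical model → sEEG → metrics.

A session follows the study protocol: propofol infused at a constant
1500 mg/h (25 mg/min) from t = 0 until the syringe-drop time (loss of
consciousness), then stopped; behavioral event times partition the session
into conscious / unconscious / recovery states.  The nine-subject cohort
(demographics + event times) ships as package data.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as _metrics
from . import nmm as _nmm
from . import pk as _pk
from .eeg import EEGRecord

__all__ = [
    "AnesthesiaTimeline",
    "SubjectResult",
    "CohortSummary",
    "PipelineConfig",
    "load_cohort",
    "run_subject",
    "run_cohort",
    "compare_records",
]

#: study infusion rate: 1500 mg/h via syringe driver
STUDY_RATE_MG_MIN = 25.0
#: recording margin past the recovery-of-consciousness marker (s)
SESSION_MARGIN_S = 60.0
STATES = ("conscious", "unconscious", "recovery")


@dataclass(frozen=True)
class AnesthesiaTimeline:
    """Behavioral event times, seconds from infusion start.

    ``number_time`` is None for subjects who recalled no number on awaking;
    their unconscious state ends at ``command_time`` (the recovery marker).
    """

    object_time: float
    syringe_drop_time: float
    command_time: float
    number_time: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.object_time < self.syringe_drop_time < self.command_time):
            raise ValueError("need 0 < object < syringe-drop < command time")
        if self.number_time is not None and not (
                self.syringe_drop_time < self.number_time < self.command_time):
            raise ValueError("number time must lie between syringe-drop and command times")

    @property
    def unconscious_end(self) -> float:
        return self.number_time if self.number_time is not None else self.command_time

    @property
    def session_end(self) -> float:
        return self.command_time + SESSION_MARGIN_S

    # ---------------------------------------------------------------- file I/O
    @classmethod
    def from_file(cls, path) -> "AnesthesiaTimeline":
        """Parse `key=value` lines (object, syringe_drop, command, optional number)."""
        kv = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, val = line.partition("=")
                kv[key.strip()] = float(val)
        return cls(object_time=kv["object"], syringe_drop_time=kv["syringe_drop"],
                   command_time=kv["command"], number_time=kv.get("number"))

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"object={self.object_time:g}\n")
            fh.write(f"syringe_drop={self.syringe_drop_time:g}\n")
            if self.number_time is not None:
                fh.write(f"number={self.number_time:g}\n")
            fh.write(f"command={self.command_time:g}\n")


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the per-subject chain (units: s, Hz, mg/min, 1/min)."""

    infusion_rate_mg_min: float = STUDY_RATE_MG_MIN
    drug_conc_mg_ml: float = 10.0  # propofol solution strength for ml/h conversions
    ke0: float = _pk.DEFAULT_KE0
    pk_step: float = 0.1
    nmm_step: float = 1e-4
    record_fs: float = 1000.0
    eeg_fs: float = 100.0
    window_s: float = 10.0
    overlap_s: float = 7.5
    pe_m: int = 6
    pe_tau: int = 1
    nmm: _nmm.NMMParameters = field(default_factory=_nmm.NMMParameters)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        """Build from a flat key/value mapping; unknown keys go to the NMM parameters."""
        mine = {f for f in cls.__dataclass_fields__ if f != "nmm"}
        top = {k: v for k, v in mapping.items() if k in mine}
        nmm_kw = {k: v for k, v in mapping.items() if k not in mine}
        return cls(nmm=_nmm.NMMParameters(**nmm_kw), **top)


@dataclass
class SubjectResult:
    """Everything the pipeline produces for one subject."""

    profile: _pk.SubjectProfile
    timeline: AnesthesiaTimeline
    pk: _pk.PKTrajectory
    seeg: EEGRecord
    pe: _metrics.MetricSeries
    sfs: _metrics.MetricSeries
    pe_states: dict
    sfs_states: dict
    seed: int


@dataclass
class CohortSummary:
    """Cross-subject per-state aggregation of per-subject state medians."""

    per_subject: pd.DataFrame  # rows: subject × state × metric → median
    per_state: pd.DataFrame    # rows: state × metric → median/min/max across subjects


def load_cohort() -> list[tuple[_pk.SubjectProfile, AnesthesiaTimeline]]:
    """The nine-subject study cohort (demographics + event times) from package data."""
    base = importlib.resources.files("pknmm") / "data"
    subs = pd.read_csv(base / "subjects.csv")
    evts = pd.read_csv(base / "events.csv")
    merged = subs.merge(evts, on="id", validate="one_to_one")
    if len(merged) != len(subs) or len(merged) != len(evts):
        raise ValueError("subject and event tables do not match one-to-one")
    cohort = []
    for _, row in merged.iterrows():
        profile = _pk.SubjectProfile(id=str(row["id"]), sex=row["sex"], age=float(row["age"]),
                                     weight=float(row["weight"]), height=float(row["height"]))
        number = None if pd.isna(row["number_time"]) else float(row["number_time"])
        timeline = AnesthesiaTimeline(
            object_time=float(row["object_time"]),
            syringe_drop_time=float(row["syringe_drop_time"]),
            command_time=float(row["command_time"]),
            number_time=number,
        )
        cohort.append((profile, timeline))
    return cohort


def run_subject(
    profile: _pk.SubjectProfile,
    timeline: AnesthesiaTimeline,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> SubjectResult:
    """Simulate one subject's full session and compute its metric suite.

    Deterministic given (config, seed).  The infusion runs at the study rate
    until syringe-drop time; the session ends one minute after command time.
    """
    cfg = config or PipelineConfig()
    try:
        params = _pk.derive_schnider_params(profile, ke0=cfg.ke0)
        protocol = _pk.InfusionProtocol.constant(
            cfg.infusion_rate_mg_min, timeline.syringe_drop_time, timeline.session_end)
        pk_traj = _pk.simulate_pk(params, protocol, step=cfg.pk_step).with_rceff()
    except Exception as exc:
        raise RuntimeError(f"[pk stage, subject {profile.id}] {exc}") from exc
    try:
        drive = _nmm.AnestheticDrive.from_pk(pk_traj, spacing=1.0)
        traj = _nmm.simulate_cortex(cfg.nmm, drive, step=cfg.nmm_step, seed=seed,
                                    record_fs=cfg.record_fs)
        seeg = _nmm.extract_seeg(traj, fs_out=cfg.eeg_fs)
    except Exception as exc:
        raise RuntimeError(f"[nmm stage, subject {profile.id}] {exc}") from exc
    try:
        pe = _metrics.metric_over_windows(seeg, "PE", cfg.window_s, cfg.overlap_s,
                                          m=cfg.pe_m, tau=cfg.pe_tau)
        sfs = _metrics.metric_over_windows(seeg, "SFS", cfg.window_s, cfg.overlap_s)
        pe_states = _metrics.state_summary(pe, timeline)
        sfs_states = _metrics.state_summary(sfs, timeline)
    except Exception as exc:
        raise RuntimeError(f"[metrics stage, subject {profile.id}] {exc}") from exc
    return SubjectResult(profile=profile, timeline=timeline, pk=pk_traj, seeg=seeg,
                         pe=pe, sfs=sfs, pe_states=pe_states, sfs_states=sfs_states,
                         seed=seed)


def run_cohort(
    cohort: list[tuple[_pk.SubjectProfile, AnesthesiaTimeline]] | None = None,
    config: PipelineConfig | None = None,
    seed: int = 0,
    keep_results: bool = False,
):
    """Run every subject and aggregate per-state metric medians across subjects.

    Per-subject seeds are ``seed + index`` (documented rule: reproducible, with
    subject-level independence).  Returns a :class:`CohortSummary`, plus the
    per-subject results when ``keep_results``.
    """
    cohort = cohort if cohort is not None else load_cohort()
    rows = []
    results = []
    for i, (profile, timeline) in enumerate(cohort):
        res = run_subject(profile, timeline, config=config, seed=seed + i)
        if keep_results:
            results.append(res)
        for metric, states in (("PE", res.pe_states), ("SFS", res.sfs_states)):
            for state in STATES:
                s = states[state]
                if not s.empty:
                    rows.append({"subject": profile.id, "metric": metric,
                                 "state": state, "median": s.median})
    per_subject = pd.DataFrame(rows)
    agg = (per_subject.groupby(["metric", "state"])["median"]
           .agg(median="median", min="min", max="max", n="count").reset_index())
    summary = CohortSummary(per_subject=per_subject, per_state=agg)
    return (summary, results) if keep_results else summary


def cohort_state_medians(summary: CohortSummary, metric: str = "PE") -> dict[str, float]:
    """Convenience: {state: cross-subject median} for one metric."""
    df = summary.per_state
    sel = df[df["metric"] == metric]
    return {row["state"]: float(row["median"]) for _, row in sel.iterrows()}


def compare_records(
    a: EEGRecord,
    b: EEGRecord,
    timeline: AnesthesiaTimeline,
    config: PipelineConfig | None = None,
) -> dict:
    """Metric-level comparison of two EEG records of the same session.

    Both records are resampled to the analysis rate, windowed PE and SFS are
    computed on each, series are aligned by window center, and the Pearson
    correlation per metric is reported together with per-state summaries.
    """
    cfg = config or PipelineConfig()
    if abs(a.duration - b.duration) > cfg.window_s:
        raise ValueError(
            f"records span different sessions ({a.duration:.1f} s vs {b.duration:.1f} s)")
    a = a.resample(cfg.eeg_fs)
    b = b.resample(cfg.eeg_fs)
    report: dict = {"correlation": {}, "states": {}}
    for metric in ("PE", "SFS"):
        kw = dict(m=cfg.pe_m, tau=cfg.pe_tau) if metric == "PE" else {}
        sa = _metrics.metric_over_windows(a, metric, cfg.window_s, cfg.overlap_s, **kw)
        sb = _metrics.metric_over_windows(b, metric, cfg.window_s, cfg.overlap_s, **kw)
        n = min(sa.values.size, sb.values.size)
        if not np.allclose(sa.window_centers[:n], sb.window_centers[:n]):
            raise ValueError("metric windows of the two records do not align")
        report["correlation"][metric] = _metrics.pearson_correlation(
            sa.values[:n], sb.values[:n])
        report["states"][metric] = {
            "a": _metrics.state_summary(sa, timeline),
            "b": _metrics.state_summary(sb, timeline),
        }
    return report
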