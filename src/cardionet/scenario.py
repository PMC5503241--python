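"""Orchestration of the canonical simulation timeline and its summaries.

A scenario couples one network configuration, one controller/heart
parameterization and one pathology configuration to the canonical 18 000-s
timeline: initialization (setpoint 0.25, 0-500 s), steady state (setpoint 0.3,
500-2500 s), three pathology episodes with onset / recovery / demand-challenge
sub-events at the canonical times, aftermath re-initialization at 13 000 s, and
a final new-normal window to 18 000 s.

The recorded channels are the four headline traces — central drive D,
heart rate H, cardiac sympathetic efferent tone S and parasympathetic efferent
tone (direct pathway, networked pathway, and their plant-side mix) — plus the
setpoint, the controller's error integral and a phase label per sample.

The *benchmark balance* of a window is the time-averaged (S, P, D) triple;
scenario outcomes are summarized by the balance in the pre-pathology prelude
(500-2500 s) against the aftermath new normal (16 000-18 000 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .network import NetworkConfig, build_network
from .dynamics import NetworkState, PlasticityParams, advance, efferent_outputs
from .control import (
    ControllerParams,
    ControllerState,
    DirectParasymParams,
    HeartParams,
    HeartState,
    SetpointSchedule,
    direct_parasympathetic,
    heart_step,
    pi_demand,
)
from .pathology import (
    DerangementState,
    EpisodeSchedule,
    PathologyConfig,
    apply_derangement,
    apply_onset,
    apply_recovery,
    reinitialize_aftermath,
    select_affected,
)

__all__ = [
    "ScenarioConfig",
    "SimulationRecord",
    "BenchmarkBalance",
    "PreludeAftermathSummary",
    "run_timeline",
    "benchmark_balance",
    "prelude_aftermath_summary",
    "scenario_matrix",
]

# fixed offsets turning one master seed into independent component sub-seeds
_NETWORK_SEED_OFFSET = 10_007
_SELECTION_SEED_OFFSET = 20_011
_SEED_MOD = 2**31


@dataclass
class ScenarioConfig:
    """Everything needed to reproduce one full timeline run."""

    label: str = "fig04"
    description: str = ("stratified network, low diversity, unstable angina, "
                        "LCN and transducers affected and alive, no derangement")
    network: NetworkConfig = field(default_factory=NetworkConfig)
    controller: ControllerParams = field(default_factory=ControllerParams)
    heart: HeartParams = field(default_factory=HeartParams)
    direct_parasym: DirectParasymParams = field(
        default_factory=DirectParasymParams)
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    pathology: PathologyConfig = field(default_factory=PathologyConfig)
    schedule: EpisodeSchedule = field(default_factory=EpisodeSchedule)
    setpoint_init: float = 0.25
    setpoint_steady: float = 0.3
    setpoint_challenge: float = 0.35
    init_end: float = 500.0
    tau_a: float = 2.0
    init_heart_rate: float = 0.25
    init_p_dir: float = 0.1
    record_stride: int = 1
    master_seed: int = 0
    prelude_window: tuple[float, float] = (500.0, 2500.0)
    aftermath_window: tuple[float, float] = (16000.0, 18000.0)

    def setpoints(self) -> SetpointSchedule:
        return SetpointSchedule.canonical(
            init_level=self.setpoint_init,
            steady_level=self.setpoint_steady,
            challenge_level=self.setpoint_challenge,
            init_end=self.init_end,
            demand_times=tuple(self.schedule.demands),
            demand_duration=self.schedule.demand_duration,
            t_end=self.schedule.t_end,
        )

    def validate(self) -> None:
        self.network.validate()
        self.controller.validate()
        self.heart.validate()
        self.direct_parasym.validate()
        self.plasticity.validate()
        self.pathology.validate()
        self.schedule.validate()
        self.setpoints().validate()
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")
        n_init = self.init_end / self.controller.dt
        if abs(n_init - round(n_init)) > 1e-9:
            raise ValueError("init_end must be a multiple of dt")

    def derived_network_seed(self) -> int:
        return (int(self.master_seed) + _NETWORK_SEED_OFFSET) % _SEED_MOD

    def derived_selection_seed(self) -> int:
        return (int(self.master_seed) + _SELECTION_SEED_OFFSET) % _SEED_MOD


@dataclass
class SimulationRecord:
    """Time series of one run, sampled every ``record_stride`` steps."""

    time: np.ndarray
    setpoint: np.ndarray
    central_drive: np.ndarray
    heart_rate: np.ndarray
    sympathetic: np.ndarray
    parasym_networked: np.ndarray
    parasym_direct: np.ndarray
    parasym_combined: np.ndarray
    error_integral: np.ndarray
    phase: np.ndarray
    events: list[dict]
    config: ScenarioConfig

    def __len__(self) -> int:
        return self.time.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.time,
            "setpoint": self.setpoint,
            "central_drive": self.central_drive,
            "heart_rate": self.heart_rate,
            "sympathetic": self.sympathetic,
            "parasym_networked": self.parasym_networked,
            "parasym_direct": self.parasym_direct,
            "parasym_combined": self.parasym_combined,
            "phase": self.phase,
        })

    def window_mask(self, t_start: float, t_end: float) -> np.ndarray:
        return (self.time >= t_start) & (self.time < t_end)


@dataclass
class BenchmarkBalance:
    """Time-averaged channel tones over one window."""

    window: tuple[float, float]
    sympathetic: float
    parasym_direct: float
    parasym_networked: float
    parasym_combined: float
    central_drive: float

    def as_dict(self) -> dict:
        return {
            "window": list(self.window),
            "sympathetic": self.sympathetic,
            "parasym_direct": self.parasym_direct,
            "parasym_networked": self.parasym_networked,
            "parasym_combined": self.parasym_combined,
            "central_drive": self.central_drive,
        }


@dataclass
class PreludeAftermathSummary:
    """Prelude vs aftermath balances with the scenario's annotation flags."""

    label: str
    prelude: BenchmarkBalance
    aftermath: BenchmarkBalance
    deltas: dict
    flags: dict   # {'ans_derangement': 'Y'/'N', 'lcn': 'D'/'S'/'N', 'sensory': ...}

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "prelude": self.prelude.as_dict(),
            "aftermath": self.aftermath.as_dict(),
            "deltas": self.deltas,
            "flags": self.flags,
        }


def _phase_labels(times: np.ndarray, schedule: EpisodeSchedule,
                  init_end: float) -> np.ndarray:
    phase = np.full(times.shape[0], "steady", dtype=object)
    phase[times < init_end] = "init"
    for j, (i, r) in enumerate(zip(schedule.onsets, schedule.recoveries),
                               start=1):
        phase[(times >= i) & (times < r)] = f"I{j}"
        end = (schedule.demands[j - 1] if j <= len(schedule.demands)
               else schedule.t_end)
        phase[(times >= r) & (times < end)] = f"R{j}"
    for j, d in enumerate(schedule.demands, start=1):
        phase[(times >= d) & (times < d + schedule.demand_duration)] = f"D{j}"
    phase[times >= schedule.aftermath_start] = "aftermath"
    return phase.astype(str)


def run_timeline(config: ScenarioConfig, return_state: bool = False):
    """Execute one full scenario; identical config and seed give identical output.

    With ``return_state=True`` the final :class:`NetworkState` is returned
    alongside the record (useful for state-level assertions and debugging).
    """
    config.validate()
    dt = config.controller.dt
    schedule = config.schedule
    setpoints = config.setpoints()

    net_cfg = replace(config.network, seed=config.derived_network_seed())
    network = build_network(net_cfg)
    state = NetworkState(network, config.plasticity, tau_a=config.tau_a)

    pathology = replace(config.pathology,
                        selection_seed=config.derived_selection_seed())
    ctrl = ControllerState()
    heart = HeartState(h=config.init_heart_rate)
    p_dir = config.init_p_dir
    der = DerangementState(hr_factor=pathology.derangement_hr_factor,
                           demand_factor=pathology.derangement_demand_factor)

    n_steps = int(round(schedule.t_end / dt))
    step_of = lambda t: int(np.ceil(t / dt - 1e-9))
    onset_steps = [step_of(t) for t in schedule.onsets]
    recovery_steps = [step_of(t) for t in schedule.recoveries]
    aftermath_step = step_of(schedule.aftermath_start)

    stride = config.record_stride
    n_rec = (n_steps + stride - 1) // stride
    rec = {k: np.empty(n_rec) for k in
           ("time", "setpoint", "central_drive", "heart_rate", "sympathetic",
            "parasym_networked", "parasym_direct", "parasym_combined",
            "error_integral")}
    events: list[dict] = []
    applied_onsets: set = set()
    deranged_only_ids = None

    active_episode = -1      # index into schedule while within [I_j, R_j)
    pathology_on = pathology.enabled
    k = 0
    for n in range(n_steps):
        t = n * dt
        # 1. read the heart-rate history (H at the top of the step)
        ctrl.record(heart.h)
        h_star = setpoints.value(t)
        # 2. PI demand — the recorded "central drive"
        D = pi_demand(config.controller, ctrl, h_star, n)
        h_delayed = ctrl.delayed(n, config.controller.delay_steps)

        # 3/4. pathology hooks
        isch = 0.0
        if pathology_on:
            if active_episode >= 0 and n == recovery_steps[active_episode]:
                thawed = apply_recovery(state, der, pathology, t)
                events.append({"t": t, "event": "recovery",
                               "episode": active_episode + 1,
                               "thawed": int(thawed.size)})
                active_episode = -1
            for j, ns in enumerate(onset_steps):
                if n == ns:
                    affected = select_affected(state, pathology, j + 1)
                    apply_onset(state, affected, pathology, t,
                                _applied_onsets=applied_onsets)
                    if pathology.derangement_affected_only:
                        deranged_only_ids = affected["transducer"]
                    events.append({
                        "t": t, "event": "onset", "episode": j + 1,
                        "lcn_affected": affected["lcn"].tolist(),
                        "transducers_affected": affected["transducer"].tolist(),
                    })
                    active_episode = j
            if active_episode >= 0:
                isch = pathology.ischemic_drive_amplitude
                if pathology.derangement:
                    apply_derangement(
                        der, state, t,
                        schedule.onsets[active_episode],
                        schedule.recoveries[active_episode],
                        ramp_kind=pathology.derangement_ramp,
                        affected_only_ids=deranged_only_ids
                        if pathology.derangement_affected_only else None)
            if n == aftermath_step:
                reinitialize_aftermath(state, der, t)
                events.append({"t": t, "event": "aftermath_reinit"})

        # 5/6. network update (synchronous activities + plasticity)
        advance(state, D, h_delayed, isch, dt)
        # 7. lumped efferent outputs
        S, P_net = efferent_outputs(state)
        # 8. direct vagal pathway
        p_dir = direct_parasympathetic(p_dir, h_delayed, h_star, dt,
                                       config.direct_parasym)
        # 9. heart plant
        heart_step(heart, config.heart, S, P_net, p_dir, dt)

        # 10. record
        if n % stride == 0:
            i = n // stride
            rec["time"][i] = t
            rec["setpoint"][i] = h_star
            rec["central_drive"][i] = D
            rec["heart_rate"][i] = heart.h
            rec["sympathetic"][i] = S
            rec["parasym_networked"][i] = P_net
            rec["parasym_direct"][i] = p_dir
            rec["parasym_combined"][i] = (config.heart.alpha * P_net +
                                          (1 - config.heart.alpha) * p_dir)
            rec["error_integral"][i] = ctrl.error_integral

    phase = _phase_labels(rec["time"], schedule, config.init_end)
    record = SimulationRecord(
        time=rec["time"], setpoint=rec["setpoint"],
        central_drive=rec["central_drive"], heart_rate=rec["heart_rate"],
        sympathetic=rec["sympathetic"],
        parasym_networked=rec["parasym_networked"],
        parasym_direct=rec["parasym_direct"],
        parasym_combined=rec["parasym_combined"],
        error_integral=rec["error_integral"],
        phase=phase, events=events, config=config)
    if return_state:
        return record, state
    return record


def benchmark_balance(record: SimulationRecord,
                      window: tuple[float, float]) -> BenchmarkBalance:
    """Channel means over ``[t_start, t_end)``; pure function of the record."""
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must have positive length")
    if t0 < record.time[0] or t1 > record.time[-1] + np.finfo(float).eps * 1e3 \
            + (record.time[1] - record.time[0] if len(record) > 1 else 0.0):
        raise ValueError("window lies outside the recorded run span")
    mask = record.window_mask(t0, t1)
    if not mask.any():
        raise ValueError("window contains no recorded samples")
    return BenchmarkBalance(
        window=(t0, t1),
        sympathetic=float(record.sympathetic[mask].mean()),
        parasym_direct=float(record.parasym_direct[mask].mean()),
        parasym_networked=float(record.parasym_networked[mask].mean()),
        parasym_combined=float(record.parasym_combined[mask].mean()),
        central_drive=float(record.central_drive[mask].mean()),
    )


def _fate_flag(pathology: PathologyConfig, population: str) -> str:
    affected = (pathology.lcn_affected if population == "lcn"
                else pathology.transducers_affected)
    if not pathology.enabled or not affected:
        return "N"
    return "D" if pathology.fate(population) == "death" else "S"


def prelude_aftermath_summary(record: SimulationRecord,
                              config: ScenarioConfig | None = None
                              ) -> PreludeAftermathSummary:
    """Paired prelude/aftermath balances plus the scenario annotation flags."""
    config = config if config is not None else record.config
    last_step = config.record_stride * config.controller.dt
    if record.time[-1] + last_step + 1e-9 < config.schedule.t_end:
        raise RuntimeError("record does not span the full timeline")
    prelude = benchmark_balance(record, config.prelude_window)
    aftermath = benchmark_balance(record, config.aftermath_window)
    deltas = {
        k: getattr(aftermath, k) - getattr(prelude, k)
        for k in ("sympathetic", "parasym_direct", "parasym_networked",
                  "parasym_combined", "central_drive")
    }
    flags = {
        "ans_derangement": "Y" if (config.pathology.enabled and
                                   config.pathology.derangement) else "N",
        "lcn": _fate_flag(config.pathology, "lcn"),
        "sensory": _fate_flag(config.pathology, "transducer"),
    }
    return PreludeAftermathSummary(label=config.label, prelude=prelude,
                                   aftermath=aftermath, deltas=deltas,
                                   flags=flags)


#: the eleven published scenario settings: (label, connectedness, diversity,
#: mode, lcn_affected, lcn_fate, transducer_fate, derangement, description)
_MATRIX = [
    ("fig04", "stratified", "low", "angina", True, None, None, False,
     "stratified, low diversity; angina; LCN and sensory stressed, alive"),
    ("fig05", "stratified", "high", "angina", True, None, None, False,
     "stratified, high diversity; angina; LCN and sensory stressed, alive"),
    ("fig06", "top_down", "low", "angina", True, None, None, False,
     "top-down, low diversity; angina; LCN and sensory stressed, alive"),
    ("fig07", "top_down", "high", "angina", True, None, None, False,
     "top-down, high diversity; angina; LCN and sensory stressed, alive"),
    ("fig08", "stratified", "high", "angina", True, None, None, True,
     "stratified, high diversity; angina; LCN and sensory stressed; "
     "autonomic derangement"),
    ("fig09", "stratified", "high", "angina", False, None, None, True,
     "stratified, high diversity; angina; LCN unaffected, sensory stressed; "
     "autonomic derangement"),
    ("fig10", "stratified", "low", "infarction", True, None, None, False,
     "stratified, low diversity; infarction; LCN and sensory die"),
    ("fig11", "stratified", "high", "infarction", True, None, None, False,
     "stratified, high diversity; infarction; LCN and sensory die"),
    ("fig12", "stratified", "high", "infarction", False, None, None, False,
     "stratified, high diversity; infarction; LCN unaffected, sensory die"),
    ("fig13", "stratified", "high", "infarction", True, None, None, True,
     "stratified, high diversity; infarction; LCN and sensory die; "
     "autonomic derangement"),
    ("fig14", "stratified", "high", "infarction", True, "stress", None, True,
     "stratified, high diversity; infarction; LCN stressed but survive, "
     "sensory die; autonomic derangement"),
]


def scenario_matrix(base: ScenarioConfig | None = None) -> list[ScenarioConfig]:
    """The eleven published figure scenarios, derived from a base configuration."""
    base = base if base is not None else ScenarioConfig()
    out = []
    for (label, conn, div, mode, lcn_aff, lcn_fate, tr_fate, der,
         desc) in _MATRIX:
        out.append(replace(
            base,
            label=label,
            description=desc,
            network=replace(base.network, connectedness=conn, diversity=div),
            pathology=replace(base.pathology, mode=mode,
                              lcn_affected=lcn_aff, lcn_fate=lcn_fate,
                              transducer_fate=tr_fate, derangement=der,
                              enabled=True),
        ))
    return out
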