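"""Canonical recurrent myocardial-infarction / unstable-angina pathology.

Each run contains three episodes ``E_j = (I_j, R_j, D_j)``: an ischemic onset
``I_j`` (affected neurons die or freeze, an excess drive hits the cardiac
level, and — if enabled — autonomic derangement of transducer sensitivities
ramps up), a recovery ``R_j`` (drive removed, frozen neurons thawed,
derangement ramp stops but its accumulated multiplier persists), and a mild
external-demand challenge ``D_j`` (a 500-s setpoint raise, handled by the
setpoint schedule).  After the last episode the transducer populations'
sensitivities are re-initialized to their pre-pathology population means and
the network seeks a new normal.

Affected neurons are drawn fresh at every onset, without replacement, from the
surviving members of each included population: approximately 15 % of the
cardiac level, 4 % of the intrathoracic and 2.5 % of the central level.
Derangement multiplies every surviving heart-rate transducer's feedback
sensitivity by 0.75 and every blood-flow-demand transducer's demand
sensitivity by 1.25 per episode, compounding across episodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .network import Level, Role, Vitality
from .dynamics import NetworkState

__all__ = [
    "EpisodeSchedule",
    "PathologyConfig",
    "DerangementState",
    "select_affected",
    "apply_onset",
    "apply_derangement",
    "apply_recovery",
    "reinitialize_aftermath",
]

log = logging.getLogger(__name__)

#: roles sampled under the "local circuit" switch (network interneurons and
#: the non-transducing parasympathetic pool cells)
_LCN_LIKE = (Role.LCN, Role.PARASYM_EFFERENT)
_TRANSDUCERS = (Role.DEMAND_TRANSDUCER, Role.HEARTRATE_TRANSDUCER)


@dataclass
class EpisodeSchedule:
    """Canonical episode timeline (seconds)."""

    onsets: tuple[float, ...] = (2500.0, 6000.0, 9500.0)
    recoveries: tuple[float, ...] = (3500.0, 7000.0, 10500.0)
    demands: tuple[float, ...] = (4500.0, 8000.0, 11500.0)
    demand_duration: float = 500.0
    aftermath_start: float = 13000.0
    t_end: float = 18000.0

    @property
    def n_episodes(self) -> int:
        return len(self.onsets)

    def validate(self) -> None:
        if len(self.onsets) != len(self.recoveries):
            raise ValueError("onset and recovery lists have unequal lengths")
        if len(self.demands) > len(self.onsets):
            raise ValueError("more demand challenges than episodes")
        seq = []
        for j, (i, r) in enumerate(zip(self.onsets, self.recoveries)):
            if not i < r:
                raise ValueError(f"need I < R within an episode, got ({i}, {r})")
            seq += [i, r]
            if j < len(self.demands):
                d = self.demands[j]
                if not r < d:
                    raise ValueError(f"need R < D within an episode, "
                                     f"got ({r}, {d})")
                seq.append(d)
        if seq != sorted(seq):
            raise ValueError("episodes must not overlap")
        if seq and seq[-1] > self.aftermath_start:
            raise ValueError("episodes must end before the aftermath")
        if self.demands and \
                self.demands[-1] + self.demand_duration > self.aftermath_start:
            raise ValueError("last demand challenge overlaps the aftermath")
        if self.aftermath_start > self.t_end:
            raise ValueError("aftermath must not start after the end of the run")

    def truncated(self, t_end: float) -> "EpisodeSchedule":
        """A copy ending at ``t_end``, keeping only sub-events that fit.

        Convenient for prelude-only or episodes-only runs (e.g. calibration
        probes over 0-2500 s): episodes whose recovery would fall beyond the
        new end are dropped, and the aftermath is clamped to ``t_end``.
        """
        keep = [j for j, r in enumerate(self.recoveries) if r <= t_end]
        sched = EpisodeSchedule(
            onsets=tuple(self.onsets[j] for j in keep),
            recoveries=tuple(self.recoveries[j] for j in keep),
            demands=tuple(d for j, d in enumerate(self.demands)
                          if j in keep and d + self.demand_duration <= t_end),
            demand_duration=self.demand_duration,
            aftermath_start=min(self.aftermath_start, t_end),
            t_end=t_end)
        sched.validate()
        return sched


@dataclass
class PathologyConfig:
    """Which populations are hit, how hard, and what happens to them.

    ``mode`` sets the fate of affected neurons ('infarction' kills them,
    'angina' freezes them for the duration of the ischemic interval);
    ``lcn_fate`` / ``transducer_fate`` override the fate per population
    ('death' | 'stress' | None = follow mode), which expresses the mixed
    scenario in which local-circuit neurons survive an infarction that kills
    the sensory transducers.
    """

    enabled: bool = True
    mode: str = "angina"                  # 'angina' | 'infarction'
    affected_fraction_by_level: dict = field(default_factory=lambda: {
        "central": 0.025, "intrathoracic": 0.04, "cardiac": 0.15})
    lcn_affected: bool = True
    transducers_affected: bool = True
    lcn_fate: str | None = None
    transducer_fate: str | None = None
    derangement: bool = False
    derangement_hr_factor: float = 0.75       # -25 % feedback sensitivity / episode
    derangement_demand_factor: float = 1.25   # +25 % demand sensitivity / episode
    derangement_ramp: str = "linear"          # 'linear' | 'step'
    derangement_affected_only: bool = False
    ischemic_drive_amplitude: float = 2.0
    selection_seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("angina", "infarction"):
            raise ValueError(f"unknown pathology mode {self.mode!r}")
        for k, v in self.affected_fraction_by_level.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"affected fraction for {k} must lie in "
                                 f"[0, 1], got {v}")
        for name in ("derangement_hr_factor", "derangement_demand_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("lcn_fate", "transducer_fate"):
            v = getattr(self, name)
            if v is not None and v not in ("death", "stress"):
                raise ValueError(f"{name} must be 'death', 'stress' or None")
        if self.derangement_ramp not in ("linear", "step"):
            raise ValueError("derangement_ramp must be 'linear' or 'step'")

    def fate(self, population: str) -> str:
        """Resolved fate ('death' | 'stress') for 'lcn' or 'transducer'."""
        override = self.lcn_fate if population == "lcn" else self.transducer_fate
        if override is not None:
            return override
        return "death" if self.mode == "infarction" else "stress"

    def fraction(self, level: Level) -> float:
        key = {Level.CENTRAL: "central",
               Level.INTRATHORACIC: "intrathoracic",
               Level.CARDIAC: "cardiac"}[level]
        return float(self.affected_fraction_by_level.get(key, 0.0))


def select_affected(state: NetworkState, config: PathologyConfig,
                    episode_index: int) -> dict[str, np.ndarray]:
    """Draw the affected neurons for one episode onset.

    Per level and per included population (local-circuit cells, transducers),
    ``floor(fraction * surviving pool)`` neurons are sampled without
    replacement from the currently alive pool; dead neurons are never
    selected.  The draw is reproducible from ``selection_seed + episode_index``
    and fresh at every episode.  Returns ``{"lcn": ids, "transducer": ids}``.
    """
    if episode_index < 1:
        raise ValueError("episode_index starts at 1")
    rng = np.random.Generator(np.random.PCG64(
        int(config.selection_seed) + int(episode_index)))
    net = state.network
    out = {"lcn": [], "transducer": []}
    populations = []
    if config.lcn_affected:
        populations.append(("lcn", _LCN_LIKE))
    if config.transducers_affected:
        populations.append(("transducer", _TRANSDUCERS))
    for lv in (Level.CENTRAL, Level.INTRATHORACIC, Level.CARDIAC):
        frac = config.fraction(lv)
        for name, roles in populations:
            pool = np.flatnonzero((net.level == lv)
                                  & np.isin(net.role, [int(r) for r in roles])
                                  & (state.vitality == Vitality.ALIVE))
            k = int(np.floor(frac * pool.shape[0]))
            if pool.shape[0] == 0:
                log.warning("empty alive pool (%s, level %s) at episode %d",
                            name, lv.name, episode_index)
                continue
            if k > 0:
                out[name].append(rng.choice(pool, size=k, replace=False))
    return {name: (np.sort(np.concatenate(parts)) if parts else
                   np.empty(0, dtype=np.int64))
            for name, parts in out.items()}


def apply_onset(state: NetworkState, affected: dict[str, np.ndarray],
                config: PathologyConfig, t: float,
                _applied_onsets: set | None = None) -> None:
    """Apply one episode onset: kill or freeze the affected populations.

    Freezing snapshots the activity just before the onset; frozen neurons keep
    transmitting that activity but ignore all input until recovery.  The
    excess ischemic cardiac drive is an input-side effect applied by the
    runner over ``[I_j, R_j)``; it does not belong to this mutation.
    Raises if the same onset time is applied twice.
    """
    if _applied_onsets is not None:
        if t in _applied_onsets:
            raise RuntimeError(f"onset at t={t} applied twice")
        _applied_onsets.add(t)
    for name, ids in affected.items():
        if ids.size == 0:
            continue
        fate = config.fate(name)
        state.set_vitality(ids, Vitality.DEAD if fate == "death"
                           else Vitality.FROZEN)


@dataclass
class DerangementState:
    """Accumulated sensitivity corruption of the transducer populations.

    After ``k`` completed episodes every surviving heart-rate transducer's
    feedback sensitivity carries the multiplier ``hr_factor**k`` and every
    demand transducer's demand sensitivity ``demand_factor**k``; during an
    ischemic interval the next factor ramps in linearly.
    """

    hr_factor: float = 0.75
    demand_factor: float = 1.25
    episodes_completed: int = 0

    @property
    def hr_multiplier(self) -> float:
        return self.hr_factor ** self.episodes_completed

    @property
    def demand_multiplier(self) -> float:
        return self.demand_factor ** self.episodes_completed

    def ramp(self, t: float, onset: float, recovery: float,
             ramp_kind: str = "linear") -> float:
        """Within-episode progress of the per-episode factor, in [0, 1]."""
        if ramp_kind == "step" or recovery <= onset:
            return 1.0
        return min(max((t - onset) / (recovery - onset), 0.0), 1.0)

    def complete_episode(self) -> None:
        self.episodes_completed += 1


def _apply_multipliers(state: NetworkState, hr_mult: float, dm_mult: float,
                       affected_only_ids: np.ndarray | None = None) -> None:
    net = state.network
    not_dead = state.vitality != Vitality.DEAD
    h_mask = (net.role == Role.HEARTRATE_TRANSDUCER) & not_dead
    d_mask = (net.role == Role.DEMAND_TRANSDUCER) & not_dead
    if affected_only_ids is not None:
        keep = np.zeros(net.n_neurons, dtype=bool)
        keep[affected_only_ids] = True
        h_mask &= keep
        d_mask &= keep
    state.feedback_sens[h_mask] = state.base_feedback_sens[h_mask] * hr_mult
    state.demand_sens[d_mask] = state.base_demand_sens[d_mask] * dm_mult


def apply_derangement(der: DerangementState, state: NetworkState, t: float,
                      onset: float, recovery: float,
                      ramp_kind: str = "linear",
                      affected_only_ids: np.ndarray | None = None) -> None:
    """Set effective sensitivities for the current derangement state.

    The per-episode factor ramps linearly from 1 at the onset to its full
    value at recovery, multiplying the accumulated compound multiplier; the
    result scales every surviving transducer's relevant base sensitivity
    (population-wide by default, or only the given ids when the
    affected-only variant is configured).
    """
    frac = der.ramp(t, onset, recovery, ramp_kind)
    hr_mult = der.hr_multiplier * (1.0 + frac * (der.hr_factor - 1.0))
    dm_mult = der.demand_multiplier * (1.0 + frac * (der.demand_factor - 1.0))
    _apply_multipliers(state, hr_mult, dm_mult, affected_only_ids)


def apply_recovery(state: NetworkState, der: DerangementState | None,
                   config: PathologyConfig, t: float) -> np.ndarray:
    """End one ischemic interval: thaw frozen neurons, lock in derangement.

    Dead neurons stay dead.  The derangement ramp stops by compounding the
    completed episode into the accumulated multiplier; the ischemic drive is
    removed by the runner (it is an input-side term active only during
    ``[I_j, R_j)``).  Returns the ids that were thawed.
    """
    thawed = state.thaw()
    if der is not None and config.derangement:
        der.complete_episode()
        # lock the completed episode into the accumulated multiplier
        _apply_multipliers(state, der.hr_multiplier, der.demand_multiplier)
    return thawed


def reinitialize_aftermath(state: NetworkState,
                           der: DerangementState | None, t: float) -> None:
    """Reset surviving transducers to the pre-pathology population means.

    Every alive transducer's relevant sensitivity is set to the population
    mean of its role stored when the network was built; dead neurons are not
    resurrected and local-circuit weights and gains are untouched.  Any
    accumulated derangement multiplier is discarded.
    """
    means = state.network.sensitivity_means
    if not means:
        raise RuntimeError("pre-pathology sensitivity means are missing")
    net = state.network
    alive = state.vitality == Vitality.ALIVE
    h_mask = (net.role == Role.HEARTRATE_TRANSDUCER) & alive
    d_mask = (net.role == Role.DEMAND_TRANSDUCER) & alive
    state.feedback_sens[h_mask] = means[int(Role.HEARTRATE_TRANSDUCER)]
    state.demand_sens[d_mask] = means[int(Role.DEMAND_TRANSDUCER)]
    state.base_feedback_sens[h_mask] = means[int(Role.HEARTRATE_TRANSDUCER)]
    state.base_demand_sens[d_mask] = means[int(Role.DEMAND_TRANSDUCER)]
    if der is not None:
        der.episodes_completed = 0
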