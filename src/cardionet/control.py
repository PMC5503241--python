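"""PI demand law, direct vagal pathway, and the first-order heart plant.

The central controller turns the delayed heart-rate tracking error into a
blood-flow-demand signal by the standard proportional-integral rule

    D(n) = K * ( e(n) + (1/Ti) * sum_{j<=n} e(j) * dt ),   e(j) = H*(j) - H(j-L),

where ``H*`` is the externally scheduled heart-rate setpoint, ``L`` a feedback
delay in steps, ``K`` the control gain and ``Ti`` the reset time.  ``D`` is
broadcast identically to every demand-transducer neuron (each scales it by its
own sensitivity) and recorded as the "central drive" channel.

The heart is reduced to a first-order responder with constant ejection
fraction, so cardiac output is proportional to heart rate and the heart rate
itself is the controlled variable:

    H <- H + (dt / tau_H) * ( -H + H0 + c_s * S - c_p * (alpha*P_net + (1-alpha)*P_dir) )

with sympathetic tone ``S`` and the two vagal pathways mixed by ``alpha``.
The direct (non-networked) parasympathetic pathway is a first-order unit that
relaxes toward a logistic function of the signed, delayed tracking error: it
sits at a small baseline tone when tracking is exact, rises to brake an
overshooting heart, and withdraws below baseline when the heart runs under
setpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "ControllerParams",
    "ControllerState",
    "HeartParams",
    "HeartState",
    "DirectParasymParams",
    "SetpointSchedule",
    "pi_demand",
    "direct_parasympathetic",
    "heart_step",
]


@dataclass
class ControllerParams:
    """PI demand-law constants.  ``delay_steps`` realizes t_L = L * dt."""

    k_pi: float = 2.0
    ti_pi: float = 1.0    # seconds; math.inf disables the integral term
    delay_steps: int = 2
    dt: float = 0.5       # seconds
    # anti-windup: the demand signal is confined to this band by clamping the
    # error integral whenever the raw PI output would leave it
    demand_min: float = -1.0
    demand_max: float = 1.5

    def validate(self) -> None:
        if self.k_pi <= 0:
            raise ValueError("k_pi must be positive")
        if self.ti_pi <= 0:
            raise ValueError("ti_pi must be positive")
        if self.delay_steps < 0 or int(self.delay_steps) != self.delay_steps:
            raise ValueError("delay_steps must be a non-negative integer")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.demand_min >= self.demand_max:
            raise ValueError("demand_min must be below demand_max")


@dataclass
class ControllerState:
    """Accumulated error integral and the heart-rate history buffer.

    The history list grows with the run (one float per step); it doubles as the
    delay line and as the raw material for brute-force re-summation of the
    demand law in oracle tests.
    """

    error_integral: float = 0.0
    history: list[float] = field(default_factory=list)

    def record(self, h: float) -> None:
        self.history.append(float(h))

    def delayed(self, n: int, L: int) -> float:
        """H(n-L); before the buffer has filled, the earliest sample stands in."""
        if not self.history:
            raise ValueError("heart-rate history is empty")
        return self.history[max(n - L, 0)]


def pi_demand(params: ControllerParams, state: ControllerState,
              h_star: float, n: int) -> float:
    """Demand signal at step ``n``; updates the error integral exactly once.

    Requires that ``state.history`` already holds the sample ``H(n-L)`` (the
    runner records H before asking for demand).
    """
    if len(state.history) <= max(n - params.delay_steps, 0):
        raise ValueError(
            f"history of length {len(state.history)} cannot serve delay "
            f"{params.delay_steps} at step {n}")
    err = h_star - state.delayed(n, params.delay_steps)
    state.error_integral += err * params.dt
    if not math.isfinite(params.ti_pi):
        return params.k_pi * err
    demand = params.k_pi * (err + state.error_integral / params.ti_pi)
    # conditional anti-windup: saturate the demand by clamping the integral,
    # so the integrator never runs away while the plant is pinned elsewhere
    if demand > params.demand_max:
        demand = params.demand_max
        state.error_integral = (demand / params.k_pi - err) * params.ti_pi
    elif demand < params.demand_min:
        demand = params.demand_min
        state.error_integral = (demand / params.k_pi - err) * params.ti_pi
    return demand


@dataclass
class DirectParasymParams:
    """Direct vagal pathway constants.

    ``baseline_bias`` fixes the tone when tracking is exact: tone ->
    ``expit(baseline_bias)``; the default puts the benchmark tone at 0.1.
    ``overshoot_gain`` sets how sharply the tone swings around baseline per
    unit of signed tracking error.
    """

    tau_p: float = 5.0                   # seconds
    overshoot_gain: float = 17.0
    baseline_bias: float = float(np.log(0.1 / 0.9))   # expit^-1(0.1)

    def validate(self) -> None:
        if self.tau_p <= 0:
            raise ValueError("tau_p must be positive")
        if self.overshoot_gain < 0:
            raise ValueError("overshoot_gain must be >= 0")


def direct_parasympathetic(p_dir: float, h_delayed: float, h_star: float,
                           dt: float,
                           params: DirectParasymParams | None = None) -> float:
    """One Euler step of the direct vagal tone; result stays in [0, 1]."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    params = params if params is not None else DirectParasymParams()
    target = expit(params.overshoot_gain * (h_delayed - h_star)
                   + params.baseline_bias)
    p_new = p_dir + (dt / params.tau_p) * (target - p_dir)
    return min(max(p_new, 0.0), 1.0)


@dataclass
class HeartParams:
    """First-order heart plant constants (all dimensionless except tau_H)."""

    tau_h: float = 10.0    # seconds
    h_0: float = 0.5695     # intrinsic rate (no efferent input)
    c_s: float = 1.0       # sympathetic coupling gain
    c_p: float = 4.0       # parasympathetic coupling gain
    alpha: float = 0.25     # networked share of the vagal mix

    def validate(self) -> None:
        if self.tau_h <= 0:
            raise ValueError("tau_h must be positive")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


@dataclass
class HeartState:
    h: float = 0.25

    def validate(self) -> None:
        if self.h < 0:
            raise ValueError("heart rate must be >= 0")


def heart_step(heart: HeartState, params: HeartParams, S: float, P_net: float,
               P_dir: float, dt: float) -> float:
    """Advance the heart plant one Euler step; heart rate is clipped at 0."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    p_mix = params.alpha * P_net + (1.0 - params.alpha) * P_dir
    h_new = heart.h + (dt / params.tau_h) * (
        -heart.h + params.h_0 + params.c_s * S - params.c_p * p_mix)
    if not math.isfinite(h_new):
        raise FloatingPointError(f"non-finite heart rate: {h_new!r}")
    heart.h = max(h_new, 0.0)
    return heart.h


@dataclass
class SetpointSchedule:
    """Piecewise-constant heart-rate setpoint covering the whole run.

    ``segments`` is a list of ``(t_start, level)`` pairs sorted by time; the
    level holds from its start until the next segment.  The canonical schedule
    is 0.25 during initialization, 0.3 in steady state, and 0.35 during each
    500-s demand challenge.
    """

    segments: list[tuple[float, float]]
    t_end: float

    def validate(self) -> None:
        if not self.segments:
            raise ValueError("setpoint schedule is empty")
        times = [t for t, _ in self.segments]
        if times != sorted(times):
            raise ValueError("setpoint segments must be sorted by time")
        if times[0] > 0:
            raise ValueError("setpoint schedule must start at t = 0")

    def value(self, t: float) -> float:
        out = self.segments[0][1]
        for t0, lvl in self.segments:
            if t >= t0:
                out = lvl
            else:
                break
        return out

    def as_array(self, times: np.ndarray) -> np.ndarray:
        starts = np.array([t for t, _ in self.segments])
        levels = np.array([v for _, v in self.segments])
        idx = np.searchsorted(starts, times, side="right") - 1
        return levels[np.clip(idx, 0, len(levels) - 1)]

    @classmethod
    def canonical(cls, init_level: float = 0.25, steady_level: float = 0.3,
                  challenge_level: float = 0.35,
                  init_end: float = 500.0,
                  demand_times: tuple[float, ...] = (4500.0, 8000.0, 11500.0),
                  demand_duration: float = 500.0,
                  t_end: float = 18000.0) -> "SetpointSchedule":
        segs: list[tuple[float, float]] = [(0.0, init_level),
                                           (init_end, steady_level)]
        for td in demand_times:
            segs.append((td, challenge_level))
            segs.append((td + demand_duration, steady_level))
        sched = cls(segments=segs, t_end=t_end)
        sched.validate()
        return sched
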