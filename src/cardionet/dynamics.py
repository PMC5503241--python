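"""Firing-rate dynamics and plasticity of the hierarchical network.

Neurons are leaky logistic rate units: the activity of an alive neuron relaxes
toward a squashed image of its net input,

    a_i <- a_i + (dt / tau_a) * (sigma(g_i * u_i + b_i) - a_i),

where ``u_i = sum_j w_ij a_j + s_i^D D + s_i^H H + ischemic drive`` collects the
recurrent synaptic input, the globally broadcast blood-flow-demand signal D and
heart-rate signal H (each scaled by that neuron's sensitivity), plus any
pathological cardiac drive; ``g_i`` is a slowly adapting intrinsic gain and
``b_i`` a fixed role-dependent bias.  Frozen neurons hold their activity but
keep transmitting it; dead neurons are silent forever.

Three plasticity channels adapt the network on slow time scales:

* Hebbian, soft-bounded:  ``w_ij <- w_ij + dt * eta * a_j a_i (w_max - w_ij)``,
  which keeps weights in ``[0, w_max]`` for any input sequence.
* Homeostatic synaptic downscaling: neurons whose running-mean activity sits
  above the common target multiplicatively shed incoming weight, balancing
  the one-way Hebbian growth.
* Homeostatic intrinsic-gain adaptation: each neuron tracks an exponential
  moving average of its own activity and slowly nudges ``g_i`` toward the
  level that restores the target, within moderate bounds.

Updates within one composite step are synchronous (Jacobi style): activities,
Hebbian and homeostatic updates are all computed from the pre-step state, so
the result is independent of neuron enumeration order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.special import expit

from .network import Branch, Level, Network, Role, Vitality

__all__ = [
    "PlasticityParams",
    "NetworkState",
    "neuron_input",
    "step_activities",
    "hebbian_update",
    "homeostatic_update",
    "efferent_outputs",
    "advance",
]

log = logging.getLogger(__name__)

#: activity relaxation time constant (seconds)
TAU_A = 2.0


@dataclass
class PlasticityParams:
    """Rates and bounds of the plasticity channels.

    Defaults make adaptation visible across a 1000-s pathology sub-event while
    staying quasi-static over one 500-s settling window.
    """

    hebb_rate: float = 2e-4          # per second
    weight_max: float = 0.15
    homeo_rate: float = 1e-4         # per second (intrinsic gain channel)
    scaling_rate: float = 1.8e-3       # per second (synaptic downscaling channel)
    activity_target: float = 0.45
    activity_avg_tau: float = 100.0  # seconds
    gain_min: float = 0.6
    gain_max: float = 1.6

    def validate(self) -> None:
        for name in ("hebb_rate", "homeo_rate", "scaling_rate"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if not 0.0 < self.activity_target < 1.0:
            raise ValueError("activity_target must lie in (0, 1)")
        if self.weight_max <= 0:
            raise ValueError("weight_max must be positive")
        if not 0 < self.gain_min <= self.gain_max:
            raise ValueError("need 0 < gain_min <= gain_max")
        if self.activity_avg_tau <= 0:
            raise ValueError("activity_avg_tau must be positive")


class NetworkState:
    """Mutable dynamical state layered over a static :class:`Network`.

    Holds per-neuron activity ``a``, running mean activity ``abar``, intrinsic
    gain ``g``, vitality, (derangeable) sensitivities, and per-synapse weights
    stored in compressed sparse row order keyed by postsynaptic neuron, so that
    the recurrent input is one sparse mat-vec per step.
    """

    def __init__(self, network: Network,
                 plasticity: PlasticityParams | None = None,
                 tau_a: float = TAU_A,
                 initial_activity: float = 0.5):
        plasticity = plasticity if plasticity is not None else PlasticityParams()
        plasticity.validate()
        self.network = network
        self.plasticity = plasticity
        self.tau_a = float(tau_a)
        n = network.n_neurons

        order = np.lexsort((network.pre, network.post))
        self.syn_pre = network.pre[order].astype(np.int32)
        self.syn_post = network.post[order].astype(np.int32)
        self.syn_klass = network.klass[order]
        self.w = network.weight[order].astype(np.float64).copy()
        counts = np.bincount(self.syn_post, minlength=n)
        self.indptr = np.concatenate(([0], np.cumsum(counts))).astype(np.int32)
        self._W = sparse.csr_matrix((self.w, self.syn_pre, self.indptr),
                                    shape=(n, n))
        self.w = self._W.data  # shared buffer: in-place edits hit the matvec

        self.a = np.full(n, float(initial_activity))
        self.abar = self.a.copy()
        self.g = np.ones(n)
        self.vitality = network.vitality.copy()
        self.demand_sens = network.demand_sensitivity.copy()
        self.feedback_sens = network.feedback_sensitivity.copy()
        # pre-pathology baselines: derangement multiplies these, aftermath
        # re-initialization restores the population means stored at build time
        self.base_demand_sens = network.demand_sensitivity.copy()
        self.base_feedback_sens = network.feedback_sensitivity.copy()
        self.frozen_snapshot = np.full(n, np.nan)
        self._extinct_warned: set[int] = set()
        # scratch buffers so the per-step updates allocate almost nothing
        nnz = self.w.shape[0]
        self._sbuf1 = np.empty(nnz)
        self._sbuf2 = np.empty(nnz)
        self._nbuf1 = np.empty(n)
        self._nbuf2 = np.empty(n)
        self._refresh_masks()

    # ------------------------------------------------------------- vitality

    def _refresh_masks(self) -> None:
        net = self.network
        self.alive = self.vitality == Vitality.ALIVE
        self.dead = self.vitality == Vitality.DEAD
        self.not_dead = ~self.dead
        self._not_alive = ~self.alive
        self._has_dead = bool(self.dead.any())
        if self._has_dead:
            self._syn_live = ~(self.dead[self.syn_pre] |
                               self.dead[self.syn_post])
            self._syn_dead = ~self._syn_live
        else:
            self._syn_live = None
            self._syn_dead = None
        cardiac = net.level == Level.CARDIAC
        self._sym_eff = cardiac & (net.branch == Branch.SYMPATHETIC) & self.not_dead
        self._par_eff = cardiac & (net.branch == Branch.PARASYMPATHETIC) & self.not_dead
        self._cardiac_alive = cardiac & self.alive
        self._cardiac_alive_f = self._cardiac_alive.astype(np.float64)

    def set_vitality(self, ids: np.ndarray, vitality: Vitality) -> None:
        """Change vitality for a set of neurons and refresh cached masks."""
        ids = np.asarray(ids, dtype=np.int64)
        self.vitality[ids] = vitality
        if vitality == Vitality.DEAD:
            self.a[ids] = 0.0
        elif vitality == Vitality.FROZEN:
            self.frozen_snapshot[ids] = self.a[ids]
        self._refresh_masks()

    def thaw(self) -> np.ndarray:
        """Return all frozen neurons to life, resuming from their snapshot."""
        frozen = np.flatnonzero(self.vitality == Vitality.FROZEN)
        self.vitality[frozen] = Vitality.ALIVE
        self.frozen_snapshot[frozen] = np.nan
        self._refresh_masks()
        return frozen

    # ------------------------------------------------------------ dynamics

    def snapshot_to_csv(self, path, stride: int = 1) -> None:
        """Export (neuron id, activity) for every ``stride``-th neuron.

        Debugging aid: a cheap dump of the instantaneous population state.
        """
        import pandas as pd

        ids = np.arange(0, self.network.n_neurons, max(int(stride), 1))
        pd.DataFrame({"neuron_id": ids, "activity": self.a[ids]}).to_csv(
            path, index=False)

    def raw_input(self, D: float, H: float,
                  ischemic_drive: float = 0.0) -> np.ndarray:
        """Net input u_i for every neuron (before gain and bias)."""
        u = self._W @ self.a
        buf = self._nbuf2
        np.multiply(self.demand_sens, D, out=buf)
        u += buf
        np.multiply(self.feedback_sens, H, out=buf)
        u += buf
        if ischemic_drive != 0.0:
            np.multiply(self._cardiac_alive_f, ischemic_drive, out=buf)
            u += buf
        return u


def neuron_input(state: NetworkState, neuron: int, D: float, H: float,
                 ischemic_drive: float = 0.0) -> float:
    """Net input of one neuron: recurrent sum + sensed signals + bias + drive.

    The ischemic term applies only to alive cardiac-level neurons (pathology
    drive does not reach frozen or dead cells).
    """
    lo, hi = state.indptr[neuron], state.indptr[neuron + 1]
    recurrent = float(state.w[lo:hi] @ state.a[state.syn_pre[lo:hi]])
    total = (recurrent
             + state.demand_sens[neuron] * D
             + state.feedback_sens[neuron] * H
             + float(state.network.bias[neuron]))
    if state._cardiac_alive[neuron]:
        total += ischemic_drive
    return total


def step_activities(state: NetworkState, D: float, H: float,
                    ischemic_drive: float, dt: float,
                    _u: np.ndarray | None = None) -> np.ndarray:
    """One Euler step of the leaky logistic rate law; returns the activities.

    Alive neurons move toward ``sigma(g * u + bias)``; frozen neurons hold
    their snapshot; dead neurons stay at zero.  Raises ``FloatingPointError``
    if any activity leaves the finite range.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    u = state.raw_input(D, H, ischemic_drive) if _u is None else _u
    buf = state._nbuf1
    np.multiply(state.g, u, out=buf)
    buf += state.network.bias
    expit(buf, out=buf)          # sigma(g * u + b)
    buf -= state.a
    buf *= dt / state.tau_a
    a_new = state.a + buf        # fresh array: the pre-step state stays valid
    np.copyto(a_new, state.a, where=state._not_alive)
    if not np.all(np.isfinite(a_new)):
        bad = int(np.flatnonzero(~np.isfinite(a_new))[0])
        raise FloatingPointError(
            f"non-finite activity at neuron {bad}: input={u[bad]!r}, "
            f"gain={state.g[bad]!r}")
    state.a = a_new
    return a_new


def hebbian_update(state: NetworkState, dt: float,
                   _a: np.ndarray | None = None) -> np.ndarray:
    """Soft-bounded Hebbian weight update; synapses touching dead cells are inert."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    rate = state.plasticity.hebb_rate
    if rate == 0.0:
        return state.w
    a = state.a if _a is None else _a
    wmax = state.plasticity.weight_max
    dw, b2 = state._sbuf1, state._sbuf2
    # indices are valid by construction; mode='clip' skips the slow
    # bounds-checking path of np.take
    np.take(a, state.syn_pre, out=dw, mode="clip")
    np.take(a, state.syn_post, out=b2, mode="clip")
    dw *= b2
    np.subtract(wmax, state.w, out=b2)
    dw *= b2
    dw *= dt * rate
    if state._syn_live is not None:
        dw *= state._syn_live
    state.w += dw
    np.clip(state.w, 0.0, wmax, out=state.w)
    return state.w


def homeostatic_update(state: NetworkState, dt: float,
                       _a: np.ndarray | None = None) -> np.ndarray:
    """Update running-average activities, intrinsic gains, and synaptic scaling.

    The running mean is an exponential moving average with time constant
    ``activity_avg_tau``.  Two homeostatic channels then pull every neuron
    toward the common activity target: the intrinsic gain moves at
    ``homeo_rate`` per second per unit of target shortfall (clipped to
    ``[gain_min, gain_max]``), and incoming synaptic weights of
    over-active neurons are multiplicatively scaled down at ``scaling_rate``
    per unit of excess running-mean activity, which balances the one-way
    Hebbian growth on long time scales without disturbing neurons that sit
    below target by design (sensory transducers).  Dead neurons and their
    synapses are left untouched.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = state.plasticity
    a = state.a if _a is None else _a
    delta = state._nbuf1
    np.subtract(a, state.abar, out=delta)
    delta *= dt / p.activity_avg_tau
    if state._has_dead:
        delta[state.dead] = 0.0
    state.abar = state.abar + delta      # fresh array, pre-step abar persists
    if p.homeo_rate != 0.0:
        np.subtract(p.activity_target, state.abar, out=delta)
        delta *= dt * p.homeo_rate
        if state._has_dead:
            delta[state.dead] = 0.0      # dead gains within bounds already
        g_new = state.g + delta
        np.clip(g_new, p.gain_min, p.gain_max, out=g_new)
        state.g = g_new
    if p.scaling_rate != 0.0:
        factor = state._sbuf1
        np.take(state.abar, state.syn_post, out=factor, mode="clip")
        factor -= p.activity_target
        np.maximum(factor, 0.0, out=factor)
        factor *= -dt * p.scaling_rate
        factor += 1.0
        if state._syn_dead is not None:
            np.copyto(factor, 1.0, where=state._syn_dead)
        state.w *= factor
        np.clip(state.w, 0.0, p.weight_max, out=state.w)
    return state.g


def efferent_outputs(state: NetworkState) -> tuple[float, float]:
    """Lumped efferent tones at the cardiac level.

    Returns ``(S, P_net)``: the mean activity of surviving (alive or frozen)
    cardiac sympathetic-branch neurons and of the surviving networked
    parasympathetic pool.  A branch with no survivors contributes 0 and logs a
    population-extinct warning once.
    """
    out = []
    for code, mask in ((int(Branch.SYMPATHETIC), state._sym_eff),
                       (int(Branch.PARASYMPATHETIC), state._par_eff)):
        n = int(mask.sum())
        if n == 0:
            if code not in state._extinct_warned:
                log.warning("cardiac efferent branch %d has no surviving "
                            "neurons; tone reported as 0", code)
                state._extinct_warned.add(code)
            out.append(0.0)
        else:
            out.append(float(state.a[mask].sum() / n))
    return out[0], out[1]


def advance(state: NetworkState, D: float, H: float,
            ischemic_drive: float, dt: float) -> None:
    """One synchronous composite step: activities, Hebbian, homeostasis.

    All three updates read the pre-step state, so the composite is a Jacobi
    update and independent of evaluation order.
    """
    a_old = state.a
    step_activities(state, D, H, ischemic_drive, dt)
    hebbian_update(state, dt, _a=a_old)
    homeostatic_update(state, dt, _a=a_old)
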