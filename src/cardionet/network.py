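"""Construction of the three-level hierarchical cardiac control network.

The sympathetic limb of the hierarchy spans three levels — central, intrathoracic
(extracardiac ganglia) and cardiac (intrinsic cardiac ganglia).  Each level holds
local circuit neurons (LCN, pure interneurons) plus transducer neurons that
receive one of the two global signals: blood-flow demand ('D' receivers, fed by
the central controller output) or heart rate ('H' receivers, fed back from the
target organ).  A separate networked parasympathetic pool lives at the cardiac
level only, alongside the sympathetic intrinsic-cardiac population.

Wiring is random but seeded: every neuron emits a fixed number of synapses,
split between peer (same level) and adjacent-layer (descending / ascending)
connections in a configurable ratio — 10:1 for "stratified" networks, 1:1 for
"top-down" networks — with at most one ascending synapse per neuron so that
information primarily flows down the hierarchy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Level",
    "Role",
    "Branch",
    "Vitality",
    "SynapseClass",
    "NetworkConfig",
    "Network",
    "build_network",
    "network_census",
    "largest_remainder",
]


class Level(IntEnum):
    CENTRAL = 0
    INTRATHORACIC = 1
    CARDIAC = 2


class Role(IntEnum):
    LCN = 0
    DEMAND_TRANSDUCER = 1
    HEARTRATE_TRANSDUCER = 2
    PARASYM_EFFERENT = 3


class Branch(IntEnum):
    SYMPATHETIC = 0
    PARASYMPATHETIC = 1


class Vitality(IntEnum):
    ALIVE = 0
    FROZEN = 1
    DEAD = 2


class SynapseClass(IntEnum):
    PEER = 0
    DESCENDING = 1
    ASCENDING = 2


#: diversity level -> transducer share of each layer population
TRANSDUCER_FRACTION = {"low": 0.10, "high": 0.50}

#: connectedness -> peer:adjacent synapse count ratio
PEER_TO_ADJACENT_RATIO = {"stratified": 10.0, "top_down": 1.0}

#: level -> (demand, heart-rate) split of the transducer population
DEMAND_TO_HEARTRATE_RATIO = {
    Level.CENTRAL: (5, 1),
    Level.INTRATHORACIC: (1, 1),
    Level.CARDIAC: (1, 5),
}


def largest_remainder(total: int, weights: Sequence[float],
                      tie_order: Sequence[int] | None = None) -> list[int]:
    """Apportion ``total`` integer units proportionally to ``weights``.

    Uses the largest-remainder (Hamilton) method.  ``tie_order`` gives the
    priority of each slot when remainders tie (lower rank wins).
    """
    weights = np.asarray(weights, dtype=float)
    if total < 0:
        raise ValueError("total must be non-negative")
    if weights.sum() <= 0:
        raise ValueError("weights must have a positive sum")
    quotas = total * weights / weights.sum()
    base = np.floor(quotas).astype(int)
    leftover = total - int(base.sum())
    remainders = quotas - base
    ranks = list(range(len(weights))) if tie_order is None else list(tie_order)
    order = sorted(range(len(weights)),
                   key=lambda i: (-remainders[i], ranks[i]))
    for i in order[:leftover]:
        base[i] += 1
    return base.tolist()


@dataclass
class NetworkConfig:
    """Structural and initialization parameters of the hierarchy.

    ``lcn_per_level`` is read as the local-circuit population of each level,
    with transducers *added* so that transducers make up ``transducer_fraction``
    of the layer total (the alternative reading, a fixed layer total with
    transducers carved out of it, is selectable via ``layer_composition``).
    """

    lcn_per_level: int = 600
    connectedness: str = "stratified"          # 'stratified' | 'top_down'
    diversity: str = "low"                      # 'low' | 'high'
    peer_to_adjacent_ratio: float | None = None  # default derived from connectedness
    transducer_fraction: float | None = None     # default derived from diversity
    layer_composition: str = "lcn_plus"          # 'lcn_plus' | 'total'
    out_degree: int = 20
    parasym_pool_size: int = 800
    seed: int = 0

    # initialization of weights, sensitivities and role biases
    weight_init_max: float = 0.15
    demand_sensitivity_scale: float = 20.0
    feedback_sensitivity_scale: float = 1.0
    sensitivity_spread: float = 0.1   # sensitivities drawn U[1-s, 1+s] * scale
    bias_lcn: float = -0.25
    bias_demand: float = -7.0
    bias_heartrate: float = -2.4
    bias_parasym: float = -0.35

    @property
    def ratio(self) -> float:
        if self.peer_to_adjacent_ratio is not None:
            return self.peer_to_adjacent_ratio
        return PEER_TO_ADJACENT_RATIO[self.connectedness]

    @property
    def fraction(self) -> float:
        if self.transducer_fraction is not None:
            return self.transducer_fraction
        return TRANSDUCER_FRACTION[self.diversity]

    def validate(self) -> None:
        if self.lcn_per_level <= 0:
            raise ValueError("lcn_per_level must be positive")
        if self.out_degree <= 0:
            raise ValueError("out_degree must be positive")
        if self.connectedness not in PEER_TO_ADJACENT_RATIO:
            raise ValueError(f"unknown connectedness {self.connectedness!r}")
        if self.diversity not in TRANSDUCER_FRACTION:
            raise ValueError(f"unknown diversity {self.diversity!r}")
        if self.layer_composition not in ("lcn_plus", "total"):
            raise ValueError(f"unknown layer_composition {self.layer_composition!r}")
        if self.ratio <= 0:
            raise ValueError("peer_to_adjacent_ratio must be positive")
        if not 0.0 < self.fraction < 1.0:
            raise ValueError("transducer_fraction must lie in (0, 1)")
        if self.parasym_pool_size <= 0:
            raise ValueError("parasym_pool_size must be positive")
        # every neuron needs at least one peer synapse after its (possibly
        # fractional) adjacent quota has been served
        if self.out_degree < 2:
            raise ValueError(
                "out_degree must be >= 2 to realize a peer:adjacent mix")

    def transducer_count(self, level: Level) -> int:
        """Transducer population of one level, before the demand/heart-rate split."""
        f = self.fraction
        if self.layer_composition == "lcn_plus":
            return int(round(self.lcn_per_level * f / (1.0 - f)))
        return int(round(self.lcn_per_level * f))

    def lcn_count(self, level: Level) -> int:
        if self.layer_composition == "lcn_plus":
            return self.lcn_per_level
        return self.lcn_per_level - self.transducer_count(level)

    def demand_heartrate_split(self, level: Level) -> tuple[int, int]:
        """Largest-remainder split of a level's transducers into (D, H) receivers.

        Remainder ties go to the demand role at the central and intrathoracic
        levels and to the heart-rate role at the cardiac level, mirroring the
        level-centric anatomy (demand-rich at the top, heart-rate-rich at the
        bottom).
        """
        d_w, h_w = DEMAND_TO_HEARTRATE_RATIO[level]
        tie = (0, 1) if level != Level.CARDIAC else (1, 0)
        d, h = largest_remainder(self.transducer_count(level), [d_w, h_w], tie)
        return d, h


@dataclass
class Network:
    """A built network: per-neuron attribute arrays plus a synapse table.

    Neuron arrays all have length ``n_neurons``; synapse arrays all have length
    ``n_synapses``.  Synapses are stored pre -> post with non-negative weights.
    """

    config: NetworkConfig
    level: np.ndarray          # int8, Level codes
    role: np.ndarray           # int8, Role codes
    branch: np.ndarray         # int8, Branch codes
    demand_sensitivity: np.ndarray   # float64, >= 0
    feedback_sensitivity: np.ndarray
    bias: np.ndarray
    vitality: np.ndarray       # int8, Vitality codes (all ALIVE at build time)
    pre: np.ndarray            # int64 synapse source ids
    post: np.ndarray           # int64 synapse target ids
    weight: np.ndarray         # float64, in [0, weight_init_max] at build time
    klass: np.ndarray          # int8, SynapseClass codes
    sensitivity_means: dict = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return self.level.shape[0]

    @property
    def n_synapses(self) -> int:
        return self.pre.shape[0]

    def ascending_out_counts(self) -> np.ndarray:
        """Number of outgoing ascending synapses per neuron (exhaustive scan)."""
        counts = np.zeros(self.n_neurons, dtype=np.int64)
        asc = self.klass == SynapseClass.ASCENDING
        np.add.at(counts, self.pre[asc], 1)
        return counts

    def validate(self) -> None:
        """Check the structural invariants; raises AssertionError on violation."""
        assert self.ascending_out_counts().max(initial=0) <= 1, \
            "a neuron has more than one ascending synapse"
        lv_pre = self.level[self.pre]
        lv_post = self.level[self.post]
        kl = self.klass
        assert np.all(lv_pre[kl == SynapseClass.PEER] ==
                      lv_post[kl == SynapseClass.PEER])
        assert np.all(lv_post[kl == SynapseClass.DESCENDING] ==
                      lv_pre[kl == SynapseClass.DESCENDING] + 1)
        assert np.all(lv_post[kl == SynapseClass.ASCENDING] ==
                      lv_pre[kl == SynapseClass.ASCENDING] - 1)
        assert np.all(self.weight >= 0)
        # transducer sensitivity pattern
        d = self.role == Role.DEMAND_TRANSDUCER
        h = self.role == Role.HEARTRATE_TRANSDUCER
        other = ~(d | h)
        assert np.all(self.demand_sensitivity[d] > 0)
        assert np.all(self.feedback_sensitivity[d] == 0)
        assert np.all(self.feedback_sensitivity[h] > 0)
        assert np.all(self.demand_sensitivity[h] == 0)
        assert np.all(self.demand_sensitivity[other] == 0)
        assert np.all(self.feedback_sensitivity[other] == 0)
        # parasympathetic branch only at the cardiac level
        pb = self.branch == Branch.PARASYMPATHETIC
        assert np.all(self.level[pb] == Level.CARDIAC)

    # ------------------------------------------------------------------ I/O

    def to_json(self) -> str:
        """Serialize the full network to a JSON document (neurons + synapses)."""
        doc = {
            "config": _config_to_dict(self.config),
            "sensitivity_means": {str(k): v for k, v in
                                  self.sensitivity_means.items()},
            "neurons": {
                "level": self.level.tolist(),
                "role": self.role.tolist(),
                "branch": self.branch.tolist(),
                "demand_sensitivity": self.demand_sensitivity.tolist(),
                "feedback_sensitivity": self.feedback_sensitivity.tolist(),
                "bias": self.bias.tolist(),
                "vitality": self.vitality.tolist(),
            },
            "synapses": {
                "pre": self.pre.tolist(),
                "post": self.post.tolist(),
                "weight": self.weight.tolist(),
                "klass": self.klass.tolist(),
            },
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "Network":
        doc = json.loads(text)
        nr = doc["neurons"]
        sy = doc["synapses"]
        return cls(
            config=NetworkConfig(**doc["config"]),
            level=np.array(nr["level"], dtype=np.int8),
            role=np.array(nr["role"], dtype=np.int8),
            branch=np.array(nr["branch"], dtype=np.int8),
            demand_sensitivity=np.array(nr["demand_sensitivity"]),
            feedback_sensitivity=np.array(nr["feedback_sensitivity"]),
            bias=np.array(nr["bias"]),
            vitality=np.array(nr["vitality"], dtype=np.int8),
            pre=np.array(sy["pre"], dtype=np.int64),
            post=np.array(sy["post"], dtype=np.int64),
            weight=np.array(sy["weight"]),
            klass=np.array(sy["klass"], dtype=np.int8),
            sensitivity_means={int(k): v for k, v in
                               doc.get("sensitivity_means", {}).items()},
        )


def _config_to_dict(cfg: NetworkConfig) -> dict:
    from dataclasses import asdict

    return asdict(cfg)


def _adjacent_quotas(ratio: float, out_degree: int,
                     sizes: dict[Level, int]) -> dict[Level, tuple[float, float]]:
    """Expected (descending, ascending) synapse counts per neuron at each level.

    The per-synapse adjacent share is 1/(1+ratio), so the network-wide target
    is ``out_degree * N / (1 + ratio)`` adjacent synapses.  The cardiac level
    can only ascend and is capped at one ascending synapse per neuron; its
    shortfall against the uniform quota is redistributed per neuron over the
    two upper levels so that the expected global peer:adjacent count ratio
    equals ``ratio`` exactly.  Middle-level ascending output is likewise
    capped at one per neuron, the rest of its quota descending.
    """
    n_total = sum(sizes.values())
    target_adjacent = out_degree * n_total / (1.0 + ratio)
    q_uniform = out_degree / (1.0 + ratio)
    asc_cardiac = min(q_uniform, 1.0)
    upper = sizes[Level.CENTRAL] + sizes[Level.INTRATHORACIC]
    q_top = (target_adjacent - asc_cardiac * sizes[Level.CARDIAC]) / upper
    asc_middle = min(q_top / 2.0, 1.0)
    return {
        Level.CENTRAL: (q_top, 0.0),
        Level.INTRATHORACIC: (q_top - asc_middle, asc_middle),
        Level.CARDIAC: (0.0, asc_cardiac),
    }


def _realize_counts(rng: np.random.Generator, quota: float, n: int) -> np.ndarray:
    """Integer counts per neuron with mean ``quota`` (floor + Bernoulli remainder)."""
    base = int(np.floor(quota))
    frac = quota - base
    counts = np.full(n, base, dtype=np.int64)
    if frac > 0:
        counts += rng.random(n) < frac
    return counts


def build_network(config: NetworkConfig) -> Network:
    """Build the hierarchy reproducibly from ``config.seed``.

    Identical configurations and seeds yield bitwise-identical networks: all
    randomness flows through one PCG64 generator consumed in a fixed order.
    """
    config.validate()
    rng = np.random.Generator(np.random.PCG64(config.seed))

    levels, roles, branches = [], [], []
    for lv in (Level.CENTRAL, Level.INTRATHORACIC, Level.CARDIAC):
        n_lcn = config.lcn_count(lv)
        n_d, n_h = config.demand_heartrate_split(lv)
        levels += [lv] * (n_lcn + n_d + n_h)
        roles += [Role.LCN] * n_lcn
        roles += [Role.DEMAND_TRANSDUCER] * n_d
        roles += [Role.HEARTRATE_TRANSDUCER] * n_h
        branches += [Branch.SYMPATHETIC] * (n_lcn + n_d + n_h)
    # networked parasympathetic pool: cardiac level only; its transducers are
    # heart-rate receivers (vagal afferent pathway), share set by diversity
    n_pool = config.parasym_pool_size
    n_pool_h = largest_remainder(n_pool, [config.fraction,
                                          1.0 - config.fraction])[0]
    levels += [Level.CARDIAC] * n_pool
    roles += [Role.HEARTRATE_TRANSDUCER] * n_pool_h
    roles += [Role.PARASYM_EFFERENT] * (n_pool - n_pool_h)
    branches += [Branch.PARASYMPATHETIC] * n_pool

    level = np.array(levels, dtype=np.int8)
    role = np.array(roles, dtype=np.int8)
    branch = np.array(branches, dtype=np.int8)
    n = level.shape[0]

    lo, hi = 1.0 - config.sensitivity_spread, 1.0 + config.sensitivity_spread
    demand_sens = np.zeros(n)
    feedback_sens = np.zeros(n)
    d_mask = role == Role.DEMAND_TRANSDUCER
    h_mask = role == Role.HEARTRATE_TRANSDUCER
    demand_sens[d_mask] = (config.demand_sensitivity_scale *
                           rng.uniform(lo, hi, int(d_mask.sum())))
    feedback_sens[h_mask] = (config.feedback_sensitivity_scale *
                             rng.uniform(lo, hi, int(h_mask.sum())))

    bias = np.empty(n)
    bias[role == Role.LCN] = config.bias_lcn
    bias[d_mask] = config.bias_demand
    bias[h_mask] = config.bias_heartrate
    bias[role == Role.PARASYM_EFFERENT] = config.bias_parasym

    # population means stored for aftermath re-initialization
    sensitivity_means = {
        int(Role.DEMAND_TRANSDUCER): float(demand_sens[d_mask].mean())
        if d_mask.any() else 0.0,
        int(Role.HEARTRATE_TRANSDUCER): float(feedback_sens[h_mask].mean())
        if h_mask.any() else 0.0,
    }

    # ---------------------------------------------------------------- wiring
    # synapse emitters are the networked (sympathetic-branch) populations;
    # parasympathetic pool neurons are postganglionic efferents whose output
    # goes to the target organ, so they receive synapses but emit none
    level_ids = {lv: np.flatnonzero(level == lv) for lv in Level}
    emitter_ids = {lv: np.flatnonzero((level == lv) &
                                      (branch == Branch.SYMPATHETIC))
                   for lv in Level}
    quotas = _adjacent_quotas(config.ratio, config.out_degree,
                              {lv: ids.shape[0]
                               for lv, ids in emitter_ids.items()})

    pre_parts, post_parts, klass_parts = [], [], []
    for lv in (Level.CENTRAL, Level.INTRATHORACIC, Level.CARDIAC):
        ids = emitter_ids[lv]
        m = ids.shape[0]
        q_desc, q_asc = quotas[lv]
        n_desc = _realize_counts(rng, q_desc, m)
        n_asc = _realize_counts(rng, q_asc, m)
        n_peer = config.out_degree - n_desc - n_asc
        if m > 0 and n_peer.min() < 1:
            raise ValueError(
                "peer_to_adjacent_ratio cannot be realized: adjacent quota "
                "leaves no peer synapses at out_degree "
                f"{config.out_degree}")

        # peer targets: uniform over the whole level (either branch),
        # self-loops excluded
        targets = level_ids[lv]
        total_peer = int(n_peer.sum())
        src = np.repeat(ids, n_peer)
        tgt = targets[rng.integers(0, targets.shape[0], total_peer)]
        self_hit = tgt == src
        while self_hit.any():
            tgt[self_hit] = targets[rng.integers(0, targets.shape[0],
                                                 int(self_hit.sum()))]
            self_hit = tgt == src
        pre_parts.append(src)
        post_parts.append(tgt)
        klass_parts.append(np.full(total_peer, SynapseClass.PEER, dtype=np.int8))

        if lv != Level.CARDIAC:
            below = level_ids[Level(lv + 1)]
            total_desc = int(n_desc.sum())
            src = np.repeat(ids, n_desc)
            tgt = below[rng.integers(0, below.shape[0], total_desc)]
            pre_parts.append(src)
            post_parts.append(tgt)
            klass_parts.append(np.full(total_desc, SynapseClass.DESCENDING,
                                       dtype=np.int8))
        if lv != Level.CENTRAL:
            above = level_ids[Level(lv - 1)]
            total_asc = int(n_asc.sum())
            src = np.repeat(ids, n_asc)
            tgt = above[rng.integers(0, above.shape[0], total_asc)]
            pre_parts.append(src)
            post_parts.append(tgt)
            klass_parts.append(np.full(total_asc, SynapseClass.ASCENDING,
                                       dtype=np.int8))

    pre = np.concatenate(pre_parts)
    post = np.concatenate(post_parts)
    klass = np.concatenate(klass_parts)
    weight = rng.uniform(0.0, config.weight_init_max, pre.shape[0])

    return Network(
        config=config,
        level=level,
        role=role,
        branch=branch,
        demand_sensitivity=demand_sens,
        feedback_sensitivity=feedback_sens,
        bias=bias,
        vitality=np.full(n, Vitality.ALIVE, dtype=np.int8),
        pre=pre.astype(np.int64),
        post=post.astype(np.int64),
        weight=weight,
        klass=klass,
        sensitivity_means=sensitivity_means,
    )


def network_census(network: Network,
                   vitality: np.ndarray | None = None) -> dict[str, pd.DataFrame]:
    """Count neurons by (level, role, branch, vitality) and synapses by class.

    A pure function of the network (and, optionally, of an externally evolved
    vitality array); never mutates its inputs.  Returns ``{"neurons": df,
    "synapses": df}`` with a ``count`` column each.
    """
    vit = network.vitality if vitality is None else vitality
    if network.n_neurons == 0:
        neurons = pd.DataFrame(
            columns=["level", "role", "branch", "vitality", "count"])
    else:
        df = pd.DataFrame({
            "level": pd.Categorical.from_codes(network.level,
                                               [lv.name for lv in Level]),
            "role": pd.Categorical.from_codes(network.role,
                                              [r.name for r in Role]),
            "branch": pd.Categorical.from_codes(network.branch,
                                                [b.name for b in Branch]),
            "vitality": pd.Categorical.from_codes(vit,
                                                  [v.name for v in Vitality]),
        })
        neurons = (df.value_counts(sort=False).rename("count").reset_index())
        neurons = neurons[neurons["count"] > 0].reset_index(drop=True)
    if network.n_synapses == 0:
        synapses = pd.DataFrame(columns=["klass", "count"])
    else:
        ks = pd.Categorical.from_codes(network.klass,
                                       [k.name for k in SynapseClass])
        synapses = (pd.Series(ks).value_counts(sort=False)
                    .rename_axis("klass").rename("count").reset_index())
    return {"neurons": neurons, "synapses": synapses}


def peer_adjacent_ratio(network: Network) -> float:
    """Network-wide peer : adjacent-layer synapse count ratio."""
    peer = int((network.klass == SynapseClass.PEER).sum())
    adjacent = network.n_synapses - peer
    if adjacent == 0:
        return float("inf")
    return peer / adjacent


def empty_network(config: NetworkConfig | None = None) -> Network:
    """A network with no neurons and no synapses (census identity case)."""
    cfg = config if config is not None else NetworkConfig()
    z = np.zeros(0)
    zi = np.zeros(0, dtype=np.int8)
    zl = np.zeros(0, dtype=np.int64)
    return Network(config=cfg, level=zi, role=zi.copy(), branch=zi.copy(),
                   demand_sensitivity=z, feedback_sensitivity=z.copy(),
                   bias=z.copy(), vitality=zi.copy(), pre=zl, post=zl.copy(),
                   weight=z.copy(), klass=zi.copy())
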