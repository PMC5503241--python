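"""Shared fixtures: miniature networks and scenarios sized for fast tests.

The reduced configurations keep every structural fraction of the full model
(transducer shares, demand:heart-rate ratios, wiring ratios, affected
fractions) while shrinking the populations, so mean-field behaviour carries
over at higher sampling noise.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from cardionet.network import Network, NetworkConfig, build_network
from cardionet.dynamics import NetworkState, PlasticityParams
from cardionet.scenario import ScenarioConfig, run_timeline


SMALL_NET = dict(lcn_per_level=120, parasym_pool_size=160)


@pytest.fixture(scope="session")
def default_network() -> Network:
    """The full-size default (stratified, low diversity) network."""
    return build_network(NetworkConfig(seed=7))


@pytest.fixture()
def small_config() -> NetworkConfig:
    return NetworkConfig(seed=11, **SMALL_NET)


@pytest.fixture()
def small_network(small_config) -> Network:
    return build_network(small_config)


def small_scenario(seed: int = 0, *, diversity: str = "low",
                   connectedness: str = "stratified",
                   t_end: float | None = None,
                   record_stride: int = 4,
                   **pathology_kw) -> ScenarioConfig:
    """A scenario over the canonical timeline with a reduced network."""
    cfg = ScenarioConfig(master_seed=seed, record_stride=record_stride)
    cfg = replace(
        cfg,
        network=replace(cfg.network, diversity=diversity,
                        connectedness=connectedness, **SMALL_NET),
        pathology=replace(cfg.pathology, **pathology_kw)
        if pathology_kw else cfg.pathology,
    )
    if t_end is not None:
        cfg = replace(cfg, schedule=cfg.schedule.truncated(t_end))
    return cfg


@pytest.fixture(scope="session")
def small_angina_record():
    """One full-timeline small-network angina run, shared across tests."""
    cfg = ScenarioConfig(master_seed=3, record_stride=4)
    cfg = replace(cfg, network=replace(cfg.network, **SMALL_NET))
    return run_timeline(cfg)


def make_line_network(weights: list[tuple[int, int, float]], n: int,
                      *, bias: float = 0.0, level=None, role=None,
                      branch=None, demand_sens=None, feedback_sens=None,
                      ) -> Network:
    """Hand-build a tiny network with explicit synapses for unit tests."""
    from cardionet.network import Branch, Level, Role, SynapseClass, Vitality

    level = np.full(n, Level.CARDIAC, dtype=np.int8) if level is None \
        else np.asarray(level, dtype=np.int8)
    role = np.full(n, Role.LCN, dtype=np.int8) if role is None \
        else np.asarray(role, dtype=np.int8)
    branch = np.full(n, Branch.SYMPATHETIC, dtype=np.int8) if branch is None \
        else np.asarray(branch, dtype=np.int8)
    ds = np.zeros(n) if demand_sens is None else np.asarray(demand_sens, float)
    fs = np.zeros(n) if feedback_sens is None \
        else np.asarray(feedback_sens, float)
    pre = np.array([p for p, _, _ in weights], dtype=np.int64)
    post = np.array([q for _, q, _ in weights], dtype=np.int64)
    w = np.array([x for _, _, x in weights], dtype=float)
    lv_pre, lv_post = level[pre] if len(pre) else pre, \
        level[post] if len(post) else post
    klass = np.where(lv_pre == lv_post, 0,
                     np.where(lv_post > lv_pre, 1, 2)).astype(np.int8)
    return Network(
        config=NetworkConfig(),
        level=level, role=role, branch=branch,
        demand_sensitivity=ds, feedback_sensitivity=fs,
        bias=np.full(n, float(bias)),
        vitality=np.zeros(n, dtype=np.int8),
        pre=pre, post=post, weight=w, klass=klass,
        sensitivity_means={1: float(ds[ds > 0].mean()) if (ds > 0).any() else 0.0,
                           2: float(fs[fs > 0].mean()) if (fs > 0).any() else 0.0},
    )


def plain_state(network: Network, **plasticity_kw) -> NetworkState:
    """State with plasticity switched off unless requested."""
    defaults = dict(hebb_rate=0.0, homeo_rate=0.0, scaling_rate=0.0)
    defaults.update(plasticity_kw)
    return NetworkState(network, PlasticityParams(**defaults))
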