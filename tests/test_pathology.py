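"""Tests of affected-neuron selection, death/freeze, derangement, aftermath."""

from dataclasses import replace

import numpy as np
import pytest

from cardionet.network import (
    Level,
    NetworkConfig,
    Role,
    Vitality,
    build_network,
)
from cardionet.dynamics import NetworkState, PlasticityParams, advance
from cardionet.pathology import (
    DerangementState,
    EpisodeSchedule,
    PathologyConfig,
    apply_derangement,
    apply_onset,
    apply_recovery,
    reinitialize_aftermath,
    select_affected,
)
from cardionet.scenario import ScenarioConfig, run_timeline

from conftest import SMALL_NET, small_scenario


@pytest.fixture()
def state(default_network):
    return NetworkState(default_network,
                        PlasticityParams(hebb_rate=0.0, homeo_rate=0.0))


class TestSelectAffected:
    def test_zero_fractions_select_nothing(self, state):
        cfg = PathologyConfig(affected_fraction_by_level={
            "central": 0.0, "intrathoracic": 0.0, "cardiac": 0.0})
        out = select_affected(state, cfg, 1)
        assert out["lcn"].size == 0 and out["transducer"].size == 0

    def test_cardiac_lcn_draw_is_floor_of_fraction(self, state):
        cfg = PathologyConfig(transducers_affected=False, selection_seed=5)
        out = select_affected(state, cfg, 1)
        net = state.network
        # local-circuit pool at the cardiac level: 600 sympathetic LCN plus
        # the non-transducing parasympathetic pool cells
        pool = int(((net.level == Level.CARDIAC)
                    & np.isin(net.role, [Role.LCN, Role.PARASYM_EFFERENT]))
                   .sum())
        cardiac = out["lcn"][net.level[out["lcn"]] == Level.CARDIAC]
        assert cardiac.size == int(np.floor(0.15 * pool))
        assert out["transducer"].size == 0

    def test_survivor_only_draw_after_deaths(self, state):
        cfg = PathologyConfig(mode="infarction", selection_seed=9)
        first = select_affected(state, cfg, 1)
        apply_onset(state, first, cfg, t=2500.0)
        dead = set(np.concatenate([first["lcn"], first["transducer"]]))
        second = select_affected(state, cfg, 2)
        drawn = set(np.concatenate([second["lcn"], second["transducer"]]))
        assert not drawn & dead
        net = state.network
        lcn_like = np.isin(net.role, [Role.LCN, Role.PARASYM_EFFERENT])
        alive_pool = int(((net.level == Level.CARDIAC) & lcn_like
                          & (state.vitality == Vitality.ALIVE)).sum())
        cardiac_drawn = second["lcn"][net.level[second["lcn"]] == Level.CARDIAC]
        assert cardiac_drawn.size == int(np.floor(0.15 * alive_pool))

    def test_reproducible_from_selection_seed(self, state):
        cfg = PathologyConfig(selection_seed=123)
        a = select_affected(state, cfg, 2)
        b = select_affected(state, cfg, 2)
        np.testing.assert_array_equal(a["lcn"], b["lcn"])
        np.testing.assert_array_equal(a["transducer"], b["transducer"])

    def test_fresh_draw_each_episode(self, state):
        cfg = PathologyConfig(selection_seed=123)
        a = select_affected(state, cfg, 1)
        b = select_affected(state, cfg, 2)
        assert not np.array_equal(a["lcn"], b["lcn"])


class TestOnsetAndRecovery:
    def test_infarction_reduces_alive_count_exactly(self, state):
        cfg = PathologyConfig(mode="infarction", selection_seed=2)
        affected = select_affected(state, cfg, 1)
        n_affected = affected["lcn"].size + affected["transducer"].size
        alive_before = int((state.vitality == Vitality.ALIVE).sum())
        apply_onset(state, affected, cfg, t=2500.0)
        alive_after = int((state.vitality == Vitality.ALIVE).sum())
        assert alive_before - alive_after == n_affected
        assert np.all(state.a[affected["lcn"]] == 0.0)

    def test_angina_freezes_and_recovery_thaws(self, state):
        cfg = PathologyConfig(mode="angina", selection_seed=2)
        affected = select_affected(state, cfg, 1)
        apply_onset(state, affected, cfg, t=2500.0)
        assert int((state.vitality == Vitality.FROZEN).sum()) == \
            affected["lcn"].size + affected["transducer"].size
        apply_recovery(state, None, cfg, t=3500.0)
        assert int((state.vitality == Vitality.FROZEN).sum()) == 0
        assert int((state.vitality == Vitality.DEAD).sum()) == 0

    def test_double_onset_at_same_time_rejected(self, state):
        cfg = PathologyConfig(selection_seed=2)
        affected = select_affected(state, cfg, 1)
        applied = set()
        apply_onset(state, affected, cfg, t=2500.0, _applied_onsets=applied)
        with pytest.raises(RuntimeError):
            apply_onset(state, affected, cfg, t=2500.0,
                        _applied_onsets=applied)

    def test_mixed_fates_for_lcn_and_transducers(self, state):
        cfg = PathologyConfig(mode="infarction", lcn_fate="stress",
                              selection_seed=4)
        affected = select_affected(state, cfg, 1)
        apply_onset(state, affected, cfg, t=2500.0)
        assert np.all(state.vitality[affected["lcn"]] == Vitality.FROZEN)
        assert np.all(state.vitality[affected["transducer"]] == Vitality.DEAD)


class TestDerangement:
    def test_compounding_after_completed_episodes(self, state):
        der = DerangementState()
        cfg = PathologyConfig(derangement=True)
        for _ in range(2):
            apply_recovery(state, der, cfg, t=0.0)
        h = state.network.role == Role.HEARTRATE_TRANSDUCER
        np.testing.assert_allclose(
            state.feedback_sens[h] / state.base_feedback_sens[h], 0.75 ** 2)
        apply_recovery(state, der, cfg, t=0.0)
        d = state.network.role == Role.DEMAND_TRANSDUCER
        np.testing.assert_allclose(
            state.demand_sens[d] / state.base_demand_sens[d], 1.25 ** 3)

    def test_linear_ramp_midpoint(self, state):
        der = DerangementState()
        apply_derangement(der, state, t=3000.0, onset=2500.0, recovery=3500.0)
        h = state.network.role == Role.HEARTRATE_TRANSDUCER
        np.testing.assert_allclose(
            state.feedback_sens[h] / state.base_feedback_sens[h],
            1.0 + 0.5 * (0.75 - 1.0))

    def test_step_ramp_applies_full_factor_at_onset(self, state):
        der = DerangementState()
        apply_derangement(der, state, t=2500.0, onset=2500.0, recovery=3500.0,
                          ramp_kind="step")
        h = state.network.role == Role.HEARTRATE_TRANSDUCER
        np.testing.assert_allclose(
            state.feedback_sens[h] / state.base_feedback_sens[h], 0.75)

    def test_disabled_derangement_leaves_sensitivities_bitwise(self):
        cfg = small_scenario(seed=1, t_end=8000.0, derangement=False,
                             mode="angina")
        record, state = run_timeline(cfg, return_state=True)
        assert any(e["event"] == "onset" for e in record.events)
        net = build_network(replace(cfg.network,
                                    seed=cfg.derived_network_seed()))
        assert np.array_equal(state.demand_sens, net.demand_sensitivity)
        assert np.array_equal(state.feedback_sens, net.feedback_sensitivity)

    def test_dead_transducers_not_deranged(self, state):
        cfg = PathologyConfig(mode="infarction", selection_seed=3)
        affected = select_affected(state, cfg, 1)
        apply_onset(state, affected, cfg, t=2500.0)
        before = state.feedback_sens[affected["transducer"]].copy()
        der = DerangementState()
        apply_derangement(der, state, 3000.0, 2500.0, 3500.0)
        np.testing.assert_array_equal(
            state.feedback_sens[affected["transducer"]], before)


class TestAftermathReinit:
    def test_alive_transducers_reset_to_stored_means(self, state):
        der = DerangementState()
        cfg = PathologyConfig(derangement=True)
        for _ in range(3):
            apply_recovery(state, der, cfg, t=0.0)
        reinitialize_aftermath(state, der, t=13000.0)
        net = state.network
        means = net.sensitivity_means
        h = (net.role == Role.HEARTRATE_TRANSDUCER) & \
            (state.vitality == Vitality.ALIVE)
        d = (net.role == Role.DEMAND_TRANSDUCER) & \
            (state.vitality == Vitality.ALIVE)
        assert np.all(state.feedback_sens[h] ==
                      means[int(Role.HEARTRATE_TRANSDUCER)])
        assert np.all(state.demand_sens[d] ==
                      means[int(Role.DEMAND_TRANSDUCER)])
        # ratio of post-reinit mean to pre-pathology mean is exactly 1
        assert state.feedback_sens[h].mean() == pytest.approx(
            means[int(Role.HEARTRATE_TRANSDUCER)])

    def test_dead_neurons_not_resurrected(self, state):
        cfg = PathologyConfig(mode="infarction", selection_seed=1)
        affected = select_affected(state, cfg, 1)
        apply_onset(state, affected, cfg, t=2500.0)
        reinitialize_aftermath(state, None, t=13000.0)
        assert np.all(state.vitality[affected["transducer"]] == Vitality.DEAD)
        assert np.all(state.a[affected["transducer"]] == 0.0)

    def test_missing_means_is_an_error(self, state):
        state.network.sensitivity_means = {}
        with pytest.raises(RuntimeError):
            reinitialize_aftermath(state, None, t=13000.0)


class TestScheduleValidation:
    def test_canonical_defaults_validate(self):
        sched = EpisodeSchedule()
        sched.validate()
        assert sched.onsets == (2500.0, 6000.0, 9500.0)
        assert sched.recoveries == (3500.0, 7000.0, 10500.0)
        assert sched.demands == (4500.0, 8000.0, 11500.0)
        assert sched.aftermath_start == 13000.0 and sched.t_end == 18000.0

    @pytest.mark.parametrize("kw", [
        dict(onsets=(3500.0, 6000.0, 9500.0)),              # I1 >= R1
        dict(demands=(3000.0, 8000.0, 11500.0)),            # D1 before R1
        dict(aftermath_start=19000.0),                      # after run end
        dict(onsets=(2500.0,), recoveries=(3500.0, 7000.0)),  # length mismatch
    ])
    def test_bad_schedules_rejected(self, kw):
        with pytest.raises(ValueError):
            replace(EpisodeSchedule(), **kw).validate()

    def test_truncation_keeps_fitting_subevents(self):
        sched = EpisodeSchedule().truncated(10500.0)
        assert sched.onsets == (2500.0, 6000.0, 9500.0)
        assert sched.demands == (4500.0, 8000.0)
        assert sched.t_end == 10500.0
        sched.validate()


class TestConservationLaws:
    """Population accounting over full (reduced-size) scenario runs."""

    def test_angina_conserves_alive_plus_frozen(self):
        cfg = small_scenario(seed=4, t_end=8000.0, mode="angina")
        record, state = run_timeline(cfg, return_state=True)
        assert int((state.vitality == Vitality.DEAD).sum()) == 0
        assert int((state.vitality == Vitality.FROZEN).sum()) == 0
        # angina never kills: the event log shows freezes and full thaws only
        onsets = [e for e in record.events if e["event"] == "onset"]
        recoveries = [e for e in record.events if e["event"] == "recovery"]
        assert len(onsets) == 2 and len(recoveries) == 2
        for on, rec in zip(onsets, recoveries):
            n_frozen = len(on["lcn_affected"]) + len(on["transducers_affected"])
            assert rec["thawed"] == n_frozen

    def test_infarction_alive_count_drops_exactly_at_onsets(self):
        cfg = small_scenario(seed=4, t_end=8000.0, mode="infarction")
        record = run_timeline(cfg)
        onsets = [e for e in record.events if e["event"] == "onset"]
        assert len(onsets) == 2
        for ev in onsets:
            assert len(ev["lcn_affected"]) > 0
        recoveries = [e for e in record.events if e["event"] == "recovery"]
        assert all(r["thawed"] == 0 for r in recoveries)
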